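"""Core data containers and plain-text I/O.

The package works on two kinds of objects: labelled feature tables
(:class:`LabeledDataset`) holding the eight shape features of candidate lung
ROIs, and binary voxel masks (:class:`ROIVolume`) those features are computed
from.  The nodule class is the minority / positive class and carries label
``+1``; non-nodules carry ``-1``.

Conventions
-----------
* CSV feature tables have the header ``id,label,<feature names...>`` with a
  ``.`` decimal separator.  Accepted label encodings: ``{1, -1}``, ``{1, 0}``
  (0 maps to -1), and the strings ``nodule`` / ``nonnodule``.
* Voxel masks are stored as NIfTI (``.nii``/``.nii.gz``, primary) or NRRD
  (secondary, requires SimpleITK).  In memory the mask array is indexed
  ``(z, y, x)`` — axis 0 walks the slices — and ``spacing`` is stated in the
  same axis order, in mm per voxel.  Values are binarised at 0.5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FEATURE_NAMES",
    "LabeledDataset",
    "ROIVolume",
    "ExperimentConfig",
    "MissingLabelColumnError",
    "NonNumericFeatureError",
    "EmptyDatasetError",
    "InvalidLabelError",
    "read_feature_table",
    "write_feature_table",
    "read_roi_volume",
    "write_roi_volume",
    "load_config",
]

#: Canonical feature-column order: four 2D features then four 3D features.
FEATURE_NAMES: tuple[str, ...] = (
    "circularity",
    "elongation",
    "compactness",
    "moment",
    "surface_area",
    "volume",
    "sphericity",
    "centroid_offset",
)


class MissingLabelColumnError(ValueError):
    """The CSV has no ``label`` column."""


class NonNumericFeatureError(ValueError):
    """A feature cell could not be parsed as a finite number."""


class EmptyDatasetError(ValueError):
    """The file contains a header but no sample rows (or nothing at all)."""


class InvalidLabelError(ValueError):
    """A label value is outside the documented encodings."""


_LABEL_MAP = {
    "1": 1, "+1": 1, "-1": -1, "0": -1,
    "nodule": 1, "nonnodule": -1, "non-nodule": -1,
}


def _map_label(value) -> int:
    if isinstance(value, str):
        key = value.strip().lower()
    elif isinstance(value, (int, np.integer)):
        key = str(int(value))
    elif isinstance(value, (float, np.floating)):
        if not np.isfinite(value) or value != int(value):
            raise InvalidLabelError(f"invalid label value: {value!r}")
        key = str(int(value))
    else:
        raise InvalidLabelError(f"invalid label value: {value!r}")
    if key not in _LABEL_MAP:
        raise InvalidLabelError(f"invalid label value: {value!r}")
    return _LABEL_MAP[key]


@dataclass
class LabeledDataset:
    """A feature matrix with binary labels.

    Parameters
    ----------
    features : (n_samples, n_features) float array
    labels : (n_samples,) int array with values in {+1, -1};
        +1 = nodule (minority/positive), -1 = non-nodule.
    feature_names : ordered feature names, one per column.
    sample_ids : opaque per-row identifiers.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim == 1:
            self.features = self.features.reshape(-1, 1)
        self.labels = np.asarray(self.labels, dtype=int)
        self.feature_names = tuple(self.feature_names)
        if not self.sample_ids:
            self.sample_ids = tuple(f"s{i:05d}" for i in range(len(self.labels)))
        else:
            self.sample_ids = tuple(str(s) for s in self.sample_ids)
        n = self.features.shape[0]
        if len(self.labels) != n or len(self.sample_ids) != n:
            raise ValueError("features, labels and sample_ids disagree on row count")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match feature columns")
        bad = set(np.unique(self.labels)) - {1, -1}
        if bad:
            raise InvalidLabelError(f"labels must be +1/-1, found {sorted(bad)}")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature values must be finite")

    # -- convenience -----------------------------------------------------
    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def minority_mask(self) -> np.ndarray:
        return self.labels == 1

    @property
    def n_minority(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_majority(self) -> int:
        return int(np.sum(self.labels == -1))

    def subset(self, indices: Sequence[int] | np.ndarray) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            self.features[idx],
            self.labels[idx],
            self.feature_names,
            tuple(self.sample_ids[i] for i in idx),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df.insert(0, "label", self.labels)
        df.insert(0, "id", list(self.sample_ids))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LabeledDataset":
        """Build a dataset from a frame with ``label`` and feature columns.

        An ``id`` column, if present, supplies the sample identifiers.
        """
        if "label" not in df.columns:
            raise MissingLabelColumnError("no 'label' column in table")
        if len(df) == 0:
            raise EmptyDatasetError("table contains no sample rows")
        ids = (
            tuple(str(v) for v in df["id"])
            if "id" in df.columns
            else tuple(f"s{i:05d}" for i in range(len(df)))
        )
        labels = np.array([_map_label(v) for v in df["label"]])
        feat_cols = [c for c in df.columns if c not in ("id", "label")]
        if not feat_cols:
            raise NonNumericFeatureError("no feature columns in table")
        try:
            feats = df[feat_cols].astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise NonNumericFeatureError(f"non-numeric feature cell: {exc}") from exc
        if not np.all(np.isfinite(feats)):
            raise NonNumericFeatureError("non-finite feature value in table")
        return cls(feats, labels, tuple(feat_cols), ids)


def read_feature_table(path: str | Path) -> LabeledDataset:
    """Read a feature-table CSV into a :class:`LabeledDataset`.

    Row order is preserved.  Raises :class:`MissingLabelColumnError`,
    :class:`NonNumericFeatureError` or :class:`EmptyDatasetError` on the
    corresponding malformed inputs.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyDatasetError(f"{path} is empty") from exc
    return LabeledDataset.from_dataframe(df)


def write_feature_table(dataset: LabeledDataset, path: str | Path) -> None:
    """Write ``dataset`` as CSV with header ``id,label,<feature names...>``.

    Lossless for finite doubles (round-trip precision ``repr``-exact).
    """
    dataset.to_dataframe().to_csv(path, index=False, float_format="%.17g")


def _write_empty_feature_table(feature_names: Sequence[str], path: str | Path) -> None:
    pd.DataFrame(columns=["id", "label", *feature_names]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ROI volumes
# ---------------------------------------------------------------------------

@dataclass
class ROIVolume:
    """A binary 3D region-of-interest mask.

    ``mask`` is boolean, indexed ``(z, y, x)``; ``spacing`` gives the voxel
    edge lengths in mm in the same axis order.
    """

    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    id: str = "roi"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask) > 0.5
        if self.mask.ndim != 3:
            raise ValueError(f"ROI mask must be 3D, got {self.mask.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


def read_roi_volume(path: str | Path) -> ROIVolume:
    """Read a NIfTI or NRRD volume as a binary ROI mask.

    Voxel spacing is taken from the file header, never guessed.  The
    on-disk (x, y, z) axis order is transposed to the in-memory (z, y, x)
    convention.  Raises ``ValueError`` for non-3D images.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D image, got {data.ndim}D: {path}")
        dx, dy, dz = (float(z) for z in img.header.get_zooms()[:3])
        mask = np.transpose(data, (2, 1, 0))
        return ROIVolume(mask, (dz, dy, dx), id=path.stem.replace(".nii", ""))
    if suffixes.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise ValueError(f"expected a 3D image, got {img.GetDimension()}D: {path}")
        data = sitk.GetArrayFromImage(img)  # already (z, y, x)
        dx, dy, dz = img.GetSpacing()
        return ROIVolume(data, (float(dz), float(dy), float(dx)), id=path.stem)
    raise ValueError(f"unsupported volume format: {path}")


def write_roi_volume(roi: ROIVolume, path: str | Path) -> None:
    """Write an ROI mask as NIfTI, inverse of :func:`read_roi_volume`."""
    import nibabel as nib

    path = Path(path)
    data = np.transpose(roi.mask.astype(np.uint8), (2, 1, 0))
    dz, dy, dx = roi.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Experiment configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Parameters of the four-classifier comparison experiment.

    Defaults mirror the reference protocol: RBF kernel with C = 10, the
    biased SVM deriving C- from the class ratio, SMOTE with N = K = 5, and
    the combined balancer with RU = 2 (one halving round), N = K = 3, over
    ``cv_repeats`` stratified half/half splits.
    """

    c: float = 10.0
    kernel: str = "rbf"
    gamma: float | str = "scale"
    cv_repeats: int = 5
    seed: int = 0
    standardize: bool = True
    resample: str = "auto"          # "auto" or "fixed"
    ru_rounds: int = 1              # RU = 2**ru_rounds
    ru_smote_n: int = 3
    ru_smote_k: int = 3
    smote_n: int = 5
    smote_k: int = 5
    swap_halves: bool = False

    def __post_init__(self) -> None:
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")
        if self.seed is None:
            raise ValueError("seed must be set explicitly")


def load_config(path: str | Path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a flat YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ExperimentConfig(**raw)
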