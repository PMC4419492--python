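"""Seeded generators for imbalanced feature clouds and toy ROI masks.

The reference study's CT-derived dataset is not deposited, so every other
module is exercised on synthetic stand-ins shaped like it:

* :func:`make_gaussian_imbalanced` — two multivariate-normal clusters in
  feature space (minority = +1) with a configurable center separation,
  optionally with *planted boundary-noise points*: majority samples placed
  inside the minority cloud's average radius yet beyond the majority's own
  95th-percentile radius, i.e. satisfying both clauses of the boundary-noise
  detection rule by construction.
* :func:`make_ellipsoid_roi` — voxelised ellipsoids: near-spherical blobs
  with mild surface perturbation for nodules, elongated tubes (long/short
  axis >= 3) for non-nodules, sized within 10–50 px in-plane and 5–13
  slices.
* :func:`make_paperlike_cohort` — 150 nodule + 908 non-nodule masks, the
  study-scale cohort for end-to-end runs.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datasets import FEATURE_NAMES, LabeledDataset, ROIVolume

__all__ = ["GeneratorSpec", "make_gaussian_imbalanced", "make_ellipsoid_roi",
           "make_paperlike_cohort", "PLANTED_NOISE_PREFIX"]

#: sample-id prefix marking planted boundary-noise majority points
PLANTED_NOISE_PREFIX = "majnoise"


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the Gaussian two-cluster generator.

    ``separation`` is the distance between class centers in units of the
    (mean) within-class standard deviation; ``noise_fraction`` of the
    majority count is planted as boundary-noise points inside the minority
    cloud.
    """

    n_min: int
    n_maj: int
    dim: int = 8
    separation: float = 3.0
    minority_scale: float = 1.0
    majority_scale: float = 1.0
    noise_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_min < 1 or self.n_maj < 1:
            raise ValueError("class sizes must be positive")
        if not 0.0 <= self.noise_fraction <= 0.05:
            raise ValueError("noise_fraction must be in [0, 0.05]")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")

    @property
    def n_ratio(self) -> float:
        return self.n_maj / self.n_min


def _feature_names(dim: int) -> tuple[str, ...]:
    return FEATURE_NAMES if dim == 8 else tuple(f"f{i}" for i in range(dim))


def make_gaussian_imbalanced(spec: GeneratorSpec) -> LabeledDataset:
    """Two Gaussian clusters with planted boundary noise.

    The minority cluster sits at the origin, the majority at
    ``separation * mean_scale`` along the first axis.  Planted noise points
    (ids prefixed ``majnoise``) are placed on the far side of the minority
    center, at 50–85 % of the minority cloud's empirical average radius —
    inside the minority cloud and farther from the majority center than its
    95th-percentile radius, so the detection rule flags them.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.dim
    offset = spec.separation * 0.5 * (spec.minority_scale + spec.majority_scale)
    c_min = np.zeros(d)
    c_maj = np.zeros(d)
    c_maj[0] = offset

    x_min = c_min + spec.minority_scale * rng.standard_normal((spec.n_min, d))
    n_noise = round(spec.noise_fraction * spec.n_maj)
    n_base = spec.n_maj - n_noise
    x_maj = c_maj + spec.majority_scale * rng.standard_normal((n_base, d))

    rows = [x_min, x_maj]
    ids = ([f"min{i:05d}" for i in range(spec.n_min)]
           + [f"maj{i:05d}" for i in range(n_base)])
    if n_noise:
        min_center = x_min.mean(axis=0)
        r_min = np.linalg.norm(x_min - min_center, axis=1).mean()
        away = np.zeros(d)
        away[0] = -1.0  # unit vector from majority toward/past minority center
        rho = rng.uniform(0.5, 0.85, size=n_noise) * r_min
        jitter = rng.standard_normal((n_noise, d))
        jitter[:, 0] = 0.0
        norms = np.linalg.norm(jitter, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        jitter = jitter / norms * (0.15 * rho)[:, None]
        planted = min_center + rho[:, None] * away + jitter
        rows.append(planted)
        ids += [f"{PLANTED_NOISE_PREFIX}{i:05d}" for i in range(n_noise)]

    features = np.vstack(rows)
    labels = np.concatenate([np.ones(spec.n_min, dtype=int),
                             -np.ones(spec.n_maj, dtype=int)])
    return LabeledDataset(features, labels, _feature_names(d), tuple(ids))


# ---------------------------------------------------------------------------
# Voxel-mask generators
# ---------------------------------------------------------------------------

def _ellipsoid_mask(semi_axes: tuple[float, float, float],
                    perturb: float, rng: np.random.Generator) -> np.ndarray:
    """Binary (z, y, x) ellipsoid with a smooth radial perturbation."""
    rz, ry, rx = semi_axes
    nz = 2 * math.ceil(rz) + 1
    ny = 2 * math.ceil(ry) + 1
    nx = 2 * math.ceil(rx) + 1
    z, y, x = np.ogrid[:nz, :ny, :nx]
    q = (((z - nz // 2) / rz) ** 2
         + ((y - ny // 2) / ry) ** 2
         + ((x - nx // 2) / rx) ** 2)
    if perturb > 0:
        field = ndimage.gaussian_filter(rng.standard_normal((nz, ny, nx)), sigma=2.0)
        threshold = 1.0 + perturb * field
    else:
        threshold = 1.0
    mask = q <= threshold
    # keep one connected blob; the perturbation can pinch off fragments
    labeled, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
        mask = labeled == (int(np.argmax(sizes)) + 1)
    return mask


def _pad_to_min(mask: np.ndarray, min_shape=(5, 10, 10)) -> np.ndarray:
    pads = []
    for have, want in zip(mask.shape, min_shape):
        extra = max(0, want - have)
        pads.append((extra // 2, extra - extra // 2))
    return np.pad(mask, pads)


def make_ellipsoid_roi(kind: str,
                       spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                       seed: int = 0) -> ROIVolume:
    """A toy nodule or non-nodule ROI mask.

    ``"nodule"``: near-spherical ellipsoid (pairwise axis ratios within
    [0.8, 1.25]) with mild surface perturbation.  ``"nonnodule"``: a
    vessel-like tube, long in-plane axis at least 3x the short axes.  Both
    fit within 50 x 50 px in-plane and 5–13 slices.
    """
    rng = np.random.default_rng(seed)
    if kind == "nodule":
        r0 = rng.uniform(4.6, 5.6)
        rz, ry, rx = (min(r0 * rng.uniform(0.9, 1.11), 5.9) for _ in range(3))
        mask = _ellipsoid_mask((rz, ry, rx), perturb=0.08, rng=rng)
    elif kind == "nonnodule":
        rx = rng.uniform(14.0, 22.0)
        ry = rng.uniform(2.5, 4.0)
        rz = rng.uniform(2.2, 4.5)
        mask = _ellipsoid_mask((rz, ry, rx), perturb=0.05, rng=rng)
    else:
        raise ValueError(f"kind must be 'nodule' or 'nonnodule', got {kind!r}")
    mask = _pad_to_min(mask)
    nz, ny, nx = mask.shape
    if not (5 <= nz <= 13 and 10 <= ny <= 50 and 10 <= nx <= 50):
        raise AssertionError(f"generated mask out of range: {mask.shape}")
    return ROIVolume(mask, spacing, id=f"{kind}_{seed:08d}")


def make_paperlike_cohort(seed: int = 0,
                          n_nodules: int = 150,
                          n_nonnodules: int = 908
                          ) -> tuple[list[ROIVolume], np.ndarray]:
    """A study-scale cohort of ROI masks: 150 nodules + 908 non-nodules.

    Returns the volumes (nodules first) and the matching {+1, -1} labels.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(n_nodules + n_nonnodules)]
    volumes = [make_ellipsoid_roi("nodule", seed=s)
               for s in child_seeds[:n_nodules]]
    volumes += [make_ellipsoid_roi("nonnodule", seed=s)
                for s in child_seeds[n_nodules:]]
    labels = np.concatenate([np.ones(n_nodules, dtype=int),
                             -np.ones(n_nonnodules, dtype=int)])
    return volumes, labels
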