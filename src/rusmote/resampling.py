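"""Boundary-noise-aware undersampling + SMOTE: the combined class balancer.

The balancer reshapes an imbalanced training set in four steps:

1. **Class geometry** — per-class centers (arithmetic means) and average
   radii (mean Euclidean distance of class members to their own center).
2. **Boundary-noise removal** — majority samples that are simultaneously in
   the top 5 % of distances from the majority center *and* closer to the
   minority center than the minority's average radius are deleted: they sit
   inside the minority cloud and drag the separating hyperplane into it.
3. **Random undersampling (RU)** — the surviving majority samples are halved
   ``ru_rounds`` times (rate RU = 2**ru_rounds) by ordered decimation: sort
   by distance to the majority center, keep every second sample.  Like
   dyadic decimation of an image, this thins the class while preserving its
   radial distribution.
4. **SMOTE oversampling** — each minority sample spawns ``amplification - 1``
   synthetic points by linear interpolation toward one of its K nearest
   minority neighbours: ``x_s = x_i + delta * (x_t - x_i)``, delta ~ U[0,1].

Distances in steps 1–4 are computed on z-scored features when
``standardize=True`` (the default): the eight shape features span orders of
magnitude and both the geometry rule and KNN are scale-sensitive.  Output
feature values stay on the original scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .datasets import LabeledDataset

__all__ = [
    "ClassGeometry",
    "ResampleParams",
    "SyntheticProvenance",
    "BalanceReport",
    "compute_class_geometry",
    "detect_boundary_noise",
    "random_undersample",
    "smote_oversample",
    "select_balance_parameters",
    "balance",
    "oversample_minority",
]

BOUNDARY_FRACTION = 0.05  # top-5% distance rule for the boundary set


@dataclass(frozen=True)
class ClassGeometry:
    """Per-class centers and average radii (Euclidean metric)."""

    center_maj: np.ndarray
    center_min: np.ndarray
    r_ave_maj: float
    r_ave_min: float
    n_maj: int
    n_min: int


@dataclass(frozen=True)
class ResampleParams:
    """Balancer parameters.

    ``ru_rounds`` halving passes give an undersampling rate RU = 2**ru_rounds;
    ``amplification`` N multiplies the minority count (total after SMOTE is
    N * n_min); ``k_neighbors`` is SMOTE's K.
    """

    ru_rounds: int = 1
    k_neighbors: int = 3
    amplification: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ru_rounds < 0:
            raise ValueError("ru_rounds must be >= 0")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.amplification < 1:
            raise ValueError("amplification must be >= 1")

    @property
    def ru(self) -> int:
        return 2 ** self.ru_rounds


@dataclass(frozen=True)
class SyntheticProvenance:
    """Records how each synthetic minority sample was built.

    For synthetic row ``j``: base sample ``base_index[j]``, chosen neighbour
    ``neighbor_index[j]`` (both indices into the minority matrix passed to
    SMOTE) and interpolation weight ``delta[j]`` in [0, 1].
    """

    base_index: np.ndarray
    neighbor_index: np.ndarray
    delta: np.ndarray

    def __len__(self) -> int:
        return len(self.delta)


@dataclass(frozen=True)
class BalanceReport:
    """Side information from a :func:`balance` run."""

    params: ResampleParams
    noise_indices: tuple[int, ...]          # row indices removed as boundary noise
    kept_majority_indices: tuple[int, ...]  # row indices surviving RU
    provenance: SyntheticProvenance
    minority_indices: tuple[int, ...]       # original minority row order


def compute_class_geometry(dataset: LabeledDataset) -> ClassGeometry:
    """Centers and average radii of the two classes.

    The center is the arithmetic mean of the class's feature rows; the
    average radius is the mean Euclidean distance of class members to their
    own center.
    """
    x_min = dataset.features[dataset.labels == 1]
    x_maj = dataset.features[dataset.labels == -1]
    if len(x_min) == 0 or len(x_maj) == 0:
        raise ValueError("both classes must be present to compute geometry")
    center_min = x_min.mean(axis=0)
    center_maj = x_maj.mean(axis=0)
    r_min = float(np.linalg.norm(x_min - center_min, axis=1).mean())
    r_maj = float(np.linalg.norm(x_maj - center_maj, axis=1).mean())
    return ClassGeometry(center_maj, center_min, r_maj, r_min,
                         n_maj=len(x_maj), n_min=len(x_min))


def detect_boundary_noise(dataset: LabeledDataset,
                          geometry: ClassGeometry | None = None) -> list[int]:
    """Indices of majority rows flagged as boundary noise.

    A majority sample is noise when it lies in the top
    ``ceil(0.05 * n_maj)`` of distances from the majority center (the
    *boundary set*, descending sort with ties broken by original index) and
    its distance to the minority center is below the minority's average
    radius.  Only majority indices are ever returned.
    """
    if geometry is None:
        geometry = compute_class_geometry(dataset)
    maj_rows = np.flatnonzero(dataset.labels == -1)
    x_maj = dataset.features[maj_rows]
    d_maj = np.linalg.norm(x_maj - geometry.center_maj, axis=1)
    n_boundary = math.ceil(BOUNDARY_FRACTION * len(maj_rows))
    # stable sort on (-distance, original index)
    order = np.lexsort((np.arange(len(d_maj)), -d_maj))
    boundary = order[:n_boundary]
    d_maj_min = np.linalg.norm(x_maj[boundary] - geometry.center_min, axis=1)
    noisy = boundary[d_maj_min < geometry.r_ave_min]
    return sorted(int(maj_rows[i]) for i in noisy)


def _undersample_order(samples: np.ndarray) -> np.ndarray:
    """Decimation order: ascending distance to the sample mean, ties by index."""
    center = samples.mean(axis=0)
    d = np.linalg.norm(samples - center, axis=1)
    return np.lexsort((np.arange(len(d)), d))


def _undersample_indices(samples: np.ndarray, ru_rounds: int) -> np.ndarray:
    kept = np.arange(len(samples))
    for _ in range(ru_rounds):
        if len(kept) <= 1:
            break
        order = _undersample_order(samples[kept])
        kept = np.sort(kept[order[::2]])
    return kept


def random_undersample(samples: np.ndarray, ru_rounds: int,
                       seed: int | None = None) -> np.ndarray:
    """Halve ``samples`` ``ru_rounds`` times by ordered decimation.

    Each pass sorts the current set by distance to its mean (ties broken by
    index) and keeps one sample of every adjacent pair — the first — so a
    pass maps m samples to ceil(m / 2) and the radial distribution is
    preserved.  The procedure is deterministic; ``seed`` is accepted for
    interface symmetry with the stochastic resamplers and is unused.
    """
    samples = np.asarray(samples, dtype=float)
    if ru_rounds < 0:
        raise ValueError("ru_rounds must be >= 0")
    return samples[_undersample_indices(samples, ru_rounds)]


def smote_oversample(minority: np.ndarray, k_neighbors: int,
                     amplification: int, seed: int | None = 0
                     ) -> tuple[np.ndarray, SyntheticProvenance]:
    """SMOTE: oversample the minority class by segment interpolation.

    Returns all original rows followed by ``(amplification - 1) * n_min``
    synthetic rows.  Each synthetic row is ``x_i + delta * (x_t - x_i)``
    where ``x_t`` is drawn uniformly among the ``k_neighbors`` Euclidean
    nearest minority neighbours of ``x_i`` (self excluded, with replacement
    across a base point's synthetics) and ``delta ~ U[0, 1]``.
    """
    minority = np.asarray(minority, dtype=float)
    n_min = len(minority)
    if n_min < 2:
        raise ValueError("SMOTE requires at least 2 minority samples")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if amplification < 1:
        raise ValueError("amplification must be >= 1")
    k = k_neighbors
    if k > n_min - 1:
        warnings.warn(
            f"k_neighbors={k} exceeds n_min-1={n_min - 1}; using {n_min - 1}",
            stacklevel=2)
        k = n_min - 1

    rng = np.random.default_rng(seed)
    n_syn = (amplification - 1) * n_min
    if n_syn == 0:
        empty = np.empty(0, dtype=int)
        return minority.copy(), SyntheticProvenance(empty, empty, np.empty(0))

    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    neigh = nn.kneighbors(minority, return_distance=False)[:, 1:]  # drop self

    base = np.repeat(np.arange(n_min), amplification - 1)
    pick = rng.integers(0, k, size=n_syn)
    neighbor = neigh[base, pick]
    delta = rng.uniform(0.0, 1.0, size=n_syn)
    synthetic = minority[base] + delta[:, None] * (minority[neighbor] - minority[base])
    prov = SyntheticProvenance(base, neighbor, delta)
    return np.vstack([minority, synthetic]), prov


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def select_balance_parameters(n_maj: int, n_min: int) -> ResampleParams:
    """Choose (RU, K, N) from the class ratio N_ratio = n_maj / n_min.

    The undersampling rate and amplification should shrink and grow the two
    classes toward each other without over-adjusting either side, under the
    constraints RU >= 2 and K in [3, 6].  The deterministic rule

    * ``ru_rounds = max(1, floor(log2(sqrt(N_ratio))))``
    * ``N = clamp(round(N_ratio / 2**ru_rounds), 1, 6)``
    * ``K = clamp(N, 3, 6)``

    reproduces the reference settings: ratio 6 -> (RU=2, K=3),
    ratio 10 -> (RU=2, K=5), ratio 20 -> (RU=4, K=5), and keeps the
    post-balance class ratio within [1/2, 2] for any N_ratio <= 20 (at
    mildly imbalanced inputs the amplification drops below the K range
    rather than overshooting the minority).
    """
    if n_min < 2:
        raise ValueError("need at least 2 minority samples")
    if n_maj < n_min:
        raise ValueError("expected n_maj >= n_min")
    n_ratio = n_maj / n_min
    ru_rounds = max(1, int(math.floor(math.log2(math.sqrt(n_ratio)))))
    n = min(6, max(1, _round_half_away(n_ratio / 2 ** ru_rounds)))
    k = min(6, max(3, n))
    return ResampleParams(ru_rounds=ru_rounds, k_neighbors=k, amplification=n)


def _standardizer(features: np.ndarray) -> np.ndarray:
    mean = features.mean(axis=0)
    scale = features.std(axis=0)
    scale[scale == 0] = 1.0
    return (features - mean) / scale


def balance(dataset: LabeledDataset,
            params: ResampleParams | str = "auto",
            seed: int = 0,
            standardize: bool = True,
            return_report: bool = False):
    """Run the combined balancer on an imbalanced dataset.

    Pipeline order: class geometry -> boundary-noise removal -> random
    undersampling of the remaining majority -> SMOTE oversampling of the
    minority.  With ``params="auto"`` the parameters come from
    :func:`select_balance_parameters` applied to the input class counts.

    Distances (geometry, noise rule, decimation order, SMOTE neighbours)
    use z-scored features when ``standardize`` is true; output rows are on
    the original feature scale.  Deterministic given (dataset, params, seed).

    Returns the balanced :class:`~rusmote.datasets.LabeledDataset`, plus a
    :class:`BalanceReport` when ``return_report`` is true.
    """
    if isinstance(params, str):
        if params != "auto":
            raise ValueError(f"params must be ResampleParams or 'auto', got {params!r}")
        params = select_balance_parameters(dataset.n_majority, dataset.n_minority)
    if params.seed is not None:
        seed = params.seed
    ss = np.random.SeedSequence(seed)
    _, smote_seed = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2))

    X = dataset.features
    Z = _standardizer(X) if standardize else X
    zds = LabeledDataset(Z, dataset.labels, dataset.feature_names, dataset.sample_ids)

    geometry = compute_class_geometry(zds)
    noise = detect_boundary_noise(zds, geometry)

    maj_rows = np.flatnonzero(dataset.labels == -1)
    min_rows = np.flatnonzero(dataset.labels == 1)
    kept_maj = np.array([i for i in maj_rows if i not in set(noise)], dtype=int)
    kept_maj = kept_maj[_undersample_indices(Z[kept_maj], params.ru_rounds)]

    # neighbours found in standardized space; interpolation replayed on the
    # original scale (the segment map is affine-equivariant)
    _, prov = smote_oversample(Z[min_rows], params.k_neighbors,
                               params.amplification, seed=smote_seed)
    X_min = X[min_rows]
    synthetic = (X_min[prov.base_index]
                 + prov.delta[:, None] * (X_min[prov.neighbor_index]
                                          - X_min[prov.base_index]))

    features = np.vstack([X_min, synthetic, X[kept_maj]])
    labels = np.concatenate([
        np.ones(len(min_rows) + len(prov), dtype=int),
        -np.ones(len(kept_maj), dtype=int),
    ])
    ids = (
        [dataset.sample_ids[i] for i in min_rows]
        + [f"syn{j:05d}" for j in range(len(prov))]
        + [dataset.sample_ids[i] for i in kept_maj]
    )
    out = LabeledDataset(features, labels, dataset.feature_names, tuple(ids))
    if return_report:
        report = BalanceReport(
            params=replace(params, seed=seed),
            noise_indices=tuple(noise),
            kept_majority_indices=tuple(int(i) for i in kept_maj),
            provenance=prov,
            minority_indices=tuple(int(i) for i in min_rows),
        )
        return out, report
    return out


def oversample_minority(dataset: LabeledDataset, amplification: int,
                        k_neighbors: int, seed: int = 0,
                        standardize: bool = True) -> LabeledDataset:
    """SMOTE-only balancing: oversample the minority, keep the majority.

    Neighbour search runs in z-scored space when ``standardize`` is true;
    synthetic rows are produced on the original feature scale.
    """
    X = dataset.features
    Z = _standardizer(X) if standardize else X
    min_rows = np.flatnonzero(dataset.labels == 1)
    maj_rows = np.flatnonzero(dataset.labels == -1)
    _, prov = smote_oversample(Z[min_rows], k_neighbors, amplification, seed=seed)
    X_min = X[min_rows]
    synthetic = (X_min[prov.base_index]
                 + prov.delta[:, None] * (X_min[prov.neighbor_index]
                                          - X_min[prov.base_index]))
    features = np.vstack([X_min, synthetic, X[maj_rows]])
    labels = np.concatenate([
        np.ones(len(min_rows) + len(prov), dtype=int),
        -np.ones(len(maj_rows), dtype=int),
    ])
    ids = (
        [dataset.sample_ids[i] for i in min_rows]
        + [f"syn{j:05d}" for j in range(len(prov))]
        + [dataset.sample_ids[i] for i in maj_rows]
    )
    return LabeledDataset(features, labels, dataset.feature_names, tuple(ids))
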