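"""2D and 3D shape descriptors of binary nodule-candidate masks.

Eight features characterise a candidate ROI, four computed on a
representative 2D slice and four on the full 3D mask:

* **circularity** — ratio of the largest inscribed circle radius to the
  circumscribed radius (max centroid-to-boundary distance); 1 for a disc.
* **elongation** — min/max centroid-to-boundary distance; 1 for a disc,
  small for elongated (vessel-like) sections.
* **compactness** — 4*pi*A / P**2 with A the slice area and P its perimeter;
  1 for a disc (isoperimetric bound).
* **moment** — rotation/translation/scale-invariant sum of normalised
  second-order central moments, eta20 + eta02; 1/(2*pi) for a disc.
* **volume** — foreground voxel count times the voxel volume, mm^3.
* **surface_area** — exposed voxel faces under 6-connectivity times the
  per-face area, mm^2.
* **sphericity** — pi^(1/3) * (6V)^(2/3) / A_s; 1 for a sphere, lower for
  elongated shapes.
* **centroid_offset** — mean in-plane distance between each slice's 2D
  centroid and the projected 3D centroid, normalised by the
  volume-equivalent radius; near 0 for compact blobs, larger for curved or
  tilted tubular structures.

The representative slice for the 2D features is the axial slice of largest
foreground area (ties -> lowest slice index).  Degenerate one-pixel shapes
take ratio features equal to 1 and moment 0.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter_crofton as _perimeter_crofton

from .datasets import FEATURE_NAMES, ROIVolume

__all__ = ["FeatureVector", "extract_2d_features", "extract_3d_features",
           "feature_vector", "features_to_array"]

logger = logging.getLogger(__name__)


class FeatureVector(dict):
    """Mapping of the eight feature names to values, in canonical order."""

    def __init__(self, **kwargs: float):
        missing = set(FEATURE_NAMES) - set(kwargs)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")
        super().__init__((k, float(kwargs[k])) for k in FEATURE_NAMES)

    def to_array(self) -> np.ndarray:
        return np.array([self[k] for k in FEATURE_NAMES])


def features_to_array(vectors: list[FeatureVector]) -> np.ndarray:
    return np.vstack([v.to_array() for v in vectors])


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labeled, n = ndimage.label(mask)
    if n <= 1:
        return mask
    logger.info("mask has %d components; keeping the largest", n)
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    return labeled == (int(np.argmax(sizes)) + 1)


def extract_2d_features(slice_mask: np.ndarray,
                        spacing: tuple[float, float] = (1.0, 1.0)
                        ) -> tuple[float, float, float, float]:
    """(circularity, elongation, compactness, moment) of a 2D binary mask.

    ``spacing`` is (dy, dx) in mm per pixel, matching the (row, col) axis
    order of ``slice_mask``.
    """
    mask = np.asarray(slice_mask) > 0.5
    if mask.ndim != 2:
        raise ValueError("slice mask must be 2D")
    if not mask.any():
        raise ValueError("empty slice mask")
    mask = _largest_component(mask)
    dy, dx = (float(s) for s in spacing)

    if mask.sum() == 1:
        logger.info("single-pixel slice: degenerate ratios")
        return 1.0, 1.0, 1.0, 0.0

    yy, xx = np.nonzero(mask)
    coords = np.column_stack([yy * dy, xx * dx])
    centroid = coords.mean(axis=0)

    # r_max: farthest foreground pixel from the centroid; r_min: distance to
    # the nearest background pixel less half a pixel, which tracks the true
    # boundary without the staircase dip of inner boundary-pixel centers
    r_max = float(np.linalg.norm(coords - centroid, axis=1).max())
    gy, gx = np.nonzero(~mask)
    if len(gy):
        gcoords = np.column_stack([gy * dy, gx * dx])
        r_min = float(np.linalg.norm(gcoords - centroid, axis=1).min()
                      - 0.25 * (dx + dy))
        r_min = max(r_min, 0.0)
    else:
        r_min = r_max
    elongation = min(1.0, r_min / r_max) if r_max > 0 else 1.0

    # inscribed radius from the Euclidean distance transform of the interior
    edt = ndimage.distance_transform_edt(mask, sampling=(dy, dx))
    r_inscribed = float(edt.max())
    circularity = min(1.0, r_inscribed / r_max) if r_max > 0 else 1.0

    area = mask.sum() * dx * dy
    if abs(dx - dy) > 1e-12:
        logger.warning("anisotropic in-plane spacing; perimeter uses mean pixel pitch")
    p = float(_perimeter_crofton(mask, directions=4)) * 0.5 * (dx + dy)
    compactness = min(1.0, 4.0 * np.pi * area / p ** 2) if p > 0 else 1.0

    # normalised second-order central moments eta20 + eta02
    mu = coords - centroid
    mu20 = float(np.sum(mu[:, 1] ** 2)) * dx * dy
    mu02 = float(np.sum(mu[:, 0] ** 2)) * dx * dy
    mu00 = area
    moment = (mu20 + mu02) / mu00 ** 2

    return float(circularity), float(elongation), float(compactness), float(moment)


def extract_3d_features(roi: ROIVolume
                        ) -> tuple[float, float, float, float]:
    """(surface_area, volume, sphericity, centroid_offset) of an ROI mask."""
    mask = roi.mask
    if not mask.any():
        raise ValueError(f"empty ROI mask: {roi.id}")
    mask = _largest_component(mask)
    dz, dy, dx = roi.spacing

    volume = float(mask.sum()) * dx * dy * dz

    # exposed faces under 6-connectivity, per-axis face areas
    face_areas = (dx * dy, dx * dz, dy * dz)  # faces normal to z, y, x
    surface = 0.0
    for axis, fa in zip((0, 1, 2), face_areas):
        padded = np.pad(mask, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        diff = np.diff(padded.astype(np.int8), axis=axis)
        surface += np.count_nonzero(diff) * fa

    sphericity = float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / surface)
    sphericity = min(1.0, sphericity)

    # centroid offset: per-slice 2D centroid vs projected 3D centroid,
    # normalised by the volume-equivalent radius
    zz, yy, xx = np.nonzero(mask)
    cy = float(np.mean(yy)) * dy
    cx = float(np.mean(xx)) * dx
    r_eq = (3.0 * volume / (4.0 * np.pi)) ** (1 / 3)
    offsets = []
    for z in np.unique(zz):
        sel = zz == z
        sy = float(np.mean(yy[sel])) * dy
        sx = float(np.mean(xx[sel])) * dx
        offsets.append(np.hypot(sy - cy, sx - cx))
    centroid_offset = float(np.mean(offsets)) / r_eq

    return float(surface), volume, sphericity, centroid_offset


def feature_vector(roi: ROIVolume) -> FeatureVector:
    """All eight features of an ROI volume.

    The 2D features are computed on the axial slice with the largest
    foreground area (ties broken toward the lowest slice index).
    """
    mask = roi.mask
    if not mask.any():
        raise ValueError(f"empty ROI mask: {roi.id}")
    dz, dy, dx = roi.spacing
    areas = mask.sum(axis=(1, 2))
    z_rep = int(np.argmax(areas))  # argmax takes the first (lowest) on ties
    circ, elong, comp, mom = extract_2d_features(mask[z_rep], (dy, dx))
    surf, vol, spher, offset = extract_3d_features(roi)
    return FeatureVector(
        circularity=circ, elongation=elong, compactness=comp, moment=mom,
        surface_area=surf, volume=vol, sphericity=spher, centroid_offset=offset,
    )
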