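"""Single-cell activation morphometrics and marker-positive fractions.

Activated myofibroblasts are stellate: long cytoplasmic extensions and a
low shape factor. The module measures, on a binary cell mask,

* roundness — the isoperimetric shape factor ``4 * pi * A / P**2``
  (1 for a circle, approaching 0 for elongated/stellate shapes), with the
  perimeter from the 4-direction Crofton estimator so a discretized disk
  actually scores ~1;
* extension lengths — straight-line distances from the mask centroid to
  each extension tip, with tips located from skeleton endpoints;

and aggregates per-image marker-positive/total-nuclei counts into a group
percent-positive fraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import perimeter_crofton
from skimage.morphology import skeletonize

from .errors import InvalidInputError, InvalidParameterError, NoCellFoundError
from .types import CellMorphology, Image2D, PositiveFraction

__all__ = [
    "segment_cell",
    "roundness",
    "extension_lengths",
    "measure_cell",
    "percent_positive",
]

_CONN8 = np.ones((3, 3), dtype=int)


def segment_cell(image: Image2D, threshold="otsu") -> np.ndarray:
    """Binary cell mask: largest above-threshold 8-connected component,
    holes filled. Idempotent on binary input."""
    px = image.pixels
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise InvalidParameterError(f"unknown threshold method {threshold!r}")
        if px.max() == px.min():
            raise NoCellFoundError("image is constant; no cell found")
        thr = float(threshold_otsu(px))
    else:
        thr = float(threshold)
    mask = px > thr
    if not mask.any():
        raise NoCellFoundError("no foreground above threshold")
    labels, n = ndimage.label(mask, structure=_CONN8)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return ndimage.binary_fill_holes(labels == largest)


def roundness(mask: np.ndarray) -> float:
    """Isoperimetric shape factor ``4 pi A / P^2`` of a single-component
    mask, capped at 1.0 (discretization can nudge a disk slightly above)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("empty mask")
    _, n = ndimage.label(mask, structure=_CONN8)
    if n != 1:
        raise InvalidInputError(f"mask has {n} components; expected exactly 1")
    area = float(mask.sum())
    perim = float(perimeter_crofton(mask, directions=4))
    return min(4.0 * np.pi * area / perim**2, 1.0)


def _skeleton_endpoints(skel: np.ndarray) -> np.ndarray:
    """Skeleton pixels with exactly one skeleton neighbour (8-connectivity)."""
    neighbours = ndimage.convolve(skel.astype(int), _CONN8, mode="constant")
    return np.argwhere(skel & (neighbours == 2))  # self + 1 neighbour


def _extend_to_boundary(
    mask: np.ndarray, centroid: np.ndarray, end: np.ndarray
) -> tuple[float, np.ndarray]:
    """Distance from the centroid to the mask boundary along the
    centroid -> endpoint ray, plus the tip position reached.

    Skeletonization retracts endpoints from blunt tips by about half the
    local width; marching the ray outward to the last foreground pixel
    recovers the true tip.
    """
    vec = end - centroid
    d0 = np.linalg.norm(vec)
    if d0 == 0:
        return 0.0, centroid
    u = vec / d0
    d = d0
    step = 0.25
    t = d0
    while True:
        t += step
        pos = centroid + u * t
        r, c = int(round(pos[0])), int(round(pos[1]))
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
            break
        d = t
    return float(d), centroid + u * d


def _dedupe_tips(candidates: list[tuple[float, np.ndarray, float]]) -> list[float]:
    """A blunt extension end skeletonizes into a Y whose corner endpoints
    both point at the same tip, and junction spurs add more; tips closer
    than the local extension width are one tip. Keep the longest per
    cluster."""
    kept: list[tuple[float, np.ndarray, float]] = []
    for length, tip, halfwidth in sorted(candidates, key=lambda lt: -lt[0]):
        merged = False
        for _, k_tip, k_hw in kept:
            radius = 2.0 * max(halfwidth, k_hw) + 1.0
            if np.linalg.norm(tip - k_tip) <= radius:
                merged = True
                break
        if not merged:
            kept.append((length, tip, halfwidth))
    return sorted(length for length, _, _ in kept)


def extension_lengths(
    mask: np.ndarray, body_radius_estimate: float | None = None
) -> list[float]:
    """Straight-line lengths from the cell centroid to each extension tip.

    The mask is skeletonized; endpoints falling inside the cell body
    (closer to the body center than ``body_radius_estimate``, defaulting
    to the radius of the largest inscribed disk) are discarded, and each
    remaining endpoint is pushed outward along its ray to the mask
    boundary before measuring. A disk yields no extensions.

    Lengths are measured from the *body* center — the center of the
    largest inscribed disk — not the whole-mask area centroid: for an
    asymmetric stellate cell the area centroid is dragged toward the
    extensions, which would bias every length.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("empty mask")
    _, n = ndimage.label(mask, structure=_CONN8)
    if n != 1:
        raise InvalidInputError(f"mask has {n} components; expected exactly 1")
    edt = ndimage.distance_transform_edt(mask)
    if body_radius_estimate is None:
        body_radius_estimate = float(edt.max())
    skel = skeletonize(mask)
    if not skel.any():
        return []
    # plateau mean recovers a sub-pixel center for symmetric bodies
    centroid = np.argwhere(edt == edt.max()).mean(axis=0)
    candidates = []
    for end in _skeleton_endpoints(skel):
        if np.linalg.norm(end - centroid) <= body_radius_estimate:
            continue
        length, tip = _extend_to_boundary(mask, centroid, end.astype(float))
        # corner endpoints of a blunt/slanted tip sit at EDT ~1; the local
        # half-width is the EDT maximum in a small neighbourhood
        r0, c0 = end
        window = edt[
            max(r0 - 3, 0) : r0 + 4,
            max(c0 - 3, 0) : c0 + 4,
        ]
        candidates.append((length, tip, float(window.max())))
    return _dedupe_tips(candidates)


def measure_cell(
    image: Image2D,
    threshold="otsu",
    body_radius_estimate: float | None = None,
) -> CellMorphology:
    """Segment one cell and measure area, perimeter, roundness and
    extension lengths in a single record."""
    mask = segment_cell(image, threshold)
    cy, cx = ndimage.center_of_mass(mask)
    return CellMorphology(
        centroid=(float(cy), float(cx)),
        area_px=int(mask.sum()),
        perimeter_px=float(perimeter_crofton(mask, directions=4)),
        roundness=roundness(mask),
        extension_lengths_px=extension_lengths(mask, body_radius_estimate),
    )


def percent_positive(counts: pd.DataFrame) -> PositiveFraction:
    """Percent marker-positive cells per image and their unweighted group
    mean, from a table with columns image_id, positive, total."""
    required = {"positive", "total"}
    if not required.issubset(counts.columns):
        raise InvalidInputError("counts table needs 'positive' and 'total' columns")
    if len(counts) == 0:
        raise InvalidInputError("counts table is empty")
    pos = counts["positive"].to_numpy(dtype=float)
    tot = counts["total"].to_numpy(dtype=float)
    if (tot <= 0).any():
        raise InvalidInputError("total must be positive in every row")
    if ((pos < 0) | (pos > tot)).any():
        raise InvalidInputError("positive counts must lie in [0, total]")
    per_image = 100.0 * pos / tot
    return PositiveFraction(
        per_image_percent=per_image.tolist(),
        group_percent=float(per_image.mean()),
        n_images=int(len(counts)),
    )
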