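"""Collagen-gel contraction assay quantification.

A cell-seeded collagen disk released from the well wall contracts in
proportion to myofibroblast activation. The silhouette area is measured
at release (baseline) and at follow-up; contraction is reported as the
percent of baseline area lost, optionally expressed as fold of the
control-group mean.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import (
    DegenerateControlError,
    InvalidInputError,
    InvalidParameterError,
    NegativeContractionWarning,
    NoGelFoundError,
)
from .types import ContractionResult, Image2D

__all__ = [
    "gel_area",
    "percent_contraction",
    "measure_contraction",
    "normalize_to_control",
]

_CONN8 = np.ones((3, 3), dtype=int)


def gel_area(image: Image2D, threshold="otsu", dark_gel: bool = False) -> float:
    """Pixel area of the dominant foreground region after thresholding and
    hole filling. ``dark_gel=True`` inverts polarity for gels darker than
    the background."""
    px = image.pixels
    if px.max() == px.min():
        raise NoGelFoundError("image is constant; no gel silhouette found")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise InvalidParameterError(f"unknown threshold method {threshold!r}")
        thr = float(threshold_otsu(px))
    else:
        thr = float(threshold)
    mask = px < thr if dark_gel else px > thr
    if not mask.any():
        raise NoGelFoundError("no foreground above threshold")
    labels, _ = ndimage.label(mask, structure=_CONN8)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return float(ndimage.binary_fill_holes(labels == largest).sum())


def percent_contraction(baseline_area: float, followup_area: float) -> float:
    """Percent of baseline silhouette area lost: ``100 * (1 - A_t / A_0)``.

    Negative contraction (gel swelling) is reported with a warning rather
    than rejected.
    """
    if baseline_area <= 0 or followup_area <= 0:
        raise InvalidInputError("areas must be positive")
    value = 100.0 * (1.0 - followup_area / baseline_area)
    if value < 0:
        warnings.warn(
            f"follow-up area exceeds baseline (contraction {value:.2f}%)",
            NegativeContractionWarning,
        )
    return value


def measure_contraction(
    baseline: Image2D,
    followup: Image2D,
    threshold="otsu",
    dark_gel: bool = False,
) -> ContractionResult:
    """End-to-end: segment both silhouettes and report percent area lost
    plus the residual area fraction."""
    a0 = gel_area(baseline, threshold, dark_gel)
    a1 = gel_area(followup, threshold, dark_gel)
    pct = percent_contraction(a0, a1)
    return ContractionResult(
        percent_contraction=pct,
        residual_area_fraction=a1 / a0,
    )


def normalize_to_control(values, control_values) -> list[float]:
    """Express each value as a fold of the control-group mean, so the
    control group itself averages 1.0."""
    control = np.asarray(list(control_values), dtype=float)
    if control.size == 0:
        raise DegenerateControlError("control group is empty")
    m = control.mean()
    if m <= 0:
        raise DegenerateControlError("control mean must be positive")
    return [float(v) / m for v in np.asarray(list(values), dtype=float)]
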