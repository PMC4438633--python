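"""Shared fixtures and independent oracles used across the suite.

The oracles deliberately avoid the code paths they check: the structure
tensor estimates fiber orientation from image gradients (no FFT), polar
binning aggregates spectrum pixels without ray interpolation, and the
flood fill is a plain BFS.
"""

import numpy as np
import pytest
from scipy import ndimage

import ecmquant as eq


@pytest.fixture
def fiber_field():
    """Factory for seeded fiber images with ground truth."""

    def make(**kw):
        return eq.generate_fiber_image(eq.FiberFieldParams(**kw))

    return make


@pytest.fixture
def isotropic_control(fiber_field):
    """A no-bias fiber field (kappa=0) for control normalization."""

    def make(seed=9001, **kw):
        img, _ = fiber_field(kappa=0.0, seed=seed, **kw)
        return img

    return make


def structure_tensor_axis(pixels: np.ndarray, sigma: float = 1.0) -> float:
    """Dominant fiber axis in degrees CCW from the x-axis, mod 180,
    estimated from the gradient structure tensor (gradient direction is
    normal to the fibers)."""
    gx = ndimage.gaussian_filter(pixels, sigma, order=[0, 1])
    gy = ndimage.gaussian_filter(pixels, sigma, order=[1, 0])
    jxx, jyy, jxy = (gx * gx).sum(), (gy * gy).sum(), (gx * gy).sum()
    phi = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    return float((np.rad2deg(-phi) + 90.0) % 180.0)


def polar_bin_profile(spectrum: np.ndarray, r_min_frac=0.02, r_max_frac=0.45):
    """Brute-force angular profile: every spectrum pixel in the radial band
    binned by its polar angle (mod 180) into 1-degree bins."""
    h, w = spectrum.shape
    cy, cx = h // 2, w // 2
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, -(yy - cy)  # CCW, y up
    r = np.hypot(dx, dy)
    R = min(h, w) / 2.0
    band = (r >= max(r_min_frac * R, 1.0)) & (r <= r_max_frac * R)
    ang = np.rad2deg(np.arctan2(dy, dx)) % 180.0
    bins = np.floor(ang[band]).astype(int)
    out = np.zeros(180)
    np.add.at(out, bins, spectrum[band])
    return out


def axial_distance_deg(a: float, b: float) -> float:
    """Distance between two axial angles on the 180-degree circle."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def bfs_component_count(mask: np.ndarray, min_voxels: int = 1) -> int:
    """Plain breadth-first flood fill over 26-connected 3D components."""
    from collections import deque

    visited = np.zeros(mask.shape, dtype=bool)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    count = 0
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        size = 0
        queue = deque([start])
        visited[start] = True
        while queue:
            z, y, x = queue.popleft()
            size += 1
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if (
                    0 <= p[0] < mask.shape[0]
                    and 0 <= p[1] < mask.shape[1]
                    and 0 <= p[2] < mask.shape[2]
                    and mask[p]
                    and not visited[p]
                ):
                    visited[p] = True
                    queue.append(p)
        if size >= min_voxels:
            count += 1
    return count
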