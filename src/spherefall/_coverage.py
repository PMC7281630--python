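"""Exact area-coverage rasterisation of disks and ellipses.

A pixel's value in a rendered brightfield frame is determined by the
exact fraction of the pixel square covered by the (projected) sample, so
sub-pixel motion of the object moves intensity between boundary pixels
smoothly — the property real sub-pixel tracking relies on.

The closed form used here is the area of a disk intersected with an
axis-aligned box, assembled from the corner primitive

    F(x, y) = area{ X <= x, Y <= y, X² + Y² <= r² }

via inclusion–exclusion.  An axis-aligned ellipse reduces to the disk by
scaling one coordinate (pixel boxes stay boxes under the scaling).
"""

from __future__ import annotations

import numpy as np

__all__ = ["disk_coverage", "ellipse_coverage"]


def _G(t: np.ndarray, r: float) -> np.ndarray:
    """Antiderivative of sqrt(r² - t²): ½(t·sqrt(r²-t²) + r²·asin(t/r))."""
    t = np.clip(t, -r, r)
    return 0.5 * (t * np.sqrt(np.maximum(r * r - t * t, 0.0)) + r * r * np.arcsin(t / r))


def _corner_area(x: np.ndarray, y: np.ndarray, r: float) -> np.ndarray:
    """Area of the disk of radius r (centred at the origin) with X<=x, Y<=y."""
    x = np.clip(np.asarray(x, dtype=float), -r, r)
    y = np.clip(np.asarray(y, dtype=float), -r, r)
    ystar = np.sqrt(np.maximum(r * r - x * x, 0.0))
    yc = np.clip(y, -ystar, ystar)
    # strip |Y| <= ystar, where the chord [−w(Y), x] is non-empty
    area = x * (yc + ystar) + _G(yc, r) - _G(-ystar, r)
    pos = x >= 0
    quarter = np.pi * r * r / 4.0
    # x >= 0: full chords below the strip, cut at y when y < -ystar ...
    area = np.where(pos, area + 2.0 * (_G(np.minimum(y, -ystar), r) + quarter), area)
    # ... and above it, up to y
    hi = pos & (y > ystar)
    area = np.where(hi, area + 2.0 * (_G(y, r) - _G(ystar, r)), area)
    return area


def disk_coverage(
    shape: tuple[int, int], center_row: float, center_col: float, radius: float
) -> np.ndarray:
    """Per-pixel covered-area fraction of a disk on a pixel grid.

    Pixel (i, j) is the unit square centred at (i, j).  The returned
    array sums to the exact disk area when the disk lies fully inside
    the grid.
    """
    return ellipse_coverage(shape, center_row, center_col, radius, radius)


def ellipse_coverage(
    shape: tuple[int, int],
    center_row: float,
    center_col: float,
    semi_axis_row: float,
    semi_axis_col: float,
) -> np.ndarray:
    """Per-pixel coverage of an axis-aligned ellipse.

    ``semi_axis_row`` is the vertical (row-direction) semi-axis,
    ``semi_axis_col`` the horizontal one.
    """
    h, w = shape
    a_r, a_c = float(semi_axis_row), float(semi_axis_col)
    if a_r <= 0 or a_c <= 0:
        raise ValueError("semi-axes must be > 0")
    out = np.zeros((h, w), dtype=float)
    # bounding window, with a 1-px skirt for partially covered pixels
    r0 = max(int(np.floor(center_row - a_r)) - 1, 0)
    r1 = min(int(np.ceil(center_row + a_r)) + 2, h)
    c0 = max(int(np.floor(center_col - a_c)) - 1, 0)
    c1 = min(int(np.ceil(center_col + a_c)) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return out
    rows = np.arange(r0, r1, dtype=float)
    cols = np.arange(c0, c1, dtype=float)
    # scale rows so the ellipse becomes a circle of radius a_c
    s = a_c / a_r
    ylo = (rows - 0.5 - center_row) * s
    yhi = (rows + 0.5 - center_row) * s
    xlo = cols - 0.5 - center_col
    xhi = cols + 0.5 - center_col
    X0, Y0 = np.meshgrid(xlo, ylo)
    X1, Y1 = np.meshgrid(xhi, yhi)
    r = a_c
    area = (
        _corner_area(X1, Y1, r)
        - _corner_area(X0, Y1, r)
        - _corner_area(X1, Y0, r)
        + _corner_area(X0, Y0, r)
    )
    out[r0:r1, c0:c1] = area / s  # undo the row scaling: box area scales by 1/s
    return out
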