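"""Per-frame cell boundary extraction, interpolation, and smoothing.

Each binary mask frame yields one closed, ordered, subpixel outline of the
largest connected cell region. Contours are traced with marching squares at
iso-level 0.5 on the {0,1} field, so the outline sits midway between
foreground and background pixels. The outline is then resampled to uniform
arc-length spacing with shape-preserving cubic (PCHIP) interpolation and
smoothed with a circular moving average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import uniform_filter1d
from skimage import measure

from .io_stacks import InputError


@dataclass
class Boundary:
    """A closed, ordered cell outline for one frame.

    ``points`` is an (N, 2) array of subpixel (y, x) vertices with no
    duplicated endpoint. Orientation is counter-clockwise in the screen
    convention (x right, y down, angles measured with the y-axis flipped).
    ``centroid`` is the arithmetic mean of the vertices.
    """

    points: np.ndarray  # (N, 2) float64, (y, x)
    frame_index: int = 0
    centroid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InputError(f"points must be (N, 2); got {self.points.shape}")
        if len(self.points) < 8:
            raise InputError(f"boundary needs >= 8 points, got {len(self.points)}")
        self.centroid = self.points.mean(axis=0)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())

    def rotated(self, k: int) -> "Boundary":
        """Circular re-indexing: new point i is old point (i + k) mod N."""
        return Boundary(np.roll(self.points, -k, axis=0), self.frame_index)


def _signed_area_screen(points: np.ndarray) -> float:
    """Shoelace signed area in (x, -y) screen coordinates.

    Positive for counter-clockwise orientation on screen (y axis pointing
    down in image storage, flipped for the angle convention).
    """
    x = points[:, 1]
    y = -points[:, 0]
    return 0.5 * float(
        np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    )


def extract_boundary(mask_frame: np.ndarray, frame_index: int = 0) -> Boundary:
    """Trace the largest closed contour of a binary mask frame.

    The frame is padded by one background pixel on all sides so that cells
    touching the image border still yield closed contours; the padding offset
    is subtracted afterwards. Among all closed contours the one enclosing the
    largest polygon area (shoelace) is kept, with orientation normalized to
    counter-clockwise and the duplicated endpoint dropped.
    """
    mask_frame = np.asarray(mask_frame)
    if not mask_frame.any():
        raise InputError(f"mask frame {frame_index} has no foreground pixels")
    padded = np.pad((mask_frame != 0).astype(np.float64), 1)
    contours = measure.find_contours(padded, 0.5)
    best = None
    best_area = -np.inf
    for c in contours:
        if not np.allclose(c[0], c[-1]):
            continue  # open contour: can't happen after padding, but be safe
        pts = c[:-1]
        area = abs(_signed_area_screen(pts))
        if area > best_area:
            best_area = area
            best = pts
    if best is None:
        raise InputError(
            f"no closed contour found in frame {frame_index}; "
            "pad the mask so the cell does not touch the image border"
        )
    pts = best - 1.0  # undo padding offset
    if _signed_area_screen(pts) < 0:
        pts = pts[::-1]
    return Boundary(pts, frame_index)


def interpolate_boundary(b: Boundary, spacing: float = 0.5) -> Boundary:
    """Resample a closed boundary at uniform arc length with PCHIP.

    The curve is parameterized by cumulative chord length; y(s) and x(s) are
    fit with shape-preserving piecewise-cubic Hermite interpolants. Wrap
    handling duplicates knots across the seam at both ends before fitting, so
    the interpolant is smooth across the closure, then the resampled points
    are cropped back to one period. The output has
    ``N_out = round(perimeter / spacing)`` points (minimum 16).
    """
    if spacing <= 0:
        raise InputError(f"spacing must be positive, got {spacing}")
    pts = b.points
    n = len(pts)
    perimeter = b.perimeter
    if perimeter < 4 * spacing:
        raise InputError(
            f"degenerate boundary: perimeter {perimeter:.3g} < 4 * spacing {spacing}"
        )
    pad = min(4, n - 1)
    ext = np.vstack([pts[-pad:], pts, pts[: pad + 1]])
    seg = np.linalg.norm(np.diff(ext, axis=0), axis=1)
    s_ext = np.concatenate([[0.0], np.cumsum(seg)])
    s_ext -= s_ext[pad]  # s = 0 at the original first point
    # Chord-length parameterization requires strictly increasing knots.
    keep = np.concatenate([[True], np.diff(s_ext) > 1e-12])
    s_ext, ext = s_ext[keep], ext[keep]
    fy = PchipInterpolator(s_ext, ext[:, 0])
    fx = PchipInterpolator(s_ext, ext[:, 1])
    n_out = max(16, int(round(perimeter / spacing)))
    s_new = np.arange(n_out) * (perimeter / n_out)
    out = np.column_stack([fy(s_new), fx(s_new)])
    return Boundary(out, b.frame_index)


def smooth_boundary(b: Boundary, window: int) -> Boundary:
    """Circular moving average of the boundary coordinates.

    Each coordinate is replaced by the unweighted mean over an odd window
    centered on it, with wrap-around indexing. The vertex-mean centroid is
    exactly preserved (up to roundoff) because the circular mean commutes
    with the coordinate mean.
    """
    n = len(b)
    if window % 2 != 1:
        raise InputError(f"window must be odd, got {window}")
    if not 1 <= window < n:
        raise InputError(f"window must satisfy 1 <= window < N={n}, got {window}")
    if window == 1:
        return Boundary(b.points.copy(), b.frame_index)
    smoothed = uniform_filter1d(b.points, size=window, axis=0, mode="wrap")
    return Boundary(smoothed, b.frame_index)


def default_smoothing_window(n_points: int) -> int:
    """Perimeter-proportional default: max(5, round(N/50)) forced odd."""
    w = max(5, int(round(n_points / 50)))
    if w % 2 == 0:
        w += 1
    return w
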