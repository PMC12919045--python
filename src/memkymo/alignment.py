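"""Inter-frame circular alignment of cell boundaries.

Cell outlines deform and rotate between frames, so the same list index does
not refer to the same membrane region over time. The first frame is anchored
at a user-chosen polar angle about the centroid (default 180 degrees, i.e.
image-left). Every later frame is aligned to its predecessor by exhaustively
testing all circular shifts of its point list and keeping the shift that
minimizes the mean Euclidean distance between index-matched points. When the
two boundaries have different point counts, the longer one is decimated by a
seeded random subset (drawn once and reused for every candidate shift, so
the minimization is a deterministic objective).

Angle convention: the polar angle of a point about the centroid is
``atan2(-(y - cy), x - cx)`` mapped to [0, 360), so 0 degrees is image-right,
90 is image-up, and 180 is image-left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boundary import Boundary
from .io_stacks import InputError


@dataclass
class AlignedSeries:
    """Per-frame boundaries after circular alignment.

    ``shifts[0]`` is the anchor index chosen for frame 0; ``shifts[t]`` for
    t >= 1 is the circular shift applied to frame t. Each re-indexing is a
    pure rotation of the point list: the point set is unchanged.
    """

    boundaries: list[Boundary]
    shifts: list[int]
    start_angle: float

    def __post_init__(self) -> None:
        if len(self.boundaries) != len(self.shifts):
            raise InputError("boundaries and shifts must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.boundaries)


def polar_angles(b: Boundary) -> np.ndarray:
    """Polar angle in degrees [0, 360) of each point about the centroid."""
    cy, cx = b.centroid
    dy = b.points[:, 0] - cy
    dx = b.points[:, 1] - cx
    return np.degrees(np.arctan2(-dy, dx)) % 360.0


def align_initial(b: Boundary, start_angle: float = 180.0) -> tuple[Boundary, int]:
    """Rotate the point list so index 0 sits at ``start_angle`` degrees.

    The anchor is the point whose polar angle about the centroid has the
    smallest absolute circular difference from ``start_angle``; ties go to
    the lowest index.
    """
    if not 0 <= start_angle < 360:
        raise InputError(f"start_angle must be in [0, 360), got {start_angle}")
    angles = polar_angles(b)
    diff = np.abs((angles - start_angle + 180.0) % 360.0 - 180.0)
    anchor = int(np.argmin(diff))
    return b.rotated(anchor), anchor


def _subsample_indices(rng: np.random.Generator, n_longer: int, m: int) -> np.ndarray:
    """One sorted draw of m indices (without replacement) from the longer list."""
    return np.sort(rng.choice(n_longer, size=m, replace=False))


def shift_objective(
    current: Boundary, prev_aligned: Boundary, rng_seed: int
) -> np.ndarray:
    """Mean point-pair distance for every candidate circular shift.

    Entry k is the mean Euclidean distance between the k-rotated current
    boundary and the previous aligned boundary, both reduced to
    ``M = min(N_cur, N_prev)`` points (the longer decimated by one fixed
    seeded subset).
    """
    cur = current.points
    prev = prev_aligned.points
    n_cur, n_prev = len(cur), len(prev)
    if abs(n_cur - n_prev) >= min(n_cur, n_prev):
        raise InputError(
            f"boundary point counts differ too much to align: "
            f"{n_cur} vs {n_prev} (catastrophic segmentation change?)"
        )
    m = min(n_cur, n_prev)
    rng = np.random.default_rng(rng_seed)
    ks = np.arange(n_cur)
    if n_cur > n_prev:
        subset = _subsample_indices(rng, n_cur, m)
        # rotate-then-decimate: rotated[i] = cur[(i + k) % N], take rows `subset`
        idx = (subset[None, :] + ks[:, None]) % n_cur
        cur_red = cur[idx]  # (n_cur, m, 2)
        prev_red = prev[None, :, :]
    elif n_prev > n_cur:
        subset = _subsample_indices(rng, n_prev, m)
        idx = (np.arange(m)[None, :] + ks[:, None]) % n_cur
        cur_red = cur[idx]
        prev_red = prev[subset][None, :, :]
    else:
        idx = (np.arange(m)[None, :] + ks[:, None]) % n_cur
        cur_red = cur[idx]
        prev_red = prev[None, :, :]
    d = cur_red - prev_red
    return np.sqrt(d[..., 0] ** 2 + d[..., 1] ** 2).mean(axis=1)


def align_to_previous(
    current: Boundary, prev_aligned: Boundary, rng_seed: int
) -> tuple[Boundary, int]:
    """Find the circular shift of ``current`` closest to ``prev_aligned``.

    All N_cur shifts are evaluated against one fixed seeded decimation of
    the longer boundary; the minimizing shift is applied (ties broken by the
    smallest shift index, preferring temporal continuity).
    """
    dists = shift_objective(current, prev_aligned, rng_seed)
    best = int(np.argmin(dists))  # argmin returns the first minimum: smallest k
    return current.rotated(best), best


def align_series(
    boundaries: list[Boundary],
    start_angle: float = 180.0,
    rng_seed: int = 0,
) -> AlignedSeries:
    """Anchor frame 0 and chain-align every later frame to its predecessor.

    Per-frame seeds are derived as ``rng_seed + frame_index`` so each frame's
    subsampling draw is reproducible independently of the others.
    """
    if len(boundaries) < 2:
        raise InputError(f"need >= 2 frames to align, got {len(boundaries)}")
    aligned0, anchor = align_initial(boundaries[0], start_angle)
    out = [aligned0]
    shifts = [anchor]
    for t in range(1, len(boundaries)):
        try:
            b, k = align_to_previous(boundaries[t], out[-1], rng_seed + t)
        except InputError as exc:
            raise InputError(f"frame {t}: {exc}") from exc
        out.append(b)
        shifts.append(k)
    return AlignedSeries(boundaries=out, shifts=shifts, start_angle=start_angle)
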