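"""Kymograph assembly, spatial smoothing, and percentile normalization.

Per-frame membrane profiles of varying length are resampled onto a fixed
number of rows by periodic linear interpolation of normalized circular
position, giving a rectangular space-time matrix (rows = membrane position,
columns = frame). Each column is then smoothed along the spatial dimension
with LOWESS (local linear regression, default bandwidth fraction 0.1), and
the smoothed matrix is rescaled to [0, 1] using the 2nd/98th percentiles of
the pooled raw (pre-smoothing) intensities, with clipping. Anchoring the
normalization on the raw distribution keeps the display range insensitive
to the smoother while the percentile anchors suppress outlier pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .io_stacks import InputError
from .sampling import MembraneProfile


@dataclass
class Kymograph:
    """Raw, smoothed, and normalized space-time matrices for one channel."""

    raw: np.ndarray  # (R, T)
    smoothed: np.ndarray  # (R, T)
    normalized: np.ndarray  # (R, T), values in [0, 1]
    channel: int = 0
    norm_lo: float = 0.0
    norm_hi: float = 1.0

    def __post_init__(self) -> None:
        if not (self.raw.shape == self.smoothed.shape == self.normalized.shape):
            raise InputError(
                f"matrix shapes differ: raw {self.raw.shape}, "
                f"smoothed {self.smoothed.shape}, normalized {self.normalized.shape}"
            )
        if self.norm_lo > self.norm_hi:
            raise InputError("norm_lo must be <= norm_hi")

    @property
    def n_rows(self) -> int:
        return self.raw.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raw.shape[1]


def assemble(profiles: list[MembraneProfile], n_rows: int | None = None) -> np.ndarray:
    """Stack per-frame profiles into an (n_rows, T) raw matrix.

    Frame t's value sequence (length N_t, varying with cell perimeter) is
    resampled to ``n_rows`` by periodic linear interpolation on normalized
    circular position u in [0, 1). Default n_rows is frame 0's point count.
    """
    if len(profiles) < 2:
        raise InputError(f"need >= 2 frames, got {len(profiles)}")
    if n_rows is None:
        n_rows = len(profiles[0].values)
    if n_rows < 2:
        raise InputError(f"n_rows must be >= 2, got {n_rows}")
    cols = []
    u_target = np.arange(n_rows) / n_rows
    for prof in profiles:
        v = prof.values
        n = len(v)
        u_src = np.arange(n + 1) / n  # wrap point appended for periodicity
        v_wrap = np.concatenate([v, v[:1]])
        cols.append(np.interp(u_target, u_src, v_wrap))
    return np.column_stack(cols)


def lowess_columns(
    raw: np.ndarray, frac: float = 0.1, it: int = 3, circular: bool = False
) -> np.ndarray:
    """LOWESS each column along the spatial (row) dimension.

    ``frac`` is the bandwidth as a fraction of the rows. By default columns
    are treated as linear sequences (standard LOWESS); ``circular=True`` pads
    each column with wrapped rows before smoothing so the closed-membrane
    seam is treated like any interior position.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if not 0 < frac <= 1:
        raise InputError(f"frac must be in (0, 1], got {frac}")
    n_rows = raw.shape[0]
    if n_rows * frac < 2:
        raise InputError(
            f"LOWESS window too small: {n_rows} rows * frac {frac} < 2 points"
        )
    pad = int(np.ceil(frac * n_rows)) if circular else 0
    out = np.empty_like(raw)
    x = np.arange(-pad, n_rows + pad, dtype=np.float64)
    frac_eff = (frac * n_rows) / (n_rows + 2 * pad)
    for t in range(raw.shape[1]):
        col = raw[:, t]
        if pad:
            col = np.concatenate([col[-pad:], col, col[:pad]])
        sm = sm_lowess(col, x, frac=frac_eff, it=it, return_sorted=False)
        out[:, t] = sm[pad : pad + n_rows]
    return out


def percentile_normalize(
    raw: np.ndarray,
    smoothed: np.ndarray,
    p_lo: float = 2.0,
    p_hi: float = 98.0,
) -> tuple[np.ndarray, float, float]:
    """Rescale the smoothed matrix to [0, 1] on raw-percentile anchors.

    The anchors are the ``p_lo``/``p_hi`` percentiles (linear interpolation
    between order statistics) of ALL raw entries pooled across frames. The
    smoothed matrix is linearly rescaled and clipped to [0, 1]. A degenerate
    anchor range (hi - lo < 1e-12) yields an all-zero matrix with a warning.
    """
    raw = np.asarray(raw, dtype=np.float64)
    smoothed = np.asarray(smoothed, dtype=np.float64)
    if raw.shape != smoothed.shape:
        raise InputError(
            f"raw shape {raw.shape} does not match smoothed shape {smoothed.shape}"
        )
    lo, hi = np.percentile(raw, [p_lo, p_hi])
    if hi - lo < 1e-12:
        warnings.warn(
            "degenerate intensity range: percentile anchors coincide; "
            "normalized kymograph set to zeros",
            stacklevel=2,
        )
        return np.zeros_like(smoothed), float(lo), float(hi)
    normalized = np.clip((smoothed - lo) / (hi - lo), 0.0, 1.0)
    return normalized, float(lo), float(hi)


def build_kymograph(
    profiles: list[MembraneProfile],
    n_rows: int | None = None,
    lowess_frac: float = 0.1,
    p_lo: float = 2.0,
    p_hi: float = 98.0,
    channel: int = 0,
    circular_lowess: bool = False,
) -> Kymograph:
    """Assemble, smooth, and normalize one channel's kymograph."""
    raw = assemble(profiles, n_rows)
    smoothed = lowess_columns(raw, frac=lowess_frac, circular=circular_lowess)
    normalized, lo, hi = percentile_normalize(raw, smoothed, p_lo, p_hi)
    return Kymograph(
        raw=raw,
        smoothed=smoothed,
        normalized=normalized,
        channel=channel,
        norm_lo=lo,
        norm_hi=hi,
    )


def mean_intensity_timeseries(k: Kymograph, use: str = "normalized") -> np.ndarray:
    """Column means: average membrane intensity per frame."""
    if use == "raw":
        return k.raw.mean(axis=0)
    if use == "normalized":
        return k.normalized.mean(axis=0)
    raise InputError(f"use must be 'raw' or 'normalized', got {use!r}")
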