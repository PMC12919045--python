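"""Frame-wise correlation between two kymographs.

For every frame (column) the spatial intensity profiles of two channels are
compared with Pearson (linear association) and Spearman (monotonic
association, Pearson on average-ranked data) coefficients, with two-sided
p-values from the t-approximation on ``n_used - 2`` degrees of freedom.
Zero-valued positions can optionally be excluded: a pair is dropped when
EITHER channel reads exactly 0, since a zero in one channel alone already
marks background or genuinely absent signal. Frames with fewer than 3
retained pairs, or with a constant retained vector, are reported as
undefined (NaN) — never silently as zero.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io_stacks import InputError, write_spreadsheet

MIN_PAIRS = 3  # df = n - 2 must be >= 1 for a p-value

COLUMNS = [
    "frame",
    "pearson_r",
    "pearson_p",
    "spearman_rho",
    "spearman_p",
    "n_used",
]


def _frame_stats(a: np.ndarray, b: np.ndarray, exclude_zeros: bool) -> dict:
    if exclude_zeros:
        keep = (a != 0) & (b != 0)
        a, b = a[keep], b[keep]
    n_used = len(a)
    row = {
        "pearson_r": np.nan,
        "pearson_p": np.nan,
        "spearman_rho": np.nan,
        "spearman_p": np.nan,
        "n_used": n_used,
    }
    if n_used < MIN_PAIRS or np.ptp(a) == 0 or np.ptp(b) == 0:
        return row
    pr = stats.pearsonr(a, b)
    sr = stats.spearmanr(a, b)
    row.update(
        pearson_r=pr.statistic,
        pearson_p=pr.pvalue,
        spearman_rho=sr.statistic,
        spearman_p=sr.pvalue,
    )
    return row


def correlate_frames(
    k1: np.ndarray, k2: np.ndarray, exclude_zeros: bool = False
) -> pd.DataFrame:
    """Per-frame Pearson/Spearman table for two same-shape kymographs.

    Returns a DataFrame with one row per frame and columns frame,
    pearson_r, pearson_p, spearman_rho, spearman_p, n_used; undefined
    coefficients are NaN.
    """
    k1 = np.asarray(k1, dtype=np.float64)
    k2 = np.asarray(k2, dtype=np.float64)
    if k1.shape != k2.shape:
        raise InputError(
            f"kymograph shapes differ: {k1.shape} vs {k2.shape}"
        )
    if k1.ndim != 2:
        raise InputError(f"expected 2-D matrices, got {k1.ndim}-D")
    rows = []
    for t in range(k1.shape[1]):
        row = _frame_stats(k1[:, t], k2[:, t], exclude_zeros)
        row["frame"] = t
        rows.append(row)
    return pd.DataFrame(rows, columns=COLUMNS)


def export_correlation(
    table: pd.DataFrame,
    out: str | Path,
    formats: tuple[str, ...] = ("png",),
    dpi: int = 300,
) -> list[Path]:
    """Write the correlation spreadsheet and time-series plots.

    The spreadsheet carries the five statistic columns plus n_used. The
    figure shows coefficients (top) and p-values (bottom, with a reference
    line at p = 0.05); undefined frames appear as gaps, not zeros.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if table.empty:
        raise InputError("correlation table is empty")
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    xlsx = write_spreadsheet(
        {"correlation": table.set_index("frame")}, out / "correlation.xlsx"
    )
    paths.append(xlsx)

    fig, (ax_r, ax_p) = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    f = table["frame"].to_numpy()
    ax_r.plot(f, table["pearson_r"], marker="o", ms=3, label="Pearson r")
    ax_r.plot(f, table["spearman_rho"], marker="s", ms=3, label="Spearman rho")
    ax_r.set_ylabel("correlation coefficient")
    ax_r.set_ylim(-1.05, 1.05)
    ax_r.axhline(0, color="0.6", lw=0.8)
    ax_r.legend(loc="best", fontsize=8)
    ax_p.plot(f, table["pearson_p"], marker="o", ms=3, label="Pearson p")
    ax_p.plot(f, table["spearman_p"], marker="s", ms=3, label="Spearman p")
    ax_p.axhline(0.05, color="r", ls="--", lw=1, label="p = 0.05")
    ax_p.set_xlabel("frame")
    ax_p.set_ylabel("p-value")
    ax_p.set_yscale("log")
    ax_p.legend(loc="best", fontsize=8)
    fig.tight_layout()
    for fmt in formats:
        p = out / f"correlation_timeseries.{fmt.lower()}"
        fig.savefig(p, dpi=dpi)
        paths.append(p)
    plt.close(fig)
    return paths
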