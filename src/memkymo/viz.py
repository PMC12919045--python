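"""Rendering of kymographs, per-frame tracking previews, and re-renders.

Kymographs are drawn with x = time (frames) and y = membrane position,
mapped through ``clip((v - vmin) / (vmax - vmin), 0, 1)`` and a colormap.
The default colormap is a bundled 256-entry parula-like lookup table
(shipped as a plain CSV asset); any matplotlib colormap name also works.
Figures export as PNG (default 300 DPI), SVG, and/or PDF. Rendering never
mutates stored matrices, so display settings can be adjusted and re-rendered
from a saved ``.npy`` file without recomputing the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .io_stacks import FormatError, InputError

_FORMATS = ("png", "svg", "pdf")


def _load_parula() -> ListedColormap:
    with resources.files("memkymo.assets").joinpath("parula.csv").open() as f:
        lut = np.loadtxt(f, delimiter=",", skiprows=1)
    return ListedColormap(lut, name="parula")


_PARULA = None


def get_colormap(name: str):
    """Resolve a colormap name; 'parula' maps to the bundled LUT."""
    global _PARULA
    if name.lower() == "parula":
        if _PARULA is None:
            _PARULA = _load_parula()
        return _PARULA
    try:
        return matplotlib.colormaps[name]
    except KeyError:
        available = ["parula"] + sorted(matplotlib.colormaps)
        raise InputError(
            f"unknown colormap {name!r}; available: {', '.join(available[:20])}, ..."
        ) from None


@dataclass
class RenderSpec:
    """Display settings for kymograph figures."""

    colormap: str = "parula"
    vmin: float = 0.0
    vmax: float = 1.0
    dpi: int = 300
    formats: tuple[str, ...] = ("png",)
    seconds_per_frame: float | None = None  # frames if None, seconds otherwise

    def __post_init__(self) -> None:
        if self.vmin >= self.vmax:
            raise InputError(f"vmin ({self.vmin}) must be < vmax ({self.vmax})")
        self.formats = tuple(f.lower() for f in self.formats)
        bad = set(self.formats) - set(_FORMATS)
        if bad:
            raise InputError(f"unsupported formats {sorted(bad)}; use {_FORMATS}")


def render_kymograph(
    matrix: np.ndarray, spec: RenderSpec, out: str | Path
) -> list[Path]:
    """Render one kymograph matrix to every requested format.

    ``out`` is the path stem; one file per format is written next to it.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.size == 0:
        raise InputError("empty kymograph matrix")
    cmap = get_colormap(spec.colormap)
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    extent = None
    xlabel = "time (frames)"
    if spec.seconds_per_frame is not None:
        extent = [0, matrix.shape[1] * spec.seconds_per_frame, matrix.shape[0], 0]
        xlabel = "time (s)"
    im = ax.imshow(
        matrix,
        aspect="auto",
        cmap=cmap,
        vmin=spec.vmin,
        vmax=spec.vmax,
        interpolation="nearest",
        extent=extent,
    )
    ax.set_xlabel(xlabel)
    ax.set_ylabel("membrane position")
    fig.colorbar(im, ax=ax, label="intensity")
    fig.tight_layout()
    paths = []
    for fmt in spec.formats:
        p = out.with_suffix(f".{fmt}")
        fig.savefig(p, dpi=spec.dpi)
        paths.append(p)
    plt.close(fig)
    return paths


def render_preview(
    image_frame: np.ndarray,
    boundary,
    sample_lines: np.ndarray | None,
    out: str | Path,
    max_segments: int = 200,
    dpi: int = 150,
) -> Path:
    """Overlay the tracked boundary and sampling segments on one frame.

    At most ``max_segments`` perpendicular segments are drawn (every k-th),
    so previews stay legible for long boundaries.
    """
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(image_frame, cmap="gray", interpolation="nearest")
    pts = boundary.points
    closed = np.vstack([pts, pts[:1]])
    ax.plot(closed[:, 1], closed[:, 0], "-", color="cyan", lw=1.0)
    ax.plot(pts[0, 1], pts[0, 0], "o", color="yellow", ms=4)  # anchor point
    if sample_lines is not None and len(sample_lines):
        step = max(1, int(np.ceil(len(sample_lines) / max_segments)))
        for seg in sample_lines[::step]:
            ax.plot(seg[:, 1], seg[:, 0], "-", color="red", lw=0.4, alpha=0.7)
    ax.set_xlim(-0.5, image_frame.shape[1] - 0.5)
    ax.set_ylim(image_frame.shape[0] - 0.5, -0.5)
    ax.set_axis_off()
    fig.savefig(out, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
    return out


def adjust_existing(
    matrix_path: str | Path, spec: RenderSpec, out: str | Path
) -> list[Path]:
    """Re-render a stored kymograph matrix with new display settings.

    Reads the ``.npy`` matrix only; no pipeline recomputation, and the
    stored file is never modified.
    """
    matrix_path = Path(matrix_path)
    if not matrix_path.exists():
        raise InputError(f"matrix file not found: {matrix_path}")
    try:
        matrix = np.load(matrix_path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read matrix file {matrix_path}: {exc}") from exc
    return render_kymograph(matrix, spec, out)
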