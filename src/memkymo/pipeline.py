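"""End-to-end pipeline orchestration, run configuration, and batch mode.

One run: load movie + mask, extract/interpolate/smooth a boundary per
frame, chain-align the boundaries, perpendicular-sample every channel,
assemble/smooth/normalize per-channel kymographs, render figures and
per-frame previews, and write everything (plus a run log with every
effective parameter, per-frame shift, and the seed) into the structured
output directories. Given identical inputs and configuration (including the
seed), all numerical outputs are bit-identical across runs.
"""

from __future__ import annotations

import dataclasses
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment, boundary, kymograph, sampling, viz
from .io_stacks import (
    ChannelResult,
    InputError,
    OutputLayout,
    RunManifest,
    load_image_stack,
    load_mask_stack,
    write_outputs,
)


@dataclass
class RunConfig:
    """Every knob of one pipeline run; serializable to flat key=value text."""

    image_path: str = ""
    mask_path: str = ""
    n_channels: int = 1
    l_perp: float = 8.0
    start_angle: float = 180.0
    spacing: float = 0.5
    smoothing_window: int = 0  # 0 = automatic (perimeter-proportional)
    n_rows: int = 0  # 0 = frame-0 point count
    lowess_frac: float = 0.1
    p_lo: float = 2.0
    p_hi: float = 98.0
    top_k: int = 5
    fit_neighborhood: int = 5
    colormap: str = "parula"
    formats: str = "png"  # comma-separated subset of png,svg,pdf
    page_order: str = "channel_interleaved"
    rng_seed: int = 0
    n_jobs: int = 1
    out_root: str = "."
    write_previews: bool = True

    _FLOATS = ("l_perp", "start_angle", "spacing", "lowess_frac", "p_lo", "p_hi")
    _INTS = (
        "n_channels",
        "smoothing_window",
        "n_rows",
        "top_k",
        "fit_neighborhood",
        "rng_seed",
        "n_jobs",
    )
    _BOOLS = ("write_previews",)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [
            f"{f.name} = {getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        kwargs: dict = {}
        known = {f.name for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InputError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise InputError(f"{path}:{lineno}: unknown key {key!r}")
            if key in cls._FLOATS:
                kwargs[key] = float(value)
            elif key in cls._INTS:
                kwargs[key] = int(value)
            elif key in cls._BOOLS:
                kwargs[key] = value.lower() in ("true", "1", "yes")
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @property
    def format_tuple(self) -> tuple[str, ...]:
        return tuple(f for f in (s.strip() for s in self.formats.split(",")) if f)

    def sampling_config(self) -> sampling.SamplingConfig:
        return sampling.SamplingConfig(
            l_perp=self.l_perp,
            spacing=self.spacing,
            top_k=self.top_k,
            fit_neighborhood=self.fit_neighborhood,
        )


@dataclass
class RunResult:
    """In-memory products of one run, plus the file manifest."""

    config: RunConfig
    series: alignment.AlignedSeries
    kymographs: list[kymograph.Kymograph]
    manifest: RunManifest


def _format_run_log(cfg: RunConfig, series: alignment.AlignedSeries) -> str:
    lines = ["# memkymo run log", "", "[parameters]"]
    lines += [f"{f.name} = {getattr(cfg, f.name)}" for f in dataclasses.fields(cfg)]
    lines += ["", "[shifts]", "# frame 0: anchor index; frames >= 1: circular shift"]
    lines += [
        f"frame {t}: shift {s} (n_points {len(b)})"
        for t, (s, b) in enumerate(zip(series.shifts, series.boundaries))
    ]
    return "\n".join(lines) + "\n"


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute one full run; see module docstring for the stage order."""
    if not Path(cfg.image_path).exists():
        raise InputError(f"image file not found: {cfg.image_path}")
    if not Path(cfg.mask_path).exists():
        raise InputError(f"mask file not found: {cfg.mask_path}")
    image = load_image_stack(cfg.image_path, cfg.n_channels, cfg.page_order)
    mask = load_mask_stack(cfg.mask_path, image)

    boundaries = []
    for t in range(mask.n_frames):
        try:
            b = boundary.extract_boundary(mask.frame(t), t)
            b = boundary.interpolate_boundary(b, cfg.spacing)
            window = cfg.smoothing_window or boundary.default_smoothing_window(len(b))
            b = boundary.smooth_boundary(b, window)
        except Exception as exc:
            raise type(exc)(f"frame {t}: {exc}") from exc
        boundaries.append(b)

    series = alignment.align_series(boundaries, cfg.start_angle, cfg.rng_seed)
    scfg = cfg.sampling_config()

    results = []
    kymos = []
    profiles_ch0 = None
    for c in range(image.n_channels):
        profiles = [
            sampling.sample_frame(
                image.frame(t, c),
                series.boundaries[t],
                scfg,
                n_jobs=cfg.n_jobs,
                frame_index=t,
                channel=c,
            )
            for t in range(image.n_frames)
        ]
        if c == 0:
            profiles_ch0 = profiles
        k = kymograph.build_kymograph(
            profiles,
            n_rows=cfg.n_rows or None,
            lowess_frac=cfg.lowess_frac,
            p_lo=cfg.p_lo,
            p_hi=cfg.p_hi,
            channel=c,
        )
        kymos.append(k)
        results.append(ChannelResult(channel=c, kymograph=k))

    layout = OutputLayout.create(cfg.out_root)
    preview_paths = []
    if cfg.write_previews:
        for t in range(image.n_frames):
            preview_paths.append(
                viz.render_preview(
                    image.frame(t, 0),
                    series.boundaries[t],
                    profiles_ch0[t].sample_lines,
                    layout.temporary / f"frame_{t:04d}.png",
                )
            )

    spec = viz.RenderSpec(colormap=cfg.colormap, formats=cfg.format_tuple or ("png",))
    render_spec = spec if cfg.format_tuple else None
    manifest = write_outputs(
        results,
        cfg.out_root,
        render_spec=render_spec,
        preview_paths=preview_paths,
        run_log=_format_run_log(cfg, series),
    )
    return RunResult(config=cfg, series=series, kymographs=kymos, manifest=manifest)


@dataclass
class BatchSummary:
    succeeded: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    failed: dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.succeeded), len(self.skipped), len(self.failed)


def run_batch(manifest_path: str | Path, resume: bool = False) -> BatchSummary:
    """Process a CSV manifest of runs, one row per (image, mask, overrides).

    The CSV header names RunConfig fields; image_path, mask_path, and
    out_root are required per row. With ``resume``, rows whose output
    directory already holds a run log are skipped. Per-row failures are
    recorded in the summary without stopping the batch.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise InputError(f"batch manifest not found: {manifest_path}")
    try:
        rows = pd.read_csv(manifest_path, dtype=str).fillna("")
    except Exception as exc:  # noqa: BLE001
        raise InputError(f"cannot parse batch manifest {manifest_path}: {exc}") from exc
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(rows.columns) - known
    if unknown:
        raise InputError(f"unknown manifest columns: {sorted(unknown)}")
    summary = BatchSummary()
    for _, row in rows.iterrows():
        kwargs: dict = {}
        for key, value in row.items():
            if value == "":
                continue
            if key in RunConfig._FLOATS:
                kwargs[key] = float(value)
            elif key in RunConfig._INTS:
                kwargs[key] = int(value)
            elif key in RunConfig._BOOLS:
                kwargs[key] = value.lower() in ("true", "1", "yes")
            else:
                kwargs[key] = value
        cfg = RunConfig(**kwargs)
        tag = cfg.image_path
        log_path = Path(cfg.out_root) / "Kymo_Processed Data" / "run_log.txt"
        if resume and log_path.exists():
            summary.skipped.append(tag)
            continue
        try:
            run_pipeline(cfg)
        except Exception:  # noqa: BLE001 - batch must keep going
            summary.failed[tag] = traceback.format_exc(limit=2)
            continue
        summary.succeeded.append(tag)
    return summary


def intensity_at(kymograph_path: str | Path, position: int, frame: int) -> float:
    """Read one entry of a stored kymograph matrix (no negative indexing)."""
    matrix = np.load(kymograph_path)
    r, t = matrix.shape
    if not (0 <= position < r and 0 <= frame < t):
        raise IndexError(
            f"(position={position}, frame={frame}) out of range for "
            f"matrix of shape {matrix.shape}"
        )
    return float(matrix[position, frame])


class KymographProcessor:
    """Object-oriented front door: configure once, process movies."""

    def __init__(self, **config_overrides):
        self.base_config = RunConfig(**config_overrides)

    def process(self, image_path, mask_path, out_root=".", **overrides) -> RunResult:
        cfg = dataclasses.replace(
            self.base_config,
            image_path=str(image_path),
            mask_path=str(mask_path),
            out_root=str(out_root),
            **overrides,
        )
        return run_pipeline(cfg)
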