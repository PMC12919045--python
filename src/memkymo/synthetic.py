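"""Synthetic single-cell movies with known membrane signal patterns.

The generator emulates the pipeline's input contract — a fluorescence movie
plus a matching binary mask of one deforming, drifting, rotating cell — with
a fully known ground truth, so every stage can be tested without external
data. The cell outline is a star-shaped Fourier contour

    r(phi, t) = base_radius * (1 + sum_m a_m(t) * cos(m * phi + phase_m)),

with seeded, smoothly oscillating mode amplitudes capped so the outline
stays simple. ``phi`` is the material angle: a fixed label for a membrane
point, carried along as the cell rotates. Fluorescence is a band of width
``band_width`` straddling the outline, modulated by a chosen angular
pattern (uniform, crescent, traveling wave, or step stimulus), over a
constant background plus optional Gaussian noise (clipped at zero).

The ground truth exposes an ideal kymograph parameterized by arc-length
fraction from the 180-degree anchor — the same coordinate the pipeline's
alignment and row resampling produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_stacks import FrameStack, MaskStack, write_image_stack, write_mask_stack

PATTERNS = ("uniform", "crescent", "traveling_wave", "step_stimulus")


class GenerationError(ValueError):
    """The requested synthetic movie violates a generator invariant."""


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic movie.

    Units: lengths in pixels, rates per frame, angles in degrees,
    intensities in arbitrary fluorescence units.
    """

    n_frames: int = 42
    height: int = 256
    width: int = 256
    base_radius: float = 60.0
    deform_amplitude: float = 0.15  # fraction of base_radius, summed over modes
    deform_modes: int = 3
    drift: float = 0.0  # pixels/frame along +x
    rotation: float = 0.0  # degrees/frame
    band_width: float = 3.0
    pattern: str = "uniform"
    pattern_params: dict = field(default_factory=dict)
    background_level: float = 10.0
    signal_level: float = 100.0
    noise_sigma: float = 2.0
    seed: int = 0
    border_margin: float = 12.0  # clearance kept between cell band and image edge

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise GenerationError(f"pattern must be one of {PATTERNS}")
        if self.signal_level <= self.background_level:
            raise GenerationError("signal_level must exceed background_level")
        if self.deform_amplitude > 0.3:
            raise GenerationError(
                "deform_amplitude capped at 0.3 to keep outlines simple"
            )
        if self.n_frames < 2:
            raise GenerationError("need at least 2 frames")


class _Shape:
    """Seeded Fourier shape-mode coefficients and center track."""

    def __init__(self, spec: SynthSpec, rng: np.random.Generator):
        self.spec = spec
        n_modes = spec.deform_modes
        self.modes = np.arange(2, 2 + n_modes)  # mode 1 is just translation
        raw = rng.uniform(0.5, 1.0, n_modes)
        self.amps = raw / raw.sum() * spec.deform_amplitude if n_modes else raw
        self.phases = rng.uniform(0, 2 * np.pi, n_modes)
        self.freqs = rng.uniform(0.01, 0.05, n_modes)  # cycles/frame
        self.tphases = rng.uniform(0, 2 * np.pi, n_modes)
        t_all = np.arange(spec.n_frames)
        cx0 = spec.width / 2.0 - spec.drift * (spec.n_frames - 1) / 2.0
        self.centers = np.column_stack(
            [np.full_like(t_all, spec.height / 2.0, dtype=float),
             cx0 + spec.drift * t_all]
        )  # (T, 2) as (cy, cx)
        max_r = spec.base_radius * (1 + spec.deform_amplitude) + spec.band_width / 2
        lo = self.centers - max_r - spec.border_margin
        hi = self.centers + max_r + spec.border_margin
        if (
            lo[:, 0].min() < 0
            or lo[:, 1].min() < 0
            or hi[:, 0].max() > spec.height
            or hi[:, 1].max() > spec.width
        ):
            raise GenerationError(
                "cell (radius + band + margin) does not fit inside the image "
                "for every frame; shrink base_radius/drift or enlarge the image"
            )

    def radius(self, phi: np.ndarray, t: int) -> np.ndarray:
        """r(phi, t) for material angle phi (radians)."""
        r = np.ones_like(phi, dtype=np.float64)
        for m, amp, ph, fq, tp in zip(
            self.modes, self.amps, self.phases, self.freqs, self.tphases
        ):
            a_t = amp * np.cos(2 * np.pi * fq * t + tp)
            r = r + a_t * np.cos(m * phi + ph)
        return self.spec.base_radius * r

    def rot(self, t: int) -> float:
        return np.deg2rad(self.spec.rotation) * t

    def outline(self, t: int, n_dense: int = 1440) -> np.ndarray:
        """Dense (y, x) polyline of frame t's outline, ordered by phi."""
        phi = 2 * np.pi * np.arange(n_dense) / n_dense
        r = self.radius(phi, t)
        theta = phi + self.rot(t)
        cy, cx = self.centers[t]
        return np.column_stack([cy - r * np.sin(theta), cx + r * np.cos(theta)])


def _pattern_value(spec: SynthSpec, phi: np.ndarray, t: int) -> np.ndarray:
    """Membrane pattern p(phi, t) in [0, 1] at material angle phi (radians)."""
    p = spec.pattern_params
    if spec.pattern == "uniform":
        return np.ones_like(phi, dtype=np.float64)
    if spec.pattern == "crescent":
        center = np.deg2rad(p.get("center_deg", 180.0))
        arc = np.deg2rad(p.get("arc_deg", 120.0))
        taper = np.deg2rad(p.get("taper_deg", 20.0))
        d = np.abs((phi - center + np.pi) % (2 * np.pi) - np.pi)
        inner, outer = arc / 2, arc / 2 + taper
        val = np.clip((outer - d) / max(taper, 1e-9), 0.0, 1.0)
        # cosine taper for smooth shoulders
        return 0.5 - 0.5 * np.cos(np.pi * val)
    if spec.pattern == "traveling_wave":
        w = p.get("wave_number", 2)
        speed = p.get("speed", 0.02)  # revolutions per frame
        u = phi / (2 * np.pi)
        return 0.5 * (1 + np.cos(2 * np.pi * (w * u - speed * t * w)))
    if spec.pattern == "step_stimulus":
        t0 = p.get("step_frame", spec.n_frames // 2)
        pre = p.get("pre_level", 0.2)
        lvl = 1.0 if t >= t0 else pre
        return np.full_like(phi, lvl, dtype=np.float64)
    raise GenerationError(f"unknown pattern {spec.pattern!r}")


@dataclass
class GroundTruth:
    """Analytic truth for one synthetic movie."""

    spec: SynthSpec
    shape: _Shape
    patterns: list  # one pattern name per channel; values via pattern_value

    def outline(self, t: int, n_dense: int = 1440) -> np.ndarray:
        return self.shape.outline(t, n_dense)

    def pattern_value(self, phi: np.ndarray, t: int, channel: int = 0) -> np.ndarray:
        base = _pattern_value(self.spec, np.asarray(phi, dtype=np.float64), t)
        return 1.0 - base if self.patterns[channel] == "complement" else base

    def ideal_kymograph(
        self,
        n_rows: int,
        n_frames: int | None = None,
        start_angle: float = 180.0,
        channel: int = 0,
    ) -> np.ndarray:
        """Pattern values on the pipeline's row/column grid.

        Row j of frame t is the pattern at the material point reached by
        walking a fraction j/n_rows of the perimeter (in boundary order)
        from the material point that sat at ``start_angle`` in frame 0 —
        exactly the coordinate an ideally aligned pipeline samples.
        """
        T = n_frames or self.spec.n_frames
        n_dense = 4096
        phi_d = 2 * np.pi * np.arange(n_dense + 1) / n_dense
        phi_start = np.deg2rad(start_angle)
        out = np.empty((n_rows, T))
        for t in range(T):
            pts = self.shape.outline(t, n_dense)
            closed = np.vstack([pts, pts[:1]])
            seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
            s = np.concatenate([[0.0], np.cumsum(seg)])  # s over phi_d grid
            L = s[-1]
            s_start = np.interp(phi_start, phi_d, s)
            s_rows = (s_start + np.arange(n_rows) * L / n_rows) % L
            phi_rows = np.interp(s_rows, s, phi_d)
            out[:, t] = self.pattern_value(phi_rows, t, channel)
        return out


def _render_frames(
    spec: SynthSpec, shape: _Shape, channels: list[str], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    T, H, W = spec.n_frames, spec.height, spec.width
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    img = np.empty((T, len(channels), H, W))
    msk = np.empty((T, H, W), dtype=np.uint8)
    for t in range(T):
        cy, cx = shape.centers[t]
        dy, dx = cy - yy, xx - cx
        rho = np.hypot(dy, dx)
        theta = np.arctan2(dy, dx)
        phi = theta - shape.rot(t)
        r_out = shape.radius(phi, t)
        msk[t] = (rho <= r_out).astype(np.uint8)
        band = np.abs(rho - r_out) <= spec.band_width / 2
        base = _pattern_value(spec, phi, t)
        for c, kind in enumerate(channels):
            pat = 1.0 - base if kind == "complement" else base
            frame = spec.background_level + (
                spec.signal_level - spec.background_level
            ) * pat * band
            if spec.noise_sigma > 0:
                frame = frame + spec.noise_sigma * rng.standard_normal((H, W))
            img[t, c] = np.clip(frame, 0.0, None)
    return img, msk


def make_movie(spec: SynthSpec) -> tuple[FrameStack, MaskStack, GroundTruth]:
    """Generate one single-channel movie, its mask, and the ground truth.

    Identical spec (including seed) gives bit-identical stacks.
    """
    rng = np.random.default_rng(spec.seed)
    shape = _Shape(spec, rng)
    img, msk = _render_frames(spec, shape, ["direct"], rng)
    return (
        FrameStack(img),
        MaskStack(msk),
        GroundTruth(spec=spec, shape=shape, patterns=["direct"]),
    )


def make_complementary_pair(spec: SynthSpec) -> tuple[FrameStack, MaskStack, GroundTruth]:
    """Two-channel movie: channel 1 carries p(phi, t), channel 2 carries 1 - p.

    Emulates front/back complementarity of membrane markers; requires the
    crescent pattern so the two channels occupy mutually exclusive arcs.
    """
    if spec.pattern != "crescent":
        raise GenerationError("complementary pair requires pattern='crescent'")
    rng = np.random.default_rng(spec.seed)
    shape = _Shape(spec, rng)
    channels = ["direct", "complement"]
    img, msk = _render_frames(spec, shape, channels, rng)
    return (
        FrameStack(img),
        MaskStack(msk),
        GroundTruth(spec=spec, shape=shape, patterns=channels),
    )


def write_movie(
    spec: SynthSpec,
    image_path: str | Path,
    mask_path: str | Path,
    complementary: bool = False,
    page_order: str = "channel_interleaved",
) -> GroundTruth:
    """Generate a movie and write the TIFF pair consumable by the pipeline."""
    maker = make_complementary_pair if complementary else make_movie
    stack, mask, truth = maker(spec)
    write_image_stack(stack, image_path, page_order)
    write_mask_stack(mask, mask_path)
    return truth
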