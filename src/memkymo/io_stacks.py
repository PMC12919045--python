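"""Reading and writing image stacks and pipeline output artifacts.

Fluorescence movies and masks arrive as multi-page TIFF files; pixel values
are carried as float64 without any bit-depth rescaling (intensity scaling is
handled later by percentile normalization). The coordinate convention
throughout the package is (row=y, col=x), 0-based, with pixel centers at
integer coordinates.
"""

from __future__ import annotations

import datetime
import io
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

PROCESSED_DIR = "Kymo_Processed Data"
TEMP_DIR = "Kymo_Temporary_Images"

PAGE_ORDERS = ("channel_interleaved", "channel_blocked")


class InputError(ValueError):
    """Invalid or inconsistent user input (bad shapes, counts, paths)."""


class FormatError(ValueError):
    """A file exists but cannot be decoded."""


@dataclass
class FrameStack:
    """A fluorescence movie: ``data[t, c, y, x]`` intensities.

    Intensities are finite and non-negative; all frames share one
    height/width.
    """

    data: np.ndarray  # (T, C, H, W) float64

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise InputError(
                f"FrameStack data must be 4-D (t, c, y, x); got shape {self.data.shape}"
            )
        if self.n_frames < 2:
            raise InputError(f"need at least 2 frames, got {self.n_frames}")
        if not 1 <= self.n_channels <= 10:
            raise InputError(f"n_channels must be in 1..10, got {self.n_channels}")
        if not np.all(np.isfinite(self.data)):
            raise InputError("intensities must be finite")
        if np.any(self.data < 0):
            raise InputError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def height(self) -> int:
        return self.data.shape[2]

    @property
    def width(self) -> int:
        return self.data.shape[3]

    def frame(self, t: int, c: int = 0) -> np.ndarray:
        return self.data[t, c]


@dataclass
class MaskStack:
    """A binary single-cell mask movie: ``data[t, y, x]`` in {0, 1}."""

    data: np.ndarray  # (T, H, W) uint8

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        self.data = (data != 0).astype(np.uint8)
        if self.data.ndim != 3:
            raise InputError(
                f"MaskStack data must be 3-D (t, y, x); got shape {data.shape}"
            )
        for t in range(self.n_frames):
            if not self.data[t].any():
                raise InputError(f"mask frame {t} contains no foreground pixels")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]


def _read_pages(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - tifffile raises various types
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(
            f"expected grayscale pages in {path}; got array of shape {pages.shape}"
        )
    return pages


def load_image_stack(
    path: str | Path,
    n_channels: int = 1,
    page_order: str = "channel_interleaved",
) -> FrameStack:
    """Load a multi-page TIFF movie into a FrameStack.

    ``page_order`` controls how pages map to (frame, channel):
    ``channel_interleaved`` expects c1f1, c2f1, c1f2, ...;
    ``channel_blocked`` expects all of channel 1 first, then channel 2, etc.
    Pixel values are cast to float64 without rescaling.
    """
    if page_order not in PAGE_ORDERS:
        raise InputError(f"page_order must be one of {PAGE_ORDERS}, got {page_order!r}")
    pages = _read_pages(path)
    n_pages = pages.shape[0]
    if n_pages % n_channels != 0:
        raise InputError(
            f"page count {n_pages} is not divisible by n_channels {n_channels}"
        )
    n_frames = n_pages // n_channels
    if page_order == "channel_interleaved":
        data = pages.reshape(n_frames, n_channels, *pages.shape[1:])
    else:
        data = pages.reshape(n_channels, n_frames, *pages.shape[1:]).transpose(1, 0, 2, 3)
    return FrameStack(data.astype(np.float64))


def load_mask_stack(path: str | Path, image: FrameStack) -> MaskStack:
    """Load a binary mask TIFF and validate it against its paired movie.

    Any nonzero pixel becomes foreground (1).
    """
    pages = _read_pages(path)
    if pages.shape[0] != image.n_frames:
        raise InputError(
            f"mask has {pages.shape[0]} frames but image has {image.n_frames}"
        )
    if pages.shape[1:] != (image.height, image.width):
        raise InputError(
            f"mask frame shape {pages.shape[1:]} does not match "
            f"image frame shape {(image.height, image.width)}"
        )
    return MaskStack(pages)


def write_image_stack(
    stack: FrameStack, path: str | Path, page_order: str = "channel_interleaved"
) -> Path:
    """Write a FrameStack as a multi-page grayscale TIFF (float32 pages)."""
    if page_order not in PAGE_ORDERS:
        raise InputError(f"page_order must be one of {PAGE_ORDERS}, got {page_order!r}")
    data = stack.data
    if page_order == "channel_interleaved":
        pages = data.reshape(stack.n_frames * stack.n_channels, stack.height, stack.width)
    else:
        pages = data.transpose(1, 0, 2, 3).reshape(
            stack.n_channels * stack.n_frames, stack.height, stack.width
        )
    path = Path(path)
    tifffile.imwrite(path, pages.astype(np.float32), photometric="minisblack")
    return path


def write_mask_stack(mask: MaskStack, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, mask.data * np.uint8(255), photometric="minisblack")
    return path


_XLSX_EPOCH = datetime.datetime(2000, 1, 1)


def write_spreadsheet(sheets: dict[str, pd.DataFrame], path: str | Path) -> Path:
    """Write one workbook with one sheet per DataFrame, deterministically.

    openpyxl stamps workbooks with the wall-clock time both in the document
    properties and in the zip member headers; identical runs would otherwise
    differ byte-wise. Properties and zip timestamps are pinned to a fixed
    epoch so that identical data produces identical files.
    """
    path = Path(path)
    buf = io.BytesIO()
    with pd.ExcelWriter(buf, engine="openpyxl") as writer:
        for name, df in sheets.items():
            df.to_excel(writer, sheet_name=name, index=True)
        props = writer.book.properties
        props.created = _XLSX_EPOCH
        props.modified = _XLSX_EPOCH
    buf.seek(0)
    out = io.BytesIO()
    with zipfile.ZipFile(buf) as zin, zipfile.ZipFile(
        out, "w", zipfile.ZIP_DEFLATED
    ) as zout:
        for name in sorted(zin.namelist()):
            payload = zin.read(name)
            if name == "docProps/core.xml":
                # openpyxl stamps dcterms:created/modified at save time
                payload = re.sub(
                    rb"(<dcterms:(created|modified)[^>]*>)[^<]*(</dcterms:)",
                    rb"\g<1>2000-01-01T00:00:00Z\g<3>",
                    payload,
                )
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zout.writestr(info, payload)
    path.write_bytes(out.getvalue())
    return path


@dataclass
class OutputLayout:
    """Resolved output directories for one run."""

    root: Path
    processed: Path
    temporary: Path

    @classmethod
    def create(
        cls,
        out_root: str | Path,
        processed_name: str = PROCESSED_DIR,
        temp_name: str = TEMP_DIR,
    ) -> "OutputLayout":
        root = Path(out_root)
        processed = root / processed_name
        temporary = root / temp_name
        try:
            processed.mkdir(parents=True, exist_ok=True)
            temporary.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"output root {root} is not writable: {exc}") from exc
        return cls(root=root, processed=processed, temporary=temporary)


@dataclass
class ChannelResult:
    """Everything the pipeline produced for one channel."""

    channel: int
    kymograph: "object"  # memkymo.kymograph.Kymograph


@dataclass
class RunManifest:
    """Paths of every artifact written by a run."""

    files: list[Path] = field(default_factory=list)

    def add(self, path: str | Path) -> Path:
        p = Path(path)
        self.files.append(p)
        return p

    def extend(self, paths) -> None:
        for p in paths:
            self.add(p)

    def __iter__(self):
        return iter(self.files)

    def __len__(self) -> int:
        return len(self.files)


def write_outputs(
    results: list[ChannelResult],
    out_root: str | Path,
    render_spec=None,
    preview_paths: list[Path] | None = None,
    run_log: str | None = None,
    processed_name: str = PROCESSED_DIR,
    temp_name: str = TEMP_DIR,
) -> RunManifest:
    """Write per-channel kymograph arrays, spreadsheets, and figures.

    Creates the processed-data and temporary-images directories under
    ``out_root``; filenames embed the channel index. Figures are rendered only
    when ``render_spec`` requests at least one format. Returns a manifest
    listing every file written.
    """
    from . import viz  # local import: viz pulls in matplotlib

    layout = OutputLayout.create(out_root, processed_name, temp_name)
    manifest = RunManifest()
    for res in results:
        k = res.kymograph
        c = res.channel
        raw_path = layout.processed / f"kymograph_ch{c}_raw.npy"
        np.save(raw_path, k.raw)
        manifest.add(raw_path)
        norm_path = layout.processed / f"kymograph_ch{c}_normalized.npy"
        np.save(norm_path, k.normalized)
        manifest.add(norm_path)

        def _df(mat: np.ndarray) -> pd.DataFrame:
            return pd.DataFrame(
                mat,
                index=pd.RangeIndex(mat.shape[0], name="membrane_position"),
                columns=pd.RangeIndex(mat.shape[1], name="frame"),
            )

        xlsx_path = layout.processed / f"kymograph_ch{c}.xlsx"
        write_spreadsheet(
            {
                "raw": _df(k.raw),
                "smoothed": _df(k.smoothed),
                "normalized": _df(k.normalized),
            },
            xlsx_path,
        )
        manifest.add(xlsx_path)
        if render_spec is not None and render_spec.formats:
            fig_paths = viz.render_kymograph(
                k.normalized,
                render_spec,
                layout.processed / f"kymograph_ch{c}",
            )
            manifest.extend(fig_paths)
    if preview_paths:
        manifest.extend(preview_paths)
    if run_log is not None:
        log_path = layout.processed / "run_log.txt"
        log_path.write_text(run_log)
        manifest.add(log_path)
    return manifest
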