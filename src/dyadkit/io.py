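"""Calibrated image containers and sidecar-metadata TIFF I/O.

Images are stored as single-page grayscale TIFF with a JSON sidecar holding
the physical calibration ({pixel_size_um, line_interval_ms, pacing_times_s,
axis order}).  Metadata lives in the sidecar rather than TIFF tags so it is
dialect-free and diff-able.

Coordinate convention used across the package: 0-based pixel indices, with
the physical coordinate of a pixel center = (index + 0.5) * pixel_size.
Kymographs are (space, time): rows are spatial pixels, columns are scan
lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

FLOAT_FMT = "%.9g"  # all floating-point outputs: 9 significant digits

_ALLOWED_DTYPES = ("uint8", "uint16", "uint32", "float32")


@dataclass
class FluorescenceImage:
    """Calibrated 2-D fluorescence intensity field."""

    pixels: np.ndarray
    pixel_size_um: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixels.shape[0] < 16 or self.pixels.shape[1] < 16:
            raise ValueError("image must be at least 16 x 16 pixels")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(np.asarray(self.pixels, dtype=float) < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LineScanKymograph:
    """Space x time line-scan recording.

    Rows are spatial pixels along the scanned line, columns are successive
    scan lines separated by ``line_interval_ms``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    line_interval_ms: float
    pacing_times_s: list[float] = field(default_factory=list)
    dye_label: str = ""
    caffeine_time_s: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D (space x time) array")
        if self.line_interval_ms <= 0:
            raise ValueError("line_interval_ms must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if np.any(np.asarray(self.pixels, dtype=float) < 0):
            raise ValueError("intensities must be non-negative")
        dur = self.duration_s
        if any(t < 0 or t > dur for t in self.pacing_times_s):
            raise ValueError("pacing times must lie within the scan duration")

    @property
    def n_space(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_time(self) -> int:
        return self.pixels.shape[1]

    @property
    def scan_length_um(self) -> float:
        return self.n_space * self.pixel_size_um

    @property
    def duration_s(self) -> float:
        return self.n_time * self.line_interval_ms / 1000.0

    def positions_um(self) -> np.ndarray:
        return (np.arange(self.n_space) + 0.5) * self.pixel_size_um

    def times_s(self) -> np.ndarray:
        return (np.arange(self.n_time) + 0.5) * self.line_interval_ms / 1000.0


def _meta_path(path: Path, meta_path: str | Path | None) -> Path:
    if meta_path is not None:
        return Path(meta_path)
    return Path(path).with_suffix(".json")


def write_image(obj: FluorescenceImage | LineScanKymograph,
                path: str | Path, meta_path: str | Path | None = None) -> Path:
    """Write a calibrated image as 16-bit TIFF + JSON sidecar; returns sidecar path."""
    path = Path(path)
    pix = np.asarray(obj.pixels)
    if pix.dtype not in (np.uint8, np.uint16):
        pix = np.clip(np.rint(pix), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, pix)
    if isinstance(obj, LineScanKymograph):
        meta = {
            "kind": "linescan",
            "axis_order": ["space", "time"],
            "pixel_size_um": obj.pixel_size_um,
            "line_interval_ms": obj.line_interval_ms,
            "pacing_times_s": list(map(float, obj.pacing_times_s)),
            "dye_label": obj.dye_label,
            "caffeine_time_s": obj.caffeine_time_s,
            "shape": list(pix.shape),
        }
    else:
        meta = {
            "kind": "image",
            "axis_order": ["y", "x"],
            "pixel_size_um": obj.pixel_size_um,
            "channel_label": obj.channel_label,
            "shape": list(pix.shape),
        }
    mp = _meta_path(path, meta_path)
    mp.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
    return mp


def read_image(path: str | Path,
               meta_path: str | Path | None = None
               ) -> FluorescenceImage | LineScanKymograph:
    """Read a TIFF + sidecar pair back into a calibrated object.

    A missing pixel size is an error: physical calibration is never assumed.
    """
    path = Path(path)
    pix = tifffile.imread(path)
    if pix.dtype.name not in _ALLOWED_DTYPES:
        raise ValueError(f"unsupported TIFF bit depth / dtype: {pix.dtype}")
    mp = _meta_path(path, meta_path)
    if not mp.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {mp}")
    meta = json.loads(mp.read_text())
    if "pixel_size_um" not in meta:
        raise ValueError("metadata lacks pixel_size_um")
    if "shape" in meta and list(pix.shape) != list(meta["shape"]):
        raise ValueError("TIFF shape does not match metadata shape")
    if meta.get("kind") == "linescan":
        return LineScanKymograph(
            pixels=pix,
            pixel_size_um=float(meta["pixel_size_um"]),
            line_interval_ms=float(meta["line_interval_ms"]),
            pacing_times_s=list(meta.get("pacing_times_s", [])),
            dye_label=meta.get("dye_label", ""),
            caffeine_time_s=meta.get("caffeine_time_s"),
        )
    return FluorescenceImage(
        pixels=pix,
        pixel_size_um=float(meta["pixel_size_um"]),
        channel_label=meta.get("channel_label", ""),
    )


def write_csv(df, path: str | Path) -> None:
    """CSV writer with the package-wide dialect (UTF-8, '.' decimal, %.9g floats)."""
    df.to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def config_to_dict(cfg) -> dict:
    if dataclasses.is_dataclass(cfg):
        return dataclasses.asdict(cfg)
    return dict(cfg)
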