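"""Raw transient-signal IO and image reconstruction.

The mass cytometer exports each acquisition as delimited text: one row per
*push* (one time-of-flight cycle, i.e. one laser spot), one column per mass
channel, values in ion counts.  Counts may be non-integer because of the
detector's dual (pulse/analog) counting calibration.  A sidecar file
records the scan geometry — image width/height in spots and whether the
raster is unidirectional or serpentine — which the file itself does not
carry.

Reconstruction maps push order back onto pixel coordinates line scan by
line scan: push ``k`` lands on row ``k // width``; columns run left-to-right
on every row for a unidirectional raster, and alternate direction on odd
rows for a serpentine one.  Pixel (0, 0) is the first acquired spot.

Partial scans (aborted acquisitions) reconstruct with NaN as the
missing-value sentinel; every downstream statistic ignores NaN pixels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import tifffile
import yaml

from .errors import DataError, GeometryError, RawFormatError
from .panel import Panel, normalize_channel_name, split_channel_name

SCAN_PATTERNS = ("unidirectional", "serpentine")

#: Missing-value sentinel for unacquired pixels in partial scans.
MISSING = float("nan")


@dataclass(frozen=True)
class ScanGeometry:
    width: int
    height: int
    scan_pattern: str = "unidirectional"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise GeometryError(f"non-positive geometry {self.width}x{self.height}")
        if self.scan_pattern not in SCAN_PATTERNS:
            raise GeometryError(f"unknown scan pattern {self.scan_pattern!r}")

    @property
    def n_pixels(self) -> int:
        return self.width * self.height


@dataclass
class RawScan:
    """Push-indexed table of ion counts, one column per mass channel."""

    push_index: np.ndarray          # (n,) int
    counts: np.ndarray              # (n, n_channels) float
    channels: list[str]
    geometry: ScanGeometry
    source: Optional[str] = None

    def __post_init__(self) -> None:
        self.push_index = np.asarray(self.push_index, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.channels):
            raise RawFormatError("counts shape inconsistent with channel list")
        if self.push_index.shape[0] != self.counts.shape[0]:
            raise RawFormatError("push index and counts row counts differ")
        if np.any(np.diff(self.push_index) <= 0):
            raise RawFormatError("push indices must be strictly increasing")

    @property
    def n_pushes(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class ChannelMeta:
    name: str
    element: Optional[str] = None
    mass: Optional[int] = None
    marker: Optional[str] = None
    role: Optional[str] = None

    @classmethod
    def from_name(cls, name: str, panel: Optional[Panel] = None) -> "ChannelMeta":
        name = normalize_channel_name(name)
        if panel is not None:
            try:
                e = panel.entry_for_channel(name)
                elem, mass = split_channel_name(e.channel_name)
                return cls(e.channel_name, elem, mass, e.marker, e.role)
            except Exception:
                pass
        elem, mass = split_channel_name(name)
        return cls(name, elem, mass)


@dataclass
class MultichannelImage:
    """Reconstructed height x width x channels ion-count image."""

    data: np.ndarray                      # (H, W, C) float64; NaN = not acquired
    channel_meta: list[ChannelMeta]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise DataError("image data must be H x W x C")
        if self.data.shape[2] != len(self.channel_meta):
            raise DataError("channel metadata length does not match channel axis")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.data) < 0:
                raise DataError("ion counts must be non-negative")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def channel_names(self) -> list[str]:
        return [m.name for m in self.channel_meta]

    def channel_index(self, name: str) -> int:
        key = normalize_channel_name(name)
        try:
            return self.channel_names.index(key)
        except ValueError:
            raise DataError(f"channel {name!r} not in image "
                            f"(have {self.channel_names})") from None

    def channel(self, name: str) -> np.ndarray:
        """Read-only 2-D view of one channel."""
        view = self.data[:, :, self.channel_index(name)]
        view.flags.writeable = False
        return view

    def channels_by_role(self, role: str) -> list[str]:
        return [m.name for m in self.channel_meta if m.role == role]

    def copy(self) -> "MultichannelImage":
        return MultichannelImage(self.data.copy(), list(self.channel_meta),
                                 dict(self.provenance))


# ---------------------------------------------------------------------------
# sidecar
# ---------------------------------------------------------------------------

def write_sidecar(path, geometry: ScanGeometry, channels: Sequence[str],
                  **extra) -> None:
    """Write a flat key-value sidecar (YAML) describing a raw scan."""
    doc = {
        "width": int(geometry.width),
        "height": int(geometry.height),
        "scan_pattern": geometry.scan_pattern,
        "n_channels": len(channels),
        "channels": list(channels),
    }
    doc.update({k: v for k, v in extra.items() if v is not None})
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_sidecar(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "width" not in doc or "height" not in doc:
        raise RawFormatError(f"sidecar {path} lacks width/height keys")
    return doc


def _geometry_from(sidecar: Union[str, Path, Mapping, ScanGeometry]) -> tuple[ScanGeometry, dict]:
    if isinstance(sidecar, ScanGeometry):
        return sidecar, {}
    if isinstance(sidecar, (str, Path)):
        doc = read_sidecar(sidecar)
    elif isinstance(sidecar, Mapping):
        doc = dict(sidecar)
    else:
        raise TypeError(f"cannot interpret sidecar of type {type(sidecar)!r}")
    geom = ScanGeometry(int(doc["width"]), int(doc["height"]),
                        doc.get("scan_pattern", "unidirectional"))
    return geom, doc


# ---------------------------------------------------------------------------
# raw text parsing
# ---------------------------------------------------------------------------

def read_raw_scan(path, sidecar, *, allow_partial: bool = False) -> RawScan:
    """Parse a transient-signal text export into a :class:`RawScan`.

    Parameters
    ----------
    path : path to the tab-separated export.  The first row holds channel
        names; an optional leading ``Push`` column is auto-detected.
    sidecar : path, mapping or :class:`ScanGeometry` providing the scan
        geometry.
    allow_partial : accept files with fewer rows than ``width*height``
        (aborted scans).  Without it a row-count mismatch is an error.
    """
    geometry, doc = _geometry_from(sidecar)
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise RawFormatError(f"{path}: empty file")
        cols = header.rstrip("\n").split("\t")
        has_push = cols[0].strip().lower() in ("push", "push_index", "pushnumber", "push number")
        channels = [normalize_channel_name(c) for c in (cols[1:] if has_push else cols)]
        if not channels:
            raise RawFormatError(f"{path}: no channel columns in header")
        ncol = len(cols)
        rows: list[list[float]] = []
        pushes: list[int] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol:
                raise RawFormatError(
                    f"{path}: line {lineno}: expected {ncol} columns, got {len(parts)}")
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise RawFormatError(f"{path}: line {lineno}: {exc}") from None
            if has_push:
                pushes.append(int(vals[0]))
                vals = vals[1:]
            else:
                pushes.append(len(pushes))
            if min(vals) < 0:
                raise RawFormatError(f"{path}: line {lineno}: negative ion count")
            rows.append(vals)
    counts = np.asarray(rows, dtype=np.float64)
    if counts.size == 0:
        counts = counts.reshape(0, len(channels))
    n = counts.shape[0]
    if n != geometry.n_pixels and not allow_partial:
        raise GeometryError(
            f"{path}: {n} pushes but geometry {geometry.width}x{geometry.height} "
            f"expects {geometry.n_pixels} (pass allow_partial to accept)")
    if n > geometry.n_pixels:
        raise GeometryError(f"{path}: more pushes ({n}) than pixels ({geometry.n_pixels})")
    extra = {k: doc[k] for k in ("mouse_id", "group", "image_id") if k in doc}
    scan = RawScan(np.asarray(pushes), counts, channels, geometry, source=str(path))
    scan.meta = extra  # type: ignore[attr-defined]
    return scan


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def push_to_pixel(k: np.ndarray, geometry: ScanGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Map push numbers to (row, col) pixel coordinates for the geometry."""
    k = np.asarray(k)
    rows = k // geometry.width
    cols = k % geometry.width
    if geometry.scan_pattern == "serpentine":
        odd = (rows % 2) == 1
        cols = np.where(odd, geometry.width - 1 - cols, cols)
    return rows, cols


def reconstruct(raw: RawScan, panel: Optional[Panel] = None,
                *, allow_partial: bool = False) -> MultichannelImage:
    """Rebuild the per-channel image from push order, line scan by line scan."""
    geom = raw.geometry
    n = raw.n_pushes
    if n != geom.n_pixels and not allow_partial:
        raise GeometryError(f"scan has {n} pushes; geometry expects {geom.n_pixels}")
    data = np.full((geom.height, geom.width, len(raw.channels)), MISSING)
    rows, cols = push_to_pixel(raw.push_index, geom)
    if rows.size and rows.max() >= geom.height:
        raise GeometryError("push index exceeds image extent")
    data[rows, cols, :] = raw.counts
    meta = [ChannelMeta.from_name(c, panel) for c in raw.channels]
    prov = {"source": raw.source, "width": geom.width, "height": geom.height,
            "scan_pattern": geom.scan_pattern}
    prov.update(getattr(raw, "meta", {}))
    return MultichannelImage(data, meta, prov)


# ---------------------------------------------------------------------------
# TIC and overlays
# ---------------------------------------------------------------------------

def compute_tic(image: MultichannelImage,
                exclude_roles: Sequence[str] = ("background",),
                exclude_channels: Sequence[str] = ()) -> np.ndarray:
    """Total ion current per pixel: sum of counts over included channels.

    The background channel (xenon) is excluded by default since it carries
    no tissue contrast.  Returns a 2-D float array; pixels that were never
    acquired are NaN.
    """
    excl = {normalize_channel_name(c) for c in exclude_channels}
    idx = [i for i, m in enumerate(image.channel_meta)
           if m.role not in exclude_roles and m.name not in excl]
    if not idx:
        raise DataError("all channels excluded from TIC")
    sub = image.data[:, :, idx]
    tic = np.nansum(sub, axis=2)
    tic[np.all(np.isnan(sub), axis=2)] = MISSING
    return tic


def _parse_color(color) -> np.ndarray:
    if isinstance(color, str):
        s = color.lstrip("#")
        if len(s) != 6:
            raise ValueError(f"cannot parse color {color!r}")
        return np.array([int(s[i:i + 2], 16) for i in (0, 2, 4)], dtype=float) / 255.0
    arr = np.asarray(color, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"cannot parse color {color!r}")
    if arr.max() > 1:
        arr = arr / 255.0
    return arr


def render_overlay(image: MultichannelImage,
                   channel_colors: Mapping[str, object],
                   clip_percentile: float = 99.0) -> np.ndarray:
    """Additive RGB overlay of selected channels.

    Each channel is clipped at its *clip_percentile*, min-max scaled to
    [0, 1], multiplied by its RGB color and summed; the result is clipped
    to [0, 1].  Deterministic; NaN pixels render black.
    """
    if not channel_colors:
        raise DataError("no channels selected for overlay")
    h, w = image.height, image.width
    rgb = np.zeros((h, w, 3), dtype=np.float64)
    for name, color in channel_colors.items():
        chan = np.array(image.channel(name), dtype=float)
        col = _parse_color(color)
        finite = np.isfinite(chan)
        chan = np.where(finite, chan, 0.0)
        if finite.any():
            hi = np.percentile(chan[finite], clip_percentile)
            lo = float(chan[finite].min())
        else:
            hi, lo = 1.0, 0.0
        if hi <= lo:
            # degenerate range: constant positive renders at full intensity
            scaled = (chan > 0).astype(float)
        else:
            scaled = np.clip((chan - lo) / (hi - lo), 0.0, 1.0)
        rgb += scaled[:, :, None] * col[None, None, :]
    return np.clip(rgb, 0.0, 1.0)


def save_overlay_png(rgb: np.ndarray, path) -> None:
    import imageio.v3 as iio
    iio.imwrite(Path(path), (np.clip(rgb, 0, 1) * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# multichannel TIFF
# ---------------------------------------------------------------------------

def write_multichannel_tiff(image: MultichannelImage, path) -> None:
    """One 32-bit float page per channel; channel metadata as JSON page description."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for i, meta in enumerate(image.channel_meta):
            desc = json.dumps({
                "name": meta.name, "element": meta.element, "mass": meta.mass,
                "marker": meta.marker, "role": meta.role,
            })
            tif.write(image.data[:, :, i].astype(np.float32), description=desc,
                      contiguous=False)


def read_multichannel_tiff(path) -> MultichannelImage:
    path = Path(path)
    pages_data = []
    metas = []
    with tifffile.TiffFile(path) as tif:
        for page in tif.pages:
            desc = page.description
            if not desc:
                raise DataError(f"{path}: TIFF page lacks channel metadata")
            try:
                d = json.loads(desc)
            except json.JSONDecodeError:
                raise DataError(f"{path}: TIFF page description is not valid metadata")
            metas.append(ChannelMeta(d["name"], d.get("element"), d.get("mass"),
                                     d.get("marker"), d.get("role")))
            pages_data.append(page.asarray().astype(np.float64))
    if not pages_data:
        raise DataError(f"{path}: empty TIFF")
    data = np.stack(pages_data, axis=2)
    return MultichannelImage(data, metas, {"source": str(path)})
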