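"""Reading multi-channel microscopy images, intensity normalisation and output writing.

Input containers are multi-plane TIFF / OME-TIFF files (8/12/16-bit grayscale
planes).  A :class:`ChannelMapping` assigns planes to roles: exactly one
counterstain channel (DAPI) and any number of named marker channels.  All
downstream computation happens on intensities normalised to [0, 1]; integer
images are divided by the full scale of their dtype (``2**b - 1``) so that
absolute thresholds such as the 0.1 marker floor keep their meaning across
images acquired with the same gain and exposure.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.morphology import binary_erosion
from skimage.segmentation import find_boundaries


class ImageIOError(ValueError):
    """Raised for unreadable inputs, bad channel mappings or shape mismatches."""


#: colour cycle for marker contours in overlays (RGB, uint8)
MARKER_COLOURS: tuple[tuple[int, int, int], ...] = (
    (255, 0, 0),
    (0, 255, 0),
    (0, 128, 255),
    (255, 0, 255),
    (0, 255, 255),
    (255, 255, 0),
)


@dataclass(frozen=True)
class RawImage:
    """One plane of an acquisition, as read from disk (arbitrary bit depth)."""

    pixels: np.ndarray
    source_path: str = "<memory>"
    channel_index: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ImageIOError(f"{self.source_path}: plane must be a 2-D grid, got shape {p.shape}")
        if self.channel_index < 0:
            raise ImageIOError("channel_index must be >= 0")


@dataclass(frozen=True)
class ChannelImage:
    """A normalised intensity field z(x) in [0, 1] with a channel role.

    ``role`` is ``"counterstain"`` for the nucleus-delineating channel (DAPI)
    and ``"marker"`` for nuclear-protein channels scored within nuclei.
    """

    z: np.ndarray
    role: str
    name: str

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if self.role not in ("counterstain", "marker"):
            raise ImageIOError(f"unknown channel role {self.role!r}")
        if z.ndim != 2:
            raise ImageIOError(f"channel {self.name}: expected 2-D grid, got shape {z.shape}")
        if z.size and (z.min() < 0.0 or z.max() > 1.0):
            raise ImageIOError(f"channel {self.name}: intensities outside [0, 1]")
        object.__setattr__(self, "z", z)

    @property
    def shape(self) -> tuple[int, int]:
        return self.z.shape


@dataclass(frozen=True)
class ChannelMapping:
    """Assignment of plane indices to the counterstain and named markers."""

    counterstain_channel: int
    marker_channels: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_channels", tuple((int(i), str(n)) for i, n in self.marker_channels))
        indices = [self.counterstain_channel] + [i for i, _ in self.marker_channels]
        if any(i < 0 for i in indices):
            raise ImageIOError("channel indices must be >= 0")
        if len(set(indices)) != len(indices):
            raise ImageIOError("channel indices must be distinct")

    @property
    def max_index(self) -> int:
        return max([self.counterstain_channel] + [i for i, _ in self.marker_channels])

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(n for _, n in self.marker_channels)


def normalize_intensities(raw: RawImage, mode: str = "dtype") -> np.ndarray:
    """Scale a raw plane to [0, 1].

    Integer planes are divided by the dtype full scale (``2**b - 1``), so a
    16-bit image saturating at 65535 maps to 1.0 and dim images stay dim —
    this keeps absolute thresholds (the 0.1 marker floor) meaningful.  With
    ``mode="minmax"`` integer planes are instead min-max rescaled per image.
    Real-valued planes already inside [0, 1] pass through unchanged; real
    planes outside that range are min-max rescaled.  Idempotent on output.
    Negative intensities are an error; constant-zero planes are permitted.
    """
    if mode not in ("dtype", "minmax"):
        raise ImageIOError(f"unknown normalisation mode {mode!r}")
    p = np.asarray(raw.pixels)
    if p.size and p.min() < 0:
        raise ImageIOError(f"{raw.source_path}: negative intensities")
    p = p.astype(float)
    if np.issubdtype(np.asarray(raw.pixels).dtype, np.integer):
        if mode == "dtype":
            full_scale = float(np.iinfo(np.asarray(raw.pixels).dtype).max)
            return p / full_scale
        return _minmax(p)
    # real-valued input
    if p.size == 0 or (p.min() >= 0.0 and p.max() <= 1.0):
        return p
    return _minmax(p)


def _minmax(p: np.ndarray) -> np.ndarray:
    lo, hi = float(p.min()), float(p.max())
    if hi == lo:
        return np.zeros_like(p)
    return (p - lo) / (hi - lo)


def _read_planes(path: Path) -> np.ndarray:
    """Read a TIFF/OME-TIFF (or LIF, when the optional adapter is present) as (planes, H, W)."""
    if path.suffix.lower() == ".lif":
        try:
            from readlif.reader import LifFile  # optional adapter
        except ImportError as exc:
            raise ImageIOError(f"{path}: LIF container requires the optional 'readlif' adapter") from exc
        lif = LifFile(str(path))
        image = lif.get_image(0)
        planes = [np.asarray(image.get_frame(z=0, t=0, c=c)) for c in range(image.channels)]
        return np.stack(planes)
    try:
        arr = tifffile.imread(str(path))
    except (FileNotFoundError, OSError, ValueError) as exc:
        raise ImageIOError(f"{path}: cannot read TIFF ({exc})") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ImageIOError(f"{path}: expected grayscale planes, got shape {arr.shape}")
    return arr


def read_multichannel(path: str | Path, mapping: ChannelMapping, mode: str = "dtype") -> list[ChannelImage]:
    """Read the mapped channels of one acquisition, normalised to [0, 1].

    Returns the counterstain channel first, then markers in mapping order.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"{path}: no such file")
    planes = _read_planes(path)
    if mapping.max_index >= planes.shape[0]:
        raise ImageIOError(
            f"{path}: channel index out of range (file has {planes.shape[0]} plane(s), "
            f"mapping requests index {mapping.max_index})"
        )
    if len({p.shape for p in planes}) != 1:
        raise ImageIOError(f"{path}: planes of unequal shape")
    channels = [
        ChannelImage(
            normalize_intensities(RawImage(planes[mapping.counterstain_channel], str(path), mapping.counterstain_channel), mode),
            "counterstain",
            "DAPI",
        )
    ]
    for idx, name in mapping.marker_channels:
        channels.append(ChannelImage(normalize_intensities(RawImage(planes[idx], str(path), idx), mode), "marker", name))
    return channels


def write_counts_csv(records: Sequence, out_dir: str | Path, timestamp: _dt.datetime | None = None) -> Path:
    """Write one CSV row per image: image name, nucleus count, marker counts.

    The filename carries an ISO-8601 timestamp: ``fins_counts_<stamp>.csv``.
    """
    if not records:
        raise ImageIOError("no count records to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = (timestamp or _dt.datetime.now()).strftime("%Y%m%dT%H%M%S")
    out_path = out_dir / f"fins_counts_{stamp}.csv"
    header = ["image_name", "DAPI"] + [name for name, _ in records[0].marker_counts]
    lines = [",".join(header)]
    for rec in records:
        row = [rec.image_name, str(rec.n_nuclei)] + [str(c) for _, c in rec.marker_counts]
        lines.append(",".join(row))
    out_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out_path


def render_overlay(
    channels: Sequence[ChannelImage],
    labels,
    positives: Mapping[str, frozenset[int] | set[int]],
    out_path: str | Path,
) -> Path:
    """Render the segmented nuclear regions with contours on marker-positive nuclei.

    The binary foreground is drawn in grey on black; for marker ``k`` (in
    ``positives`` order) the boundary of each positive nucleus, eroded ``k``
    times so overlapping annotations stay distinguishable, is drawn in the
    ``k``-th colour of :data:`MARKER_COLOURS`.  Deterministic for fixed input.
    """
    out_path = Path(out_path)
    shape = labels.label_map.shape
    for ch in channels:
        if ch.shape != shape:
            raise ImageIOError(f"channel {ch.name}: shape {ch.shape} does not match labels {shape}")
    rgb = np.zeros(shape + (3,), dtype=np.uint8)
    rgb[labels.label_map > 0] = (200, 200, 200)
    for k, (name, ids) in enumerate(positives.items()):
        colour = MARKER_COLOURS[k % len(MARKER_COLOURS)]
        for i in sorted(ids):
            region = labels.label_map == i
            for _ in range(k):
                region = binary_erosion(region)
            rgb[find_boundaries(region, mode="inner")] = colour
    out_path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_path, rgb)
    return out_path
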