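"""Per-nucleus marker positivity counting.

Each marker channel gets one global Otsu threshold with a floor of 0.1 (on
the normalised [0,1] scale); a nucleus is positive for a marker when any of
its pixels exceeds that threshold strictly.  Signal outside the segmented
nuclear foreground is ignored entirely, and foci multiplicity within a
nucleus is not quantified — the readout is binary presence/absence, so each
marker count is at most the nucleus count n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from fins.image_io import ChannelImage, ChannelMapping
from fins.segmentation import (
    DegenerateImageError,
    NucleusLabels,
    SolverParams,
    otsu_threshold,
    segment_nuclei,
)

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 0.1


@dataclass(frozen=True)
class MarkerThreshold:
    """Global threshold for one marker channel; ``floored`` records whether
    the 0.1 floor overrode the Otsu value (including the degenerate constant
    channel, where Otsu is undefined)."""

    t: float
    floored: bool
    channel_name: str


@dataclass(frozen=True)
class CountRecord:
    """Counts for one image: total nuclei and positives per marker."""

    image_name: str
    n_nuclei: int
    marker_counts: tuple[tuple[str, int], ...]
    positive_region_ids: tuple[tuple[str, frozenset[int]], ...] = ()

    def __post_init__(self) -> None:
        for name, count in self.marker_counts:
            if not 0 <= count <= self.n_nuclei:
                raise ValueError(f"{self.image_name}: {name} count {count} outside 0..{self.n_nuclei}")
        ids = dict(self.positive_region_ids)
        for name, count in self.marker_counts:
            if name in ids and len(ids[name]) != count:
                raise ValueError(f"{self.image_name}: {name} count inconsistent with positive ids")


def marker_threshold(z: ChannelImage | np.ndarray, floor: float = DEFAULT_FLOOR, channel_name: str = "") -> MarkerThreshold:
    """max(Otsu, floor) for a marker channel; a degenerate histogram falls back to the floor."""
    try:
        t_otsu = otsu_threshold(z)
    except DegenerateImageError:
        return MarkerThreshold(t=floor, floored=True, channel_name=channel_name)
    if t_otsu < floor:
        return MarkerThreshold(t=floor, floored=True, channel_name=channel_name)
    return MarkerThreshold(t=float(t_otsu), floored=False, channel_name=channel_name)


def count_positive_nuclei(
    z: ChannelImage | np.ndarray,
    labels: NucleusLabels,
    t: MarkerThreshold | float,
) -> tuple[int, frozenset[int]]:
    """Count nuclei containing any strictly supra-threshold marker signal.

    Nucleus i is positive iff max over its pixels of z exceeds t strictly;
    returns the count and the set of positive nucleus labels.
    """
    arr = z.z if isinstance(z, ChannelImage) else np.asarray(z, dtype=float)
    if arr.shape != labels.label_map.shape:
        raise ValueError(f"marker shape {arr.shape} does not match labels {labels.label_map.shape}")
    threshold = t.t if isinstance(t, MarkerThreshold) else float(t)
    if labels.n == 0:
        return 0, frozenset()
    peaks = ndimage.maximum(arr, labels=labels.label_map, index=np.arange(1, labels.n + 1))
    positive = np.flatnonzero(np.asarray(peaks) > threshold) + 1
    return int(positive.size), frozenset(int(i) for i in positive)


def analyze_image(
    channels: list[ChannelImage],
    mapping: ChannelMapping,
    params: SolverParams = SolverParams(),
    image_name: str = "",
    floors: dict[str, float] | None = None,
    min_area: int = 0,
    connectivity: int = 8,
) -> tuple[CountRecord, NucleusLabels]:
    """Run the full pipeline on one acquisition, returning counts and labels.

    Segments nuclei from the counterstain, then thresholds and scores each
    marker channel within the nuclear regions.  ``channels`` follows the
    order produced by :func:`fins.image_io.read_multichannel` (counterstain
    first, then markers in mapping order).  A degenerate (constant)
    counterstain yields an all-zero record and a log warning rather than an
    error, so one blank image cannot abort a batch.
    """
    expected = 1 + len(mapping.marker_channels)
    if len(channels) != expected:
        raise ValueError(f"{image_name}: expected {expected} channels for mapping, got {len(channels)}")
    counterstain, markers = channels[0], channels[1:]
    floors = floors or {}
    try:
        labels, u_star, t_delta = segment_nuclei(counterstain, params, min_area=min_area, connectivity=connectivity)
        logger.info(
            "%s: t_delta=%.4f n=%d iterations=%d converged=%s",
            image_name, t_delta, labels.n, u_star.iterations, u_star.converged,
        )
    except DegenerateImageError:
        logger.warning("%s: degenerate counterstain histogram; recording zero counts", image_name)
        labels = NucleusLabels(label_map=np.zeros(counterstain.shape, dtype=np.int32), n=0)
    counts = []
    ids = []
    for ch, (_, name) in zip(markers, mapping.marker_channels):
        mt = marker_threshold(ch, floor=floors.get(name, DEFAULT_FLOOR), channel_name=name)
        count, pos = count_positive_nuclei(ch, labels, mt)
        logger.info("%s: marker %s t=%.4f floored=%s positive=%d/%d", image_name, name, mt.t, mt.floored, count, labels.n)
        counts.append((name, count))
        ids.append((name, pos))
    record = CountRecord(
        image_name=image_name,
        n_nuclei=labels.n,
        marker_counts=tuple(counts),
        positive_region_ids=tuple(ids),
    )
    return record, labels


def process_image(
    channels: list[ChannelImage],
    mapping: ChannelMapping,
    params: SolverParams = SolverParams(),
    image_name: str = "",
    floors: dict[str, float] | None = None,
    min_area: int = 0,
    connectivity: int = 8,
) -> CountRecord:
    """Counts for one acquisition; see :func:`analyze_image` for the pipeline."""
    record, _ = analyze_image(channels, mapping, params, image_name, floors, min_area, connectivity)
    return record
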