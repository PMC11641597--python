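"""Inter-counter concordance metrics for (DAPI, marker) count pairs.

Validation of automated counting against several human raters: for each
image the raters' (DAPI, marker) pairs define a centroid; a counter is
concordant on that image when its Euclidean distance to the centroid is
strictly below the farthest rater's distance.  The percentage of concordant
images is the percentage concordance.  When a count falls outside the
raters' range, the signed excess is reported relative to the nearest range
boundary (max when above, min when below).

Note the metric is asymmetric by construction: the algorithm is compared
against the centroid of all raters, whereas a rater under leave-one-out is
compared against the centroid of the remaining raters only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RaterCountSet:
    """All counts for one image: rater (DAPI, marker) pairs plus the algorithm's pair."""

    image_name: str
    pairs: tuple[tuple[str, int, int], ...]
    algorithm_pair: tuple[int, int]

    def __post_init__(self) -> None:
        for rater, dapi, marker in self.pairs:
            if dapi < 0 or marker < 0:
                raise ValueError(f"{self.image_name}: negative count for rater {rater}")
        if len(self.pairs) < 2:
            raise ValueError(f"{self.image_name}: need >= 2 rater pairs for a centroid")


@dataclass(frozen=True)
class ConcordanceResult:
    """Per-image distances and the resulting percentage concordance."""

    per_image: tuple[tuple[str, float, float, bool], ...]
    percentage: float


def centroid_distance(pairs: Sequence[tuple[float, float]], query: tuple[float, float]) -> float:
    """Euclidean distance from ``query`` to the arithmetic mean of ``pairs``."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] != 2:
        raise ValueError("pairs must be a non-empty sequence of 2-D count pairs")
    centroid = arr.mean(axis=0)
    return float(np.linalg.norm(np.asarray(query, dtype=float) - centroid))


def percentage_concordance(sets: Sequence[RaterCountSet], leave_out: str | None = None) -> ConcordanceResult:
    """Percentage of images where the evaluated counter beats the farthest rater.

    With ``leave_out=None`` the algorithm's pair is evaluated against the
    centroid of all raters; with ``leave_out=<rater id>`` that rater's pair
    is evaluated against the centroid of the remaining raters.  "Within"
    requires the evaluated distance to be strictly below the maximum of the
    reference raters' distances to the same centroid, so an exact tie (as in
    the degenerate all-identical case) counts as non-concordant.
    """
    per_image = []
    n_within = 0
    for s in sets:
        if leave_out is None:
            reference = [(d, m) for _, d, m in s.pairs]
            query = s.algorithm_pair
        else:
            reference = [(d, m) for r, d, m in s.pairs if r != leave_out]
            matches = [(d, m) for r, d, m in s.pairs if r == leave_out]
            if not matches:
                raise ValueError(f"{s.image_name}: rater {leave_out!r} absent")
            query = matches[0]
        if len(reference) < 2:
            raise ValueError(f"{s.image_name}: fewer than 2 raters remain after leave-out")
        d_query = centroid_distance(reference, query)
        d_max = max(centroid_distance(reference, p) for p in reference)
        within = d_query < d_max
        n_within += within
        per_image.append((s.image_name, d_query, d_max, within))
    if not per_image:
        raise ValueError("no rater count sets supplied")
    return ConcordanceResult(
        per_image=tuple(per_image),
        percentage=100.0 * n_within / len(per_image),
    )


def percent_over_range(algorithm_count: int, rater_counts: Sequence[int]) -> float:
    """Signed percentage by which a count falls outside the raters' range.

    Positive when above the range (relative to the maximum rater count),
    negative when below (relative to the minimum), zero when inside.
    """
    counts = list(rater_counts)
    if not counts:
        raise ValueError("rater_counts must be non-empty")
    lo, hi = min(counts), max(counts)
    if hi <= 0:
        raise ValueError("maximum rater count must be positive")
    if algorithm_count > hi:
        return 100.0 * (algorithm_count - hi) / hi
    if algorithm_count < lo:
        return 100.0 * (algorithm_count - lo) / lo
    return 0.0


def load_rater_counts(path: str | Path, marker: str, algorithm_id: str = "FINS", counterstain: str = "DAPI") -> list[RaterCountSet]:
    """Read rater counts from a long-format CSV (image_name, rater_id, channel, count).

    Pairs each counter's counterstain and ``marker`` counts per image; rows
    with ``rater_id == algorithm_id`` become the algorithm pair.
    """
    df = pd.read_csv(path)
    required = {"image_name", "rater_id", "channel", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    sets = []
    for image, group in df.groupby("image_name", sort=True):
        wide = group.pivot_table(index="rater_id", columns="channel", values="count", aggfunc="first")
        if counterstain not in wide.columns or marker not in wide.columns:
            raise ValueError(f"{path}: image {image} lacks {counterstain}/{marker} counts")
        if algorithm_id not in wide.index:
            raise ValueError(f"{path}: image {image} lacks an {algorithm_id} row")
        algo = (int(wide.loc[algorithm_id, counterstain]), int(wide.loc[algorithm_id, marker]))
        pairs = tuple(
            (str(rid), int(row[counterstain]), int(row[marker]))
            for rid, row in wide.drop(index=algorithm_id).iterrows()
        )
        sets.append(RaterCountSet(image_name=str(image), pairs=pairs, algorithm_pair=algo))
    return sets


def write_concordance_csv(result: ConcordanceResult, path: str | Path) -> Path:
    """Write per-image distances and the summary percentage as CSV."""
    path = Path(path)
    df = pd.DataFrame(result.per_image, columns=["image_name", "distance", "max_rater_distance", "within"])
    df.to_csv(path, index=False)
    with path.open("a", encoding="utf-8") as fh:
        fh.write(f"# percentage_concordance,{result.percentage:.6g}\n")
    return path
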