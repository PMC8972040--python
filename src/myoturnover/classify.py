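"""Eight-category classification of myosin incorporation patterns.

A pulse-chase experiment labels pre-existing myosin green and newly
synthesized myosin red.  Per sarcomere, the position(s) of the red peak(s)
relative to the green waveform place the sarcomere into one of eight
patterns: both sides, predominantly right/left side, right/left side,
center, random fashion, or no incorporation.  Side-pattern sarcomeres
additionally yield red-peak-to-center distances, whose distribution over
chase time tracks the inward spread of newly inserted myosin from the
filament tips.

The category names come from the source experiment; the numeric decision
boundaries (zone widths, balance ratio, similarity and signal thresholds)
are this package's own, exposed in :class:`ClassificationRules` and
recorded in every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import CategoryError, InvalidConfigurationError
from .waveform import SarcomereWaveform


class PatternCategory(str, Enum):
    BOTH_SIDES = "both_sides"
    PREDOMINANTLY_RIGHT = "predominantly_right"
    PREDOMINANTLY_LEFT = "predominantly_left"
    RIGHT_SIDE = "right_side"
    LEFT_SIDE = "left_side"
    CENTER = "center"
    RANDOM_FASHION = "random_fashion"
    NO_INCORPORATION = "no_incorporation"


#: The five side patterns that qualify for peak-shift measurement.
SIDE_CATEGORIES = frozenset(
    {
        PatternCategory.BOTH_SIDES,
        PatternCategory.PREDOMINANTLY_RIGHT,
        PatternCategory.PREDOMINANTLY_LEFT,
        PatternCategory.RIGHT_SIDE,
        PatternCategory.LEFT_SIDE,
    }
)

#: Rollup used by the stacked frequency chart.
ROLLUP_GROUPS = {
    "side_group": sorted(c.value for c in SIDE_CATEGORIES),
    "center": [PatternCategory.CENTER.value],
    "random_fashion": [PatternCategory.RANDOM_FASHION.value],
    "no_incorporation": [PatternCategory.NO_INCORPORATION.value],
}

_SUBCATEGORY = {
    PatternCategory.BOTH_SIDES: "both_sides",
    PatternCategory.PREDOMINANTLY_RIGHT: "predominantly",
    PatternCategory.PREDOMINANTLY_LEFT: "predominantly",
    PatternCategory.RIGHT_SIDE: "one_side",
    PatternCategory.LEFT_SIDE: "one_side",
}


@dataclass(frozen=True)
class ClassificationRules:
    """Decision boundaries of the eight-pattern classifier.

    center_zone_halfwidth
        |x| below which a principal peak counts as central.
    side_zone_min
        |x| above which a peak counts as a side (tip-zone) peak.
    balance_ratio
        Minimum min/max height ratio of two side peaks for "both sides";
        below it the taller side is "predominantly" that side.
    shape_similarity_min
        Red-green correlation at or above which (absent excess side
        peaks) the pattern is "random fashion".
    red_signal_floor
        Red dynamic range, as a fraction of the green dynamic range,
        below which the sarcomere is "no incorporation".
    peak_prominence_min
        Minimum peak prominence as a fraction of the channel maximum.
    """

    center_zone_halfwidth: float = 0.25
    side_zone_min: float = 0.40
    balance_ratio: float = 0.60
    shape_similarity_min: float = 0.90
    red_signal_floor: float = 0.15
    peak_prominence_min: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.center_zone_halfwidth < self.side_zone_min < 1:
            raise InvalidConfigurationError(
                "need 0 < center_zone_halfwidth < side_zone_min < 1"
            )
        if not 0 < self.balance_ratio <= 1:
            raise InvalidConfigurationError("balance_ratio must be in (0, 1]")
        if not 0 < self.shape_similarity_min < 1:
            raise InvalidConfigurationError("shape_similarity_min must be in (0, 1)")
        if self.red_signal_floor <= 0 or self.peak_prominence_min <= 0:
            raise InvalidConfigurationError("thresholds must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RedPeak:
    position: float  # normalized x
    prominence: float
    height: float


@dataclass
class ClassifiedSarcomere:
    waveform: SarcomereWaveform
    category: PatternCategory
    peaks: tuple[RedPeak, ...]
    shape_similarity: float
    range_ratio: float  # red dynamic range / green dynamic range
    low_confidence: bool = False

    @property
    def side_peaks(self) -> tuple[RedPeak, ...]:
        return self.peaks  # kept for interface symmetry; peaks are filtered upstream


@dataclass
class PeakShiftRecord:
    source_id: str
    myotube: int | None
    time_min: float
    distance: float  # |x_peak|, normalized units
    subcategory: str


@dataclass
class FrequencySummary:
    """Category frequencies and peak-shift tables over time points."""

    per_myotube: pd.DataFrame  # time_min, myotube, category, proportion, n
    summary: pd.DataFrame  # time_min, category, mean, se, n_sarcomeres, n_myotubes
    rollup: pd.DataFrame  # time_min, group, mean, se
    peak_shifts: pd.DataFrame  # long records
    histogram: pd.DataFrame  # time_min, bin_left, bin_right, count
    medians: pd.DataFrame  # time_min, median_distance, n_records
    rules: ClassificationRules = field(default_factory=ClassificationRules)


def detect_red_peaks(
    w: SarcomereWaveform, rules: ClassificationRules | None = None
) -> list[RedPeak]:
    """Local maxima of the red waveform with sufficient prominence.

    Prominence is thresholded at ``peak_prominence_min`` times the channel
    maximum; peaks are returned sorted by |position| descending.  Maxima at
    the grid ends count as peaks (a tip peak may sit at the window edge).
    """
    rules = rules or ClassificationRules()
    red = np.asarray(w.red, dtype=float)
    vmax = float(np.max(red)) if np.max(red) > 0 else 1.0
    # pad with the channel minimum so edge maxima are detectable with
    # finite prominence (a tip peak may sit at the window edge)
    padded = np.concatenate([[red.min()], red, [red.min()]])
    idx, props = signal.find_peaks(padded, prominence=rules.peak_prominence_min * vmax)
    peaks = [
        RedPeak(
            position=float(w.x[i - 1]),
            prominence=float(p),
            height=float(red[i - 1]),
        )
        for i, p in zip(idx, props["prominences"])
    ]
    return sorted(peaks, key=lambda p: -abs(p.position))


def classify_pattern(
    w: SarcomereWaveform, rules: ClassificationRules | None = None
) -> ClassifiedSarcomere:
    """Assign one of the eight incorporation patterns to a waveform.

    Decision cascade:

    1. *no incorporation* — red dynamic range below ``red_signal_floor``
       times the green dynamic range;
    2. *random fashion* — red and green shapes near-identical
       (correlation >= ``shape_similarity_min``) and no side peak where
       red exceeds green by the prominence threshold;
    3. side peaks in both side zones — *both sides* when balanced
       (min/max >= ``balance_ratio``), else *predominantly* the taller
       side;
    4. a single side-zone peak — *right side* / *left side*;
    5. a principal peak inside the center zone — *center*;
    6. otherwise *random fashion*, flagged low-confidence.
    """
    rules = rules or ClassificationRules()
    if len(w.green) != len(w.red):
        raise InvalidConfigurationError("green and red must share one grid")

    green_range = w.green_range if w.green_range > 0 else np.inf
    ratio = w.red_range / green_range
    sim = float(stats.pearsonr(w.red, w.green).statistic) if np.std(w.red) > 0 and np.std(
        w.green
    ) > 0 else 0.0

    def result(cat: PatternCategory, peaks=(), low=False) -> ClassifiedSarcomere:
        return ClassifiedSarcomere(
            waveform=w, category=cat, peaks=tuple(peaks),
            shape_similarity=sim, range_ratio=float(ratio), low_confidence=low,
        )

    if w.red_empty or ratio < rules.red_signal_floor:
        return result(PatternCategory.NO_INCORPORATION)

    peaks = detect_red_peaks(w, rules)
    side = [p for p in peaks if abs(p.position) >= rules.side_zone_min]

    excess_side = [
        p for p in side
        if p.height - float(np.interp(p.position, w.x, w.green)) >= rules.peak_prominence_min
    ]
    if sim >= rules.shape_similarity_min and not excess_side:
        return result(PatternCategory.RANDOM_FASHION, peaks)

    right = [p for p in side if p.position > 0]
    left = [p for p in side if p.position < 0]
    if right and left:
        hr = max(p.height for p in right)
        hl = max(p.height for p in left)
        if min(hr, hl) / max(hr, hl) >= rules.balance_ratio:
            return result(PatternCategory.BOTH_SIDES, side)
        taller_right = hr > hl
        return result(
            PatternCategory.PREDOMINANTLY_RIGHT if taller_right
            else PatternCategory.PREDOMINANTLY_LEFT,
            side,
        )
    if right:
        return result(PatternCategory.RIGHT_SIDE, side)
    if left:
        return result(PatternCategory.LEFT_SIDE, side)

    if peaks:
        principal = max(peaks, key=lambda p: p.height)
        if abs(principal.position) <= rules.center_zone_halfwidth:
            return result(PatternCategory.CENTER, peaks)
    return result(PatternCategory.RANDOM_FASHION, peaks, low=True)


def peak_shift(c: ClassifiedSarcomere) -> list[PeakShiftRecord]:
    """Red-peak-to-center distances for a side-pattern sarcomere.

    One record per side-zone peak (|x| of the peak); both peaks of a
    "both sides" / "predominantly" waveform contribute separately.
    Raises :class:`CategoryError` for non-side categories.
    """
    if c.category not in SIDE_CATEGORIES:
        raise CategoryError(
            f"peak shift is defined for side patterns only, got {c.category.value}"
        )
    w = c.waveform
    return [
        PeakShiftRecord(
            source_id=w.source_id,
            myotube=w.myotube,
            time_min=float(w.time_min),
            distance=abs(p.position),
            subcategory=_SUBCATEGORY[c.category],
        )
        for p in c.peaks
    ]


def summarize(
    classified: Sequence[ClassifiedSarcomere],
    rules: ClassificationRules | None = None,
    bin_width: float = 0.05,
) -> FrequencySummary:
    """Category frequencies (mean ± SE over myotubes) and peak-shift tables.

    Proportions are computed per myotube and time point, then averaged
    across myotubes (SE across myotubes, matching how the per-myotube
    replication structure is reported).  Side-pattern peaks feed a
    |x_peak| histogram (default bin width 0.05 on [0, 1]) and a per-time
    median used for trend reporting.
    """
    rules = rules or ClassificationRules()
    if not classified:
        raise InvalidConfigurationError("no classified sarcomeres supplied")
    rows = [
        {
            "time_min": float(c.waveform.time_min),
            "myotube": c.waveform.myotube if c.waveform.myotube is not None else 0,
            "category": c.category.value,
        }
        for c in classified
    ]
    df = pd.DataFrame(rows)
    cats = [c.value for c in PatternCategory]

    per_myotube = (
        df.groupby(["time_min", "myotube"])["category"]
        .value_counts(normalize=True)
        .rename("proportion")
        .reset_index()
    )
    counts = (
        df.groupby(["time_min", "myotube"]).size().rename("n_sarcomeres").reset_index()
    )
    per_myotube = per_myotube.merge(counts, on=["time_min", "myotube"])

    # complete the grid so absent categories count as proportion 0
    grid = (
        per_myotube[["time_min", "myotube"]]
        .drop_duplicates()
        .merge(pd.DataFrame({"category": cats}), how="cross")
    )
    full = grid.merge(per_myotube, on=["time_min", "myotube", "category"], how="left")
    full["proportion"] = full["proportion"].fillna(0.0)

    def _sem(v):
        return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0

    summary = (
        full.groupby(["time_min", "category"])["proportion"]
        .agg(mean="mean", se=_sem, n_myotubes="size")
        .reset_index()
    )
    n_total = df.groupby("time_min").size().rename("n_sarcomeres").reset_index()
    summary = summary.merge(n_total, on="time_min")

    roll_rows = []
    for group, members in ROLLUP_GROUPS.items():
        sub = (
            full[full["category"].isin(members)]
            .groupby(["time_min", "myotube"])["proportion"]
            .sum()
            .reset_index()
        )
        agg = sub.groupby("time_min")["proportion"].agg(mean="mean", se=_sem).reset_index()
        agg["group"] = group
        roll_rows.append(agg)
    rollup = pd.concat(roll_rows, ignore_index=True)[["time_min", "group", "mean", "se"]]

    shift_records = []
    for c in classified:
        if c.category in SIDE_CATEGORIES:
            shift_records.extend(peak_shift(c))
    peak_df = pd.DataFrame(
        [
            {
                "source_id": r.source_id,
                "myotube": r.myotube,
                "time_min": r.time_min,
                "distance": r.distance,
                "subcategory": r.subcategory,
            }
            for r in shift_records
        ],
        columns=["source_id", "myotube", "time_min", "distance", "subcategory"],
    )

    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    hist_rows = []
    med_rows = []
    for t, sub in peak_df.groupby("time_min"):
        counts_h, _ = np.histogram(sub["distance"], bins=edges)
        for left, right, n in zip(edges[:-1], edges[1:], counts_h):
            hist_rows.append(
                {"time_min": t, "bin_left": left, "bin_right": right, "count": int(n)}
            )
        med_rows.append(
            {
                "time_min": t,
                "median_distance": float(sub["distance"].median()),
                "n_records": len(sub),
            }
        )
    histogram = pd.DataFrame(
        hist_rows, columns=["time_min", "bin_left", "bin_right", "count"]
    )
    medians = pd.DataFrame(med_rows, columns=["time_min", "median_distance", "n_records"])

    return FrequencySummary(
        per_myotube=per_myotube,
        summary=summary,
        rollup=rollup,
        peak_shifts=peak_df,
        histogram=histogram,
        medians=medians,
        rules=rules,
    )
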