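"""The two-letter feed-intake pattern taxonomy.

Clusters found by PAM are turned into named patterns in three steps:

1. summarize every sow-cycle's total feed intake (TFI) over the table
   periods (days 0-6, 7-14, 15-21, 22-28) and the week-1 / rest-of-lactation
   split (days 0-6 vs 7-28);
2. rank clusters by descending mean whole-lactation TFI; the top cluster is
   the *reference*;
3. assign each cluster a letter per period — High, Medium or Low — and name
   it ``<rank>-<letters>`` (``1-HH`` ... ``5-LL`` when k = 5).

Two threshold conventions are provided.  The default, ``"reference"``,
grades a cluster's mean TFI against fractions of the reference cluster's
mean: High above 90%, Medium between 65% and 90%, Low below 65%.  This is
the only convention that reproduces the canonical letter assignment of all
five patterns from their calibration period totals.  The alternative,
``"percentile"``, uses the 65th/90th percentiles of the sow-level TFI
distribution (linear-interpolation, type-7 convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_records import SowLactation

__all__ = [
    "TfiSummary",
    "PatternThresholds",
    "PatternLabel",
    "DegenerateThresholdsError",
    "tfi_summary",
    "tfi_table",
    "compute_thresholds",
    "reference_thresholds",
    "label_cluster",
    "name_patterns",
    "pattern_proportions",
    "pattern_table",
]

#: Inclusive day ranges of the reporting periods.
TABLE_PERIODS: tuple[tuple[int, int], ...] = ((0, 6), (7, 14), (15, 21), (22, 28))

#: High / Low cutoffs as fractions of the reference cluster's mean TFI.
REFERENCE_HIGH_FRACTION = 0.90
REFERENCE_LOW_FRACTION = 0.65


class DegenerateThresholdsError(ValueError):
    """Raised when the H/M/L thresholds collapse (p65 == p90)."""


@dataclass(frozen=True)
class TfiSummary:
    """Period feed totals (kg) of one sow-cycle.

    The four table periods partition the lactation days, so their totals sum
    to ``tfi_0_28`` exactly.  ``tfi_week1``/``tfi_rest`` is the split used
    for pattern lettering (days 0-6 vs 7-28); ``dfi`` is the mean daily
    intake, ``tfi_0_28 / lactation_length``.
    """

    sow_id: str
    cycle: int
    lactation_length: int
    tfi_0_6: float
    tfi_7_14: float
    tfi_15_21: float
    tfi_22_28: float

    @property
    def tfi_0_28(self) -> float:
        return self.tfi_0_6 + self.tfi_7_14 + self.tfi_15_21 + self.tfi_22_28

    @property
    def tfi_week1(self) -> float:
        return self.tfi_0_6

    @property
    def tfi_rest(self) -> float:
        return self.tfi_0_28 - self.tfi_0_6

    @property
    def dfi(self) -> float:
        return self.tfi_0_28 / self.lactation_length


def tfi_summary(lactation: SowLactation) -> TfiSummary:
    """Period feed totals of one validated lactation (observed days only)."""
    x = lactation.intakes
    totals = [float(x[lo : hi + 1].sum()) for lo, hi in TABLE_PERIODS]
    return TfiSummary(
        lactation.sow_id, lactation.cycle, lactation.lactation_length, *totals
    )


def tfi_table(lactations: Iterable[SowLactation]) -> pd.DataFrame:
    """TFI summaries of a cohort as a DataFrame (one row per sow-cycle)."""
    rows = [tfi_summary(lac) for lac in lactations]
    return pd.DataFrame(
        {
            "sow_id": [r.sow_id for r in rows],
            "cycle": [r.cycle for r in rows],
            "lactation_length": [r.lactation_length for r in rows],
            "tfi_0_6": [r.tfi_0_6 for r in rows],
            "tfi_7_14": [r.tfi_7_14 for r in rows],
            "tfi_15_21": [r.tfi_15_21 for r in rows],
            "tfi_22_28": [r.tfi_22_28 for r in rows],
            "tfi_0_28": [r.tfi_0_28 for r in rows],
            "tfi_week1": [r.tfi_week1 for r in rows],
            "tfi_rest": [r.tfi_rest for r in rows],
            "dfi": [r.dfi for r in rows],
        }
    )


@dataclass(frozen=True)
class PatternThresholds:
    """H/M/L cutoffs (kg) for the week-1 and rest-of-lactation periods."""

    p65_week1: float
    p90_week1: float
    p65_rest: float
    p90_rest: float
    convention: str = "reference"
    degenerate: bool = False

    def __post_init__(self):
        if self.p65_week1 > self.p90_week1 or self.p65_rest > self.p90_rest:
            raise ValueError("lower threshold exceeds upper threshold")


def compute_thresholds(summaries: Sequence[TfiSummary] | pd.DataFrame) -> PatternThresholds:
    """Sow-level percentile thresholds (65th/90th, type-7 linear interpolation).

    This is the ``"percentile"`` convention; it needs at least 10 sow-cycles.
    All-equal TFIs collapse the cutoffs and set the ``degenerate`` flag.
    """
    if isinstance(summaries, pd.DataFrame):
        week1 = summaries["tfi_week1"].to_numpy(dtype=float)
        rest = summaries["tfi_rest"].to_numpy(dtype=float)
    else:
        week1 = np.array([s.tfi_week1 for s in summaries], dtype=float)
        rest = np.array([s.tfi_rest for s in summaries], dtype=float)
    if week1.size < 10:
        raise ValueError("percentile thresholds need at least 10 sow-cycles")
    p65_w, p90_w = np.percentile(week1, [65, 90], method="linear")
    p65_r, p90_r = np.percentile(rest, [65, 90], method="linear")
    degenerate = bool(p65_w == p90_w or p65_r == p90_r)
    return PatternThresholds(
        float(p65_w), float(p90_w), float(p65_r), float(p90_r),
        convention="percentile", degenerate=degenerate,
    )


def reference_thresholds(ref_mean_week1: float, ref_mean_rest: float) -> PatternThresholds:
    """Thresholds as fractions (65% / 90%) of the reference cluster's mean TFI."""
    if ref_mean_week1 <= 0 or ref_mean_rest <= 0:
        raise ValueError("reference means must be positive")
    return PatternThresholds(
        REFERENCE_LOW_FRACTION * ref_mean_week1,
        REFERENCE_HIGH_FRACTION * ref_mean_week1,
        REFERENCE_LOW_FRACTION * ref_mean_rest,
        REFERENCE_HIGH_FRACTION * ref_mean_rest,
        convention="reference",
    )


def _letter(value: float, p65: float, p90: float) -> str:
    # "above percentile 90" is read strictly: values exactly at a cutoff are M
    if value > p90:
        return "H"
    if value < p65:
        return "L"
    return "M"


def label_cluster(
    cluster_mean_week1: float,
    cluster_mean_rest: float,
    thresholds: PatternThresholds,
) -> tuple[str, str]:
    """Letter pair (week-1, rest) for one cluster's mean TFIs."""
    if thresholds.degenerate:
        raise DegenerateThresholdsError("cannot letter clusters: thresholds collapsed")
    return (
        _letter(cluster_mean_week1, thresholds.p65_week1, thresholds.p90_week1),
        _letter(cluster_mean_rest, thresholds.p65_rest, thresholds.p90_rest),
    )


@dataclass(frozen=True)
class PatternLabel:
    """A cluster's letter pair and its rank name (``1-HH`` ... ``5-LL``)."""

    cluster: int
    letters: tuple[str, str]
    rank: int
    rank_name: str
    is_reference: bool


def name_patterns(
    cluster_letters: Mapping[int, tuple[str, str]],
    cluster_mean_tfi: Mapping[int, float],
    cluster_mean_week1: Mapping[int, float] | None = None,
) -> dict[int, PatternLabel]:
    """Rank lettered clusters by descending mean whole-lactation TFI.

    With k = 5 names follow the canonical ``1-HH`` style; any other k falls
    back to generic ``P1-..`` names.  A tie on mean TFI breaks by the higher
    week-1 mean (then by cluster id).
    """
    if set(cluster_letters) != set(cluster_mean_tfi):
        raise ValueError("letter and mean-TFI maps must cover the same clusters")
    w1 = cluster_mean_week1 or {}

    def sort_key(c):
        return (-cluster_mean_tfi[c], -w1.get(c, 0.0), c)

    ranked = sorted(cluster_letters, key=sort_key)
    generic = len(ranked) != 5
    out: dict[int, PatternLabel] = {}
    for rank, c in enumerate(ranked, start=1):
        letters = cluster_letters[c]
        prefix = f"P{rank}" if generic else str(rank)
        out[c] = PatternLabel(
            cluster=c,
            letters=letters,
            rank=rank,
            rank_name=f"{prefix}-{letters[0]}{letters[1]}",
            is_reference=(rank == 1),
        )
    return out


def pattern_proportions(assignments: Sequence) -> tuple[dict, dict]:
    """Share of sow-cycles per pattern.

    Returns ``(rounded, raw)``: percentages rounded to one decimal for
    reporting, and the exact fractions.
    """
    labels = list(assignments)
    if not labels:
        raise ValueError("no assignments")
    n = len(labels)
    raw: dict = {}
    for lab in labels:
        raw[lab] = raw.get(lab, 0) + 1
    raw = {lab: cnt / n for lab, cnt in sorted(raw.items(), key=lambda kv: str(kv[0]))}
    rounded = {lab: round(100.0 * frac, 1) for lab, frac in raw.items()}
    return rounded, raw


def pattern_table(
    tfi: pd.DataFrame,
    assignments: Sequence[int],
    *,
    convention: Literal["reference", "percentile"] = "reference",
) -> tuple[pd.DataFrame, dict[int, PatternLabel], PatternThresholds]:
    """Build the per-pattern summary table (the Table-1 analogue).

    ``tfi`` is a :func:`tfi_table` frame aligned row-for-row with
    ``assignments``.  Returns the summary frame (one row per cluster, ranked),
    the cluster -> label map and the thresholds used.
    """
    tfi = tfi.reset_index(drop=True)
    labels = np.asarray(assignments)
    if len(labels) != len(tfi):
        raise ValueError("assignments must align with the TFI table")
    clusters = sorted(set(labels.tolist()))
    means = {
        c: tfi.loc[labels == c, ["tfi_week1", "tfi_rest", "tfi_0_28"]].mean()
        for c in clusters
    }
    ref = max(clusters, key=lambda c: (means[c]["tfi_0_28"], means[c]["tfi_week1"], -c))
    if convention == "reference":
        thresholds = reference_thresholds(
            float(means[ref]["tfi_week1"]), float(means[ref]["tfi_rest"])
        )
    else:
        thresholds = compute_thresholds(tfi)
    letters = {
        c: label_cluster(float(means[c]["tfi_week1"]), float(means[c]["tfi_rest"]), thresholds)
        for c in clusters
    }
    names = name_patterns(
        letters,
        {c: float(means[c]["tfi_0_28"]) for c in clusters},
        {c: float(means[c]["tfi_week1"]) for c in clusters},
    )
    pct, _ = pattern_proportions(labels.tolist())
    rows = []
    for c in sorted(clusters, key=lambda c: names[c].rank):
        sub = tfi.loc[labels == c]
        rows.append(
            {
                "cluster": c,
                "rank_name": names[c].rank_name,
                "letters": "".join(names[c].letters),
                "n_sows": int(len(sub)),
                "pct": pct[c],
                "tfi_0_6": sub["tfi_0_6"].mean(),
                "tfi_7_14": sub["tfi_7_14"].mean(),
                "tfi_15_21": sub["tfi_15_21"].mean(),
                "tfi_22_28": sub["tfi_22_28"].mean(),
                "tfi_0_28": sub["tfi_0_28"].mean(),
                "dfi": sub["dfi"].mean(),
            }
        )
    return pd.DataFrame(rows), names, thresholds
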