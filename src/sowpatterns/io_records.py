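"""Reading, validation and inclusion filtering of intake and reproductive records.

CSV dialect: comma-separated, UTF-8, dot decimal, fixed header names.
Leading ``#`` lines are treated as comments (the simulator writes the seed
there).  The record unit throughout is the sow-cycle: one lactation of one
sow, identified by ``(sow_id, cycle)``.

Intake CSV columns: ``sow_id, parity, cycle, day, intake_kg, is_nurse``.
Reproductive CSV columns mirror :class:`ReproRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MAX_LACTATION_DAYS",
    "MIN_LACTATION_DAYS",
    "IntakeRecord",
    "SowLactation",
    "ReproRecord",
    "RecordValidationError",
    "ExcludedLactation",
    "read_intake_csv",
    "read_repro_csv",
    "write_intake_csv",
    "write_repro_csv",
    "write_truth_csv",
    "read_truth_csv",
    "assemble_lactations",
    "apply_inclusion_filters",
    "exclusion_report",
]

#: Lactations are truncated to 28 days (days 0-27, day 0 = farrowing) ...
MAX_LACTATION_DAYS = 28
#: ... and sow-cycles shorter than 21 days are excluded from analysis.
MIN_LACTATION_DAYS = 21

INTAKE_COLUMNS = ["sow_id", "parity", "cycle", "day", "intake_kg", "is_nurse"]
REPRO_COLUMNS = [
    "sow_id", "cycle", "total_born", "born_alive", "stillborn", "mummified",
    "start_piglets", "weaned", "pwm_pct", "wfsi_days", "farrowed_next",
    "next_total_born", "next_born_alive", "next_stillborn", "next_mummified",
]


class RecordValidationError(ValueError):
    """Raised when input records violate the schema; carries per-row messages."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid records:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


@dataclass(frozen=True)
class IntakeRecord:
    """One sow-day of feed intake."""

    sow_id: str
    parity: int
    cycle: int
    day: int
    intake_kg: float
    is_nurse: bool = False


@dataclass
class SowLactation:
    """One sow-cycle's daily intake vector plus metadata; the clustering unit."""

    sow_id: str
    parity: int
    cycle: int
    lactation_length: int
    intakes: np.ndarray  # kg/day, index = lactation day, day 0 = farrowing
    is_nurse: bool = False

    def __post_init__(self) -> None:
        self.intakes = np.asarray(self.intakes, dtype=float)
        if len(self.intakes) != min(self.lactation_length, MAX_LACTATION_DAYS):
            raise ValueError(
                f"sow {self.sow_id} cycle {self.cycle}: intake vector length "
                f"{len(self.intakes)} != min(lactation_length, {MAX_LACTATION_DAYS})"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.sow_id, self.cycle)


@dataclass(frozen=True)
class ReproRecord:
    """Current- and next-cycle reproductive outcomes of one sow-cycle.

    ``start_piglets`` is the post-fostering litter size, the denominator of
    preweaning mortality (PWM).  Next-cycle prolificacy fields are ``None``
    for sows that did not farrow again.
    """

    sow_id: str
    cycle: int
    total_born: int
    born_alive: int
    stillborn: int
    mummified: int
    start_piglets: int
    weaned: int
    pwm_pct: float
    wfsi_days: float
    farrowed_next: bool
    next_total_born: Optional[int] = None
    next_born_alive: Optional[int] = None
    next_stillborn: Optional[int] = None
    next_mummified: Optional[int] = None

    def __post_init__(self) -> None:
        if self.born_alive + self.stillborn > self.total_born:
            raise ValueError(
                f"sow {self.sow_id}: born_alive + stillborn > total_born"
            )
        if min(self.mummified, self.weaned, self.stillborn, self.born_alive) < 0:
            raise ValueError(f"sow {self.sow_id}: negative piglet count")


@dataclass(frozen=True)
class ExcludedLactation:
    """A filtered-out sow-cycle with its machine-readable reason code."""

    lactation: SowLactation
    reason: str


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordValidationError(
            [f"{path.name}: missing required column(s) {', '.join(missing)}"]
        )
    return df


def read_intake_csv(path) -> list[IntakeRecord]:
    """Read and validate daily intake records.

    Any malformed row (unparseable numerics, negative intake, bad day index)
    is reported with its line number; one or more bad rows abort the run.
    """
    df = _read_csv(path, INTAKE_COLUMNS)
    problems: list[str] = []
    records: list[IntakeRecord] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header occupies line 1
        try:
            parity = int(row["parity"])
            cycle = int(row["cycle"])
            day = int(row["day"])
            intake = float(row["intake_kg"])
            nurse = bool(row["is_nurse"])
        except (TypeError, ValueError):
            problems.append(f"line {line}: unparseable numeric field")
            continue
        if not np.isfinite(intake) or intake < 0:
            problems.append(f"line {line}: intake_kg must be finite and >= 0")
            continue
        if day < 0:
            problems.append(f"line {line}: day must be >= 0")
            continue
        if parity < 1 or cycle < 1:
            problems.append(f"line {line}: parity and cycle must be >= 1")
            continue
        records.append(
            IntakeRecord(str(row["sow_id"]), parity, cycle, day, intake, nurse)
        )
    if problems:
        raise RecordValidationError(problems)
    return records


def read_repro_csv(path) -> list[ReproRecord]:
    """Read and validate reproductive records (one row per sow-cycle)."""
    df = _read_csv(path, REPRO_COLUMNS)
    problems: list[str] = []
    records: list[ReproRecord] = []
    next_cols = ["next_total_born", "next_born_alive", "next_stillborn", "next_mummified"]
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            nxt = {
                c: (None if pd.isna(row[c]) else int(row[c])) for c in next_cols
            }
            rec = ReproRecord(
                sow_id=str(row["sow_id"]),
                cycle=int(row["cycle"]),
                total_born=int(row["total_born"]),
                born_alive=int(row["born_alive"]),
                stillborn=int(row["stillborn"]),
                mummified=int(row["mummified"]),
                start_piglets=int(row["start_piglets"]),
                weaned=int(row["weaned"]),
                pwm_pct=float(row["pwm_pct"]),
                wfsi_days=float(row["wfsi_days"]),
                farrowed_next=bool(row["farrowed_next"]),
                **nxt,
            )
        except (TypeError, ValueError) as exc:
            problems.append(f"line {line}: {exc}")
            continue
        records.append(rec)
    if problems:
        raise RecordValidationError(problems)
    return records


def _write_with_header(df: pd.DataFrame, path, seed: Optional[int]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def write_intake_csv(lactations: Iterable[SowLactation], path, seed: Optional[int] = None) -> None:
    """Write lactations in the long daily-record schema (one row per sow-day)."""
    rows = [
        {
            "sow_id": lac.sow_id,
            "parity": lac.parity,
            "cycle": lac.cycle,
            "day": day,
            "intake_kg": float(kg),
            "is_nurse": lac.is_nurse,
        }
        for lac in lactations
        for day, kg in enumerate(lac.intakes)
    ]
    _write_with_header(pd.DataFrame(rows, columns=INTAKE_COLUMNS), path, seed)


def write_repro_csv(records: Iterable[ReproRecord], path, seed: Optional[int] = None) -> None:
    rows = [{f.name: getattr(r, f.name) for f in fields(ReproRecord)} for r in records]
    _write_with_header(pd.DataFrame(rows, columns=REPRO_COLUMNS), path, seed)


def write_truth_csv(truth: dict[str, str], path, seed: Optional[int] = None) -> None:
    """Write ground-truth pattern assignments of a simulated cohort."""
    df = pd.DataFrame(sorted(truth.items()), columns=["sow_id", "true_pattern"])
    _write_with_header(df, path, seed)


def read_truth_csv(path) -> dict[str, str]:
    df = _read_csv(path, ["sow_id", "true_pattern"])
    return dict(zip(df["sow_id"].astype(str), df["true_pattern"].astype(str)))


# ---------------------------------------------------------------------------
# Assembly and inclusion filters
# ---------------------------------------------------------------------------

def assemble_lactations(
    records: Iterable[IntakeRecord],
    *,
    interpolate_gaps: bool = False,
) -> list[SowLactation]:
    """Group daily records into per-sow-cycle lactation vectors.

    Days are sorted and truncated at day 27 (the 28-day grid).  Duplicate
    ``(sow_id, cycle, day)`` entries are fatal.  A gap (missing day before the
    last observed day) is an error by default; with ``interpolate_gaps`` the
    missing days are filled by linear interpolation between neighbours.
    """
    by_key: dict[tuple[str, int], list[IntakeRecord]] = {}
    for rec in records:
        by_key.setdefault((rec.sow_id, rec.cycle), []).append(rec)

    problems: list[str] = []
    lactations: list[SowLactation] = []
    for (sow_id, cycle), recs in by_key.items():
        recs = sorted(recs, key=lambda r: r.day)
        days = [r.day for r in recs]
        if len(set(days)) != len(days):
            dup = sorted({d for d in days if days.count(d) > 1})
            problems.append(f"sow {sow_id} cycle {cycle}: duplicate day(s) {dup}")
            continue
        recs = [r for r in recs if r.day < MAX_LACTATION_DAYS]
        days = [r.day for r in recs]
        length = days[-1] + 1
        intakes = np.full(length, np.nan)
        for r in recs:
            intakes[r.day] = r.intake_kg
        if np.isnan(intakes).any():
            gaps = np.flatnonzero(np.isnan(intakes)).tolist()
            if not interpolate_gaps:
                problems.append(f"sow {sow_id} cycle {cycle}: missing day(s) {gaps}")
                continue
            obs = np.flatnonzero(~np.isnan(intakes))
            intakes = np.interp(np.arange(length), obs, intakes[obs])
        lactations.append(
            SowLactation(
                sow_id=sow_id,
                parity=recs[0].parity,
                cycle=cycle,
                lactation_length=length,
                intakes=intakes,
                is_nurse=recs[0].is_nurse,
            )
        )
    if problems:
        raise RecordValidationError(problems)
    return lactations


#: Exclusion reason codes, in the priority order they are checked.
EXCLUSION_REASONS = ("primiparous", "nurse_sow", "short_lactation")


def apply_inclusion_filters(
    lactations: Iterable[SowLactation],
) -> tuple[list[SowLactation], list[ExcludedLactation]]:
    """Apply the study's inclusion rules.

    Kept sow-cycles have parity >= 2, are not nurse sows and lactated at
    least 21 days.  Every exclusion carries one reason code (the first
    matching rule in the order primiparous, nurse_sow, short_lactation).
    Filtering is total and idempotent; kept and excluded partition the input.
    """
    kept: list[SowLactation] = []
    excluded: list[ExcludedLactation] = []
    for lac in lactations:
        if lac.parity < 2:
            excluded.append(ExcludedLactation(lac, "primiparous"))
        elif lac.is_nurse:
            excluded.append(ExcludedLactation(lac, "nurse_sow"))
        elif lac.lactation_length < MIN_LACTATION_DAYS:
            excluded.append(ExcludedLactation(lac, "short_lactation"))
        else:
            kept.append(lac)
    return kept, excluded


def exclusion_report(excluded: Sequence[ExcludedLactation]) -> pd.DataFrame:
    """Tabular exclusion report (sow_id, cycle, parity, lactation_length, reason)."""
    return pd.DataFrame(
        [
            {
                "sow_id": e.lactation.sow_id,
                "cycle": e.lactation.cycle,
                "parity": e.lactation.parity,
                "lactation_length": e.lactation.lactation_length,
                "reason": e.reason,
            }
            for e in excluded
        ],
        columns=["sow_id", "cycle", "parity", "lactation_length", "reason"],
    )
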