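"""Subperiod-mean clustering features and column standardization.

Each sow-cycle is summarized by six variables: the mean daily intake over
lactation days 0-3, 4-6, 7-10, 11-14, 15-21 and 22-28 (inclusive day ranges,
day 0 = farrowing, restricted to observed days).  Before clustering, each
feature column is z-scored, (x - mean(x)) / sd(x), with the sample (n-1)
standard deviation, so no subperiod dominates the Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .io_records import SowLactation

__all__ = [
    "SUBPERIODS",
    "FEATURE_NAMES",
    "FeatureVector",
    "NormalizedMatrix",
    "DegenerateColumnError",
    "EmptySubperiodError",
    "subperiod_means",
    "feature_table",
    "zscore_columns",
]

#: Inclusive day ranges of the six clustering subperiods.
SUBPERIODS: tuple[tuple[int, int], ...] = (
    (0, 3), (4, 6), (7, 10), (11, 14), (15, 21), (22, 28),
)
FEATURE_NAMES: tuple[str, ...] = (
    "m0_3", "m4_6", "m7_10", "m11_14", "m15_21", "m22_28",
)


class EmptySubperiodError(ValueError):
    """Raised when a subperiod contains no observed days and imputation is off."""


class DegenerateColumnError(ValueError):
    """Raised when a feature column has zero variance and cannot be z-scored."""


@dataclass(frozen=True)
class FeatureVector:
    """The six subperiod means (kg/day) of one sow-cycle.

    For lactations of exactly 21 days the 22-28 d subperiod has no observed
    days; under the default policy its mean is imputed from the 15-21 d
    subperiod and ``imputed_m22_28`` is flagged.
    """

    sow_id: str
    cycle: int
    m0_3: float
    m4_6: float
    m7_10: float
    m11_14: float
    m15_21: float
    m22_28: float
    imputed_m22_28: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def subperiod_means(
    lactation: SowLactation,
    *,
    empty_tail: Literal["impute", "error"] = "impute",
) -> FeatureVector:
    """Compute the six subperiod means of one lactation.

    Each mean uses only the days actually observed (a 25-day lactation
    contributes days 22-24 to the 22-28 d subperiod).  ``empty_tail``
    controls length-21 lactations, whose 22-28 d subperiod is empty:
    ``"impute"`` copies the 15-21 d mean and flags the record, ``"error"``
    raises :class:`EmptySubperiodError`.
    """
    if lactation.lactation_length < 21:
        raise ValueError(
            f"sow {lactation.sow_id}: subperiod features require >= 21 lactation days"
        )
    x = lactation.intakes
    means: list[float] = []
    imputed = False
    for lo, hi in SUBPERIODS:
        seg = x[lo : hi + 1]
        if seg.size == 0:
            if empty_tail == "error":
                raise EmptySubperiodError(
                    f"sow {lactation.sow_id}: no observed days in subperiod {lo}-{hi}"
                )
            means.append(means[-1])  # carry the 15-21 d mean forward
            imputed = True
        else:
            means.append(float(seg.mean()))
    return FeatureVector(lactation.sow_id, lactation.cycle, *means, imputed_m22_28=imputed)


def feature_table(
    lactations: Iterable[SowLactation],
    *,
    empty_tail: Literal["impute", "error"] = "impute",
) -> pd.DataFrame:
    """Feature matrix as a DataFrame: id columns plus the six feature columns."""
    rows = [subperiod_means(lac, empty_tail=empty_tail) for lac in lactations]
    return pd.DataFrame(
        [
            {
                "sow_id": fv.sow_id,
                "cycle": fv.cycle,
                **{n: getattr(fv, n) for n in FEATURE_NAMES},
                "imputed_m22_28": fv.imputed_m22_28,
            }
            for fv in rows
        ]
    )


@dataclass(frozen=True)
class NormalizedMatrix:
    """Column-standardized feature matrix with its means/sds for exact inversion."""

    values: np.ndarray  # n x p standardized scores
    col_means: np.ndarray
    col_sds: np.ndarray
    columns: tuple[str, ...]

    def inverse_transform(self, z: np.ndarray | None = None) -> np.ndarray:
        """Map standardized scores back to the raw scale."""
        z = self.values if z is None else np.asarray(z, dtype=float)
        return z * self.col_sds + self.col_means


def zscore_columns(matrix) -> NormalizedMatrix:
    """Z-score each column of a feature matrix.

    ``matrix`` may be an ndarray, a DataFrame (feature columns are selected
    by :data:`FEATURE_NAMES` when present) or a sequence of
    :class:`FeatureVector`.  Uses the sample (ddof=1) standard deviation.
    A zero-variance column is fatal and named in the error.
    """
    names = FEATURE_NAMES
    if isinstance(matrix, pd.DataFrame):
        cols = [c for c in FEATURE_NAMES if c in matrix.columns] or list(matrix.columns)
        names = tuple(cols)
        x = matrix[cols].to_numpy(dtype=float)
    elif len(matrix) and isinstance(matrix[0], FeatureVector):
        x = np.vstack([fv.as_array() for fv in matrix])
    else:
        x = np.asarray(matrix, dtype=float)
        if x.ndim != 2:
            raise ValueError("expected a 2-D feature matrix")
        if x.shape[1] != len(names):
            names = tuple(f"x{j}" for j in range(x.shape[1]))
    if x.shape[0] < 2:
        raise ValueError("z-scoring needs at least two rows")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        raise DegenerateColumnError(
            f"zero-variance column(s): {', '.join(names[j] for j in dead)}"
        )
    return NormalizedMatrix((x - means) / sds, means, sds, names)
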