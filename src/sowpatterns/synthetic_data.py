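"""Synthetic cohorts of lactating-sow feed-intake trajectories and reproductive outcomes.

The generator emulates a commercial multiparous-sow herd monitored by ad-libitum
electronic feeders: five archetypal daily-feed-intake (DFI) curves over a
28-day lactation (day 0 = farrowing), multiplicative day-to-day noise, sporadic
intake-drop events, the feeder's early-lactation cap (1.20 x the previous day's
intake, applied through day 6), and per-pattern reproductive outcomes for the
current and subsequent cycle.

Each archetype rises geometrically at exactly the feeder-cap rate (1.20x per
day) over days 0-6 — the cap is the binding constraint on appetite recovery
after farrowing, so the expected curve satisfies it with equality — then,
once the cap is lifted on day 7, follows a piecewise-linear course with knots
at days 7, 14 and 21 and a flat plateau from day 21.  The day-0 level and the
three knot levels per pattern are the exact closed-form solution so that the
curve's expected feed totals over days 0-6, 7-14, 15-21 and 22-27 equal the
calibrated period totals (kg) of the five patterns.  With noise switched off,
every simulated trajectory equals its archetype exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .io_records import ReproRecord, SowLactation

__all__ = [
    "PATTERN_IDS",
    "PATTERN_PERIOD_TFI",
    "DEFAULT_PATTERN_MIX",
    "ArchetypeCurve",
    "OutcomeParams",
    "SimConfig",
    "PatternIdError",
    "archetype_mean_curve",
    "archetype_curves",
    "generate_cohort",
]

#: Canonical pattern names, ranked by descending whole-lactation feed intake.
#: Letters: week-1 intake level / rest-of-lactation intake level (High/Medium/Low).
PATTERN_IDS: tuple[str, ...] = ("1-HH", "2-MH", "3-HM", "4-MM", "5-LL")

#: Calibrated total feed intake (kg) per lactation period
#: (days 0-6, 7-14, 15-21, 22-27 on the 28-day grid) for each archetype.
PATTERN_PERIOD_TFI: dict[str, tuple[float, float, float, float]] = {
    "1-HH": (25.5, 61.3, 61.2, 57.0),
    "2-MH": (21.6, 56.8, 56.8, 52.6),
    "3-HM": (24.9, 53.7, 49.2, 45.8),
    "4-MM": (19.9, 46.2, 45.9, 43.4),
    "5-LL": (11.9, 30.9, 36.0, 37.0),
}

#: Cohort pattern proportions (fraction of sow-cycles per archetype).
DEFAULT_PATTERN_MIX: tuple[float, ...] = (0.385, 0.240, 0.184, 0.152, 0.039)

#: Parity classes and their cohort frequencies: parity 2, parity 3-5, parity 6+.
_PARITY_CLASS_P = (229 / 1058, 656 / 1058, 173 / 1058)

_PERIOD_SLICES = (slice(0, 7), slice(7, 15), slice(15, 22), slice(22, 28))
_RISE_DAY = 21
_DEFAULT_WEEK1_GROWTH = 1.20  # the feeder-cap factor


class PatternIdError(ValueError):
    """Raised for a pattern id outside the five-pattern taxonomy."""


@dataclass(frozen=True)
class ArchetypeCurve:
    """Noise-free expected DFI curve of one feed-intake pattern.

    Days 0-6: geometric rise ``day0_level * week1_growth**d`` (the feeder-cap
    trajectory).  Days 7-21: linear between the kg/day ``knots`` at days 7,
    14 and 21.  From ``rise_day`` (= 21) on: constant at the plateau.
    """

    pattern_id: str
    day0_level: float
    knots: tuple[float, float, float]  # levels at days 7, 14, 21
    week1_growth: float = _DEFAULT_WEEK1_GROWTH
    rise_day: int = _RISE_DAY

    @property
    def week1_level(self) -> float:
        """Mean expected intake (kg/day) over days 0-6."""
        return float(np.mean(self.daily(np.arange(7))))

    @property
    def plateau_level(self) -> float:
        """Expected intake (kg/day) from ``rise_day`` onward."""
        return self.knots[-1]

    def daily(self, day) -> np.ndarray:
        """Expected intake at ``day`` (scalar or array), constant past the plateau."""
        d = np.minimum(np.asarray(day, dtype=float), float(self.rise_day))
        early = self.day0_level * self.week1_growth ** d
        late = np.interp(d, (7.0, 14.0, float(self.rise_day)), self.knots)
        return np.where(d < 7.0, early, late)

    def period_totals(self) -> tuple[float, float, float, float]:
        """Expected feed totals (kg) over days 0-6, 7-14, 15-21, 22-27."""
        f = self.daily(np.arange(28))
        return tuple(float(f[s].sum()) for s in _PERIOD_SLICES)


def _solve_curve(period_tfi: Sequence[float], growth: float) -> tuple[float, tuple[float, float, float]]:
    # Closed-form calibration against the four period totals:
    #   S1 = v0 * sum(g^d, d=0..6)
    #   S2 = sum over days 7..14 of the 7->14 segment = 4*v7 + 4*v14
    #   S3 = sum over days 15..21 of the 14->21 segment = 3*v14 + 4*v21
    #   S4 = 6 * v21 (plateau days 22..27)
    s1, s2, s3, s4 = (float(v) for v in period_tfi)
    v0 = s1 / sum(growth ** d for d in range(7))
    v21 = s4 / 6.0
    v14 = (s3 - 4.0 * v21) / 3.0
    v7 = s2 / 4.0 - v14
    return v0, (v7, v14, v21)


@lru_cache(maxsize=1)
def archetype_curves() -> dict[str, ArchetypeCurve]:
    """The five calibrated archetypes, keyed by pattern id."""
    out = {}
    for pid, tfi in PATTERN_PERIOD_TFI.items():
        v0, knots = _solve_curve(tfi, _DEFAULT_WEEK1_GROWTH)
        out[pid] = ArchetypeCurve(pid, v0, knots)
    return out


def archetype_mean_curve(pattern_id: str, day) -> float | np.ndarray:
    """Noise-free expected intake (kg/day) of ``pattern_id`` at ``day``.

    ``day`` may be a scalar or array in [0, 28]; values past the plateau day
    (21) all return the plateau level.

    Raises
    ------
    PatternIdError
        If ``pattern_id`` is not one of the five patterns.
    ValueError
        If any day lies outside [0, 28].
    """
    try:
        curve = archetype_curves()[pattern_id]
    except KeyError:
        raise PatternIdError(
            f"unknown pattern id {pattern_id!r}; expected one of {PATTERN_IDS}"
        ) from None
    d = np.asarray(day, dtype=float)
    if np.any(d < 0) or np.any(d > 28):
        raise ValueError("day must lie in [0, 28]")
    out = curve.daily(d)
    return float(out) if np.isscalar(day) or np.ndim(day) == 0 else out


# ---------------------------------------------------------------------------
# Reproductive-outcome calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeParams:
    """Pattern-conditional means driving the reproductive-outcome draws.

    Litter counts are drawn as rounded normals (``born_alive``) or Poisson
    (``stillborn``, ``mummified``); ``total_born`` is their sum.  The weaned
    count comes from a binomial survival draw on a post-fostering start litter
    whose mean is implied by ``weaned_mean`` and ``pwm_pct_mean``.  The
    weaning-to-first-service interval (WFSI) is a right-skewed gamma draw,
    and the next-cycle farrowing outcome a Bernoulli draw.
    """

    born_alive_mean: float
    stillborn_mean: float
    mummified_mean: float
    weaned_mean: float
    pwm_pct_mean: float
    wfsi_days_mean: float
    farrowing_rate: float  # fraction in [0, 1]
    next_born_alive_mean: float
    next_stillborn_mean: float
    next_mummified_mean: float
    born_alive_sd: float = 3.0
    start_litter_sd: float = 2.0
    wfsi_shape: float = 2.0  # gamma shape; 2 gives the long right tail seen in WFSI

    @property
    def start_litter_mean(self) -> float:
        """Post-fostering litter size implied by the weaned mean and PWM."""
        return self.weaned_mean / (1.0 - self.pwm_pct_mean / 100.0)


#: Per-pattern outcome calibration: current-cycle prolificacy/weaning and
#: next-cycle WFSI, farrowing rate and prolificacy.
DEFAULT_OUTCOME_PARAMS: dict[str, OutcomeParams] = {
    "1-HH": OutcomeParams(14.7, 1.23, 0.59, 11.5, 15.9, 6.34, 0.910, 14.8, 1.89, 0.68),
    "2-MH": OutcomeParams(14.8, 1.53, 0.54, 11.0, 14.9, 5.93, 0.898, 15.1, 1.89, 0.59),
    "3-HM": OutcomeParams(14.7, 1.07, 0.66, 10.9, 15.8, 6.55, 0.896, 15.1, 1.76, 0.58),
    "4-MM": OutcomeParams(14.5, 1.65, 0.59, 10.9, 15.9, 6.50, 0.926, 14.7, 1.67, 0.53),
    "5-LL": OutcomeParams(13.2, 2.68, 0.81, 9.99, 16.9, 13.11, 0.750, 13.6, 2.22, 0.51),
}


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a simulated cohort.

    Defaults reproduce the study conditions of the reference herd: 1,058
    multiparous sow-cycles, pattern mix 38.5/24.0/18.4/15.2/3.9 %, lactation
    length ~ N(27.15, 1.13^2) days rounded and truncated to [21, 28], and the
    electronic feeder's 1.20x day-over-day cap during days 1-6.

    ``invalid_sow_rate`` injects records the inclusion filters must remove
    (primiparous sows, short lactations, nurse sows, in equal shares) so the
    filtering stage is exercised on every simulated cohort.
    """

    n_sows: int = 1058
    pattern_mix: tuple[float, ...] = DEFAULT_PATTERN_MIX
    lactation_length_mean: float = 27.15
    lactation_length_sd: float = 1.13
    day_noise_cv: float = 0.08
    drop_event_rate: float = 0.0
    drop_factor_range: tuple[float, float] = (0.2, 0.6)
    feeder_cap_factor: float = 1.20
    apply_feeder_cap: bool = True
    invalid_sow_rate: float = 0.02
    seed: int = 0
    outcome_params: Mapping[str, OutcomeParams] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_PARAMS)
    )

    def validate(self) -> None:
        if not isinstance(self.n_sows, (int, np.integer)) or isinstance(self.n_sows, bool):
            raise TypeError("n_sows must be an integer")
        if self.n_sows < 1:
            raise ValueError("n_sows must be >= 1")
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise TypeError("seed must be an integer")
        if len(self.pattern_mix) != len(PATTERN_IDS):
            raise ValueError("pattern_mix must have five proportions")
        if abs(sum(self.pattern_mix) - 1.0) > 1e-9:
            raise ValueError("pattern_mix must sum to 1")
        for name, rate in [
            ("drop_event_rate", self.drop_event_rate),
            ("invalid_sow_rate", self.invalid_sow_rate),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.day_noise_cv < 0:
            raise ValueError("day_noise_cv must be >= 0")
        for pid in PATTERN_IDS:
            if pid not in self.outcome_params:
                raise ValueError(f"outcome_params missing pattern {pid}")
            if not 0.0 <= self.outcome_params[pid].farrowing_rate <= 1.0:
                raise ValueError(f"farrowing_rate for {pid} must lie in [0, 1]")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def _draw_parity(rng: np.random.Generator) -> int:
    cls = rng.choice(3, p=_PARITY_CLASS_P)
    if cls == 0:
        return 2
    if cls == 1:
        return int(rng.integers(3, 6))
    return int(rng.integers(6, 9))


def _simulate_trajectory(
    rng: np.random.Generator, curve: ArchetypeCurve, length: int, cfg: SimConfig
) -> np.ndarray:
    intake = curve.daily(np.arange(length)) * _lognormal_noise(rng, cfg.day_noise_cv, length)
    drops = rng.random(length) < cfg.drop_event_rate
    if drops.any():
        lo, hi = cfg.drop_factor_range
        intake[drops] *= rng.uniform(lo, hi, size=int(drops.sum()))
    if cfg.apply_feeder_cap:
        for d in range(1, min(7, length)):
            cap = cfg.feeder_cap_factor * intake[d - 1]
            if intake[d] > cap:
                intake[d] = cap
    return intake


def _draw_repro(
    rng: np.random.Generator, sow_id: str, cycle: int, p: OutcomeParams
) -> ReproRecord:
    born_alive = int(max(0, round(rng.normal(p.born_alive_mean, p.born_alive_sd))))
    stillborn = int(rng.poisson(p.stillborn_mean))
    mummified = int(rng.poisson(p.mummified_mean))
    total_born = born_alive + stillborn + mummified
    start = int(max(1, round(rng.normal(p.start_litter_mean, p.start_litter_sd))))
    weaned = int(rng.binomial(start, 1.0 - p.pwm_pct_mean / 100.0))
    pwm_pct = 100.0 * (start - weaned) / start
    wfsi = float(rng.gamma(p.wfsi_shape, p.wfsi_days_mean / p.wfsi_shape))
    farrowed = bool(rng.random() < p.farrowing_rate)
    if farrowed:
        nba = int(max(0, round(rng.normal(p.next_born_alive_mean, p.born_alive_sd))))
        nsb = int(rng.poisson(p.next_stillborn_mean))
        nmu = int(rng.poisson(p.next_mummified_mean))
        ntb = nba + nsb + nmu
    else:
        nba = nsb = nmu = ntb = None
    return ReproRecord(
        sow_id=sow_id,
        cycle=cycle,
        total_born=total_born,
        born_alive=born_alive,
        stillborn=stillborn,
        mummified=mummified,
        start_piglets=start,
        weaned=weaned,
        pwm_pct=pwm_pct,
        wfsi_days=wfsi,
        farrowed_next=farrowed,
        next_total_born=ntb,
        next_born_alive=nba,
        next_stillborn=nsb,
        next_mummified=nmu,
    )


def generate_cohort(
    config: SimConfig,
) -> tuple[list[SowLactation], list[ReproRecord], dict[str, str]]:
    """Simulate a cohort of sow-cycles under ``config``.

    Returns the lactation trajectories, the linked reproductive records and
    the ground-truth pattern assignment per sow id.  Identical configs
    (including seed) produce identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    curves = archetype_curves()
    mix = np.asarray(config.pattern_mix, dtype=float)

    lactations: list[SowLactation] = []
    repro: list[ReproRecord] = []
    truth: dict[str, str] = {}

    for i in range(config.n_sows):
        sow_id = f"S{i + 1:05d}"
        pid = PATTERN_IDS[int(rng.choice(len(PATTERN_IDS), p=mix))]
        truth[sow_id] = pid

        parity = _draw_parity(rng)
        is_nurse = False
        length = int(np.clip(
            round(rng.normal(config.lactation_length_mean, config.lactation_length_sd)),
            21, 28,
        ))
        # deliberately invalid records keep the inclusion filters honest
        if rng.random() < config.invalid_sow_rate:
            kind = int(rng.integers(3))
            if kind == 0:
                parity = 1
            elif kind == 1:
                length = int(rng.integers(10, 21))
            else:
                is_nurse = True

        intake = _simulate_trajectory(rng, curves[pid], length, config)
        cycle = parity  # one monitored cycle per sow; cycle number tracks parity
        lactations.append(
            SowLactation(
                sow_id=sow_id,
                parity=parity,
                cycle=cycle,
                lactation_length=length,
                intakes=intake,
                is_nurse=is_nurse,
            )
        )
        repro.append(_draw_repro(rng, sow_id, cycle, config.outcome_params[pid]))

    return lactations, repro, truth
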