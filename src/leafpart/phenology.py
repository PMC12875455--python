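"""Physiological development time: a generic daily accumulator.

Development is measured in days of physiological development (DPD).
Each calendar day contributes

    k_j · T_ebj^p_j · T_euj^q_j · P_ej^G_j · f(E_Ci)

where ``k_j`` is the cultivar-specific basic development rate of stage
*j*, ``T_ebj``/``T_euj`` are lower/upper temperature effect factors,
``P_ej`` the photoperiod effect factor (each in [0, 1], raised to
genotypic exponents ``p_j``, ``q_j``, ``G_j``) and ``f(E_Ci)`` an
agronomic-practice effect.  The concrete shapes of the effect functions
belong to a full phenology model and are deliberately pluggable here:
the defaults return 1, so the accumulator degrades to ``k_j`` per day
(calendar accumulation) until the user supplies response curves.

An alternative reading of the daily increment with a leading
``exp(k_j)`` factor is selectable via ``PhenologyParams.leading``.

DPD is normalized so that 0 is sowing and 1 physiological maturity
(nDPD), which is the time axis of the partitioning model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EffectContractError


@dataclass(frozen=True)
class DailyEnvironment:
    """One day of driving data for the accumulator."""

    date: object = None
    tmean_c: float = float("nan")
    daylength_h: float = 12.0
    agronomic: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.daylength_h <= 24.0:
            raise DomainError(f"daylength_h must lie in [0, 24], got {self.daylength_h}")


@dataclass(frozen=True)
class StageParams:
    """Stage-specific development parameters (k > 0; unit exponents default)."""

    k: float
    p: float = 1.0
    q: float = 1.0
    G: float = 1.0

    def __post_init__(self):
        if not self.k > 0:
            raise DomainError(f"basic development parameter k must be > 0, got {self.k}")


@dataclass(frozen=True)
class PhenologyParams:
    stages: Mapping[str, StageParams]
    leading: Literal["k", "exp_k"] = "k"

    def __post_init__(self):
        if not self.stages:
            raise DomainError("at least one stage is required")
        if self.leading not in ("k", "exp_k"):
            raise DomainError(f"leading must be 'k' or 'exp_k', got {self.leading!r}")


EffectFn = Callable[[DailyEnvironment, StageParams], float]


def _one(day: DailyEnvironment, stage: StageParams) -> float:
    return 1.0


def _agronomic_passthrough(day: DailyEnvironment, stage: StageParams) -> float:
    return day.agronomic


@dataclass(frozen=True)
class EffectFunctions:
    """Pluggable effect factors; each must return a value in [0, 1].

    Defaults are identity stubs (the agronomic factor passes through the
    per-day ``agronomic`` input) so the accumulator works without a full
    temperature/photoperiod response parameterization.
    """

    t_lower: EffectFn = _one
    t_upper: EffectFn = _one
    photoperiod: EffectFn = _one
    agronomic: EffectFn = _agronomic_passthrough


DEFAULT_EFFECTS = EffectFunctions()


def _checked(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise EffectContractError(
            f"effect function {name!r} returned {value}, outside [0, 1]"
        )
    return value


def dpd_series(
    days: Sequence[DailyEnvironment],
    params: PhenologyParams,
    effects: EffectFunctions | None = None,
    stage_of_day: Callable[[int, DailyEnvironment], str] | None = None,
) -> np.ndarray:
    """Cumulative DPD after each day of ``days``.

    ``stage_of_day(i, day)`` maps a day to a stage key of ``params``;
    by default every day belongs to the first declared stage.
    """
    if len(days) == 0:
        raise DomainError("days must be non-empty")
    effects = effects or DEFAULT_EFFECTS
    first_key = next(iter(params.stages))
    increments = np.empty(len(days))
    for i, day in enumerate(days):
        key = stage_of_day(i, day) if stage_of_day is not None else first_key
        stage = params.stages[key]
        lead = math.exp(stage.k) if params.leading == "exp_k" else stage.k
        increments[i] = (
            lead
            * _checked("t_lower", effects.t_lower(day, stage)) ** stage.p
            * _checked("t_upper", effects.t_upper(day, stage)) ** stage.q
            * _checked("photoperiod", effects.photoperiod(day, stage)) ** stage.G
            * _checked("agronomic", effects.agronomic(day, stage))
        )
    return np.cumsum(increments)


def accumulate_dpd(
    days: Sequence[DailyEnvironment],
    params: PhenologyParams,
    effects: EffectFunctions | None = None,
    stage_of_day: Callable[[int, DailyEnvironment], str] | None = None,
) -> float:
    """Total DPD accumulated over a day sequence."""
    return float(dpd_series(days, params, effects, stage_of_day)[-1])


def normalize_dpd(dpd: float, dpd_at_maturity: float) -> float:
    """Rescale DPD so 0 is sowing and 1 physiological maturity."""
    if not dpd_at_maturity > 0:
        raise DomainError(f"dpd_at_maturity must be > 0, got {dpd_at_maturity}")
    if not 0.0 <= dpd <= dpd_at_maturity:
        raise DomainError(
            f"dpd must lie in [0, dpd_at_maturity={dpd_at_maturity}], got {dpd}"
        )
    return dpd / dpd_at_maturity


def read_weather_csv(path) -> list[DailyEnvironment]:
    """Read a daily weather table (date, tmean_c, daylength_h[, agronomic])."""
    df = pd.read_csv(path)
    required = {"date", "tmean_c", "daylength_h"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"weather table is missing columns: {sorted(missing)}")
    if "agronomic" not in df.columns:
        df["agronomic"] = 1.0
    return [
        DailyEnvironment(
            date=row.date,
            tmean_c=float(row.tmean_c),
            daylength_h=float(row.daylength_h),
            agronomic=float(row.agronomic),
        )
        for row in df.itertuples(index=False)
    ]
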