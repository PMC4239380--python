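"""Gompertzian tumour growth laws and their dormancy extensions.

The size of a lesion that has grown for ``t`` days is

    x(t) = exp(ln(b) * (1 - exp(-a * (t + t0))))  =  b ** (1 - exp(-a (t + t0)))

where ``a`` (day^-1) is the growth-rate constant, ``b`` (cells) the saturation
size and ``t0`` (days) an offset encoding the start size: a lesion founded by a
single cell has ``t0 = 0`` (x(0) = 1), while a lesion starting from ``x0``
cells uses the closed-form offset of :func:`offset_from_start_size`.

Metastases may additionally pass through dormant phases during which the
queried size is frozen: an initial dormancy (size stays 1 for ``t_d`` days
after founding) or a late dormancy (growth arrests for ``t_ld`` days once the
lesion reaches a sampled trigger size, e.g. while awaiting neoangiogenesis).
Both are implemented as piecewise time shifts of the plain Gompertz curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Union

import numpy as np

__all__ = [
    "GompertzGrowth",
    "DormancyConfig",
    "LateDormancyConfig",
    "MetastasisState",
    "gompertz_size",
    "offset_from_start_size",
    "invert_growth_time",
    "size_with_dormancy",
    "size_with_late_dormancy",
    "metastasis_size",
    "sample_duration",
    "sample_trigger_size",
    "make_metastasis",
]


@dataclass(frozen=True)
class GompertzGrowth:
    """Parameters of one Gompertz growth curve.

    Parameters
    ----------
    a : float
        Growth-rate constant, per day. ``a = 0`` is permitted only as the
        degenerate "no growth" case (the curve is then constant at 1 cell).
    b : float
        Saturation size, cells. Must exceed 1.
    t0 : float
        Start-size time offset, days. ``t0 = 0`` means the lesion starts as a
        single cell.
    """

    a: float
    b: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"growth rate constant a must be >= 0, got {self.a}")
        if self.b <= 1:
            raise ValueError(f"saturation size b must be > 1 cell, got {self.b}")
        if self.t0 < 0:
            raise ValueError(f"start-size offset t0 must be >= 0, got {self.t0}")

    @classmethod
    def from_start_size(cls, a: float, b: float, x0: float) -> "GompertzGrowth":
        """Build a curve that starts at ``x0`` cells at time 0."""
        return cls(a=a, b=b, t0=offset_from_start_size(a, b, x0))

    @property
    def start_size(self) -> float:
        """Size at t = 0, cells."""
        return _gompertz(self.a, self.b, self.t0, 0.0)

    def scaled_rate(self, factor: float) -> "GompertzGrowth":
        """Same saturation, growth rate multiplied by ``factor``, single-cell start."""
        return GompertzGrowth(a=self.a * factor, b=self.b, t0=0.0)


def _gompertz(a: float, b: float, t0: float, t):
    # raw formula, no domain checks; t may be scalar or ndarray
    return np.exp(np.log(b) * (1.0 - np.exp(-a * (np.asarray(t, dtype=float) + t0))))


def gompertz_size(growth: GompertzGrowth, t):
    """Lesion size in cells after growing for ``t`` days (scalar or array).

    Strictly increasing in ``t`` for ``a > 0`` and bounded above by ``b``.
    Negative times are rejected.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time t must be >= 0")
    out = _gompertz(growth.a, growth.b, growth.t0, t_arr)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def offset_from_start_size(a: float, b: float, x0: float) -> float:
    """Closed-form time offset t0 such that x(0) = x0.

    t0 = -ln(1 - ln(x0)/ln(b)) / a.  A single-cell start (x0 = 1) gives t0 = 0.
    """
    if a <= 0:
        raise ValueError("offset inversion requires a > 0")
    if not (1 <= x0 < b):
        raise ValueError(f"start size must satisfy 1 <= x0 < b, got x0={x0}, b={b}")
    return -math.log(1.0 - math.log(x0) / math.log(b)) / a


def invert_growth_time(growth: GompertzGrowth, x: float) -> float:
    """Days needed for the curve to reach ``x`` cells (inverse of gompertz_size).

    Requires x(0) <= x < b; the saturation size itself is never reached.
    """
    if growth.a <= 0:
        raise ValueError("inversion requires a > 0")
    if x >= growth.b:
        raise ValueError(f"size {x} >= saturation b={growth.b} is never reached")
    if x < 1:
        raise ValueError("size must be >= 1 cell")
    t = -math.log(1.0 - math.log(x) / math.log(growth.b)) / growth.a - growth.t0
    if t < -1e-9:
        raise ValueError(f"size {x} is below the start size {growth.start_size}")
    return max(t, 0.0)


# --------------------------------------------------------------------------
# dormancy


@dataclass(frozen=True)
class DormancyConfig:
    """Initial dormancy: a freshly seeded metastasis stays at size 1 for a
    normally distributed number of days (truncated at 0)."""

    mean_duration: float  # days
    sd_duration: float = 0.0  # days

    def __post_init__(self) -> None:
        if self.mean_duration < 0 or self.sd_duration < 0:
            raise ValueError("dormancy mean and SD must be >= 0")


@dataclass(frozen=True)
class LateDormancyConfig:
    """Late dormancy: growth arrests for a while once the metastasis reaches a
    sampled trigger size.

    The trigger size is drawn normal(size_mean, size_sd) and clipped to
    [size_min, size_max]; the arrest duration is normal(mean_duration,
    sd_duration) truncated at 0.
    """

    size_mean: float = 55.0  # cells
    size_sd: float = 22.5  # cells
    size_min: float = 10.0  # cells
    size_max: float = 100.0  # cells
    mean_duration: float = 30.0  # days
    sd_duration: float = 7.0  # days

    def __post_init__(self) -> None:
        if self.size_min < 2:
            raise ValueError("late-dormancy trigger size_min must be >= 2 cells")
        if self.size_max < self.size_min:
            raise ValueError("size_max must be >= size_min")
        if self.mean_duration < 0 or self.sd_duration < 0:
            raise ValueError("late-dormancy durations must be >= 0")


DormancyRegime = Union[None, DormancyConfig, LateDormancyConfig]

Status = Literal["dormant", "growing", "late_dormant", "resumed"]


@dataclass(frozen=True)
class MetastasisState:
    """One metastasis compartment: founding time, its growth curve and the
    sampled dormancy schedule.

    ``dormancy_end`` is set for initially dormant lesions; ``frozen_size``,
    ``trigger_time`` and ``late_dormancy_end`` are set for late-dormancy
    lesions (the trigger time follows from the trigger size via the growth
    inverse). Status transitions only along
    dormant -> growing -> late_dormant -> resumed.
    """

    founded_at: float  # days
    growth: GompertzGrowth
    status: Status = "growing"
    dormancy_end: Optional[float] = None  # absolute days
    frozen_size: Optional[float] = None  # cells
    trigger_time: Optional[float] = None  # absolute days
    late_dormancy_end: Optional[float] = None  # absolute days

    def status_at(self, t: float) -> Status:
        if self.dormancy_end is not None and t < self.dormancy_end:
            return "dormant"
        if self.late_dormancy_end is not None:
            assert self.trigger_time is not None
            if t < self.trigger_time:
                return "growing"
            if t <= self.late_dormancy_end:
                return "late_dormant"
            return "resumed"
        return "growing"

    def size_at(self, t: float) -> float:
        return metastasis_size(self, t)


def sample_duration(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) duration truncated at 0 days."""
    return max(0.0, float(rng.normal(mean, sd))) if sd > 0 else max(0.0, mean)


def sample_trigger_size(rng: np.random.Generator, cfg: LateDormancyConfig) -> float:
    s = float(rng.normal(cfg.size_mean, cfg.size_sd)) if cfg.size_sd > 0 else cfg.size_mean
    return float(np.clip(s, cfg.size_min, cfg.size_max))


def make_metastasis(
    founded_at: float,
    growth: GompertzGrowth,
    regime: DormancyRegime,
    rng: np.random.Generator,
) -> MetastasisState:
    """Create a metastasis under the configured dormancy regime, sampling any
    dormancy duration / trigger size it needs."""
    if regime is None:
        return MetastasisState(founded_at=founded_at, growth=growth)
    if isinstance(regime, DormancyConfig):
        t_d = sample_duration(rng, regime.mean_duration, regime.sd_duration)
        return MetastasisState(
            founded_at=founded_at,
            growth=growth,
            status="dormant" if t_d > 0 else "growing",
            dormancy_end=founded_at + t_d,
        )
    if isinstance(regime, LateDormancyConfig):
        size = sample_trigger_size(rng, regime)
        t_ld = sample_duration(rng, regime.mean_duration, regime.sd_duration)
        trigger = founded_at + invert_growth_time(growth, size)
        return MetastasisState(
            founded_at=founded_at,
            growth=growth,
            frozen_size=size,
            trigger_time=trigger,
            late_dormancy_end=trigger + t_ld,
        )
    raise TypeError(f"unknown dormancy regime {regime!r}")


def size_with_dormancy(state: MetastasisState, t: float) -> float:
    """Size of an initially dormant metastasis at absolute time ``t``.

    Returns 1 while dormant; afterwards the plain curve evaluated at
    ``t - founded_at - t_d`` (the dormancy acts as a pure time shift).
    """
    if t < state.founded_at:
        raise ValueError("t precedes the founding of the metastasis")
    end = state.dormancy_end if state.dormancy_end is not None else state.founded_at
    if t < end:
        return 1.0
    return gompertz_size(state.growth, t - end)


def size_with_late_dormancy(state: MetastasisState, t: float) -> float:
    """Size of a late-dormancy metastasis at absolute time ``t``.

    Grows as plain Gompertz until the trigger size is reached, returns exactly
    the frozen size during the arrest, then resumes on the plain curve shifted
    by the arrest duration.
    """
    if t < state.founded_at:
        raise ValueError("t precedes the founding of the metastasis")
    assert state.trigger_time is not None and state.late_dormancy_end is not None
    rel = t - state.founded_at
    if t < state.trigger_time:
        return gompertz_size(state.growth, rel)
    if t <= state.late_dormancy_end:
        return float(state.frozen_size)  # type: ignore[arg-type]
    t_ld = state.late_dormancy_end - state.trigger_time
    return gompertz_size(state.growth, rel - t_ld)


def metastasis_size(state: MetastasisState, t: float) -> float:
    """Size of the metastasis at absolute time ``t`` under its regime."""
    if state.late_dormancy_end is not None:
        return size_with_late_dormancy(state, t)
    if state.dormancy_end is not None:
        return size_with_dormancy(state, t)
    if t < state.founded_at:
        raise ValueError("t precedes the founding of the metastasis")
    return gompertz_size(state.growth, t - state.founded_at)
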