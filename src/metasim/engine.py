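"""Discrete-event simulation of metastatic spread in a tumour-bearing host.

Compartments
------------
* primary tumour — continuous, grows along a Gompertz curve and emits
  intravasation events as a non-homogeneous Poisson process with intensity
  beta(x(t)) = m * x(t)**alpha;
* blood — discrete; each founder cell entering the blood is either killed by
  NK cells (probability ``kill_probability``) or extravasates and founds a new
  metastasis. Kill/extravasation is resolved at the intravasation instant
  (zero blood dwell time);
* metastases — continuous, each growing from a single cell at a configurable
  fraction (1/3, 1/2 or 1) of the primary growth-rate constant, optionally
  under a dormancy or late-dormancy regime. Metastases never seed further
  metastases.

Snapshots of the system state (primary size, number of metastases, total
metastatic cells, log-binned size histogram) are taken at a configurable
interval and at the final time. Replicate runs use seeds base_seed + i and are
aggregated into per-bin means and standard deviations.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from . import binning
from .colonization import ColonizationModel, CumulativeIntensity, expected_founder_count
from .growth import (
    DormancyRegime,
    GompertzGrowth,
    MetastasisState,
    gompertz_size,
    make_metastasis,
)

__all__ = [
    "PrimaryTumor",
    "SimulationConfig",
    "Event",
    "Snapshot",
    "SimulationResult",
    "ReplicateSummary",
    "sample_next_intravasation",
    "resolve_blood_fate",
    "run_simulation",
    "run_replicates",
    "snapshots_to_dataframe",
]

GROWTH_FACTORS = (1.0 / 3.0, 0.5, 1.0)


@dataclass(frozen=True)
class PrimaryTumor:
    """Primary-tumour growth inputs: rate constant ``a`` (day^-1), saturation
    ``b`` (cells) and surviving inoculum ``x0`` (cells)."""

    a: float
    b: float = 4.5e9
    x0: float = 1e4

    def growth(self) -> GompertzGrowth:
        return GompertzGrowth.from_start_size(self.a, self.b, self.x0)


@dataclass(frozen=True)
class SimulationConfig:
    """Full scenario definition for one simulation run."""

    primary: PrimaryTumor
    colonization: ColonizationModel
    duration: float  # days
    kill_probability: float = 0.0
    metastasis_growth_factor: float = 1.0
    dormancy: DormancyRegime = None
    snapshot_interval: float = 1.0
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.kill_probability <= 1.0):
            raise ValueError("kill_probability must be in [0, 1]")
        if self.duration <= 0:
            raise ValueError("duration must be > 0 days")
        if self.snapshot_interval <= 0:
            raise ValueError("snapshot_interval must be > 0 days")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.metastasis_growth_factor <= 0:
            raise ValueError("metastasis_growth_factor must be > 0")

    def metastasis_growth(self) -> GompertzGrowth:
        """Growth curve of a freshly founded (single-cell) metastasis."""
        return GompertzGrowth(
            a=self.primary.a * self.metastasis_growth_factor, b=self.primary.b, t0=0.0
        )


EventKind = Literal["intravasation", "blood_fate", "snapshot", "end"]


@dataclass(frozen=True, order=True)
class Event:
    """A scheduled occurrence; ordered by time with FIFO tie-break on ``seq``."""

    time: float
    seq: int
    kind: EventKind = field(compare=False)


@dataclass(frozen=True)
class Snapshot:
    """System state at one instant: primary size, metastasis count, total
    metastatic cell burden and the log-binned size histogram."""

    time: float
    primary_size: float
    n_metastases: int
    total_metastatic_cells: float
    size_histogram: np.ndarray  # counts per binning.BIN_LABELS bin


@dataclass(frozen=True)
class SimulationResult:
    """Snapshots of one replicate plus founder bookkeeping.

    ``n_founders == n_killed + n_extravasated`` holds exactly in every run.
    """

    snapshots: tuple[Snapshot, ...]
    n_founders: int
    n_killed: int
    n_extravasated: int
    seed: int
    final_sizes: tuple[float, ...] = ()
    event_times: Optional[tuple[float, ...]] = None

    @property
    def final(self) -> Snapshot:
        return self.snapshots[-1]


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-bin mean and SD of final-snapshot histograms over replicates."""

    bin_labels: tuple[str, ...]
    bin_mean: np.ndarray
    bin_sd: np.ndarray
    mean_n_metastases: float
    sd_n_metastases: float
    n_replicates: int
    final_counts: np.ndarray  # final n_metastases of each replicate


def sample_next_intravasation(
    rng: np.random.Generator,
    model: ColonizationModel,
    growth: GompertzGrowth,
    t_now: float,
    horizon: float,
    cumulative: Optional[CumulativeIntensity] = None,
) -> Optional[float]:
    """Time of the next intravasation after ``t_now``, or None if no further
    event occurs before ``horizon``.

    The waiting time is the first arrival of a non-homogeneous Poisson process
    with intensity beta(x(t)): draw E ~ Exponential(1) and solve
    Lambda(t_next) - Lambda(t_now) = E, where Lambda is the cumulative
    intensity. With a precomputed ``cumulative`` tabulation the inversion is a
    monotone interpolation; otherwise Lambda is evaluated by adaptive
    quadrature and the root bracketed by Brent's method.
    """
    if t_now < 0:
        raise ValueError("t_now must be >= 0")
    if model.m == 0:
        return None
    excess = float(rng.exponential(1.0))
    if cumulative is not None:
        target = cumulative.value(t_now) + excess
        if target > cumulative.total:
            return None
        return cumulative.inverse(target)

    from scipy.optimize import brentq

    remaining = expected_founder_count(model, growth, horizon) - expected_founder_count(
        model, growth, t_now
    )
    if excess > remaining:
        return None

    def f(t: float) -> float:
        return (
            expected_founder_count(model, growth, t)
            - expected_founder_count(model, growth, t_now)
            - excess
        )

    return float(brentq(f, t_now, horizon, xtol=1e-10, rtol=1e-12))


def resolve_blood_fate(
    rng: np.random.Generator, kill_probability: float
) -> Literal["killed", "extravasated"]:
    """Fate of one founder cell in the blood: killed by NK cells with
    probability ``kill_probability``, else extravasation."""
    if not (0.0 <= kill_probability <= 1.0):
        raise ValueError("kill_probability must be in [0, 1]")
    return "killed" if rng.random() < kill_probability else "extravasated"


def _snapshot_times(duration: float, interval: float) -> np.ndarray:
    times = np.arange(interval, duration, interval)
    if times.size == 0 or duration - times[-1] > 1e-9:
        times = np.append(times, duration)
    else:
        times[-1] = duration
    return times


def _metastasis_sizes(mets: list[MetastasisState], t: float) -> np.ndarray:
    """Vectorised size query for all metastases at time t.

    Every dormancy regime reduces to evaluating the shared metastasis growth
    curve at a piecewise effective time, so a single vectorised Gompertz
    evaluation covers the whole population.
    """
    if not mets:
        return np.empty(0)
    g = mets[0].growth
    founded = np.array([m.founded_at for m in mets])
    rel = t - founded
    teff = rel.copy()
    for i, m in enumerate(mets):
        if m.late_dormancy_end is not None:
            trig_rel = m.trigger_time - m.founded_at
            t_ld = m.late_dormancy_end - m.trigger_time
            if rel[i] >= trig_rel + t_ld:
                teff[i] = rel[i] - t_ld
            elif rel[i] >= trig_rel:
                teff[i] = trig_rel
        elif m.dormancy_end is not None:
            t_d = m.dormancy_end - m.founded_at
            teff[i] = max(rel[i] - t_d, 0.0) if rel[i] >= t_d else -1.0
    sizes = np.where(
        teff < 0, 1.0, np.exp(np.log(g.b) * (1.0 - np.exp(-g.a * np.maximum(teff, 0.0))))
    )
    return sizes


def run_simulation(
    config: SimulationConfig,
    seed: Optional[int] = None,
    record_events: bool = False,
) -> SimulationResult:
    """Run one replicate of the discrete-event simulation.

    Events are processed in non-decreasing time order with FIFO tie-breaking.
    An intravasation event resolves the blood fate immediately; a surviving
    cell founds a metastasis under the configured growth factor and dormancy
    regime, and the next intravasation is scheduled from the colonization
    intensity. Snapshots are recorded at the configured interval and at the
    final time.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    primary = config.primary.growth()
    met_growth = config.metastasis_growth()
    cumulative = (
        CumulativeIntensity(config.colonization, primary, config.duration)
        if config.colonization.m > 0
        else None
    )

    heap: list[Event] = []
    seq = 0

    def push(time: float, kind: EventKind) -> None:
        nonlocal seq
        heapq.heappush(heap, Event(time=time, seq=seq, kind=kind))
        seq += 1

    for t_snap in _snapshot_times(config.duration, config.snapshot_interval):
        push(float(t_snap), "snapshot")
    push(config.duration, "end")

    t_first = sample_next_intravasation(
        rng, config.colonization, primary, 0.0, config.duration, cumulative
    )
    if t_first is not None:
        push(t_first, "intravasation")

    mets: list[MetastasisState] = []
    snapshots: list[Snapshot] = []
    n_founders = n_killed = n_extravasated = 0
    event_times: list[float] = []
    last_sizes = np.empty(0)

    while heap:
        ev = heapq.heappop(heap)
        if record_events:
            event_times.append(ev.time)
        if ev.kind == "intravasation":
            n_founders += 1
            fate = resolve_blood_fate(rng, config.kill_probability)
            if fate == "killed":
                n_killed += 1
            else:
                n_extravasated += 1
                mets.append(
                    make_metastasis(ev.time, met_growth, config.dormancy, rng)
                )
            t_next = sample_next_intravasation(
                rng, config.colonization, primary, ev.time, config.duration, cumulative
            )
            if t_next is not None:
                push(t_next, "intravasation")
        elif ev.kind == "snapshot":
            sizes = _metastasis_sizes(mets, ev.time)
            last_sizes = sizes
            snapshots.append(
                Snapshot(
                    time=ev.time,
                    primary_size=gompertz_size(primary, ev.time),
                    n_metastases=len(mets),
                    total_metastatic_cells=float(sizes.sum()),
                    size_histogram=binning.histogram_counts(sizes),
                )
            )
        elif ev.kind == "end":
            break

    return SimulationResult(
        snapshots=tuple(snapshots),
        n_founders=n_founders,
        n_killed=n_killed,
        n_extravasated=n_extravasated,
        seed=seed,
        final_sizes=tuple(float(s) for s in last_sizes),
        event_times=tuple(event_times) if record_events else None,
    )


def run_replicates(config: SimulationConfig) -> ReplicateSummary:
    """Run ``config.replicates`` replicates (seed = base seed + i) and
    aggregate the final-snapshot histograms into per-bin mean and SD."""
    hists = np.empty((config.replicates, binning.N_BINS))
    counts = np.empty(config.replicates)
    for i in range(config.replicates):
        try:
            result = run_simulation(config, seed=config.seed + i)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"replicate {i} (seed {config.seed + i}) failed") from exc
        hists[i] = result.final.size_histogram
        counts[i] = result.final.n_metastases
    if config.replicates == 1:
        bin_sd = np.zeros(binning.N_BINS)
        sd_n = 0.0
    else:
        bin_sd = hists.std(axis=0, ddof=1)
        sd_n = float(counts.std(ddof=1))
    return ReplicateSummary(
        bin_labels=binning.BIN_LABELS,
        bin_mean=hists.mean(axis=0),
        bin_sd=bin_sd,
        mean_n_metastases=float(counts.mean()),
        sd_n_metastases=sd_n,
        n_replicates=config.replicates,
        final_counts=counts,
    )


def snapshots_to_dataframe(result: SimulationResult) -> pd.DataFrame:
    """One row per snapshot: time, primary size, counts and histogram bins."""
    rows = []
    for s in result.snapshots:
        row = {
            "time": s.time,
            "primary_cells": s.primary_size,
            "n_metastases": s.n_metastases,
            "total_met_cells": s.total_metastatic_cells,
        }
        row.update({f"bin_{lbl}": int(c) for lbl, c in zip(binning.BIN_LABELS, s.size_histogram)})
        rows.append(row)
    return pd.DataFrame(rows)
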