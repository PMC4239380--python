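"""Calibration of the model constants from cohort summary statistics.

Every constant is fitted from printed cohort means, exactly as the study
design implies:

* growth-rate constant ``a`` — closed-form inversion of the Gompertz curve
  through (mean tumour weight, mean experiment duration);
* colonization constant ``m`` — linear inversion of the expected-founder
  integral against the observed lung-metastasis count;
* NK kill probability — closed form 1 - observed/expected, cross-checked by
  a simulated grid scan;
* total metastases per lung — the histology section-count correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .colonization import ColonizationModel, expected_founder_count
from .engine import PrimaryTumor, SimulationConfig, run_replicates
from .growth import GompertzGrowth

__all__ = [
    "CalibrationInputs",
    "fit_growth_rate_constant",
    "fit_colonization_constant",
    "fit_kill_probability",
    "KillProbabilityFit",
    "estimate_total_metastases",
]

CELLS_PER_GRAM = 1e9


@dataclass(frozen=True)
class CalibrationInputs:
    """Printed cohort summaries that drive the fits."""

    mean_tumor_weight: float  # grams
    mean_duration: float  # days
    max_tumor_weight_b: float = 4.5  # grams
    start_cells_x0: float = 1e4  # cells
    cells_per_gram: float = CELLS_PER_GRAM
    observed_metastases: float = 0.0
    alpha: float = 0.663

    def __post_init__(self) -> None:
        for name in (
            "mean_tumor_weight",
            "mean_duration",
            "max_tumor_weight_b",
            "start_cells_x0",
            "cells_per_gram",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mean_tumor_weight >= self.max_tumor_weight_b:
            raise ValueError("mean tumour weight must be below the saturation weight b")
        if self.observed_metastases < 0:
            raise ValueError("observed_metastases must be >= 0")

    @property
    def b_cells(self) -> float:
        return self.max_tumor_weight_b * self.cells_per_gram

    @property
    def final_cells(self) -> float:
        return self.mean_tumor_weight * self.cells_per_gram

    def growth(self) -> GompertzGrowth:
        """Gompertz curve with the fitted growth-rate constant and the
        configured start size."""
        a = fit_growth_rate_constant(self)
        return GompertzGrowth.from_start_size(a, self.b_cells, self.start_cells_x0)


def fit_growth_rate_constant(inputs: CalibrationInputs) -> float:
    """Growth-rate constant ``a`` (day^-1) through the cohort mean endpoint.

    Closed form: a = ln[(1 - ln x0/ln b) / (1 - ln x_T/ln b)] / T with
    x_T = weight * cells_per_gram. The resulting curve reproduces x_T at T to
    machine precision. Zero growth (x_T = x0) yields a = 0.
    """
    b = inputs.b_cells
    x0 = inputs.start_cells_x0
    x_T = inputs.final_cells
    if x_T >= b:
        raise ValueError("final tumour size reaches saturation; a is unidentifiable")
    if x_T < x0:
        raise ValueError("final tumour size below the start size implies shrinkage")
    a = math.log((1 - math.log(x0) / math.log(b)) / (1 - math.log(x_T) / math.log(b)))
    return a / inputs.mean_duration


def fit_colonization_constant(
    inputs: CalibrationInputs, growth: Optional[GompertzGrowth] = None
) -> float:
    """Colonization constant ``m`` ((cell*day)^-1) from the observed count.

    The expected founder count is linear in m, so
    m = observed / integral_0^T x(t)**alpha dt — an exact inversion of the
    quadrature.
    """
    if growth is None:
        growth = inputs.growth()
    unit = expected_founder_count(
        ColonizationModel(m=1.0, alpha=inputs.alpha), growth, inputs.mean_duration
    )
    if unit <= 0:
        raise ValueError("expected founder integral is zero; m is unidentifiable")
    return inputs.observed_metastases / unit


@dataclass(frozen=True)
class KillProbabilityFit:
    """Closed-form and simulation-grid estimates of the NK kill probability."""

    closed_form: float
    grid_value: float
    grid: np.ndarray
    grid_means: np.ndarray
    expected_founders: float

    def __post_init__(self) -> None:
        step = float(self.grid[1] - self.grid[0]) if len(self.grid) > 1 else 1.0
        if abs(self.closed_form - self.grid_value) > step + 1e-12:
            raise RuntimeError(
                "closed-form and simulated kill probabilities disagree by more "
                f"than one grid step: {self.closed_form:.4f} vs {self.grid_value:.2f}"
            )


def fit_kill_probability(
    observed: float,
    model: ColonizationModel,
    growth: GompertzGrowth,
    T: float,
    grid_step: float = 0.05,
    replicates: int = 100,
    base_seed: int = 0,
    b: Optional[float] = None,
    x0: float = 1e4,
) -> KillProbabilityFit:
    """NK kill probability matching the observed metastasis count.

    Returns both the closed form 1 - observed/expected_founders and the value
    on a probability grid (default step 0.05) whose simulated mean final count
    over ``replicates`` replicates is closest to ``observed``; the two must
    agree within one grid step. An observed count above the expectation clips
    the closed form at 0 with a warning.
    """
    expected = expected_founder_count(model, growth, T)
    if expected <= 0:
        raise ValueError("expected founder count is zero; kill probability unidentifiable")
    closed = 1.0 - observed / expected
    if closed < 0:
        warnings.warn(
            "observed count exceeds expected founders; kill probability clipped at 0",
            stacklevel=2,
        )
        closed = 0.0

    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    # back out the start size from the curve's own offset so the simulated
    # primary matches the fitted growth exactly
    primary = PrimaryTumor(a=growth.a, b=growth.b, x0=_start_size(growth))
    means = np.empty(len(grid))
    for j, p in enumerate(grid):
        config = SimulationConfig(
            primary=primary,
            colonization=model,
            duration=T,
            kill_probability=float(p),
            snapshot_interval=T,
            replicates=replicates,
            seed=base_seed + j * replicates,
        )
        means[j] = run_replicates(config).mean_n_metastases
    grid_value = float(grid[int(np.argmin(np.abs(means - observed)))])
    return KillProbabilityFit(
        closed_form=closed,
        grid_value=grid_value,
        grid=grid,
        grid_means=means,
        expected_founders=expected,
    )


def _start_size(growth: GompertzGrowth) -> float:
    return math.exp(math.log(growth.b) * (1.0 - math.exp(-growth.a * growth.t0)))


def estimate_total_metastases(mean_per_section: float, total_sections: int) -> int:
    """Whole-lung metastasis estimate from histological sections:
    mean count per section x number of sections, reduced by 20% to correct
    for deposits spanning adjacent sections; rounded to the nearest integer."""
    if mean_per_section < 0 or total_sections < 0:
        raise ValueError("section counts must be >= 0")
    return int(round(mean_per_section * total_sections * 0.8))
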