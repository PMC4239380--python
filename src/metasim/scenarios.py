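"""Scenario grid: dormancy regimes x metastasis growth rates.

Reproduces the in-silico experiment that discriminates between dormancy
hypotheses: for each strain, every combination of a dormancy regime (none,
21-day dormancy, 30-day dormancy, 30-day late dormancy) and a metastasis
growth-rate factor (1/3, 1/2, 1 x the primary constant) is simulated over
replicates, and the final metastasis-size histograms (log-binned, with a
dedicated single-cell DTC bin) are summarised as per-bin mean +/- SD. A
morphology verdict compares each histogram against the observed lung
morphology (e.g. "mostly DTCs" in rag2 mice, deposits of 10-100 cells in
pfp/rag2 mice).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import binning
from .binning import BIN_LABELS, DTC_BIN, classify_deposit
from .engine import GROWTH_FACTORS, ReplicateSummary, SimulationConfig, run_replicates
from .growth import DormancyConfig, DormancyRegime, LateDormancyConfig

__all__ = [
    "SizeHistogram",
    "ScenarioGrid",
    "MorphologyTarget",
    "Verdict",
    "DEFAULT_REGIMES",
    "classify_deposit",
    "run_scenario_grid",
    "grid_to_frame",
    "morphology_verdict",
    "plot_scenario_grid",
]

DEFAULT_REGIMES: Mapping[str, DormancyRegime] = {
    "none": None,
    "dormancy_21d": DormancyConfig(mean_duration=21.0, sd_duration=7.0),
    "dormancy_30d": DormancyConfig(mean_duration=30.0, sd_duration=7.0),
    "late_dormancy_30d": LateDormancyConfig(mean_duration=30.0, sd_duration=7.0),
}


@dataclass(frozen=True)
class SizeHistogram:
    """Per-bin mean and SD of final metastasis counts over replicates."""

    labels: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int

    @property
    def total(self) -> float:
        """Mean total number of deposits."""
        return float(self.mean.sum())

    @property
    def modal_bin(self) -> Optional[str]:
        if self.total == 0:
            return None
        return self.labels[int(np.argmax(self.mean))]

    def fraction(self, label: str) -> float:
        """Mean fraction of deposits falling in the named bin."""
        if self.total == 0:
            return 0.0
        return float(self.mean[self.labels.index(label)] / self.total)

    @classmethod
    def from_summary(cls, summary: ReplicateSummary) -> "SizeHistogram":
        return cls(
            labels=summary.bin_labels,
            mean=summary.bin_mean,
            sd=summary.bin_sd,
            n_replicates=summary.n_replicates,
        )


@dataclass(frozen=True)
class ScenarioGrid:
    """The dormancy-regime x growth-factor design."""

    regimes: Mapping[str, DormancyRegime] = field(
        default_factory=lambda: dict(DEFAULT_REGIMES)
    )
    growth_factors: tuple[float, ...] = GROWTH_FACTORS


def run_scenario_grid(
    base_config: SimulationConfig,
    grid: Optional[ScenarioGrid] = None,
    replicates: Optional[int] = None,
) -> dict[tuple[str, float], SizeHistogram]:
    """Simulate every grid cell from ``base_config`` (dormancy and growth
    factor are overridden per cell) and return the per-cell histograms."""
    if grid is None:
        grid = ScenarioGrid()
    out: dict[tuple[str, float], SizeHistogram] = {}
    for name, regime in grid.regimes.items():
        for factor in grid.growth_factors:
            config = replace(
                base_config,
                dormancy=regime,
                metastasis_growth_factor=factor,
                **({"replicates": replicates} if replicates is not None else {}),
            )
            out[(name, factor)] = SizeHistogram.from_summary(run_replicates(config))
    return out


def grid_to_frame(results: Mapping[tuple[str, float], SizeHistogram]) -> pd.DataFrame:
    """Long-format table: one row per (regime, growth factor, bin)."""
    rows = []
    for (regime, factor), hist in results.items():
        for label, mean, sd in zip(hist.labels, hist.mean, hist.sd):
            rows.append(
                {
                    "regime": regime,
                    "growth_factor": factor,
                    "bin": label,
                    "mean": mean,
                    "sd": sd,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MorphologyTarget:
    """Observed-morphology descriptor: the bin that must be modal and the
    minimum fraction of deposits it must contain."""

    modal_bin: str = DTC_BIN
    min_fraction: float = 0.5


@dataclass(frozen=True)
class Verdict:
    fraction: float
    modal_bin: Optional[str]
    consistent: bool
    reason: str


def morphology_verdict(hist: SizeHistogram, target: MorphologyTarget) -> Verdict:
    """Compare a simulated histogram against an observed-morphology target.

    Consistent when the modal bin matches the target bin and holds more than
    ``min_fraction`` of all deposits.
    """
    if hist.total == 0:
        return Verdict(0.0, None, False, "no metastases")
    frac = hist.fraction(target.modal_bin)
    modal = hist.modal_bin
    ok = modal == target.modal_bin and frac > target.min_fraction
    reason = (
        f"modal bin {modal}, fraction in {target.modal_bin} = {frac:.2f} "
        f"(threshold {target.min_fraction:.2f})"
    )
    return Verdict(frac, modal, ok, reason)


def plot_scenario_grid(
    results: Mapping[tuple[str, float], SizeHistogram], path: Optional[str] = None
):
    """Bar-chart panel per growth factor, bars grouped by dormancy regime
    over the log size bins (mirrors the published figure layout)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    factors = sorted({f for _, f in results})
    regimes = list(dict.fromkeys(r for r, _ in results))
    fig, axes = plt.subplots(1, len(factors), figsize=(5 * len(factors), 4), squeeze=False)
    width = 0.8 / max(len(regimes), 1)
    # only plot bins that are occupied somewhere
    occupied = np.zeros(binning.N_BINS, dtype=bool)
    for hist in results.values():
        occupied |= hist.mean > 0
    n_show = max(int(np.max(np.nonzero(occupied)[0])) + 1 if occupied.any() else 1, 4)
    xs = np.arange(n_show)
    for ax, factor in zip(axes[0], factors):
        for k, regime in enumerate(regimes):
            hist = results[(regime, factor)]
            ax.bar(
                xs + k * width,
                hist.mean[:n_show],
                width=width,
                yerr=hist.sd[:n_show],
                label=regime,
                capsize=2,
            )
        ax.set_xticks(xs + 0.4 - width / 2)
        ax.set_xticklabels(BIN_LABELS[:n_show], rotation=45, ha="right")
        ax.set_title(f"metastasis growth factor {factor:g}")
        ax.set_xlabel("metastasis size (cells)")
        ax.set_ylabel("mean count per run")
    axes[0][0].legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
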