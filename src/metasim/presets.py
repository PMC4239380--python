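"""Study presets for the two mouse strains.

The HT29 xenograft cohorts behind the model:

* ``pfp_rag2`` — perforin/rag2 double knockout: NK cells present but unable to
  kill via perforin. Mean primary weight 1.23 g at a mean 49.9 days; 788 lung
  metastases used for the colonization fit; kill probability 0.
* ``rag2`` — rag2 single knockout with cytotoxic NK cells. Mean 1.16 g at
  69.4 days; 209 metastases; fitted NK kill probability 0.8. The colonization
  constant is shared with pfp_rag2 (same cell line, same spreading behaviour).

The growth-rate and colonization constants are recomputed from these inputs at
call time via the calibration module, never stored as magic numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from .calibration import (
    CalibrationInputs,
    fit_colonization_constant,
    fit_growth_rate_constant,
)
from .colonization import ColonizationModel
from .engine import PrimaryTumor, SimulationConfig
from .growth import DormancyRegime

__all__ = [
    "PFP_RAG2",
    "RAG2",
    "STRAINS",
    "StrainPreset",
    "calibrated_constants",
    "scenario_config",
]

PFP_RAG2 = CalibrationInputs(
    mean_tumor_weight=1.23,
    mean_duration=49.9,
    observed_metastases=788,
)

RAG2 = CalibrationInputs(
    mean_tumor_weight=1.16,
    mean_duration=69.4,
    observed_metastases=209,
)

STRAINS = {"pfp_rag2": PFP_RAG2, "rag2": RAG2}

# fitted NK kill probabilities (0: perforin-deficient NK cells cannot kill)
KILL_PROBABILITY = {"pfp_rag2": 0.0, "rag2": 0.8}


@dataclass(frozen=True)
class StrainPreset:
    """Calibrated constants for one strain scenario."""

    strain: str
    growth_rate: float  # a, day^-1
    colonization_m: float  # (cell*day)^-1
    kill_probability: float
    duration: float  # days


@lru_cache(maxsize=None)
def calibrated_constants() -> dict[str, StrainPreset]:
    """Fit (a_pfp, a_rag2, m) from the printed cohort means.

    The colonization constant is fitted on the pfp_rag2 cohort and applied to
    both strains.
    """
    a = {s: fit_growth_rate_constant(inp) for s, inp in STRAINS.items()}
    m = fit_colonization_constant(PFP_RAG2)
    return {
        s: StrainPreset(
            strain=s,
            growth_rate=a[s],
            colonization_m=m,
            kill_probability=KILL_PROBABILITY[s],
            duration=STRAINS[s].mean_duration,
        )
        for s in STRAINS
    }


def scenario_config(
    strain: str,
    dormancy: DormancyRegime = None,
    metastasis_growth_factor: float = 1.0,
    replicates: int = 100,
    seed: int = 0,
    snapshot_interval: Optional[float] = None,
    kill_probability: Optional[float] = None,
) -> SimulationConfig:
    """Calibrated SimulationConfig for one strain scenario."""
    preset = calibrated_constants()[strain]
    inputs = STRAINS[strain]
    return SimulationConfig(
        primary=PrimaryTumor(
            a=preset.growth_rate, b=inputs.b_cells, x0=inputs.start_cells_x0
        ),
        colonization=ColonizationModel(m=preset.colonization_m, alpha=inputs.alpha),
        duration=preset.duration,
        kill_probability=(
            preset.kill_probability if kill_probability is None else kill_probability
        ),
        metastasis_growth_factor=metastasis_growth_factor,
        dormancy=dormancy,
        snapshot_interval=(
            preset.duration if snapshot_interval is None else snapshot_interval
        ),
        replicates=replicates,
        seed=seed,
    )
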