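"""Kinase / VEGF-binding inhibitor experiments under normoxia and hypoxia.

A :class:`DrugExperiment` sweeps one drug target over a ``[D]/K_i`` grid
at one or more O₂ levels.  Per case and O₂ level, the readout at each
dose is normalised to the *same-O₂ no-drug* steady state, so hypoxia and
drug effects are never conflated.  Sensitivity at a reference dose is
banded as strong (≥40% readout reduction), intermediate, or ineffective
(<10% reduction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network_model import DRUG_TARGETS, Environment, ReactionNetwork
from .population import EnsembleRecord
from .simulation import DEFAULT_SETTINGS, SolverSettings, integrate_to_steady_state

__all__ = [
    "DrugExperiment",
    "DoseResponseCurve",
    "run_drug_experiment",
    "half_inhibition_shift",
    "classify_sensitivity",
    "REFERENCE_DOSES",
]

#: reference [D]/K_i doses used for the sensitivity histograms/trees
REFERENCE_DOSES = {
    "RAF_phospho": 100.0,
    "MEK_phospho": 2000.0,
    "AKT_phospho": 200.0,
    "VEGF_binding": 1000.0,
}


def default_dose_grid() -> Tuple[float, ...]:
    """13 log-spaced points over 10⁻¹–10⁵ (covers the response dynamic range)."""
    return tuple(np.geomspace(0.1, 1e5, 13))


@dataclass(frozen=True)
class DrugExperiment:
    """One drug target swept over a dose grid at given O₂ levels."""

    target: str
    readout: str = "pERK"
    d_over_ki_grid: Tuple[float, ...] = field(default_factory=default_dose_grid)
    o2_levels: Tuple[float, ...] = (1.0, 0.005)
    sensitivity_bands: Tuple[float, float] = (0.6, 0.9)

    def __post_init__(self) -> None:
        if self.target not in DRUG_TARGETS:
            raise ValueError(f"unknown drug target {self.target!r}")
        grid = tuple(float(d) for d in self.d_over_ki_grid)
        if any(d <= 0 for d in grid) or any(np.diff(grid) <= 0):
            raise ValueError("d_over_ki_grid must be ascending and positive")
        object.__setattr__(self, "d_over_ki_grid", grid)


@dataclass
class DoseResponseCurve:
    """Readout ratio vs dose for one case at one O₂ level.

    Ratios are relative to the same-O₂ no-drug steady state; the
    implicit dose-zero point is therefore exactly 1.  ``half_inhibition``
    is the log-linearly interpolated dose where the ratio crosses 0.5
    (None when never crossed).
    """

    case_id: int
    o2_fraction: float
    doses: np.ndarray
    ratios: np.ndarray
    converged: np.ndarray

    @property
    def half_inhibition(self) -> Optional[float]:
        return interpolate_crossing(self.doses, self.ratios, 0.5)


def interpolate_crossing(
    doses: np.ndarray, ratios: np.ndarray, level: float
) -> Optional[float]:
    """Log-linear interpolation of the first downward crossing of ``level``."""
    doses = np.asarray(doses, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    ok = np.isfinite(ratios)
    doses, ratios = doses[ok], ratios[ok]
    if ratios.size == 0:
        return None
    if ratios[0] <= level:
        return float(doses[0])
    for i in range(1, ratios.size):
        if ratios[i] <= level:
            x0, x1 = math.log(doses[i - 1]), math.log(doses[i])
            y0, y1 = ratios[i - 1], ratios[i]
            frac = (y0 - level) / (y0 - y1)
            return float(math.exp(x0 + frac * (x1 - x0)))
    return None


def run_drug_experiment(
    net: ReactionNetwork,
    records: Sequence[EnsembleRecord],
    experiment: DrugExperiment,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> Dict[Tuple[int, float], DoseResponseCurve]:
    """Dose–response curves for every converged case × O₂ level.

    Each point integrates the case from its normoxic baseline to the
    steady state of (O₂ level, dose); the readout is normalised to the
    no-drug steady state at the same O₂ level.  Non-converged points are
    flagged NaN and the batch continues.
    """
    if experiment.readout not in net.index:
        raise KeyError(f"readout species {experiment.readout!r} not in network")
    ridx = net.index[experiment.readout]
    curves: Dict[Tuple[int, float], DoseResponseCurve] = {}
    for rec in records:
        if not rec.baseline.converged:
            continue
        for o2 in experiment.o2_levels:
            env0 = Environment(o2_fraction=o2)
            base = rec.conditions.get(env0)
            if base is None:
                base = integrate_to_steady_state(net, rec.baseline.state, env0, settings)
                rec.conditions[env0] = base
            if not base.converged or base.state[ridx] <= 0:
                continue
            ref = float(base.state[ridx])
            ratios = np.full(len(experiment.d_over_ki_grid), np.nan)
            conv = np.zeros(len(experiment.d_over_ki_grid), dtype=bool)
            for k, dose in enumerate(experiment.d_over_ki_grid):
                env = Environment(
                    o2_fraction=o2, drugs=((experiment.target, dose),)
                )
                res = rec.conditions.get(env)
                if res is None:
                    res = integrate_to_steady_state(
                        net, rec.baseline.state, env, settings
                    )
                    rec.conditions[env] = res
                conv[k] = res.converged
                if res.converged:
                    ratios[k] = float(res.state[ridx]) / ref
            curves[(rec.case_id, o2)] = DoseResponseCurve(
                case_id=rec.case_id,
                o2_fraction=o2,
                doses=np.asarray(experiment.d_over_ki_grid),
                ratios=ratios,
                converged=conv,
            )
    return curves


def half_inhibition_shift(
    curve_normoxia: DoseResponseCurve, curve_hypoxia: DoseResponseCurve
) -> Optional[float]:
    """Fold shift of the half-inhibition dose between two curves.

    ``shift = dose₅₀(normoxia) / dose₅₀(hypoxia)`` — values > 1 mean the
    drug is more potent under hypoxia.  None when either curve never
    crosses a ratio of 0.5.
    """
    a = curve_normoxia.half_inhibition
    b = curve_hypoxia.half_inhibition
    if a is None or b is None:
        return None
    return a / b


def classify_sensitivity(
    ratio_at_reference_dose: float,
    bands: Tuple[float, float] = (0.6, 0.9),
) -> str:
    """Band a readout ratio at the reference dose.

    ``sensitive`` ⇔ ratio ≤ 0.6 (≥40% reduction); ``ineffective`` ⇔
    ratio ≥ 0.9 (<10% reduction); otherwise ``intermediate``.
    """
    if ratio_at_reference_dose < 0:
        raise ValueError("ratio must be >= 0")
    lo, hi = bands
    if ratio_at_reference_dose <= lo:
        return "sensitive"
    if ratio_at_reference_dose >= hi:
        return "ineffective"
    return "intermediate"


def curves_table(curves: Dict[Tuple[int, float], DoseResponseCurve]) -> pd.DataFrame:
    """Tidy export keyed by (case_id, o2, d_over_ki)."""
    rows = []
    for (case_id, o2), c in sorted(curves.items()):
        for dose, ratio, conv in zip(c.doses, c.ratios, c.converged):
            rows.append(
                {
                    "case_id": case_id,
                    "o2_fraction": o2,
                    "d_over_ki": dose,
                    "ratio": ratio,
                    "converged": bool(conv),
                }
            )
    return pd.DataFrame(rows)
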