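"""Virtual-cell ensembles and test fixtures.

A "virtual cell" (case) is one Latin-hypercube draw of initial
biomolecule concentrations, equilibrated to its normoxic steady state.
Sampling is log₁₀-uniform over a configurable total fold range centred on
the nominal value (``[x₀/10, 10·x₀]`` for the default 100-fold span) and
stratified per species: exactly one draw per equal-log-width bin.  Only
tumor-module species are sampled by default; the HIF and ATP modules are
held at their nominal values.

The module also builds the package's test oracles: tiny networks with
closed-form steady states and planted-threshold classification datasets
for the decision-tree stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .network_model import (
    Environment,
    NORMOXIA,
    ReactionDef,
    ReactionNetwork,
    SpeciesDef,
)
from .simulation import (
    DEFAULT_SETTINGS,
    SolverSettings,
    SteadyStateResult,
    integrate_to_steady_state,
)

__all__ = [
    "EnsembleConfig",
    "EnsembleRecord",
    "lhs_sample",
    "generate_population",
    "simulate_conditions",
    "planted_threshold_dataset",
    "toy_fixture_network",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Sampling plan for the virtual-cell population.

    ``n_cases`` defaults to the full study size (20,000); scaled-down runs
    pass a smaller value explicitly.  ``fold_range`` is the total span of
    the sampled concentration range (100 → one decade either side of the
    nominal).  ``sampled_species`` of ``None`` means every tumor-module
    species.
    """

    n_cases: int = 20_000
    fold_range: float = 100.0
    seed: int = 0
    sampled_species: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        if self.fold_range <= 1:
            raise ValueError("fold_range must be > 1")


@dataclass
class EnsembleRecord:
    """One virtual cell: sampled initials and its steady states."""

    case_id: int
    sampled_initials: np.ndarray
    baseline: SteadyStateResult
    conditions: Dict[Environment, SteadyStateResult] = field(default_factory=dict)
    derived: Dict[str, float] = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.baseline.converged


def _resolve_sampled(net: ReactionNetwork, cfg: EnsembleConfig) -> List[int]:
    if cfg.sampled_species is None:
        idx = [i for i, s in enumerate(net.species) if s.module == "tumor"]
    else:
        missing = [s for s in cfg.sampled_species if s not in net.index]
        if missing:
            raise ValueError(f"sampled_species not in network: {missing}")
        idx = [net.index[s] for s in cfg.sampled_species]
    return idx


def lhs_sample(
    nominals: np.ndarray,
    cfg: EnsembleConfig,
    sampled_idx: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Latin-hypercube initial-condition matrix (``n_cases × n_species``).

    For each sampled species the ``n_cases`` values are a stratified
    log₁₀-uniform sample over ``[x₀/√fold, x₀·√fold]`` (one value per
    equal-log-width bin); unsampled species keep their nominal values.
    Deterministic for a fixed seed.
    """
    nominals = np.asarray(nominals, dtype=float)
    if sampled_idx is None:
        sampled_idx = list(range(nominals.size))
    sampled_idx = list(sampled_idx)
    if any(nominals[i] <= 0 for i in sampled_idx):
        bad = [i for i in sampled_idx if nominals[i] <= 0]
        raise ValueError(
            f"sampled species need positive nominal values (indices {bad})"
        )
    out = np.tile(nominals, (cfg.n_cases, 1))
    if cfg.n_cases == 0 or not sampled_idx:
        return out
    sampler = qmc.LatinHypercube(d=len(sampled_idx), seed=cfg.seed)
    u = sampler.random(cfg.n_cases)  # stratified in [0, 1) per column
    half_span = 0.5 * np.log10(cfg.fold_range)
    for col, i in enumerate(sampled_idx):
        log0 = np.log10(nominals[i])
        out[:, i] = 10.0 ** (log0 + (2.0 * u[:, col] - 1.0) * half_span)
    return out


def generate_population(
    net: ReactionNetwork,
    cfg: EnsembleConfig,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> List[EnsembleRecord]:
    """Sample ``n_cases`` virtual cells and equilibrate each at normoxia.

    Non-converged cases are flagged on their record (``converged``) and
    never abort the batch.
    """
    sampled_idx = _resolve_sampled(net, cfg)
    mat = lhs_sample(net.initial_state(), cfg, sampled_idx)
    records: List[EnsembleRecord] = []
    for k in range(cfg.n_cases):
        ss = integrate_to_steady_state(net, mat[k], NORMOXIA, settings)
        records.append(EnsembleRecord(case_id=k, sampled_initials=mat[k], baseline=ss))
    return records


def simulate_conditions(
    net: ReactionNetwork,
    records: Sequence[EnsembleRecord],
    conditions: Sequence[Environment],
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> None:
    """Fill ``record.conditions`` with per-condition steady states.

    Each condition is a step change applied to the case's own normoxic
    steady state; conditions are independent (no carry-over).  Cases with
    a non-converged baseline are skipped.
    """
    for rec in records:
        if not rec.baseline.converged:
            continue
        for env in conditions:
            if env in rec.conditions:
                continue
            rec.conditions[env] = integrate_to_steady_state(
                net, rec.baseline.state, env, settings
            )


def population_table(
    net: ReactionNetwork,
    records: Sequence[EnsembleRecord],
    condition: Optional[Environment] = None,
) -> pd.DataFrame:
    """Wide table (rows = cases, columns = species) of steady states."""
    rows = []
    idx = []
    for rec in records:
        res = rec.baseline if condition is None else rec.conditions.get(condition)
        if res is None or not res.converged:
            continue
        rows.append(res.state)
        idx.append(rec.case_id)
    return pd.DataFrame(rows, index=idx, columns=net.species_ids())


def planted_threshold_dataset(
    n: int,
    threshold: float,
    feature_count: int = 5,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Labelled table whose class is ``feature_0 > threshold`` plus label noise.

    All features are i.i.d. uniform on [0, 1); labels are flipped with
    probability ``noise_rate`` (< 0.5).  The planted feature/threshold is
    the oracle for decision-tree recovery tests.
    """
    if not (0.0 <= noise_rate < 0.5):
        raise ValueError("noise_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    x = rng.random((n, feature_count))
    labels = (x[:, 0] > threshold).astype(int)
    flip = rng.random(n) < noise_rate
    labels = np.where(flip, 1 - labels, labels)
    df = pd.DataFrame(x, columns=[f"feature_{i}" for i in range(feature_count)])
    df["label"] = labels
    return df


def toy_fixture_network(kind: str, seed: int = 0) -> ReactionNetwork:
    """Small networks with analytically known steady states.

    Kinds
    -----
    ``linear_chain``
        ∅ → A → B → ∅ with mass-action/degradation kinetics; the steady
        state solves a linear system.
    ``phospho_cycle``
        E ⇌ pE with an ATP-dependent forward law and Michaelis–Menten
        dephosphorylation; total E + pE is conserved.
    ``vegf_loop``
        Tumor-side VEGF loop: constant-rate synthesis, first-order
        degradation and reversible receptor binding.
    ``toy_hif``
        Two-species HIF stand-in: O₂-coupled hydroxylase degradation of
        HIF drives mRNA production; hypoxia raises mRNA in closed form.

    Across kinds every rate-law type is exercised at least once.  ``seed``
    jitters nothing structural and is accepted for interface symmetry.
    """
    if kind == "linear_chain":
        species = [
            SpeciesDef("A", 2.0),
            SpeciesDef("B", 0.0),
        ]
        reactions = [
            ReactionDef("syn_A", (), (("A", 1),), "mass_action", {"kf": 1.0}),
            ReactionDef("A_to_B", (("A", 1),), (("B", 1),), "mass_action", {"kf": 0.5}),
            ReactionDef("deg_B", (("B", 1),), (), "degradation", {"k": 0.25}),
        ]
        return ReactionNetwork(species, reactions)
    if kind == "phospho_cycle":
        species = [
            SpeciesDef("E", 10.0, phospho_pair=None),
            SpeciesDef("pE", 0.0, is_phospho_form=True, phospho_pair="E"),
        ]
        reactions = [
            ReactionDef(
                "phos",
                (("E", 1),),
                (("pE", 1),),
                "atp_phospho",
                {"vmax": 1.0, "k_prime": 5.0},
                atp_dependent=True,
            ),
            ReactionDef(
                "dephos",
                (("pE", 1),),
                (("E", 1),),
                "michaelis_menten",
                {"vmax": 1.2, "km": 8.0},
            ),
        ]
        return ReactionNetwork(species, reactions)
    if kind == "vegf_loop":
        species = [
            SpeciesDef("VEGF", 0.5),
            SpeciesDef("VEGFR", 10.0),
            SpeciesDef("VVEGFR", 0.0),
        ]
        reactions = [
            ReactionDef("vegf_syn", (), (("VEGF", 1),), "vegf_synthesis", {"k_syn": 0.02}),
            ReactionDef("vegf_deg", (("VEGF", 1),), (), "degradation", {"k": 0.04}),
            ReactionDef(
                "vegf_bind",
                (("VEGF", 1), ("VEGFR", 1)),
                (("VVEGFR", 1),),
                "vegf_binding",
                {"k1f": 0.01, "k1r": 0.1},
                drug_target="VEGF_binding",
            ),
        ]
        return ReactionNetwork(species, reactions)
    if kind == "toy_hif":
        species = [
            SpeciesDef("HIF1a", 1.0, module="hif"),
            SpeciesDef("mRNA", 1.0, module="hif"),
        ]
        reactions = [
            ReactionDef("hif_syn", (), (("HIF1a", 1),), "mass_action", {"kf": 0.02}, provenance="toy"),
            ReactionDef(
                "hif_deg",
                (("HIF1a", 1),),
                (),
                "michaelis_menten",
                {"vmax": 0.04, "km": 1.0, "o2_coupled": 1.0},
            ),
            ReactionDef(
                "hif_basal_deg", (("HIF1a", 1),), (), "degradation", {"k": 0.002}
            ),
            ReactionDef(
                "mrna_syn",
                (),
                (("mRNA", 1),),
                "mass_action",
                {"kf": 0.01, "modifiers": ["HIF1a"]},
            ),
            ReactionDef("mrna_deg", (("mRNA", 1),), (), "degradation", {"k": 0.005}),
        ]
        return ReactionNetwork(species, reactions)
    raise ValueError(f"unknown toy network kind {kind!r}")
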