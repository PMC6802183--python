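"""Reaction-network container, table I/O, assembly and ODE right-hand side.

The integrated model couples three pieces:

* a HIF module whose output species (``mRNA``) rises switch-like as O₂
  falls,
* a tumor-signaling module (VEGF/EGF receptors → PI3K/Akt and
  RAF/MEK/ERK cascades) whose phosphorylation reactions are tagged
  ``atp_dependent``,
* an algebraic ATP module mapping the O₂ fraction to cellular ATP.

Networks are defined in two delimited tables (species, reactions) and
assembled by :func:`assemble_integrated_model`, which

1. replaces every tagged phosphorylation law by its ATP-explicit form
   with ``K^AB`` calibrated to reproduce the original kinetics at
   normoxic ATP,
2. drives VEGF synthesis by ``(mRNA/mRNA₀)^k_alpha`` with ``mRNA₀``
   computed by equilibrating the HIF module at normoxia,
3. re-baselines the VEGF degradation constant so the integrated model's
   normoxic VEGF steady state equals the tumor table's baseline value.

By construction every reaction rate of the assembled model at normoxia
with no drug equals the corresponding original-model rate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .rate_laws import (
    ATPModel,
    UM_TO_NM,
    atp_level,
    calibrate_kab,
)

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "ReactionNetwork",
    "CouplingConfig",
    "Environment",
    "DRUG_TARGETS",
    "RATE_LAWS",
    "ModelSchemaError",
    "ModelValidationError",
    "AssemblyError",
    "load_model_tables",
    "assemble_integrated_model",
    "moiety_conservation_totals",
    "reaction_rates",
    "rhs",
    "jacobian",
]

DRUG_TARGETS = ("RAF_phospho", "MEK_phospho", "AKT_phospho", "VEGF_binding")
RATE_LAWS = (
    "mass_action",
    "michaelis_menten",
    "atp_phospho",
    "vegf_synthesis",
    "vegf_binding",
    "degradation",
)


class ModelSchemaError(ValueError):
    """A model table violates the documented column/value schema."""


class ModelValidationError(ValueError):
    """A structurally parsed model fails cross-reference validation."""


class AssemblyError(ValueError):
    """The HIF/tumor networks cannot be coupled as requested."""


@dataclass(frozen=True)
class SpeciesDef:
    """One biomolecule species; concentrations are held in nM."""

    id: str
    initial_conc: float
    module: str = "tumor"
    is_phospho_form: bool = False
    phospho_pair: Optional[str] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.initial_conc < 0:
            raise ModelValidationError(
                f"species {self.id!r}: initial_conc must be >= 0"
            )
        if self.module not in ("hif", "tumor"):
            raise ModelValidationError(
                f"species {self.id!r}: module must be 'hif' or 'tumor'"
            )


@dataclass(frozen=True)
class ReactionDef:
    """One reaction: stoichiometry, rate-law tag and named parameters.

    ``reactants``/``products`` map species id → positive integer
    coefficient; an empty mapping denotes synthesis from / degradation to
    the outside.  ``params`` may reference species by id (e.g. the
    ``enzyme`` of a catalysed phosphorylation or ``modifiers`` of a
    mass-action law).
    """

    id: str
    reactants: Tuple[Tuple[str, int], ...]
    products: Tuple[Tuple[str, int], ...]
    rate_law: str
    params: Mapping[str, object]
    atp_dependent: bool = False
    drug_target: Optional[str] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.rate_law not in RATE_LAWS:
            raise ModelSchemaError(
                f"reaction {self.id!r}: unknown rate law {self.rate_law!r}"
            )
        for sp, coef in (*self.reactants, *self.products):
            if not (isinstance(coef, int) and coef > 0):
                raise ModelValidationError(
                    f"reaction {self.id!r}: stoichiometric coefficient for "
                    f"{sp!r} must be a positive integer"
                )
        if self.drug_target is not None and self.drug_target not in DRUG_TARGETS:
            raise ModelSchemaError(
                f"reaction {self.id!r}: unknown drug target {self.drug_target!r}"
            )


@dataclass(frozen=True)
class Environment:
    """External input vector: O₂ fraction of normoxia plus drug levels.

    ``drugs`` maps a target name (one of :data:`DRUG_TARGETS`) to the
    dimensionless dose ``[D]/K_i``.
    """

    o2_fraction: float = 1.0
    drugs: Tuple[Tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.o2_fraction <= 1.0):
            raise ModelValidationError(
                f"o2_fraction must be in (0, 1], got {self.o2_fraction}"
            )
        drugs = tuple(sorted(dict(self.drugs).items()))
        object.__setattr__(self, "drugs", drugs)
        for target, dose in drugs:
            if target not in DRUG_TARGETS:
                raise ModelValidationError(f"unknown drug target {target!r}")
            if dose < 0:
                raise ModelValidationError(
                    f"d_over_ki for {target!r} must be >= 0, got {dose}"
                )

    def d_over_ki(self, target: Optional[str]) -> float:
        if target is None:
            return 0.0
        return dict(self.drugs).get(target, 0.0)

    @property
    def is_baseline(self) -> bool:
        return self.o2_fraction == 1.0 and not self.drugs

    def label(self) -> str:
        parts = [f"o2={100 * self.o2_fraction:g}%"]
        parts += [f"{t}={d:g}" for t, d in self.drugs if d > 0]
        return ",".join(parts)


NORMOXIA = Environment()


@dataclass
class CouplingConfig:
    """How the HIF, tumor and ATP modules are wired together."""

    mrna_species: str = "mRNA"
    vegf_species: str = "VEGF"
    vegf_synthesis_reaction: Optional[str] = None
    vegf_degradation_reaction: Optional[str] = None
    k_alpha: float = 2.0
    mrna0: Optional[float] = None
    atp_params: ATPModel = field(default_factory=ATPModel)
    default_k_m_atp: float = 100.0  # nM, applied where the table gives none
    kab_calibration: Dict[str, Tuple[float, float, float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.k_alpha <= 0:
            raise ModelValidationError("k_alpha must be > 0")
        if self.mrna0 is not None and self.mrna0 <= 0:
            raise ModelValidationError("mrna0 must be > 0 once computed")


class ReactionNetwork:
    """Ordered species + reactions with a consistent stoichiometry matrix.

    A network is *original* (``integrated=False``: tagged phosphorylation
    reactions use the ATP-implicit law, VEGF synthesis is constant) until
    :func:`assemble_integrated_model` attaches a :class:`CouplingConfig`.
    """

    def __init__(
        self,
        species: Sequence[SpeciesDef],
        reactions: Sequence[ReactionDef],
        coupling: Optional[CouplingConfig] = None,
    ) -> None:
        self.species: List[SpeciesDef] = list(species)
        self.reactions: List[ReactionDef] = list(reactions)
        self.coupling = coupling
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelValidationError(f"duplicate species ids: {dupes}")
        self.index: Dict[str, int] = {s.id: i for i, s in enumerate(self.species)}
        self._validate_references()
        self._stoich: Optional[np.ndarray] = None
        self._compiled: Optional["_Compiled"] = None
        self._env_cache: Dict[tuple, "_EnvContext"] = {}

    # -- construction helpers ------------------------------------------------

    def _validate_references(self) -> None:
        for s in self.species:
            if s.phospho_pair is not None and s.phospho_pair not in self.index:
                raise ModelValidationError(
                    f"species {s.id!r}: phospho_pair {s.phospho_pair!r} "
                    "names no existing species"
                )
        for r in self.reactions:
            for sp, _ in (*r.reactants, *r.products):
                if sp not in self.index:
                    raise ModelValidationError(
                        f"reaction {r.id!r}: references undeclared species {sp!r}"
                    )
            for key in ("enzyme", "modifiers"):
                ref = r.params.get(key)
                if ref is None:
                    continue
                names = ref if isinstance(ref, (list, tuple)) else [ref]
                for name in names:
                    if name not in self.index:
                        raise ModelValidationError(
                            f"reaction {r.id!r}: {key} references undeclared "
                            f"species {name!r}"
                        )
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dupes = sorted({i for i in rids if rids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")

    # -- basic views ----------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_ids(self) -> List[str]:
        return [s.id for s in self.species]

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_conc for s in self.species], dtype=float)

    @property
    def integrated(self) -> bool:
        return self.coupling is not None

    @property
    def stoichiometry(self) -> np.ndarray:
        """Dense species × reactions integer matrix (products − reactants)."""
        if self._stoich is None:
            mat = np.zeros((self.n_species, self.n_reactions), dtype=int)
            for j, r in enumerate(self.reactions):
                for sp, coef in r.reactants:
                    mat[self.index[sp], j] -= coef
                for sp, coef in r.products:
                    mat[self.index[sp], j] += coef
            self._stoich = mat
        return self._stoich

    def parameter_count(self) -> Dict[str, int]:
        """Number of numeric rate parameters; K^AB counted separately.

        Returns both conventions: ``original`` counts the parameters of
        the source tables, ``with_kab`` additionally counts each derived
        K^AB as a distinct constant.
        """
        n = 0
        for r in self.reactions:
            n += sum(
                1
                for v in r.params.values()
                if isinstance(v, (int, float)) and not isinstance(v, bool)
            )
        n_kab = len(self.coupling.kab_calibration) if self.coupling else 0
        return {"original": n, "with_kab": n + n_kab}

    # -- compiled evaluation --------------------------------------------------

    def _compile(self) -> "_Compiled":
        if self._compiled is None:
            self._compiled = _Compiled(self)
        return self._compiled

    def _env_context(self, env: Environment) -> "_EnvContext":
        key = (env.o2_fraction, env.drugs)
        ctx = self._env_cache.get(key)
        if ctx is None:
            ctx = _EnvContext(self._compile(), self.coupling, env)
            self._env_cache[key] = ctx
        return ctx

    def invalidate(self) -> None:
        """Drop compiled caches after in-place edits (assembly only)."""
        self._stoich = None
        self._compiled = None
        self._env_cache = {}


# ---------------------------------------------------------------------------
# compiled rate evaluation
# ---------------------------------------------------------------------------

_MA, _DEG, _MM, _PH, _VS, _VB = range(6)


class _Compiled:
    """Index/parameter arrays for vectorised rate evaluation.

    The padded state carries a constant 1.0 in its last slot so optional
    factors (second reactant, modifier, enzyme) can always be gathered.
    """

    def __init__(self, net: ReactionNetwork) -> None:
        n_r = net.n_reactions
        one = net.n_species  # index of the constant-1 pad
        self.one = one
        self.kind = np.zeros(n_r, dtype=int)
        # generic factor gathers: forward f1*f2*m1*m2, reverse p1*p2
        self.f1 = np.full(n_r, one)
        self.f2 = np.full(n_r, one)
        self.m1 = np.full(n_r, one)
        self.m2 = np.full(n_r, one)
        self.p1 = np.full(n_r, one)
        self.p2 = np.full(n_r, one)
        self.kf = np.zeros(n_r)
        self.kr = np.zeros(n_r)
        # michaelis_menten / atp_phospho
        self.sub = np.full(n_r, one)
        self.enz = np.full(n_r, one)
        self.vmax = np.zeros(n_r)  # constant part of Vmax
        self.kcat = np.zeros(n_r)  # enzyme-proportional part
        self.km = np.ones(n_r)  # K_M (MM) or K' (original phospho law)
        self.o2_coupled = np.zeros(n_r, dtype=bool)
        self.k_m_atp = np.zeros(n_r)  # nM
        self.k_ab = np.full(n_r, np.nan)  # nM, set at assembly
        self.target = np.full(n_r, -1, dtype=int)  # index into DRUG_TARGETS
        # sparse stoichiometry triplets ordered by reaction
        rows: List[int] = []
        cols: List[int] = []
        vals: List[float] = []

        def expand(pairs: Tuple[Tuple[str, int], ...]) -> List[int]:
            out: List[int] = []
            for sp, coef in pairs:
                out.extend([net.index[sp]] * coef)
            return out

        for j, r in enumerate(net.reactions):
            react = expand(r.reactants)
            prod = expand(r.products)
            if len(react) > 2 or len(prod) > 2:
                raise ModelValidationError(
                    f"reaction {r.id!r}: at most bimolecular steps supported"
                )
            p = dict(r.params)
            if r.rate_law == "mass_action":
                self.kind[j] = _MA
                self.kf[j] = float(p["kf"])
                self.kr[j] = float(p.get("kr", 0.0))
                if react:
                    self.f1[j] = react[0]
                if len(react) == 2:
                    self.f2[j] = react[1]
                mods = p.get("modifiers", [])
                mods = mods if isinstance(mods, (list, tuple)) else [mods]
                if len(mods) > 2:
                    raise ModelValidationError(
                        f"reaction {r.id!r}: at most two modifiers supported"
                    )
                if mods:
                    self.m1[j] = net.index[mods[0]]
                if len(mods) == 2:
                    self.m2[j] = net.index[mods[1]]
                if prod:
                    self.p1[j] = prod[0]
                if len(prod) == 2:
                    self.p2[j] = prod[1]
            elif r.rate_law == "degradation":
                self.kind[j] = _DEG
                self.kf[j] = float(p["k"])
                if len(react) != 1:
                    raise ModelValidationError(
                        f"reaction {r.id!r}: degradation needs one reactant"
                    )
                self.f1[j] = react[0]
            elif r.rate_law == "michaelis_menten":
                self.kind[j] = _MM
                if len(react) != 1:
                    raise ModelValidationError(
                        f"reaction {r.id!r}: michaelis_menten needs one reactant"
                    )
                self.sub[j] = react[0]
                self.km[j] = float(p["km"])
                if "enzyme" in p:
                    self.enz[j] = net.index[p["enzyme"]]
                    self.kcat[j] = float(p["kcat"])
                else:
                    self.vmax[j] = float(p["vmax"])
                self.o2_coupled[j] = bool(p.get("o2_coupled", False))
            elif r.rate_law == "atp_phospho":
                self.kind[j] = _PH
                if len(react) != 1:
                    raise ModelValidationError(
                        f"reaction {r.id!r}: atp_phospho needs one substrate"
                    )
                self.sub[j] = react[0]
                self.km[j] = float(p["k_prime"])
                if "enzyme" in p:
                    self.enz[j] = net.index[p["enzyme"]]
                    self.kcat[j] = float(p["kcat"])
                else:
                    self.vmax[j] = float(p["vmax"])
                if "k_m_atp" in p:
                    self.k_m_atp[j] = float(p["k_m_atp"])
                if "k_ab" in p:
                    self.k_ab[j] = float(p["k_ab"])
                if r.drug_target is not None:
                    self.target[j] = DRUG_TARGETS.index(r.drug_target)
            elif r.rate_law == "vegf_synthesis":
                self.kind[j] = _VS
                self.kf[j] = float(p["k_syn"])
            elif r.rate_law == "vegf_binding":
                self.kind[j] = _VB
                if len(react) != 2 or len(prod) != 1:
                    raise ModelValidationError(
                        f"reaction {r.id!r}: vegf_binding is A + B -> C"
                    )
                self.f1[j], self.f2[j] = react
                self.p1[j] = prod[0]
                self.kf[j] = float(p["k1f"])
                self.kr[j] = float(p["k1r"])
                if r.drug_target is not None:
                    self.target[j] = DRUG_TARGETS.index(r.drug_target)
            for sp, coef in r.reactants:
                rows.append(net.index[sp])
                cols.append(j)
                vals.append(-float(coef))
            for sp, coef in r.products:
                rows.append(net.index[sp])
                cols.append(j)
                vals.append(float(coef))
        self.rows = np.array(rows, dtype=int)
        self.cols = np.array(cols, dtype=int)
        self.vals = np.array(vals, dtype=float)
        self.n_species = net.n_species
        self.species_ids = net.species_ids()
        self.stoich = net.stoichiometry.astype(float)
        # per-law index arrays (precomputed once; hot path avoids masks)
        self.idx = {k: np.flatnonzero(self.kind == k) for k in range(6)}


class _EnvContext:
    """Environment-resolved constants: ATP (nM) and per-reaction doses."""

    def __init__(
        self, comp: _Compiled, coupling: Optional[CouplingConfig], env: Environment
    ) -> None:
        self.env = env
        self.o2 = env.o2_fraction
        n_r = comp.kind.size
        self.dose = np.zeros(n_r)
        for t_idx, name in enumerate(DRUG_TARGETS):
            d = env.d_over_ki(name)
            if d > 0:
                self.dose[comp.target == t_idx] = d
        if coupling is not None:
            self.atp_nm = atp_level(env.o2_fraction, coupling.atp_params) * UM_TO_NM
            self.atp_norm_nm = coupling.atp_params.atp_normoxia * UM_TO_NM
        else:
            self.atp_nm = math.nan
            self.atp_norm_nm = math.nan


_NEG_CLAMP_ATOL = 1e-9  # solver absolute tolerance on the nM scale


def _padded_state(net: ReactionNetwork, state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (net.n_species,):
        raise ModelValidationError(
            f"state length {state.size} != species count {net.n_species}"
        )
    if not np.all(np.isfinite(state)):
        bad = [net.species[i].id for i in np.flatnonzero(~np.isfinite(state))]
        raise FloatingPointError(f"non-finite concentration for species {bad}")
    floor = -10.0 * _NEG_CLAMP_ATOL
    if np.any(state < floor):
        bad = [net.species[i].id for i in np.flatnonzero(state < floor)]
        raise FloatingPointError(
            f"concentration below -10*atol for species {bad}"
        )
    clamped = np.where(state < 0.0, 0.0, state)
    return np.append(clamped, 1.0)


def reaction_rates(
    net: ReactionNetwork, state: np.ndarray, env: Environment = NORMOXIA
) -> np.ndarray:
    """Per-reaction rate vector at ``state`` under ``env``.

    Original (non-integrated) networks evaluate tagged phosphorylation
    reactions with the ATP-implicit law and VEGF synthesis at its
    constant rate; integrated networks use the ATP-explicit and
    mRNA-driven forms.
    """
    comp = net._compile()
    ctx = net._env_context(env)
    x = _padded_state(net, state)
    rates = np.zeros(comp.kind.size)

    ma = comp.idx[_MA]
    if ma.size:
        fwd = comp.kf[ma] * x[comp.f1[ma]] * x[comp.f2[ma]]
        fwd *= x[comp.m1[ma]] * x[comp.m2[ma]]
        rev = comp.kr[ma] * x[comp.p1[ma]] * x[comp.p2[ma]]
        rates[ma] = fwd - rev

    deg = comp.idx[_DEG]
    if deg.size:
        rates[deg] = comp.kf[deg] * x[comp.f1[deg]]

    mm = comp.idx[_MM]
    if mm.size:
        s = x[comp.sub[mm]]
        v = comp.vmax[mm] + comp.kcat[mm] * x[comp.enz[mm]]
        v = np.where(comp.o2_coupled[mm], v * ctx.o2, v)
        rates[mm] = v * s / (comp.km[mm] + s)

    ph = comp.idx[_PH]
    if ph.size:
        s = x[comp.sub[ph]]
        v = comp.vmax[ph] + comp.kcat[ph] * x[comp.enz[ph]]
        if net.integrated:
            atp = ctx.atp_nm
            kab = comp.k_ab[ph]
            denom = (
                comp.k_m_atp[ph] * kab * (1.0 + ctx.dose[ph])
                + kab * atp
                + atp * s
            )
            rates[ph] = v * atp * s / denom
        else:
            rates[ph] = v * s / (comp.km[ph] + s)

    vs = comp.idx[_VS]
    if vs.size:
        scale = 1.0
        if net.integrated:
            c = net.coupling
            mrna = x[net.index[c.mrna_species]]
            if c.mrna0 is None or c.mrna0 <= 0:
                raise AssemblyError("coupling.mrna0 not computed")
            scale = (mrna / c.mrna0) ** c.k_alpha
        rates[vs] = comp.kf[vs] * scale

    vb = comp.idx[_VB]
    if vb.size:
        fwd = comp.kf[vb] * x[comp.f1[vb]] * x[comp.f2[vb]]
        rates[vb] = fwd / (1.0 + ctx.dose[vb]) - comp.kr[vb] * x[comp.p1[vb]]

    return rates


def rhs(
    net: ReactionNetwork, state: np.ndarray, env: Environment = NORMOXIA
) -> np.ndarray:
    """Time derivative ``dx/dt = S · rates(x)`` of every species (nM/s).

    The sum over reactions is accumulated in reaction order, which makes
    it bit-identical to a per-reaction accumulation loop.
    """
    rates = reaction_rates(net, state, env)
    comp = net._compile()
    dx = np.zeros(net.n_species)
    np.add.at(dx, comp.rows, comp.vals * rates[comp.cols])
    return dx


def jacobian(
    net: ReactionNetwork, state: np.ndarray, env: Environment = NORMOXIA
) -> np.ndarray:
    """Analytic Jacobian ``d(rhs)/d(state)`` (n_species × n_species).

    Each rate law's partial derivatives are accumulated into a
    reactions × species matrix ``D`` and contracted with the
    stoichiometry, ``J = S · D``.  Supplying this to the stiff solver
    avoids finite-difference Jacobian sweeps, which dominate the cost of
    population runs.
    """
    comp = net._compile()
    ctx = net._env_context(env)
    x = _padded_state(net, state)
    n_r, n_sp = comp.kind.size, comp.n_species
    d = np.zeros((n_r, n_sp + 1))  # last column = pad slot, discarded

    ma = comp.idx[_MA]
    if ma.size:
        a, b = x[comp.f1[ma]], x[comp.f2[ma]]
        c, e = x[comp.m1[ma]], x[comp.m2[ma]]
        kf = comp.kf[ma]
        np.add.at(d, (ma, comp.f1[ma]), kf * b * c * e)
        np.add.at(d, (ma, comp.f2[ma]), kf * a * c * e)
        np.add.at(d, (ma, comp.m1[ma]), kf * a * b * e)
        np.add.at(d, (ma, comp.m2[ma]), kf * a * b * c)
        kr = comp.kr[ma]
        np.add.at(d, (ma, comp.p1[ma]), -kr * x[comp.p2[ma]])
        np.add.at(d, (ma, comp.p2[ma]), -kr * x[comp.p1[ma]])

    deg = comp.idx[_DEG]
    if deg.size:
        np.add.at(d, (deg, comp.f1[deg]), comp.kf[deg])

    mm = comp.idx[_MM]
    if mm.size:
        s = x[comp.sub[mm]]
        scale = np.where(comp.o2_coupled[mm], ctx.o2, 1.0)
        v = (comp.vmax[mm] + comp.kcat[mm] * x[comp.enz[mm]]) * scale
        km = comp.km[mm]
        np.add.at(d, (mm, comp.sub[mm]), v * km / (km + s) ** 2)
        np.add.at(d, (mm, comp.enz[mm]), comp.kcat[mm] * scale * s / (km + s))

    ph = comp.idx[_PH]
    if ph.size:
        s = x[comp.sub[ph]]
        v = comp.vmax[ph] + comp.kcat[ph] * x[comp.enz[ph]]
        if net.integrated:
            atp = ctx.atp_nm
            kab = comp.k_ab[ph]
            const = comp.k_m_atp[ph] * kab * (1.0 + ctx.dose[ph]) + kab * atp
            denom = const + atp * s
            np.add.at(d, (ph, comp.sub[ph]), v * atp * const / denom**2)
            np.add.at(d, (ph, comp.enz[ph]), comp.kcat[ph] * atp * s / denom)
        else:
            kp = comp.km[ph]
            np.add.at(d, (ph, comp.sub[ph]), v * kp / (kp + s) ** 2)
            np.add.at(d, (ph, comp.enz[ph]), comp.kcat[ph] * s / (kp + s))

    vs = comp.idx[_VS]
    if vs.size and net.integrated:
        c = net.coupling
        m_idx = net.index[c.mrna_species]
        mrna = x[m_idx]
        grad = (
            comp.kf[vs]
            * c.k_alpha
            * (mrna / c.mrna0) ** (c.k_alpha - 1.0)
            / c.mrna0
        )
        np.add.at(d, (vs, np.full(vs.size, m_idx)), grad)

    vb = comp.idx[_VB]
    if vb.size:
        inhib = 1.0 + ctx.dose[vb]
        np.add.at(d, (vb, comp.f1[vb]), comp.kf[vb] * x[comp.f2[vb]] / inhib)
        np.add.at(d, (vb, comp.f2[vb]), comp.kf[vb] * x[comp.f1[vb]] / inhib)
        np.add.at(d, (vb, comp.p1[vb]), -comp.kr[vb])

    return comp.stoich @ d[:, :n_sp]


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

_SPECIES_COLS = ["id", "initial_conc", "unit", "module"]
_REACTION_COLS = ["id", "reactants", "products", "rate_law", "params"]


def _parse_side(text: object, rid: str) -> Tuple[Tuple[str, int], ...]:
    """Parse ``"A + 2 B"`` → ((A,1),(B,2)); empty/'-' → ()."""
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return ()
    s = str(text).strip()
    if s in ("", "-", "none", "0"):
        return ()
    out: List[Tuple[str, int]] = []
    for term in s.split("+"):
        term = term.strip()
        if not term:
            raise ModelSchemaError(f"reaction {rid!r}: empty term in {s!r}")
        bits = term.split()
        if len(bits) == 1:
            out.append((bits[0], 1))
        elif len(bits) == 2:
            try:
                coef = int(bits[0])
            except ValueError as exc:
                raise ModelSchemaError(
                    f"reaction {rid!r}: bad coefficient in {term!r}"
                ) from exc
            out.append((bits[1], coef))
        else:
            raise ModelSchemaError(f"reaction {rid!r}: cannot parse term {term!r}")
    return tuple(out)


def _parse_params(text: object, rid: str) -> Dict[str, object]:
    """Parse ``"kf=0.01; kr=0.1; modifiers=A+B"`` into a dict."""
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return {}
    s = str(text).strip()
    if not s:
        return {}
    out: Dict[str, object] = {}
    for item in s.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ModelSchemaError(
                f"reaction {rid!r}: param entry {item!r} is not key=value"
            )
        key, val = (t.strip() for t in item.split("=", 1))
        if key in ("enzyme",):
            out[key] = val
        elif key in ("modifiers",):
            out[key] = [v.strip() for v in val.split("+") if v.strip()]
        else:
            try:
                out[key] = float(val)
            except ValueError as exc:
                raise ModelSchemaError(
                    f"reaction {rid!r}: param {key!r} has non-numeric "
                    f"value {val!r}"
                ) from exc
    return out


def _as_bool(v: object) -> bool:
    if isinstance(v, bool):
        return v
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return False
    return str(v).strip().lower() in ("1", "true", "yes", "y")


def _read_table(path_or_df, **kw) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        return path_or_df.copy()
    return pd.read_csv(path_or_df, sep=None, engine="python", **kw)


def load_model_tables(species_table, reaction_table) -> ReactionNetwork:
    """Build a validated :class:`ReactionNetwork` from two delimited tables.

    ``species_table`` columns: ``id, initial_conc, unit, module,
    is_phospho_form, phospho_pair, provenance`` (unit ``nM`` or ``uM``;
    values are normalised to nM).  ``reaction_table`` columns: ``id,
    reactants, products, rate_law, params, atp_dependent, drug_target,
    provenance``.  Row order of the species table is preserved as species
    order.  Either argument may be a path or an already-loaded DataFrame.
    """
    sdf = _read_table(species_table)
    rdf = _read_table(reaction_table)
    for col in _SPECIES_COLS:
        if col not in sdf.columns:
            raise ModelSchemaError(f"species table lacks column {col!r}")
    for col in _REACTION_COLS:
        if col not in rdf.columns:
            raise ModelSchemaError(f"reaction table lacks column {col!r}")

    species: List[SpeciesDef] = []
    for i, row in sdf.iterrows():
        unit = str(row.get("unit", "nM")).strip()
        conc = float(row["initial_conc"])
        if unit in ("nM", "nm", ""):
            pass
        elif unit in ("uM", "um", "µM"):
            conc *= UM_TO_NM
        else:
            raise ModelSchemaError(
                f"species table row {i} ({row['id']!r}): unknown unit {unit!r}"
            )
        pair = row.get("phospho_pair")
        if pair is not None and (
            (isinstance(pair, float) and math.isnan(pair)) or str(pair).strip() == ""
        ):
            pair = None
        species.append(
            SpeciesDef(
                id=str(row["id"]).strip(),
                initial_conc=conc,
                module=str(row["module"]).strip(),
                is_phospho_form=_as_bool(row.get("is_phospho_form")),
                phospho_pair=None if pair is None else str(pair).strip(),
                provenance=str(row.get("provenance", "") or ""),
            )
        )

    reactions: List[ReactionDef] = []
    for i, row in rdf.iterrows():
        rid = str(row["id"]).strip()
        law = str(row["rate_law"]).strip()
        if law not in RATE_LAWS:
            raise ModelSchemaError(
                f"reaction table row {i} ({rid!r}): unknown rate law {law!r}"
            )
        target = row.get("drug_target")
        if target is not None and (
            (isinstance(target, float) and math.isnan(target))
            or str(target).strip() == ""
        ):
            target = None
        reactions.append(
            ReactionDef(
                id=rid,
                reactants=_parse_side(row["reactants"], rid),
                products=_parse_side(row["products"], rid),
                rate_law=law,
                params=_parse_params(row["params"], rid),
                atp_dependent=_as_bool(row.get("atp_dependent")),
                drug_target=None if target is None else str(target).strip(),
                provenance=str(row.get("provenance", "") or ""),
            )
        )
    return ReactionNetwork(species, reactions)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def assemble_integrated_model(
    hif: ReactionNetwork,
    tumor: ReactionNetwork,
    coupling: Optional[CouplingConfig] = None,
    rebaseline_tol: float = 1e-6,
) -> ReactionNetwork:
    """Merge the HIF and tumor networks into the O₂/drug-sensitive model.

    Performs, in order: (a) species/reaction union (shared species ids
    merged, HIF definition wins), (b) per-reaction ``K^AB`` calibration of
    every ``atp_dependent`` phosphorylation, (c) normoxic equilibration of
    the HIF module alone to fix ``mRNA₀``, (d) VEGF degradation-rate
    re-baselining so the integrated normoxic VEGF steady state equals the
    tumor table's VEGF baseline.  If the shipped degradation constant
    already satisfies (d) within ``rebaseline_tol`` (relative) it is kept
    bit-identical, preserving exact normoxia equivalence of rates.
    """
    from .simulation import integrate_to_steady_state  # local: avoid cycle

    coupling = coupling if coupling is not None else CouplingConfig()

    problems: List[str] = []
    if coupling.mrna_species not in hif.index:
        problems.append(
            f"HIF network lacks mRNA species {coupling.mrna_species!r}"
        )
    for r in tumor.reactions:
        if r.rate_law == "atp_phospho" and not r.atp_dependent:
            problems.append(
                f"phosphorylation reaction {r.id!r} is not tagged atp_dependent"
            )
        if r.atp_dependent and r.rate_law != "atp_phospho":
            problems.append(
                f"reaction {r.id!r} tagged atp_dependent but law is {r.rate_law!r}"
            )
    syn = [r for r in tumor.reactions if r.rate_law == "vegf_synthesis"]
    if coupling.vegf_synthesis_reaction is None:
        if len(syn) != 1:
            problems.append(
                f"expected exactly one vegf_synthesis reaction, found {len(syn)}"
            )
        else:
            coupling.vegf_synthesis_reaction = syn[0].id
    if problems:
        raise AssemblyError("; ".join(problems))

    # (a) union, preserving HIF-then-tumor order; shared ids keep HIF def
    merged_species = list(hif.species)
    seen = {s.id for s in merged_species}
    merged_species += [s for s in tumor.species if s.id not in seen]
    merged_reactions = list(hif.reactions) + list(tumor.reactions)

    # (b) K^AB calibration (all constants in nM).  The reference ATP is the
    # value the ATP-O2 relation actually produces at normoxia (f = 1), not
    # the maximal-ATP parameter: only then does the ATP-explicit law
    # reproduce the original kinetics exactly in the normoxic simulation.
    atp_norm_nm = atp_level(1.0, coupling.atp_params) * UM_TO_NM
    coupling.kab_calibration = {}
    calibrated: List[ReactionDef] = []
    for r in merged_reactions:
        if r.rate_law != "atp_phospho":
            calibrated.append(r)
            continue
        p = dict(r.params)
        k_prime = float(p["k_prime"])
        k_m_atp = float(p.get("k_m_atp", coupling.default_k_m_atp))
        k_ab = calibrate_kab(k_prime, k_m_atp, atp_norm_nm)
        p["k_m_atp"] = k_m_atp
        p["k_ab"] = k_ab
        coupling.kab_calibration[r.id] = (k_prime, k_m_atp, k_ab)
        calibrated.append(replace(r, params=p))
    merged_reactions = calibrated

    # (c) normoxic mRNA baseline from the HIF module alone
    hif_ss = integrate_to_steady_state(hif, hif.initial_state(), NORMOXIA)
    if not hif_ss.converged:
        raise AssemblyError("HIF module failed to equilibrate at normoxia")
    mrna0 = float(hif_ss.state[hif.index[coupling.mrna_species]])
    if mrna0 <= 0:
        raise AssemblyError("normoxic mRNA baseline is not positive")
    coupling.mrna0 = mrna0

    net = ReactionNetwork(merged_species, merged_reactions, coupling=coupling)
    # carry the equilibrated HIF state into the merged initial conditions
    init = net.initial_state()
    for sid, i in hif.index.items():
        init[net.index[sid]] = hif_ss.state[i]
    for i, s in enumerate(net.species):
        net.species[i] = replace(s, initial_conc=float(init[i]))
    net.invalidate()

    # (d) VEGF degradation re-baselining
    _rebaseline_vegf_degradation(net, coupling, rebaseline_tol)
    return net


def _find_vegf_degradation(net: ReactionNetwork, coupling: CouplingConfig) -> int:
    if coupling.vegf_degradation_reaction is not None:
        for j, r in enumerate(net.reactions):
            if r.id == coupling.vegf_degradation_reaction:
                return j
        raise AssemblyError(
            f"no reaction {coupling.vegf_degradation_reaction!r} in network"
        )
    hits = [
        j
        for j, r in enumerate(net.reactions)
        if r.rate_law == "degradation"
        and r.reactants == ((coupling.vegf_species, 1),)
    ]
    if len(hits) != 1:
        raise AssemblyError(
            f"expected exactly one degradation of {coupling.vegf_species!r}, "
            f"found {len(hits)}"
        )
    coupling.vegf_degradation_reaction = net.reactions[hits[0]].id
    return hits[0]


def _rebaseline_vegf_degradation(
    net: ReactionNetwork, coupling: CouplingConfig, tol: float, max_iter: int = 40
) -> None:
    """Adjust k_deg(VEGF) so the normoxic VEGF steady state hits baseline.

    Fixed-point iteration ``k ← k · VEGF_ss / VEGF₀`` (degradation flux at
    the target baseline must absorb the same net synthesis).  The shipped
    constant is kept untouched when it already satisfies the condition.
    """
    from .simulation import integrate_to_steady_state

    j = _find_vegf_degradation(net, coupling)
    v_idx = net.index[coupling.vegf_species]
    target = net.species[v_idx].initial_conc
    if target <= 0:
        raise AssemblyError("VEGF baseline (initial_conc) must be > 0")

    for _ in range(max_iter):
        ss = integrate_to_steady_state(net, net.initial_state(), NORMOXIA)
        if not ss.converged:
            raise AssemblyError(
                "integrated model failed to equilibrate during VEGF "
                "re-baselining"
            )
        v_ss = float(ss.state[v_idx])
        rel = abs(v_ss - target) / target
        if rel < tol:
            return
        r = net.reactions[j]
        p = dict(r.params)
        p["k"] = float(p["k"]) * v_ss / target
        net.reactions[j] = replace(r, params=p)
        net.invalidate()
    raise AssemblyError(
        f"VEGF re-baselining did not converge within {max_iter} iterations"
    )


# ---------------------------------------------------------------------------
# conservation analysis
# ---------------------------------------------------------------------------


def moiety_conservation_totals(
    net: ReactionNetwork,
) -> List[Dict[str, float]]:
    """Basis of conserved linear combinations under interconversion only.

    Synthesis and degradation reactions (empty reactant or product side,
    or ``degradation``/``vegf_synthesis`` laws) are excluded; the left
    null space of the remaining stoichiometry is returned as integer
    combinations ``{species_id: coefficient}``.  Each combination is
    constant along any trajectory in which only the retained reactions
    fire.
    """
    import sympy

    keep = [
        j
        for j, r in enumerate(net.reactions)
        if r.reactants
        and r.products
        and r.rate_law not in ("degradation", "vegf_synthesis")
    ]
    if not keep:
        return []
    keep_mat = net.stoichiometry[:, keep]
    # species untouched by any retained reaction are trivially constant and
    # (being open) are not reported
    active = np.flatnonzero(np.any(keep_mat != 0, axis=1))
    if active.size == 0:
        return []
    mat = sympy.Matrix(keep_mat[active, :].T.tolist())
    basis = mat.nullspace()
    out: List[Dict[str, float]] = []
    for vec in basis:
        denom = sympy.lcm([sympy.fraction(v)[1] for v in vec if v != 0] or [1])
        ints = [sympy.nsimplify(v * denom) for v in vec]
        if all(v <= 0 for v in ints if v != 0):
            ints = [-v for v in ints]
        combo = {
            net.species[active[i]].id: float(v)
            for i, v in enumerate(ints)
            if v != 0
        }
        if combo:
            out.append(combo)
    return out
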