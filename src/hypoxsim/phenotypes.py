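"""Categorical response phenotypes and population summaries.

Per-case steady states are reduced to perturbed/baseline ratios of a
readout (a species or a derived phospho/total ratio), categorised as

* ``decrease``  — ratio < 0.9,
* ``no_change`` — 0.9 ≤ ratio ≤ 1.1 (closed band, "within ±10% change"),
* ``increase``  — ratio > 1.1,

and summarised as population fractions with binomial 95% intervals
(Wilson) for scaled-down runs.  "Total" protein for the derived ratios
includes complexed forms via an explicit mapping (e.g. PIP3-bound Akt
counts toward total Akt), so the ratios stay in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .network_model import Environment, ReactionNetwork
from .population import EnsembleRecord

__all__ = [
    "CategoryRule",
    "PhenotypeSummary",
    "RatioMapping",
    "categorize",
    "derived_ratio",
    "response_ratio",
    "summarize",
    "phenotype_table",
]

CATEGORIES = ("decrease", "no_change", "increase")

#: pair name → (phospho-form species, all-form species) for derived ratios
RatioMapping = Mapping[str, Tuple[Tuple[str, ...], Tuple[str, ...]]]


@dataclass(frozen=True)
class CategoryRule:
    """Categorisation rule for one readout.

    ``ratio_band`` compares the perturbed/baseline ratio against the
    no-change band; ``fold_threshold`` (e.g. 100 for the "large vs small"
    VEGF split) dichotomises a fold-change magnitude instead.
    """

    readout: str
    kind: str = "ratio_band"
    band: Tuple[float, float] = (0.9, 1.1)
    fold_threshold: float = 100.0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (lo < 1.0 < hi):
            raise ValueError("no-change band must straddle 1")
        if self.kind not in ("ratio_band", "fold_threshold"):
            raise ValueError(f"unknown rule kind {self.kind!r}")


def categorize(ratio: float, rule: CategoryRule) -> str:
    """Map a perturbed/baseline ratio to its category.

    The no-change band is closed: boundary values 0.9 and 1.1 are
    ``no_change``.  For ``fold_threshold`` rules, returns ``"large"`` or
    ``"small"``.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    if rule.kind == "fold_threshold":
        return "large" if ratio > rule.fold_threshold else "small"
    lo, hi = rule.band
    if ratio < lo:
        return "decrease"
    if ratio > hi:
        return "increase"
    return "no_change"


def derived_ratio(
    state: np.ndarray,
    net: ReactionNetwork,
    pair: str,
    mapping: RatioMapping,
) -> float:
    """Phospho/total ratio of one state vector, complexed forms included.

    Both numerator and denominator species sets come from ``mapping``;
    the value lies in [0, 1] whenever the numerator set is a subset of
    the denominator set.
    """
    if pair not in mapping:
        raise KeyError(f"no total-mapping entry for derived ratio {pair!r}")
    num_ids, den_ids = mapping[pair]
    missing = [s for s in (*num_ids, *den_ids) if s not in net.index]
    if missing:
        raise KeyError(f"ratio {pair!r} references unknown species {missing}")
    num = float(sum(state[net.index[s]] for s in num_ids))
    den = float(sum(state[net.index[s]] for s in den_ids))
    if den <= 0:
        return math.nan
    return num / den


def _readout_value(
    state: np.ndarray,
    net: ReactionNetwork,
    readout: str,
    mapping: Optional[RatioMapping],
) -> float:
    if readout in net.index:
        return float(state[net.index[readout]])
    if mapping is not None and readout in mapping:
        return derived_ratio(state, net, readout, mapping)
    raise KeyError(f"readout {readout!r} is neither a species nor a derived ratio")


def response_ratio(
    record: EnsembleRecord,
    condition: Environment,
    readout: str,
    net: ReactionNetwork,
    mapping: Optional[RatioMapping] = None,
) -> Optional[float]:
    """Perturbed/baseline readout ratio for one case, or None if excluded.

    Exclusion reasons (recorded in ``record.derived['excluded']``): either
    steady state non-converged, or a non-positive baseline readout.
    """
    res = record.conditions.get(condition)
    if res is None or not res.converged or not record.baseline.converged:
        record.derived.setdefault("excluded", "non_converged")
        return None
    base = _readout_value(record.baseline.state, net, readout, mapping)
    if not (base > 0):
        record.derived.setdefault("excluded", "baseline_nonpositive")
        return None
    return _readout_value(res.state, net, readout, mapping) / base


@dataclass
class PhenotypeSummary:
    """Population fractions of each response category for one condition."""

    condition: Environment
    readout: str
    n_cases: int
    n_converged: int
    fractions: Dict[str, float]
    counts: Dict[str, int]
    ci95: Dict[str, Tuple[float, float]]
    hist_edges: np.ndarray
    hist_counts: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "condition": self.condition.label(),
                "readout": self.readout,
                "category": cat,
                "count": self.counts.get(cat, 0),
                "fraction": self.fractions.get(cat, 0.0),
                "ci_low": self.ci95.get(cat, (math.nan, math.nan))[0],
                "ci_high": self.ci95.get(cat, (math.nan, math.nan))[1],
            }
            for cat in sorted(self.fractions)
        ]
        return pd.DataFrame(rows)


def summarize(
    records: Sequence[EnsembleRecord],
    condition: Environment,
    rule: CategoryRule,
    net: ReactionNetwork,
    mapping: Optional[RatioMapping] = None,
    n_bins: int = 40,
) -> PhenotypeSummary:
    """Category fractions over converged cases, with Wilson 95% intervals.

    Fractions are computed over cases with converged baseline *and*
    condition steady states and a positive baseline readout; the excluded
    count is implicit in ``n_cases − n_converged``.  A log-spaced ratio
    histogram is attached for distribution-shape checks.
    """
    ratios: List[float] = []
    for rec in records:
        r = response_ratio(rec, condition, rule.readout, net, mapping)
        if r is not None and np.isfinite(r):
            ratios.append(r)
    if not ratios:
        raise ValueError("no converged cases to summarise")
    arr = np.asarray(ratios)
    cats = [categorize(r, rule) for r in arr]
    labels = (
        ("small", "large") if rule.kind == "fold_threshold" else CATEGORIES
    )
    counts = {c: int(sum(1 for x in cats if x == c)) for c in labels}
    n = len(cats)
    fractions = {c: counts[c] / n for c in labels}
    ci = {
        c: binomtest(counts[c], n).proportion_ci(
            confidence_level=0.95, method="wilson"
        )
        for c in labels
    }
    ci95 = {c: (float(lo), float(hi)) for c, (lo, hi) in ci.items()}
    pos = arr[arr > 0]
    lo = float(np.min(pos)) if pos.size else 0.1
    hi = float(np.max(pos)) if pos.size else 10.0
    edges = np.geomspace(min(lo, 0.999), max(hi, 1.001), n_bins + 1)
    hist, _ = np.histogram(arr, bins=edges)
    return PhenotypeSummary(
        condition=condition,
        readout=rule.readout,
        n_cases=len(records),
        n_converged=n,
        fractions=fractions,
        counts=counts,
        ci95=ci95,
        hist_edges=edges,
        hist_counts=hist,
    )


def phenotype_table(
    records: Sequence[EnsembleRecord],
    conditions: Sequence[Environment],
    rules: Sequence[CategoryRule],
    net: ReactionNetwork,
    mapping: Optional[RatioMapping] = None,
) -> pd.DataFrame:
    """Tidy per-case table: case_id, condition, readout, ratio, category."""
    rows = []
    for rec in records:
        for env in conditions:
            for rule in rules:
                r = response_ratio(rec, env, rule.readout, net, mapping)
                rows.append(
                    {
                        "case_id": rec.case_id,
                        "condition": env.label(),
                        "readout": rule.readout,
                        "ratio": math.nan if r is None else r,
                        "category": None if r is None else categorize(r, rule),
                    }
                )
    return pd.DataFrame(rows)
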