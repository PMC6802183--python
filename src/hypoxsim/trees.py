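"""Decision-tree explanation of categorical responses.

Shallow CART trees map per-case features — baseline (normoxic
steady-state) concentrations plus derived phospho/total ratios — to
response categories, exposing which biomolecule levels separate e.g.
hypoxia-sensitive from insensitive cells.  The printed trees of interest
are 1–3 splits deep, so the default configuration is ``max_depth=3`` with
minimum-leaf-fraction pruning.

The two-stage Akt procedure first separates *change* from *no-change*
cases, then splits the change subset into *increase* vs *decrease*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .network_model import Environment, ReactionNetwork
from .phenotypes import CategoryRule, RatioMapping, categorize, response_ratio
from .population import EnsembleRecord

__all__ = [
    "TreeConfig",
    "TreeNode",
    "TreeReport",
    "fit_tree",
    "features_from_records",
    "two_stage_akt_analysis",
    "extract_threshold",
]


@dataclass(frozen=True)
class TreeConfig:
    """Hyperparameters of the explanation trees."""

    max_depth: int = 3
    min_leaf_fraction: float = 0.05
    split_criterion: str = "gini"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not (0 < self.min_leaf_fraction < 0.5):
            raise ValueError("min_leaf_fraction must be in (0, 0.5)")


@dataclass
class TreeNode:
    """One node of the fitted tree (leaf ⇔ ``feature is None``)."""

    node_id: int
    feature: Optional[str]
    threshold: Optional[float]
    left: Optional[int]
    right: Optional[int]
    class_counts: Dict[str, int]
    depth: int

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return sum(self.class_counts.values())

    @property
    def majority_class(self) -> str:
        return max(sorted(self.class_counts), key=lambda c: self.class_counts[c])

    @property
    def purity(self) -> float:
        n = self.n
        return self.class_counts[self.majority_class] / n if n else math.nan


@dataclass
class TreeReport:
    """Fitted tree: nodes, accuracies and a text rendering."""

    nodes: List[TreeNode]
    classes: Tuple[str, ...]
    feature_names: Tuple[str, ...]
    misclassification: float
    degenerate: bool = False
    note: str = ""

    @property
    def root(self) -> TreeNode:
        return self.nodes[0]

    @property
    def root_feature(self) -> Optional[str]:
        return self.root.feature

    @property
    def root_threshold(self) -> Optional[float]:
        return self.root.threshold

    def leaf_accuracies(self) -> Dict[int, float]:
        return {n.node_id: n.purity for n in self.nodes if n.is_leaf}

    def render(self) -> str:
        lines: List[str] = []

        def walk(nid: int, indent: str) -> None:
            node = self.nodes[nid]
            if node.is_leaf:
                lines.append(
                    f"{indent}leaf: {node.majority_class} "
                    f"(n={node.n}, purity={node.purity:.3f})"
                )
                return
            lines.append(
                f"{indent}{node.feature} <= {node.threshold:.6g} (n={node.n})"
            )
            walk(node.left, indent + "  ")
            walk(node.right, indent + "  ")

        walk(0, "")
        return "\n".join(lines)

    def to_dot(self) -> str:
        out = ["digraph tree {", "  node [shape=box];"]
        for n in self.nodes:
            if n.is_leaf:
                label = f"{n.majority_class}\\nn={n.n}, purity={n.purity:.2f}"
            else:
                label = f"{n.feature} <= {n.threshold:.4g}\\nn={n.n}"
            out.append(f'  n{n.node_id} [label="{label}"];')
            if not n.is_leaf:
                out.append(f"  n{n.node_id} -> n{n.left};")
                out.append(f"  n{n.node_id} -> n{n.right};")
        out.append("}")
        return "\n".join(out)


def fit_tree(
    features: pd.DataFrame,
    labels: Sequence[str],
    cfg: TreeConfig = TreeConfig(),
) -> TreeReport:
    """Fit a shallow CART tree and report splits, thresholds and purities.

    Deterministic for fixed seed and data (and invariant to row order:
    splits are chosen exhaustively on sorted feature values).  A
    single-class input yields a degenerate single-leaf report, flagged
    rather than raised.
    """
    if features.isna().any().any():
        raise ValueError("feature table contains missing values")
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != len(features):
        raise ValueError("labels length must match feature rows")
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        counts = {classes[0]: len(labels)} if classes else {}
        node = TreeNode(0, None, None, None, None, counts, 0)
        return TreeReport(
            nodes=[node],
            classes=classes,
            feature_names=tuple(features.columns),
            misclassification=0.0,
            degenerate=True,
            note="single-class input: degenerate single-leaf tree",
        )
    min_leaf = max(1, int(math.ceil(cfg.min_leaf_fraction * len(labels))))
    clf = DecisionTreeClassifier(
        max_depth=cfg.max_depth,
        min_samples_leaf=min_leaf,
        criterion=cfg.split_criterion,
        random_state=cfg.seed,
    )
    clf.fit(features.to_numpy(), labels)
    mis = float(np.mean(clf.predict(features.to_numpy()) != labels))
    t = clf.tree_
    feat_names = tuple(features.columns)
    nodes: List[TreeNode] = []

    def depth_of(nid: int, d: Dict[int, int]) -> None:
        l, r = t.children_left[nid], t.children_right[nid]
        if l >= 0:
            d[l] = d[nid] + 1
            depth_of(l, d)
        if r >= 0:
            d[r] = d[nid] + 1
            depth_of(r, d)

    depths = {0: 0}
    depth_of(0, depths)
    class_order = list(clf.classes_)
    for nid in range(t.node_count):
        leaf = t.children_left[nid] < 0
        # tree_.value holds per-class fractions; rescale to sample counts
        frac = np.asarray(t.value[nid][0], dtype=float)
        total = frac.sum()
        scale = t.n_node_samples[nid] / total if total > 0 else 0.0
        counts = {
            cls: int(round(frac[k] * scale)) for k, cls in enumerate(class_order)
        }
        nodes.append(
            TreeNode(
                node_id=nid,
                feature=None if leaf else feat_names[t.feature[nid]],
                threshold=None if leaf else float(t.threshold[nid]),
                left=None if leaf else int(t.children_left[nid]),
                right=None if leaf else int(t.children_right[nid]),
                class_counts=counts,
                depth=depths[nid],
            )
        )
    return TreeReport(
        nodes=nodes,
        classes=classes,
        feature_names=feat_names,
        misclassification=mis,
    )


def features_from_records(
    records: Sequence[EnsembleRecord],
    net: ReactionNetwork,
    mapping: Optional[RatioMapping] = None,
    use_sampled_initials: bool = False,
    feature_species: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-case feature table: baseline steady states plus derived ratios.

    Features default to the *pre-stimulus* (normoxic steady-state)
    concentrations of the tumor-module species; ``use_sampled_initials``
    switches to the raw sampled vectors instead.  Derived ratio columns
    (e.g. ``pAkt/tAkt``) are appended when a mapping is supplied.  Rows
    are indexed by case id; non-converged cases are dropped.
    """
    if feature_species is None:
        feature_species = [s.id for s in net.species if s.module == "tumor"]
    from .phenotypes import derived_ratio  # late import keeps module tree flat

    rows = []
    idx = []
    for rec in records:
        if not rec.baseline.converged:
            continue
        state = rec.sampled_initials if use_sampled_initials else rec.baseline.state
        row = {s: float(state[net.index[s]]) for s in feature_species}
        if mapping:
            for pair in mapping:
                row[pair] = derived_ratio(state, net, pair, mapping)
        rows.append(row)
        idx.append(rec.case_id)
    return pd.DataFrame(rows, index=idx)


def two_stage_akt_analysis(
    records: Sequence[EnsembleRecord],
    condition: Environment,
    net: ReactionNetwork,
    mapping: RatioMapping,
    rule: Optional[CategoryRule] = None,
    cfg: TreeConfig = TreeConfig(),
) -> Tuple[TreeReport, Optional[TreeReport]]:
    """Two-stage explanation of the pAkt response at one condition.

    Stage 1 classifies *change* vs *no_change*; stage 2 refits on the
    change subset only, separating *increase* from *decrease*.  When the
    change subset is empty (or single-class), stage 2 is skipped and
    ``None`` is returned with a notice on stage 1's report.
    """
    rule = rule or CategoryRule(readout="pAkt")
    feats = features_from_records(records, net, mapping)
    cats: Dict[int, str] = {}
    for rec in records:
        r = response_ratio(rec, condition, rule.readout, net, mapping)
        if r is not None and np.isfinite(r):
            cats[rec.case_id] = categorize(r, rule)
    keep = [cid for cid in feats.index if cid in cats]
    feats = feats.loc[keep]
    labels3 = [cats[cid] for cid in keep]
    stage1_labels = [
        "no_change" if c == "no_change" else "change" for c in labels3
    ]
    stage1 = fit_tree(feats, stage1_labels, cfg)
    change_idx = [cid for cid, lab in zip(keep, labels3) if lab != "no_change"]
    if not change_idx:
        stage1.note = (stage1.note + "; " if stage1.note else "") + (
            "change subset empty: second stage skipped"
        )
        return stage1, None
    labels2 = [cats[cid] for cid in change_idx]
    if len(set(labels2)) < 2:
        stage1.note = (stage1.note + "; " if stage1.note else "") + (
            "change subset single-class: second stage skipped"
        )
        return stage1, None
    stage2 = fit_tree(feats.loc[change_idx], labels2, cfg)
    return stage1, stage2


def extract_threshold(report: TreeReport, feature: str) -> List[float]:
    """All split thresholds on ``feature`` in root-to-leaf (preorder) order.

    Empty list when the feature never appears in the tree.
    """
    out: List[float] = []

    def walk(nid: Optional[int]) -> None:
        if nid is None:
            return
        node = report.nodes[nid]
        if node.is_leaf:
            return
        if node.feature == feature:
            out.append(float(node.threshold))
        walk(node.left)
        walk(node.right)

    walk(0)
    return out
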