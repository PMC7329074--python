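"""Joint progression criteria and marginal-significance calibration.

A joint criterion is a boolean tree over per-index one-tailed trend tests:
leaves name indices, ALL nodes require every child to fire (logical AND), ANY
nodes require at least one (logical OR). Every leaf shares one marginal
significance level alpha — a leaf fires when its one-tailed p-value is
strictly below alpha.

Under a stable eye each leaf p-value is Uniform(0, 1); assuming independence
across leaves, the probability that the tree fires is an exact polynomial in
alpha, computed recursively:

    ALL:  prod(child firing probabilities)
    ANY:  1 - prod(1 - child firing probabilities)

Fixing the joint specificity S means choosing alpha so this polynomial equals
1 - S. For a flat ALL-of-k tree the closed form is alpha = (1 - S)**(1/k);
for a flat ANY-of-k tree, alpha = 1 - S**(1/k); arbitrary nested trees are
solved by bisection on the strictly increasing firing-probability polynomial.

For two indices at S = 0.95 this gives alpha ≈ 0.224 (ALL) and ≈ 0.025 (ANY);
conversely, running both tests naively at alpha = 0.05 yields specificities of
99.75% (ALL) and 89.75% (ANY), which is why calibration is needed for a fair
comparison of positive rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CriterionNode",
    "CalibratedCriterion",
    "joint_firing_probability",
    "calibrate",
    "evaluate",
    "specificity_table",
]

_BISECT_TOL = 1e-13


@dataclass(frozen=True)
class CriterionNode:
    """One node of a criterion tree: a leaf index test, or an ALL/ANY combiner."""

    kind: str  # "leaf" | "all" | "any"
    index_name: str | None = None
    children: tuple["CriterionNode", ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "leaf":
            if not self.index_name or self.children:
                raise ValueError("a leaf needs an index name and no children")
        elif self.kind in ("all", "any"):
            if self.index_name is not None:
                raise ValueError(f"{self.kind.upper()} nodes carry no index name")
            if len(self.children) < 2:
                raise ValueError(f"{self.kind.upper()} nodes need at least 2 children")
        else:
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.kind != "leaf":
            leaves = self.leaf_names()
            if len(leaves) != len(set(leaves)):
                dupes = sorted({n for n in leaves if leaves.count(n) > 1})
                raise ValueError(f"duplicate leaf indices in criterion tree: {dupes}")

    # -- constructors -------------------------------------------------------

    @staticmethod
    def leaf(index_name: str) -> "CriterionNode":
        return CriterionNode("leaf", index_name=index_name)

    @staticmethod
    def all_of(*children: "CriterionNode | str") -> "CriterionNode":
        return CriterionNode("all", children=tuple(_as_node(c) for c in children))

    @staticmethod
    def any_of(*children: "CriterionNode | str") -> "CriterionNode":
        return CriterionNode("any", children=tuple(_as_node(c) for c in children))

    @staticmethod
    def from_spec(spec) -> "CriterionNode":
        """Build a tree from a nested-list expression.

        Examples: ``"RNFLT_global"``, ``["ANY", "RNFLT_global", "MS_global"]``,
        ``["ANY", ["ALL", "RNFLT_global", "MS_global"], "MS_central"]``.
        """
        if isinstance(spec, str):
            return CriterionNode.leaf(spec)
        if isinstance(spec, CriterionNode):
            return spec
        if isinstance(spec, (list, tuple)) and spec:
            op = str(spec[0]).lower()
            if op not in ("all", "any"):
                raise ValueError(f"criterion operator must be ALL or ANY, got {spec[0]!r}")
            children = tuple(CriterionNode.from_spec(c) for c in spec[1:])
            return CriterionNode(op, children=children)
        raise ValueError(f"cannot parse criterion expression: {spec!r}")

    # -- introspection ------------------------------------------------------

    def leaf_names(self) -> list[str]:
        if self.kind == "leaf":
            return [self.index_name]  # type: ignore[list-item]
        return [name for child in self.children for name in child.leaf_names()]

    def is_flat(self) -> bool:
        """True for a single leaf or a one-level ALL/ANY over leaves only."""
        return self.kind == "leaf" or all(c.kind == "leaf" for c in self.children)

    def label(self) -> str:
        if self.kind == "leaf":
            return self.index_name  # type: ignore[return-value]
        sep = " & " if self.kind == "all" else " | "
        return "(" + sep.join(c.label() for c in self.children) + ")"


def _as_node(c: "CriterionNode | str") -> CriterionNode:
    return CriterionNode.leaf(c) if isinstance(c, str) else c


@dataclass(frozen=True)
class CalibratedCriterion:
    """A criterion tree with the shared marginal alpha hitting a target specificity.

    Calibration assumes leaf p-values are independent Uniform(0, 1) under the
    null; correlated measurement noise moves the realised specificity away from
    the target (upward for ALL, downward for ANY), which the simulator can
    quantify empirically.
    """

    tree: CriterionNode
    target_specificity: float
    marginal_alpha: float

    def evaluate(self, pvalues: dict[str, float]) -> bool:
        return evaluate(self.tree, pvalues, self.marginal_alpha)


def joint_firing_probability(tree: CriterionNode, alpha: float) -> float:
    """Probability the tree fires when each leaf fires independently w.p. alpha."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return _fire(tree, alpha)


def _fire(node: CriterionNode, alpha: float) -> float:
    if node.kind == "leaf":
        return alpha
    if node.kind == "all":
        p = 1.0
        for c in node.children:
            p *= _fire(c, alpha)
        return p
    q = 1.0
    for c in node.children:
        q *= 1.0 - _fire(c, alpha)
    return 1.0 - q


def calibrate(tree: CriterionNode, target_specificity: float) -> CalibratedCriterion:
    """Find the unique shared alpha with firing probability 1 - specificity.

    Closed forms cover single leaves and flat ALL-of-k / ANY-of-k trees; any
    nested tree falls back to bisection on the monotone firing-probability
    polynomial (tolerance 1e-13 on alpha).
    """
    s = float(target_specificity)
    if not 0.0 < s < 1.0:
        raise ValueError(f"target specificity must be in (0, 1), got {s}")
    miss = 1.0 - s

    if tree.kind == "leaf":
        alpha = miss
    elif tree.is_flat() and tree.kind == "all":
        alpha = miss ** (1.0 / len(tree.children))
    elif tree.is_flat() and tree.kind == "any":
        alpha = 1.0 - s ** (1.0 / len(tree.children))
    else:
        lo, hi = 0.0, 1.0
        while hi - lo > _BISECT_TOL:
            mid = 0.5 * (lo + hi)
            if _fire(tree, mid) < miss:
                lo = mid
            else:
                hi = mid
        alpha = 0.5 * (lo + hi)

    return CalibratedCriterion(tree=tree, target_specificity=s, marginal_alpha=alpha)


def evaluate(tree: CriterionNode, pvalues: dict[str, float], alpha: float) -> bool:
    """Evaluate the tree: a leaf fires iff its p-value is strictly below alpha.

    Every leaf must have a p-value — an eye is never silently skipped.
    """
    if tree.kind == "leaf":
        name = tree.index_name
        if name not in pvalues:
            raise KeyError(f"no p-value supplied for index {name!r}")
        return pvalues[name] < alpha
    results = (evaluate(c, pvalues, alpha) for c in tree.children)
    return all(results) if tree.kind == "all" else any(results)


def specificity_table(
    trees: dict[str, CriterionNode],
    specificities: tuple[float, ...] = (0.90, 0.95, 0.99),
    decimals: int | None = None,
) -> pd.DataFrame:
    """Marginal alphas per criterion (rows) and target specificity (columns).

    Full precision by default; pass ``decimals=3`` for the conventional
    3-decimal display.
    """
    rows = {
        label: {s: calibrate(tree, s).marginal_alpha for s in specificities}
        for label, tree in trees.items()
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.columns = [f"{s:.0%}" for s in specificities]
    table.index.name = "criterion"
    return table.round(decimals) if decimals is not None else table
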