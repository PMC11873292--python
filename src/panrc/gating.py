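"""Boolean gating-tree engine for flow-cytometry event classification.

A gating tree is an ordered hierarchy of named nodes, each carrying a
conjunction of threshold comparisons over intensity channels ('+' means
strictly above the channel threshold, '-' strictly below or equal — events
exactly at threshold are negative). An event belongs to a population leaf
iff it satisfies the full chain of conditions from the root down to that
leaf. The packaged default tree encodes the skeletal stem/progenitor gating
used for growth-plate cells: viable -> lineage-negative (CD45- Tie2-
Ter119-) -> mCherry+ -> {BCSP: CD51+ Thy- 6C3- CD105+; SSC: CD51+ Thy- 6C3-
CD105- CD200+; pre-BCSP: CD51+ Thy- 6C3- CD105- CD200-}. The CD105+ branch
(BCSP) is declared first: BCSP is defined irrespective of CD200, and
declared order is the tie-break should predicates ever overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import ValidationError

__all__ = [
    "GateCondition",
    "GateNode",
    "GatingTree",
    "GatingResult",
    "default_gating_tree",
    "load_gating_tree",
    "save_gating_tree",
    "evaluate_gates",
]


@dataclass(frozen=True)
class GateCondition:
    channel: str
    sign: str  # '+' or '-'
    threshold: float = 0.0

    def __post_init__(self):
        if self.sign not in ("+", "-"):
            raise ValidationError(f"gate sign must be '+' or '-', got {self.sign!r}")

    def satisfied(self, values: np.ndarray) -> np.ndarray:
        if self.sign == "+":
            return values > self.threshold
        return values <= self.threshold


@dataclass(frozen=True)
class GateNode:
    name: str
    parent: str | None
    conditions: tuple[GateCondition, ...]


@dataclass
class GatingTree:
    nodes: list[GateNode]
    populations: tuple[str, ...]

    def __post_init__(self):
        if not self.nodes:
            raise ValidationError("gating tree has no nodes")
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate node names in gating tree")
        roots = [n for n in self.nodes if n.parent is None]
        if len(roots) != 1:
            raise ValidationError(f"gating tree must have exactly one root, got "
                                  f"{len(roots)}")
        seen: set[str] = set()
        for n in self.nodes:
            if n.parent is not None and n.parent not in seen:
                raise ValidationError(
                    f"node {n.name!r} declared before its parent {n.parent!r}"
                )
            seen.add(n.name)
        self.populations = tuple(self.populations)
        if not self.populations:
            raise ValidationError("gating tree declares no populations")
        parents = {n.parent for n in self.nodes if n.parent is not None}
        for p in self.populations:
            if p not in names:
                raise ValidationError(f"population {p!r} is not a tree node")
            if p in parents:
                raise ValidationError(f"population {p!r} is not a leaf")
        self._by_name = {n.name: n for n in self.nodes}

    def node(self, name: str) -> GateNode:
        try:
            return self._by_name[name]
        except KeyError:
            raise ValidationError(f"unknown gate node {name!r}") from None

    def chain(self, name: str) -> list[GateCondition]:
        """All conditions from the root down to ``name`` (inclusive)."""
        out: list[GateCondition] = []
        node = self.node(name)
        stack = []
        while node is not None:
            stack.append(node)
            node = self._by_name[node.parent] if node.parent else None
        for n in reversed(stack):
            out.extend(n.conditions)
        return out

    def channels(self) -> list[str]:
        seen: list[str] = []
        for n in self.nodes:
            for c in n.conditions:
                if c.channel not in seen:
                    seen.append(c.channel)
        return seen

    def to_dict(self) -> dict:
        return {
            "populations": list(self.populations),
            "nodes": [
                {
                    "name": n.name,
                    "parent": n.parent,
                    "gates": [
                        {"channel": c.channel, "sign": c.sign,
                         "threshold": c.threshold}
                        for c in n.conditions
                    ],
                }
                for n in self.nodes
            ],
        }


def _tree_from_dict(d: dict) -> GatingTree:
    try:
        nodes = [
            GateNode(
                name=str(nd["name"]),
                parent=(None if nd.get("parent") in (None, "null") else
                        str(nd["parent"])),
                conditions=tuple(
                    GateCondition(str(g["channel"]), str(g["sign"]),
                                  float(g.get("threshold", 0.0)))
                    for g in nd.get("gates", [])
                ),
            )
            for nd in d["nodes"]
        ]
        pops = tuple(str(p) for p in d["populations"])
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed gating tree file: {exc}") from exc
    return GatingTree(nodes, pops)


def load_gating_tree(path: str) -> GatingTree:
    """Load a YAML/JSON gating-tree file (YAML is a JSON superset)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValidationError("gating tree file must contain a mapping")
    return _tree_from_dict(d)


def save_gating_tree(tree: GatingTree, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(tree.to_dict(), fh, sort_keys=False)


def default_gating_tree(threshold: float = 0.0) -> GatingTree:
    """The packaged skeletal stem/progenitor gating scheme (see module docs)."""
    t = threshold
    nodes = [
        GateNode("viable", None, (GateCondition("viability", "-", t),)),
        GateNode("Lin-", "viable", (
            GateCondition("CD45", "-", t),
            GateCondition("Tie2", "-", t),
            GateCondition("Ter119", "-", t),
        )),
        GateNode("mCherry+", "Lin-", (GateCondition("mCherry", "+", t),)),
        GateNode("BCSP", "mCherry+", (
            GateCondition("CD51", "+", t),
            GateCondition("Thy", "-", t),
            GateCondition("6C3", "-", t),
            GateCondition("CD105", "+", t),
        )),
        GateNode("SSC", "mCherry+", (
            GateCondition("CD51", "+", t),
            GateCondition("Thy", "-", t),
            GateCondition("6C3", "-", t),
            GateCondition("CD105", "-", t),
            GateCondition("CD200", "+", t),
        )),
        GateNode("pre-BCSP", "mCherry+", (
            GateCondition("CD51", "+", t),
            GateCondition("Thy", "-", t),
            GateCondition("6C3", "-", t),
            GateCondition("CD105", "-", t),
            GateCondition("CD200", "-", t),
        )),
    ]
    return GatingTree(nodes, ("BCSP", "SSC", "pre-BCSP"))


@dataclass
class GatingResult:
    """Per-event population assignment plus population counts and percentages
    of the declared denominator population."""

    assignments: pd.Series  # event id -> population name or 'other'
    counts: dict[str, int]
    denominator: str
    denominator_count: int
    pct_of_denominator: dict[str, float | None] = field(default_factory=dict)

    @property
    def unassigned_in_denominator(self) -> int:
        return self.denominator_count - sum(self.counts.values())


def evaluate_gates(
    events: pd.DataFrame, tree: GatingTree, denominator: str
) -> GatingResult:
    """Classify each event into the first declared population whose full
    ancestor chain it satisfies; report percentages of the denominator node.
    """
    tree.node(denominator)  # raises if unknown
    missing = [c for c in tree.channels() if c not in events.columns]
    if missing:
        raise ValidationError(f"event table lacks channels: {missing}")

    def chain_mask(name: str) -> np.ndarray:
        mask = np.ones(len(events), dtype=bool)
        for cond in tree.chain(name):
            mask &= cond.satisfied(events[cond.channel].to_numpy(dtype=float))
        return mask

    assigned = np.full(len(events), "other", dtype=object)
    taken = np.zeros(len(events), dtype=bool)
    counts: dict[str, int] = {}
    for pop in tree.populations:
        mask = chain_mask(pop) & ~taken
        assigned[mask] = pop
        taken |= mask
        counts[pop] = int(mask.sum())

    denom_mask = chain_mask(denominator)
    denom_n = int(denom_mask.sum())
    pct = {
        pop: (100.0 * c / denom_n if denom_n else None)
        for pop, c in counts.items()
    }
    return GatingResult(
        assignments=pd.Series(assigned, index=events.index, name="population"),
        counts=counts,
        denominator=denominator,
        denominator_count=denom_n,
        pct_of_denominator=pct,
    )
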