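"""Exploration tree: the lineage of every improver inserted during a run.

Nodes are molecules (one per canonical SMILES, scored at insertion time);
edges carry the ordered labels of the actions that turned the parent into
the child (Ad/Rm/Ch/Sub/In/Ct/Mv).  Nodes persist after their individual is
replaced out of the population — the tree records history, not current
membership.  Exportable as Graphviz DOT and as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .actions import Action

__all__ = ["TreeNode", "TreeEdge", "ExplorationTree"]


@dataclass
class TreeNode:
    key: str
    score: float
    step: int
    sub_scores: dict[str, float] = field(default_factory=dict)


@dataclass
class TreeEdge:
    parent: str
    child: str
    labels: tuple[str, ...]


class ExplorationTree:
    """Rooted forest over canonical SMILES keys.

    Roots are the initial-population molecules; every other node has exactly
    one incoming edge, added by :meth:`record` when its molecule is inserted
    as an improver.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, TreeNode] = {}
        self.edges: dict[str, TreeEdge] = {}  # child key -> edge
        self.roots: set[str] = set()

    def add_root(self, key: str, score: float, step: int = 0,
                 sub_scores: Optional[dict[str, float]] = None) -> None:
        if key in self.nodes:
            raise ValueError(f"node {key!r} already recorded")
        self.nodes[key] = TreeNode(key, score, step, dict(sub_scores or {}))
        self.roots.add(key)

    def record(self, parent_key: str, child_key: str, score: float,
               step: int, actions: Sequence[Action | str],
               sub_scores: Optional[dict[str, float]] = None) -> None:
        """Add an improver node and its action-labelled incoming edge."""
        if parent_key not in self.nodes:
            raise ValueError(
                f"parent {parent_key!r} was never inserted in the tree")
        if child_key in self.nodes:
            raise ValueError(f"child {child_key!r} already recorded")
        if not actions:
            raise ValueError("an improver edge needs at least one action")
        labels = tuple(a.type.label if isinstance(a, Action) else str(a)
                       for a in actions)
        self.nodes[child_key] = TreeNode(child_key, score, step,
                                         dict(sub_scores or {}))
        self.edges[child_key] = TreeEdge(parent_key, child_key, labels)

    # -- queries ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def children(self, key: str) -> list[str]:
        return sorted(e.child for e in self.edges.values()
                      if e.parent == key)

    def path_to_root(self, key: str) -> list[str]:
        path = [key]
        while key in self.edges:
            key = self.edges[key].parent
            path.append(key)
        return path

    # -- export -----------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "nodes": [{"smiles": n.key, "score": n.score, "step": n.step,
                       "sub_scores": n.sub_scores}
                      for n in self.nodes.values()],
            "edges": [{"from": e.parent, "to": e.child,
                       "labels": list(e.labels)}
                      for e in self.edges.values()],
            "roots": sorted(self.roots),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ExplorationTree":
        payload = json.loads(text)
        tree = cls()
        for n in payload["nodes"]:
            tree.nodes[n["smiles"]] = TreeNode(
                n["smiles"], n["score"], n["step"],
                dict(n.get("sub_scores", {})))
        for e in payload["edges"]:
            tree.edges[e["to"]] = TreeEdge(e["from"], e["to"],
                                           tuple(e["labels"]))
        tree.roots = set(payload["roots"])
        return tree

    def to_dot(self) -> str:
        """Graphviz DOT rendering; node colour intensity tracks the score."""
        scores = [n.score for n in self.nodes.values()]
        lo, hi = (min(scores), max(scores)) if scores else (0.0, 1.0)
        span = (hi - lo) or 1.0
        ids = {key: f"n{i}" for i, key in enumerate(self.nodes)}
        lines = ["digraph exploration {", "  node [style=filled];"]
        for key, node in self.nodes.items():
            frac = (node.score - lo) / span
            colour = f"0.60 {0.15 + 0.75 * frac:.3f} 1.0"  # HSV blue ramp
            shape = ", shape=doublecircle" if key in self.roots else ""
            lines.append(
                f'  {ids[key]} [label="{key}\\n{node.score:.3f}", '
                f'fillcolor="{colour}"{shape}];')
        for edge in self.edges.values():
            lines.append(
                f'  {ids[edge.parent]} -> {ids[edge.child]} '
                f'[label="{",".join(edge.labels)}"];')
        lines.append("}")
        return "\n".join(lines)

    def export(self, fmt: str) -> str:
        if fmt == "json":
            return self.to_json()
        if fmt == "dot":
            return self.to_dot()
        raise ValueError(f"unknown export format {fmt!r}")
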