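"""Hierarchical food ontology and enumeration of discriminant contrasts.

Foods are organized in a rooted category tree (e.g. plant → fruit →
blueberry) and each reference sample is assigned to one leaf. Biomarker
learning runs one one-vs-rest discriminant analysis per category at every
hierarchical level, so internal nodes ("fleshy fruit") and leaves
("blueberry") can both carry biomarkers. This module owns the tree
representation, its on-disk formats (nested JSON or TSV edge lists) and the
enumeration of those one-vs-rest contrasts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyNode",
    "FoodOntology",
    "ContrastSpec",
    "read_ontology",
    "write_ontology",
    "read_ontology_tables",
    "enumerate_contrasts",
]


class OntologyError(ValueError):
    """The ontology violates its structural invariants."""


@dataclass(frozen=True)
class OntologyNode:
    category_id: str
    name: str
    parent_id: str | None
    level: int


@dataclass
class FoodOntology:
    """Rooted food-category tree with sample→leaf assignments.

    Exactly one root; every non-root node has one parent; ``level`` is the
    depth from the root (root = 0); samples may only be assigned to leaves.
    """

    nodes: dict[str, OntologyNode]
    sample_assignments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise OntologyError(f"expected exactly one root, found {len(roots)}")
        children: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        for node in self.nodes.values():
            if node.parent_id is not None:
                if node.parent_id not in self.nodes:
                    raise OntologyError(
                        f"node {node.category_id!r} references unknown parent {node.parent_id!r}"
                    )
                children[node.parent_id].append(node.category_id)
        # depth-first from root: detects cycles/orphans and checks levels
        seen: set[str] = set()
        stack = [(roots[0].category_id, 0)]
        while stack:
            nid, depth = stack.pop()
            if nid in seen:
                raise OntologyError(f"cycle detected at node {nid!r}")
            seen.add(nid)
            if self.nodes[nid].level != depth:
                raise OntologyError(
                    f"node {nid!r} has level {self.nodes[nid].level}, expected depth {depth}"
                )
            stack.extend((c, depth + 1) for c in children[nid])
        if seen != set(self.nodes):
            orphans = sorted(set(self.nodes) - seen)
            raise OntologyError(f"nodes unreachable from root (cycle or orphan): {orphans}")
        self._children = children
        leaf_set = self.leaves()
        for sample, cat in self.sample_assignments.items():
            if cat not in self.nodes:
                raise OntologyError(f"sample {sample!r} assigned to unknown node {cat!r}")
            if cat not in leaf_set:
                raise OntologyError(f"sample {sample!r} assigned to internal node {cat!r}")

    @property
    def root(self) -> OntologyNode:
        return next(n for n in self.nodes.values() if n.parent_id is None)

    def children(self, category_id: str) -> list[str]:
        return list(self._children[category_id])

    def leaves(self) -> set[str]:
        return {nid for nid, kids in self._children.items() if not kids}

    def subtree(self, category_id: str) -> set[str]:
        """All category ids in the subtree rooted at ``category_id`` (inclusive)."""
        if category_id not in self.nodes:
            raise KeyError(category_id)
        out: set[str] = set()
        stack = [category_id]
        while stack:
            nid = stack.pop()
            out.add(nid)
            stack.extend(self._children[nid])
        return out

    def subtree_samples(self, category_id: str) -> set[str]:
        """Samples assigned to any leaf in the subtree of ``category_id``."""
        cats = self.subtree(category_id)
        return {s for s, c in self.sample_assignments.items() if c in cats}

    def categories_at_level(self, level: int) -> list[str]:
        return sorted(n.category_id for n in self.nodes.values() if n.level == level)

    @property
    def max_level(self) -> int:
        return max(n.level for n in self.nodes.values())

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str | None, str]],
        assignments: Mapping[str, str] | None = None,
    ) -> "FoodOntology":
        """Build from ``(child_id, parent_id, name)`` triples; levels are computed."""
        raw = {child: (parent, name) for child, parent, name in edges}
        levels: dict[str, int] = {}

        def depth(nid: str, trail: tuple[str, ...] = ()) -> int:
            if nid in levels:
                return levels[nid]
            if nid in trail:
                cycle = " -> ".join(trail + (nid,))
                raise OntologyError(f"cycle detected: {cycle}")
            parent = raw[nid][0]
            if parent is None:
                levels[nid] = 0
            else:
                if parent not in raw:
                    raise OntologyError(f"node {nid!r} references unknown parent {parent!r}")
                levels[nid] = depth(parent, trail + (nid,)) + 1
            return levels[nid]

        for nid in raw:
            depth(nid)
        nodes = {
            nid: OntologyNode(nid, name, parent, levels[nid])
            for nid, (parent, name) in raw.items()
        }
        return cls(nodes=nodes, sample_assignments=dict(assignments or {}))


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------


def _tree_to_dict(ontology: FoodOntology, category_id: str) -> dict:
    node = ontology.nodes[category_id]
    out: dict = {"id": node.category_id, "name": node.name}
    kids = sorted(ontology.children(category_id))
    if kids:
        out["children"] = [_tree_to_dict(ontology, c) for c in kids]
    return out


def write_ontology(ontology: FoodOntology, path: str | Path) -> None:
    """Write the nested-JSON format: ``{"tree": {...}, "assignments": {...}}``."""
    doc = {
        "tree": _tree_to_dict(ontology, ontology.root.category_id),
        "assignments": dict(sorted(ontology.sample_assignments.items())),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def read_ontology(path: str | Path) -> FoodOntology:
    """Read the nested-JSON ontology format.

    Accepts either ``{"tree": node, "assignments": {...}}`` or a bare root
    node ``{"id", "name", "children": [...]}`` with no assignments.
    """
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if "tree" in doc:
        tree, assignments = doc["tree"], doc.get("assignments", {})
    else:
        tree, assignments = doc, {}
    edges: list[tuple[str, str | None, str]] = []

    def walk(node: dict, parent: str | None) -> None:
        nid = str(node["id"])
        edges.append((nid, parent, str(node.get("name", nid))))
        for child in node.get("children", []):
            walk(child, nid)

    walk(tree, None)
    return FoodOntology.from_edges(edges, assignments)


def read_ontology_tables(
    edges_path: str | Path, assignments_path: str | Path | None = None
) -> FoodOntology:
    """Read the TSV format: an edge list (child_id, parent_id, name) plus an
    optional assignment table (sample_id, category_id). An empty/missing
    parent_id marks the root."""
    edges_df = pd.read_csv(edges_path, sep=None, engine="python", dtype=str)
    required = {"child_id", "parent_id", "name"}
    if not required.issubset(edges_df.columns):
        raise OntologyError(f"{edges_path}: edge list needs columns {sorted(required)}")
    edges = [
        (
            str(row.child_id),
            None if pd.isna(row.parent_id) or row.parent_id == "" else str(row.parent_id),
            str(row.name),
        )
        for row in edges_df.itertuples(index=False)
    ]
    assignments: dict[str, str] = {}
    if assignments_path is not None:
        adf = pd.read_csv(assignments_path, sep=None, engine="python", dtype=str)
        if not {"sample_id", "category_id"}.issubset(adf.columns):
            raise OntologyError(
                f"{assignments_path}: assignment table needs sample_id, category_id"
            )
        assignments = dict(zip(adf["sample_id"], adf["category_id"]))
    return FoodOntology.from_edges(edges, assignments)


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastSpec:
    """One one-vs-rest discriminant contrast.

    ``positive_samples`` are all provided samples assigned under the target
    category's subtree; ``negative_samples`` are the rest of the provided
    samples (scope ``global``) or only those under the same parent (scope
    ``siblings``).
    """

    target_category: str
    level: int
    positive_samples: frozenset[str]
    negative_samples: frozenset[str]
    scope: str

    def __post_init__(self) -> None:
        if self.positive_samples & self.negative_samples:
            raise ValueError("positive and negative sample sets overlap")
        if not self.positive_samples or not self.negative_samples:
            raise ValueError("contrast has an empty class")


def enumerate_contrasts(
    ontology: FoodOntology,
    samples: Iterable[str],
    scope: str = "global",
    min_group_size: int = 3,
) -> list[ContrastSpec]:
    """Enumerate one one-vs-rest contrast per non-root category.

    With ``scope="global"`` (the default — fold-changes compare a category
    against *all other* foods) negatives are every provided sample outside
    the target subtree; with ``scope="siblings"`` negatives are restricted
    to samples under the same parent. Contrasts whose positive or negative
    class has fewer than ``min_group_size`` samples are dropped and logged.
    """
    if scope not in ("global", "siblings"):
        raise ValueError(f"unknown scope {scope!r}")
    if min_group_size < 2:
        raise ValueError("min_group_size must be >= 2")
    samples = set(samples)
    unknown = samples - set(ontology.sample_assignments)
    if unknown:
        raise ValueError(f"samples not assigned in ontology: {sorted(unknown)[:5]}")
    contrasts: list[ContrastSpec] = []
    dropped = 0
    order = sorted(
        (n for n in ontology.nodes.values() if n.parent_id is not None),
        key=lambda n: (n.level, n.category_id),
    )
    for node in order:
        positives = ontology.subtree_samples(node.category_id) & samples
        if scope == "global":
            negatives = samples - positives
        else:
            parent_samples = ontology.subtree_samples(node.parent_id) & samples
            negatives = parent_samples - positives
        if len(positives) < min_group_size or len(negatives) < min_group_size:
            dropped += 1
            logger.info(
                "contrast %s dropped: %d vs %d below min_group_size=%d",
                node.category_id,
                len(positives),
                len(negatives),
                min_group_size,
            )
            continue
        contrasts.append(
            ContrastSpec(
                target_category=node.category_id,
                level=node.level,
                positive_samples=frozenset(positives),
                negative_samples=frozenset(negatives),
                scope=scope,
            )
        )
    if not contrasts:
        raise ValueError(
            "no valid contrasts; all category groups are smaller than "
            f"min_group_size={min_group_size} — consider lowering it"
        )
    if dropped:
        logger.info("%d contrast(s) dropped for insufficient group size", dropped)
    return contrasts
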