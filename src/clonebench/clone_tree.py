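"""Clone trees and bulk compositions.

A tumour's subclonal architecture is modelled as a rooted tree of clones
hanging off a ``germline`` root.  Each clone is described by a triplet
``name,branch_weight,parent`` in a comma-separated *structure string*, e.g.
``"cloneA,2,germline,cloneB,1,cloneA"``.  The branch weight is a relative
mutational branch length used to distribute somatic mutation counts across
branches.

A :class:`BulkComposition` describes what fraction of a bulk sample's reads
come from each clone and from normal (germline) cells; purity is
``1 - normal_fraction``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

#: Reserved parent token marking the root of a clone tree.
ROOT_MARKER = "germline"

__all__ = [
    "ROOT_MARKER",
    "CloneNode",
    "CloneTree",
    "BulkComposition",
    "StructureParseError",
    "parse_structure",
    "subtree_ccf",
    "branch_weights",
]


class StructureParseError(ValueError):
    """Raised when a structure string cannot be parsed into a valid tree.

    Carries the offending triplet (when attributable) in ``triplet``.
    """

    def __init__(self, message: str, triplet: tuple[str, ...] | None = None):
        self.triplet = triplet
        if triplet is not None:
            message = f"{message} [offending triplet: {','.join(triplet)}]"
        super().__init__(message)


@dataclass(frozen=True)
class CloneNode:
    """One clone: its name, parent clone (or the root marker) and branch weight."""

    name: str
    parent: str
    branch_weight: float

    def __post_init__(self) -> None:
        if not self.name or self.name == ROOT_MARKER:
            raise ValueError(f"invalid clone name {self.name!r}")
        if not math.isfinite(self.branch_weight) or self.branch_weight < 0:
            raise ValueError(
                f"branch weight of {self.name!r} must be finite and >= 0, "
                f"got {self.branch_weight}"
            )


class CloneTree:
    """A rooted tree of clones.

    Nodes keep their input order.  The implicit root (``germline``) is not a
    node; its children are the clones whose parent is the root marker.
    """

    def __init__(self, nodes: Iterable[CloneNode]):
        self.nodes: list[CloneNode] = list(nodes)
        if not self.nodes:
            raise ValueError("a clone tree needs at least one clone")
        self._by_name: dict[str, CloneNode] = {}
        for node in self.nodes:
            if node.name in self._by_name:
                raise ValueError(f"duplicate clone name {node.name!r}")
            self._by_name[node.name] = node
        self._children: dict[str, list[str]] = {n.name: [] for n in self.nodes}
        for node in self.nodes:
            if node.parent == ROOT_MARKER:
                continue
            if node.parent not in self._by_name:
                raise ValueError(
                    f"clone {node.name!r} has unknown parent {node.parent!r}"
                )
            self._children[node.parent].append(node.name)
        # Reachability from the root catches cycles and detached components.
        reachable: set[str] = set()
        stack = [n.name for n in self.nodes if n.parent == ROOT_MARKER]
        if not stack:
            raise ValueError("no clone is attached to the root marker")
        while stack:
            name = stack.pop()
            if name in reachable:
                continue
            reachable.add(name)
            stack.extend(self._children[name])
        unreachable = [n.name for n in self.nodes if n.name not in reachable]
        if unreachable:
            raise ValueError(
                "clones not reachable from the root (cycle or detached "
                f"component): {unreachable}"
            )

    # -- queries ---------------------------------------------------------

    @property
    def clones(self) -> list[str]:
        return [n.name for n in self.nodes]

    @property
    def root_children(self) -> list[str]:
        return [n.name for n in self.nodes if n.parent == ROOT_MARKER]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, name: str) -> CloneNode:
        return self._by_name[name]

    def parent(self, name: str) -> str:
        """Parent clone name, or :data:`ROOT_MARKER` for root children."""
        return self._by_name[name].parent

    def children(self, name: str) -> list[str]:
        return list(self._children[name])

    def subtree(self, name: str) -> list[str]:
        """``name`` and all its descendants, preorder."""
        if name not in self._by_name:
            raise KeyError(f"unknown clone {name!r}")
        out: list[str] = []
        stack = [name]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(reversed(self._children[cur]))
        return out

    def preorder(self) -> list[str]:
        """All clones, parents before children."""
        out: list[str] = []
        for child in self.root_children:
            out.extend(self.subtree(child))
        return out

    # -- serialisation ---------------------------------------------------

    def to_structure_string(self) -> str:
        parts: list[str] = []
        for node in self.nodes:
            # str() keeps the shortest exact float representation (round trips)
            weight = node.branch_weight
            text = str(int(weight)) if weight == int(weight) else str(weight)
            parts.extend([node.name, text, node.parent])
        return ",".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"CloneTree({self.to_structure_string()!r})"


def parse_structure(text: str) -> CloneTree:
    """Parse a ``name,weight,parent`` structure string into a :class:`CloneTree`.

    The reserved parent token ``"germline"`` marks root children.  Raises
    :class:`StructureParseError` naming the offending triplet on malformed
    input (wrong token count, duplicate name, unknown parent, non-numeric
    weight, cycle).
    """
    # Tolerate config files pasted with typographic quotes.
    cleaned = text.strip().strip('"').strip("“”").strip()
    tokens = [t.strip() for t in cleaned.split(",")] if cleaned else []
    if not tokens or len(tokens) % 3 != 0:
        raise StructureParseError(
            f"structure string has {len(tokens)} tokens; expected a multiple of 3"
        )
    triplets = [tuple(tokens[i : i + 3]) for i in range(0, len(tokens), 3)]
    nodes: list[CloneNode] = []
    seen: set[str] = set()
    for triplet in triplets:
        name, weight_text, parent = triplet
        if name in seen:
            raise StructureParseError("duplicate clone name", triplet)
        try:
            weight = float(weight_text)
        except ValueError:
            raise StructureParseError("non-numeric branch weight", triplet) from None
        try:
            nodes.append(CloneNode(name=name, parent=parent, branch_weight=weight))
        except ValueError as exc:
            raise StructureParseError(str(exc), triplet) from None
        seen.add(name)
    names = {n.name for n in nodes}
    for triplet, node in zip(triplets, nodes):
        if node.parent != ROOT_MARKER and node.parent not in names:
            raise StructureParseError("unknown parent clone", triplet)
    try:
        return CloneTree(nodes)
    except ValueError as exc:
        raise StructureParseError(str(exc)) from None


@dataclass(frozen=True)
class BulkComposition:
    """Read-fraction composition of a bulk sample.

    ``clone_fractions`` maps clone name to the fraction of the sample's reads
    originating from that clone; ``normal_fraction`` is the germline (normal
    cell) read fraction.  Fractions must be non-negative and sum to 1.
    """

    clone_fractions: Mapping[str, float]
    normal_fraction: float

    _SUM_TOL = 1e-9

    def __post_init__(self) -> None:
        if self.normal_fraction < 0:
            raise ValueError("normal_fraction must be >= 0")
        for clone, frac in self.clone_fractions.items():
            if frac < 0:
                raise ValueError(f"negative fraction for clone {clone!r}")
        total = sum(self.clone_fractions.values()) + self.normal_fraction
        if abs(total - 1.0) > self._SUM_TOL:
            raise ValueError(f"fractions sum to {total}, expected 1")

    @property
    def purity(self) -> float:
        """Tumour purity: fraction of reads from tumour cells."""
        return 1.0 - self.normal_fraction

    @property
    def tumour_proportions(self) -> dict[str, float]:
        """Clone fractions renormalised to sum to 1 over tumour cells only."""
        if self.purity <= 0:
            raise ValueError("tumour proportions undefined at purity 0")
        return {c: f / self.purity for c, f in self.clone_fractions.items()}

    @classmethod
    def from_weights(
        cls, weights: Mapping[str, float], purity: float = 1.0
    ) -> "BulkComposition":
        """Build a composition from relative clone weights and a purity.

        Weights are renormalised to sum to ``purity``; the remainder is the
        normal fraction.
        """
        if not 0 < purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {purity}")
        total = sum(weights.values())
        if total <= 0:
            raise ValueError("clone weights must have a positive sum")
        fractions = {c: purity * w / total for c, w in weights.items()}
        return cls(clone_fractions=fractions,
                   normal_fraction=max(0.0, 1.0 - sum(fractions.values())))


def subtree_ccf(tree: CloneTree, comp: BulkComposition, clone: str) -> float:
    """Cancer cell fraction of a clone's subtree.

    The sum of tumour proportions (clone fractions renormalised to exclude
    normal cells) over ``clone`` and all of its descendants — the CCF of a
    mutation arising on the branch leading to ``clone`` and never lost.
    """
    if clone not in tree:
        raise KeyError(f"unknown clone {clone!r}")
    proportions = comp.tumour_proportions
    return sum(proportions.get(c, 0.0) for c in tree.subtree(clone))


def branch_weights(tree: CloneTree) -> dict[str, float]:
    """Normalised branch weights: each clone's share of somatic mutations."""
    total = sum(n.branch_weight for n in tree.nodes)
    if total <= 0:
        raise ValueError("all branch weights are zero")
    return {n.name: n.branch_weight / total for n in tree.nodes}
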