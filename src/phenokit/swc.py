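"""SWC neuron reconstruction IO and validation.

SWC is the plain-text standard for traced neuron morphologies: one node per
line with seven whitespace-separated columns ``id type x y z radius parent``.
Coordinates are interpreted as micrometres (the tracing-tool default).
The dialect accepted here is the common single-rooted one: exactly one node
has ``parent == -1`` (the soma), every other node's parent occurs in the
file, and the parent pointers form a tree.  Multifurcations (three or more
children) are allowed and count once as a branch point downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


class SWCError(ValueError):
    """Raised for malformed or invalid SWC content."""


@dataclass(frozen=True)
class NeuronNode:
    """One SWC record: a sample point of the reconstruction.

    ``type_code`` follows the SWC convention (1 soma, 2 axon, 3 dendrite;
    other integers are permitted and passed through).  ``parent_id`` is -1
    for the root.
    """

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class NeuronTree:
    """A rooted geometric tree of :class:`NeuronNode` samples.

    Node order is preserved from the source file.  The implicit edge of a
    non-root node runs from the node to its parent; edge lengths are 3D
    Euclidean distances in μm.
    """

    nodes: list[NeuronNode]
    comments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[int, NeuronNode] = {n.id: n for n in self.nodes}
        self._children: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1 and n.parent_id in self._children:
                self._children[n.parent_id].append(n.id)

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, node_id: int) -> NeuronNode:
        return self._index[node_id]

    @property
    def root_id(self) -> int:
        roots = [n.id for n in self.nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise SWCError(f"tree has {len(roots)} roots, expected exactly 1")
        return roots[0]

    @property
    def root(self) -> NeuronNode:
        return self._index[self.root_id]

    def children(self, node_id: int) -> list[int]:
        return list(self._children[node_id])

    def leaves(self) -> list[int]:
        return [i for i, kids in self._children.items() if not kids]

    def edges(self) -> Iterator[tuple[NeuronNode, NeuronNode]]:
        """Yield (parent, child) node pairs for every non-root node."""
        for n in self.nodes:
            if n.parent_id != -1:
                yield self._index[n.parent_id], n

    def edge_length(self, child_id: int) -> float:
        c = self._index[child_id]
        p = self._index[c.parent_id]
        return math.dist(p.xyz(), c.xyz())

    def total_length(self) -> float:
        return sum(math.dist(p.xyz(), c.xyz()) for p, c in self.edges())


def validate_tree(tree: NeuronTree) -> list[str]:
    """Return human-readable invariant violations (empty list = valid).

    Checks uniqueness of ids, single root, parent existence, acyclicity,
    finite coordinates and non-negative radii.  Violations name the
    offending node id; nothing is raised.
    """
    violations: list[str] = []
    if not tree.nodes:
        violations.append("empty tree: at least 1 node required")
        return violations

    seen: set[int] = set()
    for n in tree.nodes:
        if n.id in seen:
            violations.append(f"duplicate id {n.id}")
        seen.add(n.id)
        if n.id <= 0:
            violations.append(f"non-positive id {n.id}")
        if not all(math.isfinite(v) for v in (n.x, n.y, n.z, n.radius)):
            violations.append(f"non-finite coordinate or radius at node {n.id}")
        if n.radius < 0:
            violations.append(f"negative radius at node {n.id}")

    roots = [n.id for n in tree.nodes if n.parent_id == -1]
    if len(roots) == 0:
        violations.append("no root: no node with parent -1")
    elif len(roots) > 1:
        violations.append(f"multiple roots: nodes {roots} all have parent -1")

    ids = {n.id for n in tree.nodes}
    for n in tree.nodes:
        if n.parent_id != -1 and n.parent_id not in ids:
            violations.append(f"missing parent {n.parent_id} referenced by node {n.id}")
        if n.parent_id == n.id:
            violations.append(f"node {n.id} is its own parent")

    # Cycle / connectivity check: walk each parent chain with a visited set.
    parent_of = {n.id: n.parent_id for n in tree.nodes}
    reaches_root: dict[int, bool] = {}
    for n in tree.nodes:
        chain: list[int] = []
        cur = n.id
        on_chain: set[int] = set()
        while True:
            if cur in reaches_root:
                ok = reaches_root[cur]
                break
            if cur in on_chain:
                violations.append(f"cycle at node {cur}")
                ok = False
                break
            on_chain.add(cur)
            chain.append(cur)
            parent = parent_of.get(cur)
            if parent == -1:
                ok = True
                break
            if parent is None or parent not in parent_of:
                ok = False  # dangling parent, reported above
                break
            cur = parent
        for c in chain:
            reaches_root[c] = ok
    return violations


def _parse_line(line: str, lineno: int) -> NeuronNode:
    fields = line.split()
    if len(fields) != 7:
        raise SWCError(
            f"line {lineno}: expected 7 whitespace-separated columns, got {len(fields)}"
        )
    try:
        return NeuronNode(
            id=int(fields[0]),
            type_code=int(fields[1]),
            x=float(fields[2]),
            y=float(fields[3]),
            z=float(fields[4]),
            radius=float(fields[5]),
            parent_id=int(fields[6]),
        )
    except ValueError as exc:
        raise SWCError(f"line {lineno}: malformed field ({exc})") from exc


def read_swc(path: str | Path) -> NeuronTree:
    """Read and validate an SWC file.

    Lines starting with ``#`` are comments and preserved on the returned
    tree.  Raises :class:`SWCError` naming the offending line or node for
    malformed records or invariant violations (duplicate id, missing
    parent, cycle, multiple roots, empty file).
    """
    path = Path(path)
    nodes: list[NeuronNode] = []
    comments: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line)
                continue
            nodes.append(_parse_line(line, lineno))
    tree = NeuronTree(nodes, comments=comments)
    violations = validate_tree(tree)
    if violations:
        raise SWCError(f"{path.name}: " + "; ".join(violations))
    return tree


def write_swc(tree: NeuronTree, path: str | Path, precision: int = 4) -> Path:
    """Write a validated tree to SWC; round-trips node-for-node.

    Coordinates and radii are printed with ``precision`` decimal places,
    so ``read_swc(write_swc(t))`` is the identity on ids, parents, type
    codes, and coordinates at that precision.  Comment lines are preserved.
    """
    violations = validate_tree(tree)
    if violations:
        raise SWCError("refusing to write invalid tree: " + "; ".join(violations))
    path = Path(path)
    fmt = f"{{:.{precision}f}}"
    with open(path, "w") as fh:
        for c in tree.comments:
            fh.write(c + "\n")
        for n in tree.nodes:
            fh.write(
                f"{n.id} {n.type_code} {fmt.format(n.x)} {fmt.format(n.y)} "
                f"{fmt.format(n.z)} {fmt.format(n.radius)} {n.parent_id}\n"
            )
    return path


def tree_from_arrays(
    ids: Iterable[int],
    type_codes: Iterable[int],
    xyz: Iterable[tuple[float, float, float]],
    radii: Iterable[float],
    parents: Iterable[int],
    comments: list[str] | None = None,
) -> NeuronTree:
    """Convenience constructor from parallel sequences (used by generators)."""
    nodes = [
        NeuronNode(i, t, float(p[0]), float(p[1]), float(p[2]), float(r), par)
        for i, t, p, r, par in zip(ids, type_codes, xyz, radii, parents)
    ]
    return NeuronTree(nodes, comments=comments or [])
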