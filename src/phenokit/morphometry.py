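"""Neurite morphometry descriptors and group comparison.

Quantifies a traced neuron's arbor: total projection path length, primary
neurite lengths (soma to the first branch point of each stem), terminal
neurite lengths (leaf back to its nearest ancestral branch point), branch
point and terminal counts, plus the growth-cone fraction of annotated
terminals.  Group contrasts are reported with per-group mean ± SEM and an
ordinary one-way ANOVA.

Conventions: a branch point is a node with at least two children; the soma
is never counted as a branch point even when several stems leave it (each
stem instead starts its own primary neurite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from phenokit.swc import NeuronTree


@dataclass
class MorphometrySummary:
    total_path_length: float
    primary_neurite_count: int
    primary_neurite_lengths: list[float]
    terminal_neurite_lengths: list[float]
    branch_point_count: int
    terminal_count: int
    neuron_id: str | None = None


@dataclass
class TerminalLabelSet:
    """Per-terminal morphology annotations for one neuron.

    ``labels`` maps a terminal node id to ``"growth_cone"`` (filopodial or
    lamellipodial end) or ``"blunt"``.  The classification is made by the
    annotator from actin staining; this package only aggregates it.
    """

    neuron_id: str
    labels: dict[int, str] = field(default_factory=dict)

    VALID = ("growth_cone", "blunt")

    def __post_init__(self) -> None:
        for node_id, lab in self.labels.items():
            if lab not in self.VALID:
                raise ValueError(
                    f"terminal {node_id}: label {lab!r} not in {self.VALID}"
                )


def _branch_nodes(tree: NeuronTree) -> set[int]:
    root = tree.root_id
    return {
        n.id
        for n in tree.nodes
        if n.id != root and len(tree.children(n.id)) >= 2
    }


def summarize_morphometry(tree: NeuronTree) -> MorphometrySummary:
    """Compute the standard arbor descriptors for one reconstruction.

    A single-node tree yields a summary of zeros.  Primary neurite length
    is the geodesic (along-path) distance from the soma to the first branch
    point of that stem, or to the stem's tip if it never branches; terminal
    neurite length is the geodesic distance from a leaf back to its nearest
    ancestral branch point (or to the soma for an unbranched path).
    """
    root = tree.root_id
    if len(tree) == 1:
        return MorphometrySummary(0.0, 0, [], [], 0, 0)

    branch_nodes = _branch_nodes(tree)
    total = tree.total_length()

    # geodesic distance from root to every node, by traversal in file order
    # (parents precede children is not guaranteed by SWC, so iterate until fixed)
    dist: dict[int, float] = {root: 0.0}
    pending = [n for n in tree.nodes if n.id != root]
    while pending:
        rest = []
        for n in pending:
            if n.parent_id in dist:
                dist[n.id] = dist[n.parent_id] + tree.edge_length(n.id)
            else:
                rest.append(n)
        if len(rest) == len(pending):  # unreachable nodes; validated trees never get here
            raise ValueError("disconnected nodes in tree")
        pending = rest

    primary_lengths: list[float] = []
    for stem in tree.children(root):
        cur = stem
        while cur not in branch_nodes and len(tree.children(cur)) == 1:
            cur = tree.children(cur)[0]
        primary_lengths.append(dist[cur])

    parent_of = {n.id: n.parent_id for n in tree.nodes}
    terminal_lengths: list[float] = []
    leaves = [l for l in tree.leaves() if l != root]
    for leaf in leaves:
        anc = parent_of[leaf]
        while anc != root and anc not in branch_nodes:
            anc = parent_of[anc]
        terminal_lengths.append(dist[leaf] - dist[anc])

    return MorphometrySummary(
        total_path_length=total,
        primary_neurite_count=len(primary_lengths),
        primary_neurite_lengths=primary_lengths,
        terminal_neurite_lengths=terminal_lengths,
        branch_point_count=len(branch_nodes),
        terminal_count=len(leaves),
    )


def growth_cone_fraction(labels: TerminalLabelSet) -> float:
    """Percent of labeled terminals classified as growth cones (per neuron)."""
    if not labels.labels:
        raise ValueError("no terminals: cannot compute growth cone fraction")
    n_gc = sum(1 for v in labels.labels.values() if v == "growth_cone")
    return 100.0 * n_gc / len(labels.labels)


@dataclass
class GroupComparison:
    group_means: dict[str, float]
    group_sems: dict[str, float]
    group_ns: dict[str, int]
    f_statistic: float
    p_value: float


def compare_groups(values: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Per-group mean ± SEM and ordinary one-way ANOVA across conditions.

    Pure reporting — no multiple-comparison decisions are made here.
    Requires at least two groups, each with at least two values.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in values.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    arrays = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat, p = stats.f_oneway(*arrays.values())
    return GroupComparison(
        group_means={k: float(a.mean()) for k, a in arrays.items()},
        group_sems={k: float(stats.sem(a)) for k, a in arrays.items()},
        group_ns={k: int(a.size) for k, a in arrays.items()},
        f_statistic=float(f_stat),
        p_value=float(p),
    )
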