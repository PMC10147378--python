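"""Sholl analysis: radial intersection profiles and semi-log decay fits.

The Sholl procedure counts neurite crossings N(r) of concentric circles of
increasing radius r centred on the soma, then fits the semi-log density

    log10( N(r) / (π r²) ) = −k·r + m

by ordinary least squares.  The slope magnitude k is the Sholl regression
coefficient ("Sholl decay"): larger k means branching falls off faster with
distance from the cell body.  Per-neuron fits are gated on R² > 0.8; a
pooled per-genotype fit averages counts across neurons at each radius and
keeps only radii whose mean count lies within the 10th–90th percentile of
the mean-count distribution before fitting.

Geometry is 2D: the z coordinate is dropped before distance computations,
matching the circle-area (πr²) normalization and projected confocal images.
A straight segment with endpoint distances d1 ≤ d2 from the soma crosses
the circle of radius r once if d1 < r ≤ d2, and twice if the segment is
re-entrant with interior minimum distance below r ≤ d1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from phenokit.swc import NeuronTree

R2_GATE_DEFAULT = 0.8


@dataclass
class ShollProfile:
    """Per-radius crossing (or branch-point) counts for one neuron."""

    radii: np.ndarray  # ascending μm grid, step s, starting at s
    counts: np.ndarray  # nonnegative integers N(r)
    soma_center: tuple[float, float]
    neuron_id: str | None = None
    step: float = 1.0
    mode: str = "intersections"

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.radii.shape != self.counts.shape:
            raise ValueError("radii and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.radii.size and (
            np.any(np.diff(self.radii) <= 0) or self.radii[0] <= 0
        ):
            raise ValueError("radii must be strictly increasing and positive")


@dataclass
class ShollFit:
    """Semi-log decay fit for one neuron.

    ``k`` is the Sholl regression coefficient (per μm, sign-flipped slope),
    ``m`` the intercept in log10 density units, and ``included`` records
    whether the fit passes the R² > 0.8 quality gate (strict inequality).
    """

    k: float
    m: float
    r_squared: float
    n_points: int
    included: bool
    neuron_id: str | None = None


@dataclass
class PooledShollFit:
    genotype: str
    radii: np.ndarray
    mean_counts: np.ndarray
    retained_radii: np.ndarray
    k_pooled: float
    m_pooled: float
    r_squared_pooled: float
    n_neurons: int


def _segment_min_distance(
    p1: np.ndarray, p2: np.ndarray, center: np.ndarray
) -> np.ndarray:
    """Min distance from `center` to each 2D segment, vectorized over rows."""
    d = p2 - p1
    w = center[None, :] - p1
    seg_len2 = np.einsum("ij,ij->i", d, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(seg_len2 > 0, np.einsum("ij,ij->i", w, d) / seg_len2, 0.0)
    t = np.clip(t, 0.0, 1.0)
    closest = p1 + t[:, None] * d
    return np.linalg.norm(closest - center[None, :], axis=1)


def sholl_profile(
    tree: NeuronTree,
    step: float = 1.0,
    mode: str = "intersections",
) -> ShollProfile:
    """Radial profile of circle crossings (or binned branch points).

    The soma centre is the root node projected to XY.  Radii run from
    ``step`` to ``ceil(max node distance / step) * step``.  In
    ``intersections`` mode N(r) counts circle-boundary crossings by edge
    segments under the half-open convention d1 < r ≤ d2 (re-entrant
    segments whose interior dips below r contribute two crossings); in
    ``branch_points`` mode N(r) counts branch-point nodes with distance in
    the annulus (r − step, r].
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if mode not in ("intersections", "branch_points"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(tree) == 0:
        raise ValueError("empty tree")

    root = tree.root
    center = np.array([root.x, root.y], dtype=float)
    coords = {n.id: np.array([n.x, n.y], dtype=float) for n in tree.nodes}
    dists = {i: float(np.linalg.norm(c - center)) for i, c in coords.items()}
    max_dist = max(dists.values())
    n_radii = max(int(math.ceil(max_dist / step)), 1)
    radii = step * np.arange(1, n_radii + 1)

    if mode == "branch_points":
        root_id = tree.root_id
        bp_d = np.array(
            [
                dists[n.id]
                for n in tree.nodes
                if n.id != root_id and len(tree.children(n.id)) >= 2
            ]
        )
        counts = np.array(
            [int(np.sum((bp_d > r - step) & (bp_d <= r))) for r in radii]
        )
        return ShollProfile(radii, counts, tuple(center), step=step, mode=mode)

    edges = [(p.id, c.id) for p, c in tree.edges()]
    if not edges:
        counts = np.zeros_like(radii, dtype=int)
        return ShollProfile(radii, counts, tuple(center), step=step, mode=mode)

    p1 = np.array([coords[a] for a, _ in edges])
    p2 = np.array([coords[b] for _, b in edges])
    d1 = np.array([dists[a] for a, _ in edges])
    d2 = np.array([dists[b] for _, b in edges])
    dlo = np.minimum(d1, d2)
    dhi = np.maximum(d1, d2)
    dmin = _segment_min_distance(p1, p2, center)

    r = radii[:, None]  # (R, 1) against (E,)
    single = (dlo[None, :] < r) & (r <= dhi[None, :])
    double = (dmin[None, :] < r) & (r <= dlo[None, :])
    counts = single.sum(axis=1) + 2 * double.sum(axis=1)
    return ShollProfile(radii, counts.astype(int), tuple(center), step=step, mode=mode)


def semilog_points(profile: ShollProfile) -> list[tuple[float, float]]:
    """Semi-log density points (r, log10(N(r)/(πr²))); zero-count radii dropped."""
    pts = []
    for r, n in zip(profile.radii, profile.counts):
        if n > 0:
            pts.append((float(r), float(np.log10(n / (math.pi * r**2)))))
    return pts


def fit_sholl(
    points: list[tuple[float, float]],
    r2_gate: float = R2_GATE_DEFAULT,
    neuron_id: str | None = None,
) -> ShollFit:
    """Ordinary least squares on semi-log points; k = −slope.

    Requires at least 3 points and a non-degenerate abscissa.  The fit is
    flagged ``included`` iff R² strictly exceeds the gate (default 0.8).
    """
    if len(points) < 3:
        raise ValueError("insufficient points: need at least 3 for a Sholl fit")
    r = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.allclose(r, r[0]):
        raise ValueError("degenerate abscissa: all radii identical")
    res = stats.linregress(r, y)
    r2 = float(res.rvalue**2)
    return ShollFit(
        k=float(-res.slope),
        m=float(res.intercept),
        r_squared=r2,
        n_points=len(points),
        included=bool(r2 > r2_gate),
        neuron_id=neuron_id,
    )


def pooled_decay(
    profiles: list[ShollProfile],
    pct_low: float = 10.0,
    pct_high: float = 90.0,
    genotype: str = "",
) -> PooledShollFit:
    """Percentile-filtered pooled decay fit for a genotype.

    Counts are averaged per radius across all neurons (a neuron shorter
    than r contributes 0 at r), radii whose mean count falls outside the
    [pct_low, pct_high] percentile band of the mean-count distribution are
    discarded (bounds inclusive, linear-interpolation percentiles), and the
    remaining semi-log points are fitted as in :func:`fit_sholl`.  No R²
    gate is applied to the pooled fit.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to pool")
    if not 0 <= pct_low < pct_high <= 100:
        raise ValueError("percentile bounds must satisfy 0 <= low < high <= 100")
    steps = {p.step for p in profiles}
    if len(steps) != 1:
        raise ValueError("profiles must share a common radial step")
    step = steps.pop()

    n_max = max(p.radii.size for p in profiles)
    radii = step * np.arange(1, n_max + 1)
    acc = np.zeros(n_max, dtype=float)
    for p in profiles:
        acc[: p.counts.size] += p.counts
    mean_counts = acc / len(profiles)

    lo, hi = np.percentile(mean_counts, [pct_low, pct_high])
    keep = (mean_counts >= lo) & (mean_counts <= hi)
    retained = radii[keep]
    if retained.size < 3:
        raise ValueError("fewer than 3 radii retained after percentile filter")

    pts = [
        (float(r), float(np.log10(n / (math.pi * r**2))))
        for r, n in zip(retained, mean_counts[keep])
        if n > 0
    ]
    fit = fit_sholl(pts, r2_gate=-np.inf)
    return PooledShollFit(
        genotype=genotype,
        radii=radii,
        mean_counts=mean_counts,
        retained_radii=retained,
        k_pooled=fit.k,
        m_pooled=fit.m,
        r_squared_pooled=fit.r_squared,
        n_neurons=len(profiles),
    )


def fit_neuron(
    tree: NeuronTree,
    step: float = 1.0,
    mode: str = "intersections",
    r2_gate: float = R2_GATE_DEFAULT,
    neuron_id: str | None = None,
) -> tuple[ShollProfile, ShollFit]:
    """Convenience: profile a tree and fit its semi-log decay in one call."""
    prof = sholl_profile(tree, step=step, mode=mode)
    prof.neuron_id = neuron_id
    fit = fit_sholl(semilog_points(prof), r2_gate=r2_gate, neuron_id=neuron_id)
    return prof, fit
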