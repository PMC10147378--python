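"""Synthetic-data generators with known ground truth.

Every input class of the pipeline can be generated here so that the whole
analysis is testable at desk scale: branched neurite trees whose
intersection density decays exponentially with radius at a chosen rate,
paired fluorescence channels with a chosen target correlation, disk-shaped
puncta of known number and size, NMJ bouton chains with side sprouts, and
survival cohorts with chosen median lifespans and censoring.

All generators are pure functions of (parameters, seed); there is no
global random state.  Generators exist to create statistical structure for
verification, not biophysical realism.

Neuron growth model
-------------------
Segments grow radially outward from the soma in 1 μm (``step``) increments
with small angular jitter, so the 2D projection assumption of the Sholl
module holds and the number of circle crossings at radius r equals the
number of live segments there.  When a target decay ``k0`` is given, the
per-step expected offspring count of a live segment at radius r is

    rho(r) = ((r + s) / r)**2 * 10**(-k0 * s)

which makes the expected live-segment count follow
E[N(r)] = stems * (r/s)**2 * 10**(-k0 (r - s)), i.e. the semi-log density
log10(N/(πr²)) is exactly linear in r with slope −k0.  Offspring counts
above one are realised as multifurcations (floor(rho) children plus a
Bernoulli remainder); below one, the segment survives with probability
rho.  Without calibration, constant per-μm branch/termination
probabilities apply (p_branch = p_term = 0 yields straight radial stems).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from phenokit.imaging import ImageChannel, RoiMask, PunctaSet, Punctum
from phenokit.organismal import Bouton, BoutonGraph, SurvivalCohort
from phenokit.swc import NeuronNode, NeuronTree


# --------------------------------------------------------------------------
# neurons
# --------------------------------------------------------------------------

@dataclass
class NeuronSimParams:
    """Growth parameters for one synthetic neuron.

    ``k0``: target Sholl decay (per μm); when set it overrides the constant
    probabilities via the calibrated offspring schedule above.  ``stems``:
    number of primary neurites leaving the soma.  ``r_max``: terminal
    radius (μm).  ``jitter_deg``: s.d. of the per-step angular perturbation.
    """

    k0: float | None = 0.08
    stems: int = 3
    p_branch: float = 0.0
    p_term: float = 0.0
    r_max: float = 40.0
    step: float = 1.0
    jitter_deg: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k0 is not None and self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if self.stems < 1:
            raise ValueError("need at least one stem")
        if not (0 <= self.p_branch <= 1 and 0 <= self.p_term <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.step <= 0 or self.r_max <= 0:
            raise ValueError("step and r_max must be positive")


def _check_degenerate(params: NeuronSimParams) -> None:
    if params.r_max < 3 * params.step:
        raise ValueError("degenerate profile: fewer than 3 radial steps")
    if params.k0 is None:
        expected = params.stems * (1.0 + params.p_branch - params.p_term) ** 3
        if expected < 0.5:
            raise ValueError(
                "degenerate profile: expected extinction before 3 radii"
            )


def simulate_neuron_with_truth(
    params: NeuronSimParams,
) -> tuple[NeuronTree, np.ndarray, np.ndarray]:
    """Grow one tree and return (tree, radii grid, live-segment counts).

    The live-segment count at radius r·step is the generator's own
    bookkeeping of how many segments cross that circle; for these purely
    radially growing trees it equals the Sholl intersection count.

    Angular perturbations are applied as arc-length jitter (s.d. capped at
    ``jitter_deg`` near the soma, shrinking like 1/r farther out), which
    keeps every segment's distance from the soma strictly increasing along
    its length — no segment is re-entrant, so the bookkeeping is exact.
    """
    _check_degenerate(params)
    rng = np.random.default_rng(params.seed)
    s = params.step
    n_steps = int(round(params.r_max / s))
    # keep nodes strictly off the counting circles: a node exactly on a grid
    # radius would make the half-open crossing convention tie-break on a
    # 1-ulp rounding of sqrt(x**2 + y**2)
    eps = 1e-6 * s

    node_ids = [1]
    type_codes = [1]
    xyz: list[tuple[float, float, float]] = [(0.0, 0.0, 0.0)]
    radii = [1.0]
    parents = [-1]
    next_id = 2

    jitter_cap = math.radians(params.jitter_deg)

    # live segments: (tip node id, direction angle)
    angles = 2 * math.pi * np.arange(params.stems) / params.stems
    angles = angles + rng.normal(0.0, jitter_cap, params.stems)
    live: list[tuple[int, float]] = []
    for theta in angles:
        node_ids.append(next_id)
        type_codes.append(3)
        xyz.append(((s + eps) * math.cos(theta), (s + eps) * math.sin(theta), 0.0))
        radii.append(0.5)
        parents.append(1)
        live.append((next_id, float(theta)))
        next_id += 1

    counts = np.zeros(n_steps, dtype=int)
    counts[0] = len(live)

    for i in range(1, n_steps):
        r = i * s
        r_next = r + s
        if params.k0 is not None:
            rho = ((r + s) / r) ** 2 * 10 ** (-params.k0 * s)
        else:
            rho = 1.0 + params.p_branch - params.p_term
        n_children_base = int(math.floor(rho))
        p_extra = rho - n_children_base

        # arc-length-limited angular changes keep radial growth monotone
        jitter_sd = min(jitter_cap, 0.5 * s / r)
        spread = min(0.3, 1.5 * s / r)

        new_live: list[tuple[int, float]] = []
        for tip_id, theta in live:
            n_children = n_children_base + (1 if rng.random() < p_extra else 0)
            if n_children == 0:
                continue
            offsets = (
                np.linspace(-spread, spread, n_children)
                if n_children > 1
                else np.zeros(1)
            )
            for off in offsets:
                theta_c = theta + float(off) + float(rng.normal(0.0, jitter_sd))
                node_ids.append(next_id)
                type_codes.append(3)
                xyz.append(
                    (
                        (r_next + eps) * math.cos(theta_c),
                        (r_next + eps) * math.sin(theta_c),
                        0.0,
                    )
                )
                radii.append(0.5)
                parents.append(tip_id)
                new_live.append((next_id, theta_c))
                next_id += 1
        live = new_live
        counts[i] = len(live)
        if not live:
            break

    nodes = [
        NeuronNode(i, t, x, y, z, rad, par)
        for i, t, (x, y, z), rad, par in zip(
            node_ids, type_codes, xyz, radii, parents
        )
    ]
    return NeuronTree(nodes), s * np.arange(1, n_steps + 1), counts


def simulate_neuron(params: NeuronSimParams) -> NeuronTree:
    """Grow one radially branching stochastic tree; deterministic given seed."""
    tree, _, _ = simulate_neuron_with_truth(params)
    return tree


@dataclass
class SimulatedPopulation:
    trees_a: list[NeuronTree]
    trees_b: list[NeuronTree]
    params_a: NeuronSimParams
    params_b: NeuronSimParams


def simulate_population(
    n: int,
    params_a: NeuronSimParams,
    params_b: NeuronSimParams | None = None,
) -> SimulatedPopulation:
    """Two labeled neuron sets emulating a two-genotype contrast.

    By default group B is generated with twice the decay rate and a shorter
    terminal radius than group A, emulating a reduced-complexity genotype.
    Ground-truth parameters are returned alongside the trees.
    """
    if n < 2:
        raise ValueError("need n >= 2 neurons per group")
    if params_b is None:
        k0_b = (params_a.k0 or 0.08) * 2.0
        params_b = replace(params_a, k0=k0_b, r_max=params_a.r_max * 0.75)
    base = np.random.default_rng(params_a.seed).integers(0, 2**31 - 1, size=2 * n)
    trees_a = [
        simulate_neuron(replace(params_a, seed=int(base[i]))) for i in range(n)
    ]
    trees_b = [
        simulate_neuron(replace(params_b, seed=int(base[n + i]))) for i in range(n)
    ]
    return SimulatedPopulation(trees_a, trees_b, params_a, params_b)


# --------------------------------------------------------------------------
# survival cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortSimParams:
    """Cohort sizes and target medians for survival simulation.

    Lifespans are drawn from a Weibull ageing distribution (shape 3, a
    realistic fly senescence profile) whose scale is set so the continuous
    median equals the requested median, then rounded up to whole days
    (deaths scored daily).
    """

    n_per_group: int = 100
    medians: dict[str, float] = field(default_factory=lambda: {"control": 20.0})
    censoring_fraction: float = 0.0
    weibull_shape: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if any(m <= 0 for m in self.medians.values()):
            raise ValueError("medians must be positive")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must be in [0, 1)")


def simulate_survival(params: CohortSimParams) -> dict[str, SurvivalCohort]:
    """Generate one cohort per requested group; deterministic given seed."""
    rng = np.random.default_rng(params.seed)
    cohorts: dict[str, SurvivalCohort] = {}
    for group, median in params.medians.items():
        scale = median / math.log(2) ** (1.0 / params.weibull_shape)
        t = scale * rng.weibull(params.weibull_shape, size=params.n_per_group)
        days = np.maximum(np.ceil(t).astype(int), 1)
        events = np.ones(params.n_per_group, dtype=int)
        n_cens = int(round(params.censoring_fraction * params.n_per_group))
        if n_cens:
            idx = rng.choice(params.n_per_group, size=n_cens, replace=False)
            for i in idx:
                # censor uniformly within the fly's (unobserved) lifespan
                days[i] = int(rng.integers(1, days[i] + 1))
                events[i] = 0
        cohorts[group] = SurvivalCohort(
            group=group, days=days.tolist(), events=events.tolist()
        )
    return cohorts


# --------------------------------------------------------------------------
# colocalization image pairs
# --------------------------------------------------------------------------

def simulate_coloc_pair(
    shape: tuple[int, int] = (256, 256),
    rho_target: float = 0.8,
    seed: int = 0,
    mean: float = 120.0,
    sd: float = 15.0,
    pixel_size: float = 0.2,
) -> tuple[ImageChannel, ImageChannel, RoiMask]:
    """Correlated nonnegative intensity fields with population correlation
    ``rho_target`` inside a full-frame mask.

    ``rho_target = ±1`` produces an exact affine copy/inversion of channel 1
    so the measured Pearson coefficient is exactly ±1.
    """
    if not -1 <= rho_target <= 1:
        raise ValueError("rho_target must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(shape)
    ch1 = mean + sd * z1
    if rho_target == 1.0:
        ch2 = ch1.copy()
    elif rho_target == -1.0:
        ch2 = 2 * mean - ch1
    else:
        z0 = rng.standard_normal(shape)
        z2 = rho_target * z1 + math.sqrt(1 - rho_target**2) * z0
        ch2 = mean + sd * z2
    ch1 = np.clip(ch1, 0.0, None)
    ch2 = np.clip(ch2, 0.0, None)
    mask = np.ones(shape, dtype=bool)
    return (
        ImageChannel(ch1, pixel_size=pixel_size, name="ch1"),
        ImageChannel(ch2, pixel_size=pixel_size, name="ch2"),
        RoiMask(mask, region_id="frame"),
    )


# --------------------------------------------------------------------------
# puncta images
# --------------------------------------------------------------------------

def simulate_puncta_image(
    shape: tuple[int, int] = (256, 256),
    puncta: list[tuple[tuple[float, float], float]] = (),
    pixel_size: float = 0.5,
    foreground: float = 200.0,
    background: float = 0.0,
    speckle_fraction: float = 0.001,
    speckle_value: float = 40.0,
    seed: int = 0,
    allow_overlap: bool = False,
) -> tuple[ImageChannel, PunctaSet]:
    """Rasterize disk-shaped puncta over a dark, sparsely speckled background.

    ``puncta`` lists ((row, col) centre in pixels, radius in μm).  Disks are
    drawn at saturating ``foreground`` intensity; the background is
    ``background`` plus isolated single-pixel speckles (fraction
    ``speckle_fraction`` at ``speckle_value``) emulating shot noise without
    creating connected structures.  Ground truth is returned as a
    :class:`PunctaSet` with exact pixel areas and the implied equivalent
    diameters.
    """
    rng = np.random.default_rng(seed)
    img = np.full(shape, float(background))
    n_speckle = int(round(speckle_fraction * img.size))
    if n_speckle:
        idx = rng.choice(img.size, size=n_speckle, replace=False)
        img.flat[idx] = speckle_value

    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    truth: list[Punctum] = []
    covered = np.zeros(shape, dtype=bool)
    for i, ((r0, c0), rad_um) in enumerate(puncta, start=1):
        rad_px = rad_um / pixel_size
        if not (0 <= r0 < shape[0] and 0 <= c0 < shape[1]):
            raise ValueError(f"punctum {i} centre outside frame")
        if (
            r0 - rad_px < -0.5
            or r0 + rad_px > shape[0] - 0.5
            or c0 - rad_px < -0.5
            or c0 + rad_px > shape[1] - 0.5
        ):
            raise ValueError(f"punctum {i} extends outside frame")
        disk = (rows - r0) ** 2 + (cols - c0) ** 2 <= rad_px**2
        if not allow_overlap and np.any(disk & covered):
            raise ValueError(f"punctum {i} overlaps an earlier punctum")
        covered |= disk
        img[disk] = foreground
        area_px = int(disk.sum())
        area_um2 = area_px * pixel_size**2
        cr, cc = rows[disk].mean(), cols[disk].mean()
        truth.append(
            Punctum(
                label=i,
                area_px=area_px,
                equivalent_diameter_um=2.0 * math.sqrt(area_um2 / math.pi),
                centroid=(float(cr), float(cc)),
            )
        )
    channel = ImageChannel(img, pixel_size=pixel_size, name="puncta")
    return channel, PunctaSet(puncta=truth, source_region="synthetic")


# --------------------------------------------------------------------------
# bouton graphs
# --------------------------------------------------------------------------

@dataclass
class SimulatedBoutons:
    graph: BoutonGraph
    true_labels: dict[str, str]


def simulate_boutons(
    chain_lengths: list[int],
    n_satellites: int = 0,
    seed: int = 0,
    nmj_id: str = "nmj",
) -> SimulatedBoutons:
    """Bouton chains with side sprouts and exact ground-truth labels.

    Each entry of ``chain_lengths`` becomes a run of consecutive boutons on
    its own branch (length ≥ 2 → all mature; length 1 → satellite).
    ``n_satellites`` sprouting boutons are attached to random mature
    boutons when any exist, otherwise to random branches.
    """
    if any(c < 1 for c in chain_lengths):
        raise ValueError("chain lengths must be >= 1")
    rng = np.random.default_rng(seed)
    boutons: list[Bouton] = []
    truth: dict[str, str] = {}
    mature_ids: list[str] = []
    branch_names: list[str] = []
    bid = 0
    for ci, clen in enumerate(chain_lengths):
        branch = f"b{ci}"
        branch_names.append(branch)
        start = int(rng.integers(0, 5))
        for j in range(clen):
            name = f"n{bid}"
            boutons.append(Bouton(id=name, branch=branch, position=start + j))
            truth[name] = "mature" if clen >= 2 else "satellite"
            if clen >= 2:
                mature_ids.append(name)
            bid += 1
    for _ in range(n_satellites):
        name = f"n{bid}"
        if mature_ids:
            target = mature_ids[int(rng.integers(0, len(mature_ids)))]
        else:
            target = branch_names[int(rng.integers(0, len(branch_names)))]
        boutons.append(Bouton(id=name, sprout_of=target))
        truth[name] = "satellite"
        bid += 1
    return SimulatedBoutons(
        graph=BoutonGraph(nmj_id=nmj_id, boutons=boutons), true_labels=truth
    )


# --------------------------------------------------------------------------
# generic random valid trees (for property/oracle testing)
# --------------------------------------------------------------------------

def random_tree(
    n_nodes: int = 30,
    spread: float = 20.0,
    seed: int = 0,
) -> NeuronTree:
    """A random valid tree with arbitrary (non-radial) geometry.

    Node i attaches to a uniformly chosen earlier node, with a random 3D
    displacement; useful for exercising the geometry code on re-entrant
    segments that the radial growth model never produces.
    """
    if n_nodes < 1:
        raise ValueError("need at least one node")
    rng = np.random.default_rng(seed)
    nodes = [NeuronNode(1, 1, 0.0, 0.0, 0.0, 1.0, -1)]
    coords = [np.zeros(3)]
    for i in range(2, n_nodes + 1):
        parent_idx = int(rng.integers(0, len(nodes)))
        step = rng.normal(0.0, spread / math.sqrt(n_nodes), size=3)
        pos = coords[parent_idx] + step
        coords.append(pos)
        nodes.append(
            NeuronNode(
                i, 3, float(pos[0]), float(pos[1]), float(pos[2]), 0.5,
                nodes[parent_idx].id,
            )
        )
    return NeuronTree(nodes)
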