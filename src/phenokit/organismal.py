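"""Fly organismal phenotype statistics.

Three assay families:

* **Climbing (negative geotaxis)** — flies tapped to the bottom of a 15 cm
  graduated vial climb upward; the position at the 5 s video frame gives a
  per-fly vertical displacement and velocity.  Groups are compared with an
  unpaired Welch t-test.
* **NMJ boutons** — synaptic boutons along a branch are classified as
  *mature* when part of a chain of two or more consecutive boutons and
  *satellite* when single (an isolated on-branch bouton, or a bouton
  sprouting off a mature bouton or branch).
* **Longevity** — deaths scored daily (integer lifespans, ties expected);
  median lifespan via the Kaplan–Meier product-limit estimator, curves
  compared by the log-rank (Mantel–Cox) test, and a *rescue* call defined
  as a strictly >5% increase in median lifespan together with log-rank
  p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

VIAL_LENGTH_CM = 15.0
CLIMB_TIME_S = 5.0
RESCUE_MEDIAN_INCREASE = 0.05
RESCUE_ALPHA = 0.05


# --------------------------------------------------------------------------
# climbing
# --------------------------------------------------------------------------

@dataclass
class ClimbRecord:
    fly_id: str
    group: str
    start_cm: float
    pos5s_cm: float
    vial_length_cm: float = VIAL_LENGTH_CM

    def __post_init__(self) -> None:
        for name, v in (("start", self.start_cm), ("position at 5 s", self.pos5s_cm)):
            if not 0 <= v <= self.vial_length_cm:
                raise ValueError(
                    f"fly {self.fly_id}: {name} {v} cm outside vial "
                    f"[0, {self.vial_length_cm}]"
                )


@dataclass
class ClimbResult:
    fly_ids: list[str]
    groups: list[str]
    displacements_cm: list[float]
    velocities_cm_s: list[float]
    group_mean_velocity: dict[str, float]
    group_sem_velocity: dict[str, float]


def pixels_to_cm(
    positions_px: Sequence[float],
    vial_length_px: float,
    vial_length_cm: float = VIAL_LENGTH_CM,
) -> list[float]:
    """Convert pixel positions along the vial axis to cm using the 15 cm vial."""
    if vial_length_px <= 0:
        raise ValueError("vial_length_px must be positive")
    scale = vial_length_cm / vial_length_px
    return [float(p) * scale for p in positions_px]


def climbing_velocity(records: list[ClimbRecord]) -> ClimbResult:
    """Per-fly vertical displacement and velocity plus per-group summary.

    displacement = position(5 s) − start; velocity = displacement / 5 s.
    Negative values are permitted (a fly that fell).
    """
    if not records:
        raise ValueError("no climbing records")
    disp = [r.pos5s_cm - r.start_cm for r in records]
    vel = [d / CLIMB_TIME_S for d in disp]
    groups = sorted({r.group for r in records})
    by_group = {
        g: [v for r, v in zip(records, vel) if r.group == g] for g in groups
    }
    return ClimbResult(
        fly_ids=[r.fly_id for r in records],
        groups=[r.group for r in records],
        displacements_cm=disp,
        velocities_cm_s=vel,
        group_mean_velocity={g: float(np.mean(v)) for g, v in by_group.items()},
        group_sem_velocity={
            g: float(stats.sem(v)) if len(v) > 1 else float("nan")
            for g, v in by_group.items()
        },
    )


def compare_climbing(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Unpaired t-test with Welch's correction (Satterthwaite df).

    Returns (t statistic, p-value); reporting only.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(
        np.asarray(group_a, float), np.asarray(group_b, float), equal_var=False
    )
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# NMJ boutons
# --------------------------------------------------------------------------

@dataclass
class Bouton:
    """One synaptic bouton: either on-branch at an integer chain position,
    or a sprout off another bouton/branch."""

    id: str
    branch: str | None = None
    position: int | None = None
    sprout_of: str | None = None

    def __post_init__(self) -> None:
        on_branch = self.branch is not None and self.position is not None
        sprout = self.sprout_of is not None
        if on_branch == sprout:
            raise ValueError(
                f"bouton {self.id}: must be either on-branch (branch+position) "
                "or a sprout (sprout_of), not both/neither"
            )


@dataclass
class BoutonGraph:
    nmj_id: str
    boutons: list[Bouton] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen_pos: set[tuple[str, int]] = set()
        ids = {b.id for b in self.boutons}
        branches = {b.branch for b in self.boutons if b.branch is not None}
        for b in self.boutons:
            if b.branch is not None:
                key = (b.branch, b.position)
                if key in seen_pos:
                    raise ValueError(
                        f"NMJ {self.nmj_id}: duplicate position {b.position} "
                        f"on branch {b.branch}"
                    )
                seen_pos.add(key)
        for b in self.boutons:
            if b.sprout_of is not None and b.sprout_of not in ids | branches:
                raise ValueError(
                    f"NMJ {self.nmj_id}: bouton {b.id} sprouts off unknown "
                    f"target {b.sprout_of!r}"
                )


@dataclass
class BoutonClassification:
    labels: dict[str, str]  # bouton id -> "mature" | "satellite"
    n_mature: int
    n_satellite: int
    nmj_id: str


def classify_boutons(graph: BoutonGraph) -> BoutonClassification:
    """Label each bouton mature or satellite.

    Chains are maximal runs of consecutive on-branch position indices on a
    branch.  Boutons in a chain of length ≥ 2 are mature; an isolated
    on-branch bouton (run length 1) and every sprout are satellites.
    """
    labels: dict[str, str] = {}
    by_branch: dict[str, list[Bouton]] = {}
    for b in graph.boutons:
        if b.branch is not None:
            by_branch.setdefault(b.branch, []).append(b)
        else:
            labels[b.id] = "satellite"
    for members in by_branch.values():
        members.sort(key=lambda b: b.position)
        run: list[Bouton] = []
        prev_pos: int | None = None
        for b in members + [None]:
            if b is not None and (prev_pos is None or b.position == prev_pos + 1):
                run.append(b)
            else:
                lab = "mature" if len(run) >= 2 else "satellite"
                for r in run:
                    labels[r.id] = lab
                run = [b] if b is not None else []
            prev_pos = b.position if b is not None else None
    n_mature = sum(1 for v in labels.values() if v == "mature")
    return BoutonClassification(
        labels=labels,
        n_mature=n_mature,
        n_satellite=len(labels) - n_mature,
        nmj_id=graph.nmj_id,
    )


# --------------------------------------------------------------------------
# longevity
# --------------------------------------------------------------------------

@dataclass
class SurvivalCohort:
    """Per-fly lifespan records for one group.

    ``days`` are integer survival times (deaths scored daily); ``events``
    is 1 for an observed death and 0 for right-censoring.
    """

    group: str
    days: list[int]
    events: list[int]
    sex: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.days) != len(self.events):
            raise ValueError("days and events must have equal length")
        if any(d < 0 for d in self.days):
            raise ValueError("days must be nonnegative")
        if any(e not in (0, 1) for e in self.events):
            raise ValueError("events must be 0 (censored) or 1 (death)")

    @property
    def n(self) -> int:
        return len(self.days)

    @property
    def n_events(self) -> int:
        return int(sum(self.events))


def km_median(cohort: SurvivalCohort) -> float:
    """Kaplan–Meier median lifespan: smallest t with S(t) ≤ 0.5.

    Censoring is handled by the product-limit estimator.  Raises if the
    survival curve never reaches 0.5 (median undefined).
    """
    if cohort.n_events < 1:
        raise ValueError("cohort has no death events")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.days, event_observed=cohort.events)
    med = float(kmf.median_survival_time_)
    if not np.isfinite(med):
        raise ValueError("median undefined: survival never reaches 0.5")
    return med


def logrank(cohort_a: SurvivalCohort, cohort_b: SurvivalCohort) -> tuple[float, float]:
    """Log-rank (Mantel–Cox) test, 1 df, with exact hypergeometric tie handling.

    Returns (chi-square statistic, p-value); symmetric in group order.
    """
    if cohort_a.n_events < 1 and cohort_b.n_events < 1:
        raise ValueError("no death events in either cohort")
    res = logrank_test(
        cohort_a.days, cohort_b.days,
        event_observed_A=cohort_a.events, event_observed_B=cohort_b.events,
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class RescueResult:
    rescued: bool
    median_control: float
    median_treatment: float
    median_increase_pct: float
    logrank_statistic: float
    p_value: float


def rescue_call(
    control: SurvivalCohort,
    treatment: SurvivalCohort,
    min_increase: float = RESCUE_MEDIAN_INCREASE,
    alpha: float = RESCUE_ALPHA,
) -> RescueResult:
    """Longevity rescue criterion.

    rescued ⇔ (median_treatment − median_control) / median_control strictly
    exceeds ``min_increase`` (default 5%) AND the log-rank p-value is below
    ``alpha`` (default 0.05).  Undefined medians propagate as errors.
    """
    med_c = km_median(control)
    med_t = km_median(treatment)
    stat, p = logrank(control, treatment)
    increase = (med_t - med_c) / med_c
    return RescueResult(
        rescued=bool(increase > min_increase and p < alpha),
        median_control=med_c,
        median_treatment=med_t,
        median_increase_pct=100.0 * increase,
        logrank_statistic=stat,
        p_value=p,
    )
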