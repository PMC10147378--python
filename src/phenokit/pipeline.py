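"""End-to-end pipeline orchestration with a plain-text config.

A :class:`RunConfig` (TOML on disk) selects stages and carries every
analysis parameter with the standard defaults: 1 μm Sholl step, R² > 0.8
per-neuron gate, 10–90 pooled percentile filter, 5/10 μm size cutoffs, 5%
median-lifespan rescue margin, α = 0.05.  ``run_pipeline`` executes the
selected stages in dependency order and writes a diffable report bundle
(CSV tables + summary JSON + log).  Identical config and seed produce
byte-identical outputs: nothing in the bundle depends on wall-clock time.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from phenokit import morphometry, organismal, sholl, simulate, swc
from phenokit.imaging import detect_puncta, pearson_colocalization, size_frequency

KNOWN_STAGES = (
    "simulate_neurons",
    "sholl",
    "morph",
    "simulate_survival",
    "survival",
    "climb",
    "nmj",
    "coloc",
    "puncta",
)


@dataclass
class RunConfig:
    """Resolved pipeline configuration; defaults are the standard analysis
    parameters (see module docstring)."""

    stages: list[str] = field(default_factory=lambda: ["simulate_neurons", "sholl"])
    seed: int = 0
    out_dir: str = "phenokit_out"

    # sholl / morphometry
    step_um: float = 1.0
    sholl_mode: str = "intersections"
    r2_gate: float = 0.8
    pct_low: float = 10.0
    pct_high: float = 90.0

    # imaging
    threshold: str | float = "otsu"
    min_area_px: int = 4
    size_cutoffs_um: list[float] = field(default_factory=lambda: [5.0, 10.0])
    rho_target: float = 0.8

    # survival
    rescue_min_increase: float = 0.05
    alpha: float = 0.05

    # simulation parameters
    n_neurons: int = 30
    k0_a: float = 0.08
    k0_b: float = 0.16
    r_max_um: float = 40.0
    n_flies: int = 100
    median_control_days: float = 20.0
    median_treatment_days: float = 26.0
    censoring_fraction: float = 0.05

    # input manifests (optional; simulation stages fill these in)
    swc_files: dict[str, list[str]] = field(default_factory=dict)
    climbing_csv: str | None = None
    survival_csv: str | None = None
    boutons_csv: str | None = None

    def validate(self) -> None:
        for st in self.stages:
            if st not in KNOWN_STAGES:
                raise ValueError(f"unknown stage {st!r}; known: {KNOWN_STAGES}")
        if self.step_um <= 0:
            raise ValueError("step_um must be positive")
        if not 0 <= self.pct_low < self.pct_high <= 100:
            raise ValueError("percentiles must satisfy 0 <= low < high <= 100")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.r2_gate < 1:
            raise ValueError("r2_gate must be in (0, 1)")
        if self.sholl_mode not in ("intersections", "branch_points"):
            raise ValueError(f"unknown sholl mode {self.sholl_mode!r}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_toml(self, path: str | Path) -> Path:
        path = Path(path)
        lines = []
        for key, val in self.to_dict().items():
            if val is None:
                continue
            lines.append(f"{key} = {_toml_value(val)}")
        path.write_text("\n".join(lines) + "\n")
        return path


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, list):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    if isinstance(v, dict):
        return (
            "{" + ", ".join(f"{json.dumps(k)} = {_toml_value(x)}" for k, x in v.items()) + "}"
        )
    raise TypeError(f"cannot serialize {type(v)}")


# --------------------------------------------------------------------------
# CSV schemas
# --------------------------------------------------------------------------

def load_climbing_csv(path: str | Path) -> list[organismal.ClimbRecord]:
    """Columns: fly, group, start, pos5s [, vial_length]."""
    df = pd.read_csv(path)
    vial = "vial_length" in df.columns
    return [
        organismal.ClimbRecord(
            fly_id=str(r.fly),
            group=str(r.group),
            start_cm=float(r.start),
            pos5s_cm=float(r.pos5s),
            vial_length_cm=float(r.vial_length) if vial else organismal.VIAL_LENGTH_CM,
        )
        for r in df.itertuples()
    ]


def load_survival_csv(path: str | Path) -> dict[str, organismal.SurvivalCohort]:
    """Columns: fly, group, sex, day, event (1 = death, 0 = censored)."""
    df = pd.read_csv(path)
    cohorts = {}
    for group, sub in df.groupby("group", sort=True):
        cohorts[str(group)] = organismal.SurvivalCohort(
            group=str(group),
            days=[int(d) for d in sub["day"]],
            events=[int(e) for e in sub["event"]],
            sex=[str(s) for s in sub["sex"]] if "sex" in sub.columns else None,
        )
    return cohorts


def load_boutons_csv(path: str | Path) -> list[organismal.BoutonGraph]:
    """Columns: nmj, bouton, branch, position, sprout_of (branch+position or
    sprout_of per row)."""
    df = pd.read_csv(path)
    graphs = []
    for nmj, sub in df.groupby("nmj", sort=True):
        boutons = []
        for r in sub.itertuples():
            sprout = getattr(r, "sprout_of", None)
            sprout = None if pd.isna(sprout) else str(sprout)
            branch = None if pd.isna(r.branch) else str(r.branch)
            position = None if pd.isna(r.position) else int(r.position)
            boutons.append(
                organismal.Bouton(
                    id=str(r.bouton), branch=branch, position=position,
                    sprout_of=sprout,
                )
            )
        graphs.append(organismal.BoutonGraph(nmj_id=str(nmj), boutons=boutons))
    return graphs


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

class PipelineError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> dict:
    """Run the selected stages in dependency order; return the summary dict.

    The report bundle under ``config.out_dir`` contains per-stage CSV
    tables, ``summary.json`` (resolved config, package version, key
    results) and ``run.log``.  A stage error aborts the run with
    :class:`PipelineError` after logging the cause.
    """
    from phenokit import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    summary: dict = {"phenokit_version": __version__, "config": config.to_dict(),
                     "stages": {}}

    def log(msg: str) -> None:
        log_lines.append(msg)

    # run in canonical dependency order regardless of listing order
    ordered = [s for s in KNOWN_STAGES if s in config.stages]
    try:
        for stage in ordered:
            log(f"stage {stage}: start")
            result = _STAGE_FUNCS[stage](config, out, log)
            summary["stages"][stage] = result
            log(f"stage {stage}: done")
    except Exception as exc:
        log(f"ERROR: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise PipelineError(str(exc)) from exc

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _stage_simulate_neurons(config: RunConfig, out: Path, log) -> dict:
    pa = simulate.NeuronSimParams(
        k0=config.k0_a, r_max=config.r_max_um, step=config.step_um,
        seed=config.seed,
    )
    pb = dataclasses.replace(pa, k0=config.k0_b, r_max=config.r_max_um * 0.75)
    pop = simulate.simulate_population(config.n_neurons, pa, pb)
    manifests: dict[str, list[str]] = {}
    for group, trees in (("A", pop.trees_a), ("B", pop.trees_b)):
        gdir = out / "swc" / group
        gdir.mkdir(parents=True, exist_ok=True)
        files = []
        for i, tree in enumerate(trees):
            path = gdir / f"neuron_{i:03d}.swc"
            swc.write_swc(tree, path)
            files.append(str(path))
        manifests[group] = files
    config.swc_files = manifests
    log(f"simulated {config.n_neurons} neurons per group "
        f"(k0 A={config.k0_a}, B={config.k0_b})")
    return {"n_per_group": config.n_neurons,
            "k0": {"A": config.k0_a, "B": config.k0_b}}


def _require_swc(config: RunConfig) -> dict[str, list[str]]:
    if not config.swc_files:
        raise ValueError(
            "no SWC inputs: provide swc_files or run simulate_neurons first"
        )
    for group, files in config.swc_files.items():
        for f in files:
            if not Path(f).exists():
                raise FileNotFoundError(f"missing input {f} (group {group})")
    return config.swc_files


def _stage_sholl(config: RunConfig, out: Path, log) -> dict:
    manifests = _require_swc(config)
    fit_rows, profile_rows, pooled_rows = [], [], []
    result: dict = {}
    for group, files in sorted(manifests.items()):
        profiles = []
        for f in files:
            tree = swc.read_swc(f)
            name = Path(f).stem
            prof, fit = sholl.fit_neuron(
                tree, step=config.step_um, mode=config.sholl_mode,
                r2_gate=config.r2_gate, neuron_id=name,
            )
            profiles.append(prof)
            for r, n, in zip(prof.radii, prof.counts):
                y = float(np.log10(n / (np.pi * r**2))) if n > 0 else np.nan
                profile_rows.append(
                    {"group": group, "neuron": name, "radius_um": r,
                     "count": int(n), "log10_density": y}
                )
            fit_rows.append(
                {"group": group, "neuron": name, "k_per_um": fit.k, "m": fit.m,
                 "r_squared": fit.r_squared, "n_points": fit.n_points,
                 "included": fit.included}
            )
        pooled = sholl.pooled_decay(
            profiles, pct_low=config.pct_low, pct_high=config.pct_high,
            genotype=group,
        )
        pooled_rows.append(
            {"group": group, "k_pooled_per_um": pooled.k_pooled,
             "m_pooled": pooled.m_pooled,
             "r_squared_pooled": pooled.r_squared_pooled,
             "n_neurons": pooled.n_neurons,
             "n_retained_radii": int(pooled.retained_radii.size)}
        )
        result[group] = {"k_pooled_per_um": pooled.k_pooled,
                         "n_neurons": pooled.n_neurons}
        log(f"sholl[{group}]: pooled k = {pooled.k_pooled:.4f}/um "
            f"({config.sholl_mode} mode)")
    _write_csv(pd.DataFrame(profile_rows), out / "sholl_profiles.csv")
    _write_csv(pd.DataFrame(fit_rows), out / "sholl_fits.csv")
    _write_csv(pd.DataFrame(pooled_rows), out / "sholl_pooled.csv")
    return result


def _stage_morph(config: RunConfig, out: Path, log) -> dict:
    manifests = _require_swc(config)
    rows = []
    by_group: dict[str, list[float]] = {}
    for group, files in sorted(manifests.items()):
        for f in files:
            tree = swc.read_swc(f)
            m = morphometry.summarize_morphometry(tree)
            rows.append(
                {"group": group, "neuron": Path(f).stem,
                 "total_path_length_um": m.total_path_length,
                 "primary_neurite_count": m.primary_neurite_count,
                 "mean_primary_neurite_length_um":
                     float(np.mean(m.primary_neurite_lengths))
                     if m.primary_neurite_lengths else 0.0,
                 "mean_terminal_neurite_length_um":
                     float(np.mean(m.terminal_neurite_lengths))
                     if m.terminal_neurite_lengths else 0.0,
                 "branch_point_count": m.branch_point_count,
                 "terminal_count": m.terminal_count}
            )
            by_group.setdefault(group, []).append(m.total_path_length)
    _write_csv(pd.DataFrame(rows), out / "morphometry.csv")
    result: dict = {g: {"mean_total_path_length_um": float(np.mean(v)), "n": len(v)}
                    for g, v in by_group.items()}
    if len(by_group) >= 2 and all(len(v) >= 2 for v in by_group.values()):
        cmp = morphometry.compare_groups(by_group)
        result["anova"] = {"F": cmp.f_statistic, "p": cmp.p_value}
        log(f"morph: ANOVA on total path length F={cmp.f_statistic:.3f} "
            f"p={cmp.p_value:.3g}")
    return result


def _stage_simulate_survival(config: RunConfig, out: Path, log) -> dict:
    params = simulate.CohortSimParams(
        n_per_group=config.n_flies,
        medians={"control": config.median_control_days,
                 "treatment": config.median_treatment_days},
        censoring_fraction=config.censoring_fraction,
        seed=config.seed + 1,
    )
    cohorts = simulate.simulate_survival(params)
    rows = []
    for group, cohort in sorted(cohorts.items()):
        for i, (d, e) in enumerate(zip(cohort.days, cohort.events)):
            rows.append({"fly": f"{group}_{i}", "group": group, "sex": "mixed",
                         "day": d, "event": e})
    path = out / "survival_simulated.csv"
    _write_csv(pd.DataFrame(rows), path)
    config.survival_csv = str(path)
    log(f"simulated survival cohorts n={config.n_flies}/group")
    return {"n_per_group": config.n_flies,
            "target_medians": {"control": config.median_control_days,
                               "treatment": config.median_treatment_days}}


def _stage_survival(config: RunConfig, out: Path, log) -> dict:
    if config.survival_csv is None:
        raise ValueError("no survival input: set survival_csv or run "
                         "simulate_survival first")
    cohorts = load_survival_csv(config.survival_csv)
    rows = []
    for group, cohort in sorted(cohorts.items()):
        try:
            med = organismal.km_median(cohort)
        except ValueError:
            med = float("nan")
        rows.append({"group": group, "n": cohort.n, "events": cohort.n_events,
                     "km_median_days": med})
    _write_csv(pd.DataFrame(rows), out / "survival_medians.csv")
    result: dict = {r["group"]: r["km_median_days"] for r in rows}
    if {"control", "treatment"} <= set(cohorts):
        rc = organismal.rescue_call(
            cohorts["control"], cohorts["treatment"],
            min_increase=config.rescue_min_increase, alpha=config.alpha,
        )
        result["rescue"] = {
            "rescued": rc.rescued,
            "median_increase_pct": rc.median_increase_pct,
            "logrank_statistic": rc.logrank_statistic,
            "p_value": rc.p_value,
        }
        with open(out / "rescue.json", "w") as fh:
            json.dump(result["rescue"], fh, indent=2, sort_keys=True)
            fh.write("\n")
        log(f"survival: rescue={rc.rescued} "
            f"(+{rc.median_increase_pct:.1f}% median, p={rc.p_value:.3g})")
    return result


def _stage_climb(config: RunConfig, out: Path, log) -> dict:
    if config.climbing_csv is None:
        raise ValueError("no climbing input: set climbing_csv")
    records = load_climbing_csv(config.climbing_csv)
    res = organismal.climbing_velocity(records)
    df = pd.DataFrame(
        {"fly": res.fly_ids, "group": res.groups,
         "displacement_cm": res.displacements_cm,
         "velocity_cm_s": res.velocities_cm_s}
    )
    _write_csv(df, out / "climbing.csv")
    result: dict = {"group_mean_velocity_cm_s": res.group_mean_velocity}
    groups = sorted(res.group_mean_velocity)
    if len(groups) == 2:
        va = [v for g, v in zip(res.groups, res.velocities_cm_s) if g == groups[0]]
        vb = [v for g, v in zip(res.groups, res.velocities_cm_s) if g == groups[1]]
        if len(va) >= 2 and len(vb) >= 2:
            t, p = organismal.compare_climbing(va, vb)
            result["welch"] = {"t": t, "p": p}
            log(f"climb: Welch t={t:.3f} p={p:.3g}")
    return result


def _stage_nmj(config: RunConfig, out: Path, log) -> dict:
    if config.boutons_csv is None:
        raise ValueError("no bouton input: set boutons_csv")
    graphs = load_boutons_csv(config.boutons_csv)
    rows = []
    for g in graphs:
        cls = organismal.classify_boutons(g)
        rows.append({"nmj": g.nmj_id, "mature": cls.n_mature,
                     "satellite": cls.n_satellite,
                     "total": cls.n_mature + cls.n_satellite})
    _write_csv(pd.DataFrame(rows), out / "nmj_boutons.csv")
    return {"n_nmjs": len(rows),
            "total_mature": int(sum(r["mature"] for r in rows)),
            "total_satellite": int(sum(r["satellite"] for r in rows))}


def _stage_coloc(config: RunConfig, out: Path, log) -> dict:
    ch1, ch2, roi = simulate.simulate_coloc_pair(
        rho_target=config.rho_target, seed=config.seed + 2
    )
    res = pearson_colocalization(ch1, ch2, roi, thresholds=(0.0, 0.0))
    _write_csv(
        pd.DataFrame([{"region": roi.region_id, "rho": res.rho,
                       "n_pixels": res.n_pixels,
                       "rho_target": config.rho_target}]),
        out / "colocalization.csv",
    )
    log(f"coloc: rho={res.rho:.4f} (target {config.rho_target})")
    return {"rho": res.rho, "rho_target": config.rho_target,
            "n_pixels": res.n_pixels}


def _stage_puncta(config: RunConfig, out: Path, log) -> dict:
    centers = [((40.0, 40.0), 2.0), ((40.0, 140.0), 4.0), ((140.0, 40.0), 6.0),
               ((140.0, 140.0), 3.0), ((200.0, 200.0), 5.0)]
    ch, truth = simulate.simulate_puncta_image(
        puncta=centers, seed=config.seed + 3
    )
    detected = detect_puncta(ch, threshold=config.threshold,
                             min_area=config.min_area_px)
    sf = size_frequency(detected, cutoffs=config.size_cutoffs_um)
    rows = [
        {"label": p.label, "area_px": p.area_px,
         "equivalent_diameter_um": p.equivalent_diameter_um,
         "centroid_row": p.centroid[0], "centroid_col": p.centroid[1]}
        for p in detected.puncta
    ]
    _write_csv(pd.DataFrame(rows), out / "puncta.csv")
    log(f"puncta: detected {len(detected)} (truth {len(truth)})")
    return {"n_detected": len(detected), "n_true": len(truth),
            "fraction_above_cutoff": {str(c): f for c, f in sf.fractions.items()},
            "mean_diameter_um": sf.mean_diameter_um}


_STAGE_FUNCS = {
    "simulate_neurons": _stage_simulate_neurons,
    "sholl": _stage_sholl,
    "morph": _stage_morph,
    "simulate_survival": _stage_simulate_survival,
    "survival": _stage_survival,
    "climb": _stage_climb,
    "nmj": _stage_nmj,
    "coloc": _stage_coloc,
    "puncta": _stage_puncta,
}
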