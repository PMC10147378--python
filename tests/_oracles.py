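"""Independent oracles used to cross-check the implementation.

These deliberately use brute force, dense sampling, closed forms, or
permutation — never the code paths they verify.
"""

from __future__ import annotations

import numpy as np


def dense_sholl_counts(tree, radii, resolution: float = 0.01) -> np.ndarray:
    """Count circle crossings by walking each edge at fixed arc resolution.

    Samples every edge at `resolution` μm (2D, z dropped) and counts
    transitions of the indicator (distance >= r) between consecutive
    samples, per radius.
    """
    root = tree.root
    center = np.array([root.x, root.y])
    radii = np.asarray(radii, dtype=float)
    counts = np.zeros(radii.size, dtype=int)
    for p, c in tree.edges():
        a = np.array([p.x, p.y])
        b = np.array([c.x, c.y])
        length = float(np.linalg.norm(b - a))
        n = max(int(np.ceil(length / resolution)), 1)
        t = np.linspace(0.0, 1.0, n + 1)
        pts = a[None, :] + t[:, None] * (b - a)[None, :]
        d = np.linalg.norm(pts - center[None, :], axis=1)
        above = d[None, :] >= radii[:, None]
        counts += np.sum(above[:, 1:] != above[:, :-1], axis=1)
    return counts


def ols_line(x, y) -> tuple[float, float, float]:
    """Closed-form least squares: slope, intercept, R² via normal equations."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - sy / n) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return float(slope), float(intercept), r2


def anova_oneway(groups) -> tuple[float, float]:
    """Textbook one-way ANOVA F and p from sums of squares."""
    from scipy.stats import f as f_dist

    groups = [np.asarray(g, float) for g in groups]
    alldata = np.concatenate(groups)
    grand = alldata.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = alldata.size - len(groups)
    f_stat = (ss_between / df_b) / (ss_within / df_w)
    return float(f_stat), float(f_dist.sf(f_stat, df_b, df_w))


def welch_t(a, b) -> tuple[float, float]:
    """Welch t statistic and p with Satterthwaite degrees of freedom."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t_stat = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float(t_stat), float(2 * t_dist.sf(abs(t_stat), df))


def logrank_oe(days_a, events_a, days_b, events_b) -> float:
    """Observed−expected log-rank chi-square with hypergeometric tie variance."""
    days_a = np.asarray(days_a)
    days_b = np.asarray(days_b)
    events_a = np.asarray(events_a)
    events_b = np.asarray(events_b)
    times = np.unique(np.concatenate([days_a[events_a == 1], days_b[events_b == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n_a = int(np.sum(days_a >= t))
        n_b = int(np.sum(days_b >= t))
        d_a = int(np.sum((days_a == t) & (events_a == 1)))
        d_b = int(np.sum((days_b == t) & (events_b == 1)))
        n = n_a + n_b
        d = d_a + d_b
        if n < 1 or d == 0:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float(o_minus_e**2 / var)


def logrank_permutation_p(days_a, events_a, days_b, events_b,
                          n_perm: int = 10_000, seed: int = 0) -> float:
    """Permutation p-value for the log-rank statistic (label shuffling)."""
    rng = np.random.default_rng(seed)
    days = np.concatenate([days_a, days_b])
    events = np.concatenate([events_a, events_b])
    n_a = len(days_a)
    observed = logrank_oe(days_a, events_a, days_b, events_b)
    count = 0
    idx = np.arange(days.size)
    for _ in range(n_perm):
        rng.shuffle(idx)
        ia, ib = idx[:n_a], idx[n_a:]
        stat = logrank_oe(days[ia], events[ia], days[ib], events[ib])
        if stat >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def km_survival_curve(days, events):
    """Product-limit estimate computed step by step: [(t, S(t)), ...]."""
    days = np.asarray(days)
    events = np.asarray(events)
    s = 1.0
    curve = []
    for t in np.unique(days[events == 1]):
        at_risk = int(np.sum(days >= t))
        d = int(np.sum((days == t) & (events == 1)))
        s *= 1.0 - d / at_risk
        curve.append((int(t), s))
    return curve


def bouton_labels_by_adjacency(graph) -> dict[str, str]:
    """Alternative bouton classification: an on-branch bouton is mature iff
    an adjacent position (±1) on the same branch is occupied; sprouts and
    isolated boutons are satellites."""
    occupied = {
        (b.branch, b.position) for b in graph.boutons if b.branch is not None
    }
    labels = {}
    for b in graph.boutons:
        if b.branch is None:
            labels[b.id] = "satellite"
        elif (b.branch, b.position - 1) in occupied or (
            b.branch, b.position + 1
        ) in occupied:
            labels[b.id] = "mature"
        else:
            labels[b.id] = "satellite"
    return labels
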