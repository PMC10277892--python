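"""Group-level inference: one-way ANOVA, Dunnett's many-to-one comparison,
Student's t-test, and four-parameter logistic (4PL) dose-response fitting.

Dunnett's procedure compares each treatment group against a single control
with family-wise error control. Adjusted p-values here come from seeded
Monte Carlo sampling of the joint null distribution of the correlated t
statistics (group means ~ normal, pooled variance ~ scaled chi-square),
which handles unbalanced group sizes exactly in distribution and reports a
Monte Carlo standard error alongside each adjusted p. With a single
treatment group the procedure reduces to the two-sided pooled t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .errors import InvalidParameterError, ValidationError

__all__ = [
    "GroupSummary",
    "DunnettComparison",
    "GroupComparison",
    "DoseResponseFit",
    "one_way_anova",
    "t_test",
    "dunnett",
    "fit_4pl",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """Figure-convention significance markers (ns, *, **, ***, ****)."""
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class DunnettComparison:
    label: str
    mean_diff: float
    t: float
    p_adjusted: float
    p_unadjusted: float
    mc_se: float
    stars: str


@dataclass(frozen=True)
class GroupComparison:
    summaries: List[GroupSummary]
    control: str
    f_statistic: float
    anova_p: float
    comparisons: List[DunnettComparison]
    alpha: float

    def comparison(self, label: str) -> DunnettComparison:
        for c in self.comparisons:
            if c.label == label:
                return c
        raise KeyError(label)


def _as_groups(groups: Mapping[str, Sequence[float]]) -> Dict[str, np.ndarray]:
    out = {}
    for label, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            raise InvalidParameterError(f"group {label!r} needs n >= 2 (got {arr.size})")
        out[str(label)] = arr
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> Tuple[float, float]:
    """One-way fixed-effects ANOVA from the between/within sum-of-squares
    decomposition.

    Degenerate conventions: identical data in every group (both sums of
    squares zero) gives ``(0.0, 1.0)``; zero within-group variance with
    distinct means gives ``(inf, 0.0)``.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise InvalidParameterError("ANOVA needs at least 2 groups")
    all_vals = np.concatenate(list(gs.values()))
    grand = all_vals.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in gs.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in gs.values())
    df_b = len(gs) - 1
    df_w = all_vals.size - len(gs)
    if ss_within == 0.0:
        return (0.0, 1.0) if ss_between == 0.0 else (float("inf"), 0.0)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def t_test(
    a: Sequence[float],
    b: Sequence[float],
    equal_var: bool = True,
) -> Tuple[float, float]:
    """Two-sided two-sample t-test (pooled by default, Welch by flag).

    Degenerate convention: zero variance in both groups gives ``(0, 1)``
    when the means are equal and ``(±inf, 0)`` otherwise.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("t_test needs n >= 2 in each group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def dunnett(
    groups: Mapping[str, Sequence[float]],
    control_label: str,
    alpha: float = 0.05,
    n_mc: int = 200_000,
    seed: int = 0,
) -> GroupComparison:
    """Dunnett's many-to-one comparison versus a named control.

    Each treatment's two-sided adjusted p is ``P(max_j |T*_j| >= |t_i|)``
    under the joint null, estimated by ``n_mc`` seeded Monte Carlo draws of
    the correlated t vector (exact in distribution for unbalanced sizes).
    The unadjusted p uses the same pooled-variance t statistic against a
    Student t reference.
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError("alpha must be in (0, 1)")
    gs = _as_groups(groups)
    if control_label not in gs:
        raise ValidationError(f"control group {control_label!r} not present in {sorted(gs)}")
    if len(gs) < 2:
        raise InvalidParameterError("dunnett needs a control and at least one treatment group")

    treat_labels = [lab for lab in gs if lab != control_label]
    y0 = gs[control_label]
    n0 = y0.size
    ns = np.array([gs[lab].size for lab in treat_labels])
    means = np.array([gs[lab].mean() for lab in treat_labels])
    k = len(treat_labels)

    n_total = n0 + int(ns.sum())
    df = n_total - (k + 1)
    pooled_ss = ((y0 - y0.mean()) ** 2).sum() + sum(
        ((gs[lab] - gs[lab].mean()) ** 2).sum() for lab in treat_labels
    )
    s2 = pooled_ss / df
    se = np.sqrt(s2 * (1.0 / ns + 1.0 / n0))

    if s2 == 0.0:
        t_obs = np.where(means == y0.mean(), 0.0, np.inf * np.sign(means - y0.mean()))
        p_adj = np.where(np.isinf(t_obs), 0.0, 1.0)
        p_un = p_adj.copy()
        mc_se = np.zeros(k)
    else:
        t_obs = (means - y0.mean()) / se
        rng = np.random.default_rng(seed)
        z0 = rng.standard_normal(n_mc) / np.sqrt(n0)
        zt = rng.standard_normal((n_mc, k)) / np.sqrt(ns)
        s_null = np.sqrt(rng.chisquare(df, n_mc) / df)
        t_null = (zt - z0[:, None]) / (s_null[:, None] * np.sqrt(1.0 / ns + 1.0 / n0))
        max_abs = np.abs(t_null).max(axis=1)
        p_adj = np.array([(max_abs >= abs(t)).mean() for t in t_obs])
        mc_se = np.sqrt(p_adj * (1.0 - p_adj) / n_mc)
        p_un = 2.0 * stats.t.sf(np.abs(t_obs), df)

    f_stat, anova_p = one_way_anova(gs)
    summaries = [
        GroupSummary(lab, gs[lab].size, float(gs[lab].mean()), float(gs[lab].std(ddof=1)))
        for lab in gs
    ]
    comparisons = [
        DunnettComparison(
            label=lab,
            mean_diff=float(means[i] - y0.mean()),
            t=float(t_obs[i]),
            p_adjusted=float(p_adj[i]),
            p_unadjusted=float(p_un[i]),
            mc_se=float(mc_se[i]),
            stars=significance_stars(float(p_adj[i])),
        )
        for i, lab in enumerate(treat_labels)
    ]
    return GroupComparison(
        summaries=summaries,
        control=control_label,
        f_statistic=f_stat,
        anova_p=anova_p,
        comparisons=comparisons,
        alpha=alpha,
    )


@dataclass(frozen=True)
class DoseResponseFit:
    ic50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool

    def predict(self, dose):
        dose = np.asarray(dose, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1.0 + (dose / self.ic50) ** self.hill)


def _4pl(d, top, bottom, log_ic50, hill):
    return bottom + (top - bottom) / (1.0 + (d / np.exp(log_ic50)) ** hill)


def fit_4pl(doses: Sequence[float], responses: Sequence[float]) -> DoseResponseFit:
    """Least-squares 4PL fit ``y = bottom + (top - bottom)/(1 + (d/IC50)^h)``.

    Initialization: top/bottom from the responses at the dose extremes,
    IC50 from the dose closest to half-response, Hill slope 1. IC50 is
    fitted on the log scale for stability. Non-convergence is flagged,
    never silent.
    """
    d = np.asarray(list(doses), dtype=float)
    y = np.asarray(list(responses), dtype=float)
    if d.shape != y.shape:
        raise InvalidParameterError("doses and responses must have equal length")
    if np.any(d <= 0):
        raise InvalidParameterError("doses must be > 0")
    if np.unique(d).size < 5:
        raise InvalidParameterError("fit_4pl needs at least 5 distinct doses")

    top0 = float(np.mean(y[d == d.min()]))
    bottom0 = float(np.mean(y[d == d.max()]))
    half = 0.5 * (top0 + bottom0)
    ic50_0 = float(d[np.argmin(np.abs(y - half))])
    p0 = (top0, bottom0, np.log(ic50_0), 1.0)

    # loose data-driven box keeps the optimizer out of degenerate plateaus
    span = float(y.max() - y.min()) or 1.0
    bounds = (
        [y.min() - span, y.min() - span, np.log(d.min()) - 3.0, -10.0],
        [y.max() + span, y.max() + span, np.log(d.max()) + 3.0, 10.0],
    )
    try:
        popt, _ = optimize.curve_fit(_4pl, d, y, p0=p0, maxfev=20_000, bounds=bounds)
        converged = bool(np.all(np.isfinite(popt)))
    except (RuntimeError, optimize.OptimizeWarning):
        return DoseResponseFit(
            ic50=float("nan"), hill=float("nan"), top=float("nan"),
            bottom=float("nan"), rss=float("nan"), converged=False,
        )
    top, bottom, log_ic50, hill = (float(v) for v in popt)
    rss = float(((y - _4pl(d, *popt)) ** 2).sum())
    return DoseResponseFit(
        ic50=float(np.exp(log_ic50)), hill=hill, top=top, bottom=bottom,
        rss=rss, converged=converged,
    )
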