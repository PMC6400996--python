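"""Group-level inference on the swing-averaged gait outcomes.

The analysis plan is the classical one for a randomized 2 (session: pre,
post) x 3 (training group) design with repeated measures on session:

* Lilliefors-corrected Kolmogorov-Smirnov normality screen per group and
  variable; parametric tests are retained unless a variable is non-normal in
  at least two groups.
* Baseline one-way ANOVA between groups at pre-test.
* Pooled dependent t-tests on gait speed per walking condition.
* Split-plot mixed ANOVA per outcome; when the session x group interaction
  is significant (p <= 0.05), post-hoc dependent t-tests within each group,
  Holm step-down corrected over the 3-group family.
* Effect sizes: Hedges-corrected d_unb (standardizer = SD of difference
  scores) with noncentral-t 95% CI; ANOVA effects converted to the d scale
  as d = 2*sqrt(F*df_num/df_den).
* JZS Bayes factors with a Cauchy(0, 0.707) prior on the standardized
  effect, integrated by adaptive quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import integrate, optimize
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .io_gait import CONDITIONS, GROUPS, OutcomeTable

__all__ = [
    "UCM_VARIABLES",
    "SECONDARY_VARIABLES",
    "TestResult",
    "AnovaResult",
    "InferenceReport",
    "ZeroVarianceError",
    "ks_normality",
    "oneway_anova",
    "paired_t",
    "independent_t",
    "mixed_anova_2x3",
    "holm_correct",
    "d_unbiased",
    "jzs_bf_paired",
    "jzs_bf_independent",
    "percent_change",
    "run_full_inference",
]

UCM_VARIABLES: tuple[str, ...] = ("dvz", "v_ucm", "v_ort", "v_tot")
SECONDARY_VARIABLES: tuple[str, ...] = (
    "tug",
    "mdrt_forward",
    "mdrt_backward",
    "mdrt_ml",
    "sts",
    "imtp",
    "hip_adduction",
    "hip_abduction",
    "knee_extension",
    "fes_i",
)


class ZeroVarianceError(ValueError):
    """A test statistic is undefined because the relevant variance is zero."""


@dataclass
class TestResult:
    """One t-test with effect size, CI, Bayes factor and adjusted p."""

    label: str
    t: float
    df: float
    p_raw: float
    n: int
    p_adj: float | None = None
    d_unb: float | None = None
    ci95: tuple[float, float] | None = None
    bf10: float | None = None

    @property
    def significant(self) -> bool:
        p = self.p_adj if self.p_adj is not None else self.p_raw
        return p <= 0.05


@dataclass
class AnovaResult:
    """Split-plot ANOVA for one outcome: time, group, time x group effects."""

    variable: str
    condition: str | None
    f_time: float
    p_time: float
    d_time: float
    f_group: float
    p_group: float
    d_group: float
    f_inter: float
    p_inter: float
    d_inter: float
    n_per_group: dict[str, int] = field(default_factory=dict)
    excluded_subjects: list[str] = field(default_factory=list)


@dataclass
class InferenceReport:
    """Everything the analysis plan produces on one outcomes table."""

    normality: pd.DataFrame
    parametric_ok: dict[str, bool]
    baseline: pd.DataFrame
    gait_speed: dict[str, TestResult]
    anovas: list[AnovaResult]
    posthoc: dict[tuple[str, str | None], list[TestResult]]
    training_load: list[TestResult]
    alpha: float


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------


def ks_normality(values: np.ndarray, corrected: bool = True) -> tuple[float, float]:
    """One-sample KS test against a normal with estimated mean and SD.

    Returns (statistic, p).  ``corrected`` applies the Lilliefors correction
    for the estimated parameters (default, matching the screening use); the
    uncorrected variant plugs the estimates into the plain KS test.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 4:
        raise ValueError("need at least 4 observations for the normality screen")
    if np.std(values) == 0:
        raise ZeroVarianceError("constant sample: normality test undefined")
    if corrected:
        stat, p = lilliefors(values, dist="norm")
    else:
        stat, p = sps.kstest(values, "norm", args=(values.mean(), values.std(ddof=1)))
    return float(stat), float(p)


def oneway_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical between-groups one-way ANOVA; returns (F, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.std(g) == 0 for g in groups):
        raise ZeroVarianceError("zero within-group variance everywhere")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def paired_t(pre: np.ndarray, post: np.ndarray) -> tuple[float, int, float]:
    """Dependent two-sided t-test on post - pre; returns (t, df, p)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    ok = np.isfinite(pre) & np.isfinite(post)
    pre, post = pre[ok], post[ok]
    n = pre.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    diff = post - pre
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("zero variance of difference scores")
    t = diff.mean() * math.sqrt(n) / sd
    df = n - 1
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def independent_t(
    x: np.ndarray, y: np.ndarray, equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-sided independent t-test (Welch by default); (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# Mixed ANOVA
# ---------------------------------------------------------------------------


def _f_to_d(f: float, df_num: float, df_den: float) -> float:
    """ANOVA effect on the d scale via the f -> d conversion d = 2 f_effect."""
    return 2.0 * math.sqrt(max(f, 0.0) * df_num / df_den)


def mixed_anova_2x3(
    table: pd.DataFrame,
    value: str,
    variable: str | None = None,
    condition: str | None = None,
) -> AnovaResult:
    """Split-plot ANOVA: between factor group, repeated factor session.

    ``table`` must carry columns subject_id, group, session and ``value``.
    Subjects missing a session (or the value in one session) are excluded and
    listed on the result.  Group is tested against subject-within-group
    error; session and session x group against the subject x session error.
    """
    df = table[["subject_id", "group", "session", value]].dropna()
    counts = df.groupby("subject_id")["session"].nunique()
    complete = counts[counts == 2].index
    excluded = sorted(set(df["subject_id"]) - set(complete))
    df = df[df["subject_id"].isin(complete)]
    if df.empty or df["group"].nunique() < 2:
        raise ValueError("not enough complete subjects/groups for the mixed ANOVA")
    piv = df.pivot_table(index=["subject_id", "group"], columns="session", values=value)
    n_per = piv.reset_index().groupby("group")["subject_id"].nunique().to_dict()
    if np.allclose(piv["post"], piv["pre"]):
        # no within-subject change anywhere: session SS and its error are both
        # exactly zero, so the repeated-measures effects are null by definition
        means = piv.mean(axis=1).groupby(level="group")
        groups = [g.to_numpy() for _, g in means]
        f_g, p_g = oneway_anova(groups)
        k = len(groups)
        n_tot = sum(len(g) for g in groups)
        return AnovaResult(
            variable=variable or value, condition=condition,
            f_time=0.0, p_time=1.0, d_time=0.0,
            f_group=f_g, p_group=p_g, d_group=_f_to_d(f_g, k - 1, n_tot - k),
            f_inter=0.0, p_inter=1.0, d_inter=0.0,
            n_per_group=n_per, excluded_subjects=excluded,
        )
    aov = pg.mixed_anova(
        df, dv=value, within="session", between="group", subject="subject_id"
    ).set_index("Source")
    g, t, i = aov.loc["group"], aov.loc["session"], aov.loc["Interaction"]
    n_per_group = (
        df[df["session"] == "pre"].groupby("group")["subject_id"].nunique().to_dict()
    )
    return AnovaResult(
        variable=variable or value,
        condition=condition,
        f_time=float(t["F"]),
        p_time=float(t["p_unc"]),
        d_time=_f_to_d(t["F"], t["DF1"], t["DF2"]),
        f_group=float(g["F"]),
        p_group=float(g["p_unc"]),
        d_group=_f_to_d(g["F"], g["DF1"], g["DF2"]),
        f_inter=float(i["F"]),
        p_inter=float(i["p_unc"]),
        d_inter=_f_to_d(i["F"], i["DF1"], i["DF2"]),
        n_per_group=n_per_group,
        excluded_subjects=excluded,
    )


# ---------------------------------------------------------------------------
# Multiplicity, effect sizes, Bayes factors
# ---------------------------------------------------------------------------


def holm_correct(p_values: np.ndarray) -> np.ndarray:
    """Step-down Holm adjusted p-values (monotone, capped at 1), same order.

    Ryan's sequential-rejective procedure coincides with Holm in adjusted-p
    form for families like these, hence a single implementation.
    """
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p_values.size
    order = np.argsort(p_values, kind="stable")
    scaled = p_values[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def d_unbiased(
    pre: np.ndarray, post: np.ndarray, ci_level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Bias-corrected paired effect size with a noncentral-t CI.

    d_z = t / sqrt(n) standardizes the mean change by the SD of the
    difference scores; the Hedges factor 1 - 3/(4 df - 1) removes the
    small-sample bias.  The CI inverts the noncentral t distribution of the
    observed statistic, rescales by sqrt(n), and applies the same correction.
    """
    t, df, _ = paired_t(pre, post)
    n = df + 1
    return _d_unb_from_t(t, n, ci_level)


def _d_unb_from_t(t: float, n: int, ci_level: float = 0.95) -> tuple[float, tuple[float, float]]:
    df = n - 1
    corr = 1.0 - 3.0 / (4.0 * df - 1.0)
    d_unb = corr * t / math.sqrt(n)
    tail = (1.0 - ci_level) / 2.0
    lo = _noncentrality_bound(t, df, 1.0 - tail)
    hi = _noncentrality_bound(t, df, tail)
    ci = (corr * lo / math.sqrt(n), corr * hi / math.sqrt(n))
    return d_unb, ci


def _nct_cdf_safe(t: float, df: int, nc: float) -> float:
    # deep-tail noncentralities underflow to NaN in scipy; the limits are known
    v = sps.nct.cdf(t, df, nc)
    if np.isnan(v):
        return 0.0 if nc > t else 1.0
    return float(v)


def _noncentrality_bound(t: float, df: int, prob: float) -> float:
    """nc such that P(T_{df,nc} <= t) = prob, by bracketed root finding."""

    def f(nc: float) -> float:
        return _nct_cdf_safe(t, df, nc) - prob  # decreasing in nc

    lo, hi, width = t, t, 2.0
    while f(lo) <= 0:
        lo -= width
        width *= 2
    width = 2.0
    while f(hi) >= 0:
        hi += width
        width *= 2
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def jzs_bf_paired(t: float, n: int, r: float = 0.707) -> float:
    """One-sample JZS Bayes factor BF10 for a (paired) t statistic.

    Marginal likelihood of t under a Cauchy(0, r) prior on the standardized
    effect delta (noncentrality sqrt(n)*delta), integrated by adaptive
    quadrature, over the central-t likelihood of the point null.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if r <= 0:
        raise ValueError("prior scale r must be positive")
    return _jzs_bf(t, n - 1, math.sqrt(n), r)


def jzs_bf_independent(t: float, n1: int, n2: int, r: float = 0.707) -> float:
    """Two-sample JZS Bayes factor with effective sample size n1 n2/(n1+n2)."""
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 per group")
    neff = n1 * n2 / (n1 + n2)
    return _jzs_bf(t, n1 + n2 - 2, math.sqrt(neff), r)


def _jzs_bf(t: float, df: int, root_n: float, r: float) -> float:
    def integrand(delta: float) -> float:
        return sps.nct.pdf(t, df, root_n * delta) * sps.cauchy.pdf(delta, 0.0, r)

    # piecewise quadrature with breakpoints at the prior mode and the
    # likelihood peak keeps the adaptive rule from missing a narrow peak
    breaks = sorted({0.0, t / root_n})
    edges = [-np.inf, *breaks, np.inf]
    num, err = 0.0, 0.0
    for a, b in zip(edges, edges[1:]):
        if a == b:
            continue
        v, e = integrate.quad(integrand, a, b, limit=200, epsabs=0.0, epsrel=1e-9)
        num += v
        err += e
    if num <= 0 or not np.isfinite(num) or err / num > 1e-6:
        raise ArithmeticError("JZS Bayes factor quadrature did not converge")
    return float(num / sps.t.pdf(t, df))


def percent_change(
    table: OutcomeTable, variable: str, group: str, condition: str | None = None
) -> float:
    """Percent change of the group mean from pre to post: 100 (m1-m0)/|m0|."""
    df = table.df
    if condition is None:
        df = df.drop_duplicates(subset=["subject_id", "session"])
    sel = df["group"] == group
    if condition is not None:
        sel &= df["condition"] == condition
    pre = df.loc[sel & (df["session"] == "pre"), variable].mean()
    post = df.loc[sel & (df["session"] == "post"), variable].mean()
    if not np.isfinite(pre) or pre == 0:
        raise ZeroVarianceError("pre-test mean is zero or missing; percent change undefined")
    return float(100.0 * (post - pre) / abs(pre))


# ---------------------------------------------------------------------------
# Full analysis plan
# ---------------------------------------------------------------------------


def _paired_result(label: str, pre: np.ndarray, post: np.ndarray, r: float) -> TestResult:
    t, df, p = paired_t(pre, post)
    n = df + 1
    d_unb, ci = _d_unb_from_t(t, n)
    return TestResult(
        label=label, t=t, df=df, p_raw=p, n=n, d_unb=d_unb, ci95=ci,
        bf10=jzs_bf_paired(t, n, r),
    )


def run_full_inference(
    table: OutcomeTable,
    variables: tuple[str, ...] | None = None,
    secondary: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    bf_prior_scale: float = 0.707,
    gait_speed: bool = True,
    posthoc: bool = True,
    training_load: bool = True,
) -> InferenceReport:
    """Run the complete analysis plan on an outcomes table.

    Per-condition mixed ANOVAs for every UCM variable in ``variables``
    (default all four), per-session-level ANOVAs for ``secondary`` measures,
    pooled paired gait-speed t-tests per condition, baseline one-way ANOVAs,
    Lilliefors normality screen, training-load pairwise Welch t-tests.
    Post-hoc within-group t-tests are computed and stored unconditionally
    (``posthoc=True``); the interaction-gating rule (run only when
    p_interaction <= alpha) is applied by the reporting layer via
    :attr:`AnovaResult.p_inter`.  ``posthoc=False`` and
    ``training_load=False`` skip the effect-size-heavy blocks, which large
    simulation studies (e.g. type-I-rate calibration) do not need.
    """
    df = table.df
    variables = UCM_VARIABLES if variables is None else variables
    if secondary is None:
        secondary = tuple(
            v for v in SECONDARY_VARIABLES if v in df.columns and df[v].notna().any()
        )

    # --- normality screen (per group, per variable/condition) -------------
    norm_rows = []
    parametric_ok: dict[str, bool] = {}
    screens: list[tuple[str, str | None]] = [(v, c) for v in variables for c in CONDITIONS]
    screens += [(v, None) for v in secondary]
    for var, cond in screens:
        n_violations = 0
        for grp in GROUPS:
            sel = (df["group"] == grp)
            sub = df[sel if cond is None else sel & (df["condition"] == cond)]
            if cond is None:
                sub = sub.drop_duplicates(subset=["subject_id", "session"])
            vals = sub[var].dropna().to_numpy()
            if vals.size < 4:
                continue
            try:
                stat, p = ks_normality(vals)
            except ZeroVarianceError:
                stat, p = np.nan, np.nan
            reject = bool(np.isfinite(p) and p < alpha)
            n_violations += reject
            norm_rows.append(
                {"variable": var, "condition": cond, "group": grp,
                 "ks_stat": stat, "p": p, "non_normal": reject}
            )
        key = var if cond is None else f"{var}:{cond}"
        parametric_ok[key] = n_violations < 2
    normality = pd.DataFrame(norm_rows)

    # --- baseline one-way ANOVAs ------------------------------------------
    base_rows = []
    for var, cond in screens:
        sel = df["session"] == "pre"
        sub = df[sel if cond is None else sel & (df["condition"] == cond)]
        if cond is None:
            sub = sub.drop_duplicates(subset=["subject_id"])
        samples = [sub.loc[sub["group"] == g, var].dropna().to_numpy() for g in GROUPS]
        if any(s.size < 2 for s in samples):
            continue
        try:
            f, p = oneway_anova(samples)
        except ZeroVarianceError:
            f, p = np.nan, np.nan
        base_rows.append({"variable": var, "condition": cond, "F": f, "p": p})
    baseline = pd.DataFrame(base_rows)

    # --- gait speed: pooled paired t per condition ------------------------
    speed_results: dict[str, TestResult] = {}
    if gait_speed and df["gait_speed"].notna().any():
        for cond in CONDITIONS:
            sub = df[df["condition"] == cond].pivot_table(
                index="subject_id", columns="session", values="gait_speed"
            ).dropna()
            if len(sub) >= 3:
                speed_results[cond] = _paired_result(
                    f"gait_speed:{cond}", sub["pre"].to_numpy(), sub["post"].to_numpy(),
                    bf_prior_scale,
                )

    # --- mixed ANOVAs + post-hoc ------------------------------------------
    anovas: list[AnovaResult] = []
    posthoc: dict[tuple[str, str | None], list[TestResult]] = {}
    analyses: list[tuple[str, str | None]] = [(v, c) for v in variables for c in CONDITIONS]
    if gait_speed and df["gait_speed"].notna().any():
        analyses += [("gait_speed", c) for c in CONDITIONS]
    analyses += [(v, None) for v in secondary]
    for var, cond in analyses:
        sub = df if cond is None else df[df["condition"] == cond]
        if cond is None:
            sub = sub.drop_duplicates(subset=["subject_id", "session"])
        if sub[var].dropna().empty:
            continue
        try:
            aov = mixed_anova_2x3(sub, var, variable=var, condition=cond)
        except ValueError:
            continue
        anovas.append(aov)
        if not posthoc:
            continue
        results = []
        for grp in GROUPS:
            piv = sub[sub["group"] == grp].pivot_table(
                index="subject_id", columns="session", values=var
            ).dropna()
            if len(piv) < 3:
                continue
            try:
                results.append(
                    _paired_result(
                        f"{var}:{cond or 'all'}:{grp}",
                        piv["pre"].to_numpy(), piv["post"].to_numpy(), bf_prior_scale,
                    )
                )
            except ZeroVarianceError:
                continue
        if results:
            adj = holm_correct([r.p_raw for r in results])
            for r, pa in zip(results, adj):
                r.p_adj = float(pa)
            posthoc[(var, cond)] = results

    # --- training load: pre-planned pairwise independent t ----------------
    load_results: list[TestResult] = []
    if training_load and "training_load" in df.columns and df["training_load"].notna().any():
        post = df[df["session"] == "post"].drop_duplicates(subset=["subject_id"])
        samples = {g: post.loc[post["group"] == g, "training_load"].dropna().to_numpy()
                   for g in GROUPS}
        pairs = [(GROUPS[0], GROUPS[1]), (GROUPS[0], GROUPS[2]), (GROUPS[1], GROUPS[2])]
        for g1, g2 in pairs:
            x, y = samples[g1], samples[g2]
            if x.size < 2 or y.size < 2:
                continue
            t, dfree, p = independent_t(x, y)
            sd_pool = math.sqrt(
                ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
                / (x.size + y.size - 2)
            )
            d = (x.mean() - y.mean()) / sd_pool if sd_pool > 0 else np.nan
            corr = 1.0 - 3.0 / (4.0 * (x.size + y.size - 2) - 1.0)
            load_results.append(
                TestResult(
                    label=f"training_load:{g1} vs {g2}", t=t, df=dfree, p_raw=p,
                    n=x.size + y.size, d_unb=corr * d,
                    bf10=jzs_bf_independent(t, x.size, y.size, bf_prior_scale),
                )
            )
        if load_results:
            adj = holm_correct([r.p_raw for r in load_results])
            for r, pa in zip(load_results, adj):
                r.p_adj = float(pa)

    return InferenceReport(
        normality=normality,
        parametric_ok=parametric_ok,
        baseline=baseline,
        gait_speed=speed_results,
        anovas=anovas,
        posthoc=posthoc,
        training_load=load_results,
        alpha=alpha,
    )
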