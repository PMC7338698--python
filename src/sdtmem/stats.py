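"""Descriptive and inferential analyses over fitted model parameters.

The analysis layer of a two-condition within-subject recognition
experiment: paired t tests (with JZS Bayes factors), Wilcoxon
signed-rank tests, Pearson correlations with Fisher-z intervals, the
2 x 2 within-subjects ANOVA on hit/false-alarm rates with partial eta
squared, and a pipeline that assembles parameter summaries, condition
contrasts and inter-parameter correlations (with listwise exclusion of
outlying MSD strength estimates, d_A > 10).

The JZS Bayes factor is the default-prior Bayes factor for a paired
t test: a Cauchy prior with scale r on the standardised effect size
delta, BF10 = integral of the noncentral-t likelihood over the prior,
divided by the central-t likelihood of the null.  The default scale
sqrt(2)/2 is the conventional "medium" prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "PairedTestResult",
    "CorrelationResult",
    "paired_t",
    "wilcoxon_signed_rank",
    "pearson_r",
    "anova_2x2_within",
    "jzs_bf_paired",
    "analysis_pipeline",
    "JZS_MEDIUM_SCALE",
]

JZS_MEDIUM_SCALE = math.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class PairedTestResult:
    """Result of a paired comparison (t or Wilcoxon signed-rank)."""

    test: str
    statistic: float
    df: float
    p_value: float
    mean_diff: float
    ci_low: float
    ci_high: float
    effect_size: float  # Cohen's d_z for t tests; NaN for Wilcoxon
    bf10: float = float("nan")

    def __str__(self):
        if self.test == "paired_t":
            return (
                f"t({self.df:.0f}) = {self.statistic:.2f}, p = {self.p_value:.3f}, "
                f"dz = {self.effect_size:.2f}, 95% CI [{self.ci_low:.2f}, "
                f"{self.ci_high:.2f}], BF10 = {self.bf10:.2f}"
            )
        return f"V = {self.statistic:.0f}, p = {self.p_value:.3f}"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p_value: float
    ci_low: float
    ci_high: float

    def __str__(self):
        return (
            f"r({self.df}) = {self.r:.2f}, p = {self.p_value:.3f}, "
            f"95% CI [{self.ci_low:.2f}, {self.ci_high:.2f}]"
        )


def _paired_diffs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need n >= 3 pairs")
    return x - y


def paired_t(x, y, bayes: bool = True, scale: float = JZS_MEDIUM_SCALE) -> PairedTestResult:
    """Two-sided paired t test with 95% CI on the mean difference.

    Cohen's d_z = mean(diff) / sd(diff).  ``bayes`` adds the JZS BF10.
    """
    d = _paired_diffs(x, y)
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    se = sd / math.sqrt(n)
    t = d.mean() / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    bf = jzs_bf_paired(x, y, scale=scale) if bayes else float("nan")
    return PairedTestResult(
        test="paired_t",
        statistic=float(t),
        df=df,
        p_value=float(p),
        mean_diff=float(d.mean()),
        ci_low=float(d.mean() - tcrit * se),
        ci_high=float(d.mean() + tcrit * se),
        effect_size=float(d.mean() / sd),
        bf10=float(bf),
    )


def wilcoxon_signed_rank(x, y) -> PairedTestResult:
    """Wilcoxon signed-rank test; V = sum of positive-difference ranks.

    Zero differences are dropped.  Exact p for n <= 25 (no ties),
    normal approximation otherwise.
    """
    d = _paired_diffs(x, y)
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    n = len(d)
    method = "exact" if n <= 25 and len(np.unique(np.abs(d))) == n else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return PairedTestResult(
        test="wilcoxon",
        statistic=v,
        df=float("nan"),
        p_value=float(res.pvalue),
        mean_diff=float(np.median(d)),
        ci_low=float("nan"),
        ci_high=float("nan"),
        effect_size=float("nan"),
    )


def pearson_r(x, y) -> CorrelationResult:
    """Pearson correlation, two-sided p (df = n - 2), Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    n = len(x)
    if abs(r) < 1.0:
        z = np.arctanh(r)
        se = 1.0 / math.sqrt(n - 3)
        lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    else:
        lo = hi = r
    return CorrelationResult(float(r), n - 2, float(p), float(lo), float(hi))


def anova_2x2_within(data, factor_names=("factor_a", "factor_b")) -> pd.DataFrame:
    """2 x 2 within-subjects ANOVA by direct sums-of-squares decomposition.

    ``data`` has shape (n_subjects, 2, 2): axis 1 = factor A, axis 2 =
    factor B.  Each effect is tested against its own effect-by-subject
    interaction, F(1, n - 1), with partial eta squared
    SS_effect / (SS_effect + SS_error).  For a two-level factor the
    main-effect F equals the squared paired t on its marginal means.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 3 or x.shape[1:] != (2, 2):
        raise ValueError("data must have shape (n_subjects, 2, 2)")
    if np.isnan(x).any():
        raise ValueError("missing cells in the within-subjects design")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")

    grand = x.mean()
    subj = x.mean(axis=(1, 2))
    a_marg = x.mean(axis=2)  # (n, 2)
    b_marg = x.mean(axis=1)
    a_mean = a_marg.mean(axis=0)
    b_mean = b_marg.mean(axis=0)
    cell = x.mean(axis=0)  # (2, 2)

    rows = []

    def effect(name, ss_eff, ss_err):
        df1, df2 = 1, n - 1
        if ss_err == 0:
            f = 0.0 if ss_eff == 0 else np.inf
        else:
            f = (ss_eff / df1) / (ss_err / df2)
        p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        rows.append(
            {"effect": name, "F": float(f), "df1": df1, "df2": df2,
             "p_value": p, "partial_eta_sq": float(eta)}
        )

    # main effect A against A x subject
    ss_a = 2 * n * ((a_mean - grand) ** 2).sum()
    ss_as = 2 * ((a_marg - a_mean[None, :] - subj[:, None] + grand) ** 2).sum()
    effect(factor_names[0], ss_a, ss_as)

    ss_b = 2 * n * ((b_mean - grand) ** 2).sum()
    ss_bs = 2 * ((b_marg - b_mean[None, :] - subj[:, None] + grand) ** 2).sum()
    effect(factor_names[1], ss_b, ss_bs)

    inter = cell - a_mean[:, None] - b_mean[None, :] + grand
    ss_ab = n * (inter**2).sum()
    resid = (
        x
        - a_marg[:, :, None]
        - b_marg[:, None, :]
        - cell[None, :, :]
        + a_mean[None, :, None]
        + b_mean[None, None, :]
        + subj[:, None, None]
        - grand
    )
    ss_abs = (resid**2).sum()
    effect(f"{factor_names[0]} x {factor_names[1]}", ss_ab, ss_abs)
    return pd.DataFrame(rows).set_index("effect")


def jzs_bf_paired(x=None, y=None, scale: float = JZS_MEDIUM_SCALE, t: float = None,
                  n: int = None) -> float:
    """JZS Bayes factor BF10 for a paired (one-sample) t test.

    Either supply paired vectors ``x, y`` (or a single difference
    vector ``x``), or the observed ``t`` statistic and sample size
    ``n`` directly.  Computed by one-dimensional numerical integration
    of the noncentral-t likelihood over the Cauchy(0, scale) prior on
    the standardised effect size.
    """
    if t is None:
        d = _paired_diffs(x, np.zeros_like(np.asarray(x, float)) if y is None else y)
        n = len(d)
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance differences")
        t = d.mean() / (sd / math.sqrt(n))
    if n is None or n < 2:
        raise ValueError("need the sample size n >= 2")
    nu = n - 1
    sqrt_n = math.sqrt(n)

    def integrand(delta):
        return stats.nct.pdf(t, nu, delta * sqrt_n) * stats.cauchy.pdf(
            delta, scale=scale
        )

    marg_alt, err = integrate.quad(
        integrand, -np.inf, np.inf, epsabs=1e-12, epsrel=1e-9, limit=200
    )
    if not np.isfinite(marg_alt) or marg_alt <= 0 or err > max(1e-8, 0.01 * marg_alt):
        raise RuntimeError(
            f"JZS integration failed (value={marg_alt}, abs err={err})"
        )
    marg_null = stats.t.pdf(t, nu)
    return float(marg_alt / marg_null)


# ---------------------------------------------------------------------------
# analysis pipeline

_PARAM_PAIRS = {
    "UVSD": ("d", "sigma_o"),
    "DPSD": ("d_prime", "R"),
    "MSD": ("d_A", "lam"),
}
_MODEL_PARAMS = {
    "UVSD": ["sigma_o", "d", "c1", "c2", "c3", "c4", "c5"],
    "DPSD": ["R", "d_prime", "c1", "c2", "c3", "c4", "c5"],
    "MSD": ["lam", "d_A", "c1", "c2", "c3", "c4", "c5"],
}


def _outlier_participants(fits: pd.DataFrame, threshold: float) -> set:
    """Participants with an MSD d_A above threshold in any condition."""
    msd = fits[fits["model"] == "MSD"]
    if msd.empty or "d_A" not in msd.columns:
        return set()
    return set(msd.loc[msd["d_A"] > threshold, "participant"])


def analysis_pipeline(
    fits: pd.DataFrame,
    trials: pd.DataFrame = None,
    outlier_threshold: float = 10.0,
    bayes: bool = True,
) -> dict:
    """Full analysis report over a tidy participant-level fit table.

    ``fits`` is the output of :func:`sdtmem.fitting.fit_trials` at the
    participant level with exactly two conditions.  The report holds:

    * ``parameters`` — per model x condition means and SDs (MSD d_A
      means computed after listwise exclusion of d_A > 10 outliers);
    * ``contrasts`` — paired t (with BF10) between conditions for each
      model's strength/variance parameters; for MSD d_A, outliers are
      excluded listwise for the t test and a Wilcoxon signed-rank test
      including them is reported alongside;
    * ``correlations`` — per model x condition Pearson r between the
      strength and variance parameters (d-sigma_o, d'-R, d_A-lam),
      MSD rows excluded listwise;
    * ``comparison`` — per condition G2 sums, best-fit and rejection
      percentages;
    * ``hit_fa`` — mean hit/FA rates per condition (if ``trials`` is
      given) and the 2 x 2 response x condition within-subjects ANOVA.
    """
    conditions = sorted(fits["condition"].unique(), key=str)
    if len(conditions) != 2:
        raise ValueError("analysis_pipeline expects exactly two conditions")
    c1, c2 = conditions
    outliers = _outlier_participants(fits, outlier_threshold)
    report = {"conditions": conditions, "excluded_participants": sorted(outliers)}

    # parameter means/SDs
    rows = []
    for model, group in fits.groupby("model"):
        for cond, sub in group.groupby("condition"):
            use = sub
            for p in _MODEL_PARAMS[model]:
                vals = use[p]
                if model == "MSD" and p == "d_A":
                    vals = use.loc[~use["participant"].isin(outliers), p]
                rows.append(
                    {"model": model, "condition": cond, "parameter": p,
                     "mean": vals.mean(), "sd": vals.std(ddof=1)}
                )
    report["parameters"] = pd.DataFrame(rows)

    models_present = [m for m in _PARAM_PAIRS if m in set(fits["model"])]

    # condition contrasts on strength/variance parameters
    contrasts = {}
    for model in models_present:
        p_strength, p_var = _PARAM_PAIRS[model]
        sub = fits[fits["model"] == model].pivot(
            index="participant", columns="condition"
        )
        for p in (p_strength, p_var):
            a, b = sub[(p, c1)], sub[(p, c2)]
            key = f"{model}.{p}"
            try:
                if model == "MSD" and p == "d_A":
                    keep = ~sub.index.isin(outliers)
                    contrasts[key] = paired_t(a[keep], b[keep], bayes=bayes)
                    contrasts[f"{key}.wilcoxon"] = wilcoxon_signed_rank(a, b)
                else:
                    contrasts[key] = paired_t(a, b, bayes=bayes)
            except ValueError as err:  # tiny or degenerate cohorts
                contrasts[key] = f"not computed: {err}"
    report["contrasts"] = contrasts

    # inter-parameter correlations
    corr_rows = []
    for model in models_present:
        p_strength, p_var = _PARAM_PAIRS[model]
        for cond in conditions:
            sub = fits[(fits["model"] == model) & (fits["condition"] == cond)]
            if model == "MSD":
                sub = sub[~sub["participant"].isin(outliers)]
            try:
                res = pearson_r(sub[p_strength], sub[p_var])
            except ValueError:
                continue
            corr_rows.append(
                {"model": model, "condition": cond,
                 "pair": f"{p_strength}-{p_var}", "r": res.r, "df": res.df,
                 "p_value": res.p_value, "ci_low": res.ci_low,
                 "ci_high": res.ci_high}
            )
    report["correlations"] = pd.DataFrame(corr_rows)

    # G2 model comparison per condition
    comp = {}
    for cond in conditions:
        sub = fits[fits["condition"] == cond]
        piv_g2 = sub.pivot(index="participant", columns="model", values="g_squared")
        piv_p = sub.pivot(index="participant", columns="model", values="p_value")
        models = list(piv_g2.columns)
        lo = piv_g2.min(axis=1)
        is_win = piv_g2.le(lo + 1e-6, axis=0)
        frac = is_win.div(is_win.sum(axis=1), axis=0)
        comp[cond] = pd.DataFrame(
            {
                "sum_g2": piv_g2.sum(),
                "pct_best": 100.0 * frac.mean(),
                "pct_rejected": 100.0 * (piv_p < 0.05).mean(),
            }
        )
    report["comparison"] = comp

    # hit/FA rates and the response x condition ANOVA
    if trials is not None:
        from .data import aggregate_counts, hit_fa_rates, validate_trials

        trials = validate_trials(trials)
        participants = sorted(trials["participant"].unique(), key=str)
        arr = np.empty((len(participants), 2, 2))
        for i, p in enumerate(participants):
            for j, cond in enumerate(conditions):
                counts = aggregate_counts(trials, p, cond)
                hit, fa = hit_fa_rates(counts)
                arr[i, 0, j] = hit
                arr[i, 1, j] = fa
        report["hit_fa"] = pd.DataFrame(
            {
                "condition": conditions * 2,
                "rate": ["hit", "hit", "fa", "fa"],
                "mean": [arr[:, 0, 0].mean(), arr[:, 0, 1].mean(),
                         arr[:, 1, 0].mean(), arr[:, 1, 1].mean()],
                "se": np.array(
                    [arr[:, 0, 0].std(ddof=1), arr[:, 0, 1].std(ddof=1),
                     arr[:, 1, 0].std(ddof=1), arr[:, 1, 1].std(ddof=1)]
                ) / math.sqrt(len(participants)),
            }
        )
        report["hit_fa_anova"] = anova_2x2_within(
            arr, factor_names=("response", "condition")
        )
    return report
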