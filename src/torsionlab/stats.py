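"""Agreement metrics, repeated-measures tests, mixed models, power analysis.

The evaluation layer of the pipeline: mean absolute deviation and Pearson r
between measurement series, two-way random-effects absolute-agreement ICC
(single rater, i.e. ICC(2,1)), one-way within-subject (repeated-measures)
ANOVA with Tukey HSD post-hoc tests, a random-intercept linear mixed-effects
model for the degradation coefficients, and the a-priori sample-size
calculation for a within-factors repeated-measures ANOVA.

ICC, RM-ANOVA and Tukey are computed from explicit mean squares so the
formulas are inspectable; the mixed model is a REML fit via statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "IccResult",
    "AnovaTable",
    "LmmResult",
    "mad",
    "pearson_ci",
    "icc_agreement",
    "rm_anova",
    "tukey_hsd",
    "fit_lmm",
    "rm_anova_power",
    "rm_anova_sample_size",
    "significance_code",
]


@dataclass
class IccResult:
    icc: float
    p_value: float
    ci95: tuple[float, float]
    model_label: str = "two-way random, absolute agreement, single rater (ICC(2,1))"

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.icc <= hi + 1e-12):
            raise ValueError("ICC outside its own confidence interval")


@dataclass
class AnovaTable:
    f_value: float
    p_value: float
    df_effect: int
    df_error: int
    ss_condition: float
    ss_subject: float
    ss_error: float
    normality_ok: bool
    n_subjects_used: int
    n_subjects_dropped: int = 0


@dataclass
class LmmResult:
    coefficients: pd.DataFrame  # term, estimate, ci_lo, ci_hi, p_value
    variance_participant: float
    variance_residual: float
    reference_levels: dict
    singular: bool = False
    converged: bool = True


def significance_code(p: float) -> str:
    """Stratify p-values the standard way: ns / * / ** / ***."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def mad(a, b) -> float:
    """Mean absolute deviation over complete pairs (pairs with NaN dropped)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("need two equal-length 1D vectors")
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        raise ValueError("no complete pairs")
    return float(np.mean(np.abs(a[ok] - b[ok])))


def pearson_ci(a, b, alpha: float = 0.05) -> tuple[float, float, tuple[float, float]]:
    """Pearson r with two-sided p (t transform) and Fisher-z 95% CI."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in at least one input")
    r, p = sps.pearsonr(a, b)
    if n > 3:
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        se = 1.0 / np.sqrt(n - 3)
        zc = sps.norm.ppf(1 - alpha / 2)
        ci = (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))
    else:
        ci = (-1.0, 1.0)  # Fisher z is undefined at n = 3
    return float(r), float(p), ci


def _two_way_mean_squares(x: np.ndarray) -> tuple[float, float, float, int, int]:
    """Mean squares of the two-way (subjects x raters) ANOVA decomposition."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse), n, k


def icc_agreement(ratings: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a complete subjects × raters matrix.  The p-value comes
    from the F test of the between-subjects mean square against the error
    mean square; the CI is the standard F-bound construction.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 5 or x.shape[1] < 2:
        raise ValueError("need a subjects x raters matrix with >= 5 subjects, >= 2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings matrix must be complete (no missing entries)")
    msr, msc, mse, n, k = _two_way_mean_squares(x)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 1.0

    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_obs = msr / mse if mse > 0 else np.inf
    p = float(sps.f.sf(f_obs, df1, df2)) if np.isfinite(f_obs) else 0.0

    # Shrout–Fleiss / McGraw–Wong CI for ICC(2,1)
    if mse > 0 and msc >= 0:
        a_ = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
        b_ = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isfinite(a_):
            v = (a_ * msc + b_ * mse) ** 2 / (
                (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_hi = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_lo * mse) / (f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f_hi * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_hi * msr)
        else:
            lo = hi = 1.0
    else:
        lo, hi = icc, icc
    lo, hi = float(min(lo, icc)), float(max(hi, icc))
    return IccResult(icc=float(icc), p_value=p, ci95=(lo, hi))


def rm_anova(values: np.ndarray) -> AnovaTable:
    """One-way within-subjects ANOVA on a subjects × conditions matrix.

    Rows with any missing value are dropped (and counted).  Residual
    normality (Shapiro–Wilk, α=0.05) is reported as an advisory flag and
    never gates the test.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a subjects x conditions matrix with >= 2 conditions")
    complete = np.all(np.isfinite(x), axis=1)
    dropped = int((~complete).sum())
    x = x[complete]
    n, k = x.shape
    if n < 2:
        raise ValueError("fewer than 2 usable subjects")

    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        f_obs, p = (0.0, 1.0) if ss_cond <= 1e-12 else (np.inf, 0.0)
    else:
        f_obs = ms_cond / ms_err
        p = float(sps.f.sf(f_obs, df1, df2))
        if ss_cond <= 1e-12 * max(1.0, ss_total):
            f_obs, p = 0.0, 1.0

    resid = x - x.mean(axis=0, keepdims=True) - x.mean(axis=1, keepdims=True) + grand
    flat = resid.ravel()
    normality_ok = True
    if len(flat) >= 3 and np.ptp(flat) > 0:
        normality_ok = bool(sps.shapiro(flat).pvalue > 0.05)
    return AnovaTable(
        f_value=float(f_obs),
        p_value=float(p),
        df_effect=df1,
        df_error=df2,
        ss_condition=float(ss_cond),
        ss_subject=float(ss_subj),
        ss_error=float(ss_err),
        normality_ok=normality_ok,
        n_subjects_used=n,
        n_subjects_dropped=dropped,
    )


def tukey_hsd(
    groups: list[np.ndarray] | np.ndarray,
    within_subjects: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons via the studentized range distribution.

    ``groups`` is a list of samples (independent groups) or a subjects ×
    conditions matrix with ``within_subjects=True``, in which case the error
    mean square of the within-subjects decomposition is used.
    """
    if within_subjects:
        x = np.asarray(groups, dtype=float)
        table = rm_anova(x)
        k = x.shape[1]
        n_each = [x.shape[0]] * k
        means = x.mean(axis=0)
        ms_err = table.ss_error / table.df_error
        df_err = table.df_error
    else:
        samples = [np.asarray(g, dtype=float) for g in groups]
        k = len(samples)
        if k < 2:
            raise ValueError("need at least 2 groups")
        n_each = [len(g) for g in samples]
        means = np.array([g.mean() for g in samples])
        df_err = sum(n_each) - k
        ms_err = sum(((g - g.mean()) ** 2).sum() for g in samples) / df_err

    rows = []
    q_crit = sps.studentized_range.ppf(1 - alpha, k, df_err)
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(ms_err / 2.0 * (1.0 / n_each[i] + 1.0 / n_each[j]))
            q_obs = np.abs(diff) / se if se > 0 else 0.0
            p_adj = float(sps.studentized_range.sf(q_obs, k, df_err)) if se > 0 else 1.0
            half = q_crit * se
            rows.append(
                {
                    "group_a": i,
                    "group_b": j,
                    "mean_diff": float(diff),
                    "p_adj": min(p_adj, 1.0),
                    "ci_lo": float(diff - half),
                    "ci_hi": float(diff + half),
                }
            )
    return pd.DataFrame(rows)


def fit_lmm(
    records: pd.DataFrame,
    response: str = "dice",
    fixed: tuple[str, ...] = ("joint_level", "severity"),
    group: str = "participant",
    reference_levels: dict | None = None,
) -> LmmResult:
    """Random-intercept linear mixed model with treatment-coded fixed factors.

    REML fit.  Coefficients are reported relative to each factor's reference
    level (first level by default).  Singular fits (zero participant
    variance) are flagged, not hidden.
    """
    import statsmodels.formula.api as smf

    df = records.dropna(subset=[response, group, *fixed]).copy()
    counts = df.groupby(group).size()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 participants with >= 2 records each")
    refs = {}
    terms = []
    for f in fixed:
        levels = list(pd.unique(df[f]))
        ref = (reference_levels or {}).get(f)
        if ref not in levels:
            ref = sorted(levels, key=str)[0]
        refs[f] = ref
        if len(levels) < 2:
            continue  # constant factor: nothing to estimate
        terms.append(f"C({f}, Treatment(reference={ref!r}))")
    if not terms:
        raise ValueError("no estimable fixed factors (all constant)")
    formula = f"{response} ~ " + " + ".join(terms)

    X = pd.get_dummies(df[list(fixed)].astype(str))
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    expected = 1 + sum(df[f].nunique() - 1 for f in fixed)
    if rank < expected:
        raise ValueError(f"unidentifiable design: factors {fixed} are aliased")

    import warnings

    model = smf.mixedlm(formula, df, groups=df[group])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)

    rows = []
    ci = fit.conf_int()
    for name in fit.fe_params.index:
        pretty = _pretty_term(name)
        rows.append(
            {
                "term": pretty,
                "estimate": float(fit.fe_params[name]),
                "ci_lo": float(ci.loc[name, 0]),
                "ci_hi": float(ci.loc[name, 1]),
                "p_value": float(fit.pvalues[name]),
            }
        )
    var_participant = float(np.asarray(fit.cov_re).ravel()[0])
    var_residual = float(fit.scale)
    return LmmResult(
        coefficients=pd.DataFrame(rows),
        variance_participant=max(var_participant, 0.0),
        variance_residual=var_residual,
        reference_levels=refs,
        singular=var_participant <= 1e-10,
        converged=bool(fit.converged),
    )


def _pretty_term(name: str) -> str:
    """'C(severity, Treatment(...))[T.severe]' -> 'severity[severe]'."""
    if name == "Intercept":
        return name
    if name.startswith("C(") and "[T." in name:
        factor = name[2:].split(",")[0].strip()
        level = name.split("[T.")[1].rstrip("]")
        return f"{factor}[{level}]"
    return name


# ---------------------------------------------------------------------------
# a-priori power / sample size for within-factors repeated-measures ANOVA


def rm_anova_power(
    n: int, effect_f: float, alpha: float, corr: float, n_measurements: int
) -> float:
    """Power of the within-factors RM-ANOVA F test at ``n`` subjects.

    Noncentrality λ = f²·n·m/(1−corr), df₁ = m−1, df₂ = (n−1)(m−1),
    sphericity correction ε fixed at 1.
    """
    m = n_measurements
    if n < 2:
        return 0.0
    lam = effect_f**2 * n * m / (1.0 - corr)
    df1 = m - 1
    df2 = (n - 1) * (m - 1)
    crit = sps.f.ppf(1 - alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def rm_anova_sample_size(
    effect_f: float,
    alpha: float = 0.05,
    power: float = 0.80,
    corr: float = 0.6,
    n_measurements: int = 4,
    n_max: int = 10**6,
) -> int:
    """Smallest n with RM-ANOVA power ≥ target (and power(n−1) < target)."""
    if effect_f <= 0:
        raise ValueError("effect size f must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if not 0 <= corr < 1:
        raise ValueError("corr must lie in [0, 1)")
    if n_measurements < 2:
        raise ValueError("need at least 2 repeated measurements")
    for n in range(2, n_max + 1):
        if rm_anova_power(n, effect_f, alpha, corr, n_measurements) >= power:
            return n
    raise RuntimeError(f"no n <= {n_max} reaches the requested power")
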