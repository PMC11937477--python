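"""Cohort statistics for the bronchial-wall biomarker study design.

Implements the analysis battery applied to two-group asthma-severity
cohorts: Shapiro–Wilk normality gating with log transforms, Student's
t-tests (pooled variance, also from summary statistics), chi-square /
Fisher's exact tests, ROC analysis with the Youden operating point and
exact Clopper–Pearson confidence intervals, forward/backward stepwise
logistic regression for exacerbation prediction, Pearson correlations,
two-way mixed-effects absolute-agreement single-measure ICC, Bland–Altman
agreement, and quartile-group ANOVA with Tukey's post-hoc test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "shapiro_gate_transform",
    "compare_groups_continuous",
    "compare_groups_categorical",
    "roc_youden",
    "clopper_pearson",
    "stepwise_logistic",
    "pearson_corr",
    "icc_absolute",
    "icc_category",
    "bland_altman",
    "quartile_anova",
    "GroupComparison",
    "RocSummary",
    "AgreementReport",
]

ALPHA = 0.05

#: ICC category bands (lower bound inclusive, label)
ICC_BANDS = (
    (0.95, "almost perfect"),
    (0.80, "very good"),
    (0.60, "good"),
    (0.40, "moderate"),
    (0.20, "fair"),
    (0.0, "slight"),
)


# ---------------------------------------------------------------------------
# distribution gating


@dataclass
class GateResult:
    values: np.ndarray
    transformed: bool
    shapiro_p: float
    geometric_mean: float | None = None
    geometric_sd: float | None = None


def shapiro_gate_transform(values, alpha: float = ALPHA) -> GateResult:
    """Natural-log transform gated on Shapiro–Wilk normality rejection.

    When the raw distribution is rejected (p < alpha) the log-transformed
    values are returned together with the geometric mean and SD on the
    back-transformed scale.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("Shapiro–Wilk needs n >= 3")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values")
    p = float(sps.shapiro(values).pvalue)
    if p >= alpha:
        return GateResult(values=values, transformed=False, shapiro_p=p)
    if np.any(values <= 0):
        raise ValueError("log transform required but values are not all positive")
    logged = np.log(values)
    return GateResult(
        values=logged,
        transformed=True,
        shapiro_p=p,
        geometric_mean=float(np.exp(logged.mean())),
        geometric_sd=float(np.exp(logged.std(ddof=1))),
    )


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class GroupComparison:
    n: tuple
    mean: tuple
    sd: tuple
    statistic: float
    df: float
    p_value: float
    transformed: bool = False
    geometric: tuple | None = None  # (geo mean, geo SD) per group if transformed
    degenerate: bool = False


def compare_groups_continuous(
    a=None,
    b=None,
    summary_a: tuple | None = None,
    summary_b: tuple | None = None,
    gate: bool = True,
) -> GroupComparison:
    """Two-sample Student's t-test (pooled variance), two-sided.

    Accepts either raw samples ``a``, ``b`` (optionally normality-gated with
    a pooled-residual Shapiro–Wilk test and log transform) or summary
    statistics ``summary_a/b = (n, mean, sd)``.
    """
    if summary_a is not None or summary_b is not None:
        if summary_a is None or summary_b is None:
            raise ValueError("both summaries required")
        n1, m1, s1 = summary_a
        n2, m2, s2 = summary_b
        res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
        return GroupComparison(
            n=(n1, n2),
            mean=(m1, m2),
            sd=(s1, s2),
            statistic=float(res.statistic),
            df=float(n1 + n2 - 2),
            p_value=float(res.pvalue),
        )

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    transformed = False
    geometric = None
    if gate and len(a) + len(b) >= 3:
        residuals = np.concatenate([a - a.mean(), b - b.mean()])
        p_norm = float(sps.shapiro(residuals).pvalue)
        if p_norm < ALPHA and np.all(a > 0) and np.all(b > 0):
            a, b = np.log(a), np.log(b)
            transformed = True
            geometric = (
                (float(np.exp(a.mean())), float(np.exp(a.std(ddof=1)))),
                (float(np.exp(b.mean())), float(np.exp(b.std(ddof=1)))),
            )
    pooled_var = (
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    )
    if pooled_var == 0:
        equal = a.mean() == b.mean()
        return GroupComparison(
            n=(len(a), len(b)),
            mean=(float(a.mean()), float(b.mean())),
            sd=(0.0, 0.0),
            statistic=0.0 if equal else np.inf,
            df=float(len(a) + len(b) - 2),
            p_value=1.0 if equal else 0.0,
            transformed=transformed,
            geometric=geometric,
            degenerate=True,
        )
    res = sps.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        n=(len(a), len(b)),
        mean=(float(a.mean()), float(b.mean())),
        sd=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        statistic=float(res.statistic),
        df=float(len(a) + len(b) - 2),
        p_value=float(res.pvalue),
        transformed=transformed,
        geometric=geometric,
    )


@dataclass
class CategoricalComparison:
    test: str  # "fisher" or "chi-square"
    statistic: float
    p_value: float


def compare_groups_categorical(table) -> CategoricalComparison:
    """Fisher's exact test when any expected cell count < 5, else chi-square."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 contingency table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise ValueError("counts must be non-negative integers")
        table = table.astype(int)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("empty margin in contingency table")
    expected = sps.contingency.expected_freq(table)
    if np.any(expected < 5):
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        return CategoricalComparison(test="fisher", statistic=float(odds), p_value=float(p))
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return CategoricalComparison(test="chi-square", statistic=float(chi2), p_value=float(p))


# ---------------------------------------------------------------------------
# ROC / Youden / exact binomial CIs


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval (beta-quantile form)."""
    if n < 1 or successes < 0 or successes > n:
        raise ValueError("need 0 <= successes <= n, n >= 1")
    alpha = 1.0 - level
    if successes == 0:
        lower = 0.0
    else:
        lower = float(sps.beta.ppf(alpha / 2.0, successes, n - successes + 1))
    if successes == n:
        upper = 1.0
    else:
        upper = float(sps.beta.ppf(1.0 - alpha / 2.0, successes + 1, n - successes))
    return lower, upper


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann–Whitney U statistic (ties count 1/2)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = sps.rankdata(scores)
    u = ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _delong_auc_ci(scores, labels, level=0.95):
    """DeLong variance for the AUC with a normal-approximation CI."""
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    m, n = len(pos), len(neg)
    # placement values (structural components)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = np.sqrt(var)
    z = sps.norm.ppf(0.5 + level / 2.0)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se)), se


@dataclass
class RocSummary:
    auc: float
    auc_ci: tuple
    auc_p: float  # vs the chance AUC of 0.5 (DeLong z-test)
    cutoff: float
    sensitivity: float
    sensitivity_ci: tuple
    specificity: float
    specificity_ci: tuple
    youden_j: float
    curve_fpr: np.ndarray
    curve_tpr: np.ndarray


def roc_youden(scores, labels, level: float = 0.95) -> RocSummary:
    """ROC analysis with the Youden-index operating point.

    Positives are predicted by ``score >= cutoff``; candidate cutoffs are
    the observed scores.  AUC is the trapezoidal area under the empirical
    curve, identical to the normalized Mann–Whitney U statistic; ties in J
    are broken toward the lowest cutoff (favoring sensitivity).
    Sensitivity/specificity carry exact Clopper–Pearson intervals.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    thresholds = np.unique(scores)
    best = None
    for t in thresholds:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        sens = tp / n_pos
        spec = tn / n_neg
        j = sens + spec - 1.0
        # strictly-greater comparison keeps the lowest cutoff on J ties
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec, tp, tn)
    j, cutoff, sens, spec, tp, tn = best

    order = np.argsort(-scores, kind="stable")
    tpr = np.concatenate([[0.0], np.cumsum(labels[order] == 1) / n_pos])
    fpr = np.concatenate([[0.0], np.cumsum(labels[order] == 0) / n_neg])
    auc = _auc_rank(scores, labels)
    (auc_lo, auc_hi), se = _delong_auc_ci(scores, labels, level)
    auc_p = float(2.0 * sps.norm.sf(abs(auc - 0.5) / se)) if se > 0 else 0.0
    return RocSummary(
        auc=auc,
        auc_ci=(auc_lo, auc_hi),
        auc_p=auc_p,
        cutoff=float(cutoff),
        sensitivity=sens,
        sensitivity_ci=clopper_pearson(tp, n_pos, level),
        specificity=spec,
        specificity_ci=clopper_pearson(tn, n_neg, level),
        youden_j=j,
        curve_fpr=fpr,
        curve_tpr=tpr,
    )


# ---------------------------------------------------------------------------
# stepwise logistic regression


@dataclass
class LogisticReport:
    selected: list
    coefficients: dict  # variable -> coef
    odds_ratios: dict  # variable -> (OR, lo, hi)
    p_values: dict
    separation_flag: bool = False


def _fit_logit(y: np.ndarray, X: np.ndarray):
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # separation is detected below via the standard errors
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(disp=False, maxiter=200)
        except Exception:
            return None
    if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 1e3):
        return None
    return res

def stepwise_logistic(
    outcome,
    predictors: dict,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    level: float = 0.95,
) -> LogisticReport:
    """Forward-selection / backward-elimination logistic regression.

    Variables enter at Wald p < ``p_enter`` and leave at p > ``p_remove``.
    Odds ratios are exp(coefficient) with Wald confidence intervals.  On
    complete separation the report is flagged and an L2-penalized fit is
    reported instead.
    """
    y = np.asarray(outcome).astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant")
    names = list(predictors)
    cols = {k: np.asarray(v, dtype=float) for k, v in predictors.items()}
    n = len(y)
    if n <= len(names):
        raise ValueError("need more observations than candidate predictors")

    selected: list[str] = []
    separation = False
    changed = True
    while changed:
        changed = False
        # forward step: best candidate by Wald p of its own coefficient
        best_p, best_var = None, None
        for var in names:
            if var in selected:
                continue
            X = np.column_stack([cols[v] for v in selected + [var]])
            res = _fit_logit(y, X)
            if res is None:
                separation = True
                continue
            p = float(res.pvalues[-1])
            if best_p is None or p < best_p:
                best_p, best_var = p, var
        if best_var is not None and best_p < p_enter:
            selected.append(best_var)
            changed = True
        # backward step
        while selected:
            X = np.column_stack([cols[v] for v in selected])
            res = _fit_logit(y, X)
            if res is None:
                separation = True
                break
            pvals = res.pvalues[1:]
            worst = int(np.argmax(pvals))
            if float(pvals[worst]) > p_remove:
                selected.pop(worst)
                changed = True
            else:
                break

    coefficients: dict = {}
    odds: dict = {}
    pvals_out: dict = {}
    if selected:
        import statsmodels.api as sm

        X = np.column_stack([cols[v] for v in selected])
        res = _fit_logit(y, X)
        if res is None:
            separation = True
            model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
            res = model.fit_regularized(alpha=1.0, disp=False, maxiter=500)
            z = sps.norm.ppf(0.5 + level / 2.0)
            for i, var in enumerate(selected):
                c = float(res.params[i + 1])
                coefficients[var] = c
                odds[var] = (float(np.exp(c)), np.nan, np.nan)
                pvals_out[var] = np.nan
        else:
            z = sps.norm.ppf(0.5 + level / 2.0)
            for i, var in enumerate(selected):
                c = float(res.params[i + 1])
                se = float(res.bse[i + 1])
                coefficients[var] = c
                odds[var] = (
                    float(np.exp(c)),
                    float(np.exp(c - z * se)),
                    float(np.exp(c + z * se)),
                )
                pvals_out[var] = float(res.pvalues[i + 1])
    return LogisticReport(
        selected=selected,
        coefficients=coefficients,
        odds_ratios=odds,
        p_values=pvals_out,
        separation_flag=separation,
    )


# ---------------------------------------------------------------------------
# correlation


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson correlation with the t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# reproducibility


@dataclass
class AgreementReport:
    icc: float | None = None
    icc_ci: tuple | None = None
    icc_label: str | None = None
    mean_difference: float | None = None
    mean_difference_ci: tuple | None = None
    loa: tuple | None = None


def icc_category(value: float) -> str:
    """Map an ICC value onto the printed agreement bands."""
    if value == 0:
        return "null"
    for lo, label in ICC_BANDS:
        if value >= lo:
            return label
    return "null"


def icc_absolute(readings, level: float = 0.95) -> AgreementReport:
    """ICC(A,1): two-way mixed-effects, absolute agreement, single measure.

    ``readings`` is subjects x raters with no missing cells.  The estimate
    comes from the two-way ANOVA mean squares; the confidence interval uses
    the F-distribution bounds of McGraw & Wong.
    """
    x = np.asarray(readings, dtype=float)
    if x.ndim != 2:
        raise ValueError("readings must be 2D (subjects x raters)")
    n, k = x.shape
    if k < 2 or n < 5:
        raise ValueError("need >= 2 raters and >= 5 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing cells are not supported")

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

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = float((msr - mse) / denom) if denom > 0 else 1.0

    # McGraw & Wong F-based interval for ICC(A,1)
    alpha = 1.0 - level
    if mse <= 0:
        ci = (icc, icc)
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = v_num / v_den if np.isfinite(a) else (n - 1) * (k - 1)
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
        ci = (float(np.clip(lower, -1, 1)), float(np.clip(upper, -1, 1)))
    return AgreementReport(icc=icc, icc_ci=ci, icc_label=icc_category(icc))


def bland_altman(a, b, level: float = 0.95) -> AgreementReport:
    """Bland–Altman agreement: mean difference (a−b), its CI, and the LoA."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    n = len(d)
    t = sps.t.ppf(0.5 + level / 2.0, n - 1)
    ci = (md - t * sd / np.sqrt(n), md + t * sd / np.sqrt(n))
    loa = (md - 1.96 * sd, md + 1.96 * sd)
    return AgreementReport(
        mean_difference=md, mean_difference_ci=(float(ci[0]), float(ci[1])), loa=loa
    )


# ---------------------------------------------------------------------------
# quartile grouping


@dataclass
class QuartileAnovaReport:
    f_statistic: float
    p_value: float
    group_means: list
    group_sizes: list
    tukey: dict  # (i, j) -> adjusted p-value
    quartiles: tuple


def quartile_groups(values) -> tuple[np.ndarray, tuple]:
    """Quartile-group assignment (0..3); boundary values go to the lower group."""
    values = np.asarray(values, dtype=float)
    q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    groups = np.searchsorted([q1, q2, q3], values, side="left")
    return groups, (float(q1), float(q2), float(q3))


def quartile_anova(grouping_values, response) -> QuartileAnovaReport:
    """One-way ANOVA + Tukey HSD across quartile groups of a biomarker."""
    grouping_values = np.asarray(grouping_values, dtype=float)
    response = np.asarray(response, dtype=float)
    if len(grouping_values) != len(response):
        raise ValueError("grouping and response must be paired")
    if len(response) < 8:
        raise ValueError("need n >= 8 for quartile grouping")
    groups, qs = quartile_groups(grouping_values)
    samples = [response[groups == g] for g in range(4)]
    empty = [g for g, s in enumerate(samples) if len(s) == 0]
    if empty:
        raise ValueError(
            f"quartile group(s) {empty} empty — massive ties in the grouping variable"
        )
    f, p = sps.f_oneway(*samples)
    tk = sps.tukey_hsd(*samples)
    tukey = {
        (i, j): float(tk.pvalue[i, j]) for i in range(4) for j in range(4) if i < j
    }
    return QuartileAnovaReport(
        f_statistic=float(f),
        p_value=float(p),
        group_means=[float(s.mean()) for s in samples],
        group_sizes=[int(len(s)) for s in samples],
        tukey=tukey,
        quartiles=qs,
    )
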