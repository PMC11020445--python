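"""The inference chain on a cohort table.

Descriptive two-group comparison with t-based 95% CIs, Pearson correlation
between EBQ and segmental height loss, ROC analysis with a Youden-index
cutoff, and multivariate logistic regression with Wald odds ratios.

Conventions
-----------
* Confidence intervals for means use the t quantile with ``n - 1`` degrees
  of freedom: ``mean +/- t_{(1+level)/2, n-1} * sd / sqrt(n)``.
* Continuous group comparisons gate on Shapiro-Wilk normality (alpha 0.05
  per group): both normal -> pooled-variance Student t; otherwise
  Mann-Whitney U with the tie-corrected normal approximation (no continuity
  correction, the large-sample convention of mainstream clinical software).
* Categorical comparisons use Pearson chi-square without Yates correction.
* ROC thresholds sit at midpoints between consecutive distinct scores plus
  -inf/+inf sentinels; a case is called positive when its score >= the
  threshold (higher EBQ predicts subsidence).  AUC is the rank (Mann-
  Whitney) statistic with ties counted one-half; its CI is DeLong's.
* Logistic regression is maximum likelihood via iteratively reweighted
  least squares; Wald standard errors come from the inverse observed
  information, and odds-ratio CIs are ``exp(B +/- 1.96 se)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

__all__ = [
    "GroupSummary",
    "LevelSummary",
    "RocResult",
    "CoefEstimate",
    "LogisticFit",
    "CorrelationResult",
    "SeparationError",
    "RankDeficiencyError",
    "t_ci_mean",
    "compare_groups",
    "pearson",
    "roc",
    "logistic_fit",
    "or_from_coef",
    "per_level_summary",
    "analyze_cohort",
    "TABLE2_COVARIATES",
    "LEVEL_ORDER",
]

LEVEL_ORDER = ("C3/4", "C4/5", "C5/6", "C6/7")

#: Covariate set of the multivariate subsidence model.
TABLE2_COVARIATES = ("age", "sex", "smoker", "bmi", "preop_height_mm", "tscore", "ebq")


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE diverges."""


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptives and the two-group test for one variable."""

    variable: str
    groups: dict  # group label -> {"n", "mean", "sd", "ci95"}
    p_value: float
    test_used: str  # {"student_t", "mann_whitney", "chi_square"}


@dataclass(frozen=True)
class LevelSummary:
    """Single-group mean/SD/CI of EBQ at one disc level."""

    level: str
    n: int
    mean: float
    sd: float
    ci95: tuple


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray = field(repr=False)
    sensitivity: np.ndarray = field(repr=False)
    specificity: np.ndarray = field(repr=False)
    auc: float = 0.0
    auc_ci95: tuple = (0.0, 1.0)
    cutoff: float = 0.0
    cutoff_sensitivity: float = 0.0
    cutoff_specificity: float = 0.0
    youden_j: float = 0.0


@dataclass(frozen=True)
class CoefEstimate:
    B: float
    se: float
    p: float
    or_: float
    or_ci95: tuple


@dataclass(frozen=True)
class LogisticFit:
    params: dict  # covariate name -> CoefEstimate (includes "intercept")
    converged: bool
    n_iter: int
    n_obs: int
    loglik: float


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------


def t_ci_mean(mean: float, sd: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """t-based confidence interval of a mean from summary statistics."""
    if n < 2:
        raise ValueError("a confidence interval needs n >= 2")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    half = sps.t.ppf((1 + level) / 2, n - 1) * sd / np.sqrt(n)
    return float(mean - half), float(mean + half)


def _numeric_group_summary(values: np.ndarray, level: float = 0.95) -> dict:
    n = len(values)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n >= 2 else 0.0
    ci = t_ci_mean(mean, sd, n, level) if n >= 2 else (mean, mean)
    return {"n": n, "mean": mean, "sd": sd, "ci95": ci}


def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    group_col: str = "subsided",
    kind: Optional[str] = None,
    welch: bool = False,
    alpha_normality: float = 0.05,
) -> GroupSummary:
    """Two-group comparison of one variable with the appropriate test.

    ``kind`` may force ``"continuous"`` or ``"categorical"``; by default a
    numeric column with more than two distinct values is treated as
    continuous, anything else as categorical.
    """
    if variable not in cohort.columns:
        raise ValueError(f"variable {variable!r} not in cohort")
    if group_col not in cohort.columns:
        raise ValueError(f"grouping column {group_col!r} not in cohort")
    col = cohort[variable]
    grp = cohort[group_col]
    labels = sorted(pd.unique(grp))
    if len(labels) != 2:
        raise ValueError(f"grouping column must have exactly 2 groups, got {labels}")
    if col.isna().any():
        raise ValueError(f"variable {variable!r} has missing values")

    if kind is None:
        numeric = pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col)
        kind = "continuous" if numeric and col.nunique() > 2 else "categorical"

    samples = [col[grp == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("both groups must be nonempty")

    if kind == "categorical":
        table = pd.crosstab(col, grp)
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any() or table.shape[0] < 2:
            raise ValueError(f"degenerate contingency table for {variable!r}")
        chi2, p, dof, _ = sps.chi2_contingency(table.values, correction=False)
        groups = {}
        for g, s in zip(labels, samples):
            entry = {"n": int(len(s))}
            if pd.api.types.is_numeric_dtype(s):
                entry["mean"] = float(np.mean(s.astype(float)))  # proportion for 0/1
            else:
                entry["mean"] = None
            entry["sd"] = None
            entry["ci95"] = None
            groups[g] = entry
        return GroupSummary(variable, groups, float(p), "chi_square")

    x, y = (np.asarray(s, dtype=float) for s in samples)
    normal = True
    for s in (x, y):
        if len(s) < 3 or np.ptp(s) == 0:
            normal = False
            break
        if sps.shapiro(s).pvalue < alpha_normality:
            normal = False
            break
    if normal:
        res = sps.ttest_ind(x, y, equal_var=not welch)
        p = float(res.pvalue)
        test = "student_t" if not welch else "welch_t"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        p = float(res.pvalue)
        test = "mann_whitney"
    groups = {g: _numeric_group_summary(s) for g, s in zip(labels, (x, y))}
    return GroupSummary(variable, groups, p, test)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(x))


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def _delong_ci(pos: np.ndarray, neg: np.ndarray, auc: float, level: float = 0.95) -> tuple:
    """DeLong CI for the AUC via midrank placements."""
    n1, n0 = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    r_all = sps.rankdata(combined)
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    v10 = (r_all[:n1] - r_pos) / n0
    v01 = 1.0 - (r_all[n1:] - r_neg) / n1
    s10 = np.var(v10, ddof=1) if n1 > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n0 > 1 else 0.0
    se = np.sqrt(s10 / n1 + s01 / n0)
    z = sps.norm.ppf((1 + level) / 2)
    return (float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se)))


def roc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC curve, rank-based AUC with DeLong CI, and the Youden cutoff.

    Ties on the Youden index are broken toward higher specificity (the
    clinically conservative operating point), then toward a lower cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])

    # AUC = Mann-Whitney U / (n0 n1), ties counted one-half
    r_all = sps.rankdata(scores)
    n1, n0 = len(pos), len(neg)
    auc = (r_all[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1)

    j = sens + spec - 1.0
    # lexicographic max: J, then specificity, then lower threshold
    order = np.lexsort((thresholds, -spec, -j))
    best = order[0]
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        auc_ci95=_delong_ci(pos, neg, float(auc)),
        cutoff=float(thresholds[best]),
        cutoff_sensitivity=float(sens[best]),
        cutoff_specificity=float(spec[best]),
        youden_j=float(j[best]),
    )


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


def _encode_design(data: pd.DataFrame, covariates: Sequence[str]) -> tuple[np.ndarray, list]:
    cols = []
    names = []
    for name in covariates:
        if name not in data.columns:
            raise ValueError(f"covariate {name!r} not in data")
        col = data[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
        else:
            cats = sorted(pd.unique(col))
            if len(cats) != 2:
                raise ValueError(
                    f"covariate {name!r} is non-numeric with {len(cats)} categories; "
                    "only binary categories are auto-encoded")
            cols.append((col == cats[1]).to_numpy(dtype=float))
            names.append(f"{name}[{cats[1]}]")
    X = np.column_stack([np.ones(len(data))] + cols)
    return X, ["intercept"] + names


def logistic_fit(
    data: pd.DataFrame,
    covariates: Sequence[str],
    outcome: str = "subsided",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression via IRLS with Wald inference.

    Convergence: max absolute score below ``tol`` (or ``max_iter`` reached,
    flagged in the result).  Rank-deficient designs raise
    :class:`RankDeficiencyError` naming the collinear columns; diverging
    coefficients (|B| > 15 with a non-vanishing gradient) raise
    :class:`SeparationError`.
    """
    y = data[outcome].to_numpy(dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary with both classes present")
    X, names = _encode_design(data, covariates)
    n, k = X.shape

    # rank check via QR: near-zero diagonal entries mark collinear columns
    r_diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
    bad = r_diag < 1e-8 * max(1.0, r_diag.max())
    if bad.any():
        culprits = [names[i] for i in np.nonzero(bad)[0]]
        raise RankDeficiencyError(f"design matrix is rank deficient; collinear columns: {culprits}")

    beta = np.zeros(k)
    converged = False
    n_iter = 0
    info = None
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        score = X.T @ (y - p)
        if np.abs(score).max() < tol:
            converged = True
            break
        w = np.clip(p * (1 - p), 1e-10, None)
        info = X.T @ (X * w[:, None])
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:  # singular information
            raise SeparationError(f"information matrix singular at iteration {n_iter}") from exc
        beta = beta + delta

    if not converged and np.abs(beta).max() > 15:
        # transient |B| > 15 during iteration is fine; divergence without a
        # vanishing gradient after max_iter marks (quasi-)separation
        raise SeparationError(
            "coefficients diverging (|B| > 15 with non-vanishing gradient): "
            "the classes are (quasi-)separated")

    eta = X @ beta
    p = expit(eta)
    w = np.clip(p * (1 - p), 1e-10, None)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * sps.norm.sf(np.abs(z))
    with np.errstate(divide="ignore"):
        loglik = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))

    params = {}
    for i, name in enumerate(names):
        params[name] = CoefEstimate(
            B=float(beta[i]),
            se=float(se[i]),
            p=float(pvals[i]),
            or_=float(np.exp(beta[i])),
            or_ci95=(float(np.exp(beta[i] - 1.96 * se[i])),
                     float(np.exp(beta[i] + 1.96 * se[i]))),
        )
    return LogisticFit(params=params, converged=converged, n_iter=n_iter,
                       n_obs=n, loglik=loglik)


def or_from_coef(B: float) -> float:
    """Odds ratio from a log-odds coefficient: exp(B)."""
    return float(np.exp(B))


# ---------------------------------------------------------------------------
# per-level summary
# ---------------------------------------------------------------------------


def per_level_summary(
    cohort: pd.DataFrame,
    value_col: str = "ebq",
    level_order: Sequence[str] = LEVEL_ORDER,
    outcome_col: str = "subsided",
) -> list[LevelSummary]:
    """Mean EBQ per disc level among non-subsided patients, cranial to caudal.

    Levels with fewer than 2 patients are omitted with a warning.
    """
    non = cohort[cohort[outcome_col].astype(int) == 0]
    out = []
    for level in level_order:
        vals = non.loc[non["level"] == level, value_col].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(f"level {level}: n={len(vals)} < 2, omitted from the per-level summary")
            continue
        s = _numeric_group_summary(vals)
        out.append(LevelSummary(level=level, n=s["n"], mean=s["mean"],
                                sd=s["sd"], ci95=s["ci95"]))
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

TABLE1_VARIABLES = ("age", "sex", "smoker", "bmi", "level", "tscore", "ebq", "height_loss_mm")


def analyze_cohort(cohort: pd.DataFrame) -> dict:
    """Run the full inference chain on a cohort table.

    Returns a dict with keys ``table1`` (list of :class:`GroupSummary`),
    ``table2`` (:class:`LogisticFit`), ``table3`` (list of
    :class:`LevelSummary`), ``roc`` (:class:`RocResult`), ``correlation``
    (:class:`CorrelationResult`) and ``prevalence``.
    """
    df = cohort.copy()
    if "height_loss_mm" not in df.columns:
        df["height_loss_mm"] = df["preop_height_mm"] - df["final_height_mm"]
    table1 = [compare_groups(df, v) for v in TABLE1_VARIABLES if v in df.columns]
    fit = logistic_fit(df, [c for c in TABLE2_COVARIATES if c in df.columns])
    table3 = per_level_summary(df)
    roc_res = roc(df["ebq"].to_numpy(float), df["subsided"].to_numpy(int))
    corr = pearson(df["ebq"].to_numpy(float), df["height_loss_mm"].to_numpy(float))
    prevalence = float(df["subsided"].astype(int).mean())
    return {
        "table1": table1,
        "table2": fit,
        "table3": table3,
        "roc": roc_res,
        "correlation": corr,
        "prevalence": prevalence,
        "n": int(len(df)),
    }
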