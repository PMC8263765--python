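"""Exploratory subgroup comparisons on cumulative methylation.

Two-group CM comparisons use the Mann-Whitney test (exact enumeration for
small tie-free groups, asymptotic with tie correction otherwise); more
than two groups use Kruskal-Wallis.  Positive-call rates across IHC
subtypes are tested with Fisher's exact test (hypergeometric for 2x2; a
seeded margin-preserving Monte-Carlo extension for 2xk).  Age trends are
ordinary least squares of CM on age, and the misclassification-vs-age
scan fits, per CM threshold, a logistic regression of the misclassification
indicator on age, separately for false positives among benign samples and
false negatives among malignant ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .classification import MALIGNANT
from .errors import DegenerateInputError, InvalidArgumentError

#: Per-group size below which the two-group test uses exact enumeration.
EXACT_ENUMERATION_MAX_N = 8


@dataclass(frozen=True)
class GroupTestResult:
    test: str
    statistic: float
    p_value: float
    n_per_group: tuple


@dataclass(frozen=True)
class CallRateResult:
    table: pd.DataFrame
    p_value: float
    method: str


@dataclass(frozen=True)
class AgeTrendResult:
    slope: float
    intercept: float
    p_value: Optional[float]  # None when residual df is zero
    r: float
    n: int


def compare_groups(values: Sequence[float], groups: Sequence) -> GroupTestResult:
    """Rank test on CM across groups: Mann-Whitney (2) or Kruskal-Wallis (>2)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise InvalidArgumentError("values and groups must have equal length")
    levels = pd.unique(groups)
    samples = [values[groups == g] for g in levels]
    if len(levels) < 2 or any(len(s) == 0 for s in samples):
        raise InvalidArgumentError("need >= 2 nonempty groups")
    sizes = tuple(len(s) for s in samples)
    if len(levels) == 2:
        a, b = samples
        no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        method = "exact" if max(sizes) < EXACT_ENUMERATION_MAX_N and no_ties else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return GroupTestResult("mann-whitney", float(res.statistic), float(res.pvalue), sizes)
    res = stats.kruskal(*samples)
    return GroupTestResult("kruskal-wallis", float(res.statistic), float(res.pvalue), sizes)


def _table_log_prob(table: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of a 2xk table given margins."""
    from scipy.special import gammaln

    def lchoose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    return float(lchoose(col, table[0]).sum() - lchoose(n, row[0]))


def call_rate_table(
    calls: Sequence,
    subtype: Sequence,
    n_mc: int = 100_000,
    seed: Optional[int] = None,
    levels: Optional[Sequence] = None,
) -> CallRateResult:
    """2xk table of positive/negative calls by subtype with an exact-style p.

    2x2 tables use the two-sided Fisher exact test; wider tables use a
    seeded Monte-Carlo Fisher test: labels are permuted (which samples
    tables from the margin-conditional null) and the p-value is the
    fraction of tables at most as probable as the observed one.
    Empty subtype levels are dropped with a warning.
    """
    calls = np.asarray(calls)
    subtype = np.asarray(subtype)
    if len(calls) != len(subtype):
        raise InvalidArgumentError("calls and subtype must have equal length")
    pos = np.asarray([c == MALIGNANT or c is True or c == 1 for c in calls])
    levels = list(levels) if levels is not None else [g for g in pd.unique(subtype)]
    counts = {g: ((subtype == g) & pos).sum() for g in levels}
    totals = {g: (subtype == g).sum() for g in levels}
    empty = [g for g in levels if totals[g] == 0]
    if empty:
        warnings.warn(f"dropping empty subtype levels: {empty}")
        levels = [g for g in levels if totals[g] > 0]
    if len(levels) < 2:
        raise DegenerateInputError("need >= 2 nonempty subtype levels")
    table = pd.DataFrame(
        {g: [int(counts[g]), int(totals[g] - counts[g])] for g in levels},
        index=["positive", "negative"],
    )
    arr = table.to_numpy()
    if len(levels) == 2:
        _, p = stats.fisher_exact(arr, alternative="two-sided")
        return CallRateResult(table, float(p), "fisher-exact")
    # Monte-Carlo Fisher for 2xk: permute the call margin across samples.
    rng = np.random.default_rng(seed)
    keep = np.isin(subtype, levels)
    sub = subtype[keep]
    pos_kept = pos[keep]
    level_index = {g: i for i, g in enumerate(levels)}
    sub_idx = np.asarray([level_index[g] for g in sub])
    obs_lp = _table_log_prob(arr)
    k = len(levels)
    hits = 0
    perm = pos_kept.copy()
    for _ in range(int(n_mc)):
        rng.shuffle(perm)
        t = np.zeros((2, k), dtype=int)
        np.add.at(t[0], sub_idx[perm], 1)
        t[1] = np.bincount(sub_idx, minlength=k) - t[0]
        if _table_log_prob(t) <= obs_lp + 1e-9:
            hits += 1
    p = (hits + 1) / (int(n_mc) + 1)
    return CallRateResult(table, float(p), "fisher-monte-carlo")


def age_trend(cm: Sequence[float], age: Sequence[float]) -> AgeTrendResult:
    """OLS slope of CM on age with its two-sided p; Pearson r alongside."""
    cm = np.asarray(cm, dtype=float)
    age = np.asarray(age, dtype=float)
    if len(cm) != len(age) or len(cm) < 2:
        raise InvalidArgumentError("need equal-length vectors with n >= 2")
    if np.all(age == age[0]):
        raise DegenerateInputError("age is constant; slope undefined")
    fit = sm.OLS(cm, sm.add_constant(age)).fit()
    slope = float(fit.params[1])
    p = None if fit.df_resid <= 0 else float(fit.pvalues[1])
    r = float(np.corrcoef(age, cm)[0, 1]) if np.std(cm) > 0 else 0.0
    return AgeTrendResult(
        slope=slope, intercept=float(fit.params[0]), p_value=p, r=r, n=len(cm)
    )


def misclassification_vs_age(
    cm: Sequence[float],
    age: Sequence[float],
    truth: Sequence,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Per-threshold logistic regressions of misclassification on age.

    Misclassification is defined per class: a benign sample called positive
    (false positive) and a malignant sample called negative (false
    negative).  Returns one row per (threshold, error type) with the age
    coefficient, its standard error and p-value; non-converged or separated
    fits are flagged rather than raised.
    """
    cm = np.asarray(cm, dtype=float)
    age = np.asarray(age, dtype=float)
    pos = np.asarray([t == MALIGNANT or t is True or t == 1 for t in truth])
    if not pos.any() or pos.all():
        raise DegenerateInputError("both truth classes must be represented")

    rows = []
    for thr in thresholds:
        called_pos = cm > thr
        for error, mask in (
            ("false_positive", ~pos),  # among benign: called positive
            ("false_negative", pos),   # among malignant: called negative
        ):
            mis = (called_pos != pos)[mask].astype(float)
            a = age[mask]
            coef = se = p = np.nan
            converged = False
            if 0.0 < mis.mean() < 1.0:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        fit = sm.Logit(mis, sm.add_constant(a)).fit(disp=0, maxiter=100)
                        converged = bool(fit.mle_retvals.get("converged", False)) and np.all(
                            np.isfinite(fit.bse)
                        )
                        if converged:
                            coef, se, p = (
                                float(fit.params[1]),
                                float(fit.bse[1]),
                                float(fit.pvalues[1]),
                            )
                    except Exception:
                        converged = False
            rows.append(
                {
                    "threshold": float(thr),
                    "error": error,
                    "n": int(mask.sum()),
                    "n_misclassified": int(mis.sum()),
                    "age_coef": coef,
                    "se": se,
                    "p_value": p,
                    "converged": converged,
                }
            )
    return pd.DataFrame(rows)
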