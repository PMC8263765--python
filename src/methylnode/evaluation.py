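"""Diagnostic accuracy against a gold standard.

Point estimates are the usual ratios (sensitivity = TP/(TP+FN), ...);
binomial confidence intervals use the Clopper-Pearson exact method.  The
ROC area is the empirical probability that a random malignant score
exceeds a random benign score (ties count 1/2), with a DeLong variance
for its confidence interval and a seeded-bootstrap alternative.
Cross-platform concordance is Spearman rank correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .classification import MALIGNANT
from .errors import DegenerateInputError, InvalidArgumentError


def _as_positive_mask(labels: Sequence) -> np.ndarray:
    return np.asarray([lab == MALIGNANT or lab is True or lab == 1 for lab in labels])


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidArgumentError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class ProportionEstimate:
    """A diagnostic proportion in percent with its exact CI (None if undefined)."""

    percent: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    numerator: int = 0
    denominator: int = 0

    @property
    def defined(self) -> bool:
        return self.percent is not None


@dataclass(frozen=True)
class DiagnosticReport:
    counts: ConfusionCounts
    sensitivity: ProportionEstimate
    specificity: ProportionEstimate
    ppv: ProportionEstimate
    npv: ProportionEstimate
    auc: Optional[float] = None
    auc_ci: Optional[tuple] = None
    ci_level: float = 0.95
    n_excluded_indeterminate: int = 0

    def to_dict(self) -> dict:
        def prop(p: ProportionEstimate) -> dict:
            if not p.defined:
                return {"percent": None, "undefined": True}
            return {
                "percent": round(p.percent, 1),
                "ci_low": round(p.ci_low, 1),
                "ci_high": round(p.ci_high, 1),
                "numerator": p.numerator,
                "denominator": p.denominator,
            }

        d = {
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
                "tn": self.counts.tn,
                "total": self.counts.total,
            },
            "sensitivity": prop(self.sensitivity),
            "specificity": prop(self.specificity),
            "ppv": prop(self.ppv),
            "npv": prop(self.npv),
            "ci_level": self.ci_level,
            "n_excluded_indeterminate": self.n_excluded_indeterminate,
        }
        if self.auc is not None:
            d["auc"] = round(self.auc, 3)
            d["auc_ci"] = [round(self.auc_ci[0], 3), round(self.auc_ci[1], 3)]
        return d


@dataclass(frozen=True)
class ConcordanceResult:
    spearman_r: Optional[float]
    n: int
    p_value: Optional[float] = None

    @property
    def defined(self) -> bool:
        return self.spearman_r is not None


def confusion(calls: Sequence, truth: Sequence) -> ConfusionCounts:
    """Tally calls against binary truth (positive = malignant)."""
    if len(calls) != len(truth):
        raise InvalidArgumentError(
            f"calls ({len(calls)}) and truth ({len(truth)}) must have equal length"
        )
    call_pos = _as_positive_mask(calls)
    true_pos = _as_positive_mask(truth)
    return ConfusionCounts(
        tp=int((call_pos & true_pos).sum()),
        fp=int((call_pos & ~true_pos).sum()),
        fn=int((~call_pos & true_pos).sum()),
        tn=int((~call_pos & ~true_pos).sum()),
    )


def _proportion(num: int, den: int, ci_level: float) -> ProportionEstimate:
    if den == 0:
        return ProportionEstimate(percent=None, numerator=num, denominator=0)
    lo, hi = proportion_confint(num, den, alpha=1 - ci_level, method="beta")
    return ProportionEstimate(
        percent=100.0 * num / den,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
        numerator=num,
        denominator=den,
    )


def diagnostic_metrics(
    counts: ConfusionCounts,
    ci_level: float = 0.95,
    auc: Optional[float] = None,
    auc_ci: Optional[tuple] = None,
    n_excluded_indeterminate: int = 0,
) -> DiagnosticReport:
    """Sensitivity/specificity/PPV/NPV with Clopper-Pearson exact CIs.

    A metric with a zero denominator is reported as undefined rather than
    raising; the others are unaffected.
    """
    c = counts
    return DiagnosticReport(
        counts=c,
        sensitivity=_proportion(c.tp, c.tp + c.fn, ci_level),
        specificity=_proportion(c.tn, c.tn + c.fp, ci_level),
        ppv=_proportion(c.tp, c.tp + c.fp, ci_level),
        npv=_proportion(c.tn, c.tn + c.fn, ci_level),
        auc=auc,
        auc_ci=auc_ci,
        ci_level=ci_level,
        n_excluded_indeterminate=n_excluded_indeterminate,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def empirical_auc(scores: Sequence[float], labels: Sequence) -> float:
    """P(random malignant score > random benign score), ties counting 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos = _as_positive_mask(labels)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateInputError("AUC needs both classes present")
    ranks = _midrank(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def delong_variance(scores: Sequence[float], labels: Sequence) -> float:
    """DeLong variance of the empirical AUC (midrank formulation)."""
    scores = np.asarray(scores, dtype=float)
    pos = _as_positive_mask(labels)
    x, y = scores[pos], scores[~pos]  # malignant, benign
    m, n = len(x), len(y)
    if m == 0 or n == 0:
        raise DegenerateInputError("AUC variance needs both classes present")
    tx = _midrank(x)
    ty = _midrank(y)
    tz = _midrank(np.concatenate([x, y]))
    v10 = (tz[:m] - tx) / n            # placements of malignant scores
    v01 = 1.0 - (tz[m:] - ty) / m      # placements of benign scores
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_auc(
    scores: Sequence[float],
    labels: Sequence,
    ci_level: float = 0.95,
    method: str = "delong",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> tuple[float, tuple]:
    """Empirical AUC with a confidence interval.

    ``method="delong"`` (default) uses the DeLong variance with a normal
    interval clipped to [0, 1]; ``method="bootstrap"`` uses a seeded
    stratified bootstrap percentile interval.
    """
    auc = empirical_auc(scores, labels)
    if method == "delong":
        var = delong_variance(scores, labels)
        z = stats.norm.ppf(0.5 + ci_level / 2.0)
        half = z * math.sqrt(var)
        return auc, (max(0.0, auc - half), min(1.0, auc + half))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        scores = np.asarray(scores, dtype=float)
        pos = _as_positive_mask(labels)
        x, y = scores[pos], scores[~pos]
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            xb = rng.choice(x, size=len(x), replace=True)
            yb = rng.choice(y, size=len(y), replace=True)
            aucs[b] = empirical_auc(
                np.concatenate([xb, yb]), [True] * len(xb) + [False] * len(yb)
            )
        alpha = 1 - ci_level
        lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
        return auc, (float(lo), float(hi))
    raise InvalidArgumentError(f"unknown AUC CI method {method!r}")


def spearman_concordance(x: Sequence[float], y: Sequence[float]) -> ConcordanceResult:
    """Spearman rank correlation between two score vectors (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidArgumentError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return ConcordanceResult(spearman_r=None, n=len(x))
    r, p = stats.spearmanr(x, y)
    return ConcordanceResult(spearman_r=float(r), n=len(x), p_value=float(p))
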