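"""Model/Results interface over CM classification and diagnostic evaluation.

`DiagnosticAccuracy` holds a cohort's cumulative-methylation scores, the
gold-standard truth (histology, or cytology in the pilot design) and
optionally the cytology calls.  `fit()` applies (or selects) the CM
threshold and returns a `DiagnosticAccuracyResults` carrying the confusion
counts, sensitivity/specificity/PPV/NPV with exact CIs, the ROC-AUC with
its DeLong CI, and a `summary()` table.  Assay combination and the
cytology-only evaluation hang off the results object.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import classification as clf
from . import evaluation as ev
from .errors import DegenerateInputError, InvalidArgumentError


class DiagnosticAccuracy:
    """Diagnostic accuracy model for a threshold classifier on CM scores.

    Parameters
    ----------
    score : array-like of float
        Cumulative methylation (CM units), one per evaluable sample.
    truth : array-like
        Gold-standard labels ('malignant'/'benign' or boolean).
    cytology : array-like, optional
        Cytology calls ('malignant'/'benign'/'indeterminate').
    """

    def __init__(self, score, truth, cytology=None):
        self.score = np.asarray(score, dtype=float)
        self.truth = list(truth)
        if len(self.score) != len(self.truth):
            raise InvalidArgumentError("score and truth must have equal length")
        if cytology is not None and len(cytology) != len(self.score):
            raise InvalidArgumentError("cytology must match score length")
        self.cytology = list(cytology) if cytology is not None else None
        pos = ev._as_positive_mask(self.truth)
        if pos.all() or (~pos).all():
            raise DegenerateInputError("both truth classes must be present")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        score: str = "cm",
        truth: str = "histology",
        cytology: Optional[str] = None,
    ) -> "DiagnosticAccuracy":
        cols = [score, truth] + ([cytology] if cytology else [])
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise InvalidArgumentError(f"dataframe missing columns {missing}")
        return cls(
            data[score].to_numpy(),
            data[truth].tolist(),
            data[cytology].tolist() if cytology else None,
        )

    def fit(
        self,
        threshold: Optional[float] = clf.DEFAULT_THRESHOLD,
        min_specificity: float = clf.DEFAULT_MIN_SPECIFICITY,
        ci_level: float = 0.95,
        auc_method: str = "delong",
        seed: Optional[int] = None,
    ) -> "DiagnosticAccuracyResults":
        """Apply the threshold (or select one if ``threshold=None``) and evaluate."""
        if threshold is None:
            threshold = clf.select_threshold(self.score, self.truth, min_specificity)
        config = clf.ClassifierConfig(threshold=max(threshold, 0.0)) if np.isfinite(threshold) and threshold >= 0 else None
        if config is None:
            calls = [clf.MALIGNANT if s > threshold else clf.BENIGN for s in self.score]
        else:
            calls = clf.classify_scores(self.score, config)
        counts = ev.confusion(calls, self.truth)
        auc, auc_ci = ev.roc_auc(self.score, self.truth, ci_level, method=auc_method, seed=seed)
        report = ev.diagnostic_metrics(counts, ci_level, auc=auc, auc_ci=auc_ci)
        return DiagnosticAccuracyResults(self, float(threshold), calls, report, ci_level)


class DiagnosticAccuracyResults:
    """Fitted diagnostic accuracy: calls, metrics with CIs, ROC-AUC."""

    def __init__(self, model, threshold, calls, report, ci_level):
        self.model = model
        self.threshold = threshold
        self.calls = calls
        self.report = report
        self.ci_level = ci_level

    # -- convenience accessors -------------------------------------------
    @property
    def counts(self) -> ev.ConfusionCounts:
        return self.report.counts

    @property
    def sensitivity(self) -> ev.ProportionEstimate:
        return self.report.sensitivity

    @property
    def specificity(self) -> ev.ProportionEstimate:
        return self.report.specificity

    @property
    def ppv(self) -> ev.ProportionEstimate:
        return self.report.ppv

    @property
    def npv(self) -> ev.ProportionEstimate:
        return self.report.npv

    @property
    def auc(self) -> float:
        return self.report.auc

    @property
    def auc_ci(self) -> tuple:
        return self.report.auc_ci

    # -- derived analyses -------------------------------------------------
    def combined_with_cytology(self) -> "DiagnosticAccuracyResults":
        """Evaluate the OR-combination of the molecular call with cytology."""
        if self.model.cytology is None:
            raise InvalidArgumentError("model was built without cytology calls")
        combined = [
            clf.combine_with_cytology(b, c) for b, c in zip(self.calls, self.model.cytology)
        ]
        counts = ev.confusion(combined, self.model.truth)
        report = ev.diagnostic_metrics(counts, self.ci_level)
        out = DiagnosticAccuracyResults(self.model, self.threshold, combined, report, self.ci_level)
        return out

    def cytology_results(self) -> "DiagnosticAccuracyResults":
        """Evaluate cytology alone vs truth, excluding indeterminate reads."""
        if self.model.cytology is None:
            raise InvalidArgumentError("model was built without cytology calls")
        keep = [c != clf.INDETERMINATE for c in self.model.cytology]
        calls = [c for c, k in zip(self.model.cytology, keep) if k]
        truth = [t for t, k in zip(self.model.truth, keep) if k]
        counts = ev.confusion(calls, truth)
        n_excl = len(keep) - sum(keep)
        report = ev.diagnostic_metrics(counts, self.ci_level, n_excluded_indeterminate=n_excl)
        return DiagnosticAccuracyResults(self.model, float("nan"), calls, report, self.ci_level)

    # -- presentation ------------------------------------------------------
    def summary(self, title: str = "Diagnostic accuracy") -> str:
        r = self.report
        lines = [
            title,
            "=" * len(title),
            f"N evaluated: {r.counts.total}"
            + (
                f"   (indeterminate excluded: {r.n_excluded_indeterminate})"
                if r.n_excluded_indeterminate
                else ""
            ),
            f"Threshold:   {self.threshold:g} CM units"
            if np.isfinite(self.threshold)
            else "Threshold:   n/a",
            f"Confusion:   TP={r.counts.tp}  FP={r.counts.fp}  FN={r.counts.fn}  TN={r.counts.tn}",
            "",
            f"{'metric':<14}{'%':>8}  {int(self.ci_level*100)}% CI",
        ]
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            p: ev.ProportionEstimate = getattr(r, name)
            if p.defined:
                lines.append(
                    f"{name:<14}{p.percent:>8.1f}  ({p.ci_low:.1f}-{p.ci_high:.1f})"
                    f"   [{p.numerator}/{p.denominator}]"
                )
            else:
                lines.append(f"{name:<14}{'undefined':>8}")
        if r.auc is not None:
            lines.append(
                f"{'roc_auc':<14}{r.auc:>8.3f}  ({r.auc_ci[0]:.3f}-{r.auc_ci[1]:.3f})"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<DiagnosticAccuracyResults threshold={self.threshold:g} n={self.counts.total}>"
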