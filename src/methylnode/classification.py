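"""CM-score classification: threshold calls, threshold selection, assay combination.

The laboratory threshold for the cumulative methylation score is 8.5 CM
units: a node scoring above 8.5 is called malignant, at or below benign
(the threshold itself is "for benign" and stays benign).  Threshold
selection from labeled data maximises sensitivity subject to a specificity
floor (default 90%), the rule used to set the companion laboratory assay's
cutoff.  The molecular call can be combined with cytology by OR-positivity:
either assay calling malignant makes the combined call malignant;
indeterminate cytology is non-informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, InvalidScoreError, NoFeasibleThresholdError

MALIGNANT = "malignant"
BENIGN = "benign"
INDETERMINATE = "indeterminate"

#: Laboratory CM threshold (benign at or below).
DEFAULT_THRESHOLD = 8.5
#: Specificity floor used when selecting a threshold from labeled data.
DEFAULT_MIN_SPECIFICITY = 0.90


@dataclass(frozen=True)
class ClassifierConfig:
    """Threshold classifier settings.

    ``positive_rule`` is ``"greater"`` (strict, the default: a score equal
    to the threshold stays benign) or ``"greater_equal"``.
    """

    threshold: float = DEFAULT_THRESHOLD
    positive_rule: str = "greater"
    min_specificity: float = DEFAULT_MIN_SPECIFICITY

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise InvalidScoreError(f"threshold must be >= 0, got {self.threshold}")
        if not (0.0 < self.min_specificity < 1.0):
            raise InvalidScoreError(
                f"min_specificity must be in (0, 1), got {self.min_specificity}"
            )
        if self.positive_rule not in ("greater", "greater_equal"):
            raise InvalidScoreError(f"unknown positive_rule {self.positive_rule!r}")


def classify(cm: float, config: ClassifierConfig | None = None) -> str:
    """Call one CM score malignant/benign against the configured threshold."""
    config = config or ClassifierConfig()
    if not math.isfinite(cm) or cm < 0:
        raise InvalidScoreError(f"CM score must be finite and >= 0, got {cm}")
    if config.positive_rule == "greater":
        positive = cm > config.threshold
    else:
        positive = cm >= config.threshold
    return MALIGNANT if positive else BENIGN


def classify_scores(scores: Sequence[float], config: ClassifierConfig | None = None) -> list[str]:
    """Vector form of :func:`classify`."""
    config = config or ClassifierConfig()
    return [classify(s, config) for s in scores]


def _sens_spec_at(threshold: float, scores: np.ndarray, positive: np.ndarray) -> tuple[float, float]:
    calls = scores > threshold
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    sens = float((calls & positive).sum() / n_pos)
    spec = float((~calls & ~positive).sum() / n_neg)
    return sens, spec


def candidate_thresholds(scores: Sequence[float]) -> list[float]:
    """Midpoints between adjacent sorted unique scores, plus -inf/+inf sentinels."""
    uniq = np.unique(np.asarray(scores, dtype=float))
    mids = ((uniq[:-1] + uniq[1:]) / 2.0).tolist()
    return [-math.inf] + mids + [math.inf]


def select_threshold(
    scores: Sequence[float],
    labels: Sequence,
    min_specificity: float = DEFAULT_MIN_SPECIFICITY,
) -> float:
    """Pick the cutoff maximising sensitivity subject to a specificity floor.

    Candidates are midpoints of adjacent unique scores (with +/-inf
    sentinels).  Ties are broken by higher specificity, then lower
    threshold.  Raises if no candidate reaches the floor.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray([lab == MALIGNANT or lab is True or lab == 1 for lab in labels])
    if len(scores) != len(positive):
        raise DegenerateInputError("scores and labels must have equal length")
    if positive.all() or (~positive).all():
        raise DegenerateInputError("both classes must be present to select a threshold")

    best: tuple[float, float, float] | None = None  # (sens, spec, -threshold) to maximise
    best_threshold = None
    for t in candidate_thresholds(scores):
        sens, spec = _sens_spec_at(t, scores, positive)
        if spec < min_specificity:
            continue
        key = (sens, spec, -t)
        if best is None or key > best:
            best = key
            best_threshold = t
    if best_threshold is None:
        raise NoFeasibleThresholdError(
            f"no threshold attains specificity >= {min_specificity}"
        )
    return float(best_threshold)


def combine_with_cytology(bcda_call: str, cytology: str) -> str:
    """OR-positivity combination of the molecular call with cytology.

    Malignant if either assay calls malignant; indeterminate cytology
    contributes nothing (the molecular call stands).
    """
    if bcda_call not in (MALIGNANT, BENIGN):
        raise InvalidScoreError(f"bcda_call must be malignant/benign, got {bcda_call!r}")
    if cytology not in (MALIGNANT, BENIGN, INDETERMINATE):
        raise InvalidScoreError(f"unknown cytology call {cytology!r}")
    if bcda_call == MALIGNANT or cytology == MALIGNANT:
        return MALIGNANT
    return BENIGN
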