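"""Study-design computations: CI-width control and enrollment probability.

Two calculations size a diagnostic accuracy study.  First, a bootstrap
simulation checks that with n subjects per arm the 90% confidence interval
for a proportion near the expected sensitivity/specificity (0.90) has
half-width below 0.1.  Second, with ~50% prevalence among sentinel-node
biopsies, an exact binomial sum gives the probability that enrolling N
subjects yields at least a minimum count in each arm (230 enrolled gives a
95% probability of at least 100 per arm).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError


@dataclass(frozen=True)
class HalfwidthSummary:
    """Distribution of bootstrap CI half-widths across simulated studies."""

    mean: float
    median: float
    p90: float
    n: int
    reps: int
    ci_level: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DesignResult:
    n_per_group: int
    halfwidth_summary: HalfwidthSummary
    enrollment_probability: float

    def to_dict(self) -> dict:
        return {
            "n_per_group": self.n_per_group,
            "halfwidth_summary": self.halfwidth_summary.to_dict(),
            "enrollment_probability": self.enrollment_probability,
        }


def ci_halfwidth_simulation(
    true_rate: float,
    n: int,
    ci_level: float = 0.90,
    n_boot: int = 1000,
    reps: int = 2000,
    seed: Optional[int] = None,
) -> HalfwidthSummary:
    """Simulate the percentile-bootstrap CI half-width for a proportion.

    Per replicate, n Bernoulli(true_rate) outcomes are drawn and the
    proportion is bootstrapped n_boot times; the percentile interval at
    ci_level gives one half-width.  Resampling a binary sample of size n
    with replacement is distributionally identical to drawing
    Binomial(n, phat)/n, which is how the bootstrap is vectorised.
    Fully seeded and reproducible.
    """
    if not 0.0 < true_rate < 1.0:
        raise InvalidArgumentError(f"true_rate must be in (0, 1), got {true_rate}")
    if min(n, n_boot, reps) < 1:
        raise InvalidArgumentError("n, n_boot and reps must all be >= 1")
    rng = np.random.default_rng(seed)
    phat = rng.binomial(n, true_rate, size=reps) / n
    boot = rng.binomial(n, phat[:, None], size=(reps, n_boot)) / n
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0], axis=1)
    halfwidths = (hi - lo) / 2.0
    return HalfwidthSummary(
        mean=float(halfwidths.mean()),
        median=float(np.median(halfwidths)),
        p90=float(np.quantile(halfwidths, 0.90)),
        n=int(n),
        reps=int(reps),
        ci_level=float(ci_level),
    )


def enrollment_probability(total: int, prevalence: float, min_per_arm: int) -> float:
    """Exact probability that both arms reach ``min_per_arm`` of ``total``.

    The malignant-arm count K is Binomial(total, prevalence); the result is
    P(min_per_arm <= K <= total - min_per_arm), zero when infeasible.
    """
    if not 0.0 < prevalence < 1.0:
        raise InvalidArgumentError(f"prevalence must be in (0, 1), got {prevalence}")
    if min_per_arm > total:
        raise InvalidArgumentError("min_per_arm cannot exceed total")
    if 2 * min_per_arm > total:
        return 0.0
    k = np.arange(min_per_arm, total - min_per_arm + 1)
    return float(stats.binom.pmf(k, total, prevalence).sum())


def design_summary(
    true_rate: float = 0.90,
    n_per_group: int = 100,
    total: int = 230,
    prevalence: float = 0.50,
    min_per_arm: int = 100,
    ci_level: float = 0.90,
    n_boot: int = 1000,
    reps: int = 2000,
    seed: Optional[int] = None,
) -> DesignResult:
    """Run both design calculations with the study's default inputs."""
    return DesignResult(
        n_per_group=n_per_group,
        halfwidth_summary=ci_halfwidth_simulation(
            true_rate, n_per_group, ci_level, n_boot, reps, seed
        ),
        enrollment_probability=enrollment_probability(total, prevalence, min_per_arm),
    )
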