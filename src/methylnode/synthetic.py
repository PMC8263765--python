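"""Synthetic calibration plates and Ct-level cohorts.

The study's per-patient data are not public, so the generator emulates the
structure the pipeline expects: an enrollment-scale cohort at roughly 50%
prevalence; benign nodes with cumulative methylation concentrated near
zero (median about 1.5-2 CM units); malignant nodes with broadly elevated,
heterogeneous per-gene methylation, a minority of which carry no
detectable methylated tumor DNA (an FNA can miss tumor cells); a cytology
caller with about 92.5% sensitivity and 95.3% specificity and a small
indeterminate rate; and a small inadequate-DNA rate (12 of 230).

Per-gene methylation in a detectable malignant sample is two-part: a
Bernoulli gate (is this gene methylated in this tumor?) times a scaled
Beta level.  Benign samples draw small exponential per-gene percents with
an optional age drift, plus a rare low-level elevated gene that produces
occasional benign scores above the threshold.  Percent profiles are
inverted through the calibration line to dCt, Ct noise is added, and gene
Ct = ACTB Ct + dCt; targets past the detection limit are undetected.
Everything is driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import dilution_series
from .errors import InvalidArgumentError
from .quantitation import ACTB, DEFAULT_PANEL, split_panel

SUBTYPES = ("ER/PR+HER2-", "ER/PR+HER2+", "ER/PR-HER2+", "ER/PR-HER2-", "unknown")
STAGES = ("I", "II", "III", "IV", "unknown")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-structure parameters for the synthetic cohort generator.

    Defaults encode the prospective study's conditions: 110 malignant and
    120 benign enrolled (230 total, ~50% prevalence), 12/230 inadequate,
    cytology at 92.5%/95.3% with 6/218 indeterminate, benign CM median
    near 1.9 units, and 90.7% of malignant nodes carrying detectable
    methylated tumor DNA.
    """

    panel: tuple = DEFAULT_PANEL
    n_malignant: int = 110
    n_benign: int = 120
    # malignant per-gene methylation (two-part: Bernoulli gate x scaled Beta)
    per_gene_positive_prob: tuple = (0.75, 0.80, 0.60, 0.70, 0.65, 0.55, 0.60, 0.50, 0.70, 0.60)
    malignant_level_params: tuple = (1.2, 2.5)  # Beta shape (a, b) of per-gene fraction
    malignant_detectable_prob: float = 0.907
    # benign background
    benign_scale: float = 0.19          # mean percent per gene; median CM ~1.9
    benign_median_target: float = 1.9   # CM units, documentation/QC target
    benign_outlier_rate: float = 0.01   # rare low-level elevated gene
    benign_outlier_range: tuple = (5.0, 30.0)
    age_model: float = 0.004            # relative benign-scale drift per year from age 50
    # observed-call error models
    cytology_sensitivity: float = 0.925
    cytology_specificity: float = 0.953
    indeterminate_rate: float = 6 / 218
    inadequate_rate: float = 12 / 230
    # Ct synthesis
    calibration_slope: float = -1.0
    calibration_intercept: float = 5.0
    ct_noise_sd: float = 0.25
    actb_ct_mean: float = 25.0
    actb_ct_sd: float = 0.8
    ct_detection_limit: float = 40.0
    plate_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_malignant < 0 or self.n_benign < 0:
            raise InvalidArgumentError("cohort sizes must be nonnegative")
        for p in (
            *self.per_gene_positive_prob,
            self.malignant_detectable_prob,
            self.cytology_sensitivity,
            self.cytology_specificity,
            self.indeterminate_rate,
            self.inadequate_rate,
            self.benign_outlier_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise InvalidArgumentError(f"probability out of [0, 1]: {p}")
        if len(self.per_gene_positive_prob) != len(self.panel):
            raise InvalidArgumentError("per_gene_positive_prob must match panel length")
        if not 0.0 <= self.benign_median_target <= 8.5:
            raise InvalidArgumentError("benign median target must lie in [0, 8.5]")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("panel", "per_gene_positive_prob", "malignant_level_params", "benign_outlier_range"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("panel", "per_gene_positive_prob", "malignant_level_params", "benign_outlier_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """Generated study: long-format Ct table, metadata, and the truth table."""

    ct_table: pd.DataFrame
    metadata: pd.DataFrame
    config: GeneratorConfig

    @property
    def truth(self) -> pd.DataFrame:
        return self.metadata[["sample_id", "histology"]].copy()

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ct_table": outdir / "ct_table.csv",
            "metadata": outdir / "metadata.csv",
            "truth": outdir / "truth.csv",
        }
        self.ct_table.to_csv(paths["ct_table"], index=False)
        self.metadata.to_csv(paths["metadata"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        return paths


# ---------------------------------------------------------------------------
# Percent-level model (shared by the cohort generator and the truth oracle)
# ---------------------------------------------------------------------------


def _benign_percents(cfg: GeneratorConfig, ages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n, k = len(ages), len(cfg.panel)
    scale = cfg.benign_scale * np.clip(1.0 + cfg.age_model * (ages - 50.0), 0.1, None)
    percents = rng.exponential(1.0, size=(n, k)) * scale[:, None]
    outlier = rng.random(n) < cfg.benign_outlier_rate
    if outlier.any():
        idx = np.flatnonzero(outlier)
        genes = rng.integers(0, k, size=len(idx))
        lo, hi = cfg.benign_outlier_range
        percents[idx, genes] += rng.uniform(lo, hi, size=len(idx))
    return np.clip(percents, 0.0, 100.0)


def _malignant_percents(cfg: GeneratorConfig, ages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n, k = len(ages), len(cfg.panel)
    detectable = rng.random(n) < cfg.malignant_detectable_prob
    gate = rng.random((n, k)) < np.asarray(cfg.per_gene_positive_prob)[None, :]
    a, b = cfg.malignant_level_params
    levels = 100.0 * rng.beta(a, b, size=(n, k))
    background = _benign_percents(cfg, ages, rng)
    percents = np.where(detectable[:, None], gate * levels, background)
    return np.clip(percents, 0.0, 100.0)


def percent_level_draw(
    cfg: GeneratorConfig, n_malignant: int, n_benign: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (malignant CM, benign CM) at the percent level, before Ct noise."""
    ages_m = np.full(n_malignant, 50.0)
    ages_b = np.full(n_benign, 50.0)
    cm_mal = _malignant_percents(cfg, ages_m, rng).sum(axis=1)
    cm_ben = _benign_percents(cfg, ages_b, rng).sum(axis=1)
    return cm_mal, cm_ben


def implied_operating_characteristics(
    cfg: GeneratorConfig,
    threshold: float = 8.5,
    n: int = 100_000,
    seed: int = 0,
) -> dict:
    """Generator-truth sensitivity/specificity/AUC at a CM threshold.

    Computed by percent-level Monte Carlo from the configuration alone
    (no Ct synthesis, no pipeline), so it is an independent target for
    parameter-recovery checks on pipeline output.
    """
    rng = np.random.default_rng(seed)
    cm_mal, cm_ben = percent_level_draw(cfg, n, n, rng)
    scores = np.concatenate([cm_mal, cm_ben])
    ranks = pd.Series(scores).rank(method="average").to_numpy()
    auc = (ranks[: len(cm_mal)].sum() - len(cm_mal) * (len(cm_mal) + 1) / 2.0) / (
        len(cm_mal) * len(cm_ben)
    )
    return {
        "sensitivity": float((cm_mal > threshold).mean()),
        "specificity": float((cm_ben <= threshold).mean()),
        "auc": float(auc),
    }


# ---------------------------------------------------------------------------
# Plate and cohort generation
# ---------------------------------------------------------------------------


def generate_calibration_plate(cfg: GeneratorConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Six-point two-fold plate (100% -> 3.125%) per gene with Ct noise.

    Returns the calibration CSV layout: gene, methylated_percent, ct_gene,
    ct_actb.  The underlying line is cfg.calibration_slope/intercept.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    series = dilution_series(100.0, 6, 2.0)
    rows = []
    for gene in cfg.panel:
        for pct in series:
            actb = rng.normal(cfg.actb_ct_mean, cfg.actb_ct_sd)
            dct = (
                cfg.calibration_slope * np.log2(pct / 100.0)
                + cfg.calibration_intercept
                + rng.normal(0.0, cfg.plate_noise_sd)
            )
            rows.append(
                {
                    "gene": gene,
                    "methylated_percent": pct,
                    "ct_gene": round(actb + dct, 4),
                    "ct_actb": round(actb, 4),
                }
            )
    return pd.DataFrame(rows)


def _draw_metadata(
    cfg: GeneratorConfig, truth: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(truth)
    malignant = truth
    age = np.where(
        malignant,
        rng.normal(51.0, 10.0, size=n),
        rng.normal(52.0, 11.0, size=n),
    )
    age = np.clip(np.round(age), 25, 85).astype(int)
    region = np.where(rng.random(n) < 0.85, "China", "US")
    subtype = rng.choice(SUBTYPES, size=n, p=(0.44, 0.19, 0.14, 0.14, 0.09))
    stage = rng.choice(STAGES, size=n, p=(0.18, 0.45, 0.28, 0.02, 0.07))
    positive_nodes = np.where(malignant, 1 + rng.poisson(2.2, size=n), 0)
    # Miller-Payne NAC response grade for ~45% of cancer patients
    has_mp = malignant & (rng.random(n) < 0.45)
    mp_grade = rng.choice([1, 2, 3, 4, 5], size=n, p=(0.10, 0.20, 0.25, 0.25, 0.20))
    miller_payne = np.where(has_mp, mp_grade.astype(str), "")
    nac_responder = np.where(has_mp, np.where(mp_grade >= 4, "yes", "no"), "")
    return pd.DataFrame(
        {
            "age": age,
            "region": region,
            "subtype": subtype,
            "stage": stage,
            "positive_nodes": positive_nodes,
            "miller_payne": miller_payne,
            "nac_responder": nac_responder,
        }
    )


def _draw_cytology(cfg: GeneratorConfig, truth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(truth)
    u = rng.random(n)
    call = np.where(
        truth,
        np.where(u < cfg.cytology_sensitivity, "malignant", "benign"),
        np.where(u < cfg.cytology_specificity, "benign", "malignant"),
    ).astype(object)  # object dtype so the longer "indeterminate" is not truncated
    call[rng.random(n) < cfg.indeterminate_rate] = "indeterminate"
    return call


def _fmt_ct(value: Optional[float]) -> str:
    return "" if value is None else f"{value:.4f}"


def generate_cohort(cfg: GeneratorConfig) -> SyntheticCohort:
    """Generate a full synthetic study: Ct table, metadata, truth.

    Fully determined by cfg.seed; the same config yields byte-identical
    CSVs.  The inadequate-DNA exclusion is applied as an exact count,
    round(inadequate_rate * n), of samples whose ACTB fails to amplify.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_malignant + cfg.n_benign
    set1, set2 = split_panel(cfg.panel)

    truth = np.array([True] * cfg.n_malignant + [False] * cfg.n_benign, dtype=bool)
    rng.shuffle(truth)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    meta = _draw_metadata(cfg, truth, rng)
    ages = meta["age"].to_numpy(dtype=float)

    percents = np.zeros((n, len(cfg.panel)))
    if truth.any():
        percents[truth] = _malignant_percents(cfg, ages[truth], rng)
    if (~truth).any():
        percents[~truth] = _benign_percents(cfg, ages[~truth], rng)

    cytology = _draw_cytology(cfg, truth, rng)

    n_inadequate = int(round(cfg.inadequate_rate * n))
    inadequate_idx = set(rng.choice(n, size=n_inadequate, replace=False).tolist()) if n_inadequate else set()

    ct_rows = []
    for i, sid in enumerate(sample_ids):
        actb = {
            1: rng.normal(cfg.actb_ct_mean, cfg.actb_ct_sd),
            2: rng.normal(cfg.actb_ct_mean, cfg.actb_ct_sd),
        }
        gene_ct: dict[str, Optional[float]] = {}
        for j, gene in enumerate(cfg.panel):
            mset = 1 if gene in set1 else 2
            pct = percents[i, j]
            noise = rng.normal(0.0, cfg.ct_noise_sd)
            if pct <= 0.0:
                gene_ct[gene] = None
                continue
            dct = cfg.calibration_slope * np.log2(pct / 100.0) + cfg.calibration_intercept + noise
            ct = actb[mset] + dct
            gene_ct[gene] = None if ct > cfg.ct_detection_limit else ct
        inadequate = i in inadequate_idx
        for mset, genes in ((1, set1), (2, set2)):
            actb_ct = None if inadequate else actb[mset]
            ct_rows.append(
                {"sample_id": sid, "marker_set": mset, "gene": ACTB, "ct": _fmt_ct(actb_ct)}
            )
            for gene in genes:
                ct_rows.append(
                    {
                        "sample_id": sid,
                        "marker_set": mset,
                        "gene": gene,
                        "ct": _fmt_ct(gene_ct[gene]),
                    }
                )

    ct_table = pd.DataFrame(ct_rows, columns=["sample_id", "marker_set", "gene", "ct"])
    metadata = pd.concat(
        [
            pd.DataFrame(
                {
                    "sample_id": pd.Series(sample_ids, dtype=str),
                    "histology": pd.Series(np.where(truth, "malignant", "benign"), dtype=str),
                    "cytology": pd.Series(cytology, dtype=str),
                }
            ),
            meta,
        ],
        axis=1,
    )
    return SyntheticCohort(ct_table=ct_table, metadata=metadata, config=cfg)
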