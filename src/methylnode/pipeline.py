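"""End-to-end orchestration of the two study workflows.

``prospective`` mode evaluates the molecular call against histology and,
when cytology calls are available, also reports cytology-vs-histology and
the OR-combined assay.  ``pilot`` mode has no histology gold standard and
evaluates the molecular call against cytology, excluding indeterminate
reads.  Every run writes the profile TSV, the per-sample call TSV, the
diagnostic report JSON and a log whose filter ledger accounts for every
input sample: input = evaluated + inadequate (+ indeterminate exclusions
when cytology is the truth).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import calibration as cal
from . import quantitation as qt
from . import subgroups as sg
from .classification import DEFAULT_THRESHOLD, INDETERMINATE, ClassifierConfig, classify_scores
from .errors import ConfigurationError
from .model import DiagnosticAccuracy

logger = logging.getLogger("methylnode")

MODES = ("prospective", "pilot")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    ``calibration`` is "default" (shared ideal-efficiency curves), a plate
    CSV (fit per-gene curves) or a curve-store JSON.  ``truth_column``
    defaults by mode: histology for prospective, cytology for pilot.
    """

    ct_table: str
    metadata: str
    outdir: str
    mode: str = "prospective"
    panel: tuple = qt.DEFAULT_PANEL
    calibration: str = "default"
    threshold: float = DEFAULT_THRESHOLD
    actb_max_ct: float = qt.DEFAULT_ACTB_MAX_CT
    truth_column: Optional[str] = None
    run_subgroups: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.truth_column is None:
            self.truth_column = "histology" if self.mode == "prospective" else "cytology"
        if self.truth_column not in ("histology", "cytology"):
            raise ConfigurationError(
                f"truth_column must be histology or cytology, got {self.truth_column!r}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["panel"] = list(d["panel"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_curves(config: RunConfig) -> dict:
    if config.calibration == "default":
        return cal.default_curves(config.panel)
    path = Path(config.calibration)
    if not path.exists():
        raise ConfigurationError(f"calibration source not found: {path}")
    if path.suffix.lower() == ".json":
        curves = cal.load_curves(path)
    else:
        curves = cal.fit_plate(path)
    missing = [g for g in config.panel if g not in curves]
    if missing:
        raise ConfigurationError(f"calibration source lacks curves for {missing}")
    return curves


def run_pipeline(config: RunConfig) -> dict:
    """Execute read -> validate -> quantify -> classify -> evaluate.

    Returns the run report (also written to ``<outdir>/report.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> dict:
    curves = _load_curves(config)
    records = qt.read_ct_table(config.ct_table, config.panel)
    logger.info("read %d samples from %s", len(records), config.ct_table)

    profiles = qt.quantify_cohort(records, curves, config.actb_max_ct)
    n_input = len(profiles)
    n_inadequate = sum(not p.valid for p in profiles)
    logger.info("adequacy filter: %d input, %d inadequate", n_input, n_inadequate)
    qt.write_profiles(profiles, outdir / "profiles.tsv", config.panel)

    prof_df = qt.profiles_to_frame(profiles, config.panel)
    metadata = pd.read_csv(config.metadata, dtype={"sample_id": str}, keep_default_na=False)
    data = prof_df.merge(metadata, on="sample_id", how="left", validate="one_to_one")
    evaluable = data[data["valid"]].copy()

    clf_config = ClassifierConfig(threshold=config.threshold)
    evaluable["bcda_call"] = classify_scores(evaluable["cm"].tolist(), clf_config)

    n_indeterminate_excluded = 0
    if config.truth_column == "cytology":
        indeterminate = evaluable["cytology"] == INDETERMINATE
        n_indeterminate_excluded = int(indeterminate.sum())
        evaluated = evaluable[~indeterminate]
    else:
        evaluated = evaluable
    n_evaluated = len(evaluated)
    logger.info(
        "evaluated %d samples against %s (indeterminate excluded: %d)",
        n_evaluated,
        config.truth_column,
        n_indeterminate_excluded,
    )

    has_cytology = "cytology" in evaluated.columns and config.truth_column == "histology"
    model = DiagnosticAccuracy(
        evaluated["cm"].to_numpy(),
        evaluated[config.truth_column].tolist(),
        evaluated["cytology"].tolist() if has_cytology else None,
    )
    results = model.fit(threshold=config.threshold, seed=config.seed)

    report = {
        "mode": config.mode,
        "truth_column": config.truth_column,
        "config_hash": config.config_hash(),
        "threshold": config.threshold,
        "filter_ledger": {
            "n_input": n_input,
            "n_inadequate": n_inadequate,
            "n_indeterminate_excluded": n_indeterminate_excluded,
            "n_evaluated": n_evaluated,
        },
        "bcda": results.report.to_dict(),
    }
    if has_cytology:
        report["cytology"] = results.cytology_results().report.to_dict()
        report["combined"] = results.combined_with_cytology().report.to_dict()

    if config.run_subgroups:
        report["subgroups"] = _subgroup_report(evaluated, config, outdir)

    calls = evaluated[["sample_id", "cm", "bcda_call", config.truth_column]].copy()
    if "cytology" in evaluated.columns and config.truth_column != "cytology":
        calls["cytology"] = evaluated["cytology"]
    calls.to_csv(outdir / "calls.tsv", sep="\t", index=False, float_format="%.1f")

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("report written to %s", outdir / "report.json")
    return report


def _subgroup_report(evaluated: pd.DataFrame, config: RunConfig, outdir: Path) -> dict:
    """Standard subgroup scans: CM by truth group, call rate by subtype, age trend."""
    out: dict = {}
    rows = []
    truth = evaluated[config.truth_column]
    res = sg.compare_groups(evaluated["cm"].to_numpy(), truth.to_numpy())
    out["cm_by_truth"] = {"test": res.test, "statistic": res.statistic, "p_value": res.p_value}
    rows.append(("cm_by_truth", len(evaluated), res.statistic, res.p_value))

    malignant = evaluated[truth == "malignant"]
    known = malignant[malignant["subtype"] != "unknown"] if "subtype" in malignant else malignant.iloc[0:0]
    if len(known) and known["subtype"].nunique() >= 2:
        cr = sg.call_rate_table(
            known["bcda_call"].to_numpy(), known["subtype"].to_numpy(), seed=config.seed
        )
        out["call_rate_by_subtype"] = {"p_value": cr.p_value, "method": cr.method,
                                       "table": cr.table.to_dict()}
        rows.append(("call_rate_by_subtype", len(known), float("nan"), cr.p_value))

    benign = evaluated[truth == "benign"]
    if "age" in benign.columns and len(benign) >= 3 and benign["age"].nunique() > 1:
        tr = sg.age_trend(benign["cm"].to_numpy(), benign["age"].to_numpy(dtype=float))
        out["benign_age_trend"] = {
            "slope": tr.slope, "r": tr.r, "p_value": tr.p_value, "n": tr.n,
        }
        rows.append(("benign_age_trend", tr.n, tr.slope, tr.p_value))

    pd.DataFrame(rows, columns=["stratum", "n", "statistic", "p_value"]).to_csv(
        outdir / "subgroups.tsv", sep="\t", index=False
    )
    return out
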