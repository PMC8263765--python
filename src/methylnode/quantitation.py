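"""Per-sample quantitation: Ct panels -> percent methylation -> CM score.

A sample is assayed in two PCR cartridges ("marker sets"), each carrying
five methylated target genes plus the ACTB reference for total amplifiable
DNA.  Each gene's dCt is taken against the ACTB of its own marker set.
Percent methylation per gene comes from the calibration curve; the
cumulative methylation score CM is the sum over the ten-gene panel
(0-1000 "CM units").  Samples whose ACTB fails to amplify (or amplifies
too late) carry inadequate DNA and are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import UNDETECTED, CalibrationCurve
from .errors import AdequacyError, ConfigurationError, FormatError

#: Five markers named for this panel; the remainder of the ten-gene panel is
#: configuration-driven (panel membership is defined by the assay, not here).
DEFAULT_PANEL: tuple[str, ...] = (
    "AKR1B1",
    "APC",
    "COL6A2",
    "HOXB4",
    "RASSF1",
    "GENE06",
    "GENE07",
    "GENE08",
    "GENE09",
    "GENE10",
)

ACTB = "ACTB"

#: ACTB adequacy cutoff in cycles (boundary inclusive).
DEFAULT_ACTB_MAX_CT = 40.0

INADEQUATE_DNA = "inadequate DNA"


@dataclass(frozen=True)
class CtPanelRecord:
    """One sample's raw Ct values: two marker sets of 5 genes + ACTB each.

    ``None`` encodes an undetected (no-amplification) target.
    """

    sample_id: str
    marker_set_1: Mapping[str, Optional[float]]
    actb_1: Optional[float]
    marker_set_2: Mapping[str, Optional[float]]
    actb_2: Optional[float]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.marker_set_1) + tuple(self.marker_set_2)


@dataclass(frozen=True)
class AdequacyDecision:
    valid: bool
    reason: str = ""


@dataclass(frozen=True)
class MethylationProfile:
    """Per-gene percent methylation and the cumulative methylation score.

    Invalid (inadequate-DNA) profiles carry ``cm = None`` and a reason.
    """

    sample_id: str
    per_gene_percent: Mapping[str, float] = field(default_factory=dict)
    cm: Optional[float] = None
    valid: bool = True
    invalid_reason: str = ""


def split_panel(panel: Sequence[str]) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Partition the 10-gene panel into its two 5-gene marker sets."""
    if len(panel) != 10 or len(set(panel)) != 10:
        raise ConfigurationError(f"panel must contain 10 distinct genes, got {list(panel)}")
    return tuple(panel[:5]), tuple(panel[5:])


def read_ct_table(path, panel: Sequence[str] = DEFAULT_PANEL) -> list[CtPanelRecord]:
    """Parse a long-format Ct CSV into one record per sample.

    Expected columns: ``sample_id, marker_set, gene, ct`` with an empty ``ct``
    field (or the sentinels ND/Undetermined) for undetected targets.  Each
    sample needs an ACTB row per marker set.  Row order determines record
    order; errors name the offending row.
    """
    set1, set2 = split_panel(panel)
    gene_to_set = {g: 1 for g in set1} | {g: 2 for g in set2}
    df = pd.read_csv(path, dtype={"sample_id": str, "gene": str}, keep_default_na=False)
    required = {"sample_id", "marker_set", "gene", "ct"}
    if not required.issubset(df.columns):
        raise FormatError(f"Ct table missing columns: {sorted(required - set(df.columns))}")

    undetected_sentinels = {"", "ND", "NA", "Undetermined"}
    # Per-sample accumulation preserving first-appearance order.
    samples: dict[str, dict] = {}
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        sid, mset, gene, ct_raw = str(row.sample_id), int(row.marker_set), str(row.gene), str(row.ct)
        if gene != ACTB and gene not in gene_to_set:
            raise FormatError(f"row {idx}: gene {gene!r} not in configured panel")
        if gene != ACTB and gene_to_set[gene] != mset:
            raise FormatError(f"row {idx}: gene {gene!r} assigned to wrong marker set {mset}")
        ct: Optional[float]
        if ct_raw.strip() in undetected_sentinels:
            ct = None
        else:
            ct = float(ct_raw)
            if not np.isfinite(ct) or ct <= 0:
                raise FormatError(f"row {idx}: Ct must be positive and finite, got {ct_raw}")
        rec = samples.setdefault(sid, {"set1": {}, "set2": {}, "actb": {1: "missing", 2: "missing"}})
        if gene == ACTB:
            if rec["actb"][mset] != "missing":
                raise FormatError(f"row {idx}: duplicate ACTB for sample {sid} marker set {mset}")
            rec["actb"][mset] = ct
        else:
            target = rec["set1"] if mset == 1 else rec["set2"]
            if gene in target:
                raise FormatError(f"row {idx}: duplicate ({sid}, {gene})")
            target[gene] = ct

    records = []
    for sid, rec in samples.items():
        for mset in (1, 2):
            if rec["actb"][mset] == "missing":
                raise FormatError(f"sample {sid}: missing ACTB row for marker set {mset}")
        missing_genes = (set(set1) - set(rec["set1"])) | (set(set2) - set(rec["set2"]))
        if missing_genes:
            raise FormatError(f"sample {sid}: missing gene rows {sorted(missing_genes)}")
        records.append(
            CtPanelRecord(
                sample_id=sid,
                marker_set_1={g: rec["set1"][g] for g in set1},
                actb_1=rec["actb"][1],
                marker_set_2={g: rec["set2"][g] for g in set2},
                actb_2=rec["actb"][2],
            )
        )
    return records


def validate_sample(record: CtPanelRecord, actb_max_ct: float = DEFAULT_ACTB_MAX_CT) -> AdequacyDecision:
    """DNA adequacy: both marker sets' ACTB detected at or before the cutoff."""
    for actb in (record.actb_1, record.actb_2):
        if actb is UNDETECTED or actb > actb_max_ct:
            return AdequacyDecision(valid=False, reason=INADEQUATE_DNA)
    return AdequacyDecision(valid=True)


def quantify_profile(
    record: CtPanelRecord,
    curves: Mapping[str, CalibrationCurve],
    actb_max_ct: float = DEFAULT_ACTB_MAX_CT,
) -> MethylationProfile:
    """Convert one valid Ct record into a methylation profile.

    Each gene's dCt uses the ACTB of its own marker set; undetected targets
    quantify as 0%.  CM is the sum over the ten-gene panel.
    """
    decision = validate_sample(record, actb_max_ct)
    if not decision.valid:
        raise AdequacyError(f"sample {record.sample_id}: {decision.reason}")
    missing = [g for g in record.genes if g not in curves]
    if missing:
        raise ConfigurationError(f"no calibration curve for genes {missing}")

    percents: dict[str, float] = {}
    for mset, actb in ((record.marker_set_1, record.actb_1), (record.marker_set_2, record.actb_2)):
        for gene, ct in mset.items():
            dct = None if ct is UNDETECTED else ct - actb
            percents[gene] = curves[gene].percent_methylation(dct)
    return MethylationProfile(
        sample_id=record.sample_id,
        per_gene_percent=percents,
        cm=float(sum(percents.values())),
    )


def quantify_cohort(
    records: Sequence[CtPanelRecord],
    curves: Mapping[str, CalibrationCurve],
    actb_max_ct: float = DEFAULT_ACTB_MAX_CT,
) -> list[MethylationProfile]:
    """Quantify every adequate record; inadequate ones become invalid profiles."""
    profiles = []
    for rec in records:
        decision = validate_sample(rec, actb_max_ct)
        if decision.valid:
            profiles.append(quantify_profile(rec, curves, actb_max_ct))
        else:
            profiles.append(
                MethylationProfile(
                    sample_id=rec.sample_id, valid=False, invalid_reason=decision.reason
                )
            )
    return profiles


def profiles_to_frame(
    profiles: Sequence[MethylationProfile], panel: Sequence[str] = DEFAULT_PANEL
) -> pd.DataFrame:
    """Tabulate profiles: sample_id, one column per gene, cm, valid, invalid_reason."""
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id}
        for g in panel:
            row[g] = p.per_gene_percent.get(g, np.nan)
        row["cm"] = np.nan if p.cm is None else p.cm
        row["valid"] = p.valid
        row["invalid_reason"] = p.invalid_reason
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles(profiles: Sequence[MethylationProfile], path, panel: Sequence[str] = DEFAULT_PANEL) -> None:
    """Write the profile TSV; CM and percents rendered to one decimal place."""
    df = profiles_to_frame(profiles, panel)
    df.to_csv(path, sep="\t", index=False, float_format="%.1f")
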