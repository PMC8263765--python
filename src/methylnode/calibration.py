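"""Standard-curve calibration for methylation-specific qPCR.

The assay reports, per gene, a cycle-threshold difference
``dCt = Ct(gene) - Ct(ACTB)`` between the methylated target and the
beta-actin reference amplified from the same bisulfite-converted DNA.
Calibration plates measure dCt on mixtures of fully methylated and
unmethylated DNA in a two-fold dilution series (100% down to 3.12%
methylated).  Because the series is two-fold, the natural model is linear
in log2 of the methylated fraction:

    dCt(f) = slope * log2(f) + intercept

with slope near -1 for an ideally efficient PCR (halving the methylated
template costs one cycle).  Inverting the fitted line converts a sample's
dCt into percent methylation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InsufficientCalibrationError,
    InvalidArgumentError,
    InvalidMeasurementError,
)

#: Sentinel for "no amplification observed" (scalar API). Mapped to 0%.
UNDETECTED = None

#: Ideal-efficiency default used when no per-gene plate is available.
DEFAULT_SLOPE = -1.0
DEFAULT_INTERCEPT = 5.0


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration well: known methylated fraction and its observed dCt."""

    methylated_fraction: float
    delta_ct: float

    def __post_init__(self) -> None:
        if not (0.0 < self.methylated_fraction <= 1.0):
            raise InvalidArgumentError(
                f"methylated_fraction must be in (0, 1], got {self.methylated_fraction}"
            )
        if not math.isfinite(self.delta_ct):
            raise InvalidArgumentError(f"delta_ct must be finite, got {self.delta_ct}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted per-gene mapping between dCt and log2 methylated fraction.

    Attributes
    ----------
    gene : str
        Marker name.
    slope : float
        Cycles per log2-unit of methylated fraction; negative (more
        methylated template amplifies earlier).
    intercept : float
        dCt at fraction 1 (100% methylated).
    points : tuple of CalibrationPoint
        The wells the curve was fitted to (empty for default curves).
    residual_rms : float
        Root-mean-square of fit residuals, in cycles.
    """

    gene: str
    slope: float
    intercept: float
    points: tuple = field(default=())
    residual_rms: float = 0.0

    def delta_ct_at(self, fraction: float) -> float:
        """Forward model: expected dCt at a methylated fraction in (0, 1]."""
        if not 0.0 < fraction <= 1.0:
            raise InvalidArgumentError(f"fraction must be in (0, 1], got {fraction}")
        return self.slope * math.log2(fraction) + self.intercept

    def percent_methylation(self, delta_ct) -> float:
        """Invert the curve: dCt -> percent methylation, clamped to [0, 100].

        ``UNDETECTED`` (None) means no amplification of the methylated
        target and maps to 0% by convention.
        """
        if delta_ct is UNDETECTED:
            return 0.0
        delta_ct = float(delta_ct)
        if not math.isfinite(delta_ct):
            raise InvalidMeasurementError(f"non-finite delta_ct: {delta_ct}")
        fraction = 2.0 ** ((delta_ct - self.intercept) / self.slope)
        return float(min(max(fraction * 100.0, 0.0), 100.0))


def dilution_series(start_percent: float, n_points: int, fold: float = 2.0) -> list[float]:
    """Geometric dilution series descending from ``start_percent``.

    The standard plate layout is ``dilution_series(100, 6, 2)`` =
    [100, 50, 25, 12.5, 6.25, 3.125], whose low endpoint displays as 3.12.
    Values are returned at full precision; use :func:`display_series` for
    the two-decimal display form.
    """
    if start_percent <= 0:
        raise InvalidArgumentError(f"start_percent must be > 0, got {start_percent}")
    if fold <= 1:
        raise InvalidArgumentError(f"fold must be > 1, got {fold}")
    if n_points < 2:
        raise InvalidArgumentError(f"n_points must be >= 2, got {n_points}")
    return [start_percent / fold**k for k in range(n_points)]


def display_series(series: Iterable[float]) -> list[float]:
    """Round a dilution series to two decimals for display/reporting."""
    return [round(v, 2) for v in series]


def fit_standard_curve(points: Sequence[CalibrationPoint], gene: str = "") -> CalibrationCurve:
    """Ordinary least squares of dCt on log2(methylated fraction).

    Requires at least three points with distinct fractions; deterministic.
    """
    points = tuple(points)
    fractions = np.array([p.methylated_fraction for p in points], dtype=float)
    if len(points) < 3 or len(np.unique(fractions)) < 2:
        raise InsufficientCalibrationError(
            f"need >= 3 calibration points with distinct fractions for {gene or 'curve'}, "
            f"got {len(points)} points / {len(np.unique(fractions)) if len(points) else 0} distinct"
        )
    x = np.log2(fractions)
    y = np.array([p.delta_ct for p in points], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    rms = float(np.sqrt(np.mean(resid**2)))
    return CalibrationCurve(
        gene=gene, slope=float(slope), intercept=float(intercept), points=points, residual_rms=rms
    )


def default_curves(panel: Sequence[str]) -> dict[str, CalibrationCurve]:
    """Shared ideal-efficiency curve (slope -1, intercept 5) for each gene.

    Used for synthetic work when per-gene calibration plates are absent.
    """
    return {
        g: CalibrationCurve(gene=g, slope=DEFAULT_SLOPE, intercept=DEFAULT_INTERCEPT)
        for g in panel
    }


# ---------------------------------------------------------------------------
# Plate I/O
# ---------------------------------------------------------------------------

PLATE_COLUMNS = ("gene", "methylated_percent", "ct_gene", "ct_actb")


def read_plate(path) -> dict[str, list[CalibrationPoint]]:
    """Read a calibration plate CSV (gene, methylated_percent, ct_gene, ct_actb)."""
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"plate file missing columns: {sorted(missing)}")
    plate: dict[str, list[CalibrationPoint]] = {}
    for _, row in df.iterrows():
        point = CalibrationPoint(
            methylated_fraction=float(row["methylated_percent"]) / 100.0,
            delta_ct=float(row["ct_gene"]) - float(row["ct_actb"]),
        )
        plate.setdefault(str(row["gene"]), []).append(point)
    return plate


def fit_plate(path) -> dict[str, CalibrationCurve]:
    """Fit a standard curve per gene from a plate CSV."""
    return {g: fit_standard_curve(pts, gene=g) for g, pts in read_plate(path).items()}


def save_curves(curves: Mapping[str, CalibrationCurve], path) -> None:
    """Serialize a curve store as JSON keyed by gene."""
    payload = {
        g: {"slope": c.slope, "intercept": c.intercept, "residual_rms": c.residual_rms}
        for g, c in curves.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_curves(path) -> dict[str, CalibrationCurve]:
    """Load a JSON curve store written by :func:`save_curves`."""
    with open(path) as fh:
        payload = json.load(fh)
    return {
        g: CalibrationCurve(
            gene=g,
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            residual_rms=float(d.get("residual_rms", 0.0)),
        )
        for g, d in payload.items()
    }
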