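"""Internal-standard recovery calibration and RSD-based variable filtering.

Matrix effects make extraction recovery vary sample to sample, so raw peak
intensities do not track the spiked concentration.  Two deuterated
internal standards spiked into every sample are quantified against
matrix-matched calibration curves; their combined recovery (harmonic mean)
summarises each sample's losses.  Each concentration group's intensities
are multiplied by a calibration coefficient kappa = 100 / mean(combined
recovery) so the group-average recovery becomes 100%.  Variables are then
required to be reproducible: relative standard deviation of calibrated
intensity strictly below a threshold (default 30%) within the QC group and
within every concentration group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import QC_GROUP, FeatureTable
from .datasets import IS_NOMINAL_NG_ML, CurveData

__all__ = [
    "LineFit",
    "RecoveryRecord",
    "CalibratedTable",
    "fit_is_curve",
    "is_recovery",
    "combined_recovery",
    "recoveries_from_table",
    "calibrate",
    "rsd_filter",
]


@dataclass(frozen=True)
class LineFit:
    """Ordinary least-squares line: area = slope * level + intercept."""

    slope: float
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class RecoveryRecord:
    """Per-sample internal-standard recoveries (percent)."""

    sample_id: str
    r_is1: float
    r_is2: float
    r_combined: float
    group: str


@dataclass
class CalibratedTable:
    """A feature table after recovery calibration, plus the filter report."""

    table: FeatureTable
    kappa: dict[str, float]
    filter_report: pd.DataFrame | None = None

    @property
    def intensities(self) -> pd.DataFrame:
        return self.table.intensities


def fit_is_curve(curve: CurveData) -> LineFit:
    """Least-squares line through a calibration curve."""
    levels, areas = curve.levels, curve.areas
    if len(levels) < 2 or np.ptp(levels) == 0:
        raise ValueError("curve fit needs at least two distinct levels")
    res = stats.linregress(levels, areas)
    return LineFit(float(res.slope), float(res.intercept), float(res.rvalue) ** 2)


def is_recovery(area: float, fit: LineFit, nominal: float) -> float:
    """Recovery (%) of an internal standard from its peak area.

    The measured concentration is read off the calibration line and
    expressed relative to the nominal spiked level.
    """
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    if fit.slope == 0:
        raise ValueError("calibration slope must be nonzero")
    measured = (area - fit.intercept) / fit.slope
    return 100.0 * measured / nominal


def combined_recovery(r1: float, r2: float) -> float:
    """Harmonic mean of the two internal-standard recoveries (percent)."""
    if r1 <= 0 or r2 <= 0:
        raise ValueError("recoveries must be positive")
    return 2.0 / (1.0 / r1 + 1.0 / r2)


def recoveries_from_table(
    table: FeatureTable,
    fits: tuple[LineFit, LineFit],
    nominal: float = IS_NOMINAL_NG_ML,
) -> list[RecoveryRecord]:
    """Compute per-sample recoveries from the internal-standard rows.

    Expects exactly two internal-standard variables in the table (in row
    order: first standard, second standard).  QC columns are skipped —
    they are calibrated with the mean group coefficient instead.
    """
    is_ids = list(table.internal_standard_ids)
    if len(is_ids) != 2:
        raise ValueError(f"expected 2 internal-standard variables, found {len(is_ids)}")
    records = []
    for sid in table.sample_ids:
        group = table.samples.loc[sid, "group"]
        if group == QC_GROUP:
            continue
        r1 = is_recovery(table.intensities.loc[is_ids[0], sid], fits[0], nominal)
        r2 = is_recovery(table.intensities.loc[is_ids[1], sid], fits[1], nominal)
        records.append(RecoveryRecord(sid, r1, r2, combined_recovery(r1, r2), group))
    return records


def calibrate(
    table: FeatureTable,
    recoveries: list[RecoveryRecord],
    per_sample: bool = False,
) -> CalibratedTable:
    """Rescale intensities so each group's mean combined recovery is 100%.

    Per group, kappa = 100 / mean(combined recovery); all intensities of
    that group's samples are multiplied by kappa.  QC columns are
    multiplied by the mean kappa across concentration groups.  With
    ``per_sample=True`` each sample is instead rescaled by its own
    100 / combined recovery.
    """
    by_sample = {r.sample_id: r for r in recoveries}
    out = table.copy()
    groups = table.concentration_groups()
    for sid in table.sample_ids:
        if table.samples.loc[sid, "group"] != QC_GROUP and sid not in by_sample:
            raise ValueError(f"no recovery record for sample {sid!r}")

    kappa: dict[str, float] = {}
    for g in groups:
        rs = [r.r_combined for r in recoveries if r.group == g]
        if not rs:
            raise ValueError(f"no recovery records for group {g!r}")
        kappa[g] = 100.0 / float(np.mean(rs))

    for sid in table.sample_ids:
        g = table.samples.loc[sid, "group"]
        if g == QC_GROUP:
            factor = float(np.mean(list(kappa.values())))
        elif per_sample:
            factor = 100.0 / by_sample[sid].r_combined
        else:
            factor = kappa[g]
        out.intensities[sid] = out.intensities[sid] * factor
    return CalibratedTable(out, kappa)


def _group_rsd(block: pd.DataFrame) -> pd.Series:
    """Per-variable RSD (%) across a group's columns; sample sd (n-1)."""
    mean = block.mean(axis=1)
    sd = block.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / mean
    return rsd.where(mean != 0, np.inf)


def rsd_filter(calibrated: CalibratedTable, threshold: float = 30.0) -> CalibratedTable:
    """Keep variables reproducible in QC and in every concentration group.

    A variable is kept iff its RSD is strictly below ``threshold`` in the
    QC group and in each concentration group.  Internal-standard variables
    are always retained (they are excluded from ranking downstream, not
    candidates).  The returned filter report lists per-group RSDs and the
    keep/drop decision for every variable.
    """
    table = calibrated.table
    check_groups = table.concentration_groups() + (
        [QC_GROUP] if len(table.group_samples(QC_GROUP)) else []
    )
    rsds = {}
    for g in check_groups:
        cols = table.group_samples(g)
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        rsds[f"rsd_{g}"] = _group_rsd(table.intensities[cols])
    report = pd.DataFrame(rsds)
    keep = (report < threshold).all(axis=1)
    is_standard = table.variables["role"].eq("internal_standard")
    keep = keep | is_standard
    report["kept"] = keep

    kept_table = table.subset(table.variable_ids[keep])
    return CalibratedTable(kept_table, dict(calibrated.kappa), filter_report=report)
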