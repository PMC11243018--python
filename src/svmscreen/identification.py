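"""Accurate-mass identification, screening rates and detection limits.

An eligible variable is assigned to a library compound when its observed
m/z lies within a ppm tolerance (default |error| < 5 ppm) of the
compound's exact [M+H]+ mass and its retention time within an absolute
window (default 0.25 min).  Among multiple candidates the smallest
|ppm error| wins, ties broken by the smallest |delta RT|.  Eligible
variables that match nothing are reported as unknowns — matrix or
impurity features needing further study.

Detection limits follow the EPA method-detection-limit procedure: the
intensity of each of n low-level spiked replicates is converted to a
concentration via c_i = I_i * spike_level / mean(I), and
LOD = t(0.99, n-1) * sd(c), converted to ug/kg with the sample
preparation factor (extract volume / sample mass).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CompoundLibrary, FeatureTable

__all__ = [
    "ppm_error",
    "match_markers",
    "screening_rate",
    "lod_estimate",
    "screen_blank",
]


def ppm_error(observed: float, reference: float) -> float:
    """Signed mass error in parts per million: 1e6 * (obs - ref) / ref."""
    if reference <= 0:
        raise ValueError("reference mass must be positive")
    return 1e6 * (observed - reference) / reference


def match_markers(
    variables: pd.DataFrame,
    library: CompoundLibrary,
    ppm_tol: float = 5.0,
    rt_tol: float = 0.25,
) -> tuple[pd.DataFrame, list[str]]:
    """Match variables to library compounds by accurate mass and RT.

    ``variables`` is indexed by variable id with ``mz`` and ``rt_min``
    columns (typically the eligible subset of a feature table's variable
    metadata).  Returns the hit table (one best hit per variable) and the
    list of unmatched variable ids.
    """
    if len(library) == 0:
        raise ValueError("compound library is empty")
    lib = library.records
    hits = []
    unmatched = []
    for vid, row in variables.iterrows():
        err = 1e6 * (row["mz"] - lib["exact_mass"]) / lib["exact_mass"]
        drt = row["rt_min"] - lib["rt_min"]
        ok = (err.abs() < ppm_tol) & (drt.abs() <= rt_tol)
        if not ok.any():
            unmatched.append(vid)
            continue
        cand = lib[ok].assign(mass_error_ppm=err[ok], delta_rt_min=drt[ok])
        cand = cand.sort_values(
            by=["mass_error_ppm", "delta_rt_min"],
            key=lambda s: s.abs(),
            kind="mergesort",
        )
        best = cand.iloc[0]
        hits.append(
            {
                "variable_id": vid,
                "compound": best["name"],
                "category": best["category"],
                "observed_mz": row["mz"],
                "reference_mass": best["exact_mass"],
                "mass_error_ppm": best["mass_error_ppm"],
                "rt_min": row["rt_min"],
                "delta_rt_min": best["delta_rt_min"],
            }
        )
    cols = [
        "variable_id",
        "compound",
        "category",
        "observed_mz",
        "reference_mass",
        "mass_error_ppm",
        "rt_min",
        "delta_rt_min",
    ]
    return pd.DataFrame(hits, columns=cols), unmatched


def _distinct_compounds(hits) -> int:
    if isinstance(hits, int):
        return hits
    if len(hits) == 0:
        return 0
    key = hits.assign(_k=hits["compound"].str.lower())
    return len(key.drop_duplicates(subset=["_k", "reference_mass"]))


def screening_rate(hits, library_size: int) -> float:
    """Percent of the library recovered: 100 * distinct matches / size.

    ``hits`` may be a hit table or a pre-counted number of distinct
    matched compounds.
    """
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return 100.0 * _distinct_compounds(hits) / library_size


def lod_estimate(
    replicate_intensities,
    spike_level: float = 20.0,
    sample_mass_g: float = 2.0,
    extract_volume_ml: float = 1.0,
    confidence: float = 0.99,
) -> float:
    """Method detection limit (ug/kg) from replicate low-level spikes.

    Replicate intensities are converted to concentrations relative to
    their mean (which corresponds to the nominal spike level, ng/mL);
    the LOD is the one-sided Student-t multiple of their standard
    deviation at the given confidence (t = 3.143 for 7 replicates at
    99%), scaled by the preparation factor extract volume / sample mass.
    """
    intensities = np.asarray(replicate_intensities, dtype=float)
    n = len(intensities)
    if n < 2:
        raise ValueError("LOD needs at least two replicates")
    mean = intensities.mean()
    if mean <= 0:
        raise ValueError("mean replicate intensity must be positive")
    conc = intensities * spike_level / mean
    t = stats.t.ppf(confidence, n - 1)
    lod_ng_ml = t * conc.std(ddof=1)
    return float(lod_ng_ml * extract_volume_ml / sample_mass_g)


def screen_blank(blank_table: FeatureTable, library: CompoundLibrary, **kwargs) -> int:
    """Run the full screening pipeline on a blank table; count library hits.

    A matrix blank contains no spiked compounds, so the expected hit
    count is zero; any hit is a false positive.
    """
    from .pipeline import run_pipeline_on_table  # local import: avoids cycle

    report = run_pipeline_on_table(blank_table, library, strict=False, **kwargs)
    return _distinct_compounds(report.hits)
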