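"""End-to-end orchestration of the screening workflow.

Stages: recovery calibration and RSD filtering; PCA / hierarchical
clustering diagnostics; per one-vs-rest contrast (lowest group vs rest,
highest group vs rest) SMOTE balancing, OPLS-DA with a permutation
validity check and VIP selection, RBF-SVM tuning and SVM-RFE ranking,
and the retained weight-table prefix; consensus of the two prefixes;
univariate confirmation (pairwise Welch t-tests, fold changes); and
accurate-mass identification against the compound library with screening
rates and LODs.

All randomness flows from one master seed through per-stage derived
seeds, so a rerun with the same configuration is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import identification, multivariate, preprocess, selection
from .balance import smote_balance
from .containers import CompoundLibrary, FeatureTable, GroundTruth
from .datasets import (
    SyntheticConfig,
    generate_is_curve,
    generate_spiked_dataset,
)
from .svm_ranking import cv_accuracy, grid_search_rbf, svmrfe_rank

__all__ = [
    "PipelineConfig",
    "ScreeningReport",
    "ModelValidityError",
    "run_pipeline",
    "run_pipeline_on_table",
]

log = logging.getLogger("svmscreen")


class ModelValidityError(RuntimeError):
    """An OPLS-DA model failed its permutation-test validity rules."""


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for one pipeline run.

    Exactly one of ``synthetic`` or the three input paths must be set.
    """

    synthetic: SyntheticConfig | None = None
    table_path: str | None = None
    samples_path: str | None = None
    library_path: str | None = None

    rsd_threshold: float = 30.0
    vip_threshold: float = 1.0
    p_threshold: float = 0.05
    fc_threshold: float = 2.0
    ppm_tol: float = 5.0
    rt_tol: float = 0.25
    n_permutations: int = 200
    opls_cv_folds: int = 7
    n_orthogonal: int = 1
    grid_folds: int = 3
    final_cv_folds: int = 10
    final_cv_repeats: int = 10
    smote_k: int = 5
    smote_for_svm: bool = True
    seed: int = 0
    outdir: str | None = None
    strict: bool = True
    blank_check: bool = True  # synthetic runs only

    def __post_init__(self) -> None:
        paths = (self.table_path, self.samples_path, self.library_path)
        has_paths = any(p is not None for p in paths)
        if (self.synthetic is None) == (not has_paths):
            raise ValueError(
                "configure exactly one input: a synthetic block or file paths"
            )
        if has_paths and not all(p is not None for p in paths):
            raise ValueError("file input needs table, samples and library paths")
        for name in (
            "rsd_threshold", "vip_threshold", "p_threshold", "fc_threshold",
            "ppm_tol", "rt_tol",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ContrastArtifacts:
    """Everything one one-vs-rest contrast produced."""

    result: selection.ContrastResult
    model: multivariate.OplsModel
    perm: multivariate.PermResult
    balanced_size: int


@dataclass
class ScreeningReport:
    """Final pipeline output."""

    hits: pd.DataFrame
    unmatched: list[str]
    eligible: selection.EligibleSet
    contrasts: dict[str, ContrastArtifacts]
    consensus: set[str]
    rate_weight: float
    rate_vip: float
    hits_vip: pd.DataFrame
    calibrated: preprocess.CalibratedTable
    pca: multivariate.PcaModel | None = None
    marker_recall: float | None = None
    vip_marker_recall: float | None = None
    blank_hits: int | None = None


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _calibrate_and_filter(
    table: FeatureTable,
    is_slopes: tuple[float, float],
    rsd_threshold: float,
) -> preprocess.CalibratedTable:
    fits = tuple(
        preprocess.fit_is_curve(generate_is_curve(slope=s)) for s in is_slopes
    )
    recov = preprocess.recoveries_from_table(table, fits)
    calibrated = preprocess.calibrate(table, recov)
    filtered = preprocess.rsd_filter(calibrated, rsd_threshold)
    log.info(
        "calibration: kappa=%s; RSD filter kept %d/%d variables",
        {g: round(k, 4) for g, k in filtered.kappa.items()},
        filtered.table.n_variables,
        table.n_variables,
    )
    return filtered


def _run_contrast(
    calibrated: preprocess.CalibratedTable,
    target_group: str,
    label: str,
    cfg: PipelineConfig,
    seeds: list[int],
) -> ContrastArtifacts:
    table = calibrated.table
    feat_ids = table.feature_ids
    spiked = [
        s for s in table.sample_ids if table.samples.loc[s, "group"] != "QC"
    ]
    x = table.intensities.loc[feat_ids, spiked].T  # samples x variables
    y = np.where(table.samples.loc[spiked, "group"] == target_group, "one", "rest")

    bal = smote_balance(x, y, k=cfg.smote_k, seed=seeds[0])
    xs = multivariate.scale(pd.DataFrame(bal.x, columns=feat_ids))
    model = multivariate.oplsda_fit(xs, bal.y, cfg.n_orthogonal, cfg.opls_cv_folds)
    perm = multivariate.permutation_test(
        xs, bal.y, cfg.n_permutations, seeds[1], cfg.n_orthogonal, cfg.opls_cv_folds
    )
    log.info(
        "%s: R2Y=%.3f Q2=%.3f; permutation intercepts R2=%.3f Q2=%.3f p=%.4f",
        label, model.r2y, model.q2, perm.r2_intercept, perm.q2_intercept, perm.p_value,
    )
    if not perm.overfit_free:
        msg = (
            f"contrast {label}: permutation test indicates over-fitting "
            f"(Q2 intercept {perm.q2_intercept:.3f}, p {perm.p_value:.4f})"
        )
        if cfg.strict:
            raise ModelValidityError(msg)
        log.warning(msg)
    elif not perm.valid:
        log.warning(
            "%s: R2Y intercept %.3f exceeds the 0.4 experience bound "
            "(expected when variables far outnumber samples)",
            label, perm.r2_intercept,
        )

    vip_ids = [v for v, s in zip(feat_ids, model.vip) if s > cfg.vip_threshold]

    if cfg.smote_for_svm:
        x_svm, y_svm = bal.x, bal.y
    else:
        x_svm, y_svm = x.to_numpy(), y
    xs_svm = multivariate.scale(x_svm).x
    tuning = grid_search_rbf(xs_svm, y_svm, folds=cfg.grid_folds, seed=seeds[2])
    tuning.cv10_accuracy = cv_accuracy(
        xs_svm, y_svm, tuning.c, tuning.g,
        folds=cfg.final_cv_folds, repeats=cfg.final_cv_repeats, seed=seeds[3],
    )
    log.info(
        "%s: best (c, g) = (%g, %g), 10-fold CV accuracy %.1f%%",
        label, tuning.c, tuning.g, tuning.cv10_accuracy,
    )
    weights = svmrfe_rank(pd.DataFrame(xs_svm, columns=feat_ids), y_svm, tuning)
    result = selection.retained_prefix(vip_ids, weights, label)
    log.info(
        "%s: %d VIP>%g variables in a %d-variable prefix (overlap %.1f%%)",
        label, len(vip_ids), cfg.vip_threshold, len(result.prefix),
        result.overlap if result.prefix else float("nan"),
    )
    return ContrastArtifacts(result, model, perm, balanced_size=len(bal.y))


def run_pipeline_on_table(
    table: FeatureTable,
    library: CompoundLibrary,
    truth: GroundTruth | None = None,
    is_slopes: tuple[float, float] = (120.0, 80.0),
    strict: bool = True,
    **overrides,
) -> ScreeningReport:
    """Run the full workflow on an existing feature table."""
    cfg = PipelineConfig(
        synthetic=SyntheticConfig(), strict=strict, blank_check=False, **overrides
    )
    return _execute(cfg, table, library, truth, is_slopes)


def run_pipeline(config: PipelineConfig) -> ScreeningReport:
    """Run the full workflow from a configuration."""
    if config.synthetic is not None:
        library = CompoundLibrary.bundled()
        if config.synthetic.n_markers > len(library):
            raise ValueError("synthetic n_markers exceeds the bundled library size")
        table, truth = generate_spiked_dataset(config.synthetic, library)
        is_slopes = config.synthetic.is_response_slopes
    else:
        table = FeatureTable.read(config.table_path, config.samples_path)
        library = CompoundLibrary.read(config.library_path)
        truth = None
        is_slopes = (120.0, 80.0)
    report = _execute(config, table, library, truth, is_slopes)

    if config.synthetic is not None and config.blank_check:
        blank_cfg = config.synthetic.blank()
        blank_table, _ = generate_spiked_dataset(blank_cfg, library)
        report.blank_hits = identification.screen_blank(
            blank_table, library,
            is_slopes=is_slopes,
            n_permutations=config.n_permutations,
            seed=config.seed + 1,
        )
        log.info("blank check: %d library hits", report.blank_hits)
    return report


def _execute(
    cfg: PipelineConfig,
    table: FeatureTable,
    library: CompoundLibrary,
    truth: GroundTruth | None,
    is_slopes: tuple[float, float],
) -> ScreeningReport:
    seeds = _derive_seeds(cfg.seed, 8)
    calibrated = _calibrate_and_filter(table, is_slopes, cfg.rsd_threshold)
    ctable = calibrated.table

    # diagnostics: PCA and HCA on all samples over candidate features
    feat = ctable.intensities.loc[ctable.feature_ids].T
    pca_model = None
    if feat.shape[1] >= 2 and feat.shape[0] >= 3:
        xs_all = multivariate.scale(feat)
        pca_model = multivariate.pca(xs_all, n_components=2)
        multivariate.hcluster(xs_all, k=3)

    groups = ctable.concentration_groups()
    contrasts = {
        "low_vs_rest": _run_contrast(calibrated, groups[0], "low_vs_rest", cfg, seeds[:4]),
        "high_vs_rest": _run_contrast(calibrated, groups[-1], "high_vs_rest", cfg, seeds[4:8]),
    }
    low, high = contrasts["low_vs_rest"], contrasts["high_vs_rest"]

    consensus = selection.consensus_candidates(low.result, high.result)
    vip_consensus = set(low.result.vip_list) & set(high.result.vip_list)
    stats_ids = sorted(consensus | vip_consensus)
    if stats_ids:
        pvals = selection.pairwise_ttests(calibrated, stats_ids)
        fcs = selection.fold_changes(calibrated, stats_ids)
        eligible = selection.confirm_eligible(
            sorted(consensus), pvals, fcs, cfg.p_threshold, cfg.fc_threshold
        )
        eligible_vip = selection.confirm_eligible(
            sorted(vip_consensus), pvals, fcs, cfg.p_threshold, cfg.fc_threshold
        )
    else:
        empty = pd.DataFrame()
        eligible = selection.EligibleSet(
            pd.DataFrame(columns=["eligible"]).astype({"eligible": bool})
        )
        eligible_vip = selection.EligibleSet(eligible.table.copy())
        pvals = fcs = empty

    def _identify(ids):
        if not ids:
            return pd.DataFrame(
                columns=["variable_id", "compound", "category", "observed_mz",
                         "reference_mass", "mass_error_ppm", "rt_min", "delta_rt_min"]
            ), []
        meta = ctable.variables.loc[ids, ["mz", "rt_min"]]
        return identification.match_markers(meta, library, cfg.ppm_tol, cfg.rt_tol)

    hits, unmatched = _identify(eligible.eligible_ids)
    hits_vip, _ = _identify(eligible_vip.eligible_ids)

    n_lib = library.n_distinct
    rate_weight = identification.screening_rate(hits, n_lib) if n_lib else 0.0
    rate_vip = identification.screening_rate(hits_vip, n_lib) if n_lib else 0.0
    log.info(
        "identification: %d hits (%d unmatched unknowns); screening rate "
        "weight=%.1f%% vip=%.1f%%",
        len(hits), len(unmatched), rate_weight, rate_vip,
    )

    report = ScreeningReport(
        hits=hits,
        unmatched=unmatched,
        eligible=eligible,
        contrasts=contrasts,
        consensus=consensus,
        rate_weight=rate_weight,
        rate_vip=rate_vip,
        hits_vip=hits_vip,
        calibrated=calibrated,
        pca=pca_model,
    )
    if truth is not None and truth.marker_ids:
        truth_compounds = set(truth.marker_compounds.values())
        found = set(hits["compound"]) & truth_compounds
        found_vip = set(hits_vip["compound"]) & truth_compounds
        report.marker_recall = 100.0 * len(found) / len(truth_compounds)
        report.vip_marker_recall = 100.0 * len(found_vip) / len(truth_compounds)
        log.info(
            "marker recall: weight route %.1f%%, VIP route %.1f%%",
            report.marker_recall, report.vip_marker_recall,
        )
    if cfg.outdir:
        _write_artifacts(Path(cfg.outdir), calibrated, contrasts, eligible, hits, report)
    return report


def _write_artifacts(outdir, calibrated, contrasts, eligible, hits, report):
    outdir.mkdir(parents=True, exist_ok=True)
    calibrated.table.write(outdir / "calibrated_table.tsv", outdir / "samples.tsv")
    if calibrated.filter_report is not None:
        calibrated.filter_report.to_csv(outdir / "filter_report.tsv", sep="\t")
    for label, art in contrasts.items():
        feat_ids = calibrated.table.feature_ids
        pd.DataFrame(
            {"vip": art.model.vip}, index=feat_ids
        ).to_csv(outdir / f"vip_{label}.tsv", sep="\t")
        art.model.splot.to_csv(outdir / f"splot_{label}.tsv", sep="\t")
        art.result.weight_table.table.to_csv(
            outdir / f"weights_{label}.tsv", sep="\t", index=False
        )
        art.perm.iterations.to_csv(
            outdir / f"permutation_{label}.tsv", sep="\t", index=False
        )
    eligible.table.to_csv(outdir / "eligibility.tsv", sep="\t")
    hits.to_csv(outdir / "marker_hits.tsv", sep="\t", index=False)
    summary = pd.Series(
        {
            "screening_rate_weight": report.rate_weight,
            "screening_rate_vip": report.rate_vip,
            "n_hits": len(hits),
            "n_unmatched": len(report.unmatched),
            "marker_recall": report.marker_recall,
            "vip_marker_recall": report.vip_marker_recall,
        }
    )
    summary.to_csv(outdir / "summary.tsv", sep="\t", header=False)
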