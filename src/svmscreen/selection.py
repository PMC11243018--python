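"""Candidate selection: VIP/weight consensus and univariate confirmation.

Each one-vs-rest contrast yields a VIP list (variables with VIP > 1) and
an SVM-RFE weight table.  Because the kernel ranking tends to be the more
reliable of the two, variables with VIP < 1 are not discarded outright:
the retained candidate set of a contrast is the smallest w^2-descending
prefix of the weight table that still contains every VIP > 1 variable.
The intersection of the two contrasts' prefixes goes to univariate
confirmation: pairwise Welch t-tests between the three concentration
groups and fold changes of the group means.  A candidate is eligible when
all three p-values fall below 0.05 and both fold changes exceed 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import CalibratedTable
from .svm_ranking import WeightTable

__all__ = [
    "ContrastResult",
    "EligibleSet",
    "retained_prefix",
    "overlap_ratio",
    "consensus_candidates",
    "pairwise_ttests",
    "fold_changes",
    "confirm_eligible",
]


@dataclass
class ContrastResult:
    """One one-vs-rest contrast: VIP list, weight table, retained prefix."""

    label: str
    vip_list: list[str]
    weight_table: WeightTable
    prefix: list[str]

    @property
    def overlap(self) -> float:
        return overlap_ratio(self.vip_list, self.prefix)


@dataclass
class EligibleSet:
    """Per-candidate univariate statistics and the eligibility verdict.

    ``table`` is indexed by variable id with the three pairwise p-values,
    the two fold changes, the flag and, for ineligible candidates, the
    failed conditions.
    """

    table: pd.DataFrame

    @property
    def eligible_ids(self) -> list[str]:
        return list(self.table.index[self.table["eligible"]])


def retained_prefix(
    vip_list, weight_table: WeightTable, label: str = ""
) -> ContrastResult:
    """Smallest w^2-descending prefix containing every VIP > 1 variable."""
    vip_list = list(vip_list)
    ranked = weight_table.table
    rank_of = dict(zip(ranked["variable_id"], ranked["rank"]))
    missing = [v for v in vip_list if v not in rank_of]
    if missing:
        raise ValueError(f"VIP variables missing from weight table: {missing[:5]}")
    if not vip_list:
        return ContrastResult(label, [], weight_table, [])
    cut = max(rank_of[v] for v in vip_list)
    prefix = list(ranked["variable_id"].iloc[:cut])
    return ContrastResult(label, vip_list, weight_table, prefix)


def overlap_ratio(vip_list, prefix) -> float:
    """Percent of the retained prefix also present in the VIP list.

    Reported to one decimal, truncated toward zero (188/214 -> 87.8).
    """
    prefix = list(prefix)
    if not prefix:
        raise ValueError("retained prefix is empty")
    inter = set(vip_list) & set(prefix)
    return np.trunc(1000.0 * len(inter) / len(prefix)) / 10.0


def consensus_candidates(
    contrast_low: ContrastResult, contrast_high: ContrastResult
) -> set[str]:
    """Variables retained by both contrasts' weight prefixes."""
    return set(contrast_low.prefix) & set(contrast_high.prefix)


def _group_blocks(calibrated: CalibratedTable):
    table = calibrated.table
    groups = table.concentration_groups()
    if len(groups) != 3:
        raise ValueError(f"expected 3 concentration groups, found {len(groups)}")
    blocks = {}
    for g in groups:
        cols = table.group_samples(g)
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        blocks[g] = table.intensities[cols]
    return groups, blocks


def pairwise_ttests(
    calibrated: CalibratedTable, variables, fdr_adjust: bool = False
) -> pd.DataFrame:
    """Two-sided Welch t-tests per variable for the three group pairs.

    Raw p-values by default; ``fdr_adjust=True`` applies a
    Benjamini-Hochberg correction across variables within each pair.  A
    pair where both groups have zero variance gets p = 1 and a warning
    flag.
    """
    groups, blocks = _group_blocks(calibrated)
    ids = pd.Index(variables)
    pairs = [(groups[0], groups[1]), (groups[0], groups[2]), (groups[1], groups[2])]
    out = pd.DataFrame(index=ids)
    out.index.name = "variable_id"
    warn = np.zeros(len(ids), dtype=bool)
    for a, b in pairs:
        xa = blocks[a].loc[ids].to_numpy()
        xb = blocks[b].loc[ids].to_numpy()
        degenerate = (xa.std(axis=1) == 0) & (xb.std(axis=1) == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
        p = np.where(degenerate, 1.0, res.pvalue)
        if fdr_adjust and len(p) > 1:
            p = stats.false_discovery_control(p, method="bh")
        out[f"p_{a}vs{b}"] = p
        warn |= degenerate
    out["zero_variance_warning"] = warn
    return out


def fold_changes(calibrated: CalibratedTable, variables) -> pd.DataFrame:
    """Group-mean intensity ratios of the higher groups over the lowest."""
    groups, blocks = _group_blocks(calibrated)
    ids = pd.Index(variables)
    low = blocks[groups[0]].loc[ids].mean(axis=1)
    if (low <= 0).any():
        bad = list(ids[low <= 0])[:5]
        raise ValueError(f"non-positive low-group mean for variables {bad}")
    out = pd.DataFrame(index=ids)
    out.index.name = "variable_id"
    out[f"fc_{groups[1]}vs{groups[0]}"] = blocks[groups[1]].loc[ids].mean(axis=1) / low
    out[f"fc_{groups[2]}vs{groups[0]}"] = blocks[groups[2]].loc[ids].mean(axis=1) / low
    return out


def confirm_eligible(
    candidates,
    pvals: pd.DataFrame,
    fcs: pd.DataFrame,
    p_threshold: float = 0.05,
    fc_threshold: float = 2.0,
) -> EligibleSet:
    """Flag candidates passing all three t-tests and both fold changes."""
    ids = pd.Index(candidates)
    missing = ids.difference(pvals.index).union(ids.difference(fcs.index))
    if len(missing):
        raise ValueError(f"statistics missing for candidates: {list(missing)[:5]}")
    p_cols = [c for c in pvals.columns if c.startswith("p_")]
    fc_cols = [c for c in fcs.columns if c.startswith("fc_")]
    table = pvals.loc[ids, p_cols].join(fcs.loc[ids, fc_cols])
    ok_p = (table[p_cols] < p_threshold).all(axis=1)
    ok_fc = (table[fc_cols] > fc_threshold).all(axis=1)
    table["eligible"] = ok_p & ok_fc
    reasons = []
    for vid in ids:
        r = []
        for c in p_cols:
            if not table.loc[vid, c] < p_threshold:
                r.append(f"{c}>={p_threshold}")
        for c in fc_cols:
            if not table.loc[vid, c] > fc_threshold:
                r.append(f"{c}<={fc_threshold}")
        reasons.append(";".join(r))
    table["reasons"] = reasons
    return EligibleSet(table)
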