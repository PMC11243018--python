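"""VIP/weight consensus, retained prefixes and univariate confirmation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svmscreen import (
    CalibratedTable,
    FeatureTable,
    SvmTuning,
    WeightTable,
    confirm_eligible,
    consensus_candidates,
    fold_changes,
    overlap_ratio,
    pairwise_ttests,
    retained_prefix,
)


def _weight_table(ids):
    n = len(ids)
    table = pd.DataFrame(
        {
            "variable_id": ids,
            "w": np.linspace(1, 0.1, n),
            "w2": np.linspace(1, 0.1, n) ** 2,
            "elimination_rank": np.arange(1, n + 1),
            "rank": np.arange(1, n + 1),
        }
    )
    return WeightTable(table, SvmTuning(1.0, 1.0, pd.DataFrame()))


class TestRetainedPrefix:
    def test_vip_equals_head_of_weight_order(self):
        wt = _weight_table([f"v{i}" for i in range(10)])
        res = retained_prefix(["v0", "v1", "v2"], wt)
        assert res.prefix == ["v0", "v1", "v2"]

    def test_prefix_extends_to_worst_ranked_vip_member(self):
        # 253-variable prefix holding 228 VIP variables, as when the
        # worst-ranked VIP member sits at rank 253
        ids = [f"v{i}" for i in range(300)]
        wt = _weight_table(ids)
        vip = [f"v{i}" for i in range(227)] + ["v252"]
        res = retained_prefix(vip, wt)
        assert len(res.prefix) == 253
        assert len(set(vip) & set(res.prefix)) == 228

    def test_empty_vip_list_gives_empty_prefix(self):
        res = retained_prefix([], _weight_table(["a", "b"]))
        assert res.prefix == []

    def test_unknown_vip_variable_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            retained_prefix(["zzz"], _weight_table(["a", "b"]))


class TestOverlapRatio:
    @pytest.mark.parametrize(
        "n_vip,n_prefix,expected",
        [(228, 253, 90.1), (188, 214, 87.8), (10, 10, 100.0)],
    )
    def test_printed_set_sizes(self, n_vip, n_prefix, expected):
        prefix = [f"v{i}" for i in range(n_prefix)]
        assert overlap_ratio(prefix[:n_vip], prefix) == expected

    def test_empty_prefix_rejected(self):
        with pytest.raises(ValueError):
            overlap_ratio(["a"], [])


class TestConsensus:
    def test_disjoint_and_identical_prefixes(self):
        wt = _weight_table(["a", "b", "c", "d"])
        lo = retained_prefix(["a", "b"], wt)
        hi = retained_prefix(["c", "d"], wt)
        # hi's prefix is a head too, so intersection equals lo's prefix
        assert consensus_candidates(lo, hi) == set(lo.prefix)
        hi2 = retained_prefix(["a", "b"], wt)
        assert consensus_candidates(lo, hi2) == {"a", "b"}


def _calibrated_from(groups: dict[str, np.ndarray], ids):
    cols, labels = [], []
    data = []
    for g, block in groups.items():
        for i in range(block.shape[1]):
            cols.append(f"{g}-{i + 1}")
            labels.append(g)
        data.append(block)
    intensities = pd.DataFrame(
        np.hstack(data), index=pd.Index(ids, name="variable_id"), columns=cols
    )
    variables = pd.DataFrame(
        {"mz": np.arange(len(ids)) + 100.0, "rt_min": 5.0, "role": "feature"},
        index=intensities.index,
    )
    samples = pd.DataFrame(
        {"group": labels, "sample_type": "spiked"},
        index=pd.Index(cols, name="sample_id"),
    )
    return CalibratedTable(FeatureTable(intensities, variables, samples), {})


class TestTTests:
    def test_identical_groups_give_p_one(self):
        cal = _calibrated_from(
            {
                "20": np.array([[1.0, 2, 3]]),
                "50": np.array([[1.0, 2, 3]]),
                "100": np.array([[9.0, 9, 9]]),
            },
            ["v1"],
        )
        p = pairwise_ttests(cal, ["v1"])
        assert p.loc["v1", "p_20vs50"] == pytest.approx(1.0)

    def test_textbook_two_sample_case(self):
        cal = _calibrated_from(
            {
                "20": np.array([[1.0, 2, 3, 4]]),
                "50": np.array([[5.0, 6, 7, 8]]),
                "100": np.array([[9.0, 9, 9, 9]]),
            },
            ["v1"],
        )
        p = pairwise_ttests(cal, ["v1"])
        # oracle: t = (mean2-mean1)/sqrt(s1^2/4 + s2^2/4) = 4/sqrt(5/6)
        from scipy import stats

        t = 4.0 / np.sqrt(5.0 / 6.0)
        # equal variances -> Welch df = 6
        expected = 2 * stats.t.sf(t, 6)
        assert t == pytest.approx(4.382, abs=0.001)
        assert expected == pytest.approx(0.0046, abs=0.0002)
        assert p.loc["v1", "p_20vs50"] == pytest.approx(expected, rel=1e-6)

    def test_degenerate_zero_variance_pair_flagged(self):
        cal = _calibrated_from(
            {
                "20": np.array([[5.0, 5, 5]]),
                "50": np.array([[5.0, 5, 5]]),
                "100": np.array([[1.0, 2, 3]]),
            },
            ["v1"],
        )
        p = pairwise_ttests(cal, ["v1"])
        assert p.loc["v1", "p_20vs50"] == 1.0
        assert bool(p.loc["v1", "zero_variance_warning"])

    def test_fdr_adjustment_never_shrinks_p(self):
        rng = np.random.default_rng(0)
        cal = _calibrated_from(
            {
                "20": rng.normal(10, 1, size=(6, 4)),
                "50": rng.normal(12, 1, size=(6, 4)),
                "100": rng.normal(20, 1, size=(6, 4)),
            },
            [f"v{i}" for i in range(6)],
        )
        ids = [f"v{i}" for i in range(6)]
        raw = pairwise_ttests(cal, ids)
        adj = pairwise_ttests(cal, ids, fdr_adjust=True)
        for col in ("p_20vs50", "p_20vs100", "p_50vs100"):
            assert (adj[col] >= raw[col] - 1e-12).all()

    def test_single_sample_group_rejected(self):
        cal = _calibrated_from(
            {
                "20": np.array([[1.0]]),
                "50": np.array([[1.0, 2]]),
                "100": np.array([[1.0, 2]]),
            },
            ["v1"],
        )
        with pytest.raises(ValueError):
            pairwise_ttests(cal, ["v1"])


class TestFoldChanges:
    def test_mean_ratios(self):
        cal = _calibrated_from(
            {
                "20": np.array([[10.0, 10], [4.0, 4]]),
                "50": np.array([[25.0, 25], [4.0, 4]]),
                "100": np.array([[50.0, 50], [4.0, 4]]),
            },
            ["up", "flat"],
        )
        fc = fold_changes(cal, ["up", "flat"])
        assert fc.loc["up", "fc_50vs20"] == pytest.approx(2.5)
        assert fc.loc["up", "fc_100vs20"] == pytest.approx(5.0)
        assert fc.loc["flat", "fc_50vs20"] == pytest.approx(1.0)

    def test_nonpositive_low_mean_rejected(self):
        cal = _calibrated_from(
            {
                "20": np.array([[0.0, 0]]),
                "50": np.array([[1.0, 2]]),
                "100": np.array([[1.0, 2]]),
            },
            ["v1"],
        )
        with pytest.raises(ValueError):
            fold_changes(cal, ["v1"])


class TestConfirmEligible:
    def _stats(self, p, fc):
        pvals = pd.DataFrame(
            {"p_20vs50": [p[0]], "p_20vs100": [p[1]], "p_50vs100": [p[2]]},
            index=pd.Index(["v1"], name="variable_id"),
        )
        fcs = pd.DataFrame(
            {"fc_50vs20": [fc[0]], "fc_100vs20": [fc[1]]}, index=pvals.index
        )
        return pvals, fcs

    @pytest.mark.parametrize(
        "p,fc,expected",
        [
            ((0.01, 0.01, 0.01), (2.5, 5.0), True),
            ((0.01, 0.01, 0.2), (2.5, 5.0), False),
            ((0.01, 0.01, 0.01), (1.9, 5.0), False),
        ],
    )
    def test_rule(self, p, fc, expected):
        res = confirm_eligible(["v1"], *self._stats(p, fc))
        assert bool(res.table.loc["v1", "eligible"]) is expected
        assert ("v1" in res.eligible_ids) is expected

    @settings(deadline=None, max_examples=60)
    @given(
        p=st.tuples(*[st.floats(1e-6, 1.0)] * 3),
        fc=st.tuples(*[st.floats(0.1, 10.0)] * 2),
        shrink=st.floats(0.1, 1.0),
        boost=st.floats(1.0, 5.0),
    )
    def test_eligibility_is_monotone(self, p, fc, shrink, boost):
        base = confirm_eligible(["v1"], *self._stats(p, fc))
        better_p = tuple(pi * shrink for pi in p)
        better_fc = tuple(fi * boost for fi in fc)
        better = confirm_eligible(["v1"], *self._stats(better_p, better_fc))
        if bool(base.table.loc["v1", "eligible"]):
            assert bool(better.table.loc["v1", "eligible"])

    def test_missing_statistics_rejected(self):
        with pytest.raises(ValueError):
            confirm_eligible(["v1", "v2"], *self._stats((0.01,) * 3, (2.5, 5.0)))
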