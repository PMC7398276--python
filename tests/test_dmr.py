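"""DMS calling, DMR merging, the bulk-baseline scan, event accounting,
categorisation and trajectory clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from methkit.dmr import (baseline_bulk, baseline_bulk_matrix, call_dms,
                         categorize_dmrs, cluster_dmr_trajectories,
                         count_mcg_events, count_events_table, effect_size,
                         mcg_h3k27ac_association, merge_dms_to_dmrs,
                         normalize_h3k27ac, tissue_specific_dmrs)


def brute_force_baseline(levels, margin=0.3):
    """Exhaustive window enumeration oracle for the bulk baseline."""
    x = np.asarray(levels, dtype=float)
    n = len(x)
    w = -(-n // 2)
    xs = np.sort(x, kind="stable")
    best_a, best_range = None, np.inf
    for a in range(n - w + 1):
        rng_ = xs[a + w - 1] - xs[a]
        if rng_ < best_range:  # strict: ties keep the smallest a
            best_a, best_range = a, rng_
    b = xs[best_a:best_a + w].mean()
    hypo = tuple(i for i in range(n) if x[i] - b <= -margin)
    return best_a, b, hypo


class TestBaselineBulk:
    def test_worked_example(self):
        res = baseline_bulk([0.10, 0.80, 0.82, 0.84])
        assert res.a == 1                       # window (0.80, 0.82), tie to smallest a
        assert res.b == pytest.approx(0.81)
        assert res.hypo == (0,)

    def test_constant_vector_has_no_outliers(self):
        res = baseline_bulk([0.7] * 6)
        assert res.b == pytest.approx(0.7)
        assert res.hypo == ()

    def test_missing_levels_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            baseline_bulk([0.5, float("nan"), 0.7])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 13))
            x = np.round(rng.random(n), 3)
            res = baseline_bulk(x)
            a, b, hypo = brute_force_baseline(x)
            assert res.a == a
            assert res.b == pytest.approx(b)
            assert res.hypo == hypo

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                    min_size=2, max_size=12))
    def test_baseline_properties_hold_on_arbitrary_levels(self, levels):
        res = baseline_bulk(levels)
        a, b, hypo = brute_force_baseline(levels)
        assert res.a == a and res.hypo == hypo
        assert res.b == pytest.approx(b, abs=1e-12)
        # baseline lies inside the data range; bulk window has ceil(N/2) members
        assert min(levels) - 1e-12 <= res.b <= max(levels) + 1e-12

    def test_matrix_version_agrees_with_scalar(self, rng):
        X = rng.random((200, 9))
        b, hypo = baseline_bulk_matrix(X)
        for i in range(len(X)):
            res = baseline_bulk(X[i])
            assert b[i] == pytest.approx(res.b)
            assert tuple(np.nonzero(hypo[i])[0]) == res.hypo


class TestEffectSize:
    def test_from_baseline_example(self):
        assert effect_size([0.10, 0.80, 0.82, 0.84]) == pytest.approx(0.71)

    def test_constant_vector_zero(self):
        assert effect_size([0.5] * 5) == 0.0

    def test_invariant_to_sample_order(self, rng):
        x = rng.random(8)
        for perm in itertools.islice(itertools.permutations(x), 20):
            assert effect_size(list(perm)) == pytest.approx(effect_size(x))


class TestCallDms:
    def counts(self, rows):
        idx = pd.MultiIndex.from_tuples([("chr1", 100 + 10 * i) for i in range(len(rows))])
        mc = pd.DataFrame([r[0] for r in rows], index=idx, columns=list("ABCDEF")[:len(rows[0][0])])
        cov = pd.DataFrame([r[1] for r in rows], index=idx, columns=mc.columns)
        return mc, cov

    def test_identical_counts_not_significant(self):
        mc, cov = self.counts([([5, 5, 5], [10, 10, 10])] * 5)
        out = call_dms(mc, cov, n_permutations=200)
        assert not out["is_dms"].any()

    def test_extreme_site_called_with_hypo_label(self):
        rows = [([0, 30, 30, 30, 30, 30], [30] * 6)]
        rows += [([15, 15, 15, 15, 15, 15], [30] * 6)] * 30
        mc, cov = self.counts(rows)
        out = call_dms(mc, cov, n_permutations=1000, seed=5)
        assert out["is_dms"].iloc[0]
        assert out["hypo_samples"].iloc[0] == ("A",)

    def test_requires_two_samples(self):
        mc, cov = self.counts([([3], [10])])
        with pytest.raises(ValueError):
            call_dms(mc, cov)

    def test_null_sites_controlled_by_fdr(self, rng):
        n = 2000
        cov = np.full((n, 4), 40)
        mc = rng.binomial(40, 0.7, size=(n, 4))
        idx = pd.MultiIndex.from_tuples([("chr1", 2 * i + 2) for i in range(n)])
        out = call_dms(pd.DataFrame(mc, index=idx), pd.DataFrame(cov, index=idx),
                       n_permutations=300, seed=3)
        assert out["is_dms"].sum() <= n * 0.01


class TestMergeDms:
    def dms(self, positions, hypos):
        idx = pd.MultiIndex.from_tuples([("chr1", p) for p in positions])
        return pd.DataFrame({"hypo_samples": hypos}, index=idx)

    def test_three_compatible_sites_form_one_dmr(self):
        out = merge_dms_to_dmrs(self.dms([100, 200, 300], [("A",)] * 3))
        assert len(out) == 1
        assert out.iloc[0][["start", "end", "n_dms"]].tolist() == [99, 301, 3]

    def test_two_sites_insufficient(self):
        assert len(merge_dms_to_dmrs(self.dms([100, 200], [("A",)] * 2))) == 0

    def test_gap_boundary_251_never_merges(self):
        out = merge_dms_to_dmrs(self.dms([100, 351, 602], [("A",)] * 3))
        assert len(out) == 0  # three singleton blocks, all below min_dms
        out = merge_dms_to_dmrs(self.dms([100, 350, 600], [("A",)] * 3))
        assert len(out) == 1

    def test_disjoint_hypo_sets_break_blocks(self):
        out = merge_dms_to_dmrs(self.dms([100, 200, 300, 400],
                                         [("A",), ("A",), ("B",), ("B",)]))
        assert len(out) == 0
        out = merge_dms_to_dmrs(self.dms([100, 200, 300],
                                         [("A",), ("A", "B"), ("B",)]))
        assert len(out) == 1  # adjacent sets intersect pairwise


class TestEvents:
    def test_mixed_trajectory(self):
        ev = count_mcg_events([0.8, 0.65, 0.60, 0.75])
        assert ev["loss"].tolist() == [True, False, False]
        assert ev["gain"].tolist() == [False, False, True]

    def test_single_loss_event(self):
        ev = count_mcg_events([0.8, 0.7])
        assert ev["loss"].sum() == 1 and ev["gain"].sum() == 0

    def test_monotone_decrease_gives_only_losses(self):
        ev = count_mcg_events([0.9, 0.75, 0.6, 0.45, 0.3])
        assert ev["loss"].sum() == 4 and ev["gain"].sum() == 0

    def test_reversal_swaps_loss_and_gain(self, rng):
        for _ in range(50):
            x = rng.random(6)
            fwd = count_mcg_events(x)
            rev = count_mcg_events(x[::-1])
            assert fwd["loss"].sum() == rev["gain"].sum()
            assert fwd["gain"].sum() == rev["loss"].sum()
            assert (fwd["loss"] | fwd["gain"]).sum() <= len(x) - 1

    def test_fewer_than_two_stages_empty(self):
        assert len(count_mcg_events([0.5])) == 0

    def test_table_aggregates_rows(self):
        traj = pd.DataFrame([[0.8, 0.7, 0.8], [0.8, 0.6, 0.6]],
                            columns=["E11.5", "E12.5", "E13.5"])
        tab = count_events_table(traj)
        assert tab["loss"].tolist() == [2, 0]
        assert tab["gain"].tolist() == [0, 1]


class TestCategorize:
    def tracks(self):
        prom = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [5000]})
        cgi = pd.DataFrame({"chrom": ["c"], "start": [1000], "end": [2000]})
        shores = pd.DataFrame({"chrom": ["c"], "start": [2000], "end": [4000]})
        te = pd.DataFrame({"chrom": ["c"], "start": [50_000], "end": [51_000]})
        return prom, cgi, shores, te

    def test_cgi_promoter_outranks_cgi(self):
        prom, cgi, shores, te = self.tracks()
        dmrs = pd.DataFrame({"chrom": ["c"], "start": [1200], "end": [1400]})
        cat = categorize_dmrs(dmrs, prom, cgi, shores, te,
                              enhancer_scores=np.array([0.9]))
        assert cat.iloc[0] == "cgi_promoter"

    def test_score_boundary_is_strict(self):
        prom, cgi, shores, te = self.tracks()
        dmrs = pd.DataFrame({"chrom": ["c", "c"], "start": [20_000, 30_000],
                             "end": [20_500, 30_500]})
        cat = categorize_dmrs(dmrs, prom, cgi, shores, te,
                              enhancer_scores=np.array([0.31, 0.30]),
                              tissue_specific=np.array([False, False]))
        assert cat.iloc[0] == "distal_fedmr"
        assert cat.iloc[1] != "distal_fedmr"

    def test_flanking_within_1kb_of_fedmr(self):
        prom, cgi, shores, te = self.tracks()
        dmrs = pd.DataFrame({"chrom": ["c", "c"], "start": [20_000, 21_400],
                             "end": [20_500, 21_600]})
        cat = categorize_dmrs(dmrs, prom, cgi, shores, te,
                              enhancer_scores=np.array([0.9, 0.0]),
                              tissue_specific=np.array([False, False]))
        assert cat.tolist() == ["distal_fedmr", "flanking_distal_fedmr"]

    def test_te_unxdmr_assignment(self):
        prom, cgi, shores, te = self.tracks()
        dmrs = pd.DataFrame({"chrom": ["c"], "start": [50_200], "end": [50_400]})
        with pytest.warns(UserWarning, match="enhancer"):
            cat = categorize_dmrs(dmrs, prom, cgi, shores, te,
                                  tissue_specific=np.array([False]))
        assert cat.iloc[0] == "te_unxdmr"

    def test_categories_partition_input(self, rng):
        prom, cgi, shores, te = self.tracks()
        starts = rng.integers(0, 90_000, size=60)
        dmrs = pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 300})
        cat = categorize_dmrs(dmrs, prom, cgi, shores, te,
                              enhancer_scores=rng.random(60),
                              tissue_specific=rng.random(60) < 0.3)
        assert cat.notna().all()
        assert cat.value_counts().sum() == 60


class TestH3K27acAssociation:
    def test_cell_assignment(self):
        tab = mcg_h3k27ac_association([0.65, 0.2], [7.1, 2.0])
        assert tab.loc["H", "(6,inf)"] == 1
        assert tab.loc["L", "[0,2]"] == 1

    def test_negative_enrichment_in_first_column(self):
        tab = mcg_h3k27ac_association([0.5], [-3.0])
        assert tab.loc["M", "[0,2]"] == 1

    def test_counts_conserved(self, rng):
        mcg, ac = rng.random(500), rng.normal(3, 3, 500)
        assert mcg_h3k27ac_association(mcg, ac).to_numpy().sum() == 500


class TestTrajectoryClustering:
    def test_normalisation_examples(self):
        assert normalize_h3k27ac(np.array([[-1.0, 2.0, 4.0]])).tolist() == [[0, 0.5, 1.0]]
        assert normalize_h3k27ac(np.array([[-1.0, -2.0, 0.0]])).tolist() == [[0, 0, 0]]

    def test_separated_groups_recovered_exactly(self, rng):
        n = 40
        mcg = np.vstack([np.tile([0.9, 0.7, 0.2], (n, 1)) + rng.normal(0, 0.02, (n, 3)),
                         np.tile([0.2, 0.6, 0.9], (n, 1)) + rng.normal(0, 0.02, (n, 3))])
        ac = np.vstack([np.tile([0.0, 2.0, 6.0], (n, 1)), np.tile([6.0, 2.0, 0.0], (n, 1))])
        labels = cluster_dmr_trajectories(mcg, ac, k=2, seed=0)
        truth = np.repeat([0, 1], n)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_larger_than_rows_rejected(self):
        with pytest.raises(ValueError):
            cluster_dmr_trajectories(np.zeros((2, 3)), np.zeros((2, 3)), k=5)


def test_tissue_specific_drops_rows_with_missing_levels():
    levels = pd.DataFrame({"a": [0.1, np.nan], "b": [0.8, 0.8],
                           "c": [0.82, 0.8], "d": [0.84, 0.8]})
    out = tissue_specific_dmrs(levels)
    assert list(out.index) == [0]
    assert out["hypo_samples"].iloc[0] == ("a",)
    assert out["tissue_specific"].iloc[0]
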