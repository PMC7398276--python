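"""Large hypo blocks, DMVs, PMD features/calls, mCH domains and profiles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from methkit.domains import (call_dmvs, call_large_hypo, call_mch_domains,
                             call_pmds, cluster_mch_domains, dmv_blocks,
                             mch_domain_profile, mch_repression_zscores,
                             pmd_bin_features, reconcile_replicates,
                             train_pmd_classifier, _sample_mch_domains)
from methkit.genome import empty_intervals
from methkit.levels import LevelTrack
from conftest import make_allc


def make_track(levels, bin_size=5000, chrom="c", nodata=()):
    n = len(levels)
    starts = np.arange(n) * bin_size
    has_data = np.array([i not in nodata and not np.isnan(levels[i]) for i in range(n)])
    tab = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + bin_size,
                        "level": [lv if has_data[i] else np.nan
                                  for i, lv in enumerate(levels)],
                        "n_sites": 1000, "frac_covered": 1.0,
                        "mc": 0, "cov": 1, "has_data": has_data})
    return LevelTrack(bin_size=bin_size, context="CH", table=tab)


class TestLargeHypo:
    def iv(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_merge_within_1kb_and_keep_2kb(self):
        out = call_large_hypo(self.iv([("c", 0, 900), ("c", 1800, 2700)]))
        assert out.iloc[0][["start", "end"]].tolist() == [0, 2700]

    def test_short_singleton_dropped(self):
        assert len(call_large_hypo(self.iv([("c", 0, 1500)]))) == 0

    def test_gap_boundary_1001_not_merged(self):
        out = call_large_hypo(self.iv([("c", 0, 1200), ("c", 2201, 3400)]))
        assert len(out) == 0  # two blocks of 1.2 kb each, both < 2 kb
        out = call_large_hypo(self.iv([("c", 0, 1200), ("c", 2200, 3400)]))
        assert len(out) == 1


class TestDmvs:
    def test_five_low_bins_called(self):
        t = make_track([0.8, 0.1, 0.1, 0.1, 0.1, 0.1, 0.8], bin_size=1000)
        out = dmv_blocks(t)
        assert out.iloc[0][["start", "end", "n_bins"]].tolist() == [1000, 6000, 5]

    def test_four_bins_insufficient(self):
        t = make_track([0.8, 0.1, 0.1, 0.1, 0.1, 0.8], bin_size=1000)
        assert len(dmv_blocks(t)) == 0

    def test_no_data_bins_skipped_not_counted_not_breaking(self):
        # run of 5 with-data low bins interrupted by a no-data bin
        t = make_track([0.1, 0.1, np.nan, 0.1, 0.1, 0.1, 0.8], bin_size=1000)
        out = dmv_blocks(t)
        assert len(out) == 1
        assert out.iloc[0]["n_bins"] == 5
        # but 4 with-data bins + gap stays insufficient
        t = make_track([0.1, 0.1, np.nan, 0.1, 0.1, 0.8], bin_size=1000)
        assert len(dmv_blocks(t)) == 0

    def test_threshold_is_strict(self):
        t = make_track([0.15, 0.15, 0.15, 0.15, 0.15], bin_size=1000)
        assert len(dmv_blocks(t)) == 0

    def test_replicate_reconciliation_keeps_overlapping_calls(self):
        r1 = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 20_000], "end": [6000, 26_000]})
        r2 = pd.DataFrame({"chrom": ["c"], "start": [4000], "end": [9000]})
        out = reconcile_replicates(r1, r2)
        assert out[["start", "end"]].to_numpy().tolist() == [[0, 9000]]

    def test_call_dmvs_merges_across_samples(self):
        t1 = make_track([0.1] * 6 + [0.8] * 4, bin_size=1000)
        t2 = make_track([0.8] + [0.1] * 6 + [0.8] * 3, bin_size=1000)
        per_sample, final = call_dmvs({"s1": [t1, t2]})
        assert len(per_sample["s1"]) == 1
        assert final.iloc[0][["start", "end"]].tolist() == [0, 7000]


class TestPmds:
    def sites(self, n, level, chrom="c", start=0, cov=20):
        mc = int(round(level * cov))
        return make_allc([(chrom, start + 40 * i + 2, "+", "CGA", mc, cov)
                          for i in range(n)])

    def test_uniform_bin_features_equal_level(self):
        feats = pmd_bin_features(self.sites(50, 0.5), {"c": 10_000}, empty_intervals())
        row = feats.iloc[0]
        assert row["has_data"]
        assert all(row[f"p{q}"] == pytest.approx(0.5) for q in range(5, 100, 5))

    def test_bin_with_nine_sites_dropped(self):
        feats = pmd_bin_features(self.sites(9, 0.5), {"c": 10_000}, empty_intervals())
        assert not feats["has_data"].any()

    def test_low_coverage_sites_excluded(self):
        sites = self.sites(20, 0.5, cov=4)  # below the 5-read floor
        feats = pmd_bin_features(sites, {"c": 10_000}, empty_intervals())
        assert not feats["has_data"].any()

    def test_features_invariant_to_site_order(self, rng):
        sites = self.sites(60, 0.5)
        sites["mc"] = rng.integers(0, 20, size=60)
        shuffled = sites.sample(frac=1, random_state=1).reset_index(drop=True)
        a = pmd_bin_features(sites, {"c": 10_000}, empty_intervals())
        b = pmd_bin_features(shuffled, {"c": 10_000}, empty_intervals())
        pd.testing.assert_frame_equal(a, b)

    def test_call_pmds_requires_both_replicates_and_length(self):
        # 30 bins: 12 PMD-like (0.45) in the middle of high background
        lengths = {"c": 300_000}
        lv = [0.85] * 9 + [0.45] * 12 + [0.85] * 9
        frames = []
        for rep in range(2):
            rows = []
            for b, level in enumerate(lv):
                rows.append(self.sites(30, level, start=b * 10_000))
            frames.append(pd.concat(rows, ignore_index=True))
        feats = [pmd_bin_features(f, lengths, empty_intervals()) for f in frames]
        labels = np.array([lv_ < 0.7 for lv_ in lv])
        clf = train_pmd_classifier(feats[0], labels, n_estimators=50, seed=0)
        out = call_pmds(clf, feats, empty_intervals(), empty_intervals())
        assert out.iloc[0][["start", "end"]].tolist() == [90_000, 210_000]
        # a 90-kb block (9 bins) fails the length floor
        lv9 = [0.85] * 10 + [0.45] * 9 + [0.85] * 11
        rows = [self.sites(30, level, start=b * 10_000) for b, level in enumerate(lv9)]
        f9 = pmd_bin_features(pd.concat(rows, ignore_index=True), lengths, empty_intervals())
        assert len(call_pmds(clf, [f9, f9], empty_intervals(), empty_intervals())) == 0


def test_pmd_classifier_round_trips_with_header(tmp_path, rng):
    from methkit.domains import load_pmd_classifier, save_pmd_classifier
    import json
    X = rng.random((40, 19))
    y = X[:, 9] < 0.5
    from sklearn.ensemble import RandomForestClassifier
    clf = RandomForestClassifier(n_estimators=20, random_state=0).fit(X, y)
    path = tmp_path / "clf.joblib"
    save_pmd_classifier(clf, path)
    header = json.loads((tmp_path / "clf.joblib.json").read_text())
    assert header["n_estimators"] == 20 and len(header["features"]) == 19
    back = load_pmd_classifier(path)
    assert (back.predict(X) == clf.predict(X)).all()


class TestMchDomains:
    def test_elevated_chunk_called(self):
        lv = [0.01] * 20 + [0.02] * 5 + [0.01] * 20
        out = _sample_mch_domains(make_track(lv), empty_intervals(), None, 1.5, 0.001)
        assert out.iloc[0][["start", "end"]].tolist() == [100_000, 125_000]

    def test_sub_threshold_elevation_rejected(self):
        # 1.5x rule: (0.014 + 0.001) / (0.01 + 0.001) = 1.36 < 1.5
        lv = [0.01] * 20 + [0.014] * 5 + [0.01] * 20
        out = _sample_mch_domains(make_track(lv), empty_intervals(), None, 1.5, 0.001)
        assert len(out) == 0

    def test_excluded_regions_are_ignored(self):
        lv = [0.01] * 20 + [0.02] * 5 + [0.01] * 20
        excl = pd.DataFrame({"chrom": ["c"], "start": [100_000], "end": [125_000]})
        out = _sample_mch_domains(make_track(lv), excl, None, 1.5, 0.001)
        assert len(out) == 0

    def meta(self):
        return pd.DataFrame({
            "tissue": ["brain"] * 4, "stage": ["e", "e", "p", "p"],
            "replicate": [1, 2, 1, 2], "is_control": [True, True, False, False]},
            index=["b_e_1", "b_e_2", "b_p_1", "b_p_2"])

    def test_control_artefacts_excluded_and_domains_survive(self):
        # artefact elevated in controls AND signal samples; true domain only in signal
        base = [0.0] * 60
        art = list(base)
        for i in range(40, 45):
            art[i] = 0.02
        sig = [0.01] * 60
        for i in range(40, 45):
            sig[i] = 0.03
        for i in range(10, 16):
            sig[i] = 0.025
        tracks = {"b_e_1": make_track(art), "b_e_2": make_track(art),
                  "b_p_1": make_track(sig), "b_p_2": make_track(sig)}
        res = call_mch_domains(tracks, self.meta())
        assert len(res.excluded) == 1
        assert res.excluded.iloc[0][["start", "end"]].tolist() == [200_000, 225_000]
        assert res.final[["start", "end"]].to_numpy().tolist() == [[50_000, 80_000]]
        assert res.n_iterations >= 2

    def test_replicate_disagreement_rejected(self):
        sig = [0.01] * 60
        for i in range(10, 16):
            sig[i] = 0.03
        tracks = {"b_e_1": make_track([0.0] * 60), "b_e_2": make_track([0.0] * 60),
                  "b_p_1": make_track(sig), "b_p_2": make_track([0.01] * 60)}
        res = call_mch_domains(tracks, self.meta())
        assert len(res.final) == 0

    def test_short_domains_filtered(self):
        sig = [0.01] * 60
        for i in range(10, 12):  # 10 kb < 15 kb minimum
            sig[i] = 0.05
        tracks = {"b_e_1": make_track([0.0] * 60), "b_e_2": make_track([0.0] * 60),
                  "b_p_1": make_track(sig), "b_p_2": make_track(sig)}
        res = call_mch_domains(tracks, self.meta())
        assert len(res.final) == 0

    def test_nonconverging_loop_raises(self):
        sig = [0.01] * 60
        for i in range(10, 16):
            sig[i] = 0.03
        tracks = {"b_e_1": make_track(sig), "b_e_2": make_track(sig),
                  "b_p_1": make_track(sig), "b_p_2": make_track(sig)}
        with pytest.raises(RuntimeError, match="converge"):
            call_mch_domains(tracks, self.meta(), max_iterations=0)


class TestProfiles:
    def domain(self):
        return pd.Series({"chrom": "c", "start": 150_000, "end": 200_000})

    def test_flat_signal_normalises_to_one(self):
        track = make_track([0.02] * 80)
        prof = mch_domain_profile(self.domain(), track)
        assert len(prof) == 50
        assert np.allclose(prof, 0.02 / 0.021, atol=1e-9)

    def test_elevated_body_reads_twice_flanks(self):
        lv = [0.01] * 30 + [0.02] * 10 + [0.01] * 40
        prof = mch_domain_profile(self.domain(), make_track(lv))
        flank_val = (0.01 / 0.011)
        assert np.allclose(prof[:20], flank_val)
        assert np.allclose(prof[20:30], 0.02 / 0.011)
        assert np.allclose(prof[30:], flank_val)

    def test_short_domain_still_ten_body_bins(self):
        dom = pd.Series({"chrom": "c", "start": 150_000, "end": 160_000})
        prof = mch_domain_profile(dom, make_track([0.01] * 80))
        assert len(prof) == 50

    def test_two_archetypes_cluster_perfectly(self):
        doms = pd.DataFrame({"chrom": "c",
                             "start": [500_000, 800_000, 1_200_000, 1_500_000],
                             "end": [550_000, 850_000, 1_250_000, 1_550_000]})
        # one long track where the first two domains are elevated, last two
        # flat; domains are spaced so no flank touches another domain
        lv = [0.01] * 400
        for i in list(range(100, 110)) + list(range(160, 170)):
            lv[i] = 0.04
        tracks = {"s": make_track(lv)}
        labels, profiles = cluster_mch_domains(doms, tracks, ["s"], k=2, seed=0)
        assert adjusted_rand_score([0, 0, 1, 1], labels) == 1.0
        assert all(p.shape == (1, 50) for p in profiles.values())


class TestRepression:
    def meta(self):
        return pd.DataFrame({"tissue": ["b"] * 3, "stage": ["s1", "s2", "s3"],
                             "stage_order": [0, 1, 2]},
                            index=["b_s1", "b_s2", "b_s3"])

    def test_identical_sets_give_zero(self):
        tpm = pd.DataFrame({"b_s1": [1, 1.0], "b_s2": [2, 2.0], "b_s3": [3, 3.0]},
                           index=["g1", "g2"])
        rel = mch_repression_zscores(tpm, self.meta(), {"g1"}, "b")
        assert np.allclose(rel, 0.0)

    def test_repressed_domain_genes_negative_late(self):
        tpm = pd.DataFrame({"b_s1": [10, 5.0], "b_s2": [5, 5.2], "b_s3": [1, 4.9]},
                           index=["dom", "out"])
        rel = mch_repression_zscores(tpm, self.meta(), {"dom"}, "b")
        assert rel.iloc[-1] < 0 < rel.iloc[0]

    def test_constant_genes_skipped(self):
        # the flat outside gene is dropped (zero variance), so the contrast
        # is driven by "rising" alone
        tpm = pd.DataFrame({"b_s1": [10, 7.0, 1.0], "b_s2": [5, 7.0, 2.0],
                            "b_s3": [1, 7.0, 3.0]},
                           index=["dom", "flat", "rising"])
        with_flat = mch_repression_zscores(tpm, self.meta(), {"dom"}, "b")
        without = mch_repression_zscores(tpm.drop("flat"), self.meta(), {"dom"}, "b")
        assert np.allclose(with_flat.to_numpy(), without.to_numpy())
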