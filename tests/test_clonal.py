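import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mthet import (
    CohortConfig,
    clump_loci,
    disease_association,
    ivw_effect_correlation,
    match_controls,
    matched_difference_test,
    mean_positional_score,
    sibling_sharing,
    simulate_cohort,
    simulate_phenotypes,
)

from conftest import make_samples


class TestMatching:
    def test_exact_age_sex_multisets(self):
        s = make_samples(400, seed=0, ages=np.random.default_rng(0).integers(60, 66, 400))
        s.loc[:39, "ch"] = True
        matched = match_controls(s, n_sets=20, seed=1)
        lookup = s.set_index("sample_id")[["age", "sex"]]
        ch_multiset = sorted(map(tuple, lookup.loc[matched.ch_ids].to_numpy()))
        for ids in matched.control_sets:
            assert sorted(map(tuple, lookup.loc[ids].to_numpy())) == ch_multiset
            assert not s.set_index("sample_id").loc[ids, "ch"].any()
            assert len(set(ids)) == len(ids)  # without replacement within a set

    def test_insufficient_stratum_raises(self):
        s = make_samples(10, ages=np.full(10, 60))
        s["sex"] = ["F"] * 9 + ["M"]
        s.loc[9, "ch"] = True  # the only M is the CH carrier
        with pytest.raises(ValueError, match="stratum"):
            match_controls(s, n_sets=2, seed=0)

    def test_seed_determinism(self):
        s = make_samples(200, seed=2, ages=np.random.default_rng(1).integers(50, 56, 200))
        s.loc[:19, "ch"] = True
        a = match_controls(s, n_sets=5, seed=3)
        b = match_controls(s, n_sets=5, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a.control_sets, b.control_sets))


class TestMatchedDifference:
    def _stat(self, samples, values):
        pos = {sid: i for i, sid in enumerate(samples["sample_id"])}
        return lambda ids: np.array([values[[pos[i] for i in ids]].mean()])

    def test_single_category_bonferroni_one(self):
        rng = np.random.default_rng(0)
        s = make_samples(600, seed=1, ages=rng.integers(55, 65, 600))
        s.loc[:59, "ch"] = True
        matched = match_controls(s, n_sets=50, seed=2)
        burden = rng.poisson(2.0, 600).astype(float)
        res = matched_difference_test(self._stat(s, burden), matched, categories=["burden"])
        assert len(res) == 1
        assert res["p_bonferroni"].iloc[0] == pytest.approx(min(1.0, res["p"].iloc[0]))

    def test_type_one_error_calibrated_under_null(self):
        """Empirical size at alpha=0.05 within [0.03, 0.07], 1000 per arm.

        The control pool is large relative to the group, as in a biobank;
        burdens are redrawn independently of CH status on every repetition.
        """
        rng = np.random.default_rng(3)
        n = 101_000
        s = make_samples(n, seed=4, ages=rng.integers(60, 70, n))
        s.loc[:999, "ch"] = True
        matched = match_controls(s, n_sets=100, seed=5)
        pos = {sid: i for i, sid in enumerate(s["sample_id"])}
        idx_cache = {id(matched.ch_ids): np.array([pos[i] for i in matched.ch_ids])}
        for ids in matched.control_sets:
            idx_cache[id(ids)] = np.array([pos[i] for i in ids])
        rejections = 0
        reps = 2000
        for _ in range(reps):
            vals = rng.poisson(2.0, n).astype(float)
            stat = lambda ids: np.array([vals[idx_cache[id(ids)]].mean()])
            res = matched_difference_test(stat, matched)
            if res["p"].iloc[0] < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07

    def test_detects_elevated_ch_burden(self):
        rng = np.random.default_rng(6)
        s = make_samples(2000, seed=7, ages=rng.integers(55, 70, 2000))
        s.loc[:199, "ch"] = True
        burden = rng.poisson(2.0, 2000).astype(float)
        burden[:200] += rng.poisson(1.0, 200)  # CH excess
        matched = match_controls(s, n_sets=100, seed=8)
        res = matched_difference_test(self._stat(s, burden), matched, permutation_p=True)
        assert res["difference"].iloc[0] > 0
        assert res["p"].iloc[0] < 1e-4
        assert res["p_permutation"].iloc[0] < 0.05


class TestSiblingSharing:
    def _toy(self):
        samples = make_samples(10, ages=np.full(10, 50))
        samples["sibling_pair"] = [0, 0, 1, 1] + [-1] * 6
        rows = []
        # a common variant (6 carriers) shared within pair 0 at very different HL
        carriers = ["S00000", "S00001", "S00004", "S00005", "S00006", "S00007"]
        hls = [0.6, 0.1, 0.2, 0.2, 0.2, 0.2]
        for sid, hl in zip(carriers, hls):
            rows.append((sid, 100, "C", "T", hl))
        # a rare variant (3 carriers) in pair 1 -- excluded by min_carriers=5
        for sid in ["S00002", "S00003", "S00008"]:
            rows.append((sid, 200, "A", "G", 0.3))
        callset = pd.DataFrame(rows, columns=["sample_id", "pos", "ref", "alt", "HL"])
        return samples, callset

    def test_shared_at_any_heteroplasmy_and_carrier_floor(self):
        samples, callset = self._toy()
        out = sibling_sharing(callset, samples, hl_bins=[(0.0, 0.95)], min_carriers=5)
        # only the common variant contributes: sibling 1 of pair 0 carries it
        # at 0.6, sibling 2 at 0.1 -> shared despite the HL gap; the rare
        # variant never enters
        assert out["n"].iloc[0] == 1
        assert out["proportion"].iloc[0] == 1.0

    def test_transmitted_variants_fully_shared(self, rcrs_ref):
        cfg = CohortConfig(
            n_samples=120, n_sibling_pairs=60, transmitted_rate=2.0,
            rates_per_year={}, rates_constant={},
        )
        out = simulate_cohort(rcrs_ref, None, cfg, seed=11)
        shared = sibling_sharing(
            out.callset, out.samples, hl_bins=[(0.0, 0.95)], min_carriers=1
        )
        assert shared["n"].iloc[0] > 20
        assert shared["proportion"].iloc[0] > 0.95
        assert shared["ci_high"].iloc[0] <= 1.0

    def test_empty_bin_reported(self):
        samples, callset = self._toy()
        out = sibling_sharing(callset, samples, hl_bins=[(0.9, 0.95)], min_carriers=5)
        assert out["n"].iloc[0] == 0 and np.isnan(out["proportion"].iloc[0])


class TestClumping:
    def test_overlapping_windows_merge(self):
        df = pd.DataFrame({"pos": [1_000_000, 1_150_000], "p": [1e-8, 1e-6]})
        out = clump_loci(df)
        assert len(out) == 1
        assert out["lead_pos"].iloc[0] == 1_000_000

    def test_distant_windows_split(self):
        df = pd.DataFrame({"pos": [1_000_000, 1_300_000], "p": [1e-8, 1e-6]})
        assert len(clump_loci(df)) == 2

    def test_no_significant_variants(self):
        df = pd.DataFrame({"pos": [1_000_000], "p": [0.5]})
        assert clump_loci(df).empty

    def test_partition_and_lead_minimality(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "pos": rng.integers(1, 50_000_000, 300),
                "p": 10.0 ** rng.uniform(-12, 0, 300),
                "chrom": rng.choice(["1", "2"], 300),
            }
        )
        out = clump_loci(df)
        sig = df[df["p"] < 5e-5]
        assert out["n_variants"].sum() == len(sig)
        for _, locus in out.iterrows():
            members = sig[
                (sig["chrom"] == locus["chrom"])
                & (sig["pos"] >= locus["start"])
                & (sig["pos"] <= locus["end"])
            ]
            assert locus["lead_p"] == members["p"].min()


class TestIvw:
    def test_exact_line_machine_precision(self):
        x = np.array([0.1, 0.2, 0.3, 0.5])
        res = ivw_effect_correlation(x, np.full(4, 0.05), 2 * x, np.full(4, 0.05))
        assert res["slope"] == pytest.approx(2.0, abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            ivw_effect_correlation([1, 2], [0.1, 0.1], [1, 2], [0.1, 0.1])

    def test_noisy_outlier_downweighted(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.1, 0.5, 20)
        y = 1.5 * x + rng.normal(0, 0.01, 20)
        base = ivw_effect_correlation(x, np.full(20, 0.05), y, np.full(20, 0.05))
        x2 = np.append(x, 0.4)
        y2 = np.append(y, 25.0)  # wild outlier with huge uncertainty
        pert = ivw_effect_correlation(
            x2, np.append(np.full(20, 0.05), 5.0), y2, np.append(np.full(20, 0.05), 50.0)
        )
        assert abs(pert["slope"] - base["slope"]) < 0.02

    def test_null_slope_coverage(self):
        rng = np.random.default_rng(2)
        covered = 0
        for _ in range(200):
            x = rng.normal(0.3, 0.1, 30)
            y = rng.normal(0, 0.1, 30)
            res = ivw_effect_correlation(
                x, np.full(30, 0.1), y, np.full(30, 0.1)
            )
            if res["ci_low"] <= 0 <= res["ci_high"]:
                covered += 1
        assert 0.88 <= covered / 200 <= 1.0


class TestDiseaseAssociation:
    def test_small_ancestry_groups_excluded(self):
        rng = np.random.default_rng(0)
        s = make_samples(500, seed=1)
        s.loc[:4, "ancestry"] = "Z"
        burden = pd.Series(rng.poisson(2, 500).astype(float),
                           index=pd.Index(s["sample_id"]))
        y = pd.Series(rng.integers(0, 2, 500), index=pd.Index(s["sample_id"]))
        y.loc[s.loc[s["ancestry"] == "Z", "sample_id"]] = [1, 1, 0, 0, 0]  # 2 cases
        res = disease_association(s, burden, y)
        assert res["n"] == 495

    def test_odds_ratio_recovery(self, rcrs_ref):
        cfg = CohortConfig(n_samples=6000)
        out = simulate_cohort(rcrs_ref, None, cfg, seed=21)
        rng = np.random.default_rng(22)
        burden = pd.Series(rng.poisson(2.0, 6000).astype(float),
                           index=pd.Index(out.samples["sample_id"]))
        y = simulate_phenotypes(out.samples, burden, intercept=-2.0,
                                beta=np.log(2.0), seed=23)
        res = disease_association(out.samples, burden, y)
        assert not res["flagged"]
        assert res["odds_ratio"] == pytest.approx(2.0, abs=0.25)
        assert res["ci_low"] < 2.0 < res["ci_high"]

    def test_separation_flagged(self):
        s = make_samples(60, seed=3)
        burden = pd.Series(np.arange(60, dtype=float), index=pd.Index(s["sample_id"]))
        y = pd.Series((np.arange(60) >= 30).astype(int), index=pd.Index(s["sample_id"]))
        res = disease_association(s, burden, y)
        assert res["flagged"] and np.isnan(res["odds_ratio"])


class TestPositionalScore:
    def test_constant_score(self, toy_callset):
        scores = pd.Series(3.5, index=pd.Index([100, 200, 300, 400]))
        out = mean_positional_score(
            toy_callset, scores, {"g1": np.array(["A"]), "g2": np.array(["B", "C"])}
        )
        assert (out["mean"] == 3.5).all()

    def test_identical_groups_identical_means(self, toy_callset):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.random(4), index=pd.Index([100, 200, 300, 400]))
        out = mean_positional_score(
            toy_callset, scores, {"a": np.array(["A"]), "b": np.array(["A"])}
        )
        assert out["mean"].iloc[0] == out["mean"].iloc[1]

    def test_affine_transform_response(self, toy_callset):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.random(4), index=pd.Index([100, 200, 300, 400]))
        g = {"a": np.array(["A", "B"])}
        base = mean_positional_score(toy_callset, scores, g)["mean"].iloc[0]
        shifted = mean_positional_score(toy_callset, 2 * scores + 1, g)["mean"].iloc[0]
        assert shifted == pytest.approx(2 * base + 1)

    def test_unscored_positions_dropped_and_counted(self, toy_callset):
        scores = pd.Series(1.0, index=pd.Index([100, 200]))
        out = mean_positional_score(toy_callset, scores, {"a": np.array(["A", "B", "C"])})
        assert out["n_unscored"].iloc[0] == 2
        assert out["n_variants"].iloc[0] == 3
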