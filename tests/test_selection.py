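import numpy as np
import pandas as pd
import pytest

from mthet import (
    GeneModel,
    ReferenceGenome,
    annotate_consequence,
    compute_dnds,
    draw_null_callset,
    enumerate_possible_snvs,
    heteroplasmy_shift,
    sampling_null_dnds,
)
from mthet.genes import Gene
from mthet.selection import translate_codon


@pytest.fixture(scope="module")
def toy_gene_system():
    """Two 3-codon genes, one per strand, both coding ATG GCA TCA."""
    seq = "ATGGCATCA" + "TGATGCCAT" + "A" * 42
    ref = ReferenceGenome(seq)
    model = GeneModel(
        [Gene("FWD", 1, 9, "heavy"), Gene("REV", 10, 18, "light")], ref.length
    )
    return ref, model


class TestEnumeration:
    def test_row_counts(self):
        assert len(enumerate_possible_snvs(ReferenceGenome("ACGTA"), ori=None)) == 15
        assert len(enumerate_possible_snvs(ReferenceGenome("ACGTN"), ori=None)) == 12

    def test_rcrs_total(self, rcrs_ref):
        table = enumerate_possible_snvs(rcrs_ref)
        assert len(table) == 49704
        assert not (table["pos"] == 3107).any()

    def test_deterministic_ordering(self, small_ref):
        table = enumerate_possible_snvs(small_ref, ori=None)
        assert table.equals(table.sort_values(["pos", "alt"], kind="stable").reset_index(drop=True))
        assert table.groupby("pos").size().eq(3).all()


class TestConsequences:
    def test_mito_code_specifics(self):
        # vertebrate mitochondrial code: ATA is Met, AGA/AGG are stops, TGA is Trp
        assert translate_codon("ATA") == "M"
        assert translate_codon("AGA") == "*"
        assert translate_codon("TGA") == "W"

    @pytest.mark.parametrize(
        "pos,ref_base,alt,expected",
        [
            (3, "G", "A", "synonymous"),  # ATG -> ATA, Met under mito code
            (5, "C", "A", "nonsynonymous"),  # GCA -> GAA, Ala -> Glu
            (8, "C", "A", "pLoF"),  # TCA -> TAA, gained stop
            (9, "A", "G", "synonymous"),  # TCA -> TCG, Ser
            (20, "A", "G", "noncoding"),  # outside any gene
        ],
    )
    def test_forward_gene(self, toy_gene_system, pos, ref_base, alt, expected):
        ref, model = toy_gene_system
        snvs = pd.DataFrame({"pos": [pos], "ref": [ref_base], "alt": [alt]})
        out = annotate_consequence(snvs, model, ref)
        assert out["consequence"].iloc[0] == expected

    def test_reverse_strand_gene(self, toy_gene_system):
        ref, model = toy_gene_system
        # position 16 is codon 1 position 3 of REV (coding base G); C>T on the
        # reference is G>A on the coding strand: ATG -> ATA, synonymous
        out = annotate_consequence(
            pd.DataFrame({"pos": [16], "ref": ["C"], "alt": ["T"]}), model, ref
        )
        assert out["gene"].iloc[0] == "REV"
        assert out["consequence"].iloc[0] == "synonymous"

    def test_ref_mismatch_raises(self, toy_gene_system):
        ref, model = toy_gene_system
        with pytest.raises(ValueError):
            annotate_consequence(
                pd.DataFrame({"pos": [1], "ref": ["C"], "alt": ["T"]}), model, ref
            )

    def test_full_annotation_consistency(self, rcrs_ref, rcrs_genes):
        table = annotate_consequence(
            enumerate_possible_snvs(rcrs_ref), rcrs_genes, rcrs_ref
        )
        in_gene = table["gene"].notna()
        assert (table.loc[~in_gene, "consequence"] == "noncoding").all()
        assert set(table.loc[in_gene, "consequence"]) <= {
            "synonymous", "nonsynonymous", "pLoF", "noncoding",
        }


def _possible(n_nonsyn, n_syn, gene="G1"):
    return pd.DataFrame(
        {
            "pos": range(n_nonsyn + n_syn),
            "ref": "C",
            "alt": "T",
            "gene": gene,
            "consequence": ["nonsynonymous"] * n_nonsyn + ["synonymous"] * n_syn,
            "substitution": "C>T",
            "strand": "heavy",
            "age_accumulating": True,
        }
    )


def _observed(n_nonsyn, n_syn, gene="G1", hl=0.1):
    df = _possible(n_nonsyn, n_syn, gene)
    df.insert(0, "sample_id", [f"S{i}" for i in range(len(df))])
    df["HL"] = hl
    return df


class TestDnDs:
    def test_hand_computed_ratio(self):
        res = compute_dnds(_observed(2, 1), _possible(10, 5), class_subset=None)
        assert res.dn == pytest.approx(0.2)
        assert res.ds == pytest.approx(0.2)
        assert res.ratio == pytest.approx(1.0)

    def test_zero_synonymous_flagged_undefined(self):
        res = compute_dnds(_observed(2, 0), _possible(10, 5), class_subset=None)
        assert np.isnan(res.ratio) and not res.defined

    def test_two_gene_oracle(self, toy_gene_system):
        """Counts match a hand enumeration on the two-gene toy genome."""
        ref, model = toy_gene_system
        possible = annotate_consequence(enumerate_possible_snvs(ref, ori=None), model, ref)
        fwd = possible[possible["gene"] == "FWD"]
        # hand enumeration: 9 coding positions x 3 alts
        by_hand = {"synonymous": 0, "nonsynonymous": 0, "pLoF": 0}
        codons = ["ATG", "GCA", "TCA"]
        for ci, codon in enumerate(codons):
            for j in range(3):
                for alt in "ACGT":
                    if alt == codon[j]:
                        continue
                    new = codon[:j] + alt + codon[j + 1 :]
                    aa0, aa1 = translate_codon(codon), translate_codon(new)
                    key = (
                        "synonymous" if aa0 == aa1
                        else "pLoF" if aa1 == "*"
                        else "nonsynonymous"
                    )
                    by_hand[key] += 1
        assert fwd["consequence"].value_counts().to_dict() == {
            k: v for k, v in by_hand.items() if v
        }

    def test_record_multiplicity_counts(self):
        obs = pd.concat([_observed(1, 1)] * 3, ignore_index=True)
        res = compute_dnds(obs, _possible(10, 5), class_subset=None)
        assert res.n_obs_nonsyn == 3 and res.n_obs_syn == 3


class TestSamplingNull:
    def _setup(self, rcrs_ref, rcrs_genes, seed=0, n_records=120):
        possible = annotate_consequence(
            enumerate_possible_snvs(rcrs_ref), rcrs_genes, rcrs_ref
        )
        gene = rcrs_genes.genes[0].name
        pool = possible[possible["gene"] == gene]
        pool = pool[pool["age_accumulating"]]
        rng = np.random.default_rng(seed)
        obs = pool.iloc[rng.choice(len(pool), size=n_records, replace=True)].copy()
        obs.insert(0, "sample_id", rng.choice([f"S{i}" for i in range(20)], n_records))
        obs["HL"] = rng.uniform(0.02, 0.9, n_records)
        return possible, gene, obs

    def test_null_preserves_per_individual_class_counts(self, rcrs_ref, rcrs_genes):
        possible, gene, obs = self._setup(rcrs_ref, rcrs_genes)
        null = draw_null_callset(obs, possible, gene=gene, seed=1)
        key = ["sample_id", "substitution", "strand"]
        a = obs.groupby(key).size().sort_index()
        b = null.groupby(key).size().sort_index()
        pd.testing.assert_series_equal(a, b)
        # each individual's draw is without replacement
        assert not null.duplicated(subset=["sample_id", "pos", "alt"]).any()

    def test_seed_reproducibility(self, rcrs_ref, rcrs_genes):
        possible, gene, obs = self._setup(rcrs_ref, rcrs_genes)
        r1 = sampling_null_dnds(obs, possible, gene=gene, n_reps=50, seed=7)
        r2 = sampling_null_dnds(obs, possible, gene=gene, n_reps=50, seed=7)
        assert np.array_equal(r1.null_ratios, r2.null_ratios, equal_nan=True)

    def test_uniform_observed_near_neutral(self, rcrs_ref, rcrs_genes):
        possible, gene, obs = self._setup(rcrs_ref, rcrs_genes, seed=3, n_records=200)
        res = sampling_null_dnds(obs, possible, gene=gene, n_reps=400, seed=4)
        assert res.defined
        assert res.null_lo <= res.ratio <= res.null_hi

    def test_degenerate_empty_observed(self, rcrs_ref, rcrs_genes):
        possible, gene, obs = self._setup(rcrs_ref, rcrs_genes)
        res = sampling_null_dnds(obs.iloc[0:0], possible, gene=gene, n_reps=20, seed=0)
        assert np.isnan(res.null_ratios).all()
        assert np.isnan(res.null_median) and np.isnan(res.observed_percentile)

    def test_count_exceeding_pool_raises(self):
        obs = pd.concat([_observed(6, 0)] * 5, ignore_index=True)
        obs["sample_id"] = "S0"  # 30 records of one class for one person
        with pytest.raises(ValueError, match="exceed"):
            sampling_null_dnds(obs, _possible(10, 5), n_reps=5, class_subset=None)

    def test_purifying_selection_declines_across_hl_bins(self, rcrs_ref, rcrs_genes):
        """Thinning nonsynonymous records with probability rising in HL
        (purifying selection at high heteroplasmy) yields monotone-declining
        dN/dS across HL bins."""
        possible, gene, obs = self._setup(rcrs_ref, rcrs_genes, seed=5, n_records=6000)
        rng = np.random.default_rng(6)
        keep = (obs["consequence"] != "nonsynonymous") | (
            rng.random(len(obs)) > obs["HL"]
        )
        thinned = obs[keep]
        bins = [(0.0, 0.3), (0.3, 0.6), (0.6, 0.95)]
        ratios = [
            compute_dnds(thinned, possible, gene=gene, hl_bin=b).ratio for b in bins
        ]
        assert ratios[0] > ratios[1] > ratios[2]


class TestHeteroplasmyShift:
    def _frame(self, hl_a, hl_b):
        return pd.DataFrame(
            {
                "HL": np.concatenate([hl_a, hl_b]),
                "consequence": ["nonsynonymous"] * len(hl_a) + ["synonymous"] * len(hl_b),
                "gene": "G1",
            }
        )

    def test_identical_distributions(self):
        rng = np.random.default_rng(0)
        hl = rng.uniform(0.05, 0.9, 1000)
        res = heteroplasmy_shift(self._frame(hl[:500], hl[500:]))
        assert abs(res["statistic"]) < 0.1
        assert res["p"] > 0.001

    def test_left_shift_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.beta(1, 6, 400)  # missense at lower HL
        b = rng.beta(2, 2, 400)
        res = heteroplasmy_shift(self._frame(a, b))
        assert res["direction"] == -1 and res["p"] < 1e-6
        # ECDF of the left-shifted arm dominates
        assert res["ecdf_a"].evaluate(0.2) > res["ecdf_b"].evaluate(0.2)

    def test_single_variant_arms(self):
        res = heteroplasmy_shift(self._frame(np.array([0.1]), np.array([0.5])))
        assert 0 < res["p"] <= 1.0

    def test_empty_arm_no_estimate(self):
        res = heteroplasmy_shift(self._frame(np.array([]), np.array([0.5])))
        assert res["statistic"] is None and res["p"] is None
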