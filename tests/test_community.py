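import math

import numpy as np
import pandas as pd
import pytest

from oracles import brute_classify, brute_cluster, expected_richness

from funcmark.community import (
    OtuTable,
    Read,
    alpha_diversity,
    bray_curtis,
    classify,
    cluster_otus,
    denoise,
    filter_reads,
    rarefaction_curve,
    subsample,
)
from funcmark.seqdb import SequenceRecord


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestFilterReads:
    def test_length_and_ambiguity_rules(self):
        reads = [
            Read("ok", "A" * 133, "S1"),
            Read("short", "A" * 119, "S1"),
            Read("long", "A" * 161, "S1"),
            Read("amb", "A" * 100 + "N" + "A" * 29, "S1"),
        ]
        kept, rejected = filter_reads(reads)
        assert [r.id for r in kept] == ["ok"]
        assert dict(rejected) == {
            "short": "too_short",
            "long": "too_long",
            "amb": "ambiguous",
        }

    def test_boundaries_inclusive(self):
        kept, _ = filter_reads([Read("a", "A" * 120, "S"), Read("b", "A" * 160, "S")])
        assert len(kept) == 2


class TestDenoise:
    def test_dereplication_and_singleton_drop(self):
        reads = [
            Read("r1", "ACGT" * 35, "S1"),
            Read("r2", "ACGT" * 35, "S1"),
            Read("r3", "TTTT" * 35, "S1"),
        ]
        with_flag = denoise(reads, drop_singletons=True)
        assert len(with_flag) == 1 and with_flag[0].abundance == 2

    def test_flag_off_is_lossless(self):
        rng = np.random.default_rng(1)
        reads = [
            Read(f"r{i}", random_seq(rng, 130), f"S{i % 2}") for i in range(20)
        ]
        uniques = denoise(reads)
        assert sum(u.abundance for u in uniques) == len(reads)
        assert {u.seq for u in uniques} == {r.seq for r in reads}

    def test_all_identical_collapse_to_one(self):
        reads = [Read(f"r{i}", "ACGT" * 33, "S1") for i in range(7)]
        uniques = denoise(reads)
        assert len(uniques) == 1 and uniques[0].abundance == 7
        assert uniques[0].rep_id == "r0"


class TestClusterOtus:
    def test_identical_sequences_one_otu(self):
        reads = [Read(f"r{i}", "ACGT" * 33, "S1") for i in range(5)]
        table = cluster_otus(denoise(reads))
        assert table.otus == ["OTU_1"]
        assert table.counts.loc["S1", "OTU_1"] == 5

    def test_ten_percent_divergence_two_otus(self):
        rng = np.random.default_rng(2)
        a = random_seq(rng, 130)
        b = mutate(a, list(range(0, 130, 10)))  # 13 subs = 10%
        reads = [Read("r1", a, "S1"), Read("r2", a, "S1"), Read("r3", b, "S1")]
        table = cluster_otus(denoise(reads))
        assert len(table.otus) == 2

    def test_three_subs_in_133nt_join_centroid(self):
        rng = np.random.default_rng(3)
        cent = random_seq(rng, 133)
        variant = mutate(cent, [5, 60, 120])  # 3/133 = 2.26% < 3%
        reads = [Read("r1", cent, "S1")] * 3 + [Read("r4", variant, "S1")]
        reads = [Read(f"r{i}", r.seq, "S1") for i, r in enumerate(reads)]
        table = cluster_otus(denoise(reads))
        assert len(table.otus) == 1
        assert table.counts.loc["S1", "OTU_1"] == 4

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        base = random_seq(rng, 100)
        reads = []
        for i in range(12):
            seq = mutate(base, list(rng.integers(0, 100, size=rng.integers(0, 8))))
            reads.append(Read(f"r{i:02d}", seq, "S1"))
        t1 = cluster_otus(denoise(reads))
        t2 = cluster_otus(denoise(reads[::-1]))
        assert t1.centroids == t2.centroids
        pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_matches_greedy_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            base = random_seq(rng, 60)
            reads = []
            for i in range(int(rng.integers(4, 12))):
                nmut = int(rng.integers(0, 6))
                seq = mutate(base, sorted(set(rng.integers(0, 60, size=nmut))))
                for dup in range(int(rng.integers(1, 4))):
                    reads.append(Read(f"r{i:02d}_{dup}", seq, "S1"))
            uniques = denoise(reads)
            table = cluster_otus(uniques)
            expected = brute_cluster(
                [(u.seq, u.abundance, u.rep_id) for u in uniques]
            )
            assert list(table.centroids.values()) == [c for c, _ in expected]

    def test_every_read_counted_once(self):
        rng = np.random.default_rng(6)
        reads = [Read(f"r{i}", random_seq(rng, 80), "S1") for i in range(25)]
        table = cluster_otus(denoise(reads))
        assert int(table.counts.to_numpy().sum()) == 25


class TestClassify:
    def make_db(self, rng, n=20):
        genera = ["Acidovorax", "Burkholderia", "Pseudomonas", "Variovorax"]
        return [
            SequenceRecord(
                f"DB{i:03d}", f"{genera[i % 4]} sp{i}", random_seq(rng, 60)
            )
            for i in range(n)
        ]

    def test_exact_hit_full_identity(self):
        rng = np.random.default_rng(17)
        db = self.make_db(rng)
        taxon, ident = classify(db[3].seq, db)
        assert ident == 1.0 and taxon == db[3].genus

    def test_tie_breaks_to_smaller_id(self):
        db = [
            SequenceRecord("B2", "Ralstonia x", "ACGTACGTAC"),
            SequenceRecord("A1", "Pseudomonas y", "ACGTACGTAC"),
        ]
        taxon, ident = classify("ACGTACGTAC", db)
        assert taxon == "Pseudomonas" and ident == 1.0

    def test_matches_exhaustive_pairwise_scan(self):
        rng = np.random.default_rng(17)
        db = self.make_db(rng)
        for _ in range(100):
            if rng.random() < 0.5:
                centroid = random_seq(rng, 60)
            else:  # near-hit: mutated db entry
                src = db[int(rng.integers(0, len(db)))]
                centroid = mutate(
                    src.seq, sorted(set(rng.integers(0, 60, size=3)))
                )
            assert classify(centroid, db) == brute_classify(centroid, db)

    def test_empty_db_errors(self):
        with pytest.raises(ValueError):
            classify("ACGT", [])


def toy_table():
    counts = pd.DataFrame(
        {"OTU_1": [30, 5], "OTU_2": [20, 0], "OTU_3": [50, 45]},
        index=["S1", "S2"],
    )
    cents = {"OTU_1": "A" * 50, "OTU_2": "C" * 50, "OTU_3": "G" * 50}
    return OtuTable(counts, cents)


class TestSubsample:
    def test_depth_equal_to_total_is_identity(self):
        table = toy_table()
        out = subsample(table, 50, seed=0)
        assert (out.counts.loc["S2"] == table.counts.loc["S2"]).all()

    def test_totals_exactly_depth(self):
        out = subsample(toy_table(), 40, seed=1)
        assert (out.counts.sum(axis=1) == 40).all()

    def test_shallow_sample_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            out = subsample(toy_table(), 60, seed=2)
        assert out.samples == ["S1"]

    def test_reproducible_under_seed(self):
        a = subsample(toy_table(), 40, seed=42)
        b = subsample(toy_table(), 40, seed=42)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_hypergeometric_expectation(self):
        table = toy_table()
        depth = 40
        draws = np.array(
            [
                subsample(table, depth, seed=s).counts.loc["S1"].to_numpy()
                for s in range(1000)
            ]
        )
        p = table.counts.loc["S1"].to_numpy() / 100
        expected = depth * p
        # within 3 sigma of the hypergeometric mean of the 1000-draw average
        var = depth * p * (1 - p) * (100 - depth) / 99
        se = np.sqrt(var / 1000)
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 3 * se + 1e-9)


class TestAlphaDiversity:
    def test_single_otu_degenerate(self):
        rec = alpha_diversity([42])
        assert rec.shannon == 0.0 and rec.simpson == 1.0 and rec.chao1 == 1.0

    def test_hand_computed_values(self):
        rec = alpha_diversity([5, 3, 2])
        assert rec.shannon == pytest.approx(1.0297, abs=1e-4)
        assert rec.simpson == pytest.approx(0.38, abs=1e-4)

    def test_chao1_singletons_doubletons(self):
        # S_obs = 10, n1 = 4, n2 = 2 -> 10 + 16/4 = 14
        counts = [1, 1, 1, 1, 2, 2, 5, 7, 9, 11]
        assert alpha_diversity(counts).chao1 == pytest.approx(14.0)

    def test_chao1_bias_corrected_when_no_doubletons(self):
        counts = [1, 1, 1, 5, 9]
        assert alpha_diversity(counts).chao1 == pytest.approx(5 + 3 * 2 / 2)

    def test_matches_skbio(self):
        from skbio.diversity.alpha import chao1, dominance, shannon

        rng = np.random.default_rng(19)
        for _ in range(20):
            counts = rng.integers(1, 30, size=rng.integers(2, 15))
            rec = alpha_diversity(counts)
            assert rec.shannon == pytest.approx(shannon(counts, base=math.e))
            assert rec.simpson == pytest.approx(dominance(counts))
            assert rec.chao1 == pytest.approx(
                chao1(counts, bias_corrected=(counts == 2).sum() == 0)
            )

    def test_shannon_bounds_and_chao_floor(self):
        rng = np.random.default_rng(20)
        for _ in range(50):
            counts = rng.integers(1, 50, size=rng.integers(1, 20))
            rec = alpha_diversity(counts)
            assert 0 <= rec.shannon <= math.log(rec.s_obs) + 1e-12
            assert rec.chao1 >= rec.s_obs

    def test_uniform_maximizes_shannon(self):
        assert alpha_diversity([10, 10, 10]).shannon == pytest.approx(math.log(3))

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            alpha_diversity([0, 0])


class TestRarefaction:
    def test_extreme_depths(self):
        counts = [5, 3, 2]
        curve = rarefaction_curve(counts, [1, 10], reps=20, seed=0)
        assert curve[1] == 1.0
        assert curve[10] == 3.0

    def test_matches_hypergeometric_closed_form(self):
        counts = [40, 25, 10, 4, 1]
        reps = 400
        curve = rarefaction_curve(counts, [5, 20, 50], reps=reps, seed=7)
        for depth, mean_obs in curve.items():
            exp = expected_richness(counts, depth)
            # binomial-ish Monte Carlo error bound on the mean of `reps` draws
            assert abs(mean_obs - exp) < 4 * math.sqrt(len(counts) / reps) + 0.05


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        counts = pd.DataFrame(
            {"O1": [5, 5, 0], "O2": [2, 2, 0], "O3": [0, 0, 9]},
            index=["A", "B", "C"],
        )
        table = OtuTable(counts, {o: "A" * 10 for o in counts.columns})
        d = bray_curtis(table)
        iA, iB, iC = (d.labels.index(x) for x in "ABC")
        assert d.values[iA, iB] == pytest.approx(0.0)
        assert d.values[iA, iC] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        counts = pd.DataFrame({"O1": [2, 2], "O2": [0, 4], "O3": [4, 0]},
                              index=["A", "B"])
        table = OtuTable(counts, {o: "A" * 10 for o in counts.columns})
        d = bray_curtis(table)
        assert d.values[0, 1] == pytest.approx(8 / 12)

    def test_matches_scipy(self):
        from scipy.spatial.distance import braycurtis

        rng = np.random.default_rng(21)
        counts = pd.DataFrame(
            rng.integers(0, 40, size=(4, 6)) + np.eye(4, 6, dtype=int),
            index=list("ABCD"),
            columns=[f"O{i}" for i in range(6)],
        )
        table = OtuTable(counts, {f"O{i}": "A" * 5 for i in range(6)})
        d = bray_curtis(table)
        for i in range(4):
            for j in range(4):
                ref = 0.0 if i == j else braycurtis(
                    counts.iloc[i].to_numpy(), counts.iloc[j].to_numpy()
                )
                assert d.values[i, j] == pytest.approx(ref)

    def test_zero_total_sample_errors(self):
        counts = pd.DataFrame({"O1": [5, 0]}, index=["A", "B"])
        table = OtuTable(counts, {"O1": "AAAA"})
        with pytest.raises(ValueError, match="zero total"):
            bray_curtis(table)
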