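import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from skbio.diversity import alpha as skbio_alpha

from stromalab import diversity as dv
from stromalab import synthetic as syn


class TestReadFilter:
    def _read(self, seq, q):
        return dv.ReadRecord("r", seq, [q] * len(seq))

    def test_mean_quality_boundary(self):
        seq = "ACGT" * 60
        good = dv.ReadRecord("g", seq, [25] * len(seq))
        bad = dv.ReadRecord("b", seq, [25] * (len(seq) - 1) + [1])  # mean < 25
        kept, rej = dv.filter_reads([good, bad])
        assert [r.identifier for r in kept] == ["g"]
        assert rej["quality"] == 1

    def test_homopolymer_boundary(self):
        ok = self._read("ACG" + "A" * 6 + "CGT" * 64, 30)
        too_long = self._read("ACG" + "A" * 7 + "CGT" * 64, 30)
        kept, rej = dv.filter_reads([ok, too_long])
        assert len(kept) == 1
        assert rej["homopolymer"] == 1

    def test_length_bounds(self):
        short = self._read("ACGT" * 49, 30)   # 196 < 200
        long_ = self._read("ACGT" * 251, 30)  # 1004 > 1000
        ok = self._read("ACGT" * 50, 30)
        kept, rej = dv.filter_reads([short, long_, ok])
        assert len(kept) == 1
        assert rej["length"] == 2

    def test_primer_mismatch_with_ambiguity(self):
        primer = "GTGCCAGCMGCCGCGGTAA"
        body = "ACGT" * 60
        match_a = self._read(primer.replace("M", "A") + body, 30)
        match_c = self._read(primer.replace("M", "C") + body, 30)
        mismatch = self._read("T" + primer.replace("M", "A")[1:] + body, 30)
        kept, rej = dv.filter_reads([match_a, match_c, mismatch], primer=primer)
        assert len(kept) == 2
        assert rej["primer"] == 1

    def test_planned_violation_ledger(self):
        plan = {i: {"quality"} for i in range(5)}
        plan.update({i: {"homopolymer"} for i in range(5, 9)})
        plan[9] = {"length_short", "quality"}
        reads, truth = syn.make_reads(50, plan, seed=11)
        kept, rej = dv.filter_reads(reads, primer=syn._PRIMER_515F)
        assert len(kept) == 40
        assert rej["quality"] == 6
        assert rej["homopolymer"] == 4
        assert rej["length"] == 1

    def test_fastq_roundtrip(self, tmp_path):
        reads, _ = syn.make_reads(5, seed=1)
        path = tmp_path / "reads.fastq"
        with open(path, "w") as fh:
            for r in reads:
                fh.write(f"@{r.identifier}\n{r.sequence}\n+\n")
                fh.write("".join(chr(q + 33) for q in r.qualities) + "\n")
        back = dv.read_fastq(path)
        assert [r.sequence for r in back] == [r.sequence for r in reads]
        assert [r.qualities for r in back] == [r.qualities for r in reads]


class TestDropRareOtus:
    def test_direct_rule(self):
        counts = pd.DataFrame({"A": [1, 2, 3]}, index=["o1", "o2", "o3"])
        table = dv.OTUTable(counts)
        out = dv.drop_rare_otus(table)
        assert list(out.counts.index) == ["o3"]

    def test_max_count_zero_is_identity(self, small_table):
        out = dv.drop_rare_otus(small_table, max_count=0)
        pd.testing.assert_frame_equal(out.counts, small_table.counts)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(0, 5, size=(30, 4)),
            index=[f"o{i}" for i in range(30)],
            columns=list("WXYZ"),
        )
        table = dv.OTUTable(counts)
        out = dv.drop_rare_otus(table, max_count=2)
        expected = [o for o in counts.index if counts.loc[o].sum() > 2]
        assert list(out.counts.index) == expected


class TestSubsampling:
    def test_depth_equals_total_identity(self, small_table):
        total = int(small_table.sample_totals["A"])
        sub = dv.subsample_replicates(small_table, depth=6, replicates=1, seed=0)[0]
        # sample C has exactly 6 reads: the subsample must equal the original
        pd.testing.assert_series_equal(
            sub.counts["C"], small_table.counts["C"], check_names=False
        )

    def test_totals_exact_and_reproducible(self, small_table):
        subs1 = dv.subsample_replicates(small_table, depth=6, replicates=3, seed=42)
        subs2 = dv.subsample_replicates(small_table, depth=6, replicates=3, seed=42)
        for t1, t2 in zip(subs1, subs2):
            assert (t1.sample_totals == 6).all()
            pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_small_samples_dropped_with_warning(self, small_table):
        with pytest.warns(UserWarning, match="C"):
            subs = dv.subsample_replicates(small_table, depth=20, replicates=1, seed=0)
        assert subs[0].samples == ["A", "B"]

    def test_hypergeometric_expectation(self):
        counts = pd.DataFrame({"S": [60, 30, 10]}, index=["a", "b", "c"])
        table = dv.OTUTable(counts)
        subs = dv.subsample_replicates(table, depth=50, replicates=400, seed=7)
        mean_a = np.mean([t.counts.loc["a", "S"] for t in subs])
        assert mean_a == pytest.approx(50 * 0.6, rel=0.03)

    def test_richness_never_exceeds_full(self, small_table):
        full = (small_table.counts > 0).sum()
        for t in dv.subsample_replicates(small_table, depth=6, replicates=5, seed=1):
            assert ((t.counts > 0).sum() <= full).all()


class TestAlphaMetrics:
    def test_uniform_closed_form(self):
        counts = pd.DataFrame({"S": [10] * 8}, index=[f"o{i}" for i in range(8)])
        m = dv.alpha_metrics(dv.OTUTable(counts)).loc["S"]
        assert m["observed_otus"] == 8
        assert m["shannon"] == pytest.approx(np.log(8))
        assert m["equitability"] == pytest.approx(1.0)

    def test_single_otu_degenerate(self):
        counts = pd.DataFrame({"S": [50, 0]}, index=["o1", "o2"])
        m = dv.alpha_metrics(dv.OTUTable(counts)).loc["S"]
        assert m["shannon"] == 0.0
        assert m["equitability"] == 0.0

    def test_chao1_formula(self):
        # S_obs=10, F1=4, F2=2 -> 10 + 16/4 = 14
        counts = pd.DataFrame(
            {"S": [1, 1, 1, 1, 2, 2, 3, 4, 5, 6]},
            index=[f"o{i}" for i in range(10)],
        )
        m = dv.alpha_metrics(dv.OTUTable(counts)).loc["S"]
        assert m["chao1"] == pytest.approx(14.0)

    def test_chao1_bias_corrected_when_no_doubletons(self):
        counts = pd.DataFrame({"S": [1, 1, 1, 5]}, index=list("abcd"))
        m = dv.alpha_metrics(dv.OTUTable(counts)).loc["S"]
        assert m["chao1"] == pytest.approx(4 + 3 * 2 / 2)

    def test_matches_skbio_and_direct_summation(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame({"S": rng.integers(0, 20, size=25)},
                              index=[f"o{i}" for i in range(25)])
        counts.loc["o0", "S"] = 3  # ensure non-empty
        m = dv.alpha_metrics(dv.OTUTable(counts)).loc["S"]
        vec = counts["S"].to_numpy()
        p = vec[vec > 0] / vec.sum()
        assert m["shannon"] == pytest.approx(-(p * np.log(p)).sum(), abs=1e-12)
        assert m["shannon"] == pytest.approx(
            float(skbio_alpha.shannon(vec, base=np.e)), abs=1e-9
        )
        # classic Chao1 (we fall back to the bias-corrected form only at F2=0)
        assert m["chao1"] == pytest.approx(
            float(skbio_alpha.chao1(vec, bias_corrected=False)), abs=1e-9
        )

    def test_chao1_never_below_observed(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            vec = rng.integers(0, 6, size=15)
            vec[0] = max(vec[0], 1)
            counts = pd.DataFrame({"S": vec}, index=[f"o{i}" for i in range(15)])
            m = dv.alpha_metrics(dv.OTUTable(counts)).loc["S"]
            assert m["chao1"] >= m["observed_otus"]


class TestRarefaction:
    def test_depth_one_and_total(self, small_table):
        curve = dv.rarefaction_curve(small_table, [1, 6], mode="analytic")
        assert curve.loc[1, "C"] == pytest.approx(1.0)
        s_obs = int((small_table.counts["C"] > 0).sum())
        assert curve.loc[6, "C"] == pytest.approx(s_obs)

    def test_analytic_matches_monte_carlo(self):
        table, _ = syn.make_otu_table(n_samples=1, S=40, depth=2000, seed=2)
        depths = [50, 200, 800]
        ana = dv.rarefaction_curve(table, depths, mode="analytic")
        reps = 1000
        mc = dv.rarefaction_curve(table, depths, reps=reps, mode="montecarlo", seed=4)
        for d in depths:
            diff = abs(ana.loc[d].iloc[0] - mc.loc[d].iloc[0])
            # binomial-ish spread of observed richness across subsamples
            se = np.sqrt(ana.loc[d].iloc[0]) / np.sqrt(reps)
            assert diff < 3 * max(se, 0.05)

    def test_curve_non_decreasing(self, small_table):
        curve = dv.rarefaction_curve(small_table, [1, 2, 3, 4, 5, 6], mode="analytic")
        assert (curve.diff().dropna() >= -1e-9).all().all()


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        counts = pd.DataFrame(
            {"A": [5, 5, 0, 0], "B": [5, 5, 0, 0], "C": [0, 0, 3, 7]},
            index=[f"o{i}" for i in range(4)],
        )
        phylum = pd.Series(["P1", "P2", "P3", "P4"], index=counts.index)
        bc = dv.bray_curtis(dv.OTUTable(counts, phylum=phylum))
        assert bc.loc["A", "B"] == pytest.approx(0.0)
        assert bc.loc["A", "C"] == pytest.approx(1.0)
        assert np.allclose(bc.values, bc.values.T)
        assert np.all(np.diag(bc.values) == 0)

    def test_matches_scipy_formula(self, small_table):
        bc = dv.bray_curtis(small_table, level="otu")
        rel = small_table.counts / small_table.counts.sum()
        for a in "ABC":
            for b in "ABC":
                expected = scipy_braycurtis(rel[a], rel[b]) if a != b else 0.0
                assert bc.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_phylum_collapse(self, small_table):
        collapsed = dv.collapse_phylum(small_table)
        assert list(collapsed.index) == ["P1", "P2", "P3"]
        assert collapsed.loc["P1", "A"] == 15


class TestUPGMA:
    def test_two_leaves_half_distance(self):
        d = pd.DataFrame([[0.0, 0.8], [0.8, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        tree = dv.upgma(d)
        tips = {t.name: t.length for t in tree.tips()}
        assert tips == {"a": pytest.approx(0.4), "b": pytest.approx(0.4)}

    def test_hand_worked_four_point_case(self):
        # a-b=2, c-d=4, between-group average 8:
        # ((a:1,b:1):3,(c:2,d:2):2) with all leaves at height 4
        names = list("abcd")
        d = pd.DataFrame(
            [[0, 2, 6, 10], [2, 0, 6, 10], [6, 6, 0, 4], [10, 10, 4, 0]],
            index=names, columns=names, dtype=float,
        )
        tree = dv.upgma(d)
        assert {t.name for t in tree.tips()} == set(names)
        assert tree.find("a").length == pytest.approx(1.0)
        assert tree.find("c").length == pytest.approx(2.0)
        assert tree.find("a").parent.length == pytest.approx(3.0)
        assert tree.find("c").parent.length == pytest.approx(2.0)
        # topology: a with b, c with d
        assert {t.name for t in tree.find("a").parent.tips()} == {"a", "b"}

    def test_ultrametric(self, small_table):
        bc = dv.bray_curtis(small_table, level="otu")
        tree = dv.upgma(bc)
        depths = {t.name: tree.distance(t) for t in tree.tips()}
        vals = list(depths.values())
        assert max(vals) - min(vals) < 1e-9

    def test_order_invariance(self):
        names = list("abcd")
        d = pd.DataFrame(
            [[0, 2, 6, 10], [2, 0, 6, 10], [6, 6, 0, 4], [10, 10, 4, 0]],
            index=names, columns=names, dtype=float,
        )
        shuffled = d.loc[["d", "b", "a", "c"], ["d", "b", "a", "c"]]
        assert str(dv.upgma(d)) == str(dv.upgma(shuffled))

    def test_nan_rejected(self):
        d = pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        with pytest.raises(ValueError):
            dv.upgma(d)


class TestFullReport:
    def test_report_pipeline(self):
        table, _ = syn.make_otu_table(n_samples=3, S=80, depth=3000, seed=6)
        rep = dv.diversity_report(table, depth=1557, replicates=10, seed=0)
        assert set(rep.alpha_mean.columns) == {
            "observed_otus", "shannon", "equitability", "chao1"
        }
        assert rep.bray_curtis.shape == (3, 3)
        assert rep.tree_newick.endswith(";")
        # equitability within [0, 1], shannon within [0, ln(observed)]
        assert ((rep.alpha_mean["equitability"] >= 0)
                & (rep.alpha_mean["equitability"] <= 1)).all()

    def test_replicate_spread_shrinks_with_more_replicates(self):
        table, _ = syn.make_otu_table(n_samples=2, S=60, depth=4000, seed=8)
        few = dv.diversity_report(table, depth=1000, replicates=4, seed=1)
        # standard error of the replicate mean scales as 1/sqrt(reps)
        many = dv.diversity_report(table, depth=1000, replicates=40, seed=1)
        se_few = few.alpha_std["shannon"].iloc[0] / np.sqrt(4)
        se_many = many.alpha_std["shannon"].iloc[0] / np.sqrt(40)
        assert se_many < se_few
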