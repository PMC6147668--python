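import numpy as np
import pandas as pd
import pytest

from conftest import make_peaks, toy_gene_models
from kbcascade.loops import (baseline_expression_by_category, categorize_loops,
                             category_kinetics, filter_pet_clusters,
                             metagene_profile, promoter_polII_status,
                             replicate_overlap)
from kbcascade.peaks import filter_reproducible
from kbcascade.simulate import (SimulationConfig, generate_gene_models,
                                make_truth, simulate_interactions,
                                simulate_peaks)


def make_bedpe(rows):
    df = pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2",
                                     "start2", "end2", "pet_count", "fdr"])
    df.insert(6, "name", [f"pet{i}" for i in range(len(df))])
    return df


class TestPetFilter:
    def test_count_and_fdr_thresholds(self):
        df = make_bedpe([
            ("chr1", 0, 100, "chr1", 500, 600, 1, 0.001),   # count too low
            ("chr1", 0, 100, "chr1", 500, 600, 5, 0.01),    # retained
            ("chr1", 0, 100, "chr1", 500, 600, 5, 0.2),     # FDR too high
            ("chr1", 0, 100, "chr1", 500, 600, 2, 0.05),    # boundary retained
        ])
        out = filter_pet_clusters(df)
        assert list(out["name"]) == ["pet1", "pet3"]

    def test_fifty_cluster_toy_matches_hand_filter(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(50):
            s1 = int(rng.integers(0, 100_000))
            rows.append(("chr1", s1, s1 + 300, "chr1", s1 + 5000, s1 + 5300,
                         int(rng.integers(1, 8)), float(rng.uniform(0, 0.2))))
        df = make_bedpe(rows)
        out = filter_pet_clusters(df, min_count=2, max_fdr=0.05)
        expected = [r.name for r in df.itertuples(index=False)
                    if r.pet_count >= 2 and r.fdr <= 0.05]
        assert list(out["name"]) == expected

    def test_fdr_computed_when_absent(self):
        # one heavily supported pair among singleton noise becomes significant
        rows = [("chr1", 0, 100, "chr1", 1000, 1100, 40, None)]
        for i in range(30):
            s = 10_000 + 2000 * i
            rows.append(("chr1", s, s + 100, "chr1", s + 900, s + 1000, 2, None))
        df = make_bedpe(rows).drop(columns="fdr")
        out = filter_pet_clusters(df)
        assert "pet0" in set(out["name"])

    def test_malformed_bedpe_row_reports_line(self, tmp_path):
        from kbcascade.io import read_bedpe
        path = tmp_path / "bad.bedpe"
        path.write_text("chr1\t0\t100\tchr1\t500\t600\tp1\t3\n"
                        "chr1\t0\t100\tchr1\t500\tX\tp2\t3\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bedpe(path)


class TestReplicateOverlap:
    def test_identical_sets_give_one(self):
        df = make_bedpe([("chr1", 0, 100, "chr1", 500, 600, 3, 0.01)])
        assert replicate_overlap(df, df) == 1.0

    def test_disjoint_chromosomes_give_zero(self):
        a = make_bedpe([("chr1", 0, 100, "chr1", 500, 600, 3, 0.01)])
        b = make_bedpe([("chr2", 0, 100, "chr2", 500, 600, 3, 0.01)])
        assert replicate_overlap(a, b) == 0.0

    def test_half_shared_fixture(self):
        shared = [("chr1", i * 10_000, i * 10_000 + 200,
                   "chr1", i * 10_000 + 5000, i * 10_000 + 5200, 3, 0.01)
                  for i in range(2)]
        only_a = [("chr1", 900_000, 900_200, "chr1", 905_000, 905_200, 3, 0.01),
                  ("chr2", 0, 200, "chr2", 5000, 5200, 3, 0.01)]
        a = make_bedpe(shared + only_a)
        b = make_bedpe(shared)
        assert replicate_overlap(a, b) == 0.5


@pytest.fixture
def three_gene_models():
    return toy_gene_models([
        ("gA", "chr1", 100_000, 130_000, "+"),
        ("gB", "chr1", 200_000, 230_000, "+"),
        ("gC", "chr1", 300_000, 330_000, "-")])


class TestPolIIStatus:
    def test_peak_spanning_tss_is_true(self, three_gene_models):
        pk = make_peaks([("chr1", 99_900, 100_100, 200.0)])
        status = promoter_polII_status(pk, three_gene_models)
        assert bool(status["gA"]) and not status["gB"] and not status["gC"]

    def test_peak_5kb_upstream_is_false(self, three_gene_models):
        pk = make_peaks([("chr1", 94_800, 95_200, 200.0)])
        assert not promoter_polII_status(pk, three_gene_models).any()


class TestCategorize:
    def test_three_trivial_cases(self, three_gene_models):
        polii = pd.Series({"gA": True, "gB": True, "gC": False})
        inter = make_bedpe([
            # intra-gene loop in gA: promoter anchor + body anchor
            ("chr1", 99_900, 100_200, "chr1", 125_000, 125_300, 3, 0.01)])
        out = categorize_loops(inter, polii, three_gene_models)
        assert out.loc["gA", "category"] == "III"
        assert out.loc["gB", "category"] == "II"
        assert out.loc["gC", "category"] == "I"

    def test_promoter_promoter_loop_makes_both_iv(self, three_gene_models):
        polii = pd.Series({"gA": True, "gB": True, "gC": False})
        inter = make_bedpe([
            ("chr1", 99_900, 100_200, "chr1", 199_900, 200_200, 3, 0.01)])
        out = categorize_loops(inter, polii, three_gene_models)
        assert out.loc["gA", "category"] == "IV"
        assert out.loc["gB", "category"] == "IV"

    def test_multi_gene_dominates_single_gene(self, three_gene_models):
        polii = pd.Series({"gA": True, "gB": True, "gC": True})
        inter = make_bedpe([
            ("chr1", 99_900, 100_200, "chr1", 125_000, 125_300, 3, 0.01),
            ("chr1", 99_900, 100_200, "chr1", 199_900, 200_200, 3, 0.01)])
        out = categorize_loops(inter, polii, three_gene_models)
        assert out.loc["gA", "category"] == "IV"

    def test_order_invariance(self, three_gene_models):
        polii = pd.Series({"gA": True, "gB": True, "gC": True})
        inter = make_bedpe([
            ("chr1", 99_900, 100_200, "chr1", 125_000, 125_300, 3, 0.01),
            ("chr1", 299_900, 300_200, "chr1", 325_000, 325_300, 3, 0.01)])
        a = categorize_loops(inter, polii, three_gene_models)
        b = categorize_loops(inter.iloc[::-1].reset_index(drop=True), polii,
                             three_gene_models)
        pd.testing.assert_frame_equal(a, b)


def test_truth_recovery_with_decoys_disabled():
    cfg = SimulationConfig(n_genes=100, seed=17, n_decoy_clusters=0,
                           n_decoy_peaks=0, replicate_reproducibility=1.0,
                           subthreshold_fraction=0.0)
    gm = generate_gene_models(cfg)
    truth = make_truth(gm, cfg)
    inter = filter_pet_clusters(simulate_interactions(gm, truth, cfg))
    pk = simulate_peaks(gm, truth, cfg)
    pol = filter_reproducible(pk[("POLII", 0, 1)], pk[("POLII", 0, 2)])
    status = promoter_polII_status(pol, gm)
    out = categorize_loops(inter, status, gm)
    expected = truth.set_index("gene_id")["true_loop_category"]
    assert (out["category"] == expected.loc[out.index]).all()
    # I and II genes carry no qualifying loops by construction
    t = truth.set_index("gene_id")
    assert set(status.index[status]) == set(
        t.index[t["true_loop_category"].isin(["II", "III", "IV"])])


def test_category_kinetics_crosstab_marginals():
    loop_status = pd.DataFrame(
        {"category": ["III", "I", "IV", "II"]},
        index=["a", "b", "c", "d"])
    records = pd.DataFrame(
        {"class": ["Ad", "Ad", "Ai", "Ai"],
         "pattern_label": ["3Ad", "3Ad", "2Ai", "2Ai"]},
        index=["a", "b", "c", "d"])
    out = category_kinetics(loop_status, records)
    table = out["table"]
    assert table.loc[("Ad", "3Ad")].sum() == 2
    assert table.loc[("Ad", "3Ad"), "looped"] == 1
    assert table.values.sum() == 4


class TestKruskal:
    def test_textbook_three_group_computation(self):
        # ranks 1..9 without ties: H = 12/(9*10) * 3*((2-5)^2+(5-5)^2+(8-5)^2)
        categories = pd.Series(["I"] * 3 + ["II"] * 3 + ["III"] * 3,
                               index=[f"g{i}" for i in range(9)])
        rpm = pd.Series([1, 2, 3, 4, 5, 6, 7, 8, 9.0],
                        index=categories.index)
        out = baseline_expression_by_category(categories, rpm)
        assert out["H"] == pytest.approx(7.2)

    def test_planted_shift_is_significant(self):
        rng = np.random.default_rng(1)
        n = 200
        categories = pd.Series(["I"] * n + ["IV"] * n,
                               index=[f"g{i}" for i in range(2 * n)])
        rpm = pd.Series(np.concatenate([rng.lognormal(0, 1, n),
                                        rng.lognormal(2, 1, n)]),
                        index=categories.index)
        out = baseline_expression_by_category(categories, rpm)
        assert out["p"] < 0.001

    def test_empty_category_warns_and_single_raises(self):
        categories = pd.Series(["I", "I", "II", "II"], index=list("abcd"))
        rpm = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        with pytest.warns(UserWarning, match="category III"):
            baseline_expression_by_category(categories, rpm)
        only = pd.Series(["I", "I"], index=list("ab"))
        with pytest.raises(ValueError, match="2 nonempty"):
            baseline_expression_by_category(only, rpm.loc[list("ab")])


class TestMetagene:
    def test_constant_coverage_gives_flat_profile(self):
        gm = toy_gene_models([("g", "chr1", 1000, 2000, "+")])
        cov = pd.DataFrame([("chr1", 0, 5000, 7.0)],
                           columns=["chrom", "start", "end", "value"])
        profile = metagene_profile(cov, gm, n_bins=50)
        assert np.allclose(profile, 7.0)

    def test_linear_step_ramp_resampled_exactly(self):
        gm = toy_gene_models([("g", "chr1", 0, 1000, "+")])
        cov = pd.DataFrame([("chr1", i * 10, (i + 1) * 10, float(i))
                            for i in range(100)],
                           columns=["chrom", "start", "end", "value"])
        profile = metagene_profile(cov, gm, n_bins=100)
        assert np.allclose(profile, np.arange(100.0))

    def test_minus_strand_orientation(self):
        gm = toy_gene_models([("g", "chr1", 0, 1000, "-")])
        cov = pd.DataFrame([("chr1", 0, 100, 9.0)],  # 5'-skewed in gene coords
                           columns=["chrom", "start", "end", "value"])
        profile = metagene_profile(cov, gm, n_bins=10)
        assert profile[-1] == pytest.approx(9.0)
        assert profile[0] == pytest.approx(0.0)

    def test_short_gene_raises(self):
        gm = toy_gene_models([("g", "chr1", 0, 50, "+")])
        cov = pd.DataFrame(columns=["chrom", "start", "end", "value"])
        with pytest.raises(ValueError, match="shorter"):
            metagene_profile(cov, gm, n_bins=100)
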