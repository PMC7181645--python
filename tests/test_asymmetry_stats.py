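"""Strand-bias statistic, bootstrap, binomial and group tests."""

import math

import numpy as np
import pandas as pd
import pytest

from indelstrand import (
    StrandCounts,
    asymmetry_matrix,
    binomial_strand_test,
    bootstrap_bias,
    downsample_zscore,
    group_comparison,
    msi_enrichment_ratio,
    simulate_gene_counts,
    strand_bias,
    substitution_orientation,
)
from indelstrand.genome_io import GeneRecord


class TestStrandBias:
    def test_basic_arithmetic(self):
        est = strand_bias(StrandCounts(20, 10, 100, 100))
        assert est.A == pytest.approx(0.2)
        assert est.B == pytest.approx(0.1)
        assert est.bias == pytest.approx(2 / 3)
        assert est.excess_pct == pytest.approx(100.0)

    def test_equal_densities(self):
        est = strand_bias(StrandCounts(15, 15, 100, 100))
        assert est.bias == pytest.approx(0.5)
        assert est.excess_pct == pytest.approx(0.0)

    def test_background_correction_removes_reference_skew(self):
        est = strand_bias(StrandCounts(30, 25, 120, 100))
        assert est.bias == pytest.approx(0.5)

    def test_scaling_invariance(self):
        a = strand_bias(StrandCounts(30, 25, 120, 100))
        b = strand_bias(StrandCounts(90, 25, 360, 100))
        assert a.bias == pytest.approx(b.bias)

    def test_undefined_cases(self):
        assert not strand_bias(StrandCounts(5, 5, 0, 10)).defined
        assert not strand_bias(StrandCounts(0, 0, 10, 10)).defined


class TestBootstrap:
    def _counts(self, rows):
        df = pd.DataFrame(rows, columns=["nt_indels", "t_indels", "nt_motifs", "t_motifs"])
        df.index = [f"g{i}" for i in range(len(df))]
        return StrandCounts(*(int(df[c].sum()) for c in df.columns), per_gene=df)

    def test_identical_genes_zero_sd(self):
        c = self._counts([[2, 1, 10, 10]] * 50)
        est = bootstrap_bias(c, n_boot=200, seed=0)
        assert est.boot_sd == pytest.approx(0.0, abs=1e-12)
        assert est.boot_mean == pytest.approx(2 / 3)

    def test_reproducible_given_seed(self):
        c = simulate_gene_counts(200, 1000, beta=0.6, seed=3)
        a = bootstrap_bias(c, n_boot=300, seed=7)
        b = bootstrap_bias(c, n_boot=300, seed=7)
        assert (a.boot_mean, a.boot_sd) == (b.boot_mean, b.boot_sd)

    def test_recovers_planted_bias(self):
        c = simulate_gene_counts(1000, 5000, beta=0.60, q=0.55, seed=4)
        est = bootstrap_bias(c, n_boot=500, seed=5)
        assert abs(est.boot_mean - 0.60) < 3 * est.boot_sd + 1e-9

    def test_sd_shrinks_with_gene_count(self):
        rng = np.random.default_rng(6)
        c1 = simulate_gene_counts(400, 4000, beta=0.55, rng=rng)
        c2 = simulate_gene_counts(800, 8000, beta=0.55, rng=rng)
        sd1 = bootstrap_bias(c1, n_boot=500, seed=1).boot_sd
        sd2 = bootstrap_bias(c2, n_boot=500, seed=1).boot_sd
        assert 1.1 < sd1 / sd2 < 1.9  # ~sqrt(2)

    def test_all_zero_counts_error(self):
        c = self._counts([[0, 0, 5, 5]] * 10)
        with pytest.raises(ValueError):
            bootstrap_bias(c)


def exact_binom_two_sided(k, n, p0):
    """Oracle: direct pmf summation of all outcomes at most as likely as k."""
    pmf = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    return sum(p for p in pmf if p <= pmf[k] * (1 + 1e-12))


class TestBinomialTest:
    def test_balanced_counts_p_one(self):
        p = binomial_strand_test(StrandCounts(10, 10, 50, 50))
        assert p > 0.8

    def test_pah_polyg_counts_significant(self):
        # 77 non-template vs 39 template indels at polyG tracts
        p = binomial_strand_test(StrandCounts(77, 39, 100, 100))
        assert p < 0.001
        assert p == pytest.approx(exact_binom_two_sided(77, 116, 0.5), rel=1e-6)

    def test_motif_share_null(self):
        # skewed background: counts proportional to motifs are not significant
        p = binomial_strand_test(StrandCounts(120, 100, 1200, 1000))
        assert p > 0.5
        p_half = binomial_strand_test(StrandCounts(120, 100, 1200, 1000), null_half=True)
        assert p_half < p  # uncorrected test sees the background skew as signal

    def test_agrees_with_oracle_on_random_counts(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(2, 60))
            k = int(rng.integers(0, n + 1))
            m_nt = int(rng.integers(1, 50))
            m_t = int(rng.integers(1, 50))
            p0 = m_nt / (m_nt + m_t)
            got = binomial_strand_test(StrandCounts(k, n - k, m_nt, m_t))
            assert got == pytest.approx(exact_binom_two_sided(k, n, p0), rel=1e-9)


class TestMsiEnrichment:
    def test_identical_groups(self):
        d = {"a": (40, 100), "b": (40, 100)}
        assert msi_enrichment_ratio(d, {"a": "MSI", "b": "MSS"}) == pytest.approx(1.0)

    def test_planted_two_fold(self):
        d = {"a": (80, 100), "b": (40, 100)}
        assert msi_enrichment_ratio(d, {"a": "MSI", "b": "MSS"}) == pytest.approx(2.0)

    def test_single_sample_group(self):
        d = {"a": (50, 100), "b": (25, 100), "c": (25, 100)}
        r = msi_enrichment_ratio(d, {"a": "MSI", "b": "MSS", "c": "MSS"})
        assert r == pytest.approx(2.0)


class TestGroupComparison:
    def test_identical_groups_high_p(self):
        vals = list(np.linspace(0.4, 0.6, 20))
        res = group_comparison({"a": vals, "b": vals}, "rank_sum")
        assert res["p_raw"] > 0.9

    def test_bonferroni_family_one_is_identity(self):
        rng = np.random.default_rng(14)
        res = group_comparison(
            {"a": rng.random(10).tolist(), "b": rng.random(10).tolist()},
            "rank_sum", family_size=1,
        )
        assert res["p_adjusted"] == res["p_raw"]

    def test_family_size_multiplies(self):
        rng = np.random.default_rng(15)
        res = group_comparison(
            {"a": rng.random(10).tolist(), "b": (rng.random(10) + 0.5).tolist()},
            "rank_sum", family_size=4,
        )
        assert res["p_adjusted"] == pytest.approx(min(1.0, res["p_raw"] * 4))

    def test_signed_rank_detects_planted_ordering(self):
        rng = np.random.default_rng(16)
        ins = 0.65 + rng.normal(0, 0.02, 20)
        dele = 0.55 + rng.normal(0, 0.02, 20)
        res = group_comparison({"ins": ins.tolist(), "del": dele.tolist()}, "signed_rank")
        assert res["p_raw"] < 0.01

    def test_small_group_excluded(self):
        res = group_comparison(
            {"a": [0.5, 0.6, 0.7], "b": [0.4, 0.5, 0.55], "tiny": [0.5]}, "kruskal"
        )
        assert res["excluded_groups"] == ["tiny"]

    def test_planted_msi_mss_separation_power(self):
        rng = np.random.default_rng(17)
        hits = 0
        for _ in range(20):
            msi = [strand_bias(simulate_gene_counts(60, 400, 0.62, rng=rng)).bias
                   for _ in range(30)]
            mss = [strand_bias(simulate_gene_counts(60, 400, 0.55, rng=rng)).bias
                   for _ in range(30)]
            if group_comparison({"MSI": msi, "MSS": mss}, "rank_sum")["p_raw"] < 0.01:
                hits += 1
        assert hits >= 18


class TestDownsampleZ:
    def _cohort(self, bias_counts):
        return {"cohort": StrandCounts(*bias_counts)}

    def test_direction(self):
        # focal unbiased sample vs strongly biased cohort -> strongly negative z
        cohorts = self._cohort((650, 350, 1000, 1000))
        df = downsample_zscore(25, 50, cohorts, n_boot=3000, seed=0)
        assert df.iloc[0]["z"] < -2

    def test_empirical_p_close_to_normal_at_n200(self):
        cohorts = self._cohort((600, 400, 1000, 1000))
        df = downsample_zscore(110, 200, cohorts, n_boot=20000, seed=1)
        from scipy import stats
        p_norm = 2 * stats.norm.sf(abs(df.iloc[0]["z"]))
        assert abs(df.iloc[0]["p_empirical"] - p_norm) < 0.02

    def test_zero_focal_errors(self):
        with pytest.raises(ValueError):
            downsample_zscore(0, 0, self._cohort((10, 10, 10, 10)))

    def test_self_draw_calibration(self):
        rng = np.random.default_rng(18)
        cohorts = self._cohort((600, 400, 1000, 1000))
        p_nt = 0.6
        within = 0
        n_rep = 60
        for i in range(n_rep):
            n = 80
            k = int(rng.binomial(n, p_nt))
            df = downsample_zscore(k, n, cohorts, n_boot=1500, seed=100 + i)
            if abs(df.iloc[0]["z"]) < 2:
                within += 1
        assert within >= 0.88 * n_rep


class TestSubstitutionOrientation:
    GENES = [GeneRecord("gp", "c", 0, 100, "+"), GeneRecord("gm", "c", 200, 300, "-")]

    def test_c_to_a_orientation(self):
        subs = [("c", 10, "C", "A"), ("c", 20, "G", "T"), ("c", 250, "C", "A")]
        sc = substitution_orientation(subs, self.GENES, "C>A")
        # ref C in + gene -> NT; ref G in + gene -> T; ref C in - gene -> T
        assert (sc.nt_indels, sc.t_indels) == (1, 2)

    def test_strand_swap_symmetry(self):
        subs = [("c", int(p), "C", "A") for p in range(5, 95, 7)]
        flipped = [GeneRecord(g.gene_id, g.chrom, g.start, g.end,
                              "-" if g.strand == "+" else "+") for g in self.GENES]
        a = substitution_orientation(subs, self.GENES, "C>A")
        b = substitution_orientation(subs, flipped, "C>A")
        assert (a.nt_indels, a.t_indels) == (b.t_indels, b.nt_indels)

    def test_n_ref_skipped(self):
        sc = substitution_orientation([("c", 10, "N", "A")], self.GENES, "C>A")
        assert sc.nt_indels + sc.t_indels == 0


class TestAsymmetryMatrix:
    @pytest.fixture()
    def dinuc_sim(self):
        from indelstrand import (SimulationConfig, find_dinucleotide_tracts,
                                 generate_cohort, generate_reference, orient_tracts)

        cfg = SimulationConfig(
            seed=22, genome_length=150_000, n_genes=16, tracts_per_gene=18,
            homopolymer_units=(), dinucleotide_units=("TG", "CT"),
            n_samples=5, indels_per_sample=200, q=0.5,
            beta={"TG": 0.7, "CT": 0.5},
        )
        genome, genes, manifest = generate_reference(cfg)
        indels, _, _ = generate_cohort(cfg, genome, manifest)
        oriented = orient_tracts(find_dinucleotide_tracts(genome), genes)
        pooled = [r for v in indels.values() for r in v]
        return pooled, oriented

    def test_complementarity(self, dinuc_sim):
        pooled, oriented = dinuc_sim
        m = asymmetry_matrix({"sim": (pooled, oriented)})
        for k in range(2, 6):
            tg = m.loc["sim", f"TGx{k}"]
            ca = m.loc["sim", f"CAx{k}"]
            if np.isfinite(tg) and np.isfinite(ca):
                assert tg == pytest.approx(1 - ca)

    def test_planted_excess_in_target_columns(self, dinuc_sim):
        pooled, oriented = dinuc_sim
        m = asymmetry_matrix({"sim": (pooled, oriented)})
        tg_cols = [c for c in m.columns if c.startswith("TGx")]
        ct_cols = [c for c in m.columns if c.startswith("CTx")]
        tg_mean = np.nanmean(m.loc["sim", tg_cols].astype(float))
        ct_mean = np.nanmean(m.loc["sim", ct_cols].astype(float))
        assert tg_mean > 0.6
        assert abs(ct_mean - 0.5) < 0.12
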