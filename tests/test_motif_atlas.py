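"""Tract scanning, orientation and reference-genome asymmetries."""

import numpy as np
import pytest

from indelstrand import (
    GeneRecord,
    GenomeSequence,
    OrientedTract,
    RepeatTract,
    find_dinucleotide_tracts,
    find_homopolymer_tracts,
    gene_bin_enrichment,
    orient_tracts,
    positional_density_profile,
    reference_asymmetry,
    sequence_skew,
)
from conftest import dinucleotide_oracle, homopolymer_oracle, random_dna


class TestHomopolymerScan:
    def test_simple_sequence(self):
        g = GenomeSequence({"c": "GAAAT"})
        tracts = find_homopolymer_tracts(g)
        assert [(t.start, t.end, t.unit) for t in tracts] == [
            (0, 1, "G"), (1, 4, "A"), (4, 5, "T")
        ]

    def test_run_longer_than_max_is_flagged(self):
        g = GenomeSequence({"c": "C" + "A" * 12 + "C"})
        tracts = [t for t in find_homopolymer_tracts(g) if t.unit == "A"]
        assert len(tracts) == 1 and tracts[0].length == 12 and tracts[0].over_max

    def test_n_breaks_runs(self):
        g = GenomeSequence({"c": "AANAA"})
        tracts = find_homopolymer_tracts(g)
        assert [(t.start, t.end) for t in tracts] == [(0, 2), (3, 5)]

    def test_agrees_with_regex_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            seq = random_dna(rng, 2000)
            got = {(t.start, t.end, t.unit, t.over_max)
                   for t in find_homopolymer_tracts(GenomeSequence({"c": seq}))}
            assert got == set(homopolymer_oracle(seq))


class TestDinucleotideScan:
    def test_greedy_leftmost(self):
        g = GenomeSequence({"c": "TGTGT"})
        tracts = find_dinucleotide_tracts(g)
        assert [(t.start, t.end, t.unit, t.n_units) for t in tracts] == [(0, 4, "TG", 2)]

    def test_palindromic_units_excluded(self):
        g = GenomeSequence({"c": "ATATATAT"})
        assert find_dinucleotide_tracts(g) == []

    def test_homo_pairs_excluded(self):
        g = GenomeSequence({"c": "AAAAAAAA"})
        assert find_dinucleotide_tracts(g) == []

    def test_agrees_with_placement_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            seq = random_dna(rng, 2000)
            got = {(t.start, t.end, t.unit, t.n_units)
                   for t in find_dinucleotide_tracts(GenomeSequence({"c": seq}))}
            assert got == set(dinucleotide_oracle(seq))


class TestOrientation:
    GENES = [GeneRecord("gp", "c", 0, 30, "+"), GeneRecord("gm", "c", 40, 70, "-")]

    def test_polyt_in_plus_gene_is_non_template(self):
        t = RepeatTract("c", 5, 9, "T", 4)
        (ot,) = orient_tracts([t], [self.GENES[0]])
        assert ot.nt_unit == "T"

    def test_polyt_in_minus_gene_is_template(self):
        t = RepeatTract("c", 45, 49, "T", 4)
        (ot,) = orient_tracts([t], [self.GENES[1]])
        assert ot.nt_unit == "A"

    def test_overlapping_genes_give_complementary_readings(self):
        genes = [GeneRecord("a", "c", 0, 50, "+"), GeneRecord("b", "c", 10, 60, "-")]
        t = RepeatTract("c", 20, 24, "G", 4)
        ots = orient_tracts([t], genes)
        assert sorted(ot.nt_unit for ot in ots) == ["C", "G"]

    def test_straddling_tract_dropped(self):
        t = RepeatTract("c", 28, 33, "T", 5)  # crosses gene end at 30
        assert orient_tracts([t], [self.GENES[0]]) == []

    def test_strand_swap_involution(self, sim_small):
        flipped = [
            GeneRecord(g.gene_id, g.chrom, g.start, g.end,
                       "-" if g.strand == "+" else "+")
            for g in sim_small["genes"]
        ]
        fwd = orient_tracts(sim_small["tracts"], sim_small["genes"])
        rev = orient_tracts(sim_small["tracts"], flipped)
        for unit in "ACGT":
            n_f = sum(ot.nt_unit == unit for ot in fwd)
            from indelstrand import revcomp
            n_r = sum(ot.nt_unit == revcomp(unit) for ot in rev)
            assert n_f == n_r

    def test_conservation(self, sim_small):
        oriented = sim_small["oriented"]
        n_t_tracts = sum(1 for ot in oriented if ot.tract.unit in ("T", "A"))
        nt = sum(ot.nt_unit == "T" for ot in oriented)
        t = sum(ot.nt_unit == "A" for ot in oriented)
        assert nt + t == n_t_tracts


class TestReferenceAsymmetry:
    def _oriented(self, n_nt, n_t, length=4):
        out = []
        for i in range(n_nt):
            out.append(OrientedTract(RepeatTract("c", 10 * i, 10 * i + length, "T", length), "g", "+"))
        for i in range(n_t):
            out.append(OrientedTract(RepeatTract("c", 10000 + 10 * i, 10000 + 10 * i + length, "A", length), "g2", "+"))
        return out

    def test_equal_planting_gives_ratio_one(self):
        df = reference_asymmetry(self._oriented(50, 50), "T")
        row = df[df["stratum"] == "weighted_average"].iloc[0]
        assert row["ratio"] == pytest.approx(1.0)

    def test_60_40_gives_1_5(self):
        df = reference_asymmetry(self._oriented(60, 40), "T")
        assert df[df["stratum"] == "4"].iloc[0]["ratio"] == pytest.approx(1.5)

    def test_strand_swap_inverts_ratio(self):
        ots = self._oriented(60, 40)
        swapped = [OrientedTract(ot.tract, ot.gene_id, "-") for ot in ots]
        r1 = reference_asymmetry(ots, "T").iloc[-1]["ratio"]
        r2 = reference_asymmetry(swapped, "T").iloc[-1]["ratio"]
        assert r1 == pytest.approx(1 / r2)

    def test_zero_template_flagged(self):
        df = reference_asymmetry(self._oriented(5, 0), "T")
        assert np.isnan(df[df["stratum"] == "4"].iloc[0]["ratio"])


class TestGeneBinEnrichment:
    def test_all_tracts_in_bin3_with_equal_bins(self):
        # 50 kb genes, body bins 5 kb; flanks 10 kb in 2 bins = 5 kb each
        genome = GenomeSequence({"c": "A" * 200_000})
        genes = [GeneRecord("g1", "c", 20_000, 70_000, "+"),
                 GeneRecord("g2", "c", 100_000, 150_000, "+")]
        tracts = []
        for g in genes:
            lo = g.start + 2 * 5000  # body bin 3
            tracts += [RepeatTract("c", lo + off, lo + off + 3, "T", 3)
                       for off in range(0, 4000, 400)]
        df = gene_bin_enrichment(tracts, genes, genome)
        e = df["enrichment"].to_numpy()
        assert e[4] == pytest.approx(14.0)  # bin index 5 = third body bin
        assert np.nansum(np.delete(e, 4)) == pytest.approx(0.0)

    def test_weighted_mean_identity(self):
        rng = np.random.default_rng(3)
        genome = GenomeSequence({"c": random_dna(rng, 300_000)})
        genes = [GeneRecord(f"g{i}", "c", 30_000 * i + 21_000, 30_000 * i + 21_000 + int(rng.integers(2000, 8000)), "+" if i % 2 else "-")
                 for i in range(8)]
        tracts = find_homopolymer_tracts(genome)
        df = gene_bin_enrichment([t for t in tracts if t.unit == "G"], genes, genome)
        weighted = np.nansum(df["enrichment"] * df["bases"]) / df["bases"].sum()
        assert weighted == pytest.approx(1.0, abs=1e-12)

    def test_short_gene_excluded(self):
        genome = GenomeSequence({"c": "A" * 100_000})
        genes = [GeneRecord("tiny", "c", 50_000, 50_005, "+")]
        df = gene_bin_enrichment([], genes, genome)
        assert df["bases"].sum() == 0


class TestSkew:
    def test_pure_g_window(self):
        genome = GenomeSequence({"c": "G" * 4000})
        genes = [GeneRecord("g", "c", 1000, 3000, "+")]
        df = sequence_skew(genome, genes, window_bp=500, kind="GC")
        assert np.allclose(df["skew"].dropna(), 1.0)

    def test_balanced_window_zero(self):
        genome = GenomeSequence({"c": "GC" * 2000})
        genes = [GeneRecord("g", "c", 1000, 3000, "+")]
        df = sequence_skew(genome, genes, window_bp=500, kind="GC")
        assert np.allclose(df["skew"].dropna(), 0.0)

    def test_revcomp_and_flip_invariance(self):
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 12_000)
        genome = GenomeSequence({"c": seq})
        genes = [GeneRecord("g1", "c", 3000, 6000, "+"), GeneRecord("g2", "c", 7000, 9500, "-")]
        from indelstrand import revcomp
        genome_rc = GenomeSequence({"c": revcomp(seq)})
        n = len(seq)
        genes_rc = [
            GeneRecord(g.gene_id, "c", n - g.end, n - g.start,
                       "-" if g.strand == "+" else "+")
            for g in genes
        ]
        for kind in ("GC", "AT"):
            a = sequence_skew(genome, genes, window_bp=1000, kind=kind)
            b = sequence_skew(genome_rc, genes_rc, window_bp=1000, kind=kind)
            np.testing.assert_allclose(a["skew"], b["skew"], rtol=1e-12)


class TestPositionalProfile:
    def test_flat_for_uniform_tracts(self, sim_small):
        df = positional_density_profile(
            sim_small["oriented"], sim_small["genes"], "T",
            window_bp=1000, n_boot=100, seed=0,
        )
        assert set(df["strand"]) == {"non_template", "template"}
        assert (df["density"] >= 0).all() and (df["se"] >= 0).all()

    def test_no_genes_is_error(self, sim_small):
        with pytest.raises(ValueError):
            positional_density_profile(sim_small["oriented"], [], "T")

    def test_bootstrap_se_shrinks_with_gene_count(self):
        rng = np.random.default_rng(7)
        genes_n = [GeneRecord(f"g{i}", "c", 5000 * i + 1000, 5000 * i + 4000, "+")
                   for i in range(40)]
        tracts = []
        for g in genes_n:
            for _ in range(10):
                s = int(rng.integers(g.start, g.end - 4))
                tracts.append(OrientedTract(RepeatTract("c", s, s + 3, "T", 3), g.gene_id, "+"))
        small = positional_density_profile(tracts, genes_n[:10], "T", window_bp=1000,
                                           n_boot=300, seed=1)
        large = positional_density_profile(tracts, genes_n, "T", window_bp=1000,
                                           n_boot=300, seed=1)
        m_small = small[small["strand"] == "non_template"]["se"].mean()
        m_large = large[large["strand"] == "non_template"]["se"].mean()
        assert m_large < m_small  # 4x genes -> roughly half the SE
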