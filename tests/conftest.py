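"""Shared fixtures: small synthetic datasets and independent oracles."""

from __future__ import annotations

import re

import numpy as np
import pytest

from indelstrand import (
    GenomeSequence,
    SimulationConfig,
    find_homopolymer_tracts,
    generate_cohort,
    generate_reference,
    orient_tracts,
)

# ---------------------------------------------------------------------------
# Independent oracles (used by unit and acceptance tests)

_ALLOWED_DINUCS = {"GT", "TG", "AC", "CA", "CT", "TC", "AG", "GA"}


def homopolymer_oracle(seq: str, min_len: int = 1):
    """Maximal single-base runs via regex; returns (start, end, base, over_max)."""
    out = []
    for m in re.finditer(r"(.)\1*", seq):
        base = m.group(1)
        if base in "ACGT" and m.end() - m.start() >= min_len:
            out.append((m.start(), m.end(), base, m.end() - m.start() > 10))
    return out


def dinucleotide_oracle(seq: str, min_units: int = 1):
    """Greedy leftmost-longest dinucleotide tracts by explicit per-position
    character comparison (no skipping logic shared with the scanner)."""

    def match_len(i: int) -> int:
        a, b = seq[i], seq[i + 1]
        k = 0
        j = i
        while j + 1 < len(seq) and seq[j] == a and seq[j + 1] == b:
            k += 1
            j += 2
        return k

    out = []
    i = 0
    n = len(seq)
    while i < n - 1:
        unit = seq[i] + seq[i + 1]
        if unit in _ALLOWED_DINUCS:
            k = match_len(i)
            if k >= min_units:
                out.append((i, i + 2 * k, unit, k))
                i += 2 * k
                continue
        i += 1
    return out


def brute_force_hits(indels, oriented_tracts, target_unit):
    """All-pairs indel x (tract, gene) intersection under the stated overlap
    rule; returns the set of hit keys for comparison with assign_hits."""
    from indelstrand import revcomp

    target_t = revcomp(target_unit)
    keys = set()
    for indel in indels:
        for ot in oriented_tracts:
            if ot.nt_unit not in (target_unit, target_t):
                continue
            t = ot.tract
            if indel.chrom != t.chrom:
                continue
            if indel.kind == "deletion":
                s, e = indel.pos, indel.pos + indel.length
                hit = s < t.end and t.start < e
            else:
                hit = t.start <= indel.pos <= t.end
            if hit:
                cls = "non_template" if ot.nt_unit == target_unit else "template"
                keys.add((indel.sample_id, indel.chrom, indel.pos, indel.kind,
                          t.start, t.end, ot.gene_id, cls))
    return keys


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def sim_small():
    """A small full simulation with a planted non-template excess."""
    cfg = SimulationConfig(
        seed=11, genome_length=120_000, n_genes=16, tracts_per_gene=15,
        homopolymer_units=("T", "G"), n_samples=6, indels_per_sample=150,
        q=0.6, beta=0.6,
    )
    genome, genes, manifest = generate_reference(cfg)
    indels, meta, truth = generate_cohort(cfg, genome, manifest)
    tracts = find_homopolymer_tracts(genome)
    oriented = orient_tracts(tracts, genes)
    return {
        "config": cfg, "genome": genome, "genes": genes, "manifest": manifest,
        "indels": indels, "meta": meta, "truth": truth,
        "tracts": tracts, "oriented": oriented,
    }


@pytest.fixture()
def toy_genome():
    return GenomeSequence({"chr1": "ACGTGAAATCCGGGTTTTAACGTACGT" * 4})
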