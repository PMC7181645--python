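"""Synthetic genomes, gene annotations, expression tables, Repli-seq tracks
and indel cohorts with known planted parameters.

The generator defines a fully-specified ground truth: every planted tract's
coordinates, unit, host gene and strand reading, and every emitted indel's
source tract and strand class, are recorded in a manifest so each pipeline
stage can be tested against closed-form expectations.

Key planted parameters
----------------------
q : reference-strand placement skew — the probability that a planted tract
    reads its unit on the non-template strand of its host gene. The default
    0.533 reproduces a non-template/template occurrence ratio of ~1.14, the
    magnitude of the polyT skew in the human reference genome.
beta : target non-template share of indel *density* (indels per motif
    occurrence). Indels are assigned to the non-template reading with
    per-unit probability beta*m_nt / (beta*m_nt + (1-beta)*m_t), so the
    background-corrected bias estimator recovers beta regardless of q.
    Default 0.55, the middle of the per-cancer-type asymmetry range.
insertion_fraction : 0.36 (cohort medians of 124 insertions / 222 deletions).
length_effect : per-tract relative indel rate length_effect**(length-1);
    slipped-strand intermediates become more likely as tracts lengthen.
msi_multiplier : fold-increase of the indel rate at repeat tracts in
    MMR-deficient samples.

The background sequence is run-suppressed: no base appears three times in a
row and no dinucleotide unit repeats twice in a row, so planted tracts are
the only homopolymer tracts of length >= 3 and the only dinucleotide tracts
of >= 2 units. Planted tract flanks are guarded so every planted tract is
maximal and detected at its exact coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    GeneRecord,
    GenomeSequence,
    IndelRecord,
    revcomp,
    write_gene_table,
    write_genome,
    write_indel_vcf,
)

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 300_000
    n_genes: int = 40
    gene_length_min: int = 3_000
    gene_length_max: int = 6_000
    chrom_name: str = "chr1"
    homopolymer_units: tuple[str, ...] = ("T", "G")
    dinucleotide_units: tuple[str, ...] = ()
    tracts_per_gene: int = 30
    tract_length_p: float = 0.30  # truncated geometric over 1..10
    max_tract_len: int = 10
    q: float = 0.533  # NT-reading placement skew; 0.533/(0.467) ~ 1.14
    intergenic_tracts: int = 50
    n_samples: int = 10
    indels_per_sample: int = 300
    beta: float | dict = 0.55
    beta_ins: float | dict | None = None
    beta_del: float | dict | None = None
    beta_by_tier: dict | None = None  # {'low': b, 'medium': b, 'high': b}
    insertion_fraction: float = 0.36
    length_effect: float = 1.5
    msi_multiplier: float = 3.0
    msi_fraction: float = 0.25
    tier_rate_multipliers: dict = field(
        default_factory=lambda: {"low": 1.0, "medium": 1.0, "high": 1.0}
    )
    background_indels_per_sample: int = 0  # indels outside declared tracts
    repliseq_bin_size: int = 1_000
    repliseq_period_bp: int = 50_000
    repliseq_amplitude: float = 1.0
    repliseq_phase: float = 0.0

    def __post_init__(self):
        for name, v in (("q", self.q), ("insertion_fraction", self.insertion_fraction),
                        ("msi_fraction", self.msi_fraction)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.length_effect <= 0 or self.msi_multiplier <= 0:
            raise ValueError("rates must be positive")


def _beta_for(cfg: SimulationConfig, unit: str, kind: str, tier: str) -> float:
    base = cfg.beta_ins if (kind == "insertion" and cfg.beta_ins is not None) else (
        cfg.beta_del if (kind == "deletion" and cfg.beta_del is not None) else cfg.beta
    )
    b = base.get(unit, 0.5) if isinstance(base, dict) else float(base)
    if cfg.beta_by_tier is not None and tier in cfg.beta_by_tier:
        b = float(cfg.beta_by_tier[tier])
    return b


def _background_sequence(n: int, rng: np.random.Generator) -> np.ndarray:
    """Near-i.i.d. sequence with homopolymer runs capped at 2 and no
    dinucleotide unit repeated twice in a row, so planted tracts are the
    only homopolymer tracts >= 3 bp and the only >= 2-unit dinucleotide
    tracts."""
    seq = np.empty(n, dtype="<U1")
    draws = rng.integers(0, 4, size=2 * n + 16)  # over-provisioned stream
    j = 0
    for i in range(n):
        while True:
            b = _BASES[draws[j] % 4]
            j += 1
            if j >= draws.size:
                draws = rng.integers(0, 4, size=2 * n + 16)
                j = 0
            if i >= 2 and b == seq[i - 1] and b == seq[i - 2]:
                continue  # would extend a run to 3
            if i >= 3 and b == seq[i - 2] and seq[i - 1] == seq[i - 3]:
                continue  # would complete xyxy
            seq[i] = b
            break
    return seq


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _guard_flanks(seq: np.ndarray, start: int, end: int, ref_unit: str,
                  rng: np.random.Generator) -> None:
    """Set the bases flanking a planted tract so the tract is maximal and
    the greedy dinucleotide scanner cannot absorb its boundary.

    Homopolymer X: flank base differs from X and from its outer neighbour
    (never extends the run or a background run past 2).
    Dinucleotide unit ab: the left flank f must not extend the tract
    (f != b) and (f, a) must not be an orientable unit, which forces
    f in {a, complement(a)}; the right flank g must satisfy g != a and
    symmetric constraints are unnecessary because the scanner skips past
    the tract once matched.
    """
    a, b = ref_unit[0], ref_unit[-1]
    if len(ref_unit) == 1:
        for flank_pos, outer_off in ((start - 1, -1), (end, 1)):
            neighbor = seq[flank_pos + outer_off] if 0 <= flank_pos + outer_off < seq.size else None
            ok = [x for x in _BASES if x != a and x != neighbor]
            seq[flank_pos] = ok[int(rng.integers(0, len(ok)))]
        return
    # left flank
    cand = [a]
    if _COMP[a] != b:
        cand.append(_COMP[a])
    neighbor = seq[start - 3] if start - 3 >= 0 else None  # 3-run check vs start-2
    prev = seq[start - 2] if start - 2 >= 0 else None
    pref = [x for x in cand if not (x == prev and x == neighbor) and not (x == prev == a)]
    pick = pref if pref else cand
    seq[start - 1] = pick[int(rng.integers(0, len(pick)))]
    # right flank: g != a (no extension); avoid runs with outer neighbour
    nxt = seq[end + 1] if end + 1 < seq.size else None
    ok = [x for x in _BASES if x != a and not (x == b == nxt)]
    seq[end] = ok[int(rng.integers(0, len(ok)))]


@dataclass
class PlantedTract:
    chrom: str
    start: int
    end: int
    unit: str  # reference-strand unit
    n_units: int
    gene_id: str | None
    gene_strand: str | None
    nt_reading: str | None  # unit as read on the host gene's non-template strand

    @property
    def length(self) -> int:
        return self.end - self.start


def generate_reference(config: SimulationConfig):
    """Generate the genome FASTA contents, gene set and planted-tract manifest.

    Returns (genome, genes, manifest) where manifest is a JSON-serializable
    dict carrying the config, per-gene tiers and every planted tract.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.genome_length
    margin = 200
    gene_lengths = rng.integers(config.gene_length_min, config.gene_length_max + 1,
                                size=config.n_genes)
    needed = int(gene_lengths.sum()) + (config.n_genes + 1) * margin
    if needed > n:
        raise ValueError(f"infeasible packing: need {needed} bp, genome is {n} bp")
    slack = n - needed
    gaps = rng.multinomial(slack, np.ones(config.n_genes + 1) / (config.n_genes + 1))
    seq = _background_sequence(n, rng)
    genes: list[GeneRecord] = []
    pos = margin + int(gaps[0])
    strands = rng.random(config.n_genes) < 0.5
    for i, glen in enumerate(gene_lengths):
        start = pos
        end = start + int(glen)
        genes.append(GeneRecord(f"g{i:04d}", config.chrom_name, start, end,
                                "+" if strands[i] else "-"))
        pos = end + margin + int(gaps[i + 1])

    tiers = ["low", "medium", "high"]
    gene_tiers = {g.gene_id: tiers[i % 3] for i, g in
                  enumerate(sorted(genes, key=lambda g: g.gene_id))}

    all_units = list(config.homopolymer_units) + list(config.dinucleotide_units)
    if not all_units:
        raise ValueError("no units configured")
    planted: list[PlantedTract] = []

    def draw_length(unit: str) -> int:
        if len(unit) == 1:
            k = 1 + rng.geometric(config.tract_length_p) - 1
            return int(min(k, config.max_tract_len))
        k = 2 + rng.geometric(config.tract_length_p) - 1  # dinucs: >=2 units
        return int(min(k, config.max_tract_len // 2))

    def plant(slot_lo: int, slot_hi: int, gene: GeneRecord | None):
        unit = all_units[rng.integers(0, len(all_units))]
        n_units = draw_length(unit)
        tract_len = n_units * len(unit)
        if slot_hi - slot_lo < tract_len + 4:
            return
        start = int(rng.integers(slot_lo + 2, slot_hi - tract_len - 1))
        end = start + tract_len
        if gene is not None:
            nt = rng.random() < config.q
            nt_reading = unit if nt else revcomp(unit)
            ref_unit = nt_reading if gene.strand == "+" else revcomp(nt_reading)
        else:
            nt_reading = None
            ref_unit = unit
        seq[start:end] = list(ref_unit * n_units)
        _guard_flanks(seq, start, end, ref_unit, rng)
        planted.append(
            PlantedTract(config.chrom_name, start, end, ref_unit, n_units,
                         gene.gene_id if gene else None,
                         gene.strand if gene else None, nt_reading)
        )

    for gene in genes:
        slot_w = gene.length // config.tracts_per_gene
        for s in range(config.tracts_per_gene):
            plant(gene.start + s * slot_w, gene.start + (s + 1) * slot_w, gene)
    # intergenic tracts at a base rate, between genes
    used: list[tuple[int, int]] = []
    for _ in range(config.intergenic_tracts):
        gene = genes[int(rng.integers(0, len(genes)))]
        lo = gene.end + 20 + int(rng.integers(0, max(1, margin - 160)))
        hi = lo + 60
        if (
            hi < n - 2
            and all(not (g.start - 2 < hi and lo < g.end + 2) for g in genes)
            and all(not (u0 - 2 < hi and lo < u1 + 2) for u0, u1 in used)
        ):
            plant(lo, hi, None)
            used.append((lo, hi))

    genome = GenomeSequence({config.chrom_name: "".join(seq)})
    manifest = {
        "config": _config_dict(config),
        "genes": [
            {"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start,
             "end": g.end, "strand": g.strand}
            for g in genes
        ],
        "gene_tiers": gene_tiers,
        "tracts": [asdict(t) for t in planted],
    }
    return genome, genes, manifest


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["homopolymer_units"] = list(d["homopolymer_units"])
    d["dinucleotide_units"] = list(d["dinucleotide_units"])
    return d


_DINUC_ALLOWED = {"GT", "TG", "AC", "CA", "CT", "TC", "AG", "GA"}


def _oriented_unit_counts(genome: GenomeSequence, manifest: dict,
                          unit_classes: list[str]) -> dict[str, tuple[int, int]]:
    """Ground-truth oriented motif counts (nt, t) per unit class.

    Re-derives, with its own scan, the non-template/template occurrence
    counts of every maximal tract fully inside a gene — including the short
    background tracts the run-suppressed sampler still produces — so the
    indel generator can calibrate its strand draw against the same
    denominators the bias estimator will use.
    """
    import re

    from collections import defaultdict

    counts: dict[str, list[int]] = {u: [0, 0] for u in unit_classes}
    per_gene: dict[tuple[str, str], list[int]] = defaultdict(lambda: [0, 0])
    genes = manifest["genes"]
    mono = [u for u in unit_classes if len(u) == 1]
    di = [u for u in unit_classes if len(u) == 2]
    for chrom in genome.chrom_names:
        seq = genome.sequence(chrom)
        runs: list[tuple[int, int, str]] = []
        if mono:
            for m in re.finditer(r"(.)\1*", seq):
                runs.append((m.start(), m.end(), m.group(1)))
        if di:
            i, n = 0, len(seq)
            while i < n - 1:
                u = seq[i : i + 2]
                if u not in _DINUC_ALLOWED:
                    i += 1
                    continue
                k = 1
                while seq[i + 2 * k : i + 2 * k + 2] == u:
                    k += 1
                runs.append((i, i + 2 * k, u))
                i += 2 * k
        by_chrom_genes = [g for g in genes if g["chrom"] == chrom]
        for start, end, ref_unit in runs:
            if ref_unit not in "ACGT" and ref_unit not in _DINUC_ALLOWED:
                continue
            for g in by_chrom_genes:
                if g["start"] <= start and end <= g["end"]:
                    reading = ref_unit if g["strand"] == "+" else revcomp(ref_unit)
                    for u in unit_classes:
                        if len(u) != len(ref_unit):
                            continue
                        if reading == u:
                            counts[u][0] += 1
                            per_gene[(u, g["gene_id"])][0] += 1
                        elif reading == revcomp(u):
                            counts[u][1] += 1
                            per_gene[(u, g["gene_id"])][1] += 1
    return {u: (c[0], c[1]) for u, c in counts.items()}, dict(per_gene)


def generate_cohort(config: SimulationConfig, genome: GenomeSequence, manifest: dict):
    """Generate per-sample indels targeting the planted genic tracts.

    Each indel picks a unit class (weighted by pool size), a strand reading
    with the beta-calibrated probability, then a tract within the pool
    weighted by length_effect**(length-1) x tier multiplier (x msi
    multiplier for MSI samples, applied as a rate increase in total indel
    number at tracts). Deletions remove one repeat unit at a uniform
    unit-aligned offset; insertions add one unit at a uniform in-tract
    insertion point. Returns (indels_by_sample, metadata DataFrame, truth
    records list).
    """
    rng = np.random.default_rng(config.seed + 1)
    tracts = [PlantedTract(**t) for t in manifest["tracts"]]
    gene_tiers = manifest["gene_tiers"]
    genic = [t for t in tracts if t.gene_id is not None]
    if not genic:
        raise ValueError("no genic tracts to target")

    # pools keyed by (nt-read unit class, reading)
    pools: dict[tuple[str, str], list[int]] = {}
    for i, t in enumerate(genic):
        unit_class = t.nt_reading if t.nt_reading in _canonical_units(config) else revcomp(t.nt_reading)
        reading = "non_template" if t.nt_reading == unit_class else "template"
        pools.setdefault((unit_class, reading), []).append(i)

    def pool_weights(idx: list[int], msi: bool) -> np.ndarray:
        w = np.array(
            [
                config.length_effect ** (genic[i].length - 1)
                * config.tier_rate_multipliers.get(gene_tiers[genic[i].gene_id], 1.0)
                for i in idx
            ]
        )
        if msi:
            w = w * config.msi_multiplier
        return w

    unit_classes = sorted({k[0] for k in pools})
    # calibrate the strand draw against the true oriented motif counts of
    # the emitted sequence (background short tracts included), so the
    # corrected bias estimator recovers beta
    motif_counts, motif_counts_per_gene = _oriented_unit_counts(genome, manifest, unit_classes)
    indels_by_sample: dict[str, list[IndelRecord]] = {}
    truth: list[dict] = []
    meta_rows = []
    msi_flags = rng.random(config.n_samples) < config.msi_fraction
    for s in range(config.n_samples):
        sample = f"s{s:03d}"
        msi = bool(msi_flags[s])
        n_indels = config.indels_per_sample
        if msi:
            n_indels = int(round(n_indels * config.msi_multiplier))
        meta_rows.append({"sample": sample, "cohort": "sim",
                          "msi_status": "MSI" if msi else "MSS"})
        records: list[IndelRecord] = []
        # unit class chosen proportional to total pool weight
        class_w = np.array(
            [
                pool_weights(pools.get((u, "non_template"), []), msi).sum()
                + pool_weights(pools.get((u, "template"), []), msi).sum()
                for u in unit_classes
            ]
        )
        class_p = class_w / class_w.sum()
        for _ in range(n_indels):
            u = unit_classes[rng.choice(len(unit_classes), p=class_p)]
            kind = "insertion" if rng.random() < config.insertion_fraction else "deletion"
            m_nt, m_t = motif_counts[u]
            if len(pools.get((u, "non_template"), [])) == 0:
                m_nt = 0
            if len(pools.get((u, "template"), [])) == 0:
                m_t = 0
            b = _beta_for(config, u, kind, "")
            if m_nt == 0 or m_t == 0:
                p_nt = 1.0 if m_t == 0 else 0.0
            else:
                p_nt = b * m_nt / (b * m_nt + (1 - b) * m_t)
            reading = "non_template" if rng.random() < p_nt else "template"
            if config.beta_by_tier is not None:
                # tier-dependent bias: pick the tract first by rate weights
                # over both readings, then re-draw the reading with the
                # tier's beta among tracts of the chosen tier
                reading, tract_i = _tier_beta_draw(
                    config, rng, pools, pool_weights, genic, gene_tiers, u, msi,
                    motif_counts_per_gene,
                )
            else:
                idx = pools.get((u, reading), [])
                if not idx:
                    continue
                w = pool_weights(idx, msi)
                tract_i = idx[rng.choice(len(idx), p=w / w.sum())]
            t = genic[tract_i]
            unit_len = len(t.unit)
            if kind == "deletion":
                off = int(rng.integers(0, t.n_units)) * unit_len
                pos = t.start + off
                seqdel = genome.sequence(t.chrom, pos, pos + unit_len)
                rec = IndelRecord(sample, t.chrom, pos, "deletion", seqdel)
            else:
                p = int(rng.integers(t.start, t.end + 1))
                # insert one unit in phase with the tract at p
                phase = (p - t.start) % unit_len
                ins = t.unit[phase:] + t.unit[:phase]
                rec = IndelRecord(sample, t.chrom, p, "insertion", ins)
            records.append(rec)
            truth.append(
                {
                    "sample": sample,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "kind": kind,
                    "unit_class": u,
                    "strand_class": reading,
                    "tract_start": t.start,
                    "tract_end": t.end,
                    "gene_id": t.gene_id,
                }
            )
        # background indels: uniform intergenic positions clear of all tracts
        tract_ivs = [(t.start - 12, t.end + 12) for t in tracts]
        gene_ivs = [(g["start"] - 2, g["end"] + 2) for g in manifest["genes"]]
        chrom = genome.chrom_names[0]
        clen = genome.length(chrom)
        placed = 0
        while placed < config.background_indels_per_sample:
            p = int(rng.integers(100, clen - 100))
            if any(lo <= p < hi for lo, hi in tract_ivs) or any(
                lo <= p < hi for lo, hi in gene_ivs
            ):
                continue
            base = genome.sequence(chrom, p, p + 1)
            if base == "N":
                continue
            kind = "insertion" if rng.random() < config.insertion_fraction else "deletion"
            if kind == "deletion":
                rec = IndelRecord(sample, chrom, p, "deletion", base)
            else:
                ins = _BASES[int(rng.integers(0, 4))]
                rec = IndelRecord(sample, chrom, p, "insertion", ins)
            records.append(rec)
            truth.append({"sample": sample, "chrom": chrom, "pos": p, "kind": kind,
                          "unit_class": None, "strand_class": None,
                          "tract_start": None, "tract_end": None, "gene_id": None})
            placed += 1
        indels_by_sample[sample] = records
    metadata = pd.DataFrame(meta_rows)
    return indels_by_sample, metadata, truth


def _canonical_units(config: SimulationConfig) -> set[str]:
    return set(config.homopolymer_units) | set(config.dinucleotide_units)


def _tier_beta_draw(config, rng, pools, pool_weights, genic, gene_tiers, u, msi,
                    motif_counts_per_gene):
    """Draw (reading, tract index) with a tier-dependent beta, calibrated
    against the tier-restricted true motif counts."""
    idx_all = pools.get((u, "non_template"), []) + pools.get((u, "template"), [])
    tiers = [gene_tiers[genic[i].gene_id] for i in idx_all]
    w_all = pool_weights(idx_all, msi)
    tier = tiers[rng.choice(len(idx_all), p=w_all / w_all.sum())]
    sub_nt = [i for i in pools.get((u, "non_template"), []) if gene_tiers[genic[i].gene_id] == tier]
    sub_t = [i for i in pools.get((u, "template"), []) if gene_tiers[genic[i].gene_id] == tier]
    b = float(config.beta_by_tier.get(tier, 0.5))
    m_nt = sum(v[0] for (uu, gid), v in motif_counts_per_gene.items()
               if uu == u and gene_tiers.get(gid) == tier)
    m_t = sum(v[1] for (uu, gid), v in motif_counts_per_gene.items()
              if uu == u and gene_tiers.get(gid) == tier)
    if not sub_nt or not sub_t or m_nt == 0 or m_t == 0:
        reading = "non_template" if not sub_t else ("template" if not sub_nt else "non_template")
    else:
        p_nt = b * m_nt / (b * m_nt + (1 - b) * m_t)
        reading = "non_template" if rng.random() < p_nt else "template"
    idx = sub_nt if reading == "non_template" else sub_t
    if not idx:
        idx = sub_nt or sub_t
    w = pool_weights(idx, msi)
    return reading, idx[int(rng.choice(len(idx), p=w / w.sum()))]


def generate_expression(config: SimulationConfig, genes: list[GeneRecord], manifest: dict) -> pd.DataFrame:
    """Log-normal RPKM per gene with tier-dependent location so the planted
    low/medium/high partition is recoverable from the 33rd/66th percentiles."""
    rng = np.random.default_rng(config.seed + 2)
    mus = {"low": -2.0, "medium": 1.0, "high": 4.0}
    rows = []
    for g in sorted(genes, key=lambda g: g.gene_id):
        tier = manifest["gene_tiers"][g.gene_id]
        rpkm = float(np.exp(rng.normal(mus[tier], 0.4)))
        rows.append({"gene_id": g.gene_id, "rpkm": rpkm})
    return pd.DataFrame(rows)


def generate_repliseq(config: SimulationConfig, genome: GenomeSequence):
    """Sawtooth replication-timing signal plus per-bin truth labels.

    Returns ({chrom: SignalTrack}, {chrom: truth label array}) where truth
    is 'right_replicating' on rising flanks, 'left_replicating' on falling
    flanks ('transition' everywhere when amplitude is 0).
    """
    from .genome_io import SignalTrack

    if config.repliseq_period_bp < 2 * config.repliseq_bin_size:
        raise ValueError("period must span at least 2 bins")
    tracks = {}
    truths = {}
    for chrom in genome.chrom_names:
        n_bins = genome.length(chrom) // config.repliseq_bin_size
        centers = (np.arange(n_bins) + 0.5) * config.repliseq_bin_size
        phase = (centers / config.repliseq_period_bp + config.repliseq_phase) % 1.0
        tri = np.where(phase < 0.5, 2 * phase, 2 - 2 * phase)  # in [0,1]
        values = config.repliseq_amplitude * tri
        if config.repliseq_amplitude == 0:
            truth = np.full(n_bins, "transition", dtype=object)
        else:
            truth = np.where(phase < 0.5, "right_replicating", "left_replicating").astype(object)
        tracks[chrom] = SignalTrack(chrom, 0, config.repliseq_bin_size, values)
        truths[chrom] = truth
    return tracks, truths


# ---------------------------------------------------------------------------
# Counts-level fast path


def simulate_gene_counts(
    n_genes: int,
    n_indels: int,
    beta: float,
    q: float = 0.5,
    motifs_per_gene: float = 20.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
):
    """Counts-level simulation of per-gene strand counts.

    Motif occurrences per gene are Poisson(``motifs_per_gene``) split
    non-template with probability ``q``; ``n_indels`` indels land on genes
    proportionally to their motif totals and are non-template with the
    beta-calibrated probability beta*m_nt/(beta*m_nt + (1-beta)*m_t), so the
    corrected bias estimator has expectation ``beta``. Returns a
    :class:`~indelstrand.asymmetry_stats.StrandCounts` with per-gene rows.
    """
    from .asymmetry_stats import StrandCounts

    if rng is None:
        rng = np.random.default_rng(seed)
    m = rng.poisson(motifs_per_gene, size=n_genes)
    m = np.maximum(m, 1)
    m_nt = rng.binomial(m, q)
    m_t = m - m_nt
    # guarantee defined denominators at the aggregate level
    if m_nt.sum() == 0:
        m_nt[0] += 1
    if m_t.sum() == 0:
        m_t[0] += 1
    M_nt, M_t = int(m_nt.sum()), int(m_t.sum())
    p_nt = beta * M_nt / (beta * M_nt + (1 - beta) * M_t)
    gene_of = rng.choice(n_genes, size=n_indels, p=m / m.sum())
    is_nt = rng.random(n_indels) < p_nt
    nt_i = np.bincount(gene_of[is_nt], minlength=n_genes)
    t_i = np.bincount(gene_of[~is_nt], minlength=n_genes)
    per_gene = pd.DataFrame(
        {
            "nt_indels": nt_i,
            "t_indels": t_i,
            "nt_motifs": m_nt,
            "t_motifs": m_t,
        },
        index=[f"g{i:05d}" for i in range(n_genes)],
    )
    return StrandCounts(int(nt_i.sum()), int(t_i.sum()), M_nt, M_t, per_gene)


# ---------------------------------------------------------------------------
# File emission


def simulate_to_dir(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Run the full generator and write FASTA/BED/VCF/TSV/bedGraph plus the
    manifest JSON to ``out_dir``. Byte-identical for identical configs."""
    from .genome_io import write_signal_track

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, genes, manifest = generate_reference(config)
    indels_by_sample, metadata, truth = generate_cohort(config, genome, manifest)
    expression = generate_expression(config, genes, manifest)
    tracks, truths = generate_repliseq(config, genome)
    write_genome(genome, out / "genome.fa")
    write_gene_table(genes, out / "genes.bed")
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for sample, records in indels_by_sample.items():
        write_indel_vcf(records, genome, vcf_dir / f"{sample}.vcf")
    metadata.to_csv(out / "samples.tsv", sep="\t", index=False)
    expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    write_signal_track(tracks, out / "repliseq.bedgraph")
    manifest_out = dict(manifest)
    manifest_out["indels"] = truth
    manifest_out["repliseq_truth"] = {c: list(map(str, v)) for c, v in truths.items()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest_out, fh, indent=1)
    return out
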