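"""Repeat-tract atlas: genome-wide mono- and dinucleotide tract discovery,
orientation relative to transcription, and reference-genome asymmetries.

A tract is a maximal run of its repeat unit on the reference strand. Each
tract overlapping a gene is given the reading of its unit 5'->3' on the
gene's non-template (coding) strand: the reference unit for a '+' gene, the
reverse complement for a '-' gene. PolyT tracts reading T on the
non-template strand of their host gene sit on the coding strand, where
transcription-coupled repair does not reach them.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_io import GeneRecord, GenomeSequence, revcomp

#: dinucleotide units that can be oriented (no palindromes, no homo-pairs)
DINUC_UNITS = ("GT", "TG", "AC", "CA", "CT", "TC", "AG", "GA")


@dataclass(frozen=True)
class RepeatTract:
    chrom: str
    start: int
    end: int
    unit: str  # as read on the reference strand
    n_units: int
    over_max: bool = False

    def __post_init__(self):
        if self.end - self.start != self.n_units * len(self.unit):
            raise ValueError("length inconsistent with unit and n_units")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class OrientedTract:
    tract: RepeatTract
    gene_id: str
    gene_strand: str

    @property
    def nt_unit(self) -> str:
        """Repeat unit as read 5'->3' on the gene's non-template strand."""
        u = self.tract.unit
        return u if self.gene_strand == "+" else revcomp(u)


def find_homopolymer_tracts(
    genome: GenomeSequence, min_len: int = 1, max_len: int = 10
) -> list[RepeatTract]:
    """Every maximal single-base run with length >= ``min_len``.

    Runs longer than ``max_len`` are emitted with their true length and
    flagged ``over_max`` (length-stratified outputs pool them as '10+').
    Ns break runs and are never emitted.
    """
    tracts: list[RepeatTract] = []
    for chrom in genome.chrom_names:
        seq = np.frombuffer(genome.sequence(chrom).encode(), dtype=np.uint8)
        if seq.size == 0:
            continue
        boundaries = np.flatnonzero(seq[1:] != seq[:-1]) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [seq.size]))
        for s, e in zip(starts.tolist(), ends.tolist()):
            base = chr(seq[s])
            if base not in "ACGT":
                continue
            length = e - s
            if length < min_len:
                continue
            tracts.append(RepeatTract(chrom, s, e, base, length, over_max=length > max_len))
    return tracts


def find_dinucleotide_tracts(
    genome: GenomeSequence, min_units: int = 1, max_units: int = 5
) -> list[RepeatTract]:
    """Greedy leftmost-longest scan for tracts of the eight orientable
    dinucleotide units. Tracts span complete units only; palindromic
    (AT/TA/GC/CG) and homo-pair (AA/CC/GG/TT) units are never emitted,
    guaranteeing that emitted tracts are mutually non-overlapping.
    """
    tracts: list[RepeatTract] = []
    allowed = set(DINUC_UNITS)
    for chrom in genome.chrom_names:
        seq = genome.sequence(chrom)
        n = len(seq)
        i = 0
        while i < n - 1:
            unit = seq[i : i + 2]
            if unit not in allowed:
                i += 1
                continue
            k = 1
            while seq[i + 2 * k : i + 2 * k + 2] == unit:
                k += 1
            if k >= min_units:
                tracts.append(
                    RepeatTract(chrom, i, i + 2 * k, unit, k, over_max=k > max_units)
                )
                i += 2 * k
            else:
                i += 1
    return tracts


def orient_tracts(
    tracts: list[RepeatTract],
    genes: list[GeneRecord],
    exclude_bidirectional: bool = False,
) -> list[OrientedTract]:
    """One :class:`OrientedTract` per (tract, gene) pair with the tract fully
    inside the gene body. Tracts straddling gene boundaries are dropped from
    genic analyses; a tract inside two overlapping genes yields one record
    per gene (``exclude_bidirectional`` drops tracts covered by genes on
    both strands).
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    gene_map: dict[str, GeneRecord] = {}
    for g in genes:
        trees[g.chrom][g.start : g.end] = g.gene_id
        gene_map[g.gene_id] = g
    out: list[OrientedTract] = []
    for t in tracts:
        hits = [iv for iv in trees[t.chrom].overlap(t.start, t.end)
                if iv.begin <= t.start and t.end <= iv.end]
        if not hits:
            continue
        if exclude_bidirectional and len({gene_map[iv.data].strand for iv in hits}) > 1:
            continue
        for iv in hits:
            g = gene_map[iv.data]
            out.append(OrientedTract(t, g.gene_id, g.strand))
    return out


def _length_stratum(tract: RepeatTract, max_len: int = 10) -> str:
    if tract.over_max:
        return f"{max_len}+"
    key = tract.n_units if len(tract.unit) == 2 else tract.length
    return str(key)


def reference_asymmetry(
    oriented_tracts: list[OrientedTract], unit: str, by_length: bool = True
) -> pd.DataFrame:
    """Non-template / template occurrence counts and their ratio for ``unit``.

    A tract counts as non-template when its non-template reading equals
    ``unit`` and as template when the reading equals the reverse complement
    (i.e. the tract reads ``unit`` on the template strand). Rows are length
    strata plus a ``weighted_average`` row whose ratio is the occurrence-
    weighted mean of the per-length ratios (weights = per-length NT+T
    totals); ratios with a zero template count are NaN-flagged.
    """
    target_t = revcomp(unit)
    counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for ot in oriented_tracts:
        stratum = _length_stratum(ot.tract) if by_length else "all"
        if ot.nt_unit == unit:
            counts[stratum][0] += 1
        elif ot.nt_unit == target_t:
            counts[stratum][1] += 1
    rows = []
    for stratum in sorted(counts, key=lambda s: (len(s), s)):
        nt, t = counts[stratum]
        rows.append(
            {"stratum": stratum, "nt": nt, "t": t, "ratio": nt / t if t > 0 else np.nan}
        )
    df = pd.DataFrame(rows, columns=["stratum", "nt", "t", "ratio"])
    valid = df.dropna(subset=["ratio"])
    w = (valid["nt"] + valid["t"]).to_numpy(dtype=float)
    wavg = float(np.average(valid["ratio"], weights=w)) if w.sum() > 0 else np.nan
    total_nt, total_t = int(df["nt"].sum()), int(df["t"].sum())
    df.loc[len(df)] = {"stratum": "weighted_average", "nt": total_nt, "t": total_t, "ratio": wavg}
    return df


# ---------------------------------------------------------------------------
# Metagene bins


def _gene_bins(gene: GeneRecord, n_body_bins: int, flank_bp: int, flank_bins: int):
    """Bin edges in genome coordinates plus the transcription-order mapping.

    Returns (edges, order): ``edges`` has len = total_bins + 1 ascending in
    genome coordinates; ``order[i]`` gives the transcription-direction index
    (0 = 5'-most flank bin) of genomic bin i.
    """
    total = n_body_bins + 2 * flank_bins
    flank_w = flank_bp // flank_bins
    left = [gene.start - flank_w * (flank_bins - i) for i in range(flank_bins)]
    body = np.linspace(gene.start, gene.end, n_body_bins + 1)
    right = [gene.end + flank_w * (i + 1) for i in range(flank_bins)]
    edges = np.array(left + list(body) + right, dtype=float)
    order = np.arange(total) if gene.strand == "+" else np.arange(total)[::-1]
    return edges, order


def gene_bin_enrichment(
    tracts: list[RepeatTract],
    genes: list[GeneRecord],
    genome: GenomeSequence | None = None,
    n_body_bins: int = 10,
    flank_bp: int = 10000,
    flank_bins: int = 2,
) -> pd.DataFrame:
    """Metagene bin densities and enrichments.

    Each gene contributes ``n_body_bins`` equal body bins plus
    ``flank_bins`` 10 kb-total flank bins upstream of the TSS and downstream
    of the TES; bin 1 is the 5'-most bin in transcription direction. A tract
    is assigned to the bin containing its start. Density = tracts per base
    aggregated over genes; enrichment = bin density / all-bin density.
    Genes shorter than ``n_body_bins`` bases are excluded.
    """
    total_bins = n_body_bins + 2 * flank_bins
    tract_counts = np.zeros(total_bins)
    base_totals = np.zeros(total_bins)
    by_chrom: dict[str, list[RepeatTract]] = defaultdict(list)
    for t in tracts:
        by_chrom[t.chrom].append(t)
    starts_by_chrom = {
        c: np.array(sorted(t.start for t in ts)) for c, ts in by_chrom.items()
    }
    n_excluded = 0
    for gene in genes:
        if gene.length < n_body_bins:
            n_excluded += 1
            continue
        edges, order = _gene_bins(gene, n_body_bins, flank_bp, flank_bins)
        chrom_len = genome.length(gene.chrom) if genome is not None else None
        clipped = np.clip(edges, 0, chrom_len) if chrom_len is not None else edges
        widths = np.diff(clipped)
        for genomic_bin, tx_bin in enumerate(order):
            lo, hi = clipped[genomic_bin], clipped[genomic_bin + 1]
            base_totals[tx_bin] += hi - lo
            if genome is not None:
                seg = genome.sequence(gene.chrom, int(lo), int(hi))
                base_totals[tx_bin] -= seg.count("N")
        starts = starts_by_chrom.get(gene.chrom)
        if starts is None or widths.sum() == 0:
            continue
        lo_all, hi_all = clipped[0], clipped[-1]
        sel = starts[(starts >= lo_all) & (starts < hi_all)]
        bins = np.searchsorted(clipped, sel, side="right") - 1
        for b in bins:
            tract_counts[order[int(b)]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(base_totals > 0, tract_counts / base_totals, np.nan)
    overall = tract_counts.sum() / base_totals.sum() if base_totals.sum() else np.nan
    enrichment = density / overall if overall else np.full(total_bins, np.nan)
    return pd.DataFrame(
        {
            "bin": np.arange(1, total_bins + 1),
            "tract_count": tract_counts,
            "bases": base_totals,
            "density": density,
            "enrichment": enrichment,
        }
    )


# ---------------------------------------------------------------------------
# Anchor profiles and skew


def _anchor_offset(pos: int, gene: GeneRecord, anchor: str) -> int:
    """Signed offset of a genomic position from the gene's TSS/TES, measured
    in the transcription direction (positive = downstream)."""
    a = gene.tss() if anchor == "TSS" else gene.tes()
    return pos - a if gene.strand == "+" else a - pos


def positional_density_profile(
    oriented_tracts: list[OrientedTract],
    genes: list[GeneRecord],
    unit: str,
    anchor: str = "TSS",
    window_bp: int = 2000,
    interval: int = 100,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Tract density per ``interval`` around the TSS or TES, split by strand.

    Offsets are measured in transcription direction; densities are tract
    starts per base aggregated over genes. The standard error per interval
    comes from a gene-level bootstrap (``n_boot`` resamples of genes with
    replacement).
    """
    if not genes:
        raise ValueError("no genes supplied")
    if window_bp % interval:
        raise ValueError("window_bp must be a multiple of interval")
    if anchor not in ("TSS", "TES"):
        raise ValueError("anchor must be 'TSS' or 'TES'")
    target_t = revcomp(unit)
    n_bins = 2 * window_bp // interval
    gene_idx = {g.gene_id: i for i, g in enumerate(genes)}
    gene_map = {g.gene_id: g for g in genes}
    nt_counts = np.zeros((len(genes), n_bins))
    t_counts = np.zeros((len(genes), n_bins))
    for ot in oriented_tracts:
        if ot.gene_id not in gene_idx:
            continue
        gene = gene_map[ot.gene_id]
        off = _anchor_offset(ot.tract.start, gene, anchor)
        if not (-window_bp <= off < window_bp):
            continue
        b = (off + window_bp) // interval
        if ot.nt_unit == unit:
            nt_counts[gene_idx[ot.gene_id], b] += 1
        elif ot.nt_unit == target_t:
            t_counts[gene_idx[ot.gene_id], b] += 1
    n_genes = len(genes)
    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, n_genes, size=(n_boot, n_genes))
    rows = []
    for label, counts in (("non_template", nt_counts), ("template", t_counts)):
        density = counts.sum(axis=0) / (n_genes * interval)
        boot = counts[boot_idx].sum(axis=1) / (n_genes * interval)
        se = boot.std(axis=0, ddof=1)
        for b in range(n_bins):
            rows.append(
                {
                    "offset": -window_bp + b * interval,
                    "strand": label,
                    "density": density[b],
                    "se": se[b],
                }
            )
    return pd.DataFrame(rows)


def sequence_skew(
    genome: GenomeSequence,
    genes: list[GeneRecord],
    anchor: str = "TSS",
    window_bp: int = 2000,
    interval: int = 100,
    kind: str = "GC",
) -> pd.DataFrame:
    """GC- or AT-skew per 100 bp window around the TSS/TES.

    Skew is read on the non-template strand of each gene: (G-C)/(G+C) or
    (A-T)/(A+T). Windows falling outside the chromosome are dropped, as are
    gene-windows with a zero denominator; the aggregate is the mean over the
    remaining genes per offset.
    """
    if kind not in ("GC", "AT"):
        raise ValueError("kind must be 'GC' or 'AT'")
    x, y = ("G", "C") if kind == "GC" else ("A", "T")
    n_bins = 2 * window_bp // interval
    sums = np.zeros(n_bins)
    ns = np.zeros(n_bins)
    for gene in genes:
        clen = genome.length(gene.chrom)
        a = gene.tss() if anchor == "TSS" else gene.tes()
        for b in range(n_bins):
            off = -window_bp + b * interval
            if gene.strand == "+":
                lo, hi = a + off, a + off + interval
                if lo < 0 or hi > clen:
                    continue
                win = genome.sequence(gene.chrom, lo, hi)
            else:
                hi, lo = a - off + 1, a - off + 1 - interval
                if lo < 0 or hi > clen:
                    continue
                win = revcomp(genome.sequence(gene.chrom, lo, hi))
            denom = win.count(x) + win.count(y)
            if denom == 0:
                continue
            sums[b] += (win.count(x) - win.count(y)) / denom
            ns[b] += 1
    with np.errstate(invalid="ignore"):
        skew = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    return pd.DataFrame(
        {"offset": [-window_bp + b * interval for b in range(n_bins)], "skew": skew, "n_genes": ns}
    )


def write_atlas_bed(tracts: list[RepeatTract], path) -> None:
    """Atlas as BED6+: name = unit:n_units, score = length, strand = '.'."""
    with open(path, "w") as fh:
        for t in sorted(tracts, key=lambda t: (t.chrom, t.start)):
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.unit}:{t.n_units}\t{t.length}\t.\n"
            )
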