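"""Indel-tract intersection and cohort summary statistics.

Overlap follows an interval-intersection definition: a deletion overlaps a
tract when its deleted interval intersects the tract interval; an insertion
overlaps when its insertion point lies anywhere across the tract or
immediately before or after it. Overlap is positional only — the inserted or
deleted sequence is not required to match the tract unit (a strict
``require_base_match`` mode is available for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genome_io import IndelRecord, revcomp
from .motif_atlas import OrientedTract, RepeatTract, _length_stratum


@dataclass(frozen=True)
class IndelTractHit:
    indel: IndelRecord
    tract: RepeatTract
    gene_id: str
    strand_class: str  # 'non_template' | 'template'

    @property
    def length_stratum(self) -> str:
        return _length_stratum(self.tract)


def overlaps(indel: IndelRecord, tract: RepeatTract) -> bool:
    """Positional overlap between an indel and a repeat tract.

    Deletions: the deleted interval intersects [tract.start, tract.end).
    Insertions: the insertion point p satisfies tract.start <= p <= tract.end
    (inside the tract or immediately flanking it).
    """
    if indel.chrom != tract.chrom:
        return False
    if indel.kind == "deletion":
        s, e = indel.interval
        return s < tract.end and tract.start < e
    return tract.start <= indel.pos <= tract.end


def assign_hits(
    indels: list[IndelRecord],
    oriented_tracts: list[OrientedTract],
    target_unit: str,
    require_base_match: bool = False,
) -> list[IndelTractHit]:
    """Intersect indels with oriented tracts of one target unit.

    Hits on tracts whose non-template reading equals ``target_unit`` are
    labelled ``non_template``; hits on tracts reading the unit on the
    template strand (non-template reading = reverse complement) are labelled
    ``template``. An indel hitting several (tract, gene) pairs yields one
    hit per pair; equivalent to the all-pairs brute force.
    """
    target_t = revcomp(target_unit)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, ot in enumerate(oriented_tracts):
        if ot.nt_unit == target_unit or ot.nt_unit == target_t:
            t = ot.tract
            # pad by 1 so boundary insertion points (p == end) are found
            trees[t.chrom][t.start : t.end + 1] = i
    hits: list[IndelTractHit] = []
    for indel in indels:
        tree = trees.get(indel.chrom)
        if tree is None:
            continue
        s, e = indel.interval
        candidates = tree.overlap(s, e) if e > s else tree.at(s) | tree.overlap(max(0, s - 1), s + 1)
        for iv in candidates:
            ot = oriented_tracts[iv.data]
            if not overlaps(indel, ot.tract):
                continue
            if require_base_match and set(indel.seq) != set(ot.tract.unit):
                continue
            cls = "non_template" if ot.nt_unit == target_unit else "template"
            hits.append(IndelTractHit(indel, ot.tract, ot.gene_id, cls))
    # deterministic order regardless of tree iteration order
    hits.sort(key=lambda h: (h.indel.chrom, h.indel.pos, h.tract.start, h.gene_id, h.strand_class))
    return hits


def cohort_summary(
    indels_by_sample: dict[str, list[IndelRecord]], callable_bp: int
) -> dict:
    """Per-sample indel counts, deletion:insertion ratios, sizes and density,
    with cohort-level location and size-variance tests.

    Density is indels per megabase of callable sequence. The location test
    is a rank-sum (Mann-Whitney U) between per-sample insertion and deletion
    counts; the size-variance test is the Brown-Forsythe (median-centred
    Levene) comparison of insertion vs deletion size distributions.
    """
    if not indels_by_sample:
        raise ValueError("no samples")
    rows = []
    all_ins_sizes: list[int] = []
    all_del_sizes: list[int] = []
    for sample, indels in indels_by_sample.items():
        ins = [r for r in indels if r.kind == "insertion"]
        dele = [r for r in indels if r.kind == "deletion"]
        all_ins_sizes += [r.length for r in ins]
        all_del_sizes += [r.length for r in dele]
        rows.append(
            {
                "sample": sample,
                "n_insertions": len(ins),
                "n_deletions": len(dele),
                "del_ins_ratio": len(dele) / len(ins) if ins else np.nan,
                "median_ins_size": float(np.median([r.length for r in ins])) if ins else np.nan,
                "median_del_size": float(np.median([r.length for r in dele])) if dele else np.nan,
                "density_per_mb": len(indels) / (callable_bp / 1e6),
            }
        )
    df = pd.DataFrame(rows)
    result = {"per_sample": df,
              "median_insertions": float(df["n_insertions"].median()),
              "median_deletions": float(df["n_deletions"].median())}
    if len(df) >= 2:
        stat, p = stats.mannwhitneyu(df["n_deletions"], df["n_insertions"], alternative="two-sided")
        result["count_rank_sum_p"] = float(p)
    if len(all_ins_sizes) >= 2 and len(all_del_sizes) >= 2:
        stat, p = stats.levene(all_ins_sizes, all_del_sizes, center="median")
        result["size_variance_stat"] = float(stat)
        result["size_variance_p"] = float(p)
    return result


def inter_indel_distances(
    indels: list[IndelRecord], kind: str | None = None
) -> list[int]:
    """Distances between consecutive indel starts of one sample, computed
    per chromosome (pairs spanning chromosomes are excluded); restrict to
    one indel class with ``kind``."""
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for r in indels:
        if kind is None or r.kind == kind:
            by_chrom[r.chrom].append(r.pos)
    dists: list[int] = []
    for positions in by_chrom.values():
        positions.sort()
        dists += [b - a for a, b in zip(positions, positions[1:])]
    return dists


def msi_length_response(
    hits: list[IndelTractHit],
    oriented_tracts: list[OrientedTract],
    sample_labels: dict[str, str],
) -> pd.DataFrame:
    """Indel frequency (hits per oriented tract occurrence) per tract-length
    stratum, split by MSI/MSS group. Strata with zero tracts are flagged."""
    tract_totals: dict[str, int] = defaultdict(int)
    for ot in oriented_tracts:
        tract_totals[_length_stratum(ot.tract)] += 1
    hit_counts: dict[tuple[str, str], int] = defaultdict(int)
    for h in hits:
        group = sample_labels.get(h.indel.sample_id)
        if group is None:
            continue
        hit_counts[(group, h.length_stratum)] += 1
    n_samples = defaultdict(int)
    for label in sample_labels.values():
        n_samples[label] += 1
    rows = []
    for group in sorted(set(sample_labels.values())):
        for stratum in sorted(tract_totals, key=lambda s: (len(s), s)):
            n_tracts = tract_totals[stratum]
            n_hits = hit_counts.get((group, stratum), 0)
            rows.append(
                {
                    "group": group,
                    "stratum": stratum,
                    "n_hits": n_hits,
                    "n_tracts": n_tracts,
                    "frequency": n_hits / n_tracts if n_tracts else np.nan,
                    "per_sample_frequency": (n_hits / n_tracts / n_samples[group])
                    if n_tracts and n_samples[group]
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def write_hits_tsv(hits: list[IndelTractHit], path) -> None:
    cols = ["sample", "chrom", "pos", "kind", "indel_len", "tract_start", "tract_end",
            "unit", "stratum", "gene_id", "strand_class"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    map(
                        str,
                        [h.indel.sample_id, h.indel.chrom, h.indel.pos, h.indel.kind,
                         h.indel.length, h.tract.start, h.tract.end, h.tract.unit,
                         h.length_stratum, h.gene_id, h.strand_class],
                    )
                )
                + "\n"
            )
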