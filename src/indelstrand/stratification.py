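"""Stratified strand-bias analyses: expression tiers, tract length,
replication timing quantiles and leading/lagging replication orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict

import numpy as np
import pandas as pd

from .genome_io import GeneRecord, SignalTrack
from .asymmetry_stats import BiasEstimate, StrandCounts, strand_bias
from .indel_catalog import IndelTractHit
from .motif_atlas import OrientedTract, _length_stratum


@dataclass
class ExpressionTiers:
    """Gene -> {low, medium, high} by 33rd/66th RPKM percentiles.

    Zero-RPKM ("not expressed") genes fall into ``low``; ties at a threshold
    go to the lower tier. ``degenerate`` is set when all values coincide.
    """

    tiers: dict[str, str]
    threshold_33: float
    threshold_66: float
    degenerate: bool = False

    def __getitem__(self, gene_id: str) -> str:
        return self.tiers[gene_id]


def expression_tiers(rpkm: pd.DataFrame | dict[str, float]) -> ExpressionTiers:
    """Assign low/medium/high expression tiers from an RPKM table.

    Accepts a DataFrame with columns gene_id/rpkm or a mapping. Thresholds
    are the 33rd and 66th percentiles over the supplied (protein-coding)
    genes; assignment is order-invariant and scale-invariant.
    """
    if isinstance(rpkm, pd.DataFrame):
        mapping = dict(zip(rpkm["gene_id"], rpkm["rpkm"].astype(float)))
    else:
        mapping = {k: float(v) for k, v in rpkm.items()}
    if not mapping:
        raise ValueError("empty expression table")
    values = np.array(list(mapping.values()))
    if np.any(values < 0):
        raise ValueError("negative RPKM")
    t33, t66 = np.percentile(values, [33, 66])
    degenerate = bool(np.all(values == values[0]))
    tiers = {}
    for gid, v in mapping.items():
        if v <= t33:
            tiers[gid] = "low"
        elif v <= t66:
            tiers[gid] = "medium"
        else:
            tiers[gid] = "high"
    return ExpressionTiers(tiers, float(t33), float(t66), degenerate)


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "rpkm" not in df.columns:
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "rpkm"])
    return df


def stratified_counts(
    hits: list[IndelTractHit],
    oriented_tracts: list[OrientedTract],
    unit: str,
    stratify_by: str = "expression",
    tiers: ExpressionTiers | None = None,
) -> dict[str, StrandCounts]:
    """Strand counts per stratum.

    ``expression``: genes grouped by tier, motif denominators restricted to
    each tier's genes. ``tract_length``: strata 1..10 / '10+'. ``both``:
    (tier, length) pairs keyed "tier|length". ``none``: a single 'all'
    stratum identical to the unstratified counts. Stratified counts sum
    exactly to the unstratified counts.
    """

    def strata_of(gene_id: str, tract) -> list[str]:
        if stratify_by == "expression":
            return [tiers[gene_id]] if gene_id in tiers.tiers else []
        if stratify_by == "tract_length":
            return [_length_stratum(tract)]
        if stratify_by == "both":
            if gene_id not in tiers.tiers:
                return []
            return [f"{tiers[gene_id]}|{_length_stratum(tract)}"]
        if stratify_by == "none":
            return ["all"]
        raise ValueError(f"unknown stratify_by {stratify_by!r}")

    from .genome_io import revcomp

    target_t = revcomp(unit)
    counts: dict[str, list[int]] = defaultdict(lambda: [0, 0, 0, 0])
    for ot in oriented_tracts:
        for s in strata_of(ot.gene_id, ot.tract):
            if ot.nt_unit == unit:
                counts[s][2] += 1
            elif ot.nt_unit == target_t:
                counts[s][3] += 1
    for h in hits:
        for s in strata_of(h.gene_id, h.tract):
            counts[s][0 if h.strand_class == "non_template" else 1] += 1
    return {s: StrandCounts(*c) for s, c in sorted(counts.items())}


def stratified_bias(
    hits: list[IndelTractHit],
    oriented_tracts: list[OrientedTract],
    unit: str,
    stratify_by: str = "expression",
    tiers: ExpressionTiers | None = None,
) -> dict[str, BiasEstimate]:
    """Strand bias per stratum (see :func:`stratified_counts`); strata with
    zero motifs on a strand yield an undefined estimate."""
    return {
        s: strand_bias(c)
        for s, c in stratified_counts(hits, oriented_tracts, unit, stratify_by, tiers).items()
    }


# ---------------------------------------------------------------------------
# Replication timing


@dataclass
class ReplicationAnnotation:
    """Per-bin replication annotation for one chromosome.

    ``orientation`` holds left_replicating / right_replicating / transition
    per bin from the sign of the smoothed first derivative of the timing
    signal; ``quantile`` holds the 1..n timing quantile. ``leading_strand``
    maps each oriented bin to the reference strand replicated as leading
    under the configured convention.
    """

    chrom: str
    bin_start: int
    bin_size: int
    timing: np.ndarray = field(repr=False)
    derivative: np.ndarray = field(repr=False)
    orientation: np.ndarray = field(repr=False)  # object array of labels
    quantile: np.ndarray = field(repr=False)
    second_derivative: np.ndarray = field(repr=False)
    convention: str = "right_lagging_plus"

    def bin_of(self, pos: int) -> int:
        return (pos - self.bin_start) // self.bin_size

    def orientation_at(self, pos: int) -> str:
        b = self.bin_of(pos)
        if 0 <= b < self.orientation.size:
            return str(self.orientation[b])
        return "transition"

    def strand_role(self, pos: int, strand: str) -> str:
        """leading/lagging role of a reference strand at a position."""
        o = self.orientation_at(pos)
        if o == "transition":
            return "transition"
        # convention right_lagging_plus: in right-replicating regions the
        # (+) reference strand is the lagging template, inverted on the left
        if self.convention == "right_lagging_plus":
            plus_role = "lagging" if o == "right_replicating" else "leading"
        else:
            plus_role = "leading" if o == "right_replicating" else "lagging"
        return plus_role if strand == "+" else ("leading" if plus_role == "lagging" else "lagging")


def replication_annotation(
    track: SignalTrack,
    smoothing_bp: int = 50000,
    derivative_threshold: float | None = None,
    n_quantiles: int = 5,
    convention: str = "right_lagging_plus",
) -> ReplicationAnnotation:
    """Annotate a Repli-seq timing track with replication direction.

    The signal is smoothed with a moving average over ``smoothing_bp``; the
    central-difference first derivative gives replication direction
    (positive slope = right-replicating), with |derivative| below
    ``derivative_threshold`` (default: its 5th percentile) labelled
    transition. The second derivative flags initiation/termination zones
    (reported only). Timing quantiles partition bins into ``n_quantiles``
    near-equal groups (quantile 1 = earliest / highest signal).
    """
    values = np.asarray(track.values, dtype=float)
    win = max(1, smoothing_bp // track.bin_size) | 1  # odd: symmetric under reversal
    if values.size < win:
        raise ValueError("track shorter than smoothing window")
    kernel = np.ones(win) / win
    pad = win // 2
    padded = np.pad(values, pad, mode="edge")
    smooth = np.convolve(padded, kernel, mode="same")[pad : pad + values.size]
    deriv = np.gradient(smooth)
    second = np.gradient(deriv)
    if derivative_threshold is None:
        derivative_threshold = float(np.percentile(np.abs(deriv), 5))
    orientation = np.where(
        np.abs(deriv) <= derivative_threshold,
        "transition",
        np.where(deriv > 0, "right_replicating", "left_replicating"),
    ).astype(object)
    order = np.argsort(-values, kind="stable")  # earliest = highest signal
    quantile = np.empty(values.size, dtype=int)
    splits = np.array_split(order, n_quantiles)
    for q, idx in enumerate(splits, start=1):
        quantile[idx] = q
    return ReplicationAnnotation(
        track.chrom, track.bin_start, track.bin_size, values, deriv,
        orientation, quantile, second, convention,
    )


def orientation_controlled_bias(
    hits: list[IndelTractHit],
    oriented_tracts: list[OrientedTract],
    unit: str,
    annotations: dict[str, ReplicationAnnotation],
) -> dict[str, BiasEstimate]:
    """Transcriptional strand bias within leading- and lagging-orientation
    tract partitions (partition by the replication orientation of the
    tract's midpoint bin; transition bins are excluded)."""
    from .genome_io import revcomp

    target_t = revcomp(unit)

    def part_of(tract) -> str | None:
        ann = annotations.get(tract.chrom)
        if ann is None:
            return None
        o = ann.orientation_at((tract.start + tract.end) // 2)
        if o == "transition":
            return None
        return "leading" if o == "right_replicating" else "lagging"

    counts: dict[str, list[int]] = defaultdict(lambda: [0, 0, 0, 0])
    for ot in oriented_tracts:
        p = part_of(ot.tract)
        if p is None:
            continue
        if ot.nt_unit == unit:
            counts[p][2] += 1
        elif ot.nt_unit == target_t:
            counts[p][3] += 1
    for h in hits:
        p = part_of(h.tract)
        if p is None:
            continue
        counts[p][0 if h.strand_class == "non_template" else 1] += 1
    return {p: strand_bias(StrandCounts(*c)) for p, c in sorted(counts.items())}


def gene_timing(
    genes: list[GeneRecord], annotations: dict[str, ReplicationAnnotation]
) -> dict[str, float]:
    """Length-weighted mean replication timing of each gene's bins."""
    out = {}
    for g in genes:
        ann = annotations.get(g.chrom)
        if ann is None:
            continue
        b0 = max(0, ann.bin_of(g.start))
        b1 = min(ann.timing.size - 1, ann.bin_of(g.end - 1))
        if b1 < b0:
            continue
        weights = []
        vals = []
        for b in range(b0, b1 + 1):
            lo = max(g.start, ann.bin_start + b * ann.bin_size)
            hi = min(g.end, ann.bin_start + (b + 1) * ann.bin_size)
            if hi > lo:
                weights.append(hi - lo)
                vals.append(ann.timing[b])
        if weights:
            out[g.gene_id] = float(np.average(vals, weights=weights))
    return out


def timing_quantile_bias(
    hits: list[IndelTractHit],
    oriented_tracts: list[OrientedTract],
    unit: str,
    gene_timing_values: dict[str, float],
    n_quantiles: int = 5,
) -> dict[int, BiasEstimate]:
    """Strand bias per replication-timing quantile of genes.

    Genes are ranked by mean timing and split into ``n_quantiles`` groups
    whose sizes differ by at most one gene (quantile 1 = earliest).
    """
    if len(gene_timing_values) < n_quantiles:
        raise ValueError("fewer genes than quantiles")
    genes_sorted = sorted(gene_timing_values, key=lambda g: -gene_timing_values[g])
    assignment: dict[str, int] = {}
    for q, chunk in enumerate(np.array_split(genes_sorted, n_quantiles), start=1):
        for g in chunk:
            assignment[g] = q
    from .genome_io import revcomp

    target_t = revcomp(unit)
    counts: dict[int, list[int]] = defaultdict(lambda: [0, 0, 0, 0])
    for ot in oriented_tracts:
        q = assignment.get(ot.gene_id)
        if q is None:
            continue
        if ot.nt_unit == unit:
            counts[q][2] += 1
        elif ot.nt_unit == target_t:
            counts[q][3] += 1
    for h in hits:
        q = assignment.get(h.gene_id)
        if q is None:
            continue
        counts[q][0 if h.strand_class == "non_template" else 1] += 1
    return {q: strand_bias(StrandCounts(*c)) for q, c in sorted(counts.items())}
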