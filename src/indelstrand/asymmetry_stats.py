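"""Background-corrected strand-bias statistics and inference.

The central statistic corrects the raw non-template/template indel count
contrast for the skewed background distribution of repeat tracts between
strands:

    A = nt_indels / nt_motifs        (non-template mutational density)
    B = t_indels  / t_motifs         (template mutational density)
    bias = A / (A + B)               (0.5 = no asymmetry)
    excess_pct = (A / B - 1) * 100   (corrected % increase on non-template)

Dispersion comes from a gene-level bootstrap: genes are resampled with
replacement, the four counts re-summed and the bias recomputed. The binomial
test compares nt_indels successes out of nt+t trials against the null
p0 = nt_motifs / (nt_motifs + t_motifs) (the motif-share null; ``null_half``
reproduces the uncorrected p0 = 0.5 test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections import defaultdict

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GeneRecord, revcomp
from .indel_catalog import IndelTractHit
from .motif_atlas import DINUC_UNITS, OrientedTract


@dataclass
class StrandCounts:
    """The four counts feeding the bias statistic, optionally per gene.

    ``per_gene`` is a DataFrame indexed by gene_id with columns
    nt_indels / t_indels / nt_motifs / t_motifs summing to the totals.
    """

    nt_indels: int
    t_indels: int
    nt_motifs: int
    t_motifs: int
    per_gene: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        for name in ("nt_indels", "t_indels", "nt_motifs", "t_motifs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} < 0")
        if self.per_gene is not None:
            for col in ("nt_indels", "t_indels", "nt_motifs", "t_motifs"):
                if int(self.per_gene[col].sum()) != getattr(self, col):
                    raise ValueError(f"per-gene {col} do not sum to the total")

    @classmethod
    def from_hits(
        cls, hits: list[IndelTractHit], oriented_tracts: list[OrientedTract], unit: str
    ) -> "StrandCounts":
        """Assemble counts for one target unit from hits and the atlas."""
        target_t = revcomp(unit)
        rows: dict[str, list[int]] = defaultdict(lambda: [0, 0, 0, 0])
        for ot in oriented_tracts:
            if ot.nt_unit == unit:
                rows[ot.gene_id][2] += 1
            elif ot.nt_unit == target_t:
                rows[ot.gene_id][3] += 1
        for h in hits:
            idx = 0 if h.strand_class == "non_template" else 1
            rows[h.gene_id][idx] += 1
        per_gene = pd.DataFrame.from_dict(
            rows, orient="index", columns=["nt_indels", "t_indels", "nt_motifs", "t_motifs"]
        ).sort_index()
        return cls(
            int(per_gene["nt_indels"].sum()),
            int(per_gene["t_indels"].sum()),
            int(per_gene["nt_motifs"].sum()),
            int(per_gene["t_motifs"].sum()),
            per_gene,
        )


@dataclass
class BiasEstimate:
    A: float
    B: float
    bias: float  # A/(A+B); NaN when undefined
    excess_pct: float  # (A/B - 1) * 100
    boot_mean: float = np.nan
    boot_sd: float = np.nan
    n_boot: int = 0
    seed: int | None = None
    p_value: float = np.nan
    p_adjusted: float = np.nan

    @property
    def defined(self) -> bool:
        return np.isfinite(self.bias)


def strand_bias(counts: StrandCounts) -> BiasEstimate:
    """Point estimate of the background-corrected strand bias."""
    if counts.nt_motifs == 0 or counts.t_motifs == 0:
        return BiasEstimate(np.nan, np.nan, np.nan, np.nan)
    A = counts.nt_indels / counts.nt_motifs
    B = counts.t_indels / counts.t_motifs
    if A + B == 0:
        return BiasEstimate(A, B, np.nan, np.nan)
    bias = A / (A + B)
    excess = (A / B - 1) * 100 if B > 0 else np.inf
    return BiasEstimate(A, B, bias, excess)


def _bias_from_sums(sums: np.ndarray) -> np.ndarray:
    """Vectorized bias for an (n, 4) array of count sums; NaN where undefined."""
    nt_i, t_i, nt_m, t_m = sums.T.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(nt_m > 0, nt_i / np.maximum(nt_m, 1), np.nan)
        B = np.where(t_m > 0, t_i / np.maximum(t_m, 1), np.nan)
        bias = A / (A + B)
        bias = np.where((nt_m == 0) | (t_m == 0) | (A + B == 0), np.nan, bias)
    return bias


def bootstrap_bias(
    counts: StrandCounts, n_boot: int = 1000, seed: int = 0, max_redraw_rounds: int = 50
) -> BiasEstimate:
    """Gene-level bootstrap of the strand bias.

    Each iteration draws genes with replacement (same number of genes), sums
    the four counts and recomputes the bias; iterations with an undefined
    bias are redrawn (warned above a 1% redraw rate). Reproducible given
    ``seed``.
    """
    if counts.per_gene is None or len(counts.per_gene) < 2:
        raise ValueError("bootstrap requires per-gene counts for >=2 genes")
    if counts.nt_indels + counts.t_indels == 0:
        raise ValueError("all-zero indel counts")
    mat = counts.per_gene[["nt_indels", "t_indels", "nt_motifs", "t_motifs"]].to_numpy()
    n_genes = mat.shape[0]
    rng = np.random.default_rng(seed)
    biases = np.full(n_boot, np.nan)
    n_redrawn = 0
    pending = np.arange(n_boot)
    for _ in range(max_redraw_rounds):
        if pending.size == 0:
            break
        idx = rng.integers(0, n_genes, size=(pending.size, n_genes))
        sums = mat[idx].sum(axis=1)
        vals = _bias_from_sums(sums)
        biases[pending] = vals
        pending = pending[~np.isfinite(vals)]
        n_redrawn += pending.size
    if pending.size:
        raise RuntimeError("bootstrap could not obtain defined bias draws")
    if n_redrawn > 0.01 * n_boot:
        warnings.warn(f"bootstrap redrew {n_redrawn}/{n_boot} undefined iterations")
    est = strand_bias(counts)
    est.boot_mean = float(biases.mean())
    est.boot_sd = float(biases.std(ddof=1))
    est.n_boot = n_boot
    est.seed = seed
    return est


def binomial_strand_test(
    counts: StrandCounts, two_sided: bool = True, null_half: bool = False
) -> float:
    """Exact binomial test of the non-template indel count.

    Null success probability is the non-template motif share
    nt_motifs/(nt_motifs+t_motifs) — the background-corrected null — or 0.5
    with ``null_half``.
    """
    n = counts.nt_indels + counts.t_indels
    if n < 1:
        raise ValueError("no indel counts")
    if null_half or counts.nt_motifs + counts.t_motifs == 0:
        p0 = 0.5
    else:
        p0 = counts.nt_motifs / (counts.nt_motifs + counts.t_motifs)
    alternative = "two-sided" if two_sided else "greater"
    return float(stats.binomtest(counts.nt_indels, n, p0, alternative=alternative).pvalue)


def msi_enrichment_ratio(
    overlap_by_sample: dict[str, tuple[int, int]], labels: dict[str, str]
) -> float:
    """MSI / MSS ratio of pooled proportions of indels overlapping tracts.

    ``overlap_by_sample`` maps sample -> (indels overlapping polyA/T tracts,
    total indels); proportions are pooled within group before the ratio.
    """
    pools = {"MSI": [0, 0], "MSS": [0, 0]}
    for sample, (n_overlap, n_total) in overlap_by_sample.items():
        group = labels[sample]
        pools[group][0] += n_overlap
        pools[group][1] += n_total
    for group, (o, t) in pools.items():
        if t == 0:
            raise ValueError(f"group {group} has no indels")
    p_msi = pools["MSI"][0] / pools["MSI"][1]
    p_mss = pools["MSS"][0] / pools["MSS"][1]
    if p_mss == 0:
        return np.nan
    return p_msi / p_mss


def group_comparison(
    values_by_group: dict[str, list[float]],
    test: str = "rank_sum",
    family_size: int = 1,
) -> dict:
    """Rank tests on per-sample bias values with explicit Bonferroni family.

    ``rank_sum`` (Mann-Whitney U, 2 groups), ``kruskal`` (>=2 groups) or
    ``signed_rank`` (Wilcoxon on paired vectors, 2 groups of equal length).
    Groups with fewer than 2 samples are excluded with a note.
    """
    groups = {k: [v for v in vs if np.isfinite(v)] for k, vs in values_by_group.items()}
    excluded = [k for k, vs in groups.items() if len(vs) < 2]
    groups = {k: vs for k, vs in groups.items() if len(vs) >= 2}
    if test == "rank_sum":
        if len(groups) != 2:
            raise ValueError("rank_sum needs exactly 2 usable groups")
        (a, b) = groups.values()
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "kruskal":
        if len(groups) < 2:
            raise ValueError("kruskal needs >=2 usable groups")
        stat, p = stats.kruskal(*groups.values())
    elif test == "signed_rank":
        if len(groups) != 2:
            raise ValueError("signed_rank needs exactly 2 usable groups")
        (a, b) = groups.values()
        if len(a) != len(b):
            raise ValueError("signed_rank needs paired vectors of equal length")
        if np.allclose(np.asarray(a) - np.asarray(b), 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "test": test,
        "statistic": float(stat),
        "p_raw": float(p),
        "p_adjusted": float(min(1.0, p * family_size)),
        "family_size": family_size,
        "excluded_groups": excluded,
    }


def downsample_zscore(
    focal_nt: int,
    focal_n: int,
    cohort_counts: dict[str, StrandCounts],
    n_boot: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Down-sampling comparison of a low-count focal sample against cohorts.

    For each cohort, ``n_boot`` draws of ``focal_n`` hits are sampled from
    the cohort's pooled hit classes, each hit non-template with probability
    equal to the cohort's observed non-template hit share (weighting by the
    observed asymmetry). The bias of each draw uses the cohort's motif
    denominators; z = (focal_bias - mean)/sd and the empirical p is the
    two-sided tail fraction.
    """
    if focal_n < 1:
        raise ValueError("focal sample has no hits; z undefined")
    rng = np.random.default_rng(seed)
    rows = []
    for cohort, counts in cohort_counts.items():
        n_hits = counts.nt_indels + counts.t_indels
        if n_hits == 0 or counts.nt_motifs == 0 or counts.t_motifs == 0:
            rows.append({"cohort": cohort, "z": np.nan, "p_empirical": np.nan})
            continue
        p_nt = counts.nt_indels / n_hits
        draws_nt = rng.binomial(focal_n, p_nt, size=n_boot)
        A = draws_nt / counts.nt_motifs
        B = (focal_n - draws_nt) / counts.t_motifs
        with np.errstate(invalid="ignore", divide="ignore"):
            draw_bias = A / (A + B)
        draw_bias = draw_bias[np.isfinite(draw_bias)]
        A_f = focal_nt / counts.nt_motifs
        B_f = (focal_n - focal_nt) / counts.t_motifs
        focal_bias = A_f / (A_f + B_f)
        mu, sd = draw_bias.mean(), draw_bias.std(ddof=1)
        z = (focal_bias - mu) / sd if sd > 0 else np.nan
        p_emp = float(np.mean(np.abs(draw_bias - mu) >= abs(focal_bias - mu)))
        rows.append({"cohort": cohort, "z": float(z), "p_empirical": p_emp,
                     "draw_mean": float(mu), "draw_sd": float(sd),
                     "focal_bias": float(focal_bias)})
    return pd.DataFrame(rows)


def substitution_orientation(
    substitutions: list[tuple[str, int, str, str]],
    genes: list[GeneRecord],
    target_change: str = "C>A",
    tracts=None,
    flank: int = 1,
) -> StrandCounts:
    """Orient single-base substitutions relative to transcription.

    A substitution of class X>Y inside a gene is non-template-assigned when
    the reference base read on the non-template strand equals X (the change
    happened on the coding strand) and template-assigned when it equals the
    complement of X. Reference-N positions are skipped. When ``tracts`` is
    given, only positions inside or within ``flank`` bases of a tract count.
    """
    from intervaltree import IntervalTree

    x = target_change.split(">")[0].upper()
    comp = revcomp(x)
    gene_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        gene_trees[g.chrom][g.start : g.end] = g.strand
    tract_trees = None
    if tracts is not None:
        tract_trees = defaultdict(IntervalTree)
        for t in tracts:
            tract_trees[t.chrom][max(0, t.start - flank) : t.end + flank] = True
    nt = t_count = 0
    for chrom, pos, ref, _alt in substitutions:
        ref = ref.upper()
        if ref == "N":
            continue
        if tract_trees is not None and not tract_trees[chrom].at(pos):
            continue
        for iv in gene_trees[chrom].at(pos):
            strand = iv.data
            nt_ref = ref if strand == "+" else revcomp(ref)
            if nt_ref == x:
                nt += 1
            elif nt_ref == comp:
                t_count += 1
    return StrandCounts(nt, t_count, 1, 1)


def asymmetry_matrix(
    cohort_data: dict[str, tuple[list, list[OrientedTract]]],
    max_units: int = 5,
) -> pd.DataFrame:
    """Strand-bias matrix: cohorts x (dinucleotide unit, repeat count).

    ``cohort_data`` maps cohort -> (indels, oriented dinucleotide tracts).
    Entries are the background-corrected bias per (unit, n_units) stratum;
    strata with no hits or no motifs on a strand are missing (NaN).
    Clustering/rendering of the matrix is left to the caller.
    """
    from .indel_catalog import assign_hits
    from .motif_atlas import _length_stratum

    columns = [f"{u}x{k}" for u in DINUC_UNITS for k in range(1, max_units + 1)]
    rows = {}
    for cohort, (indels, oriented) in cohort_data.items():
        row = {}
        for unit in DINUC_UNITS:
            target_t = revcomp(unit)
            hits = assign_hits(indels, oriented, unit)
            for k in range(1, max_units + 1):
                stratum = str(k)
                nt_m = sum(1 for ot in oriented
                           if ot.nt_unit == unit and _length_stratum(ot.tract) == stratum)
                t_m = sum(1 for ot in oriented
                          if ot.nt_unit == target_t and _length_stratum(ot.tract) == stratum)
                nt_i = sum(1 for h in hits
                           if h.strand_class == "non_template" and h.length_stratum == stratum)
                t_i = sum(1 for h in hits
                          if h.strand_class == "template" and h.length_stratum == stratum)
                est = strand_bias(StrandCounts(nt_i, t_i, nt_m, t_m))
                row[f"{unit}x{k}"] = est.bias
        rows[cohort] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
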