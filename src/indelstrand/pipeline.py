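"""End-to-end orchestration: atlas -> hit annotation -> bias -> strata -> report.

A single :class:`RunConfig` drives every stage; the config and all seeds are
serialized into the output directory so any run can be reproduced exactly.
Stages stream one cohort at a time and write plain TSVs with "NA" for
missing values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genome_io, indel_catalog, motif_atlas, asymmetry_stats, stratification

logger = logging.getLogger("indelstrand")


@dataclass
class RunConfig:
    genome: str
    genes: str
    vcf_dir: str
    samples: str  # metadata TSV: sample, cohort, msi_status
    out_dir: str
    expression: str | None = None
    repliseq: str | None = None
    units: tuple[str, ...] = ("T", "G")
    dinucleotides: bool = False
    min_len: int = 1
    max_len: int = 10
    coords: str = "bed"
    chrom_style: str = "keep"
    biotype_filter: str | None = None
    normalize_indels: bool = True
    split_ins_del: bool = True
    msi_comparison: bool = True
    expression_strata: bool = True
    replication_strata: bool = True
    n_boot: int = 1000
    seed: int = 0
    family_size: int = 1
    null_half: bool = False
    repliseq_bin_size: int = 1000
    rep_smoothing_bp: int = 50000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "units" in data:
            data["units"] = tuple(data["units"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["units"] = list(d["units"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d["units"] = list(d["units"])
        d.pop("out_dir", None)  # analysis identity is independent of destination
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def _bias_row(unit, stratum, counts, est, family_size):
    return {
        "unit": unit,
        "stratum": stratum,
        "nt_indels": counts.nt_indels,
        "t_indels": counts.t_indels,
        "nt_motifs": counts.nt_motifs,
        "t_motifs": counts.t_motifs,
        "A": est.A,
        "B": est.B,
        "bias": est.bias,
        "excess_pct": est.excess_pct,
        "boot_mean": est.boot_mean,
        "boot_sd": est.boot_sd,
        "p_raw": est.p_value,
        "p_adj": est.p_adjusted,
        "family_size": family_size,
    }


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the whole pipeline and write the report directory.

    Produces atlas BED files, per-sample hit TSVs, per-cohort bias tables
    (overall, by tract length, insertion/deletion split, MSI split,
    expression tiers, replication strata), the dinucleotide asymmetry
    matrix when enabled, and a log of seeds, versions and filter counts.
    Deterministic under fixed config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_inputs"
    results: dict = {}
    try:
        genome = genome_io.read_genome(config.genome)
        genes = genome_io.read_gene_table(
            config.genes, biotype_filter=config.biotype_filter, coords=config.coords,
            known_chroms=set(genome.chrom_names), chrom_style=config.chrom_style,
        )
        meta = pd.read_csv(config.samples, sep="\t")
        indels_by_sample = {}
        for _, row in meta.iterrows():
            vcf = Path(config.vcf_dir) / f"{row['sample']}.vcf"
            indels_by_sample[row["sample"]] = genome_io.read_indel_vcf(
                vcf, row["sample"], genome=genome, normalize=config.normalize_indels,
                chrom_style=config.chrom_style,
            )

        stage = "atlas"
        tracts = motif_atlas.find_homopolymer_tracts(genome, config.min_len, config.max_len)
        oriented = motif_atlas.orient_tracts(tracts, genes)
        motif_atlas.write_atlas_bed(tracts, out / "atlas_homopolymer.bed")
        oriented_di = []
        if config.dinucleotides:
            di_tracts = motif_atlas.find_dinucleotide_tracts(genome)
            oriented_di = motif_atlas.orient_tracts(di_tracts, genes)
            motif_atlas.write_atlas_bed(di_tracts, out / "atlas_dinucleotide.bed")

        stage = "annotate"
        cohorts = dict(tuple(meta.groupby("cohort")))
        all_hits: dict[tuple[str, str], list] = {}
        for cohort, cmeta in cohorts.items():
            pooled = [r for s in cmeta["sample"] for r in indels_by_sample[s]]
            for unit in config.units:
                hits = indel_catalog.assign_hits(pooled, oriented, unit)
                all_hits[(cohort, unit)] = hits
                indel_catalog.write_hits_tsv(hits, out / f"hits_{cohort}_{unit}.tsv")

        stage = "bias"
        rows = []
        rng_seed = config.seed
        per_sample_bias_rows = []
        for (cohort, unit), hits in all_hits.items():
            counts = asymmetry_stats.StrandCounts.from_hits(hits, oriented, unit)
            if counts.nt_indels + counts.t_indels == 0:
                continue
            est = (
                asymmetry_stats.bootstrap_bias(counts, config.n_boot, seed=rng_seed)
                if counts.per_gene is not None and len(counts.per_gene) >= 2
                else asymmetry_stats.strand_bias(counts)
            )
            est.p_value = asymmetry_stats.binomial_strand_test(
                counts, null_half=config.null_half
            )
            est.p_adjusted = min(1.0, est.p_value * config.family_size)
            row = _bias_row(unit, "all", counts, est, config.family_size)
            row["cohort"] = cohort
            rows.append(row)
            # by tract length
            by_len = stratification.stratified_bias(hits, oriented, unit, "tract_length")
            for stratum, e in by_len.items():
                rows.append({**_bias_row(unit, f"len_{stratum}", _counts_placeholder(e), e,
                                          config.family_size), "cohort": cohort})
            # insertion/deletion split
            if config.split_ins_del:
                for kind in ("insertion", "deletion"):
                    sub = [h for h in hits if h.indel.kind == kind]
                    c = asymmetry_stats.StrandCounts.from_hits(sub, oriented, unit)
                    if c.nt_indels + c.t_indels == 0:
                        continue
                    e = asymmetry_stats.strand_bias(c)
                    e.p_value = asymmetry_stats.binomial_strand_test(c, null_half=config.null_half)
                    e.p_adjusted = min(1.0, e.p_value * config.family_size)
                    rows.append({**_bias_row(unit, kind, c, e, config.family_size),
                                 "cohort": cohort})
            # per-sample biases for group tests
            for sample in cohorts[cohort]["sample"]:
                sub = [h for h in hits if h.indel.sample_id == sample]
                c = asymmetry_stats.StrandCounts.from_hits(sub, oriented, unit)
                e = asymmetry_stats.strand_bias(c)
                per_sample_bias_rows.append(
                    {"cohort": cohort, "unit": unit, "sample": sample, "bias": e.bias}
                )

        stage = "msi"
        msi_tests = []
        if config.msi_comparison and "msi_status" in meta.columns:
            labels = dict(zip(meta["sample"], meta["msi_status"]))
            psb = pd.DataFrame(per_sample_bias_rows)
            for unit in config.units:
                sub = psb[psb["unit"] == unit]
                groups = {
                    g: sub[sub["sample"].map(labels) == g]["bias"].dropna().tolist()
                    for g in ("MSI", "MSS")
                }
                if all(len(v) >= 2 for v in groups.values()):
                    res = asymmetry_stats.group_comparison(
                        groups, "rank_sum", config.family_size
                    )
                    res["unit"] = unit
                    msi_tests.append(res)

        stage = "expression"
        expr_rows = []
        if config.expression_strata and config.expression:
            tiers = stratification.expression_tiers(
                stratification.read_expression_tsv(config.expression)
            )
            for (cohort, unit), hits in all_hits.items():
                by_tier = stratification.stratified_bias(
                    hits, oriented, unit, "expression", tiers
                )
                for tier, e in by_tier.items():
                    expr_rows.append({"cohort": cohort, "unit": unit, "tier": tier,
                                      "bias": e.bias, "excess_pct": e.excess_pct})

        stage = "replication"
        rep_rows = []
        if config.replication_strata and config.repliseq:
            tracks = genome_io.read_signal_track(config.repliseq, config.repliseq_bin_size)
            annotations = {
                c: stratification.replication_annotation(tr, config.rep_smoothing_bp)
                for c, tr in tracks.items()
            }
            for (cohort, unit), hits in all_hits.items():
                parts = stratification.orientation_controlled_bias(
                    hits, oriented, unit, annotations
                )
                for part, e in parts.items():
                    rep_rows.append({"cohort": cohort, "unit": unit,
                                     "partition": part, "bias": e.bias})

        stage = "matrix"
        matrix = None
        if config.dinucleotides:
            cohort_data = {}
            for cohort, cmeta in cohorts.items():
                pooled = [r for s in cmeta["sample"] for r in indels_by_sample[s]]
                cohort_data[cohort] = (pooled, oriented_di)
            matrix = asymmetry_stats.asymmetry_matrix(cohort_data)
            matrix.to_csv(out / "asymmetry_matrix.tsv", sep="\t", na_rep="NA")

        stage = "report"
        results = {
            "bias_table": pd.DataFrame(rows),
            "per_sample_bias": pd.DataFrame(per_sample_bias_rows),
            "msi_tests": pd.DataFrame(msi_tests),
            "expression_table": pd.DataFrame(expr_rows),
            "replication_table": pd.DataFrame(rep_rows),
            "matrix": matrix,
        }
        write_report(results, out, config)
        return results
    except Exception:
        (out / "INCOMPLETE").write_text(f"failed at stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise


def _counts_placeholder(est):
    # stratified_bias returns estimates without attached counts; report NA counts
    class _C:
        nt_indels = t_indels = nt_motifs = t_motifs = "NA"

    return _C()


def write_report(results: dict, out_dir: str | Path, config: RunConfig) -> None:
    """Write the TSV set, the serialized config and a summary text file.

    Fixed column schema; missing values are written as "NA". The summary
    lists every adjusted p-value with its family size.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schemas = {
        "bias_table": ["cohort", "unit", "stratum", "nt_indels", "t_indels", "nt_motifs",
                        "t_motifs", "A", "B", "bias", "excess_pct", "boot_mean", "boot_sd",
                        "p_raw", "p_adj", "family_size"],
        "per_sample_bias": ["cohort", "unit", "sample", "bias"],
        "msi_tests": ["unit", "test", "statistic", "p_raw", "p_adjusted", "family_size"],
        "expression_table": ["cohort", "unit", "tier", "bias", "excess_pct"],
        "replication_table": ["cohort", "unit", "partition", "bias"],
    }
    for name, cols in schemas.items():
        df = results.get(name)
        if df is None or (hasattr(df, "empty") and df.empty):
            df = pd.DataFrame(columns=cols)
        else:
            for c in cols:
                if c not in df.columns:
                    df[c] = np.nan
            df = df[cols + [c for c in df.columns if c not in cols]]
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, na_rep="NA")
    config.to_yaml(out / "run_config.yaml")
    lines = [f"config_digest\t{config.digest()}", f"seed\t{config.seed}"]
    bias = results.get("bias_table")
    if bias is not None and not bias.empty:
        for _, r in bias.iterrows():
            if pd.notna(r.get("p_adj")):
                lines.append(
                    f"p_adj\t{r['cohort']}\t{r['unit']}\t{r['stratum']}\t"
                    f"{r['p_adj']:.4g}\tfamily={r['family_size']}"
                )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
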