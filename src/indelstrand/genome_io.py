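"""Readers/writers for the standard formats and indel normalization.

All internal coordinates are 0-based half-open. VCF conversion happens at
the boundary: for an anchor-style deletion REF="AT" ALT="A" at POS, the
anchor occupies reference offset POS-1 and the deleted bases occupy
[POS, POS+len); for an insertion REF="A" ALT="AT" at POS the insertion
point is p = POS (between offsets POS-1 and POS). Indels are left-aligned
against the reference before any overlap analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("indelstrand")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Genome


class GenomeSequence:
    """In-memory genome: upper-cased sequences keyed by chromosome name."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise FormatError("genome has no sequences")
        for name, seq in sequences.items():
            if len(seq) < 1:
                raise FormatError(f"empty record {name!r}")
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def sequence(self, chrom: str, start: int | None = None, end: int | None = None) -> str:
        seq = self._seqs[chrom]
        if start is None:
            return seq
        if end is None:
            end = start + 1
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(f"[{start},{end}) outside [0,{len(seq)}) on {chrom}")
        return seq[start:end]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs


def read_genome(path: str | Path) -> GenomeSequence:
    """Load a FASTA file, upper-casing sequences; duplicate names are an error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate FASTA header {rec.id!r} in {path}")
        if len(rec.seq) == 0:
            raise FormatError(f"empty FASTA record {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeSequence(seqs)


def write_genome(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reconcile_chrom(name: str, style: str = "keep") -> str:
    """Apply a chromosome-name prefix policy: 'chr', 'plain' or 'keep'."""
    if style == "chr":
        return name if name.startswith("chr") else "chr" + name
    if style == "plain":
        return name[3:] if name.startswith("chr") else name
    return name


# ---------------------------------------------------------------------------
# Genes


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # '+' or '-'
    biotype: str = "protein_coding"

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} >= end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def tss(self) -> int:
        """Transcription start position (0-based base index)."""
        return self.start if self.strand == "+" else self.end - 1

    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def read_gene_table(
    path: str | Path,
    biotype_filter: str | None = None,
    coords: str = "bed",
    known_chroms: set[str] | None = None,
    chrom_style: str = "keep",
) -> list[GeneRecord]:
    """Read a BED6 (``coords='bed'``) or 1-based TSV (``coords='one-based'``)
    gene table into 0-based half-open :class:`GeneRecord` s.

    BED6 columns: chrom start end gene_id score strand [biotype].
    1-based TSV columns: chrom start end gene_id strand [biotype], with
    start/end inclusive as in Ensembl-style exports.
    """
    if coords not in ("bed", "one-based"):
        raise ValueError(f"coords must be 'bed' or 'one-based', got {coords!r}")
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 columns, got {len(parts)}")
            if coords == "bed":
                if len(parts) < 6:
                    raise FormatError(f"{path}:{lineno}: BED6 needs a strand column")
                chrom, start, end, gid, _score, strand = parts[:6]
                biotype = parts[6] if len(parts) > 6 else "protein_coding"
                start, end = int(start), int(end)
            else:
                chrom, start, end, gid, strand = parts[:5]
                biotype = parts[5] if len(parts) > 5 else "protein_coding"
                start, end = int(start) - 1, int(end)  # inclusive 1-based -> half-open 0-based
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            chrom = reconcile_chrom(chrom, chrom_style)
            if biotype_filter is not None and biotype != biotype_filter:
                continue
            if known_chroms is not None and chrom not in known_chroms:
                n_dropped += 1
                continue
            if gid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            seen.add(gid)
            genes.append(GeneRecord(gid, chrom, start, end, strand, biotype))
    if n_dropped:
        logger.info("read_gene_table: dropped %d genes on unknown chromosomes", n_dropped)
    return genes


def write_gene_table(genes: list[GeneRecord], path: str | Path) -> None:
    """Write genes as BED6+biotype (0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t.\t{g.strand}\t{g.biotype}\n")


# ---------------------------------------------------------------------------
# Indels


@dataclass(frozen=True)
class IndelRecord:
    """A normalized insertion or deletion.

    ``pos`` is the 0-based first affected reference base for deletions; for
    insertions it is the insertion point p, meaning between bases p-1 and p.
    """

    sample_id: str
    chrom: str
    pos: int
    kind: str  # 'insertion' | 'deletion'
    seq: str

    def __post_init__(self):
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"bad kind {self.kind!r}")
        if len(self.seq) < 1 or set(self.seq) - set("ACGT"):
            raise ValueError(f"bad indel sequence {self.seq!r}")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def interval(self) -> tuple[int, int]:
        """Affected reference interval; zero-width [p, p) for insertions."""
        if self.kind == "deletion":
            return (self.pos, self.pos + self.length)
        return (self.pos, self.pos)


def left_align(indel: IndelRecord, genome: GenomeSequence) -> IndelRecord:
    """Shift an indel to its lowest-coordinate equivalent representation.

    Within a repeat, an indel can be placed at several equivalent positions;
    the canonical representation slides it left while the base preceding the
    event equals the last base of the event sequence (rotating the sequence).
    Idempotent; never changes kind, length, or the multiset of bases.
    """
    chrom_seq = genome.sequence(indel.chrom)
    pos, seq = indel.pos, indel.seq
    while pos > 0 and chrom_seq[pos - 1] == seq[-1]:
        seq = chrom_seq[pos - 1] + seq[:-1]
        pos -= 1
    if pos == indel.pos:
        return indel
    return replace(indel, pos=pos, seq=seq)


def read_indel_vcf(
    path: str | Path,
    sample_id: str,
    genome: GenomeSequence | None = None,
    normalize: bool = True,
    chrom_style: str = "keep",
) -> list[IndelRecord]:
    """Parse anchor-style biallelic indels from a VCF 4.x file.

    Multi-allelic rows are split per ALT. Substitutions, MNVs and complex
    REF/ALT pairs (neither allele length 1) are skipped with a logged count.
    Records are left-aligned against ``genome`` unless ``normalize=False``.
    """
    records: list[IndelRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 VCF columns")
            chrom = reconcile_chrom(parts[0], chrom_style)
            pos1 = int(parts[1])
            ref = parts[3].upper()
            for alt in parts[4].upper().split(","):
                if alt in (".", "*") or len(ref) == len(alt):
                    n_skipped += 1
                    continue
                # split multi-allelic rows may share a suffix; trim to anchor style
                r, a = ref, alt
                while len(r) > 1 and len(a) > 1 and r[-1] == a[-1]:
                    r, a = r[:-1], a[:-1]
                if not (len(r) == 1 or len(a) == 1):
                    n_skipped += 1  # complex event
                    continue
                if len(r) > 1:  # deletion: REF='A'+deleted, ALT=anchor
                    if r[0] != a:
                        n_skipped += 1
                        continue
                    rec = IndelRecord(sample_id, chrom, pos1, "deletion", r[1:])
                else:  # insertion: ALT='A'+inserted
                    if a[0] != r:
                        n_skipped += 1
                        continue
                    rec = IndelRecord(sample_id, chrom, pos1, "insertion", a[1:])
                if normalize and genome is not None and chrom in genome:
                    rec = left_align(rec, genome)
                records.append(rec)
    if n_skipped:
        logger.info("read_indel_vcf %s: skipped %d non-indel/complex ALTs", path, n_skipped)
    return records


def write_indel_vcf(records: list[IndelRecord], genome: GenomeSequence, path: str | Path) -> None:
    """Write indels as anchor-style VCF 4.2 (the inverse of :func:`read_indel_vcf`)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in genome.chrom_names:
            fh.write(f"##contig=<ID={chrom},length={genome.length(chrom)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        ordered = sorted(records, key=lambda r: (genome.chrom_names.index(r.chrom), r.pos))
        for r in ordered:
            anchor = genome.sequence(r.chrom, r.pos - 1, r.pos)
            if r.kind == "deletion":
                ref, alt = anchor + r.seq, anchor
            else:
                ref, alt = anchor, anchor + r.seq
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# Signal tracks (Repli-seq)


@dataclass
class SignalTrack:
    """Constant-width binned signal on one chromosome."""

    chrom: str
    bin_start: int
    bin_size: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise FormatError(f"non-finite signal values on {self.chrom}")

    @property
    def n_bins(self) -> int:
        return self.values.size

    def bin_of(self, pos: int) -> int:
        return (pos - self.bin_start) // self.bin_size


def read_signal_track(path: str | Path, bin_size: int | None = None) -> dict[str, SignalTrack]:
    """Read a bedGraph into per-chromosome constant-width tracks.

    Input intervals must be sorted and non-overlapping per chromosome. When
    ``bin_size`` is given, the signal is re-binned to that width using the
    length-weighted mean of overlapping input values.
    """
    raw: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            start, end, value = int(start), int(end), float(value)
            ivs = raw.setdefault(chrom, [])
            if ivs and start < ivs[-1][1]:
                raise FormatError(f"{path}:{lineno}: overlapping/unsorted intervals on {chrom}")
            ivs.append((start, end, value))
    tracks: dict[str, SignalTrack] = {}
    for chrom, ivs in raw.items():
        start0 = ivs[0][0]
        width = bin_size if bin_size is not None else ivs[0][1] - ivs[0][0]
        end_last = ivs[-1][1]
        n_bins = max(1, -(-(end_last - start0) // width))
        sums = np.zeros(n_bins)
        weights = np.zeros(n_bins)
        for s, e, v in ivs:
            b0 = (s - start0) // width
            b1 = -(-(e - start0) // width)
            for b in range(b0, b1):
                lo = max(s, start0 + b * width)
                hi = min(e, start0 + (b + 1) * width)
                if hi > lo:
                    sums[b] += v * (hi - lo)
                    weights[b] += hi - lo
        with np.errstate(invalid="ignore"):
            values = np.where(weights > 0, sums / np.maximum(weights, 1), np.nan)
        covered = weights > 0
        values = values[covered.cumsum() > 0]  # drop leading empties only; keep alignment
        tracks[chrom] = SignalTrack(chrom, start0, width, np.nan_to_num(values, nan=float(np.nanmean(values))) if values.size else values)
    return tracks


def write_signal_track(tracks: dict[str, SignalTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, tr in tracks.items():
            for i, v in enumerate(tr.values):
                s = tr.bin_start + i * tr.bin_size
                fh.write(f"{chrom}\t{s}\t{s + tr.bin_size}\t{v:.6g}\n")
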