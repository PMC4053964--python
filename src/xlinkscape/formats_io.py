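"""Shared genomic data model, format readers/writers, and RPM/RPKM tables.

All coordinates are 0-based half-open on an explicit strand. GFF3 (1-based
inclusive on disk) is converted at the I/O boundary; BED passes through.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

REGION_KINDS = ("five_utr", "cds", "three_utr", "intron")

_GFF3_TYPES = {
    "five_prime_UTR": "five_utr",
    "CDS": "cds",
    "three_prime_UTR": "three_utr",
    "intron": "intron",
}
_GFF3_TYPES_INV = {v: k for k, v in _GFF3_TYPES.items()}


class ParseError(ValueError):
    """Raised for malformed records, naming the offending line."""


class ValidationError(ValueError):
    """Raised when a parsed object violates a model invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-explicit genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start < 0:
            raise ValidationError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValidationError(f"empty or inverted interval: {self}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-': {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared nucleotides (0 if different chrom/strand)."""
        if self.chrom != other.chrom or self.strand != other.strand:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class AlignedRead:
    """A strand-specific alignment with its T-to-C conversion positions.

    tc_positions are 0-based genomic positions of reference-T -> read-C
    substitutions on the transcribed strand (reference-A -> read-G for
    minus-strand alignments).
    """

    interval: GenomicInterval
    library_id: str
    n_mismatches: int = 0
    tc_positions: tuple = ()
    is_unique: bool = True
    provenance: str = ""

    def __post_init__(self):
        self.tc_positions = tuple(sorted(self.tc_positions))
        for p in self.tc_positions:
            if not (self.interval.start <= p < self.interval.end):
                raise ValidationError(
                    f"tc position {p} outside read {self.interval}"
                )
        if len(self.tc_positions) > self.n_mismatches:
            raise ValidationError("more tc events than mismatches")


@dataclass
class TranscriptModel:
    """Gene anatomy: 5' UTR / CDS / 3' UTR / intron interval lists."""

    gene_id: str
    chrom: str
    strand: str
    regions: dict = field(default_factory=dict)

    def __post_init__(self):
        for kind, ivs in self.regions.items():
            if kind not in REGION_KINDS:
                raise ValidationError(f"unknown region kind {kind!r}")
            ivs.sort(key=lambda iv: iv.start)
            for iv in ivs:
                if iv.chrom != self.chrom or iv.strand != self.strand:
                    raise ValidationError(
                        f"{self.gene_id}: region on wrong chrom/strand"
                    )
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"{self.gene_id}: overlapping {kind} intervals"
                    )

    @property
    def tx_length(self) -> int:
        """Summed exonic (non-intron) length in nucleotides."""
        return sum(
            len(iv)
            for kind, ivs in self.regions.items()
            if kind != "intron"
            for iv in ivs
        )

    def exonic_intervals(self) -> list:
        return sorted(
            (iv for k, ivs in self.regions.items() if k != "intron" for iv in ivs),
            key=lambda iv: iv.start,
        )

    @property
    def span(self) -> GenomicInterval:
        ivs = [iv for ivs in self.regions.values() for iv in ivs]
        return GenomicInterval(
            self.chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs),
            self.strand,
        )


@dataclass
class LibraryTable:
    """Per-gene read counts with RPM and RPKM for one sequencing library."""

    library_id: str
    total_mapped_reads: int
    table: pd.DataFrame  # index gene_id; columns count, rpm, rpkm

    def rpm(self, gene_id: str) -> float:
        return float(self.table.at[gene_id, "rpm"]) if gene_id in self.table.index else 0.0

    def rpkm(self, gene_id: str) -> float:
        return float(self.table.at[gene_id, "rpkm"]) if gene_id in self.table.index else 0.0


class ScoreTrack:
    """Sparse per-position numeric values keyed by (chrom, position)."""

    def __init__(self, semantics: str = "score", data: Mapping | None = None):
        self.semantics = semantics
        self.data: dict = dict(data) if data else {}

    def set(self, chrom: str, pos: int, value: float):
        if not np.isfinite(value):
            raise ValidationError(f"non-finite score at {chrom}:{pos}")
        self.data[(chrom, pos)] = float(value)

    def get(self, chrom: str, pos: int):
        """Return the value at a position, or None if absent."""
        return self.data.get((chrom, pos))

    def __len__(self):
        return len(self.data)


# ---------------------------------------------------------------------------
# Annotation I/O


def read_annotation(path: str, dialect: str | None = None) -> dict:
    """Read transcript models from GFF3 or BED12.

    Returns a dict gene_id -> TranscriptModel. GFF3 coordinates (1-based
    inclusive) are converted to 0-based half-open.
    """
    if dialect is None:
        dialect = "BED12" if str(path).endswith((".bed", ".bed12")) else "GFF3"
    if dialect == "GFF3":
        return _read_gff3(path)
    if dialect == "BED12":
        return _read_bed12(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_gff3(path: str) -> dict:
    raw: dict = {}
    meta: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype not in _GFF3_TYPES:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            gene_id = None
            for item in attrs.rstrip(";").split(";"):
                key, _, val = item.strip().partition("=")
                if key in ("gene_id", "Parent", "ID"):
                    gene_id = val
                    break
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: no gene_id/Parent attribute")
            iv = GenomicInterval(chrom, start_i - 1, end_i, strand)
            raw.setdefault(gene_id, {}).setdefault(_GFF3_TYPES[ftype], []).append(iv)
            meta[gene_id] = (chrom, strand)
    return {
        g: TranscriptModel(g, meta[g][0], meta[g][1], regions)
        for g, regions in sorted(raw.items())
    }


def _read_bed12(path: str) -> dict:
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, cstart, cend, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_s, thick_e = int(f[6]), int(f[7])
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ParseError(f"{path}:{lineno}: block count mismatch")
            exons = [
                (cstart + off, cstart + off + size)
                for off, size in zip(starts, sizes)
            ]
            if not (cstart <= thick_s <= thick_e <= cend):
                raise ValidationError(
                    f"{path}:{lineno}: CDS extends past transcript bounds"
                )
            regions: dict = {}
            for (s, e) in exons:
                _split_exon(regions, chrom, strand, s, e, thick_s, thick_e)
            for (a_s, a_e), (b_s, b_e) in zip(exons, exons[1:]):
                regions.setdefault("intron", []).append(
                    GenomicInterval(chrom, a_e, b_s, strand)
                )
            out[name] = TranscriptModel(name, chrom, strand, regions)
    return out


def _split_exon(regions, chrom, strand, s, e, thick_s, thick_e):
    """Partition one exon into UTR/CDS pieces around the thick range."""
    left_kind = "five_utr" if strand == "+" else "three_utr"
    right_kind = "three_utr" if strand == "+" else "five_utr"
    if thick_s >= thick_e:  # non-coding: call it all left_kind
        regions.setdefault(left_kind, []).append(GenomicInterval(chrom, s, e, strand))
        return
    if s < min(thick_s, e):
        regions.setdefault(left_kind, []).append(
            GenomicInterval(chrom, s, min(thick_s, e), strand)
        )
    cs, ce = max(s, thick_s), min(e, thick_e)
    if cs < ce:
        regions.setdefault("cds", []).append(GenomicInterval(chrom, cs, ce, strand))
    if max(s, thick_e) < e:
        regions.setdefault(right_kind, []).append(
            GenomicInterval(chrom, max(s, thick_e), e, strand)
        )


def write_annotation_gff3(transcripts: Mapping[str, TranscriptModel], path: str):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(transcripts):
            tx = transcripts[gid]
            for kind in REGION_KINDS:
                for iv in tx.regions.get(kind, []):
                    fh.write(
                        "\t".join(
                            [
                                iv.chrom,
                                "xlinkscape",
                                _GFF3_TYPES_INV[kind],
                                str(iv.start + 1),
                                str(iv.end),
                                ".",
                                iv.strand,
                                ".",
                                f"gene_id={gid}",
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Alignment I/O

_TAB_COLUMNS = [
    "chrom", "start", "end", "strand", "library_id",
    "n_mismatches", "tc_positions", "is_unique", "provenance",
]


def read_alignments(path: str, unique_only: bool = True) -> list:
    """Read AlignedReads from SAM (via pysam, MD-tag based) or the tabular
    dialect (TSV: chrom start end strand library n_mismatches tc_positions
    is_unique [provenance])."""
    if str(path).endswith((".sam", ".bam")):
        reads = _read_sam(path)
    else:
        reads = _read_tabular(path)
    if unique_only:
        reads = [r for r in reads if r.is_unique]
    return reads


def _read_tabular(path: str) -> list:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_TAB_COLUMNS) - 1] != _TAB_COLUMNS[:-1]:
            raise ParseError(f"{path}: unrecognized alignment header {header}")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            tc = () if f[6] in (".", "") else tuple(int(x) for x in f[6].split(","))
            out.append(
                AlignedRead(
                    GenomicInterval(f[0], int(f[1]), int(f[2]), f[3]),
                    library_id=f[4],
                    n_mismatches=int(f[5]),
                    tc_positions=tc,
                    is_unique=f[7] == "1",
                    provenance=f[8] if len(f) > 8 else "",
                )
            )
    return out


def write_alignments(reads: Iterable[AlignedRead], path: str):
    with open(path, "w") as fh:
        fh.write("\t".join(_TAB_COLUMNS) + "\n")
        for r in reads:
            tc = ",".join(str(p) for p in r.tc_positions) or "."
            fh.write(
                "\t".join(
                    [
                        r.interval.chrom,
                        str(r.interval.start),
                        str(r.interval.end),
                        r.interval.strand,
                        r.library_id,
                        str(r.n_mismatches),
                        tc,
                        "1" if r.is_unique else "0",
                        r.provenance,
                    ]
                )
                + "\n"
            )


def _read_sam(path: str) -> list:
    import pysam

    out = []
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            try:
                pairs = aln.get_aligned_pairs(with_seq=True)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: read {aln.query_name} lacks MD tag; supply MD or "
                    "use the tabular dialect"
                ) from exc
            strand = "-" if aln.is_reverse else "+"
            want_ref, want_read = ("t", "C") if strand == "+" else ("a", "G")
            seq = aln.query_sequence or ""
            tc, n_mm = [], 0
            for qpos, rpos, refbase in pairs:
                if qpos is None or rpos is None or refbase is None:
                    continue
                if refbase.islower():
                    n_mm += 1
                    if refbase == want_ref and seq[qpos].upper() == want_read:
                        tc.append(rpos)
            lib = aln.get_tag("RG") if aln.has_tag("RG") else os.path.basename(path)
            nh = aln.get_tag("NH") if aln.has_tag("NH") else 1
            out.append(
                AlignedRead(
                    GenomicInterval(
                        aln.reference_name, aln.reference_start,
                        aln.reference_end, strand,
                    ),
                    library_id=str(lib),
                    n_mismatches=n_mm,
                    tc_positions=tuple(tc),
                    is_unique=nh == 1,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Gene assignment and library tables


class GeneIndex:
    """Interval index assigning reads to genes by majority exonic overlap.

    A read is assigned to the gene whose exonic span covers the strict
    majority (> half) of the read; ties go to the lexicographically smaller
    gene_id; a read covered by no gene is left unassigned.
    """

    def __init__(self, transcripts: Mapping[str, TranscriptModel]):
        self._trees: dict = {}
        self.transcripts = dict(transcripts)
        for gid, tx in transcripts.items():
            for iv in tx.exonic_intervals():
                tree = self._trees.setdefault((tx.chrom, tx.strand), IntervalTree())
                tree[iv.start:iv.end] = gid

    def assign(self, interval: GenomicInterval) -> str | None:
        tree = self._trees.get((interval.chrom, interval.strand))
        if tree is None:
            return None
        overlaps: dict = {}
        for hit in tree.overlap(interval.start, interval.end):
            ov = min(hit.end, interval.end) - max(hit.begin, interval.start)
            overlaps[hit.data] = overlaps.get(hit.data, 0) + ov
        if not overlaps:
            return None
        best = min(overlaps.items(), key=lambda kv: (-kv[1], kv[0]))
        if best[1] * 2 > len(interval):
            return best[0]
        return None

    def region_kind(self, interval: GenomicInterval, gene_id: str) -> str | None:
        """Region kind of the gene with maximal overlap with the interval."""
        tx = self.transcripts[gene_id]
        best_kind, best_ov = None, 0
        for kind in REGION_KINDS:
            ov = sum(interval.overlap(iv) for iv in tx.regions.get(kind, []))
            if ov > best_ov:
                best_kind, best_ov = kind, ov
        return best_kind


def compute_library_table(
    reads: Iterable[AlignedRead],
    transcripts: Mapping[str, TranscriptModel],
    library_id: str | None = None,
    gene_index: GeneIndex | None = None,
) -> LibraryTable:
    """Count reads per gene (majority-exonic-overlap rule) and derive
    RPM = count * 1e6 / total and RPKM = RPM * 1e3 / tx_length."""
    reads = list(reads)
    total = len(reads)
    if total == 0:
        raise ValueError("zero total mapped reads")
    if library_id is None:
        library_id = reads[0].library_id
    index = gene_index or GeneIndex(transcripts)
    counts = dict.fromkeys(transcripts, 0)
    for r in reads:
        gid = index.assign(r.interval)
        if gid is not None:
            counts[gid] += 1
    rows = []
    for gid in sorted(transcripts):
        length = transcripts[gid].tx_length
        if length == 0:
            raise ValueError(f"gene {gid} has length 0")
        rpm = counts[gid] * 1e6 / total
        rows.append((gid, counts[gid], rpm, rpm * 1e3 / length))
    table = pd.DataFrame(
        rows, columns=["gene_id", "count", "rpm", "rpkm"]
    ).set_index("gene_id")
    return LibraryTable(library_id, total, table)


def replicate_correlation(table_a: LibraryTable, table_b: LibraryTable) -> float:
    """Pearson correlation of per-gene RPM over the union gene universe
    (genes missing from one table contribute RPM 0)."""
    genes = sorted(set(table_a.table.index) | set(table_b.table.index))
    a = np.array([table_a.rpm(g) for g in genes])
    b = np.array([table_b.rpm(g) for g in genes])
    if len(genes) < 2 or a.std() == 0 or b.std() == 0:
        raise ValueError("need >= 2 genes with nonzero RPM variance")
    return float(stats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# Score tracks


def read_score_track(path: str, dialect: str | None = None,
                     semantics: str = "score") -> ScoreTrack:
    """Read a per-position score track from bedGraph or fixed-step wig."""
    if dialect is None:
        dialect = "wig" if str(path).endswith(".wig") else "bedGraph"
    track = ScoreTrack(semantics)
    if dialect == "bedGraph":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split()
                if len(f) != 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 columns")
                chrom, s, e, v = f[0], int(f[1]), int(f[2]), float(f[3])
                for pos in range(s, e):
                    old = track.data.get((chrom, pos))
                    if old is not None and old != v:
                        raise ValidationError(
                            f"{path}:{lineno}: conflicting values at {chrom}:{pos}"
                        )
                    track.set(chrom, pos, v)
    elif dialect == "wig":
        chrom, pos, step = None, 0, 1
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(item.split("=") for item in line.split()[1:])
                    chrom = kv["chrom"]
                    pos = int(kv["start"]) - 1  # wig is 1-based
                    step = int(kv.get("step", 1))
                    continue
                if chrom is None:
                    raise ParseError(f"{path}:{lineno}: data before fixedStep")
                track.set(chrom, pos, float(line))
                pos += step
    else:
        raise ValueError(f"unknown track dialect {dialect!r}")
    return track


def write_score_track(track: ScoreTrack, path: str):
    """Write a track as bedGraph, collapsing runs of equal adjacent values."""
    keys = sorted(track.data)
    with open(path, "w") as fh:
        i = 0
        while i < len(keys):
            chrom, start = keys[i]
            val = track.data[keys[i]]
            j = i + 1
            while (
                j < len(keys)
                and keys[j] == (chrom, keys[j - 1][1] + 1)
                and track.data[keys[j]] == val
            ):
                j += 1
            fh.write(f"{chrom}\t{start}\t{keys[j - 1][1] + 1}\t{val:g}\n")
            i = j
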