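"""Barcode demultiplexing and raw-read quality filtering.

Libraries are distinguished by the first six nucleotides of the 3' DNA
linker; the remainder of the linker (starting TCGTATGCC) is constant. A raw
read is therefore insert + barcode + constant linker (possibly truncated).
Demultiplexing prefers perfect barcode matches over single-mismatch ones and,
within a tier, the 3'-most occurrence.

Filtering discards a read that meets any of, attributed to the first failing
criterion in order: shorter than 18 nt, homopolymer-A insert, missing 3'
adapter, 5'-3' adapter-ligation dimer, 5'-5' adapter dimer, or low quality
(more than 4 bases below Q10 or more than 6 below Q13, Phred+33).
"""

from __future__ import annotations

from dataclasses import dataclass, field

# First six nt of each 3' DNA linker oligo (the library barcodes), and the
# constant sequences shared by every library.
DEFAULT_BARCODES = {
    "Index1": "ATCACG",
    "Index2": "CGATGT",
    "Index3": "TTAGGC",
    "Index4": "TGACCA",
    "Index5": "ACAGTG",
    "Index6": "GCCAAT",
    "Index7": "CAGATC",
    "Index8": "ACTTGA",
}
LINKER3_CONSTANT = "TCGTATGCC"
LINKER5 = "GTTCAGAGTTCTACAGTCCGACGATC"  # 5' RNA linker, DNA alphabet

DISCARD_REASONS = (
    "too_short",
    "polyA_only",
    "missing_3adapter",
    "adapter_dimer_53",
    "adapter_dimer_55",
    "low_quality",
)


@dataclass
class BarcodeTable:
    """Library-id -> 6-nt barcode mapping."""

    barcodes: dict = field(default_factory=lambda: dict(DEFAULT_BARCODES))

    def __post_init__(self):
        seen = set()
        for lib, bc in self.barcodes.items():
            if len(bc) != 6 or set(bc) - set("ACGT"):
                raise ValueError(f"{lib}: barcode must be 6 nt of ACGT: {bc!r}")
            if bc in seen:
                raise ValueError(f"duplicate barcode {bc}")
            seen.add(bc)


@dataclass
class FilterReport:
    """Per-reason discard counts; kept + discards == input."""

    input_count: int = 0
    kept: int = 0
    discards: dict = field(
        default_factory=lambda: {r: 0 for r in DISCARD_REASONS}
    )

    def reconciles(self) -> bool:
        return self.kept + sum(self.discards.values()) == self.input_count


@dataclass
class FilterParams:
    min_length: int = 18
    max_below_q10: int = 4  # "more than 4 bases below 10" discards
    max_below_q13: int = 6
    linker3: str = LINKER3_CONSTANT
    linker5: str = LINKER5
    dimer5_suffix_len: int = 12
    dimer_max_insert: int = 18


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _find_approx(read: str, pattern: str, max_mm: int):
    """All (start, n_mismatches) placements of pattern with <= max_mm."""
    k = len(pattern)
    return [
        (i, mm)
        for i in range(len(read) - k + 1)
        if (mm := _mismatches(read[i:i + k], pattern)) <= max_mm
    ]


def demultiplex(read: str, table: BarcodeTable | None = None,
                linker3: str = LINKER3_CONSTANT):
    """Assign a read to a library by its 3'-linker barcode.

    Returns (library_id or None, insert) where the insert is the read with
    barcode and linker removed (the whole read when unassigned). Candidate
    placements immediately 5' of the constant linker are preferred; if the
    linker is absent anywhere, barcodes are scanned freely. Exact matches
    beat one-mismatch matches; within a tier the 3'-most placement wins,
    then the lowest library index.
    """
    table = table or BarcodeTable()
    read = read.upper()
    libs = sorted(table.barcodes)
    linker_starts = {i for i, _ in _find_approx(read, linker3, 1)}

    def candidates(max_mm):
        hits = []
        for rank, lib in enumerate(libs):
            for start, mm in _find_approx(read, table.barcodes[lib], max_mm):
                anchored = (start + 6) in linker_starts
                hits.append((anchored, start, mm, rank, lib))
        return hits

    for tier in (0, 1):
        hits = [h for h in candidates(tier) if h[2] == tier]
        if not hits:
            continue
        if any(h[0] for h in hits):
            hits = [h for h in hits if h[0]]
        # 3'-most start, then lowest library index
        anchored, start, _, _, lib = max(hits, key=lambda h: (h[1], -h[3]))
        return lib, read[:start]
    return None, read


def _insert_bounds(seq: str, params: FilterParams):
    """(insert_end, adapter_found): insert is everything 5' of the 3'
    adapter (barcode + constant linker); the barcode occupies the 6 nt just
    before the linker when present."""
    hits = _find_approx(seq, params.linker3, 1)
    if not hits:
        return len(seq), False
    start = min(h[0] for h in hits)
    return max(0, start - 6), True


def filter_reads(records, params: FilterParams | None = None):
    """Apply the quality filters to (name, sequence, quality) records.

    Returns (kept_records, FilterReport); kept records are adapter-trimmed
    (name, insert, insert_quality) tuples. Qualities are Phred+33.
    """
    params = params or FilterParams()
    report = FilterReport()
    kept = []
    for name, seq, qual in records:
        if len(seq) != len(qual):
            raise ValueError(f"{name}: quality length != sequence length")
        report.input_count += 1
        seq_u = seq.upper()
        insert_end, has_adapter = _insert_bounds(seq_u, params)
        insert = seq_u[:insert_end]
        reason = _discard_reason(seq_u, qual[:insert_end], insert, has_adapter,
                                 params)
        if reason is None:
            report.kept += 1
            kept.append((name, insert, qual[:insert_end]))
        else:
            report.discards[reason] += 1
    return kept, report


def _discard_reason(seq, insert_qual, insert, has_adapter, params):
    if len(seq) < params.min_length:
        return "too_short"
    if insert and set(insert) == {"A"}:
        return "polyA_only"
    if not has_adapter:
        return "missing_3adapter"
    if _is_dimer_53(seq, insert, params):
        return "adapter_dimer_53"
    if _is_dimer_55(seq, params):
        return "adapter_dimer_55"
    below10 = sum(ord(q) - 33 < 10 for q in insert_qual)
    below13 = sum(ord(q) - 33 < 13 for q in insert_qual)
    if below10 > params.max_below_q10 or below13 > params.max_below_q13:
        return "low_quality"
    return None


def _is_dimer_53(seq, insert, params):
    """5'-3' ligation product: a 5'-linker suffix sits just before the 3'
    adapter with a sub-threshold insert between them (declared heuristic)."""
    suffix = params.linker5[-params.dimer5_suffix_len:]
    for start, _ in _find_approx(seq, suffix, 1):
        gap = len(insert) - (start + len(suffix))
        if 0 <= gap < params.dimer_max_insert:
            return True
    return False


def _is_dimer_55(seq, params):
    """5'-5' product: two occurrences of the 5' linker (declared heuristic)."""
    suffix = params.linker5[-params.dimer5_suffix_len:]
    return len(_find_approx(seq, suffix, 1)) >= 2


# ---------------------------------------------------------------------------
# FASTQ plumbing


def read_fastq(path: str):
    """Yield (name, sequence, quality) from a Phred+33 FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header[1:], seq, qual


def write_fastq(records, path: str):
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def assemble_raw_read(insert: str, barcode: str,
                      linker3: str = LINKER3_CONSTANT) -> str:
    """Construct a raw read the way the library structure dictates:
    insert + barcode + constant 3' linker (for building test inputs)."""
    return insert + barcode + linker3
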