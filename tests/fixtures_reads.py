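"""A constructed 50-read FASTQ-style fixture with known demultiplexing and
filtering fates, built programmatically (no data files)."""

from xlinkscape.read_processing import (
    DEFAULT_BARCODES,
    LINKER3_CONSTANT,
    LINKER5,
    assemble_raw_read,
)

GOOD_INSERT = "CGTCGTGCAGTCGATCGTAGCTAGC"  # 25 nt, no homopolymer A
Q9, Q12, HI = chr(33 + 9), chr(33 + 12), "I"


def _rec(name, seq, qual=None):
    return (name, seq, qual if qual is not None else HI * len(seq))


def build_filter_fixture():
    """Returns (records, expected) where expected holds the per-reason
    discard counts, kept count, and per-library assignment of kept reads."""
    records = []
    # 10 clean Index1 reads + 5 clean Index2 reads: kept
    for i in range(10):
        records.append(_rec(
            f"keep1_{i}", assemble_raw_read(GOOD_INSERT,
                                            DEFAULT_BARCODES["Index1"])))
    for i in range(5):
        records.append(_rec(
            f"keep2_{i}", assemble_raw_read(GOOD_INSERT,
                                            DEFAULT_BARCODES["Index2"])))
    # 5 boundary-quality reads: exactly 4 bases below Q10 and 6 (cumulative)
    # below Q13 -> kept under the "more than 4" / "more than 6" rule
    for i in range(5):
        seq = assemble_raw_read(GOOD_INSERT, DEFAULT_BARCODES["Index1"])
        qual = Q9 * 4 + Q12 * 2 + HI * (len(seq) - 6)
        records.append(_rec(f"keepq_{i}", seq, qual))
    # 5 too-short raw reads (17 nt)
    for i in range(5):
        records.append(_rec(f"short_{i}", "C" * 17))
    # 5 homopolymer-A inserts
    for i in range(5):
        records.append(_rec(
            f"polya_{i}", assemble_raw_read("A" * 25,
                                            DEFAULT_BARCODES["Index1"])))
    # 5 reads without any 3' adapter
    for i in range(5):
        records.append(_rec(f"noadapt_{i}", "CG" * 15))
    # 5 5'-3' adapter-ligation dimers (empty insert between linkers)
    for i in range(5):
        records.append(_rec(
            f"d53_{i}",
            LINKER5 + DEFAULT_BARCODES["Index1"] + LINKER3_CONSTANT))
    # 5 5'-5' dimers followed by a legitimate insert and 3' adapter
    for i in range(5):
        records.append(_rec(
            f"d55_{i}",
            LINKER5 + LINKER5 + GOOD_INSERT
            + DEFAULT_BARCODES["Index1"] + LINKER3_CONSTANT))
    # 5 low-quality reads: five bases below Q10
    for i in range(5):
        seq = assemble_raw_read(GOOD_INSERT, DEFAULT_BARCODES["Index1"])
        records.append(_rec(f"lowq_{i}", seq, Q9 * 5 + HI * (len(seq) - 5)))

    expected = {
        "input": 50,
        "kept": 20,
        "discards": {
            "too_short": 5,
            "polyA_only": 5,
            "missing_3adapter": 5,
            "adapter_dimer_53": 5,
            "adapter_dimer_55": 5,
            "low_quality": 5,
        },
        "kept_assignments": {"Index1": 15, "Index2": 5},
    }
    return records, expected
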