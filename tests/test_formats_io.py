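import numpy as np
import pytest

from xlinkscape import (
    AlignedRead,
    GenomicInterval,
    LibraryTable,
    ScoreTrack,
    TranscriptModel,
    compute_library_table,
    read_alignments,
    read_annotation,
    read_score_track,
    replicate_correlation,
    write_alignments,
    write_annotation_gff3,
    write_score_track,
)
from xlinkscape.formats_io import GeneIndex, ValidationError

import pandas as pd


def make_table(library_id, total, counts, lengths):
    rows = []
    for g, c in counts.items():
        rpm = c * 1e6 / total
        rows.append((g, c, rpm, rpm * 1e3 / lengths[g]))
    df = pd.DataFrame(rows, columns=["gene_id", "count", "rpm", "rpkm"])
    return LibraryTable(library_id, total, df.set_index("gene_id"))


class TestGenomicInterval:
    @pytest.mark.parametrize("start,end,strand", [
        (-1, 10, "+"), (10, 10, "+"), (10, 5, "-"), (0, 10, "plus"),
    ])
    def test_invalid_rejected(self, start, end, strand):
        with pytest.raises(ValidationError):
            GenomicInterval("chrI", start, end, strand)

    def test_overlap_requires_same_chrom_and_strand(self):
        a = GenomicInterval("chrI", 0, 10, "+")
        assert a.overlap(GenomicInterval("chrI", 5, 15, "+")) == 5
        assert a.overlap(GenomicInterval("chrI", 5, 15, "-")) == 0
        assert a.overlap(GenomicInterval("chrII", 5, 15, "+")) == 0


class TestAnnotationIO:
    def test_gff3_round_trip_and_coordinate_conversion(
            self, two_gene_annotation, tmp_path):
        path = tmp_path / "anno.gff3"
        write_annotation_gff3(two_gene_annotation, path)
        # on-disk GFF3 is 1-based inclusive: [100,150) -> start=101,end=150
        text = path.read_text()
        assert "\t101\t150\t" in text
        back = read_annotation(path, dialect="GFF3")
        assert set(back) == {"geneA", "geneB"}
        for gid, tx in two_gene_annotation.items():
            assert back[gid].regions == tx.regions
            assert back[gid].tx_length == tx.tx_length

    def test_tx_length_excludes_introns(self, two_gene_annotation):
        assert two_gene_annotation["geneA"].tx_length == 50 + 150 + 140 + 100

    def test_bed12_two_exons_yield_one_intron(self, tmp_path):
        bed = tmp_path / "a.bed"
        bed.write_text(
            "chrI\t100\t400\tgeneX\t0\t+\t150\t350\t0\t2\t100,100\t0,200\n"
        )
        tx = read_annotation(bed, dialect="BED12")["geneX"]
        assert tx.regions["intron"] == [GenomicInterval("chrI", 200, 300, "+")]
        assert tx.regions["cds"] == [
            GenomicInterval("chrI", 150, 200, "+"),
            GenomicInterval("chrI", 300, 350, "+"),
        ]
        assert tx.tx_length == 200

    def test_bed12_cds_outside_bounds_rejected(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text(
            "chrI\t100\t400\tg\t0\t+\t50\t350\t0\t2\t100,100\t0,200\n"
        )
        with pytest.raises(ValidationError):
            read_annotation(bed, dialect="BED12")

    def test_overlapping_region_intervals_rejected(self):
        with pytest.raises(ValidationError):
            TranscriptModel(
                "g", "chrI", "+",
                {"cds": [GenomicInterval("chrI", 0, 100, "+"),
                         GenomicInterval("chrI", 50, 150, "+")]},
            )


class TestAlignmentIO:
    def test_tabular_round_trip(self, tmp_path):
        reads = [
            AlignedRead(GenomicInterval("chrI", 10, 40, "+"), "lib1",
                        n_mismatches=2, tc_positions=(12, 30),
                        provenance="background"),
            AlignedRead(GenomicInterval("chrI", 100, 130, "-"), "lib1",
                        n_mismatches=0, is_unique=False),
        ]
        path = tmp_path / "reads.tsv"
        write_alignments(reads, path)
        assert read_alignments(path, unique_only=False) == reads
        assert read_alignments(path, unique_only=True) == reads[:1]

    def test_tc_position_outside_read_rejected(self):
        with pytest.raises(ValidationError):
            AlignedRead(GenomicInterval("chrI", 10, 40, "+"), "lib",
                        n_mismatches=1, tc_positions=(50,))

    def test_sam_mismatch_extraction_is_strand_aware(self, tmp_path):
        # plus strand: ref T -> read C is a conversion; minus: ref A -> G
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chrI\tLN:1000\n"
            # ref TTTAGGGGGG, read C at ref offset 3? MD says mismatch T at 3
            "r1\t0\t chrI\t101\t255\t10M\t*\t0\t0\tAAACGGGGGG\tIIIIIIIIII\tMD:Z:3T6\tNM:i:1\n".replace(" chrI", "chrI")
            + "r2\t16\tchrI\t201\t255\t10M\t*\t0\t0\tAAAGGGGGGG\tIIIIIIIIII\tMD:Z:3A6\tNM:i:1\n"
            + "r3\t0\tchrI\t301\t255\t10M\t*\t0\t0\tAAAAGGGGGG\tIIIIIIIIII\tMD:Z:3G6\tNM:i:1\n"
        )
        reads = read_alignments(sam)
        by_start = {r.interval.start: r for r in reads}
        assert by_start[100].tc_positions == (103,)   # T->C on +
        assert by_start[200].tc_positions == (203,)   # A->G on -
        assert by_start[200].interval.strand == "-"
        assert by_start[300].tc_positions == ()       # G->A is not T-to-C
        assert by_start[300].n_mismatches == 1


class TestLibraryTable:
    def make_reads(self, spans, lib="lib1"):
        return [AlignedRead(GenomicInterval("chrT", s, e, st), lib)
                for s, e, st in spans]

    def test_rpm_rpkm_formulas(self, two_gene_annotation):
        # geneA exonic length 440; put 44 reads on geneA of 1000 total
        reads = self.make_reads([(150, 180, "+")] * 44)
        reads += self.make_reads([(5000, 5030, "+")] * 956)  # intergenic
        table = compute_library_table(reads, two_gene_annotation)
        assert table.total_mapped_reads == 1000
        assert table.rpm("geneA") == pytest.approx(44 * 1e6 / 1000)
        assert table.rpkm("geneA") == pytest.approx(44 * 1e6 / 1000 * 1e3 / 440)
        assert table.rpm("geneB") == 0.0

    def test_majority_overlap_assignment(self, two_gene_annotation):
        # 30-nt read with 20 nt in geneA's CDS, 10 in the intron: majority
        reads = self.make_reads([(280, 310, "+")])
        table = compute_library_table(reads, two_gene_annotation)
        assert table.table.loc["geneA", "count"] == 1
        # read halfway outside any gene: 15 of 30 nt is not a majority
        table2 = compute_library_table(
            self.make_reads([(85, 115, "+")]), two_gene_annotation)
        assert table2.table["count"].sum() == 0

    def test_strandedness_respected(self, two_gene_annotation):
        reads = self.make_reads([(820, 850, "+")])  # geneB is minus-strand
        table = compute_library_table(reads, two_gene_annotation)
        assert table.table["count"].sum() == 0

    def test_rpm_sum_invariant(self, two_gene_annotation, rng):
        spans = []
        for _ in range(300):
            s = int(rng.integers(100, 1020))
            spans.append((s, s + 30, "+" if rng.random() < 0.5 else "-"))
        reads = self.make_reads(spans)
        table = compute_library_table(reads, two_gene_annotation)
        assigned = table.table["count"].sum()
        assert assigned <= table.total_mapped_reads
        assert table.table["rpm"].sum() == pytest.approx(
            1e6 * assigned / table.total_mapped_reads)

    def test_zero_reads_rejected(self, two_gene_annotation):
        with pytest.raises(ValueError):
            compute_library_table([], two_gene_annotation)


class TestReplicateCorrelation:
    LENGTHS = {"g1": 1000, "g2": 1000, "g3": 500}

    def test_identical_and_scaled_tables_give_one(self):
        a = make_table("a", 1000, {"g1": 10, "g2": 50, "g3": 200}, self.LENGTHS)
        b = make_table("b", 2000, {"g1": 20, "g2": 100, "g3": 400}, self.LENGTHS)
        assert replicate_correlation(a, a) == pytest.approx(1.0)
        assert replicate_correlation(a, b) == pytest.approx(1.0)

    def test_union_universe_with_missing_genes(self):
        a = make_table("a", 1000, {"g1": 10, "g2": 50}, self.LENGTHS)
        b = make_table("b", 1000, {"g2": 50, "g3": 10}, self.LENGTHS)
        r = replicate_correlation(a, b)
        assert -1.0 <= r < 1.0

    def test_constant_table_rejected(self):
        a = make_table("a", 1000, {"g1": 5, "g2": 5, "g3": 5}, self.LENGTHS)
        with pytest.raises(ValueError):
            replicate_correlation(a, a)

    def test_binomial_replicates_correlate_highly(self, rng):
        # two libraries sampled from one expression vector at high depth
        expr = rng.lognormal(3, 1, size=60)
        p = expr / expr.sum()
        lengths = {f"g{i}": 1000 for i in range(60)}
        c1 = rng.multinomial(200_000, p)
        c2 = rng.multinomial(200_000, p)
        a = make_table("a", 200_000, {f"g{i}": c1[i] for i in range(60)}, lengths)
        b = make_table("b", 200_000, {f"g{i}": c2[i] for i in range(60)}, lengths)
        assert replicate_correlation(a, b) > 0.95


class TestScoreTrack:
    def test_bedgraph_expansion_and_absent_lookup(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chrI\t0\t3\t0.5\nchrI\t10\t11\t2.0\n")
        track = read_score_track(p)
        assert [track.get("chrI", i) for i in range(3)] == [0.5] * 3
        assert track.get("chrI", 5) is None
        assert track.get("chrII", 0) is None

    def test_conflicting_overlap_rejected(self, tmp_path):
        p = tmp_path / "bad.bedgraph"
        p.write_text("chrI\t0\t5\t1.0\nchrI\t3\t6\t2.0\n")
        with pytest.raises(ValidationError):
            read_score_track(p)

    def test_empty_file_gives_empty_track(self, tmp_path):
        p = tmp_path / "empty.bedgraph"
        p.write_text("")
        assert len(read_score_track(p)) == 0

    def test_fixed_step_wig(self, tmp_path):
        p = tmp_path / "t.wig"
        p.write_text("fixedStep chrom=chrI start=11 step=2\n1.5\n2.5\n")
        track = read_score_track(p, dialect="wig")
        assert track.get("chrI", 10) == 1.5  # wig start is 1-based
        assert track.get("chrI", 12) == 2.5

    def test_write_read_round_trip(self, tmp_path, rng):
        track = ScoreTrack("conservation")
        for pos in rng.choice(200, size=50, replace=False):
            track.set("chrI", int(pos), round(float(rng.random()), 6))
        path = tmp_path / "rt.bedgraph"
        write_score_track(track, path)
        assert read_score_track(path).data == track.data


class TestGeneIndex:
    def test_region_kind_by_max_overlap(self, two_gene_annotation):
        idx = GeneIndex(two_gene_annotation)
        iv = GenomicInterval("chrT", 140, 170, "+")  # 10 UTR + 20 CDS
        assert idx.assign(iv) == "geneA"
        assert idx.region_kind(iv, "geneA") == "cds"
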