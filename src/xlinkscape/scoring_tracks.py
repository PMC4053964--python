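"""Per-nucleotide crosslinking scores and aggregate coverage analyses.

The crosslinking score (CLS) at a genomic T is the RPM of conversion-bearing
reads with a T-to-C event exactly at that position, divided by the gene's
mRNA-seq RPKM and multiplied by 1000; positions on genes without mRNA-seq
coverage are removed. CLS-ranked positions are binned with 50% overlap
between adjacent bins and compared with external score tracks (conservation,
unpaired probability) against randomly ranked controls. Metagene profiles
aggregate coverage around anatomical anchors (5' UTR start, intron branch
point, poly(A) junction), and interval-overlap utilities implement the
conserved-block and site-capture counting rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import chi2_contingency

from .formats_io import (
    AlignedRead,
    GeneIndex,
    GenomicInterval,
    ScoreTrack,
    TranscriptModel,
)
from .site_calling import contributing_reads


def _iv(x) -> GenomicInterval:
    return x.interval if hasattr(x, "interval") else x


class CLSTrack:
    """Per-(chrom, position, strand) crosslinking scores at reference Ts."""

    def __init__(self):
        self.data: dict = {}     # (chrom, pos, strand) -> cls value
        self.regions: dict = {}  # (chrom, pos, strand) -> region kind

    def set(self, chrom, pos, strand, value, region=None):
        if value < 0:
            raise ValueError("CLS values must be >= 0")
        self.data[(chrom, pos, strand)] = float(value)
        if region is not None:
            self.regions[(chrom, pos, strand)] = region

    def get(self, chrom, pos, strand):
        return self.data.get((chrom, pos, strand))

    def __len__(self):
        return len(self.data)

    def items(self):
        return self.data.items()


def compute_cls(
    gparclip_reads: Iterable[AlignedRead],
    gene_index: GeneIndex,
    rpkm: Mapping[str, float],
    total_mapped_reads: int | None = None,
) -> CLSTrack:
    """Crosslinking score for every T with conversion coverage.

    CLS = (RPM of 1-2-conversion reads with a T-to-C at the position) /
    gene RPKM x 1000. Positions whose gene has no mRNA-seq coverage (RPKM 0)
    or no assignable gene are removed.
    """
    reads = list(gparclip_reads)
    total = total_mapped_reads if total_mapped_reads is not None else len(reads)
    if total <= 0:
        raise ValueError("library has no mapped reads")
    counts: dict = {}
    for r in contributing_reads(reads):
        for p in r.tc_positions:
            key = (r.interval.chrom, p, r.interval.strand)
            counts[key] = counts.get(key, 0) + 1
    track = CLSTrack()
    for (chrom, pos, strand), n in counts.items():
        point = GenomicInterval(chrom, pos, pos + 1, strand)
        gene = gene_index.assign(point)
        if gene is None:
            continue
        gene_rpkm = rpkm.get(gene, 0.0)
        if gene_rpkm <= 0:
            continue
        rpm = n * 1e6 / total
        track.set(chrom, pos, strand, rpm / gene_rpkm * 1000,
                  region=gene_index.region_kind(point, gene))
    return track


# ---------------------------------------------------------------------------
# Ranked 50%-overlap binning


@dataclass
class BinSeries:
    """Ranked, 50%-overlapping bins with per-bin external-score means."""

    bin_size: int
    stride: int
    start_ranks: np.ndarray
    means: np.ndarray                 # per-bin mean external score
    rank_means: np.ndarray | None = None   # per-bin mean of the ranking score
    rep_means: np.ndarray | None = None    # reps x bins matrix for controls
    n_dropped: int = 0


def _bin_layout(n: int, n_bins: int, bin_size: int | None,
                overlap: float = 0.5):
    if bin_size is None:
        bin_size = max(1, int(2 * n / (n_bins + 1)))
    stride = max(1, int(round(bin_size * (1 - overlap))))
    if bin_size > n:
        raise ValueError(f"fewer positions ({n}) than one bin ({bin_size})")
    starts = np.arange(0, n - bin_size + 1, stride)
    return bin_size, stride, starts


def ranked_overlap_bins(
    cls_values: np.ndarray,
    external_values: np.ndarray,
    n_bins: int = 100,
    bin_size: int | None = None,
) -> BinSeries:
    """Sort positions by CLS ascending and average the external score in
    bins that overlap their neighbors by 50%.

    ``external_values[i]`` must be the external score of the position whose
    CLS is ``cls_values[i]``; positions lacking an external value should be
    dropped by the caller (see :func:`paired_scores`).
    """
    cls_values = np.asarray(cls_values, float)
    external_values = np.asarray(external_values, float)
    if len(cls_values) != len(external_values):
        raise ValueError("cls and external arrays differ in length")
    order = np.argsort(cls_values, kind="stable")
    ext = external_values[order]
    ranked_cls = cls_values[order]
    size, stride, starts = _bin_layout(len(ext), n_bins, bin_size)
    means = np.array([ext[s:s + size].mean() for s in starts])
    rank_means = np.array([ranked_cls[s:s + size].mean() for s in starts])
    return BinSeries(size, stride, starts, means, rank_means=rank_means)


def random_control_bins(
    external_values: np.ndarray,
    n_bins: int = 100,
    bin_size: int | None = None,
    reps: int = 10,
    seed: int | np.random.Generator = 0,
) -> BinSeries:
    """Randomly rank positions (no CLS) and bin identically, ``reps`` times.

    Returns the mean across replicates per bin, with per-replicate values
    retained in ``rep_means``.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ext = np.asarray(external_values, float)
    size, stride, starts = _bin_layout(len(ext), n_bins, bin_size)
    rep_means = np.empty((reps, len(starts)))
    for r in range(reps):
        shuffled = rng.permutation(ext)
        rep_means[r] = [shuffled[s:s + size].mean() for s in starts]
    return BinSeries(size, stride, starts, rep_means.mean(axis=0),
                     rep_means=rep_means)


def paired_scores(track: CLSTrack, external: ScoreTrack,
                  region: str | None = None):
    """CLS / external value pairs for positions carrying both, plus the
    count of CLS positions dropped for lacking an external value."""
    cls_vals, ext_vals, dropped = [], [], 0
    for (chrom, pos, strand), v in sorted(track.items()):
        if region is not None and track.regions.get(
                (chrom, pos, strand)) != region:
            continue
        e = external.get(chrom, pos)
        if e is None:
            dropped += 1
            continue
        cls_vals.append(v)
        ext_vals.append(e)
    return np.array(cls_vals), np.array(ext_vals), dropped


# ---------------------------------------------------------------------------
# Metagene profiles


@dataclass
class MetageneProfile:
    """Aggregate strand-oriented coverage around an anatomical anchor."""

    anchor: str
    offsets: np.ndarray
    values: np.ndarray          # per-offset mean over contributing features
    n_contributing: np.ndarray  # features contributing at each offset
    n_features: int = 0

    def argmax_offset(self) -> int:
        return int(self.offsets[int(np.argmax(self.values))])


def coverage_tracks(reads: Iterable[AlignedRead], genome: Mapping[str, str],
                    what: str = "depth", rpm: bool = False) -> dict:
    """Per-(chrom, strand) coverage arrays from reads.

    ``what``: "depth" (read coverage) or "tc" (conversion-event coverage).
    """
    reads = list(reads)
    tracks = {
        (c, s): np.zeros(len(seq) + 1)
        for c, seq in genome.items() for s in "+-"
    }
    for r in reads:
        key = (r.interval.chrom, r.interval.strand)
        if what == "depth":
            tracks[key][r.interval.start] += 1
            tracks[key][r.interval.end] -= 1
        elif what == "tc":
            for p in r.tc_positions:
                tracks[key][p] += 1
        else:
            raise ValueError(f"unknown coverage kind {what!r}")
    if what == "depth":
        tracks = {k: np.cumsum(v)[:-1] for k, v in tracks.items()}
    else:
        tracks = {k: v[:-1] for k, v in tracks.items()}
    if rpm and reads:
        scale = 1e6 / len(reads)
        tracks = {k: v * scale for k, v in tracks.items()}
    return tracks


def _anchor_position(tx: TranscriptModel, anchor: str,
                     bp_anchors: Mapping[str, int] | None):
    """(genomic anchor position, anchoring region interval) or None."""
    if anchor == "polya":
        utr3 = tx.regions.get("three_utr")
        if not utr3:
            return None
        block = utr3[-1] if tx.strand == "+" else utr3[0]
        pos = block.end - 1 if tx.strand == "+" else block.start
        return pos, block
    if anchor == "utr5_start":
        utr5 = tx.regions.get("five_utr")
        if not utr5:
            return None
        block = utr5[0] if tx.strand == "+" else utr5[-1]
        pos = block.start if tx.strand == "+" else block.end - 1
        return pos, block
    if anchor == "branch_point":
        if not bp_anchors or tx.gene_id not in bp_anchors:
            return None
        introns = tx.regions.get("intron")
        if not introns:
            return None
        pos = bp_anchors[tx.gene_id]
        for block in introns:
            if block.start <= pos < block.end:
                return pos, block
        return None
    raise ValueError(f"unknown anchor {anchor!r}")


def metagene_profile(
    tracks: Mapping[tuple, np.ndarray],
    transcripts: Mapping[str, TranscriptModel],
    anchor: str,
    window: tuple = (-300, 100),
    bp_anchors: Mapping[str, int] | None = None,
) -> MetageneProfile:
    """Mean per-offset coverage across features, strand-oriented.

    Offsets are relative to the anchor (negative = 5' of it); a feature
    contributes only at offsets that fall inside its anchoring region
    (truncation counted via ``n_contributing``).
    """
    lo, hi = window
    offsets = np.arange(lo, hi)
    total = np.zeros(len(offsets))
    n_contrib = np.zeros(len(offsets), dtype=int)
    n_features = 0
    for gid in sorted(transcripts):
        tx = transcripts[gid]
        anchored = _anchor_position(tx, anchor, bp_anchors)
        if anchored is None:
            continue
        pos, block = anchored
        track = tracks.get((tx.chrom, tx.strand))
        if track is None:
            continue
        n_features += 1
        sign = 1 if tx.strand == "+" else -1
        gpos = pos + sign * offsets
        ok = (gpos >= block.start) & (gpos < block.end)
        total[ok] += track[gpos[ok]]
        n_contrib[ok] += 1
    values = np.divide(total, n_contrib, out=np.zeros_like(total),
                       where=n_contrib > 0)
    return MetageneProfile(anchor, offsets, values, n_contrib, n_features)


# ---------------------------------------------------------------------------
# Interval-overlap analyses


def _merged_union(intervals: Iterable[GenomicInterval]) -> dict:
    """(chrom, strand) -> sorted, merged [start, end) pairs."""
    by_key: dict = {}
    for iv in intervals:
        by_key.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
    merged = {}
    for key, spans in by_key.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[key] = out
    return merged


def _union_overlap_len(block: GenomicInterval, merged: dict) -> int:
    spans = merged.get((block.chrom, block.strand), [])
    return sum(
        max(0, min(e, block.end) - max(s, block.start)) for s, e in spans
    )


def capture_overlap(query_sites, reference_sites,
                    min_frac: float = 0.5) -> list:
    """Per query: captured iff >= min_frac of its nucleotides overlap the
    union of reference sites."""
    merged = _merged_union(_iv(s) for s in reference_sites)
    out = []
    for q in query_sites:
        iv = _iv(q)
        out.append(_union_overlap_len(iv, merged) >= min_frac * len(iv))
    return out


def block_fully_covered(block: GenomicInterval, sites,
                        mode: str = "single") -> bool:
    """Whether a block is 100% covered by one site ("single") or by the
    union of sites ("union")."""
    if mode == "single":
        return any(
            _iv(s).chrom == block.chrom and _iv(s).strand == block.strand
            and _iv(s).start <= block.start and _iv(s).end >= block.end
            for s in sites
        )
    if mode == "union":
        return _union_overlap_len(block, _merged_union(
            _iv(s) for s in sites)) == len(block)
    raise ValueError(f"unknown overlap mode {mode!r}")


@dataclass
class BlockOverlapResult:
    observed_overlapped: int
    observed_total: int
    control_overlapped: int
    control_total: int
    chi2: float
    p_value: float
    table: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))


def random_control_blocks(blocks, region_intervals, rng,
                          max_attempts: int = 1000) -> list:
    """Size-matched random blocks placed within the given region class."""
    regions = list(region_intervals)
    out = []
    for b in blocks:
        biv = _iv(b)
        length = len(biv)
        candidates = [r for r in regions if len(r) >= length]
        if not candidates:
            raise ValueError(
                f"no region large enough to place a {length}-nt control block"
            )
        for attempt in range(max_attempts):
            r = candidates[rng.integers(len(candidates))]
            start = int(rng.integers(r.start, r.end - length + 1))
            out.append(GenomicInterval(r.chrom, start, start + length,
                                       r.strand))
            break
        else:
            raise ValueError("could not place control block in 1000 attempts")
    return out


def block_overlap(blocks, sites, region_intervals=None,
                  mode: str = "single",
                  seed: int | np.random.Generator = 0) -> BlockOverlapResult:
    """Count blocks fully covered by crosslinking sites versus size-matched
    random control blocks; 2x2 chi-square without continuity correction."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    blocks = list(blocks)
    obs = sum(block_fully_covered(_iv(b), sites, mode) for b in blocks)
    if region_intervals is None:
        raise ValueError("region_intervals required to place control blocks")
    controls = random_control_blocks(blocks, region_intervals, rng)
    ctl = sum(block_fully_covered(c, sites, mode) for c in controls)
    table = np.array([
        [obs, len(blocks) - obs],
        [ctl, len(controls) - ctl],
    ])
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p = chi2_contingency(table, correction=False)[:2]
    return BlockOverlapResult(obs, len(blocks), ctl, len(controls),
                              float(chi2), float(p), table)


def site_density(covered_fraction: float, region_length: float,
                 mean_site_length: float) -> float:
    """Average number of sites per ``region_length`` nt given the fraction
    of nucleotides inside sites and the mean site length."""
    if mean_site_length <= 0:
        raise ValueError("mean site length must be > 0")
    return covered_fraction * region_length / mean_site_length
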