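"""Crosslinking-site calling from conversion-bearing reads.

Reads carrying one or two T-to-C conversion events define read clusters
(maximal strand-specific stretches of contributing coverage). Each
cluster's coverage profile is smoothed with a Gaussian kernel (default
bandwidth 21 nt in the classical quartile convention, sigma = 0.25 x 21 /
0.6745 ~ 7.78 nt) and split into individual crosslinking sites at the
inflection points of the smoothed curve: one site per local maximum,
bounded by the nearest second-difference sign change on each flank (cluster
ends when no interior inflection exists).

Sites are then quantified against the full library: mean per-nucleotide
RPM, occupancy (mean RPM / gene RPKM x 1000), and T-to-C conversion rate
(reads with a conversion in the site / reads covering at least one site T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from intervaltree import IntervalTree

from .formats_io import AlignedRead, GenomicInterval, GeneIndex

# Gaussian sigma such that the kernel quartiles sit at +/- bandwidth/4
QUARTILE_TO_SIGMA = 0.25 / 0.6744897501960817


@dataclass
class SegmentationParams:
    """Kernel-smoothing and segmentation settings."""

    bandwidth: float = 21.0
    sigma: float | None = None  # overrides the bandwidth convention
    min_site_length: int = 1

    def __post_init__(self):
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")

    @property
    def kernel_sigma(self) -> float:
        return self.sigma if self.sigma is not None else (
            self.bandwidth * QUARTILE_TO_SIGMA
        )


@dataclass
class CoverageProfile:
    """Per-position depth of contributing reads over one cluster."""

    interval: GenomicInterval
    depth: np.ndarray      # contributing (1-2 conversion) read depth
    tc_depth: np.ndarray   # per-position conversion-event depth

    def __post_init__(self):
        n = len(self.interval)
        if len(self.depth) != n or len(self.tc_depth) != n:
            raise ValueError("profile arrays must match interval length")


@dataclass
class CrosslinkSite:
    """One crosslinking site with its quantification."""

    interval: GenomicInterval
    gene_id: str | None = None
    region_kind: str | None = None
    mean_rpm: float = 0.0
    tc_reads: int = 0
    total_reads_over_T: int = 0
    conversion_rate: float | None = None
    occupancy: float | None = None
    fdr: float | None = None
    excluded: bool = False
    library_id: str = ""

    @property
    def length(self) -> int:
        return len(self.interval)


def contributing_reads(reads: Iterable[AlignedRead]) -> list:
    """Reads with exactly one or two T-to-C conversion events."""
    return [r for r in reads if 1 <= len(r.tc_positions) <= 2]


def build_clusters(reads: Iterable[AlignedRead]) -> list:
    """Maximal strand-specific intervals covered by conversion-bearing reads.

    Returns a list of (GenomicInterval, CoverageProfile), ordered by
    (chrom, strand, start). Reads with 0 or >2 conversions do not contribute.
    """
    by_key: dict = {}
    for r in contributing_reads(reads):
        by_key.setdefault((r.interval.chrom, r.interval.strand), []).append(r)
    clusters = []
    for (chrom, strand), rs in sorted(by_key.items()):
        hi = max(r.interval.end for r in rs)
        depth_diff = np.zeros(hi + 1)
        tc = np.zeros(hi)
        for r in rs:
            depth_diff[r.interval.start] += 1
            depth_diff[r.interval.end] -= 1
            for p in r.tc_positions:
                tc[p] += 1
        depth = np.cumsum(depth_diff)[:hi]
        covered = depth > 0
        edges = np.diff(covered.astype(np.int8), prepend=0, append=0)
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1)
        for a, b in zip(starts, ends):
            iv = GenomicInterval(chrom, int(a), int(b), strand)
            clusters.append(
                (iv, CoverageProfile(iv, depth[a:b].copy(), tc[a:b].copy()))
            )
    return clusters


def gaussian_kernel(sigma: float) -> np.ndarray:
    radius = max(1, int(math.ceil(4 * sigma)))
    x = np.arange(-radius, radius + 1)
    return np.exp(-0.5 * (x / sigma) ** 2)


def smooth_profile(profile: CoverageProfile,
                   params: SegmentationParams) -> np.ndarray:
    """Kernel-weighted moving average of the raw depth.

    Weights are renormalized at the cluster edges, so a constant profile
    maps to the same constant everywhere.
    """
    w = gaussian_kernel(params.kernel_sigma)
    # np.convolve 'same' keys on the longer input; clusters can be shorter
    # than the kernel, so slice the 'full' result around its center instead
    lo = (len(w) - 1) // 2
    hi = lo + len(profile.depth)
    num = np.convolve(profile.depth, w, mode="full")[lo:hi]
    den = np.convolve(np.ones_like(profile.depth), w, mode="full")[lo:hi]
    return num / den


def _plateau_maxima(s: np.ndarray) -> list:
    """Local maxima with plateaus collapsed to their (left-biased) midpoint."""
    L = len(s)
    maxima = []
    i = 0
    while i < L:
        j = i
        while j + 1 < L and s[j + 1] == s[i]:
            j += 1
        left_ok = i == 0 or s[i - 1] < s[i]
        right_ok = j == L - 1 or s[j + 1] < s[j]
        if left_ok and right_ok:
            maxima.append((i + j) // 2)
        i = j + 1
    return maxima


def _inflection_points(s: np.ndarray) -> list:
    """Positions where the discrete second difference changes sign.

    A zero second difference adopts the sign of the next nonzero value to
    its right; the inflection is placed at the position where the new sign
    begins.
    """
    L = len(s)
    if L < 4:
        return []
    d2 = s[2:] - 2 * s[1:-1] + s[:-2]  # defined at positions 1 .. L-2
    sgn = np.sign(d2)
    for i in range(len(sgn) - 2, -1, -1):
        if sgn[i] == 0:
            sgn[i] = sgn[i + 1]
    return [
        p for p in range(2, L - 1)
        if sgn[p - 1] != 0 and sgn[p - 2] != 0 and sgn[p - 1] != sgn[p - 2]
    ]


def segment_cluster(profile: CoverageProfile, smoothed: np.ndarray,
                    params: SegmentationParams) -> list:
    """Split one cluster into crosslinking-site intervals.

    One site per local maximum of the smoothed curve, bounded by the
    inflection point nearest the maximum on each side (cluster ends when a
    flank has none; boundary positions are included in the site). Sites
    lacking any conversion-positive position are dropped; sites shorter
    than ``min_site_length`` merge into the neighboring site with the
    higher peak.
    """
    L = len(smoothed)
    maxima = _plateau_maxima(smoothed)
    inflections = _inflection_points(smoothed)
    raw = []
    for m in maxima:
        lefts = [p for p in inflections if p <= m]
        rights = [p for p in inflections if p >= m]
        lo = max(lefts) if lefts else 0
        hi = min(rights) if rights else L - 1
        raw.append([lo, hi + 1, m])  # half-open, with peak position
    raw.sort()
    # adjacent sites may share a single inflection position: keep disjoint
    for prev, cur in zip(raw, raw[1:]):
        if cur[0] < prev[1]:
            cur[0] = prev[1]
    segments = [(lo, hi, m) for lo, hi, m in raw if hi > lo]
    segments = [
        (lo, hi, m) for lo, hi, m in segments
        if profile.tc_depth[lo:hi].max(initial=0) > 0
    ]
    segments = _merge_short(segments, smoothed, params.min_site_length)
    base = profile.interval.start
    return [
        GenomicInterval(profile.interval.chrom, base + lo, base + hi,
                        profile.interval.strand)
        for lo, hi, _ in segments
    ]


def _merge_short(segments, smoothed, min_len):
    segments = [list(s) for s in segments]
    changed = True
    while changed and len(segments) > 1:
        changed = False
        for i, seg in enumerate(segments):
            if seg[1] - seg[0] >= min_len:
                continue
            neighbors = [j for j in (i - 1, i + 1) if 0 <= j < len(segments)]
            j = max(neighbors, key=lambda j: smoothed[segments[j][2]])
            a, b = sorted((i, j))
            segments[a] = [
                segments[a][0],
                segments[b][1],
                max(segments[a][2], segments[b][2], key=lambda m: smoothed[m]),
            ]
            del segments[b]
            changed = True
            break
    return [tuple(s) for s in segments]


def call_site_intervals(reads: Iterable[AlignedRead],
                        params: SegmentationParams | None = None) -> list:
    """Cluster + smooth + segment: crosslinking-site intervals from reads."""
    params = params or SegmentationParams()
    out = []
    for _, profile in build_clusters(reads):
        smoothed = smooth_profile(profile, params)
        out.extend(segment_cluster(profile, smoothed, params))
    return out


# ---------------------------------------------------------------------------
# Quantification


class SiteQuantifier:
    """Quantifies site intervals against one library's full read set."""

    def __init__(self, reads: Iterable[AlignedRead], genome: Mapping[str, str],
                 gene_index: GeneIndex | None = None,
                 rpkm: Mapping[str, float] | None = None,
                 total_mapped_reads: int | None = None,
                 library_id: str = ""):
        reads = list(reads)
        self.total = total_mapped_reads if total_mapped_reads is not None else len(reads)
        if self.total <= 0:
            raise ValueError("library has no mapped reads")
        self.gene_index = gene_index
        self.rpkm = dict(rpkm) if rpkm else {}
        self.library_id = library_id or (reads[0].library_id if reads else "")
        self._trees: dict = {}
        self._depth: dict = {}
        self._is_t = {
            (c, s): np.frombuffer(seq.encode(), dtype="S1")
            == (b"T" if s == "+" else b"A")
            for c, seq in genome.items()
            for s in "+-"
        }
        self._reads = reads
        for i, r in enumerate(reads):
            key = (r.interval.chrom, r.interval.strand)
            # store indices: duplicate reads are distinct observations and
            # must not collapse in the tree's interval set
            self._trees.setdefault(key, IntervalTree())[
                r.interval.start:r.interval.end
            ] = i
            d = self._depth.setdefault(
                key, np.zeros(len(genome[r.interval.chrom]) + 1)
            )
            d[r.interval.start] += 1
            d[r.interval.end] -= 1
        self._depth = {k: np.cumsum(v)[:-1] for k, v in self._depth.items()}

    def quantify(self, interval: GenomicInterval) -> CrosslinkSite:
        key = (interval.chrom, interval.strand)
        depth = self._depth.get(key)
        if depth is None:
            mean_rpm = 0.0
        else:
            mean_rpm = float(
                depth[interval.start:interval.end].mean() * 1e6 / self.total
            )
        tmask = self._is_t[key]
        t_pos = interval.start + np.flatnonzero(
            tmask[interval.start:interval.end]
        )
        over_t = 0
        tc_reads = 0
        tree = self._trees.get(key)
        if tree is not None and len(t_pos):
            tset = set(int(p) for p in t_pos)
            for hit in tree.overlap(interval.start, interval.end):
                r = self._reads[hit.data]
                if any(r.interval.start <= p < r.interval.end for p in tset):
                    over_t += 1
                    if any(interval.start <= p < interval.end
                           for p in r.tc_positions):
                        tc_reads += 1
        rate = tc_reads / over_t if over_t else None
        gene_id = (
            self.gene_index.assign(interval) if self.gene_index else None
        )
        region = (
            self.gene_index.region_kind(interval, gene_id)
            if gene_id else None
        )
        rpkm = self.rpkm.get(gene_id, 0.0) if gene_id else 0.0
        occupancy = mean_rpm / rpkm * 1000 if rpkm > 0 else None
        return CrosslinkSite(
            interval=interval, gene_id=gene_id, region_kind=region,
            mean_rpm=mean_rpm, tc_reads=tc_reads, total_reads_over_T=over_t,
            conversion_rate=rate, occupancy=occupancy,
            excluded=(rpkm <= 0), library_id=self.library_id,
        )


def quantify_site(interval: GenomicInterval, reads: Iterable[AlignedRead],
                  genome: Mapping[str, str], gene_id: str | None,
                  gene_rpkm: float, total_mapped_reads: int) -> CrosslinkSite:
    """Convenience single-site quantification (see SiteQuantifier)."""
    q = SiteQuantifier(reads, genome, total_mapped_reads=total_mapped_reads)
    site = q.quantify(interval)
    site.gene_id = gene_id
    site.occupancy = site.mean_rpm / gene_rpkm * 1000 if gene_rpkm > 0 else None
    site.excluded = gene_rpkm <= 0
    return site


def site_length_summary(sites: Iterable[CrosslinkSite],
                        bins: int = 20) -> dict:
    """Mean / median / histogram of site lengths."""
    lengths = np.array([s.length for s in sites])
    if len(lengths) == 0:
        raise ValueError("no sites")
    counts, edges = np.histogram(lengths, bins=bins)
    return {
        "n": int(len(lengths)),
        "mean": float(lengths.mean()),
        "median": float(np.median(lengths)),
        "hist_counts": counts,
        "hist_edges": edges,
    }


def start_distance_histogram(sites: Iterable[CrosslinkSite],
                             max_distance: int = 100) -> np.ndarray:
    """Histogram of start-to-start distances between consecutive sites on
    the same chromosome/strand (periodicity diagnostic)."""
    starts: dict = {}
    for s in sites:
        starts.setdefault(
            (s.interval.chrom, s.interval.strand), []
        ).append(s.interval.start)
    counts = np.zeros(max_distance + 1, dtype=int)
    for key, ps in starts.items():
        ps.sort()
        for a, b in zip(ps, ps[1:]):
            d = b - a
            if d <= max_distance:
                counts[d] += 1
    return counts
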