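"""Empirical FDR assignment from an mRNA-seq sequencing-error null.

mRNA-seq reads carrying one or two T-to-C mismatches reflect the platform's
T-to-C sequencing error. Running the identical cluster / segmentation /
quantification pipeline on them yields "error clusters" whose conversion
rates form a coverage-dependent null. Sites and error clusters are binned
by total read coverage (log2-spaced bins, sparse bins merged upward until
each holds a minimum number of null clusters); a site's FDR is the
proportion of null clusters in its bin with a strictly higher conversion
rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .formats_io import AlignedRead, GeneIndex
from .site_calling import (
    CrosslinkSite,
    SegmentationParams,
    SiteQuantifier,
    call_site_intervals,
)


@dataclass
class FdrBinning:
    """Coverage-binning scheme for the empirical FDR.

    Bin edges are log2-spaced over total read coverage by default; bins with
    fewer than ``min_null_per_bin`` null clusters are merged upward (the
    topmost sparse bin merges downward).
    """

    edges: np.ndarray | None = None
    min_null_per_bin: int = 50

    def resolve_edges(self, coverages: np.ndarray) -> np.ndarray:
        if self.edges is not None:
            edges = np.asarray(self.edges, dtype=float)
            if not np.all(np.diff(edges) > 0):
                raise ValueError("bin edges must be strictly increasing")
            return edges
        hi = max(2.0, float(coverages.max(initial=1)))
        n = int(np.ceil(np.log2(hi))) + 1
        return 2.0 ** np.arange(0, n + 1)


def build_error_clusters(
    mrnaseq_reads: Iterable[AlignedRead],
    genome: Mapping[str, str],
    params: SegmentationParams | None = None,
    gene_index: GeneIndex | None = None,
    rpkm: Mapping[str, float] | None = None,
) -> list:
    """Run the full site-calling pipeline on mRNA-seq reads.

    Clusters and boundaries come from the 1-2 mismatch subset; coverage and
    conversion-rate denominators use the complete library, exactly as for
    gPAR-CLIP sites. Returns CrosslinkSites labelled ``error-null``.
    """
    reads = list(mrnaseq_reads)
    intervals = call_site_intervals(reads, params)
    if not intervals:
        return []
    quant = SiteQuantifier(reads, genome, gene_index=gene_index, rpkm=rpkm)
    out = []
    for iv in intervals:
        site = quant.quantify(iv)
        site.library_id = "error-null"
        out.append(site)
    return out


def _bin_index(coverage: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin assignment, clipping values outside the edge range into the
    first/last bin so every site falls in exactly one bin."""
    idx = np.digitize(coverage, edges) - 1
    return np.clip(idx, 0, len(edges) - 2)


def _merge_sparse(null_idx: np.ndarray, n_bins: int, min_per_bin: int):
    """Map raw bin index -> merged bin id such that each merged bin holds at
    least ``min_per_bin`` null clusters (when possible)."""
    counts = np.bincount(null_idx, minlength=n_bins)
    mapping = np.zeros(n_bins, dtype=int)
    merged_id = 0
    acc = 0
    for b in range(n_bins):
        mapping[b] = merged_id
        acc += counts[b]
        if acc >= min_per_bin:
            merged_id += 1
            acc = 0
    if merged_id > 0:
        # leftover sparse (possibly empty) top bins merge downward
        mapping[mapping == merged_id] = merged_id - 1
    return mapping


def assign_fdr(
    sites: list,
    nulls: list,
    binning: FdrBinning | None = None,
) -> list:
    """Assign each site the proportion of same-coverage-bin null clusters
    with a strictly greater conversion rate. Modifies sites in place and
    returns them."""
    binning = binning or FdrBinning()
    rated_sites = [s for s in sites if s.conversion_rate is not None]
    rated_nulls = [n for n in nulls if n.conversion_rate is not None]
    if not rated_sites:
        return sites
    cov_sites = np.array([s.total_reads_over_T for s in rated_sites], float)
    if not rated_nulls:
        warnings.warn("empty error-cluster null: all FDRs set to 0")
        for s in rated_sites:
            s.fdr = 0.0
        return sites
    cov_nulls = np.array([n.total_reads_over_T for n in rated_nulls], float)
    edges = binning.resolve_edges(np.concatenate([cov_sites, cov_nulls]))
    n_bins = len(edges) - 1
    null_idx = _bin_index(cov_nulls, edges)
    site_idx = _bin_index(cov_sites, edges)
    mapping = _merge_sparse(null_idx, n_bins, binning.min_null_per_bin)
    null_rates: dict = {}
    for b, n in zip(mapping[null_idx], rated_nulls):
        null_rates.setdefault(b, []).append(n.conversion_rate)
    null_rates = {b: np.sort(np.array(v)) for b, v in null_rates.items()}
    for b, s in zip(mapping[site_idx], rated_sites):
        rates = null_rates.get(b)
        if rates is None or len(rates) == 0:
            warnings.warn(
                f"no null clusters in coverage bin {b}; FDR set to 0"
            )
            s.fdr = 0.0
            continue
        greater = len(rates) - np.searchsorted(rates, s.conversion_rate,
                                               side="right")
        s.fdr = float(greater / len(rates))
    return sites


def threshold_sites(sites: Iterable[CrosslinkSite],
                    fdr_max: float = 0.01) -> list:
    """Sites passing the strict FDR cut (fdr < fdr_max)."""
    return [s for s in sites if s.fdr is not None and s.fdr < fdr_max]
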