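"""Differential RBP occupancy between growth conditions.

Site occupancancies (mean site RPM / gene RPKM x 1000) are averaged across
replicate libraries per condition; sites with raw coverage of at most
``min_rpm`` (default 5 RPM) in both conditions are excluded, and the rest
are classified as increased / decreased when the occupancy fold change
exceeds ``fold_threshold`` (default 4, the study's 3-sigma rule at a
replicate error of sigma = 1.3-fold).

Replicate reproducibility is modelled two ways: the binomial-partitioning
floor (a site's N total reads split Binomial(N, 1/2) between replicates,
predicting std 1/(2 sqrt N) of the replicate-1 fraction) and the empirical
sigma of log2 replicate coverage ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OccupancyMatrix:
    """Sites x libraries occupancy and raw mean-RPM matrices.

    Columns are library ids; ``conditions`` maps each library id to
    (condition, replicate).
    """

    occupancy: pd.DataFrame
    mean_rpm: pd.DataFrame
    conditions: dict = field(default_factory=dict)

    def libraries_for(self, condition: str) -> list:
        return [lib for lib, (c, _) in self.conditions.items()
                if c == condition]

    def condition_mean(self, condition: str, raw: bool = False) -> pd.Series:
        libs = self.libraries_for(condition)
        if not libs:
            raise ValueError(f"condition {condition!r} absent from matrix")
        frame = self.mean_rpm if raw else self.occupancy
        return frame[libs].mean(axis=1)


@dataclass
class ReplicateStats:
    """Observed vs binomially predicted replicate variability."""

    bin_edges: np.ndarray
    observed_std: np.ndarray   # std of replicate-1 fraction per bin (NaN = absent)
    predicted_std: np.ndarray  # binomial prediction at the bin's mean N
    n_sites: np.ndarray
    sigma_log2: float | None = None
    fold_sigma: float | None = None


@dataclass
class DifferentialParams:
    min_rpm: float = 5.0
    fold_threshold: float = 4.0
    pseudocount: float = 0.1

    def __post_init__(self):
        if self.min_rpm <= 0:
            raise ValueError("min_rpm must be > 0")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")


@dataclass
class DifferentialCall:
    site_id: str
    gene_id: str | None
    occupancy_a: float
    occupancy_b: float
    log2_fold: float
    call: str  # increased / decreased / unchanged / excluded_low_coverage
    infinite_fold: bool = False


def min_rpm_for_reads(n_reads: float, library_depth: int) -> float:
    """RPM cutoff equivalent to a raw read-count floor at a given depth.

    The coverage filter marks where counting statistics stop dominating
    replicate error; that is a property of read counts, so scaled-down
    libraries should translate the count floor back into RPM units
    (50 reads at 10M-read depth is the canonical 5 RPM)."""
    if library_depth <= 0:
        raise ValueError("library_depth must be > 0")
    return n_reads / library_depth * 1e6


def binomial_partition_std(total_reads: int) -> float:
    """Predicted std of the replicate-1 fraction under Binomial(N, 1/2)
    partitioning: std(X/N) = 1 / (2 sqrt N)."""
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    return 0.5 / np.sqrt(total_reads)


def replicate_fraction_std(
    matrix: OccupancyMatrix,
    lib_a: str,
    lib_b: str,
    bin_edges: np.ndarray | None = None,
    counts: pd.DataFrame | None = None,
) -> ReplicateStats:
    """Per-coverage-bin std of the replicate-1 read fraction r1/(r1+r2).

    ``counts`` (sites x libraries read counts) defaults to the matrix's raw
    mean-RPM columns, which are proportional to counts within a library
    pair of similar depth. Bins with fewer than 2 sites report NaN.
    """
    frame = counts if counts is not None else matrix.mean_rpm
    r1 = frame[lib_a].to_numpy(float)
    r2 = frame[lib_b].to_numpy(float)
    total = r1 + r2
    ok = total > 0
    r1, total = r1[ok], total[ok]
    if bin_edges is None:
        hi = max(2.0, float(total.max(initial=2)))
        bin_edges = 2.0 ** np.arange(0, int(np.ceil(np.log2(hi))) + 2)
    idx = np.clip(np.digitize(total, bin_edges) - 1, 0, len(bin_edges) - 2)
    n_bins = len(bin_edges) - 1
    obs = np.full(n_bins, np.nan)
    pred = np.full(n_bins, np.nan)
    n_sites = np.zeros(n_bins, dtype=int)
    frac = r1 / total
    for b in range(n_bins):
        sel = idx == b
        n_sites[b] = sel.sum()
        if n_sites[b] >= 2:
            obs[b] = frac[sel].std(ddof=1)
            pred[b] = binomial_partition_std(max(1, round(total[sel].mean())))
    return ReplicateStats(np.asarray(bin_edges, float), obs, pred, n_sites)


def replicate_sigma(matrix: OccupancyMatrix, lib_a: str, lib_b: str,
                    min_rpm: float = 5.0) -> tuple:
    """(sigma_log2, fold_sigma): std of log2 replicate coverage ratios over
    sites with raw coverage >= min_rpm in both replicates."""
    r1 = matrix.mean_rpm[lib_a].to_numpy(float)
    r2 = matrix.mean_rpm[lib_b].to_numpy(float)
    keep = (r1 >= min_rpm) & (r2 >= min_rpm)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 sites pass the coverage filter")
    sigma = float(np.std(np.log2(r1[keep] / r2[keep])))
    return sigma, float(2.0 ** sigma)


def call_differential(matrix: OccupancyMatrix, cond_a: str, cond_b: str,
                      params: DifferentialParams | None = None) -> list:
    """Classify each site's occupancy change from cond_a to cond_b.

    Sites with raw coverage <= min_rpm in both conditions are excluded;
    fold = (occ_b + pseudocount) / (occ_a + pseudocount); increased when
    fold > fold_threshold, decreased when fold < 1/fold_threshold.
    """
    params = params or DifferentialParams()
    occ_a = matrix.condition_mean(cond_a)
    occ_b = matrix.condition_mean(cond_b)
    raw_a = matrix.condition_mean(cond_a, raw=True)
    raw_b = matrix.condition_mean(cond_b, raw=True)
    gene_ids = (matrix.occupancy["gene_id"]
                if "gene_id" in matrix.occupancy.columns else None)
    calls = []
    for site_id in matrix.occupancy.index:
        a, b = float(occ_a[site_id]), float(occ_b[site_id])
        if raw_a[site_id] <= params.min_rpm and raw_b[site_id] <= params.min_rpm:
            call = "excluded_low_coverage"
            fold = np.nan
        else:
            fold = (b + params.pseudocount) / (a + params.pseudocount)
            if fold > params.fold_threshold:
                call = "increased"
            elif fold < 1.0 / params.fold_threshold:
                call = "decreased"
            else:
                call = "unchanged"
        calls.append(DifferentialCall(
            site_id=str(site_id),
            gene_id=(str(gene_ids[site_id]) if gene_ids is not None else None),
            occupancy_a=a,
            occupancy_b=b,
            log2_fold=float(np.log2(fold)) if np.isfinite(fold) else np.nan,
            call=call,
            infinite_fold=(a == 0.0) != (b == 0.0),
        ))
    return calls


def overlap_sets(calls_1: Iterable[DifferentialCall],
                 calls_2: Iterable[DifferentialCall],
                 level: str = "site") -> dict:
    """Venn counts per class between two condition comparisons.

    Returns {class: (unique_to_1, unique_to_2, shared)} for increased and
    decreased. At gene level a gene belongs to a class if any of its sites
    does.
    """
    calls_1, calls_2 = list(calls_1), list(calls_2)
    if {c.site_id for c in calls_1} != {c.site_id for c in calls_2}:
        raise ValueError("call lists cover different site universes")

    def members(calls, klass):
        if level == "site":
            return {c.site_id for c in calls if c.call == klass}
        if level == "gene":
            return {c.gene_id for c in calls
                    if c.call == klass and c.gene_id is not None}
        raise ValueError(f"unknown level {level!r}")

    out = {}
    for klass in ("increased", "decreased"):
        s1, s2 = members(calls_1, klass), members(calls_2, klass)
        out[klass] = (len(s1 - s2), len(s2 - s1), len(s1 & s2))
    return out


def welch_t(values_a: np.ndarray, values_b: np.ndarray) -> tuple:
    """Welch's unequal-variance t statistic and p-value (report column)."""
    res = stats.ttest_ind(values_a, values_b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
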