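"""Canonical synthetic study configurations.

Each function returns the SimConfig (and, where relevant, analysis
parameters) for one of the package's standard desk-scale studies. The
analysis drivers, the test suite, and the reproduction script all use these
so that every entry point exercises identical study conditions.

Scale notes (see docs/methods.md): fragment length in the site-recovery and
boundary studies is matched to the protected footprint (23 nt) because
inflection-point segmentation recovers the read-coverage footprint; the
coverage filter for differential calls translates the canonical 5 RPM floor
(50 reads at 10M-read depth) into the same 50-read floor at the study's
depth.
"""

from __future__ import annotations

from .differential import DifferentialParams, min_rpm_for_reads
from .synthetic_data import SimConfig


def calibration_config(seed: int) -> SimConfig:
    """Pure-null study: conversions arise only from sequencing error in both
    library types, and gPAR-CLIP read placement follows the mRNA-seq process
    (no planted pileups), making the two libraries exchangeable."""
    return SimConfig(
        seed=seed, n_genes=30, conversion_prob=0.0, background_frac=1.0,
        conditions=("WT",), replicates=1,
        gparclip_depth=20_000, mrnaseq_depth=20_000,
    )


def recovery_config(seed: int, n_genes: int = 200) -> SimConfig:
    """Site-recovery study: planted ~23-nt sites at ~50 reads per site per
    library, crosslink conversion probability 0.3, footprint-matched
    fragments, uniform expression so every site sees the nominal depth."""
    site_reads_per_library = n_genes * 2 * 50 // 2
    return SimConfig(
        seed=seed, n_genes=n_genes, conditions=("WT",), replicates=2,
        read_length=23, expression_sigma=0.0, site_occupancy_sigma=0.0,
        conversion_prob=0.3,
        gparclip_depth=int(site_reads_per_library / 0.7),
        mrnaseq_depth=60_000,
    )


def differential_config(seed: int) -> SimConfig:
    """Differential-occupancy study: three conditions, duplicate libraries,
    8-fold occupancy changes planted on 10% of sites."""
    return SimConfig(
        seed=seed, n_genes=100, frac_changed=0.1, change_fold=8.0,
        gparclip_depth=20_000, mrnaseq_depth=30_000,
    )


def differential_params(config: SimConfig) -> DifferentialParams:
    """4-fold classification with the 50-read coverage floor in RPM units."""
    return DifferentialParams(
        min_rpm=min_rpm_for_reads(50, config.gparclip_depth),
        fold_threshold=4.0,
    )


def metagene_config(seed: int) -> SimConfig:
    """Poly(A)-junction study: one single-nucleotide crosslink signal planted
    exactly 20 nt upstream of every annotated poly(A) junction."""
    return SimConfig(
        seed=seed, n_genes=60, site_placement="polya_upstream",
        polya_upstream_offset=20, conditions=("WT",), replicates=1,
        gparclip_depth=12_000, mrnaseq_depth=20_000,
    )


def reproducibility_config(seed: int) -> SimConfig:
    """Replicate-reproducibility study: duplicate libraries at moderate
    depth for gene-level RPM correlation and replicate-sigma estimates."""
    return SimConfig(
        seed=seed, n_genes=60, conditions=("WT",), replicates=2,
        gparclip_depth=20_000, mrnaseq_depth=40_000,
    )
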