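"""End-to-end workflow: pooled site calling, FDR, and occupancy matrices.

Clusters and site boundaries are derived from the pooled set of all
gPAR-CLIP libraries, FDR from the pooled mRNA-seq error null, and each site
is then quantified separately in every gPAR-CLIP library to build the
sites x libraries occupancy matrix used for differential analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .differential import OccupancyMatrix
from .fdr_empirical import FdrBinning, assign_fdr, build_error_clusters
from .formats_io import GeneIndex, compute_library_table
from .site_calling import SegmentationParams, SiteQuantifier, call_site_intervals


@dataclass
class StudyResult:
    """Everything the pooled pipeline produces."""

    site_intervals: list
    sites: list                  # pooled-quantified CrosslinkSites with FDR
    error_clusters: list
    matrix: OccupancyMatrix
    mrna_tables: dict            # (condition, replicate) -> LibraryTable
    gene_index: GeneIndex = None
    rpkm: dict = field(default_factory=dict)


def condition_rpkm(mrna_tables: Mapping, condition: str | None = None) -> dict:
    """Per-gene RPKM averaged over mRNA-seq replicates (of one condition,
    or of all libraries when condition is None)."""
    tables = [
        t for (cond, _), t in mrna_tables.items()
        if condition is None or cond == condition
    ]
    if not tables:
        raise ValueError(f"no mRNA-seq tables for condition {condition!r}")
    genes = tables[0].table.index
    stacked = np.column_stack([t.table["rpkm"].reindex(genes).to_numpy()
                               for t in tables])
    return dict(zip(genes, stacked.mean(axis=1)))


def run_pipeline(
    libraries: Mapping[tuple, list],
    transcripts: Mapping,
    genome: Mapping[str, str],
    seg_params: SegmentationParams | None = None,
    binning: FdrBinning | None = None,
) -> StudyResult:
    """Pooled site calling with per-library quantification.

    ``libraries`` maps (kind, condition, replicate) -> AlignedRead list with
    kind in {"gparclip", "mrnaseq"}.
    """
    seg_params = seg_params or SegmentationParams()
    gene_index = GeneIndex(transcripts)

    gpar_libs = {k: v for k, v in libraries.items() if k[0] == "gparclip"}
    mrna_libs = {k: v for k, v in libraries.items() if k[0] == "mrnaseq"}
    if not gpar_libs or not mrna_libs:
        raise ValueError("need at least one gPAR-CLIP and one mRNA-seq library")

    mrna_tables = {
        (cond, rep): compute_library_table(
            reads, transcripts, library_id=f"mrnaseq_{cond}_rep{rep}",
            gene_index=gene_index,
        )
        for (_, cond, rep), reads in mrna_libs.items()
    }
    pooled_rpkm = condition_rpkm(mrna_tables)

    pooled_gpar = [r for reads in gpar_libs.values() for r in reads]
    pooled_mrna = [r for reads in mrna_libs.values() for r in reads]

    site_intervals = call_site_intervals(pooled_gpar, seg_params)
    quant = SiteQuantifier(pooled_gpar, genome, gene_index=gene_index,
                           rpkm=pooled_rpkm, library_id="pooled")
    sites = [quant.quantify(iv) for iv in site_intervals]
    error_clusters = build_error_clusters(
        pooled_mrna, genome, params=seg_params, gene_index=gene_index,
        rpkm=pooled_rpkm,
    )
    assign_fdr(sites, error_clusters, binning)

    site_ids = [f"site{i:05d}" for i in range(len(sites))]
    occ_cols, rpm_cols, cond_map = {}, {}, {}
    for (_, cond, rep), reads in sorted(gpar_libs.items()):
        lib = f"gparclip_{cond}_rep{rep}"
        lib_rpkm = condition_rpkm(mrna_tables, cond)
        lq = SiteQuantifier(reads, genome, gene_index=gene_index,
                            rpkm=lib_rpkm, library_id=lib)
        quantified = [lq.quantify(iv) for iv in site_intervals]
        occ_cols[lib] = [
            s.occupancy if s.occupancy is not None else np.nan
            for s in quantified
        ]
        rpm_cols[lib] = [s.mean_rpm for s in quantified]
        cond_map[lib] = (cond, rep)

    occupancy = pd.DataFrame(occ_cols, index=site_ids)
    mean_rpm = pd.DataFrame(rpm_cols, index=site_ids)
    occupancy["gene_id"] = [s.gene_id for s in sites]
    matrix = OccupancyMatrix(occupancy, mean_rpm, cond_map)
    return StudyResult(site_intervals, sites, error_clusters, matrix,
                       mrna_tables, gene_index, pooled_rpkm)


# ---------------------------------------------------------------------------
# Site tables on disk


def sites_to_dataframe(sites) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(sites):
        rows.append({
            "site_id": f"site{i:05d}",
            "chrom": s.interval.chrom,
            "start": s.interval.start,
            "end": s.interval.end,
            "strand": s.interval.strand,
            "gene_id": s.gene_id or ".",
            "region": s.region_kind or ".",
            "mean_rpm": s.mean_rpm,
            "tc_reads": s.tc_reads,
            "total_reads_over_T": s.total_reads_over_T,
            "conversion_rate": (np.nan if s.conversion_rate is None
                                else s.conversion_rate),
            "occupancy": np.nan if s.occupancy is None else s.occupancy,
            "fdr": np.nan if s.fdr is None else s.fdr,
            "excluded": s.excluded,
        })
    return pd.DataFrame(rows)


def write_sites_tsv(sites, path: str):
    sites_to_dataframe(sites).to_csv(path, sep="\t", index=False)


def write_sites_bed(sites, path: str):
    """BED6+ export: score = round(1000 x (1 - FDR))."""
    df = sites_to_dataframe(sites)
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            score = 0 if np.isnan(r.fdr) else int(round(1000 * (1 - r.fdr)))
            extras = [
                r.gene_id, r.region, f"{r.mean_rpm:.4g}", str(r.tc_reads),
                str(r.total_reads_over_T), f"{r.conversion_rate:.4g}",
                f"{r.occupancy:.4g}", f"{r.fdr:.4g}",
            ]
            fh.write("\t".join([
                r.chrom, str(r.start), str(r.end), r.site_id, str(score),
                r.strand, *extras,
            ]) + "\n")
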