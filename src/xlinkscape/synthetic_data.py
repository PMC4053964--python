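"""Synthetic 4sU-CLIP study generator with known ground truth.

Builds a toy transcriptome (genes with 5' UTR / CDS / 3' UTR anatomy and
occasional introns laid out on a few chromosomes, both strands), plants RBP
crosslinking sites of ~23 nt, and samples replicate gPAR-CLIP and mRNA-seq
libraries for several growth conditions:

* gPAR-CLIP reads pile up on planted sites; each site uridine covered by a
  site-derived read converts T-to-C with probability ``conversion_prob``,
  and every read additionally picks up rare T-to-C sequencing errors at
  ``seq_error_tc_rate``.
* mRNA-seq reads sample transcripts uniformly in proportion to expression
  and carry only sequencing-error conversions — the error null used for
  empirical FDR assignment.
* Per-site occupancy fold changes are planted in the stress conditions so
  differential calls can be checked against truth.

Random streams are split hierarchically by (stage, condition, replicate):
adding a library never perturbs the reads of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .formats_io import AlignedRead, GenomicInterval, TranscriptModel

_STAGE_GENOME = 0
_STAGE_TRUTH = 1
_STAGE_GPAR = 2
_STAGE_MRNA = 3

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_genes: int = 50
    genes_per_chrom: int = 25
    gene_gap: int = 200
    t_content: float = 0.3
    utr5_len: tuple = (100, 30)
    cds_len: tuple = (900, 300)
    utr3_len: tuple = (166, 50)
    min_region_len: int = 40
    intron_prob: float = 0.05
    intron_len: tuple = (150, 50)
    expression_mean: float = 50.0
    expression_sigma: float = 1.0
    sites_per_gene: int = 2
    site_length: tuple = (23.0, 4.0)
    min_site_length: int = 10
    site_min_gap: int = 50
    site_region_weights: dict = field(
        default_factory=lambda: {"three_utr": 0.6, "five_utr": 0.2, "cds": 0.2}
    )
    site_occupancy_sigma: float = 0.5
    conversion_prob: float = 0.3
    seq_error_tc_rate: float = 0.001
    read_length: int = 30
    jitter: int = 5
    max_conversions: int = 2
    enforce_max_conversions: bool = True
    gparclip_depth: int = 20000
    mrnaseq_depth: int = 50000
    background_frac: float = 0.3
    conditions: tuple = ("WT", "glucose_starv", "nitrogen_starv")
    replicates: int = 2
    frac_changed: float = 0.25
    change_fold: float = 8.0
    p_both_conditions: float = 0.2
    p_increase: float = 0.5
    site_placement: str = "random"  # or "polya_upstream"
    polya_upstream_offset: int = 20

    def validate(self):
        for name in ("t_content", "conversion_prob", "seq_error_tc_rate",
                     "background_frac", "frac_changed", "p_both_conditions",
                     "p_increase"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("utr5_len", "cds_len", "utr3_len", "intron_len"):
            if getattr(self, name)[0] <= 0:
                raise ValueError(f"{name} mean must be > 0")
        if self.min_region_len <= 0 or self.read_length <= 0:
            raise ValueError("lengths must be > 0")
        if self.intron_len[0] >= self.cds_len[0]:
            raise ValueError("intron longer than CDS on average: infeasible")
        if self.site_placement not in ("random", "polya_upstream"):
            raise ValueError(f"unknown site_placement {self.site_placement!r}")


@dataclass
class PlantedSite:
    """Ground truth for one planted crosslinking site."""

    site_id: str
    gene_id: str
    interval: GenomicInterval
    region_kind: str
    base_occupancy: float
    fold: dict  # condition -> occupancy fold relative to base


@dataclass
class TruthSet:
    """Planted sites, per-condition expression, and per-read provenance."""

    sites: list
    expression: pd.DataFrame  # index gene_id, columns conditions

    def occupancy(self, site: PlantedSite, condition: str) -> float:
        return site.base_occupancy * site.fold[condition]


def _rng(config: SimConfig, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def _draw_len(rng, spec, minimum) -> int:
    return int(max(minimum, round(rng.normal(spec[0], spec[1]))))


def build_genome(config: SimConfig):
    """Build reference sequences and transcript models.

    Returns (genome: dict chrom -> str, transcripts: dict gene_id ->
    TranscriptModel). Deterministic under ``config.seed``.
    """
    config.validate()
    rng = _rng(config, _STAGE_GENOME)
    genome: dict = {}
    transcripts: dict = {}
    chrom_seqs: dict = {}
    probs = np.array(
        [(1 - config.t_content) / 3] * 3 + [config.t_content]
    )  # A C G T
    for i in range(config.n_genes):
        gid = f"gene{i:04d}"
        chrom = f"chr{i // config.genes_per_chrom + 1}"
        strand = "+" if i % 2 == 0 else "-"
        utr5 = _draw_len(rng, config.utr5_len, config.min_region_len)
        cds = _draw_len(rng, config.cds_len, config.min_region_len)
        utr3 = _draw_len(rng, config.utr3_len, config.min_region_len)
        intron = 0
        if rng.random() < config.intron_prob:
            intron = _draw_len(rng, config.intron_len, config.min_region_len)
            if intron >= cds:
                intron = 0
        parts = chrom_seqs.setdefault(chrom, [])
        offset = sum(len(p) for p in parts) + config.gene_gap
        parts.append("".join(rng.choice(_BASES, size=config.gene_gap, p=probs)))
        # genomic layout 5'->3' on + strand; mirrored for - strand
        lens_5to3 = [("five_utr", utr5)]
        if intron:
            half = cds // 2
            lens_5to3 += [("cds", half), ("intron", intron), ("cds", cds - half)]
        else:
            lens_5to3 += [("cds", cds)]
        lens_5to3 += [("three_utr", utr3)]
        if strand == "-":
            lens_5to3 = lens_5to3[::-1]
        regions: dict = {}
        pos = offset
        for kind, length in lens_5to3:
            regions.setdefault(kind, []).append(
                GenomicInterval(chrom, pos, pos + length, strand)
            )
            pos += length
        gene_len = pos - offset
        parts.append("".join(rng.choice(_BASES, size=gene_len, p=probs)))
        transcripts[gid] = TranscriptModel(gid, chrom, strand, regions)
    for chrom, parts in chrom_seqs.items():
        parts.append("".join(
            rng.choice(_BASES, size=config.gene_gap, p=probs)
        ))
        genome[chrom] = "".join(parts)
    return genome, transcripts


def _t_base(strand: str) -> str:
    """Reference base that reads as U on the transcribed strand."""
    return "T" if strand == "+" else "A"


def _force_site_uridines(seq_arrays, site: GenomicInterval, rng,
                         min_frac: float = 0.25):
    """Rewrite the reference so the site carries enough uridines to
    crosslink (at least max(1, len/4) transcribed-strand Ts)."""
    arr = seq_arrays[site.chrom]
    tb = _t_base(site.strand)
    span = arr[site.start:site.end]
    need = max(1, int(np.ceil(len(span) * min_frac))) - int((span == tb).sum())
    if need > 0:
        non_t = np.flatnonzero(span != tb)
        pick = rng.choice(non_t, size=min(need, len(non_t)), replace=False)
        span[pick] = tb
        arr[site.start:site.end] = span


def plant_sites(genome: dict, transcripts: Mapping[str, TranscriptModel],
                config: SimConfig):
    """Plant crosslinking sites and draw per-condition truth.

    Returns (genome, TruthSet); the genome is re-issued because site
    placement guarantees each site enough uridines by rewriting bases.
    """
    config.validate()
    rng = _rng(config, _STAGE_TRUTH)
    seq_arrays = {c: np.array(list(s)) for c, s in genome.items()}
    sites: list = []
    margin = config.read_length // 2 + config.jitter + 1
    kinds = sorted(config.site_region_weights)
    weights = np.array([config.site_region_weights[k] for k in kinds], float)
    weights /= weights.sum()
    expr = {}
    for gid in sorted(transcripts):
        tx = transcripts[gid]
        base_expr = float(
            np.exp(rng.normal(np.log(config.expression_mean),
                              config.expression_sigma))
        )
        expr[gid] = {c: base_expr for c in config.conditions}
        occupied: list = []
        if config.site_placement == "polya_upstream":
            placements = [_polya_site(tx, config)]
        else:
            placements = []
            for _ in range(config.sites_per_gene):
                placed = _random_site(tx, config, rng, kinds, weights,
                                      occupied, margin)
                if placed is not None:
                    occupied.append(placed[0])
                placements.append(placed)
        for placed in placements:
            if placed is None:
                continue
            interval, kind = placed
            if config.site_placement == "polya_upstream":
                occupied.append(interval)
            _force_site_uridines(seq_arrays, interval, rng)
            base_occ = float(
                np.exp(rng.normal(0.0, config.site_occupancy_sigma))
            )
            fold = {c: 1.0 for c in config.conditions}
            stress = [c for c in config.conditions if c != "WT"]
            if stress and rng.random() < config.frac_changed:
                f = (config.change_fold
                     if rng.random() < config.p_increase
                     else 1.0 / config.change_fold)
                if len(stress) > 1 and rng.random() < config.p_both_conditions:
                    chosen = stress
                else:
                    chosen = [stress[rng.integers(len(stress))]]
                for c in chosen:
                    fold[c] = f
            sites.append(
                PlantedSite(f"planted{len(sites):05d}", gid, interval, kind,
                            base_occ, fold)
            )
    genome = {c: "".join(a) for c, a in seq_arrays.items()}
    expr_df = pd.DataFrame(
        {c: {g: expr[g][c] for g in expr} for c in config.conditions}
    ).sort_index()
    return genome, TruthSet(sites, expr_df)


def _random_site(tx, config, rng, kinds, weights, occupied, margin):
    """Pick a region and position for one site; None if no room."""
    for _ in range(20):
        kind = kinds[rng.choice(len(kinds), p=weights)]
        blocks = [iv for iv in tx.regions.get(kind, [])]
        if not blocks:
            continue
        block = max(blocks, key=len)
        length = int(np.clip(round(rng.normal(*config.site_length)),
                             config.min_site_length, None))
        lo = block.start + margin
        hi = block.end - margin - length
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        iv = GenomicInterval(tx.chrom, start, start + length, tx.strand)
        if all(
            iv.overlap(o) == 0
            and min(abs(iv.start - o.end), abs(o.start - iv.end))
            >= config.site_min_gap
            for o in occupied
        ):
            return iv, kind
    return None


def _polya_site(tx, config):
    """Single-nucleotide site exactly ``polya_upstream_offset`` nt upstream
    of the poly(A) junction (the strand-aware 3' UTR end)."""
    utr3 = tx.regions.get("three_utr")
    if not utr3:
        return None
    block = utr3[-1] if tx.strand == "+" else utr3[0]
    if tx.strand == "+":
        pos = block.end - 1 - config.polya_upstream_offset
    else:
        pos = block.start + config.polya_upstream_offset
    if not (block.start <= pos < block.end):
        return None
    return GenomicInterval(tx.chrom, pos, pos + 1, tx.strand), "three_utr"


# ---------------------------------------------------------------------------
# Read sampling


def _transcript_blocks(tx: TranscriptModel) -> list:
    return tx.exonic_intervals()


def _draw_conversions(rng, t_positions, site_mask, conversion_prob,
                      error_rate, config):
    """Draw converted T positions for one read.

    ``t_positions``: genomic positions of transcribed-strand Ts the read
    covers; ``site_mask``: which of those lie inside the planted site
    (crosslinkable). Rejection keeps at most ``max_conversions`` events.
    """
    n = len(t_positions)
    if n == 0:
        return ()
    p = np.where(site_mask, 1 - (1 - conversion_prob) * (1 - error_rate),
                 error_rate)
    for _ in range(100):
        hits = rng.random(n) < p
        k = int(hits.sum())
        if not config.enforce_max_conversions or k <= config.max_conversions:
            return tuple(int(t_positions[i]) for i in np.flatnonzero(hits))
    # pathological config: keep the first max_conversions events
    idx = np.flatnonzero(hits)[: config.max_conversions]
    return tuple(int(t_positions[i]) for i in idx)


def _read_t_positions(is_t: np.ndarray, start: int, end: int) -> np.ndarray:
    return start + np.flatnonzero(is_t[start:end])


def _uniform_read(rng, tx, blocks, read_length):
    """A read placed uniformly along the transcript, kept inside one exon
    block (junction-spanning placements are clamped to the block end)."""
    lens = np.array([len(b) for b in blocks])
    block = blocks[rng.choice(len(blocks), p=lens / lens.sum())]
    rl = min(read_length, len(block))
    start = int(rng.integers(block.start, block.end - rl + 1))
    return GenomicInterval(tx.chrom, start, start + rl, tx.strand)


def simulate_gparclip(genome: dict, transcripts: Mapping[str, TranscriptModel],
                      truth: TruthSet, config: SimConfig, condition: str,
                      replicate: int) -> list:
    """Sample one gPAR-CLIP library: site-derived reads centered (with
    positional jitter) on planted sites in proportion to expression x
    occupancy, plus background reads along transcripts; conversions at
    crosslinked uridines plus sequencing error everywhere."""
    config.validate()
    cond_idx = config.conditions.index(condition)
    rng = _rng(config, _STAGE_GPAR, cond_idx, replicate)
    lib = f"gparclip_{condition}_rep{replicate}"
    is_t = {
        (c, s): np.frombuffer(seq.encode(), dtype="S1") == _t_base(s).encode()
        for c, seq in genome.items()
        for s in "+-"
    }
    blocks = {g: _transcript_blocks(tx) for g, tx in transcripts.items()}

    n_bg = int(round(config.gparclip_depth * config.background_frac))
    n_site_total = config.gparclip_depth - n_bg
    site_w = np.array(
        [truth.expression.at[s.gene_id, condition] * truth.occupancy(s, condition)
         for s in truth.sites]
    )
    reads: list = []
    if len(truth.sites) and site_w.sum() > 0:
        counts = rng.multinomial(n_site_total, site_w / site_w.sum())
        for site, n in zip(truth.sites, counts):
            tx = transcripts[site.gene_id]
            block = _containing_block(blocks[site.gene_id], site.interval)
            center = (site.interval.start + site.interval.end) // 2
            tmask = is_t[(site.interval.chrom, site.interval.strand)]
            for _ in range(int(n)):
                c = center + int(rng.integers(-config.jitter, config.jitter + 1))
                start = c - config.read_length // 2
                start = int(np.clip(start, block.start,
                                    max(block.start, block.end - config.read_length)))
                end = min(start + config.read_length, block.end)
                tpos = _read_t_positions(tmask, start, end)
                in_site = (tpos >= site.interval.start) & (tpos < site.interval.end)
                tc = _draw_conversions(rng, tpos, in_site,
                                       config.conversion_prob,
                                       config.seq_error_tc_rate, config)
                reads.append(AlignedRead(
                    GenomicInterval(tx.chrom, start, end, tx.strand),
                    library_id=lib, n_mismatches=len(tc), tc_positions=tc,
                    provenance=f"site:{site.site_id}",
                ))
    reads.extend(
        _background_reads(rng, transcripts, blocks, truth, config, condition,
                          is_t, n_bg, lib)
    )
    return reads


def simulate_mrnaseq(genome: dict, transcripts: Mapping[str, TranscriptModel],
                     truth: TruthSet, config: SimConfig, condition: str,
                     replicate: int) -> list:
    """Sample one mRNA-seq library: uniform coverage proportional to
    expression; T-to-C events arise only from sequencing error."""
    config.validate()
    cond_idx = config.conditions.index(condition)
    rng = _rng(config, _STAGE_MRNA, cond_idx, replicate)
    lib = f"mrnaseq_{condition}_rep{replicate}"
    is_t = {
        (c, s): np.frombuffer(seq.encode(), dtype="S1") == _t_base(s).encode()
        for c, seq in genome.items()
        for s in "+-"
    }
    blocks = {g: _transcript_blocks(tx) for g, tx in transcripts.items()}
    return _background_reads(rng, transcripts, blocks, truth, config,
                             condition, is_t, config.mrnaseq_depth, lib)


def _containing_block(blocks, interval):
    for b in blocks:
        if b.start <= interval.start and interval.end <= b.end:
            return b
    # intronic site: fall back to the site's own span padded to read length
    return interval


def _background_reads(rng, transcripts, blocks, truth, config, condition,
                      is_t, n_reads, lib):
    genes = sorted(transcripts)
    w = np.array(
        [truth.expression.at[g, condition] * transcripts[g].tx_length
         for g in genes]
    )
    counts = rng.multinomial(n_reads, w / w.sum())
    out = []
    for g, n in zip(genes, counts):
        tx = transcripts[g]
        tmask = is_t[(tx.chrom, tx.strand)]
        for _ in range(int(n)):
            iv = _uniform_read(rng, tx, blocks[g], config.read_length)
            tpos = _read_t_positions(tmask, iv.start, iv.end)
            tc = _draw_conversions(
                rng, tpos, np.zeros(len(tpos), bool), 0.0,
                config.seq_error_tc_rate, config,
            )
            out.append(AlignedRead(iv, library_id=lib, n_mismatches=len(tc),
                                   tc_positions=tc, provenance="background"))
    return out


def simulate_study(config: SimConfig):
    """Run the full generator: genome, truth, and every library.

    Returns (genome, transcripts, truth, libraries) where libraries maps
    (kind, condition, replicate) -> list[AlignedRead], kind in
    {"gparclip", "mrnaseq"}.
    """
    genome, transcripts = build_genome(config)
    genome, truth = plant_sites(genome, transcripts, config)
    libraries = {}
    for cond in config.conditions:
        for rep in range(1, config.replicates + 1):
            libraries[("gparclip", cond, rep)] = simulate_gparclip(
                genome, transcripts, truth, config, cond, rep
            )
            libraries[("mrnaseq", cond, rep)] = simulate_mrnaseq(
                genome, transcripts, truth, config, cond, rep
            )
    return genome, transcripts, truth, libraries


# ---------------------------------------------------------------------------
# On-disk outputs


def write_fasta(genome: dict, path: str, width: int = 70):
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_truth_tables(truth: TruthSet, sites_path: str, expr_path: str):
    rows = []
    for s in truth.sites:
        row = {
            "site_id": s.site_id, "gene_id": s.gene_id,
            "chrom": s.interval.chrom, "start": s.interval.start,
            "end": s.interval.end, "strand": s.interval.strand,
            "region": s.region_kind, "base_occupancy": s.base_occupancy,
        }
        row.update({f"fold_{c}": f for c, f in s.fold.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(sites_path, sep="\t", index=False)
    truth.expression.to_csv(expr_path, sep="\t", index_label="gene_id")
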