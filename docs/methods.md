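# Methods

`xlinkscape` analyzes 4sU-based CLIP sequencing data, in which a
photoactivatable uridine analog crosslinks RNA to contacting proteins and
reads out as a T-to-C substitution after reverse transcription. The pipeline
identifies protein-contacted RNA intervals ("crosslinking sites") from
conversion-bearing reads, controls them against the sequencing-error rate,
normalizes crosslink evidence for transcript abundance, and compares
protein occupancy between growth conditions. Because real
gPAR-CLIP sequencing libraries are far larger than anything a
test suite should process, the package ships a synthetic study generator
with planted ground truth; every claim the tests make is about recovery of
that truth.

## Read processing

Libraries are multiplexed via the first six nucleotides of the 3' DNA
linker; the rest of the linker (`TCGTATGCC...`) is constant. Demultiplexing
scans each read for barcode placements, preferring placements immediately
5' of the constant linker, with exact matches taking precedence over
single-mismatch matches; within a tier the 3'-most placement wins, then the
lowest library index. Quality filtering discards a read that meets any of,
attributed to the first failing rule: raw length < 18 nt; adapter-trimmed
insert consisting only of A; no 3' adapter (no ≤1-mismatch linker match);
5'-3' adapter-ligation product (a 5'-linker suffix directly abutting the 3'
adapter with a sub-18-nt insert); 5'-5' product (two 5'-linker
occurrences); more than 4 bases below Q10 or more than 6 bases below Q13
(Phred+33, cumulative counts — bases below Q10 also count against the Q13
rule). The dimer detectors are declared heuristics; the underlying library
structure only fixes what the products look like qualitatively.

## Site calling

Reads carrying exactly one or two T-to-C conversions define *read
clusters*: maximal strand-specific runs of positions covered by at least
one such read. Each cluster's contributing-read coverage is smoothed with a
Gaussian kernel and split into sites at inflection points of the smoothed
curve: one site per local maximum, extending to the nearest sign change of
the discrete second difference on each flank, or to the cluster end when a
flank has none.

Numerical choices:

* **Bandwidth.** "Bandwidth 21" is interpreted in the classical
  kernel-smoother convention that places the kernel quartiles at
  ±bandwidth/4, i.e. σ = 0.25·21/Φ⁻¹(0.75) ≈ 7.78 nt. σ is independently
  configurable; whether bandwidth denotes σ, FWHM, or the quartile width is
  a genuinely open convention and this is a declared choice.
* **Edge handling.** Kernel weights are renormalized inside the cluster, so
  a constant profile smooths to the same constant; clusters shorter than
  the kernel support are handled by slicing the centered window of the full
  convolution.
* **Discrete inflections.** The second difference s[i+1] − 2s[i] + s[i−1]
  is evaluated at interior positions; a zero adopts the sign of the next
  nonzero value to its right; the boundary is the sign-change position
  nearest the maximum, included in the site (closed, then converted to
  half-open). Plateau maxima collapse to their left-biased midpoint.
  When two maxima share one inflection, the shared position belongs to the
  left site. Sites with no conversion-positive position are dropped; sites
  shorter than `min_site_length` merge into the neighbor with the higher
  peak (default 1 nt, i.e. no merging).
* **Pooling.** Clusters and boundaries are derived from all gPAR-CLIP
  libraries pooled; each site is then quantified separately per library.

Quantification uses the **full** library (converted and unconverted reads):
`mean_rpm` is the mean per-nucleotide RPM over the site; *occupancy* is
mean_rpm / gene RPKM × 1000, with RPKM taken from the ribosome-depleted
mRNA-seq libraries of the same condition (replicate-averaged); the
*conversion rate* is the fraction of reads covering at least one site T
that carry a conversion inside the site. Counting the numerator locally
(conversion inside the site rather than anywhere on the read) is a declared
choice; it keeps the statistic attributable to the interval it describes.
Sites on genes without mRNA-seq coverage are flagged and excluded from
occupancy comparisons. Reads are assigned to genes by strict-majority
exonic overlap, ties to the lexicographically smaller gene id.

## Empirical FDR

mRNA-seq reads with one or two T-to-C mismatches carry only sequencing
error; running the identical clustering/segmentation/quantification on them
yields *error clusters* whose conversion rates form a coverage-dependent
null. Sites and error clusters are binned by total read coverage (log2
edges; bins holding fewer than 50 null clusters merge upward, leftover top
bins merge down), and a site's FDR is the proportion of null clusters in
its bin with a *strictly* higher conversion rate. Thresholding is strict
(`fdr < 0.01`). With tied discrete rates the strict rule is slightly
anti-conservative; a +1/+1 pseudocount mode is available. An empty null bin
after merging yields FDR 0 with a warning — reachable in simulation, not in
data of realistic depth.

## Crosslinking scores and aggregate analyses

The per-nucleotide crosslinking score at a genomic T is the RPM of
conversion-bearing reads with an event exactly there, divided by the gene's
mRNA-seq RPKM, × 1000; positions on genes without mRNA-seq coverage are
removed. For comparison with external per-nucleotide tracks (conservation,
unpaired probability — consumed, never computed here), scored positions are
ranked by CLS and binned so adjacent bins overlap by 50% (default 100 bins;
bin size ⌊2N/(n+1)⌋, stride half that); controls randomly rank the
unscored positions and are averaged over ten replicates with per-replicate
values retained. Metagene profiles average coverage at strand-oriented
offsets around an anchor — 5' UTR start, intron branch-point, or the
poly(A) junction (the annotated 3' UTR end) — counting only offsets inside
the anchoring region, with per-offset contributor counts so sums are
recoverable. Conserved-block overlap uses single-site full coverage by
default (union-coverage mode available; the two readings are both
defensible) against number- and size-matched random blocks from the same
region class, summarized by a 2×2 chi-square without continuity correction.
Site capture uses ≥50% of the query's nucleotides overlapping the union of
reference sites.

## Replicate error and differential occupancy

Counting statistics set a floor on replicate agreement: a site's N total
reads split between two replicate libraries as Binomial(N, 1/2), so the
replicate-1 fraction has standard deviation 1/(2√N). The package reports
this prediction per coverage bin alongside the observed spread, and
estimates overall replicate error as σ = std of log2 site-coverage ratios
between replicates (population std, reported as 2^σ fold).

Differential calls compare replicate-averaged occupancy between two
conditions. Sites below the coverage floor in **both** conditions are
excluded; the floor is 5 RPM at canonical (10M-read) depth, which the
package translates into the equivalent read-count floor (50 reads) at the
study's actual depth via `min_rpm_for_reads`, because the floor marks where
counting noise stops dominating and that is a property of counts, not of
RPM. Fold change is (occ_B + c)/(occ_A + c) with pseudocount c = 0.1 RPM so
sites lost entirely in one condition remain classifiable (flagged as
infinite raw fold); calls are *increased* above 4-fold, *decreased* below
1/4. The 4-fold default follows the 3σ logic at a replicate error of
1.3-fold as printed; note that no standard definition of σ on log2 ratios
makes 1.3³ equal 4 (1.3³ ≈ 2.2), so σ estimation and the fold threshold are
deliberately independent knobs. Set overlaps between two stress conditions
are reported per class at site and gene level (a gene is in a class if any
of its sites is). Welch's t statistics on gene-set shifts are emitted as
report columns only.

## Synthetic data generator

The generator emulates the structure of a full gPAR-CLIP experiment: duplicate gPAR-CLIP
and mRNA-seq libraries for rich media and glucose/nitrogen starvation;
gPAR-CLIP reads carrying 1–2 conversions at protein-contacted uridines;
mRNA-seq reads with rare T-to-C sequencing errors; condition-specific
occupancy fold changes at planted sites.

Genes with 5' UTR / CDS / 3' UTR anatomy (3' UTR mean 166 nt, the yeast
median; occasional introns) are laid out on a few chromosomes, alternating
strands, with log-normal expression. Each gene gets (by default) two
planted sites of length ~N(23, 4) nt, ≥50 nt apart, placed 60/20/20 across
3' UTR / 5' UTR / CDS, each guaranteed at least len/4 transcribed-strand
uridines by rewriting the (synthetic) reference. Site-derived reads are
fixed-length fragments (default 30 nt) centered on the site with ±5 nt
uniform jitter; each covered site uridine converts with probability
`conversion_prob` (default 0.3 — the mapping from 4sU incorporation density
to per-U conversion probability is not derivable from first principles, so
this is a free parameter); every read additionally picks up errors at
`seq_error_tc_rate` (default 10⁻³ per T). Reads drawing ≥3 conversions are
rejection-resampled so simulated reads satisfy the cluster filter at a
controlled rate (a no-rejection mode exists for testing the filter itself).
Background and mRNA-seq reads sample transcripts ∝ expression × length,
clamped inside one exon block. Random streams split hierarchically by
(stage, condition, replicate): adding a library never perturbs another, and
a fixed config is byte-reproducible.

Fold changes (default 8×, up/down with equal probability, on 10–25% of
sites, shared between stress conditions with probability 0.2) are planted
as occupancy multipliers; expected read counts follow expression ×
occupancy through a multinomial of the library depth, so RPM is
compositional exactly as in real sequencing.

What the generator does **not** emulate: sequence composition (codon
structure, splice signals, motifs), variable trimmed read lengths, PCR
duplicates, mappability, or genuinely overdispersed biological replicate
variation (replicates differ only by sampling). Passing tests therefore
demonstrate the algorithms' correctness and calibration under the stated
sampling model, not robustness to those real-data artifacts.

## Canonical study configurations and scale

`xlinkscape.studies` fixes one configuration per question, shared by the
analysis drivers, the test suite, and `scripts/acceptance.py`:

* **Recovery** (200 genes, 400 planted sites, ~50 reads/site/library,
  conversion 0.3, uniform expression): fragment length is set to 23 nt,
  matched to the protected footprint, because inflection segmentation
  recovers the read-coverage footprint, whose width equals the fragment
  length — with RNase-trimmed fragments matched to sites, called length
  centers near 23 nt and boundaries land within a few nt of truth.
* **Calibration** (30 genes, conversion probability 0, 20 independent
  seeds): gPAR-CLIP reads follow the mRNA-seq placement process (no planted
  pileups), making the two libraries' conversion processes exchangeable —
  the property the empirical FDR needs; the fraction of null sites at
  FDR < 1% is then checked against ~1%.
* **Differential** (100 genes, three conditions, duplicate libraries,
  8-fold changes on 10% of sites, 20k reads/library): the 50-read coverage
  floor and 4-fold threshold classify changes; at 10% planted prevalence the
  compositional RPM distortion (≈1.3×) leaves measured 8-fold changes far
  from the threshold.
* **Metagene** (60 genes, one single-nucleotide crosslink signal exactly
  20 nt upstream of every poly(A) junction): the conversion-coverage
  metagene must peak at offset −20.

These problem sizes keep the full test suite within a few minutes on one
CPU while leaving each check hundreds of sites of statistical resolution.

## Known limitations

* Conversion-rate numerators count only events inside the site; a read
  crosslinked just outside a boundary contributes coverage but not
  evidence.
* The strict-greater FDR rule is anti-conservative under heavy rate ties
  (very low coverage); use the pseudocount mode if that regime matters.
* Site boundaries inherit the read-footprint geometry: with fragments much
  longer than binding sites, called sites are systematically wider than the
  protected region.
* The BED12 reader derives UTRs from the thick range and treats fully
  non-coding transcripts as 5'-UTR-only.
* `replicate_fraction_std` accepts RPM in place of raw counts when depths
  are similar; pass true counts for exact binomial comparisons.
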