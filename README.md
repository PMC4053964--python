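# xlinkscape

Transcriptome-wide analysis of RNA-protein crosslinking from 4sU-CLIP
sequencing data.

In 4sU-based CLIP experiments (PAR-CLIP and its transcriptome-global
variant), a photoactivatable uridine analog incorporated into nascent RNA
crosslinks to contacting proteins under 365 nm UV and leaves a diagnostic
T-to-C substitution in the sequenced cDNA. `xlinkscape` turns such reads
into a quantitative map of RNA-binding-protein (RBP) contacts:

1. **Read processing** — demultiplexing by 6-nt 3'-linker barcodes (exact
   matches before single-mismatch, 3'-most occurrence wins) and quality
   filtering with per-reason accounting.
2. **Site calling** — reads with 1–2 T-to-C conversions define read
   clusters; each cluster's coverage is smoothed with a Gaussian kernel
   (bandwidth 21 nt) and split into *crosslinking sites* at the inflection
   points of the smoothed curve.
3. **Empirical FDR** — the identical pipeline applied to mRNA-seq reads
   with 1–2 T-to-C mismatches (pure sequencing error) yields null clusters;
   within coverage bins, a site's FDR is the proportion of null clusters
   with a strictly higher conversion rate, where the conversion rate is
   (reads with a conversion in the site) / (reads covering a site T).
4. **Crosslinking scores** — per-T score CLS = conversion-read RPM /
   gene RPKM × 1000, normalizing crosslink evidence for mRNA abundance;
   ranked 50%-overlap binning against external tracks (conservation,
   unpaired probability) with randomized controls; metagene profiles around
   the 5' UTR start, intron branch point, and poly(A) junction.
5. **Differential occupancy** — a site's occupancy (mean site RPM /
   gene RPKM × 1000) is averaged over replicate libraries per condition;
   after a coverage floor (>5 RPM at canonical depth, translated to the
   equivalent read-count floor at any depth), >4-fold changes are called
   increased/decreased, with glucose/nitrogen starvation set overlaps at
   site and gene level. Replicate error is modelled by binomial
   partitioning (std of the replicate fraction = 1/(2√N)) and summarized
   as σ = 2^std(log₂ r₁/r₂).

Because real gPAR-CLIP libraries run to millions of reads, the package
includes a first-class **synthetic study generator**
(`xlinkscape.synthetic_data`) producing duplicate gPAR-CLIP and mRNA-seq
libraries for three growth conditions with planted sites, known occupancy
fold changes, and per-read provenance — every downstream stage is tested
against that ground truth. See `docs/methods.md` for the model and all
numerical conventions.

## Worked example

Run the analysis drivers in order (each takes a `seed` argument,
default 1):

```sh
python analysis/01_simulate.py
python analysis/02_reproducibility.py
python analysis/03_call_sites.py
python analysis/04_differential.py
python analysis/05_tracks_metagene.py
```

Output (seed 1):

```
simulated 100 genes, 200 planted sites (18 with occupancy changes), 12 libraries -> results/study_data
mrnaseq WT replicate gene-RPM Pearson r = 0.9994
gparclip WT replicate gene-RPM Pearson r = 0.9977
replicate error sigma = 1.14-fold (std of log2 ratios 0.187) over 192 sites
...
glucose_starv: 3/69 analyzed sites changed >4-fold (1 up, 2 down); vs planted truth: sensitivity 100%, false calls 0.0%
nitrogen_starv: 8/71 analyzed sites changed >4-fold (6 up, 2 down); vs planted truth: sensitivity 100%, false calls 0.0%
venn counts match planted truth: True
...
poly(A) metagene over 60 3' UTRs peaks at offset -20 nt
```

Reading this: replicate libraries sampled from one expression vector
correlate >0.99 at the gene level, so condition comparisons use
replicate-averaged coverage; the replicate error σ (1.14-fold here, purely
counting noise at this depth) sits well below the 4-fold call threshold;
differential calls recover every planted 8-fold occupancy change with no
false calls among unchanged sites; and the crosslink signal planted 20 nt
upstream of each poly(A) junction is recovered at exactly offset −20 in the
metagene profile. Tables land under `results/` (site tables as TSV and
BED6+, differential calls and Venn summaries, CLS track and bins, metagene
profile).

The same functionality is scriptable via the `xlinkscape` CLI
(`simulate`, `demux`, `filter`, `tables`, `correlate`, `call-sites`,
`fdr`, `cls`, `bins`, `metagene`, `overlap`, `diff`); run
`xlinkscape --help`.

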