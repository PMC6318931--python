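# Methods

## Scope and data model

The package screens one low-pass single-cell WGA sequencing sample at a
time against a panel of euploid controls, on three nested tilings of hg19:
20 kb working bins (counting, GC correction), 500 kb superbins
(segmentation) and 1 Mb bins (the CV noise metric). Coordinates are
0-based half-open; chromosomes are chr1..chr22, chrX, chrY in karyotype
order, with mitochondrial and alternate contigs excluded. The last bin of
each chromosome is shorter than nominal; ratios are computed on count
density rescaled to full-bin width so these bins need no special handling.

## Read filtering and counting

A read is retained iff it is mapped, primary, has MAPQ > 0 and is not a
duplicate. "Multi-hit" is operationalized as the secondary/supplementary
flag or MAPQ 0 (the usual multi-mapper signature); duplicates honor the
duplicate flag when present and otherwise are exact (chrom, start, strand)
collisions, which is exact on coordinate-sorted input and keeps counting
stream-wise with bounded memory. Each retained read increments the bin
containing its leftmost mapped coordinate; with 150 bp reads in 20 kb bins
the assignment rule is immaterial.

## Normalization

1. **Raw ratio.** Count density per bin divided by the mean density over
   unmasked autosomal bins. The chain is invariant to rescaling all counts,
   and each sample is its own diploid baseline — a consequence is that
   genome-wide uniform ploidy changes (e.g. triploidy) are invisible, as
   for read-depth methods generally.
2. **LOESS GC correction.** A degree-1 LOESS curve f(gc) (span 0.3, one
   robustifying iteration) is fitted to (gc, ratio) over unmasked autosomal
   bins and divided out: `corrected = ratio × median(ratio) / f(gc)`. Sex
   chromosomes are corrected with the autosomal fit so their copy state
   cannot distort it. For speed the fit uses an even GC-ordered subsample
   of at most 30,000 bins and linear interpolation; the fitted curve is
   floored at 5% of the median to avoid blow-ups in sparse GC tails. Fewer
   than 100 usable bins is an error. After correction the rank correlation
   between ratio and GC on biased simulations is below 0.05.
3. **Panel normalization and outlier masking.** The panel stores the
   per-bin mean and sd of the corrected control ratios; a sample is divided
   by the per-bin mean (removing the reproducible component of WGA bias)
   and rescaled so its unmasked autosomal median is 1. A bin is masked when
   its across-control median deviates from its chromosome's median level by
   more than t_loc = 0.5 (relative), or its across-control CV exceeds
   3 × the median CV over bins (floored at an absolute CV of 0.05 so
   noise-free data cannot mask everything). Judging location against the
   chromosome level keeps the single-copy sex chromosomes of male controls
   usable. On homogeneous simulated controls under defaults, < 1% of bins
   are masked.

The bin-ratio distribution of WGA data is right-skewed, so a
median-anchored scale has mean slightly above 1. Bin-level ratios keep the
median anchor (the documented diploid-expectation-1 contract), while the
500 kb segmentation track is re-anchored so its unmasked autosomal *mean*
is exactly 1: the 1.4/2.6 copy thresholds and the minimum mosaic effect
are absolute copy numbers and must not inherit that skew (without the
re-anchor, 30%-mosaic deletions sit at reported copy ≈ 1.82 instead of 1.7
and fall inside the neutrality band).

## Aneuploidy calling

Per chromosome, `z = (r̄ − μ) / max(σ, σ_min)` with μ, σ the panel's
per-chromosome mean and sd of chromosome-mean panel-normalized ratios;
z > 3 is trisomy, z < −3 monosomy, otherwise disomy. The floor
σ_min = 0.035 (ratio units) makes a call require an absolute deviation of
at least ≈ 0.105 — roughly a 21% mosaic — in addition to statistical
surprise. Rationale: a chromosome mean aggregates ~2,400 bins and is
Gaussian with sd ≈ 0.01, so a plain |z| > 3 rule on a correctly estimated
σ fires on ~0.27% of euploid chromosomes (≈ 6% of euploid embryos across
24 chromosomes), which contradicts the zero-false-positive operating point
this class of assay runs at. With the floor, full aneuploidies sit at
z ≈ 14 and 30%-mosaic aneuploidies at z ≈ 4.3, both comfortably called,
while euploid fluctuations would need ~9 sampling sd to reach the
threshold. Setting `min_chrom_sd=0` restores the plain Z-score.

## CBS segmentation and CNV significance

At each recursion step the arc (i, j] maximizing the two-sample t-like
statistic between in-arc and out-of-arc superbins is found by a vectorized
scan of all arcs (minimum width 3 superbins = 1.5 Mb). The split is
accepted when max |t| exceeds the normal quantile Bonferroni-corrected
over the number of candidate arcs at `alpha_split = 1e-4` per chromosome
(genome-wide family-wise split error ≈ 0.24% per sample); a
permutation-quantile acceptance mode is available for small tracks.
Accepted pieces are segmented recursively; adjacent segments whose means
differ by less than 0.2 copies are merged; segments partition each
chromosome's unmasked superbins. Superbins with fewer than 5 unmasked
20 kb children are masked.

Power analysis behind the defaults (SurePlex noise at 4.1 M reads):
panel-normalized superbins have sd ≈ 0.084, so a full-proportion
duplication of k superbins has expected statistic
t ≈ (0.5/0.084)·√k ≈ 10 at k = 3, against an acceptance threshold ≈ 5.9 —
hence the 1.5 Mb resolution floor — while 30%-mosaic events need
k ≳ 10–20 (5–10 Mb), matching the observed mosaic detection limits. A
conventional per-chromosome split alpha of 0.01 would instead mark ~20% of
euploid samples with a spurious segment across 24 chromosomes, which is
irreconcilable with the assay's zero-false-positive behavior; the
stricter default was chosen from this analysis, not fitted to data.

Each candidate segment receives a permutation P: the unmasked superbin
values of its chromosome are shuffled (default 10,000 times, seeded) and
the best same-length contiguous window's absolute deviation from the track
mean forms the null; P uses the add-one estimator
(1 + #extreme)/(n_perm + 1). A chromosome that was never split gets P = 1
(its single segment cannot deviate from its own mean). Classification on
the copy scale: mean < 1.4 microdeletion, > 2.6 microduplication,
permutation-significant segments inside the band with |copy − 2| ≥ 0.25
are intermediate (mosaic-range) events; *detected* = P < 0.01 and a
non-neutral label. The separation of detection from the 1.4/2.6 labels is
what lets 30%-mosaic events (expected copy 2.3 / 1.7) be reported at all.

An embryo is implantable iff no trisomy/monosomy and no detected CNV; more
than 5 aneuploid chromosomes flags the sample as a failed assay. An
array-CGH-style comparator (per-chromosome median log2 ratio, ±0.3 for
gain/loss) is included for concordance checks on synthetic data.

## Simulator

Per-bin expected counts are
`λ_i ∝ copy_i/2 × exp(slope·(gc_i − ḡ)) × W_i × width_i`, scaled to the
target unique-read count, with counts Poisson around λ after a per-sample
per-bin lognormal effect — i.e. negative-binomial-like overdispersion.
`W` is a lognormal "amplification wave", constant within 1 Mb blocks and
*fixed per grid and kit preset* (shared by all samples): the reproducible
part of WGA bias, which is what reference-panel normalization removes and
why control-based masking exists. Samples are male (XY) by default so all
24 chromosomes carry signal. Mosaic samples use
`copy = p·abnormal + (1−p)·euploid`. Filter tallies are set so the
duplicate fraction and unique-mapped fraction match the kit's observed
values.

Calibration closes the CV(1 Mb) budget analytically. With the 1 Mb
aggregate of 50 bin ratios,

    CV² = wave_sd² + (1/λ̄ + (1 + wave_sd²)·s²) / 50,

solved for the per-bin lognormal sd s at the preset's nominal depth
(λ̄ ≈ 27 unique reads per 20 kb bin at 4.1 M reads). Presets: SurePlex —
CV target 0.133, wave sd 0.12, GC mean 0.448, duplicate fraction 0.187,
4.1 M reads; DOP-PCR — CV 0.11, wave sd 0.099, GC mean 0.414, duplicate
fraction 0.199, 3.95 M reads. The wave/sample split (wave sd 0.12 of the
0.133 total) encodes that most WGA bias is reproducible across samples of
a kit; it is the only split under which a ~2 Mb minimum detectable region,
zero false positives and CV(1 Mb) = 0.133 can coexist, since a purely
sample-random budget of that size leaves superbin noise ≈ 0.19 and makes
2 Mb segments undetectable at usable specificity. Bin GC is drawn once per
grid from a Beta distribution (concentration 80) when no genome FASTA is
supplied. Simulated CNV events are aligned to 500 kb boundaries, one event
per sample.

The mixing-experiment design (`table2_design`) fixes category counts —
2 pure aneuploidies; pure CNVs < 4 Mb ×4, 4–10 Mb ×1, > 10 Mb ×1; CNVs at
proportion 0.3 (< 4 ×1, 4–10 ×3, > 10 ×9) and 0.7 (4–10 ×5, > 10 ×8);
aneuploidies at 0.3 ×4 and 0.7 ×4 — plus 16 euploid controls for the
panel; event sizes and chromosomes are fixed in the source.

### What the simulator does not emulate

Sequence-level errors, chimeric reads, mappability and segmental
duplications, amplification branching processes (MDA/MALBAC trees),
GC–wave coupling, and real inter-embryo biological variability. Passing
tests therefore demonstrate the *algorithmic* operating characteristics
(calibration, resolution, specificity under the stated noise family), not
clinical performance on real embryos.

## Numerical and reproducibility choices

All stochastic steps take explicit seeds; per-sample streams are derived
from a base seed plus a CRC of the sample id, so results are independent
of processing order. Grid-level fixtures (GC landscape, wave) are seeded
by preset name and grid shape only, so they act as fixed "biology" across
runs. Degenerate inputs are errors, not warnings: empty chromosome tables,
non-positive bin sizes, < 3 controls, zero panel sd with the floor
disabled, unsorted alignments, segments longer than their track. The test
suite reduces permutations to 2,000 (alpha unchanged) and the problem
sizes stated above (16-control panels, 20 replicates per sweep size,
200 euploid samples for specificity, 50 samples for calibration) were
chosen to keep a full run at desk scale.

## Known limitations

* Resolution is floored at 3 × 500 kb superbins; sub-1.5 Mb events are out
  of reach by construction.
* Mosaicism below ~20% is indistinguishable from euploid by design of the
  sd floor; the package reports mosaic-range events only between the
  detection and labeling thresholds.
* The Z-score and CBS operate on the same normalized track, so a
  whole-chromosome event appears in both views; whole-chromosome segments
  get P = 1 and are reported through the aneuploidy channel only.
* chrY statistics in female samples are meaningless (near-zero counts);
  the panel masks chrY when controls are female.
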