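# Methods

This note documents the models, conventions and numerical choices behind
`nucorg`, in the order data flows through the pipeline.

## Scope and data model

The package starts from aligned paired-end fragments (BED intervals or
properly paired BAM/SAM templates) and a gene annotation; read alignment is
out of scope.  All coordinates are 0-based half-open.  Transcript offsets
are measured from the strand-aware TSS with downstream positive, so every
statistic is strand-symmetric by construction (mirroring the genome and
flipping strands leaves offsets, shifts and classifications unchanged; this
is property-tested).

## Fragment filters

- **Size selection** keeps fragments with length in the closed interval
  [140, 160] bp — the mono-nucleosome band; "140–160" is read as inclusive
  on both ends.
- **Region exclusion** removes a fragment if it overlaps a blacklisted
  interval by ≥ 1 bp (any-overlap, not midpoint containment — the
  conservative reading for repetitive loci such as the yeast rDNA,
  chrXII:451000–469000, treated as 0-based half-open).
- **Subsampling** draws exactly min(n, available) fragments uniformly
  without replacement (default n = 5 × 10⁶ *fragments*; in a paired-end
  protocol a template is counted once).  The draw is seeded and preserves
  input order, so filter→exclude→subsample commutes with
  exclude→filter→subsample at a fixed seed.  The canonical order is
  filter, exclude, subsample.  Duplicates are kept (no deduplication step).

## Dyad tracks

The dyad of a fragment [start, end) is floor((start+end)/2); even-length
fragments have no central base, and flooring keeps the estimator
deterministic.  Each dyad is extended symmetrically by ±50 bp (a 101 bp
footprint approximating the nucleosome) into an integer per-base coverage
array per chromosome.  "Extended by 50 bp" is implemented as symmetric
extension; one-sided extension would break strand symmetry.  Away from
chromosome edges the genome-wide sum is exactly n_fragments × 101, which is
asserted on every simulated dataset.  Tracks round-trip losslessly through
bedGraph (maximal runs, zero runs omitted) and bigWig; a lossless fixedStep
wiggle writer is also provided.

## Nucleosome calling

Full peak-calling machinery (Poisson enrichment tests, FDR) is unnecessary
downstream — only summit coordinates and heights are used — so the caller
is deliberately minimal and fully specified:

1. optional per-base cap (default 200) guards against clonal pile-ups;
2. convolution with a discrete Gaussian kernel (sd = bandwidth, default
   15 bp), truncated at ±4 sd and renormalized to sum 1; edges are
   zero-padded so output length equals input length;
3. strict local maxima (plateaus resolved to their leftmost base) at or
   above a height floor are ranked by height (ties: smaller coordinate,
   then chromosome name) and accepted greedily unless within 110 bp of an
   accepted summit.

The 110 bp minimum distance is below the 147 bp nucleosome footprint, so
tightly packed arrays are not merged, while double-called summits of one
nucleosome are.  The default height floor is 5% of the track mean over
nonzero bases, making the caller invariant to sequencing depth; an absolute
override exists.  Low background bumps can pass this floor, but they cannot
corrupt +1 assignment in practice: any candidate inside the ±(−30..250) bp
search window is within 110 bp of the (much higher, hence
earlier-accepted) +1 or +2 summit and is therefore suppressed by the
distance constraint.  On constructed tracks with well-separated distinct
peaks the greedy solution coincides with the exhaustive
maximum-total-height solution under the same constraint (tested).

## +1 assignment, shifts, dependence

The +1 nucleosome of a gene is the called summit with the smallest
transcript offset within [−30, +250] bp of the TSS.  The window is a design
choice: −30 admits slightly upstream reference +1 dyads; +250 still
captures a +1 that a mutant has pushed one linker downstream.  "Smallest
offset", not "smallest absolute offset": the +1 is the first nucleosome
*downstream*, and a slightly upstream candidate (offset ≥ −30) outranks the
true +1 only if it is a real called summit, which the caller's distance
constraint prevents in the NFR.

Shift per replicate pair: Δ = offset_mut − offset_ref (downstream
positive).  With equal replicate counts, pairs are matched by sorted
replicate index; with unequal counts each mutant replicate is compared to
the mean reference offset (recorded in the table metadata).  A gene is
**dependent** iff Δ ≥ threshold (default 10 bp) in *every* replicate pair —
the all-replicates reading of replicate consistency; a pooled-comparison
alternative would be more powerful but less stringent.  Genes lacking a +1
call in any required sample are excluded from classification and reported
with an NA reason, rather than treated as infinite shift.

## NRL estimation and comparison

Per-gene NRL is the OLS slope of summit offset against nucleosome index
0..k−1 over the first min(N, 8) calls of the +1..+N array (N ≥ 4 required).
For a phased array this equals the repeat length exactly, and under
Gaussian positional noise it is the maximum-likelihood spacing; an
autocorrelation/phaseogram estimator would behave equivalently on phased
arrays but is not implemented.  r² is reported as a phasing-quality
diagnostic.  Translation invariance and scale equivariance of the slope are
property-tested.

Gene-set distributions are summarized with type-7 (linear-interpolation)
quartiles and Tukey whiskers at 1.5×IQR clipped to the data range — stated
because boxplot statistics depend on the quartile convention.  Strains are
compared by a two-tailed Welch's t-test on per-replicate mean NRLs.  With
the usual 2–3 datasets per strain this test has very low power; it is kept
because it matches the experimental design, and the implementation refuses
groups with n < 2 or zero variance instead of returning an undefined p.
The t, Welch–Satterthwaite df, and p are cross-checked against closed-form
textbook formulas to 1e-9 relative error.

## Composite profiles

Profiles average coverage over genes in a window around the TSS (default
−300..+1300 bp, covering +1 through ~+6 nucleosomes at NRL 165) or around
per-gene +1 summits; minus-strand windows are reversed so downstream is
rightward.  Genes whose window leaves the chromosome are dropped and
counted.  Optional per-gene-mean normalization removes depth differences
between genes; the default is off so amplitudes reflect raw coverage.
Composites are linear: the profile of a union of disjoint sets is the
n-weighted mean of the sets' profiles (tested).  The peak-shift read-out is
the difference of argmax positions (leftmost on plateaus) inside a peak
window, default 0..200 bp — the +1 region.

## Synthetic data

The generator emulates exactly the structure the analysis assumes:

- genes on regularly spaced slots (default 4 kb) with alternating strands,
  on chromosomes with a 1 kb edge margin so no fragment is ever clipped;
- a +1 dyad at TSS + 60 bp (a typical yeast-scale offset; configurable, not
  a biological claim) and k = 0..7 further dyads at multiples of the NRL
  (default 165 bp);
- observed dyads ~ Normal(true, fuzziness_sd = 20 bp), rounded;
- fragment lengths ~ Normal(151, 6) rounded and *rejection-sampled* into
  [120, 200] (rejection, not clipping, keeps the distribution shape
  unbiased), so the 140–160 filter keeps the analytic normal mass (tested
  against the closed-form CDF);
- a background fraction (default 5%) of fragments uniform over the genome;
- condition effects at a configurable gene subset: all dyads displaced
  downstream by `plus1_shift` and the array re-phased with `nrl + nrl_delta`.

The default depth (505,263 fragments) gives ~300 signal fragments per
nucleosome for the default 200-gene genome — the reference condition used
by the recovery tests and the acceptance script.  Replicates share the
truth and differ only by derived seeds (np.random.SeedSequence spawn keys,
kept below 2³¹).

What the generator does *not* emulate — MNase sequence bias, variable
occupancy and fuzziness across genes, di-nucleosome fragments, overlapping
or nested genes, non-uniform gene spacing, chromatin domains — bounds what
passing tests prove: parameter recovery shows the pipeline is correct and
well-calibrated under its own model assumptions, not that those assumptions
hold in any particular organism.

## Degenerate inputs and tie-breaks

Empty fragment files yield empty (logged) streams; depth 0 is a valid
simulation; an empty gene set or NRL set is an explicit error; a track of
zeros produces no calls (height floor becomes +∞).  All ordering ties —
plateau summits, equal heights, equal offsets — resolve to the smaller
coordinate, making every stage deterministic.  Rerunning the pipeline with
the same YAML config reproduces byte-identical outputs; the manifest
records a SHA-256 checksum for every file.

## Problem sizes

The test-suite and the acceptance script run simulations of 10–200 genes at
~300 fragments per nucleosome (0.2–2 Mb genomes, ≤ 0.5 M fragments per
sample), chosen as the smallest scale at which the recovery targets
(±3 bp mean shift, ±2 bp NRL, ≤1% null false positives) are comfortably
inside the estimators' sampling noise.

## Full-scale reproduction recipe (real data)

For the deposited yeast dataset (GEO accession GSE205956): download the
paired-end FASTQs, align to sacCer3 (R64-1-1) with Bowtie2
(`-X 500 --no-discordant --no-mixed`), name-sort, and feed the BAMs to
`nucorg dyads` with defaults (140–160 bp, rDNA exclusion BED for
chrXII:451000–469000, subsample 5,000,000, extend 50), then `nucorg call`,
`nucorg shifts` (reference = WT, threshold 10) and `nucorg nrl` per strain.
This package intentionally stops at the aligned-fragment boundary, so the
alignment step is external.
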