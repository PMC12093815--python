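# nucorg

Nucleosome organization analysis for paired-end MNase-Seq, built for
studying chromatin remodelers in budding yeast — in particular, ISWI-family
complexes (such as ISW2) that position the +1 nucleosome at their target
genes and set the spacing of the downstream array.

Micrococcal nuclease digestion protects nucleosomal DNA; sequencing the
protected mono-nucleosome fragments and taking each paired-end fragment's
midpoint estimates the nucleosome *dyad* (the central base pair).  From
there this package answers three questions a remodeler-mutant experiment
asks:

1. **Where are nucleosomes?**  Dyads from 140–160 bp fragments are extended
   ±50 bp into a coverage track; summits are called from a Gaussian-smoothed
   track (bandwidth 15 bp) by greedy height-ranked selection under a hard
   110 bp minimum-distance constraint.
2. **Does the mutant move the +1 nucleosome?**  For each gene, the +1 is the
   called summit with the smallest transcript offset in a window of −30 to
   +250 bp around the TSS (downstream positive on both strands).  The per-gene
   shift is Δ = offset(mutant) − offset(reference); a gene is classified
   remodeler-*dependent* when Δ ≥ 10 bp downstream in **every** replicate.
3. **Does it change the repeat length?**  The nucleosome repeat length
   (NRL) per gene is the OLS slope of summit offset against nucleosome index
   over the +1..+k array (4 ≤ k ≤ 8); gene-set NRL distributions are compared
   between strains with a two-tailed Welch's t-test on per-replicate mean
   NRLs.

TSS-anchored composite profiles over gene sets (with peak-shift read-out)
and per-locus bedGraph excerpts cover the usual figure panels.

A fully seeded synthetic fragment generator produces toy genomes with
phased nucleosome arrays (configurable +1 offset, NRL, positional
fuzziness, fragment-length law, uniform background) plus ground-truth
sidecars, so every stage is verified by parameter recovery — no downloads
needed.

## Worked example

Simulate a two-condition experiment in which 2 of 8 genes carry a 24 bp
downstream +1 shift, then run the whole pipeline from one config:

```bash
cat > run.yaml <<EOF
output_dir: demo_out
seed: 3
simulate:
  n_genes: 8
  chrom_length: 60000
  depth: 20000
  replicates: 2
  effect_genes: [gene_0002, gene_0005]
  plus1_shift: 24
EOF
nucorg run --config run.yaml
```

prints (abridged):

```json
{
  "n_dependent": 2,
  "n_genes": 8,
  "n_samples": 4,
  "n_unclassified": 0,
  "peak_shifts_bp": {"all": 6, "dependent": 30},
  "welch": {"dependent": {"t": -0.0289, "df": 1.01, "p": 0.982}, ...}
}
```

Both injected genes — and no others — are classified dependent
(`n_dependent: 2`).  The composite +1 peak over the two dependent genes
moves ~30 bp (the injected 24 bp plus argmax noise at this tiny gene count;
at the reference scale of 50 effect genes the read-out is 24–26 bp, see
below), while the all-gene composite moves only 6 bp because 6 of 8 genes
are unshifted.  The Welch p ≈ 0.98 correctly reports no NRL difference —
none was injected.
`demo_out/` contains per-sample dyad tracks (bedGraph), nucleosome calls,
the per-gene shift table (`shifts.tsv`), the dependent-gene BED, per-gene
NRL tables with boxplot summaries and Welch results, composite profiles
(TSV + PNG), and a `manifest.json` with a checksum for every output.
Reruns with the same config are byte-identical.

Each stage is also exposed separately (`nucorg simulate | dyads | call |
shifts | nrl | composite`), e.g.:

```bash
nucorg dyads --fragments wt_rep1.bed --chrom-sizes chrom.sizes \
    --min-len 140 --max-len 160 --subsample 5000000 --seed 7 \
    --extend 50 --out wt_rep1.bedgraph
```

## Layout

- `src/nucorg/simulate.py` — synthetic genomes, truth tables, fragment BEDs
- `src/nucorg/fragments.py` — BED/BAM ingestion, size selection, region
  exclusion (e.g. rDNA), seeded subsampling
- `src/nucorg/tracks.py` — extended-dyad coverage; bedGraph/wig/bigWig IO
- `src/nucorg/calling.py` — smoothing + constrained summit selection
- `src/nucorg/shifts.py` — +1 assignment, shifts, all-replicates rule
- `src/nucorg/nrl.py` — per-gene NRL regression, set summaries, Welch test
- `src/nucorg/composite.py` — composite profiles, peak shifts, locus excerpts
- `src/nucorg/pipeline.py` / `cli.py` — YAML-driven orchestration and CLI
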