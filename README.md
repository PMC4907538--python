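# ihscape

Analysis of chromatin heterogeneity inside **intercalary heterochromatin
(IH)** — the large, late-replicating, gene-poor repressed domains embedded in
the euchromatic chromosome arms of *Drosophila*. Starting from a four-state
chromatin map called on 200 bp fragments (**aquamarine** = open/regulatory,
**lazurite** = gene bodies, **malachite** = transitional, **ruby** =
repressed), the package builds chromatin domains, classifies IH malachite
into *border* and *internal* subclasses, tests annotation tracks
(insulators, enhancers, polymerase peaks, conserved elements) for
enrichment in each chromatin type with a domain-shuffle permutation null,
and summarises expression breadth and replication-timing gradients per
class. It is written for chromatin/regulatory genomicists who want these
analyses reproducible, seedable and testable on synthetic data with known
ground truth.

## The statistical core

For one chromatin type on one chromosome of length *L*, let
*A* = {a₁…a_N} be the ordered domain lengths and *S* = {s₁…s_{N+1}} the
inter-domain spacer lengths (s₁ from the chromosome start, s_{N+1} to the
chromosome end), so Σa + Σs = L exactly. The null model permutes the order
of *A* and the order of *S* independently and lays the lengths out as
s a s a … s: domain positions are randomised while both length
distributions and L are conserved every iteration. With a fixed track *T*
and statistic *X* = total overlap length(domains, T):

- p_enrich = #{X_null ≥ X_obs}/M, p_deplete = #{X_null ≤ X_obs}/M,
  ties counted as extreme (M defaults to 10⁶);
- if an empirical tail is exactly 0 or 1, it is replaced by the Gaussian
  tail at z = (X_obs − mean)/sd of the null sample (`method=normal_approx`);
- genome-wide: every chromosome shuffled independently per iteration,
  statistic summed.

Density ratios (observed track fraction in a class / expected fraction),
overlap profiles against reference genome partitions, expression breadth
(tissues with RPKM > 3 strictly), ≥50%-overlap probe assignment with
0.5-wide timing-score bins, and a border-distance gradient statistic
(Spearman ρ plus least-squares slope, score per kb) complete the toolkit.
`ihscape.synthetic_data` generates every input with planted truth: maps
with IH regions and the malachite-buffer rule, tracks with planted fold
enrichment, RPKM matrices with class-dependent breadth, probes with a
planted border gradient, scored peaks with per-state rates.

## Worked example

Generate a synthetic dataset and run the full pipeline:

```sh
ihscape fixtures --seed 11 --out fx
ihscape run --config fx/config.yaml --out results
```

`results/composition_ih.tsv` — composition of the 12 synthetic IH regions
(ruby-dominated, as in the real map):

```
     state      bp  fraction
aquamarine    3400  0.002703
  lazurite   22800  0.018128
 malachite  145000  0.115285
      ruby 1050800  0.835456
       gap   35756  0.028428
```

`results/shuffle_tests.tsv` — the fixture set plants a 5-fold
insulator-track enrichment inside aquamarine and a null enhancer track;
the shuffle test (M = 2000 here) recovers exactly that:

```
             track      state  observed  null_mean  p_enrich  p_deplete        method  density_ratio
     enhancer_null aquamarine   18258.0 18106.7775    0.4675     0.5325     empirical         1.0084
     enhancer_null  malachite   42740.0 40016.0855    0.2330     0.7670     empirical         1.0681
insulator_enriched aquamarine   90786.0 24378.4500   5.0e-115    1.0000 normal_approx         3.7240
insulator_enriched  malachite   40778.0 53817.9975    0.9995     0.0005     empirical         0.7577
```

The planted track is overwhelmingly enriched in aquamarine (empirical p hit
0/M, so the Gaussian tail reports 5×10⁻¹¹⁵) and correspondingly depleted
from malachite; the independent track sits squarely in the null. Note the
density ratio against the genome-wide baseline reads 3.7, not 5: with
aquamarine ~8% of this genome the baseline itself absorbs part of the
planted excess (see `docs/methods.md`).

`results/timing_gradients.tsv` — the planted replication gradient
(score falling 0.02 per kb of border distance, noise sd 0.2) is recovered
per region:

```
region  n_probes  spearman_rho  slope_per_kb  slope_se
  IH01       243       -0.8860       -0.0217    0.0007
  IH02       181       -0.7817       -0.0194    0.0012
  IH03       248       -0.8919       -0.0196    0.0007
```

Per-region JSON "passports" (composition, border/internal malachite counts,
each embedded aquamarine fragment's track co-occupancy, the gradient) land
in `results/passports.json`, and `results/run_log.json` records the seed,
iteration count and every flag that resolves a methodological choice.

The same analyses run on real data by pointing `config.yaml` at a fragment
map (BED4: chrom, start, end, state; legacy cyan/blue/green/magenta labels
accepted), IH region list (BED4 with band names), chromosome sizes,
reference partitions, and BED tracks; `ihscape shuffle-test` exposes the
permutation test alone.

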