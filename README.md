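# scn3c

Processing, bias quantification and normalization of genomic 3C
(Hi-C-class) chromosomal contact maps, with a modified ROC test for the 3D
colocalization of genomic features and a fully seeded synthetic-library
generator for validation.

The package is aimed at people analyzing restriction-fragment-level
contact data — yeast-scale maps especially — who need to go from aligned
paired-end tags to a normalized, interpretable contact matrix while
keeping explicit control over every filtering and normalization step.

## What it does

3C-class protocols produce, besides the long-range contacts of interest, a
large majority of predictable byproducts and several systematic biases.
`scn3c` implements the corresponding processing chain:

1. **Restriction map** (`scn3c.restriction`): in-silico digest with a
   primary enzyme (RE1, e.g. HindIII), annotation of secondary-enzyme
   (RE2) sites, circularization arm lengths, 20 bp end-flank GC content
   and a mappability flag.
2. **Event classification** (`scn3c.events`): each mate engages the
   fragment extremity in its 3′ direction; extremity patterns separate
   self-circles (−/+ on one fragment), religations (+/− on adjacent
   fragments), two-fragment loops (−/+ adjacent) from genuine long-range
   intra/inter contacts. A filter cascade (MAPQ ≥ 30; tag-to-cut distance
   window 20–22 bp or 21–23 bp depending on the experimental condition;
   RE2 validity of the engaged extremity; byproduct removal) yields the
   events that enter symmetric contact matrices.
3. **Bias quantification** (`scn3c.biases`): binned
   reads-per-possible-interaction curves r_i = R_i/N_i for fragment
   length (fitted with the crosslink saturation law
   f(x) = A(1 − (1 − p_c)^x)), end GC content, and circularization length
   d_A + d_B (including the ~10.5 bp helical-twist ripple, estimated
   spectrally); plus the genomic-distance decay expectation fitted as a
   log-log polynomial.
4. **Normalization** (`scn3c.normalize`): Sequential Component
   Normalization (SCN) — alternate scaling of columns then rows to unit
   Euclidean norm until the matrix is symmetric and balanced — plus the
   single-pass norm-product and marginal-sum alternatives, low-norm
   fragment filtering, distance normalization, Pearson correlation maps,
   fragment binning for large genomes, and the 3×3 display blur.
5. **Colocalization ROC** (`scn3c.coloc`): among interactions touching a
   feature, ranks by normalized score and measures whether
   feature–feature pairs concentrate at the top (AUC above 0.5 ⇒
   colocalization). On raw maps, fragments with globally inflated
   coverage fake this signal; after SCN they do not.
6. **Synthetic libraries** (`scn3c.simulate`): seeded toy genomes with
   planted restriction sites and a forward model of the protocol —
   distance decay, event-class mixture (~80% byproducts), crosslink, GC
   and circularization acceptance biases, planted colocalization blocks —
   emitting pairs tables with ground-truth labels.

See `docs/methods.md` for the models, estimators and their assumptions.

## Worked example

Simulate a 300,000-pair library over a ~450-fragment toy genome and run
the full pipeline (the low-norm threshold is scaled down from its
deep-library default of 30 to suit this depth):

```
$ scn3c simulate --n-pairs 300000 --seed 11 -o sim
300000 pairs over 451 fragments -> sim
$ scn3c run --fasta sim/genome.fasta --pairs sim/pairs.tsv \
      --low-norm-threshold 10 -o out
pipeline artifacts in out
$ cat out/pipeline_summary.json
{
  "n_events_kept": 59370,
  "scn_sweeps_intra": 20,
  "n_retained_intra": 436,
  "scn_sweeps_inter": 4,
  "n_retained_inter": 311
}
```

Of 300,000 pairs, 59,370 survive the cascade — the rest are mostly
self-circles and religations, matching the ~80% byproduct rate such
protocols produce. The event census (`out/event_summary.json`) reads

```
{'self_loop': 0.465, 'religation': 0.219, 'adjacent_loop': 0.107,
 'long_range_intra': 0.126, 'long_range_inter': 0.084}
```

and the dense inter map balances in 4 SCN sweeps (the sparser
distance-normalized intra map takes 20). Bias profiles come from the
`bias` subcommand:

```
$ scn3c bias sim/genome.fasta sim/pairs.tsv -o biasout
$ cat biasout/fits.json
{
  "crosslink": { ... "degenerate": true },
  "periodicity": {
    "period_bp": 10.502564102564103,
    "power_fraction": 0.04648802214176502,
    "significant": true
  }
}
```

The helical-twist ripple planted by the generator is recovered at
10.50 bp. The crosslink fit is honestly flagged degenerate here: with
~2 kb fragments and p_c = 0.004/bp almost every fragment is in the
saturated regime, so this library carries no information about p_c (the
dedicated recovery study below samples lengths 100–3000 bp instead).

The normalized maps are written as dense TSV (`out/scn_intra.tsv`,
`out/scn_inter.tsv`) with JSON sidecars recording the full normalization
history.

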