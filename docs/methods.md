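# Methods

This note describes the models, estimators and design choices behind
`scn3c`, the conditions its synthetic-data generator emulates, and what the
package's validation does and does not demonstrate about real data.

## Background and data model

A genomic 3C (Hi-C-class) experiment crosslinks chromatin, digests it with
a primary 6-cutter (RE1, e.g. HindIII), ligates fragments trapped in the
same complex, re-digests with a secondary 4-cutter (RE2, e.g. MspI),
circularizes, and sequences short paired-end tags anchored ~20 bp from the
RE1 cut sites. The unit of analysis is the restriction fragment (RF): the
interval between consecutive RE1 cuts. Each RF has a low-coordinate (`-`)
and a high-coordinate (`+`) extremity. Coordinates are 0-based half-open
throughout, and all distances are measured from the enzyme's cut
coordinate (motif start + cut offset; offset 1 for A^AGCTT and C^CGG).

A mate on the forward strand reads toward the fragment's `+` boundary and
is assigned to that extremity; a reverse mate to the `-` extremity. The
extremity pattern of a pair identifies the ligation product:

| pattern | product |
| --- | --- |
| same fragment, `-/+` | self-circularized RF (loop) |
| adjacent fragments, `+/-` | religation (or undigested site) |
| adjacent fragments, `-/+` | two-fragment loop |
| anything else, same chromosome | long-range intra contact |
| different chromosomes | long-range inter contact |

The filter cascade applies, to both mates: mapping quality ≥ 30
(Q = −10·log10 p, so Q30 means a 1/1000 chance of a wrong position); tag
start within the condition window of the engaged cut (20–22 bp for
condition A, 21–23 bp for condition B); RE2 validity of the engaged
extremity (an internal RE2 cut ≥ 20 bp from the boundary); finally removal
of the three byproduct classes. Surviving long-range events accumulate
into symmetric fragment × fragment count matrices, intra and inter scopes
kept separate.

## Bias quantification

All biases are expressed as binned reads-per-possible-interaction curves:
per bin, N_i counts the possible fragments or extremity pairs, R_i the
detected reads, and r_i = R_i/N_i. Bins with N_i = 0 carry NaN, never a
silent zero.

**Fragment length.** r_i against fragment length (100 bp bins) follows the
probability that a fragment is crosslinked at least once,
f(x) = A(1 − (1 − p_c)^x), fitted by unweighted least squares on bin
midpoints (`scipy.optimize.curve_fit`, bounds 0 < p_c < 1). The fit is
flagged degenerate when the curve is saturated over the sampled range
(p_c → 1, or no variation above numerical noise): such data carry no
information about p_c.

**End GC.** The covariate of an event is the mean GC of the two engaged
20 bp end flanks; bins are 2.5% wide. N_i is the distribution of that mean
over all RE2-valid extremity pairs, computed by self-convolution of the
single-end GC histogram (a binning-level approximation of the exact pair
enumeration, which would be quadratic in the number of ends).

**Circularization length.** The circle formed at the re-circularization
step has length d_A + d_B, the summed distances from each engaged RE1
boundary to the nearest internal RE2 cut. r_i is binned at 1 bp; N_i is
again a histogram self-convolution, here of the arm-length histogram over
valid extremities.

**Smoothing and mode.** Where a smoothed ratio is needed, R_i and N_i are
each averaged over the moving window (default 21 bp) before dividing;
smoothing the raw ratio instead lets bins with one or two possible pairs
dominate. The profile mode masks windows with less than 5% of the peak
support and then refines the argmax with a parabola fitted to log r over
the contiguous region above half maximum, reporting the vertex: a smooth
efficiency peak is locally quadratic in log-length, and the vertex pools
the whole peak region instead of trusting one noisy bin.

**Helical periodicity.** The twist ripple is estimated on circle lengths
below 500 bp: subtract a 21 bp moving-average envelope, take the magnitude
spectrum of the residual (FFT zero-padded ×8 for sub-bin period
resolution), and report the strongest period in the 5–50 bp band. The
ripple is called significant when its peak carries ≥ 2% of in-band power
and exceeds 10× the in-band median; on simulated data these margins are
≥ 2× on both sides of the flat/rippled regimes.

**Distance decay.** For intra maps, r_i is computed over logarithmic bins
of the midpoint separation D_g, and a degree-8 polynomial is fitted to
log10 r against the pair-weighted mean log10 D_g per bin (midpoints bias
the fit near domain edges). Low-degree polynomials in linear space cannot
follow a heavy-tailed decay, hence log-log coordinates. The evaluator
exponentiates the polynomial — strictly positive by construction — and
clamps queries to the fitted domain.

## Normalization

**SCN.** One sweep normalizes every column to unit Euclidean norm, then
every row of the result. Sweeps repeat until max |‖·‖₂ − 1| < tol (default
1e-3) over rows and columns, then the matrix is symmetrized as (M+Mᵀ)/2.
Zero rows/columns are fatal; `filter_low_norm` (default threshold 30, the
value appropriate for a ~50M-read library — scale it down for shallow
ones) must run first. Convergence is not guaranteed for arbitrary
matrices; dense positive maps balance in 2–3 sweeps, while the bipartite
pattern of a 2-chromosome inter map provably limit-cycles and is reported
as a ConvergenceError rather than silently returned.

**Alternatives.** `norm_product` divides c_ij by ‖row_i‖·‖col_j‖ in one
pass (close to SCN on well-conditioned input, but marginal norms are not
exactly one); `marginal_sum` uses L1 marginals and yields lower-contrast
maps. Both are scale-invariant only up to one global constant.

**Distance normalization** divides each intra contact by the fitted
expectation at its D_g, exposing contacts stronger than the polymer decay
predicts; SCN applies afterwards. **Correlation maps** replace entries by
the Pearson correlation of the two interaction profiles. **Binning** sums
counts over runs of b fragments per chromosome (partial final bins kept;
mass conserved). The **blur** is exactly ten passes of the uniform 3×3
kernel of 0.05 (sum 0.45 — intensity deliberately not preserved; it is a
display convention, not an operation maps should be analyzed on).

## Colocalization ROC

Among interactions touching a feature-bearing fragment, the test asks
whether interactions whose *both* fragments carry the feature concentrate
at the top of the score ranking. Pairs are ranked by normalized score
(ties broken by fragment index for determinism), labeled positive iff both
ends carry the feature, and the curve of cumulative % negatives vs
% positives is integrated by trapezoid into an AUC. A feature whose
fragments merely have inflated global coverage scores AUC > 0.5 on a raw
map — two promiscuous fragments also contact each other more — and falls
back to ~0.5 after SCN, while genuinely colocalized features keep
AUC > 0.5 on the balanced map. Fragments carry a feature on ≥ 1 bp BED
overlap; telomere sets can be built as the last ten fragments of each arm.

## Synthetic-data generator

The generator is a forward model of the protocol over a toy genome
(default: four chromosomes totalling 900 kb, RE1 planted at ~2 kb mean
spacing for ~450 fragments, RE2 at ~250 bp; accidental motif occurrences
are scrubbed so the digest recovers exactly the planted sites). Ground
truth propensities combine D_g^−1.5 decay within chromosomes, a uniform
inter base, optional colocalization blocks (×γ when both fragments are
members) and per-fragment factors (crosslink saturation, explicit coverage
multipliers). Events draw a class from the mixture
(self-loop 0.45, religation 0.25, adjacent loop 0.10, intra 0.12,
inter 0.08 — 80% byproducts), partners from the propensities, and are
accepted or rejected by the bias factors:

* crosslink: f(L) = 1 − (1 − p_c)^L with p_c = 0.004/bp (enters the
  sampling weights);
* GC: Gaussian acceptance exp(−(gc−0.45)²/2·0.08²);
* circularization: exp(−ln²(L/500)/2·0.35²) ×
  (1 + α·cos(2πL/10.5))/(1+α), default α = 0.3. The 0.35 log-width
  reflects how steeply circularization efficiency (the J factor) falls
  away from its optimum — within a length factor of ~1.5; a much broader
  envelope would make "the optimum" meaningless at tens-of-bp precision.

Fragments without an RE2 site get a fixed depleted acceptance (0.2):
such products are observed in real libraries at reduced rates. Mate 5'
ends are placed 20–22 bp from the engaged cuts with the correct strands;
truth labels (class, fragments, extremities, circle length) ride along.
Rejection sampling (not reweighting) mimics the protocol's physical
losses; everything is driven by one integer seed and is byte-reproducible.

One emergent coupling is worth knowing: when an RE2 site sits close to a
cut, its GC-rich recognition motif lies inside the 20 bp flank, so short
circle arms have elevated end GC. The GC acceptance therefore distorts
the circle-length profile (and vice versa), exactly the kind of bias
interaction that motivates normalizing globally instead of correcting
covariates one at a time. The circularization recovery studies disable
the GC factor so they measure the circularization law in isolation.

What the generator does **not** emulate: base-level reads (coordinates
only), alignment ambiguity and repeats, chromatin-state coverage
structure, cell-population heterogeneity, duplicate pairs, or trans
ligation noise beyond the uniform inter base. Passing recovery tests
therefore show the estimators are correct and well-conditioned under the
modelled biases at realistic depth — not that real libraries contain no
further biases.

## Validation and problem sizes

`recovery.py` holds the parameter-recovery studies: refitting p_c on
Poisson-noised saturation profiles (30 bins, 25 fragments/bin, expected
counts ≥ 100), and full-generator circularization studies (2.15 Mb /
~1200-fragment genome so the 1 bp circle-length universe is densely
populated; 1.2M emitted pairs leaving ~230k long-range events after
filtering). Across seeds these return p_c within ~1%, the twist period
within 0.03 bp, and the envelope optimum within ~10 bp. The test suite
additionally checks the classifier reproduces every generator truth label
exactly, conservation identities of all profiles (ΣR_i equals the
contributing events/ends), SCN against an independent brute-force sweep
oracle run to 1e-12, the degenerate ROC cases, and the raw-vs-SCN
coverage-artifact contrast on maps whose per-cell depth matches the real
~50M-read regime (SCN cannot rescale empty cells, so very sparse synthetic
maps retain a small residual artifact that deeper maps do not).

Default sizes keep the full suite around a minute and the recovery script
a few minutes on one core: 60k-pair fixtures for event/bias tests,
100k-pair pipeline smoke runs, 200k-pair ROC maps over a 230 kb genome,
1.2M-pair circularization studies.

## Known limitations

* SCN convergence is empirical; pathological sparsity patterns
  (bipartite-like supports) are detected and reported, not repaired.
* The per-interaction bias *correction* route (dividing by expected
  values per covariate) is deliberately not implemented: the
  non-monotonic circularization ripple defeats it; only the distance
  expectation is divided out.
* The GC pair-mean universe is computed at binning resolution, not by
  exact pair enumeration.
* Mappability is an exact-duplicate 20-mer proxy, not an aligner-based
  measure, and is off by default on scrubbed toy genomes.
* `filter_low_norm`'s default (30) presumes deep libraries; shallow
  synthetic runs should scale it with depth (roughly with √mean counts).
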