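# Methods

## The estimation problem

GSTM1 and GSTT1 deletion polymorphisms are *dominant* markers: a multiplex
PCR assay shows a band when at least one functional copy is present, so the
three genotypes (+/+, +/−, −/−) collapse into two observable phenotype
classes.  With observed null-genotype proportion *f* = n_null/n in a cohort
of n unrelated individuals, the package estimates the null-allele frequency
under Hardy-Weinberg equilibrium as q = √f and p = 1 − q.

Two consequences of the dominant design are treated as first-class facts:

1. **HWE is untestable here.**  After estimating q, the expected two-class
   split (p² + 2pq vs q²) fits the observed split exactly — zero residual
   degrees of freedom.  The package therefore performs no HWE goodness-of-fit
   test; equilibrium is an *assumption* whose sensitivity is explored with
   the Wahlund simulation option (below).
2. **The estimator is biased at small n.**  E[√f̂] < √E[f̂] by Jensen's
   inequality.  The recovery experiments report the bias rather than hiding
   it; at n = 300 and q ≈ 0.35–0.65 it is below 0.003 and negligible
   relative to the SE.

### Uncertainty

The delta method gives se(q) = √(f(1−f)/n) / (2√f), with a Wald interval
truncated to [0, 1] (default level 95%).  At f ∈ {0, 1} the delta method
degenerates; the package falls back to a Clopper-Pearson bound on f,
√-transformed.  A percentile bootstrap (default B = 2000, seeded,
bit-reproducible) is available as an alternative; since individuals are
exchangeable binary calls, resampling n calls is implemented as a binomial
draw, which is exact and fast.

Simulation at the study's size (n = 300, 95% intervals, 1000 replicates)
gives empirical coverage of 0.93–0.97 across q ∈ [0.3, 0.65]; the
acceptance suite re-verifies this at every run.

## Contingency comparisons

Published surveys store (n, f) pairs, not raw counts, so comparisons first
reconstruct counts.  The default policy is nearest-integer rounding of n·f;
the reconstruction is flagged in every result (`provenance="reconstructed"`)
because rounding can move a p-value visibly for small n.  A
`exact_fractional` policy keeps n·f unrounded — admissible for the Pearson
statistic, rejected for Fisher's exact test, which is only defined on
integer tables.

The Pearson statistic is the textbook Σ(O−E)²/E on the 2×2 table with
E from the margins, df = 1, p from the χ² upper tail; the default applies
**no Yates correction**.  Reconstructed-count χ² values computed this way
bracket, but do not exactly match, the values typically printed in
frequency-survey papers (whose exact count-reconstruction conventions are
unstated); the package standardises on the transparent computation and
exposes both the Yates flag and the count policy so any convention can be
reproduced explicitly.

Fisher's exact test uses the two-sided point-probability criterion (sum of
hypergeometric probabilities of all same-margin tables no more probable than
the observed one), delegated to `scipy.stats.fisher_exact` and verified
against full enumeration on every 2×2 table with total ≤ 30 in the test
suite.  For panel sweeps the method is auto-selected by the classical
rule of thumb: Fisher when the smallest expected cell is below 5.  Fisher's
conditional p-value tracks the *continuity-corrected* χ² p far more closely
than the uncorrected one (about 1e-3 vs about 0.014 discrepancy on a
balanced n = 1000 table), which is the expected asymptotic behaviour.

No multiple-testing correction is applied by default — each comparison is
reported as a stand-alone two-population test, matching how such surveys are
conventionally read — but Bonferroni and Benjamini-Hochberg columns are
available behind a flag (via statsmodels).

## Nei identity and distance

Per locus, I = (p₁p₂ + q₁q₂) / √((p₁² + q₁²)(p₂² + q₂²)) and D = −ln I.
Profiles are always derived from *allele* frequencies (q = √f), not genotype
frequencies: the two conventions differ in the fourth decimal, and the
allele-frequency convention is the one consistent with deriving q before the
distance step.  Multi-locus D is the arithmetic mean over loci with data on
both sides; loci missing on either side are excluded and listed in the
result.  D = +∞ (opposite fixation, I = 0) is represented explicitly,
excluded from averages with a warning, and rejected by MDS/UPGMA with an
instruction to drop the offending population — silent clamping would
manufacture geometry that the data cannot support.

For biallelic profiles the denominator of I is ≥ 1/2, so I is always well
defined, and I = 0 only at opposite fixation.  D is monotone in |q₁ − q₂|
along one side of a fixed profile (verified on a grid in the tests).

## Classical MDS

Torgerson scaling: B = −½ J D² J with J the centering matrix,
eigendecomposition of the symmetrised B, coordinates = eigenvectors ×
√eigenvalues for the top k non-negative eigenvalues.  Nei distance matrices
are generally non-Euclidean; negative eigenvalues are reported as a
`negative_inertia` diagnostic and never used, and k is capped at the count
of positive eigenvalues (tolerance n·max|λ|·ε).  Axis signs are fixed by
orienting each axis so the first-listed population is non-negative, making
coordinates deterministic.  The reconstruction error (Frobenius norm of the
residual between input distances and embedded distances) quantifies how much
the 2-D picture distorts.

## UPGMA

Hand-rolled agglomerative average linkage, chosen over a library call to pin
down two conventions the output format depends on:

* **tie-breaking** — among minimal-distance pairs, the pair whose smallest
  member labels sort lexicographically first is merged, so the dendrogram is
  a deterministic function of the labelled matrix;
* **heights** — the merge height is *half* the inter-cluster distance, so
  the cophenetic distance between two leaves equals the cluster distance at
  which they were joined.

The inter-cluster update is the size-weighted average, the defining UPGMA
rule.  Correctness is cross-checked in the tests against
`scipy.cluster.hierarchy` (linkage + cophenet) on random matrices, and
ultrametricity (the two largest cophenetic distances of any leaf triple are
equal) is asserted as a property.  Newick serialization orders children by
smallest leaf label and writes branch lengths as height differences.

## Synthetic cohorts

The generator models the study design: one-generation admixture of ≤ 3
ancestral sources with stated weights, followed by random mating, so the
cohort is at HWE at the mixed frequency q_mix = Σ w·q_source and each
individual is null at a locus with probability q_mix², independently across
loci (the loci are treated as unlinked, mirroring how such surveys analyse
them even when physically co-located).  The default study spec uses n = 300,
European/Amerindian/African weights 0.60/0.24/0.16 (genome-wide ancestry
estimates typical of urban Venezuelan cohorts) and ancestral allele
frequencies HWE-derived from representative panel rows (European GSTM1/GSTT1
null-genotype frequencies 0.50/0.18; Amerindian 0.40/0.00, i.e. a
functionally fixed GSTT1; West African 0.23/0.36).

What the generator does *not* emulate: linkage/haplotype structure between
loci, drift over multiple generations, selection, genotyping error, and
relatedness between individuals.  Passing recovery tests therefore show the
estimator is correct *under its own assumptions*, not that real cohorts meet
them — which is exactly why the Wahlund variant exists: drawing each
individual's source before mating inflates the null-genotype fraction to
Σ w·q², and the √-estimator then overestimates q_mix (e.g. 0.407 vs a true
0.351 at GSTT1 under the default spec), quantifying the cost of hidden
structure.

## Presentation and rounding

All computation is full precision; rounding happens only in the report
layer.  Percentages and genotype frequencies round half-up (2 and 4
decimals).  Allele frequencies print with q *truncated* at 4 decimals and p
as the complement of the printed q — the convention under which the printed
pair always sums to 1 and which reproduces the conventional table strings
for this cohort (q = 0.6218/p = 0.3782 and q = 0.5715/p = 0.4285, where
independent half-up rounding would print 0.6219/0.3781 for GSTM1).  The
one-ulp ambiguity between these conventions is inherent to reading published
4-decimal tables.

## Problem sizes and defaults

| parameter | default | why |
|---|---|---|
| CI level | 0.95 | field convention |
| bootstrap B | 2000 | percentile CI stable to ~0.001 at n = 300 |
| count reconstruction | round_nearest | only integer policy valid for both tests |
| expected-count rule | Fisher if min E < 5 | classical rule of thumb |
| MDS k | 2 | plotting; capped by positive spectrum |
| recovery replicates | 1000 | binomial SE on coverage ≈ 0.7% |
| generator n | 300 | the study cohort size |

The acceptance suite exercises the full enumeration sweep (46 375 Fisher
tables), 1000-replicate coverage at n = 1000 for three allele frequencies,
and a complete double pipeline run for byte-identical determinism; the whole
suite runs in under a minute on one core.

## Known limitations

* Published distance tables for these markers are frequently not
  reproducible from the stated formula and the published frequencies (the
  packaged panel supports exact reproduction of the study-vs-Portugal GSTM1
  cell, 0.0003, but most other published per-locus D values are mutually
  inconsistent with any monotone frequency distance).  The package computes
  the stated formula transparently and leaves reconciliation to the reader.
* Reconstructed-count tests inherit the rounding of published frequencies;
  p-values from them are approximate and flagged as such.
* Two-locus analyses assume independence; co-located deletions may violate
  this, and the combination table plus the independence property test are
  the only guardrails.
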