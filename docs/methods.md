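# Methods

## Model and assumptions

The central object is a rooted, dated phylogeny with branch lengths in
millions of years. Extinctions are modelled as independent Bernoulli events
per species over a fixed horizon, with probabilities given by a named
category → probability map; the built-in `IUCN50` map assigns 50-year
probabilities LC = 0.00005, NT = 0.004, VU = 0.05, EN = 0.42, CR = 0.97.
Under independence, a branch of length `L_b` is lost iff every tip below it
goes extinct, so

```
expPD = Σ_b L_b (1 − Π_{i below b} p_i),   PDloss = (PD − expPD)/PD ∈ [0, 1].
```

The computation is vectorized through a branch × tip incidence matrix and
log-space products; `p = 0` is mapped to a log value whose exponential
underflows to exactly zero, so boundary cases (`p ≡ 0 → PDloss = 0`,
`p ≡ 1 → PDloss = 1`) are exact. Alternative probability maps (other
horizons or more pessimistic calibrations) are supplied as JSON; they are
validated to lie in [0,1] and warned about if non-monotone over the
category order.

**Stem convention.** A clade's subtree excludes the stem branch above its
most recent common ancestor: clade PD sums branch lengths strictly inside
the clade. Including the stem would let a single surviving species retain
it and systematically deflate clade-level loss. Polytomies are allowed
everywhere and never resolved; zero-length branches contribute nothing.

**Data-deficient species** are resolved before any probabilistic step by an
explicit scenario: dropped (`exclude`, the default), or recoded wholesale as
LC or CR to bracket the possible impact of missing assessments.

## Permutation tests

All permutation p-values use `(1 + count)/(1 + n_perm)`, so 200 permutations
bottom out near 0.005 and 999 near 0.001. PDloss is nonnegative, so a naive
"|statistic| at least as large" rule could only ever detect excess loss; the
two-tailed procedure therefore centres on the null mean and compares
absolute deviations, reporting the deviation's sign as the direction. A
clade losing *less* than random expectation is a genuine, reportable
finding (species-rich clades whose risk is spread thin), which the centred
construction recovers. The probability vector is shuffled across **all**
tips even for clade-level statistics — the hypothesis is "risk is
independent of phylogeny", not "risk is exchangeable within this clade" — a
within-clade shuffle is available behind `scope="within_clade"`.
Single-species clades fall back to their pendant branch (the statistic is
then the species' own extinction probability), with a warning.

## Distinctiveness indices

ED divides each branch equally among the tips below it; ES divides by the
child count at each node passed descending to the tip (the generalization
of halving to polytomies). Both are apportionments of total branch length,
so each sums to PD — asserted to 1e−9 on every generated fixture. The QE
originality weights maximize Rao's quadratic entropy `w'Dw/2` on the
patristic matrix over the probability simplex. Tree metrics are
conditionally negative definite, so the objective is concave on the
simplex; an active-set method solves the KKT system `(Dw)_i = λ` on the
support (tolerance 1e−9), removing negative weights and re-admitting
violating species until optimal. At the optimum all supported species have
equal expected distance to the weighted assemblage. Duplicate zero-distance
tips make the system singular; the least-squares solve then splits their
weight arbitrarily, which is harmless for the objective value. The
simplex-optimal-weight reading of QE originality is one of several in use;
it is the one implemented here and tested against a grid-search oracle.

Risk correlations are Spearman with midranks on both sides — the standard
treatment when one variable has only five levels — and are reported as
not-computable when either side is constant.

## Ordination

DPCoA: species affected by at least one threat are embedded by weighted
principal coordinates of their pairwise distances, each threat is placed at
the centroid of its species, and the principal axes of the centroids are
extracted with threats weighted proportionally to the number of species
they affect (down-weighting rare threats such as geological events).
Eigenvalues decompose the between-threat share of Rao's quadratic entropy,
which the tests verify against a direct computation of the between-group
term. Patristic distances are square-root transformed by default — any
tree metric becomes Euclidean-embeddable under the square root, so the
embedding never fails on valid input — with a Cailliez additive correction
available (`transform="cailliez"`) and a hard error, rather than silent
truncation, if a user-supplied matrix is not embeddable. Axis signs are
fixed by making the largest-magnitude loading on each axis positive.

Correspondence analysis delegates to scikit-bio's implementation and
re-expresses both clouds in principal coordinates; total inertia equals the
Pearson chi-square over the grand total (checked to 1e−10). Land-only and
marine-only analyses are column subsets of the same threats × areas table,
selected in the pipeline config rather than via separate code paths.

## Threat-diversity statistics

Phi is the product-moment correlation of binary occurrence vectors;
constant vectors yield missing entries rather than a crash. Moran's I uses
`I = (n/ΣW)·(z'Wz)/(z'z)` with mean-centred `z`; under a free shuffle its
null expectation is `−1/(n−1)`, which the uniform-weight case attains
exactly and the tests verify empirically for arbitrary weights.

Default proximity structures: phylogenetic `w_ij = (d_max − d_ij)/d_max`
from patristic distances; geographic and habitat proximities are Jaccard
similarities of label sets. Any user-supplied symmetric nonnegative matrix
with zero diagonal is accepted.

**Restricted permutations.** The structure-corrected tests need null
arrangements that respect a proximity matrix. The sampler processes values
in random order and places each at a free position with probability
proportional to `1 + strength × s`, where `s` is the proximity-weighted
mean similarity (1 − normalized rank distance) of the value to those
already placed. With uniform proximities every placement weight is equal
and the scheme reduces *exactly* to free permutation, which the tests check
by total-variation distance on an exhaustive small case. `strength`
defaults to 1; the generalized-permutation idea admits many weighting
schemes, and this one was chosen for being samplable, exactly reducible in
the uniform case, and empirically level-holding (the 1,000-replicate
calibration in the acceptance suite).

The mean-shift test between adjacent risk categories enumerates all label
assignments exhaustively when their number is at most 10^6 and no proximity
correction is requested (the "exact" regime; `T` is the mean difference
standardized by the enumeration's standard deviation), otherwise it draws
`n_perm` Monte-Carlo (optionally restricted) assignments. Directional
hypotheses (threat diversity increasing with risk) default to one-tailed;
every test exposes a `tail` option.

## Synthetic data

The generator is the package's study-condition definition, not a tuning
surface. Defaults: 300 species; pure-birth tree with imbalance 0.3 (the
split lineage is the newest with that probability — real mammal trees are
heavily unbalanced, and the knob spans Yule to near-caterpillar); per-threat
prevalences between 0.02 (geological events) and 0.30 (harvesting) roughly
graded like Red List threat frequencies; liability-threshold threats with
signal 0.5 (liability = √h · standardized Brownian motion + √(1−h) · white
noise, thresholded at the prevalence quantile — a single interpretable
signal knob, which a discrete gain/loss Markov model would not give);
proportional-odds risk with slope 1 around a baseline category mix of
0.69/0.06/0.12/0.08/0.05 (roughly the assessed-mammal mix: a quarter
threatened, most LC); DD fraction 0.15; 8 areas and 6 habitats assigned
from clade- and threat-linked multinomials, 2 labels per species. "Orders"
are the k deepest disjoint subclades covering all tips (k = 8 by default),
so clade-level tests always have material.

What the generator does *not* emulate: real taxonomic structure, spatial
contiguity of areas, assessment dynamics, or correlated extinctions.
Passing tests therefore demonstrate correctness of the estimators and
calibration of the tests under the stated model, not fidelity to any real
Red List dataset.

## Problem sizes and numerical choices

The calibration experiments use 1,000 replicates of 24–30-species trees
with 99 permutations per test (the smallest `n_perm` at which 0.05 is
exactly attainable under the add-one convention), and direction-recovery
uses 150 replicates at 80 species; the oracle comparison for expected PD
uses 2×10^5 Monte-Carlo draws (agreement required within 3 standard
errors), and the QE grid search runs at resolution 0.01 on the 5-tip
simplex. Eigenvalue cutoffs for retained ordination axes are 1e−10
relative; proximity symmetry is required to 1e−12. Species present in
tables but absent from the tree are dropped with a logged warning (exact,
case-sensitive matching after trimming whitespace).

## Known limitations

- Extinction independence is a first-order assumption; spatially or
  phylogenetically correlated extinction scenarios are out of scope.
- The restricted-permutation null is approximate for strongly informative
  proximities; its exactness holds in the uniform limit and its level was
  verified empirically under the generator's null, not proved.
- QE weights on trees with many near-duplicate tips are non-unique up to
  weight-splitting among duplicates.
- The correspondence analyses treat species–area records as independent
  counts; a species in several areas contributes once per area.
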