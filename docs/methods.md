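# Methods

## Model

CONCUR tests the aggregate association between rare CNVs and a phenotype
in the kernel machine regression

    g(mu_i) = beta0 + X_i' betaX + h(Z_i),

where `Z_i` is individual *i*'s CNV matrix (dosage, chromosome, start,
end per event), `g` is the identity (continuous traits) or logit link
(binary traits), and `h` is an unspecified function whose vector over
individuals is treated as a random effect with covariance `tau * K`.
Testing "no CNV effect" is testing the variance component `tau = 0`.

### Profile curves and the cAUC kernel

Each individual's duplication and deletion events on a chromosome define
two piecewise-constant curves: each event contributes amplitude
`|d - 2|^c` on its interval (amplitude 1 for categorical DUP/DEL codes),
and overlapping same-type events of one individual sum. The kernel entry
for a pair of individuals is the integral of the pointwise minimum of
their same-type curves, summed over chromosomes and both event types —
the common area under the curves. Degenerate and edge cases follow from
the definition: zero-CNV individuals have identically zero curves and
zero kernel row/column (diagonal included); events of opposite type never
contribute to the same curve; the diagonal is each individual's own curve
area; and `K[i,j] <= min(K[i,i], K[j,j])`.

Conventions:

- **Coordinates.** Intervals are half-open `[bp1, bp2)`, so event length
  is `bp2 - bp1` and the counting measure over integer basepair positions
  coincides with ordinary length arithmetic. Single boundary points carry
  no area; this is a measure-zero difference from a closed-interval
  indicator and cannot change any kernel value.
- **Dosage modes.** `integer` calls d > 2 duplication and d < 2 deletion;
  `continuous` uses platform thresholds (defaults: duplication at >= 2.3,
  deletion at <= 1.7); `categorical` uses literal DUP/DEL codes with unit
  amplitude (numeric values are binarized by the integer rule). The
  transform exponent `c` defaults to 1; `c = 0` turns curves into
  presence indicators, `c > 1` up-weights high-magnitude events.
- **Computation.** The n x n kernel is assembled by cutting all events of
  one chromosome and type into elementary segments at every distinct
  endpoint; a segment of length L with carrier amplitudes a_i adds
  `L * min(a_i, a_j)` to each carrier pair. This is algebraically
  identical to the pairwise merged-breakpoint sweep (`cauc_pair`) and to
  the per-basepair brute force, and both identities are asserted in the
  test suite. Entries are exact integers when coordinates and dosages are
  integers and c = 1.

### Score test

With null-model residuals `r = Y - mu0_hat`, the score statistic is
`T = r'Kr / 2` (binary) or `T = r'Kr / (2 sigma2_hat)` (continuous, with
`sigma2_hat = RSS / (n - r - 1)` so the weights below are free of sigma).
Null fits are ordinary least squares, or logistic IRLS run to a relative
deviance change below 1e-10 (at most 50 iterations), with rank and
single-class checks up front.

Two null references are implemented:

1. **Projection weighted chi-square (asymptotic).** T is asymptotically
   `sum_l lambda_l chi2_1` with `lambda` the nonzero eigenvalues of
   `(1/2) P0 K P0` (continuous; `P0` the residual projection) or
   `(1/2) P0 K` (binary; `P0 = V - V X (X'V X)^-1 X' V`,
   `V = diag(mu0(1-mu0))`, computed in a symmetric congruent form).
   Eigenvalues below 1e-10 of the largest are discarded. Tail
   probabilities invert the characteristic function (the classical
   Davies/Imhof integral) with the oscillatory tail handled by
   QUADPACK's Fourier-weight rule, giving ~1e-10 absolute accuracy; a
   Kuonen saddlepoint and a Liu moment approximation are recorded
   fallbacks ("davies" / "saddlepoint" / "moment" in the result).
2. **Conditional permutation moments (default in `concur_test`).** The
   permutation distribution of T over rearrangements of the observed
   residuals is the exact conditional null for exchangeable residuals
   (binary intercept-only models; case-control samples condition on the
   case quota). Its first three moments are computed exactly in closed
   form from O(n^3) graph invariants of K (edge, triangle, path, star,
   cherry and matching sums — formulas verified against exhaustive
   permutation enumeration at small n) and matched with a Pearson
   type-III curve. This matters for rare-CNV kernels, whose large
   diagonal is permutation-invariant: the unconditional reference then
   badly overstates the variance of T in case-control samples (we
   measured essentially zero rejections at nominal 0.05), while the
   conditional reference is calibrated. When the conditional moments are
   degenerate the projection path is used.

Holm's step-down adjustment is applied across regions within one
invocation. The permutation negative control reruns the test on B
permuted trait vectors against a once-computed kernel.

## Simulation framework

Observed CNVs are cut into segments at every endpoint, so each carrier
has a constant dosage within a segment. Design matrices code presence
(categorical) or `|d - 2|` (continuous) and segment length in kb. A
case-control phenotype is drawn from

    logit P(Y=1) = gamma0 + betaX X + sum_j beta_j^Dup Z^Dup_ij + ...
                   + sum_j beta_j^Dup*Len Z^Dup_ij Z^Len_ij + (Del terms),

with `X ~ Bernoulli(0.5)`, `beta^Len = 0` (length modifies dosage effects
rather than acting alone), `gamma0 = -2`, `betaX = log 1.1` (baseline
disease rate 0.124, i.e. "roughly 0.12"; `gamma0 = -3` gives 0.0496).
Causal segments are drawn without replacement among segments containing
the event type, restricted to at least the median length of that type's
segments, and signed by a deleterious/protective percentage mix. Effect
sizes are a single shared log-OR magnitude per scenario — per carried
segment for dosage signals, per kb for dosage x length signals.
Case-control sampling draws exact quotas from a simulated population
sized ~1.4x the quota requirement (doubling on the rare shortfall).
Endpoint-error injection shifts each endpoint by
Uniform(-f L, +f L), f = 0.025 by default, on an analysis copy only —
phenotypes always come from unperturbed data.

### Synthetic cohorts

- **Integer-dosage rare-CNV style ("TGP-like").** 300 recurrent,
  non-overlapping loci placed across autosomes 1-22 proportionally to
  chromosome length; per-locus carrier frequency Uniform(0.002, 0.009),
  capped below 1% of the cohort; event lengths log-uniform on
  (102 kb, 1 Mb) with jittered endpoints; deletion dosages {1: 0.9,
  0: 0.1}, duplication dosages {3: 0.9, 4: 0.1}; 45% duplication loci.
  At n = 2000 this yields ~276 chromosome-1 carriers on average (the
  reference cohort reports 291) with large across-seed spread, and ~78%
  of samples carry at least one event genome-wide.
- **Continuous-dosage style ("TWB-like").** 250 loci on chromosome 1
  (loci may overlap), deletion dosages Uniform(0.5, 1.7), duplication
  dosages Uniform(2.3, 3.4), lengths log-uniform on (20 kb, 800 kb);
  ~1420/2000 samples carry events (reference: 1432).

What the generators emulate: rarity, length scale, dosage support,
recurrent-locus overlap structure, and carrier fractions. What they do
not: linkage/haplotype structure, locus-specific frequency spectra,
calling artifacts beyond uniform endpoint error, relatedness, and the
reference cohorts' guarantee that every sample carries an event. Passing
tests therefore demonstrate statistical correctness of the method under
realistic rare-CNV geometry, not fidelity to any particular cohort.

### Problem sizes

Replicated studies run at a reduced scale chosen for desk-size
reproducibility: type-I error uses 1000 replicates of 250 cases + 250
controls sampled from populations of ~2100 (the reference design used
2000 + 2000 and 5000 replicates); power uses 300 replicates per effect
size on chromosome-1-style cohorts with 20 + 20 causal segments and
effect grid (0.005, 0.02, 0.06) log-OR per kb; small-sample agreement
uses n = 40 with 50,000-draw permutation oracles.

## Numerical choices and edge cases

- All randomness flows through `numpy.random.Generator`; replicated
  scenarios spawn independent child streams per replicate from one seed.
- Curves are canonicalized (equal-value neighbours merged, zero flanks
  trimmed) so curve equality is well-defined.
- A zero kernel on the residual space, or a constant trait after
  permutation, yields p = 1 with a degeneracy flag rather than a
  mid-pipeline error; a constant continuous trait fails the null fit
  with a clear message.
- Kernel validity reporting (symmetry defect, minimum eigenvalue with
  tolerance `-1e-8 * max eigenvalue`, min-operator bound violations) is
  diagnostic and never raises.
- Region subsetting keeps whole CNVs on >= 1 bp overlap by default;
  clipping to the region union is opt-in, and a clipped record spanning
  disjoint region intervals is split. BED input (0-based half-open) is
  converted to the internal 1-based half-open convention.

## Known limitations

- The residual-permutation reference treats adjusted residuals as
  exchangeable; with strong covariate effects this is approximate (the
  projection weighted-chi-square path remains available and is used
  whenever the conditional moments degenerate).
- Sex chromosomes and mitochondria are out of scope (dropped with a
  warning on input).
- Frequency- or type-weighted variants of the common-area measure are
  not implemented.
- The weighted-chi-square inversion assumes non-negative weights, i.e. a
  PSD kernel; indefinite user-supplied kernels are surfaced by
  `validate_kernel` rather than supported in the test.
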