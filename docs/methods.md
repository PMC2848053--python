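# Methods

## Model

Each MUPT is a point **x** ∈ ℝ¹⁵ on the transformed feature scale (five
amplitude/area-like features natural-log mapped to mitigate the skew of
multiplicative physical processes; the rest on their physical scale).
Each class ω_k ∈ {Normative, NSAP} is modelled as a multivariate
Gaussian N(**m**_k, **S**_k) with prior P(ω_k). The per-MUPT
discriminant is

δ_k(x) = −½ (x−m_k)ᵀ S_k⁻¹ (x−m_k) − ½ ln|S_k| + ln P(ω_k),

the log of the prior-weighted class density with the (2π)^{d/2} factor
dropped (it is identical across classes and cancels in any argmax).
With equal priors and equal covariance determinants, argmax δ coincides
with argmin of the Mahalanobis distance r_k; the test suite property-tests
both this equivalence and the agreement of argmax δ with a brute-force
prior×density oracle.

Estimation is the standard plug-in: per-feature arithmetic means and the
sample covariance about them with divisor n−1 (unbiased, the
conventional choice for plug-in Gaussian classifiers). Full per-class
covariances are used — not pooled, not diagonal — because the
discriminant carries class-specific S_k and ln|S_k|.

Muscle-level aggregation treats a muscle study's MUPTs as conditionally
independent given the class:

* **bayes**: ln Δ_k = Σ_i δ_k(x_i). The per-MUPT δ is already a
  logarithm and is typically negative, so the joint evidence is formed
  as a sum in the log domain — mathematically the log of the product of
  prior-weighted densities, which a literal product of δ values would
  not be (and which would underflow). The shared normalisation is again
  dropped.
* **vote**: counts of per-MUPT argmax labels; the margin of each MUPT's
  discriminant is deliberately ignored.
* **mean distance**: per class, the mean of r_k over the muscle's MUPTs,
  argmin assigned. This averages *distances*, not discriminants —
  averaging δ would reproduce the bayes decision exactly (mean = sum/n),
  whereas the distance version is a genuinely different rule: it drops
  the prior and the ln|S| volume term, which makes it systematically
  favour the class with the wider covariance and is why it serves as a
  cautionary comparator rather than a recommended scheme.

The prior defaults to the uninformative 0.5/0.5 and is configurable; it
is deliberately *not* re-estimated from fold frequencies, so the
classifier encodes no assumption about class prevalence.

## Cross-validation

Muscle studies are atomic: a study's MUPTs share subject, muscle and
session, and splitting them across folds would leak test information
into training. `build_pools` walks the NSAP studies and the normative
studies separately, dealing study i of a class to pool i mod n_pools.
This keeps both classes present in every pool under imbalance. Ten pools
are the default (k-fold with k=10 has less bias than leave-one-out for
performance estimation); the count is configurable. The deal order
defaults to collection order — deterministic and reproducible — with a
seeded-shuffle option for sensitivity analysis. The experiment driver
fits per-class models on the nine training pools, scores every test-pool
MUPT, applies all four schemes, and retains every fold's models so
stability statistics can be computed afterwards. A structural test
asserts, fold by fold, that the fitted means and covariances equal those
of exactly the non-test studies.

## Evaluation statistics

*Performance* is the product of per-class accuracies: bounded in [0, 1],
monotone in each factor, and equal-weighting of classes regardless of
imbalance (an overall accuracy of 0.77 can hide an NSAP sensitivity of
0.2; the product cannot). Metrics are computed from unrounded count
ratios and rounded half-up to 3 decimals only for display.

*McNemar*: two classifiers' predictions on the same studies are reduced
to four paired counts; the discordant pairs α (first wrong, second
right) and β (first right, second wrong) give the continuity-corrected
χ² = (|α−β|−1)²/(α+β) on 1 d.f. — for α = β this is 1/(α+β), not zero —
with the two-tailed p from the upper χ²₁ tail and odds ratio α/β. The
95% CI uses the Woolf log-interval, exp(ln OR ± 1.96·√(1/α+1/β)); CI
methods vary across the literature and this one has not been validated
against an external reference, so downstream decisions should rest on
χ² and p, not the interval.

*Feature stability*: across the F folds, each feature/class has the mean
and SD (divisor F−1) of its fold-wise means, and the mean of its
fold-wise within-class SDs. ψ = (mean within-fold SD)/(SD of fold means)
is large when the location estimate is stable relative to the feature's
own spread. The between-class separation t = |μ₁−μ₂| / √((σ₁²+σ₂²)/F)
uses the mean within-fold SDs and is weighted by the d.f. the folds
introduce (F = 10 by default); it is reported as a magnitude. It ranks
features by their marginal contribution to the Gaussian classifier, not
by information content under non-Gaussian truth.

## Synthetic generator

The generator emulates the study conditions the pipeline is designed
for: 40 normative and 17 NSAP muscle studies, 30 MUPTs per study, and
per-class per-feature means/SDs on the transformed scale taken from
published reference statistics for this feature set (the packaged
defaults of `table4_defaults`). NSAP studies are mixtures: each MUPT is
drawn from the *normative* Gaussian with probability c (contamination,
default 0.3) and from the NSAP Gaussian otherwise, while the study keeps
its NSAP label — the simplest mechanism that produces normative-looking
MUPTs inside affected muscles. c is a free simulation parameter, not an
estimate of any clinical quantity.

What the generator does **not** emulate, and what passing tests on it
therefore do not show about real data: inter-feature covariance (the
reference statistics publish none, so the default covariance is
diagonal; a constant-correlation option ρ exists to exercise
full-covariance code paths, not to mimic EMG physiology),
between-subject heterogeneity within a class (all studies of a class
share one distribution), non-Gaussian skew remaining after the log
transforms, and any dependence between the MUPTs of one contraction.
Synthetic muscle-level accuracies are therefore optimistic relative to
clinical data; they are used for structural and monotonicity checks
(aggregation beats the per-MUPT baseline; NSAP sensitivity is
non-increasing in c; parameters are recovered at large n), not as
performance claims.

## Numerical choices and degenerate inputs

* Covariance regularisation: if the sample covariance is not positive
  definite (fewer than d+1 training MUPTs, or degenerate data), a ridge
  ε·(tr S/d)·I with ε = 10⁻⁶ is added, growing tenfold until a Cholesky
  factorisation succeeds, with a logged warning; identical records yield
  εI. Deterministic, scale-aware, minimal distortion.
* All discriminant algebra runs through Cholesky factorisations (no
  explicit inverses or determinants); ln|S| is cached per model.
* Ties: a per-MUPT δ tie (measure-zero for continuous features) breaks
  deterministically to the first-listed class, flagged and logged. Vote
  ties at muscle level break uniformly at random from the caller's
  seeded generator, flagged. Bayes/mean-distance exact ties break to the
  first-listed class, flagged.
* Fewer than 2 training records is an estimation error; empty score
  lists, empty tables, inconsistent study labels, unknown class
  spellings and non-finite features are each distinct, named errors.
* Table I/O: floats are written with `repr` and parsed with round-trip
  precision, so write→load is bit-exact on the transformed scale.
* The acceptance script reports metrics rounded half-up to 3 decimals
  (t statistics to 2), matching the display convention.

## Problem sizes

The packaged experiments run the emulated study conditions at full size
(57 studies × 30 MUPTs = 1710 records, 10 folds). Stochastic property
checks use 200 studies per condition (100 per class, 5 folds) and
parameter-recovery checks use ≥10,000 MUPTs per class; the whole suite
completes in a few seconds on one core.

## Known limitations

* The Gaussian assumption is structural: with real EMG features the
  transforms reduce but do not remove skew, and the bayes scheme's
  advantage over simple voting disappears when the assumed shape is
  wrong — the package reproduces that behaviour rather than fixing it
  (a non-parametric density estimate would be the extension point).
* The mean-distance scheme's Normative bias is inherent to comparing
  raw Mahalanobis distances across classes with unequal covariance
  volumes; it is retained for comparison, not recommended for use.
* Aggregation treats a muscle study as the unit; per-contraction
  aggregation within a study is not implemented.
* The McNemar odds-ratio CI method is flagged unvalidated (above).
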