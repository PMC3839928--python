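# Methods

## The model

A set of P transcripts is assayed for mRNA abundance across X agarose gel
slices; slice position x (mm) is the electrophoretic migration distance,
which decreases approximately log-linearly with transcript length L (nt):
x = a − b·ln L. The profile matrix D (P × X, nonnegative, no missing
values) collects one abundance profile per transcript.

The package models D as a sample from an *asymmetric generalized coherent
state*: a two-level distribution in which

1. each transcript's profile is an asymmetric Gaussian
   `g(x; b_p) = exp(−K(x)(x − b_p)² / 2)` centred at its peak migration
   `b_p`, and
2. the peaks `b_p` are themselves asymmetric-Gaussian distributed around an
   equilibrium migration `x0`.

The curvature `K` is a generalized Hooke's constant taking two values on
the two sides of the centre. The package's fixed convention is

    K(x) = k          for x ≤ centre,
    K(x) = k·s²       for x > centre,        k > 0, s > 0,

so the standard deviation on the greater-migration (shorter-transcript)
side is 1/s times the other side's, and the restoring force −K(x)(x − c)
is s² times stronger there. `s = 1` recovers the symmetric Gaussian,
Hermite functions, and Hooke's law exactly. The same asymmetry s is shared
by the per-transcript profiles (curvature magnitude `k_β`) and the peak
distribution (curvature magnitude `k_α`); the equilibrium `x0` is the mode
of the peak distribution.

Such a distribution has, approximately, the asymmetric Hermite functions

    ψ_q(x) = H_q(√K(x)·(x − x0)) · exp(−K(x)(x − x0)²/2)

(`H_q` the physicists' Hermite polynomial) among its eigenfunctions, with
eigenvalues proportional to a geometric series η^q. SVD identification
works backwards: decompose D, check that the leading right singular
vectors fit ψ_0..ψ_4 and the leading eigenvalues a geometric series, and
read off (x0, k, s, η).

## Identification pipeline

* **decompose** — thin SVD of D; eigenvalues λ_q = ε_q², fractions
  p_q = λ_q/Σλ, normalized Shannon entropy d = −(1/ln X)·Σ p_q ln p_q
  (0 = rank one, 1 = isotropic).
* **fit_hermite_series** — one shared (x0, k, s) maximizing the mean
  absolute Pearson correlation between the (q+1)-th right singular vector
  and ψ_q, q = 0..4. Candidate equilibria are the slice positions (2 mm
  resolution — every equilibrium such gel data can resolve is an even-mm
  value); a continuous refinement within one slice is available behind
  `continuous_x0=True`. The (k, s) search runs on a fixed logarithmic grid
  (32 points each over k ∈ [10⁻³, 10] mm⁻², s ∈ [1/8, 8]) followed by a
  Nelder-Mead refinement from the best grid point; ties break toward
  smaller x0, then smaller k, then s nearer 1. The procedure is fully
  deterministic: identical inputs give identical outputs. Singular-vector
  signs are aligned to the basis after fitting (SVD fixes them only up to
  sign). Basis functions are normalized to unit Euclidean norm on the
  grid, matching unit-norm eigenvectors.
* **fit_geometric_series** — η = exp(slope) of the least-squares
  regression of ln λ_q on q (q = 0..4); the reported correlation is
  Pearson's r between λ_q and the fitted c·η^q. Eigenvalues (squared
  singular values) are fitted, not singular values.
* **fit_profile_gaussian** — least squares of amplitude·g over a
  grid-constrained centre and continuous (k, s), for overall profiles
  (column sums of D) and single-transcript rows.
* **calibration** — x = a − b·ln L fitted to anchor points; defaults are
  the organism gel-range endpoints (human 26 mm ↔ 6,400 nt, 124 mm ↔
  500 nt; yeast 42 mm ↔ 4,500 nt, 100 mm ↔ 300 nt). Equilibrium lengths
  carry a ± uncertainty equal to half the length change across one slice
  width at x0. This two-anchor log-linear map is a deliberate
  simplification of a per-transcript regression (also supported via
  user-supplied anchors); its absolute lengths differ from maps calibrated
  on per-transcript data, which is why an 84 mm equilibrium converts to
  ≈1,400 nt here rather than the ≈1,700 nt a denser calibration yields.

### Orthogonality of the asymmetric basis

For s ≠ 1 the asymmetric Hermite functions are *not* exactly orthogonal
under the ordinary inner product (the piecewise-scaled argument breaks the
parity cancellation for mixed even/odd pairs). The package measures and
reports the Gram deviation rather than asserting it away; at s = 1.5 the
largest off-diagonal Gram entry is of order 0.1 while the basis stays
well-conditioned for correlation fitting.

### Self-consistency regime of the identification

The asymmetric Hermite functions are only approximately the eigenfunctions
of the per-centre asymmetric coherent state. Diagonalizing the exact
covariance operator of the generative model shows a systematic shrinkage:
the eigenbasis asymmetry understates the generative s (about −12% at
s = 1.3, collapsing toward 1 by s = 1.5) and the fitted equilibrium drifts
one to two slices toward the broad side. Parameter recovery in the sense
"the fitter returns the generator's (x0, s)" therefore holds only for mild
asymmetry. The synthetic study consequently uses s = 1.1, inside the
self-consistent regime; for strongly asymmetric data the fitted s should
be read as the eigenbasis asymmetry, a lower bound on the generative one.
This is a genuine limitation of eigenvector-based identification, not of
the simulator.

## Finite-population length statistics

For a set of N transcript lengths with population moments (μ, σ²)
(variance divided by N — the convention under which the closed forms below
are *exact*), three sampling-without-replacement null designs:

* **one subset** (subset of M vs the set): statistic δ = mean(subset) − μ;
  E[δ] = 0, Var[δ] = σ²(N − M)/(M(N − 1)).
* **two independent subsets** (sizes L, M, each drawn from the union of
  the two observed subsets, which may overlap): statistic is the
  difference of subset means; the null variance is the sum of the two
  one-subset variances computed on the union's moments.
* **exclusive split** (universe of M split into L and M − L): statistic is
  the difference of the two parts' means; Var = σ_M²·M²/(L(M − L)(M − 1)).

Both non-trivial variance forms are verified against exhaustive
enumeration in exact rational arithmetic (they are also related:
mean(part) − mean(complement) = (M/(M − L))(mean(part) − μ)).

The P-value is the one-sided Cantelli (one-sided Chebyshev) bound

    P ≤ Var / (Var + δ²),

applied in the direction of the observed sign of δ and depending only on
the null's first two moments. It is an upper bound: the enumerated exact
tail never exceeds it (property-tested over random small instances).
Degenerate cases: δ = 0 or zero-variance universes give P = 1. No
multiple-testing correction is applied; reports list every tested subset
so users can correct downstream. An enumeration/Monte-Carlo `null_oracle`
(exhaustive below 10⁶ subsets, seed-deterministic otherwise) provides
exact or empirical tails alongside the bound.

## Overexpression annotation and enrichment

An entity is *overexpressed* in a condition if it ranks in the top X by
abundance (per-sample descending sort, ties broken by stable input order)
in at least a fraction f of that condition's samples; f defaults to 1/5
and the comparison count/S ≥ f is exact rational, so for ten normal
samples the threshold is exactly two. Ranking is invariant to any strictly
monotone per-sample transform, so upstream normalization choices that
preserve within-sample order are irrelevant. Two conditions' calls
partition entities into mutually exclusive normal-only / tumor-only / both
subsets plus the two overalls. Enrichment of a subset of M entities in a
flat annotation term with Y members among N is the hypergeometric upper
tail Σ_{i≥y} C(Y,i)C(N−Y,M−i)/C(N,M), computed through log-gamma
(scipy) and validated against exact rational enumeration for N ≤ 100.
Raw p-values are reported; robustness is assessed by requiring an
enrichment to persist across all overexpression cutoffs rather than by
correction. GO-style annotations are treated as flat sets (no ontology
graph propagation).

## Synthetic data: what it emulates, and what it does not

All analyses run on generated data; every generator is a pure function of
(config, seed).

* **Profile matrices** — rows amplitude·g(x; b_p) with peaks drawn from
  the normalized asymmetric Gaussian (side chosen with mass ratio s:1,
  then a half-normal draw with the side's standard deviation), log-normal
  amplitudes (σ_log = 0.5), element-wise multiplicative log-normal noise
  with σ = 0.05 — matching a gel measurement precision of about 5% — and
  an optional additive floor. Human-scale study conditions: P = 4,109,
  50 slices of 2 mm spanning 26–124 mm, x0 = 84 mm, σ_α = 16 mm
  (k_α = 1/256), σ_β = 4 mm (k_β = 1/16); chosen so the five leading
  eigenvalues capture ≈0.8 of the information, as reported for the real
  human set, with η ≈ 0.7. Yeast-scale: P = 3,620, 30 slices spanning
  42–100 mm, x0 = 78 mm, σ_α = 10 mm, σ_β = 4 mm (the peak spread must fit
  the shorter yeast gel). Asymmetry defaults to s = 1.1 (see the
  self-consistency section; the printed asymmetry of the original data is
  not recoverable, so it is treated as a free parameter).
* **Length tables** — log-normal lengths (positive, right-skewed, as real
  transcriptomes are; only the first two moments matter to the statistics)
  with planted annotation subsets at the reported subset sizes and mean
  lengths (human global mean 2,480 nt, σ = 1,000 nt; yeast 1,621 nt,
  σ = 500 nt); the background mean is derived so the realized global mean
  matches the stated one despite the planted subsets' pull. Planted terms
  are disjoint, unlike real GO terms — the tested statistics see only
  counts and means, so overlap structure is irrelevant there.
* **Expression matrices** — rank-constructed values: each condition's
  planted entities occupy top-X ranks in a staggered round-robin subset of
  that condition's samples (so planted sets larger than X are legal — a
  flag needs only ≥20% of samples), and the remaining top slots rotate
  through the non-planted pool slowly enough that no decoy can reach the
  flagging threshold. Recovery of the planted flags by the annotation
  step is therefore exact by construction, which is what makes the
  annotate → partition → enrich stage testable end to end. Real
  microarray data have no such guarantee; passing these tests shows the
  bookkeeping is right, not that real calls are noise-free.

The synthetic data do not emulate probe chemistry, cross-hybridization,
band-broadening physics, correlated noise between slices, or overlapping
ontology terms; real-data correlations (e.g. the reported mean
eigenvector–Hermite correlations of 0.78–0.89) are accordingly lower than
the ≈0.99 the clean synthetic study attains.

## Numerical choices and degenerate inputs

* Inflection points of ψ_q (for the "asymmetric parabola" overlay
  K(x)(x − x0)², sampled at K·u² = 2q + 1 by the non-node inflections)
  are located by sign change of the discrete second difference on a
  100×-refined grid, ties to the lower coordinate; accuracy is limited to
  about one refined step.
* Hypergeometric tails are clipped to [0, 1] after log-space summation.
* All-zero profiles, empty subsets, M ∈ {0, N} subsets, zero eigenvalues
  inside the fitted range, and mismatched universes raise errors rather
  than returning silent defaults.
* Monte-Carlo oracles and all generators take explicit integer seeds;
  repeated runs are bitwise identical.

## Problem sizes used by the test suite and acceptance script

Recovery checks use P = 2,000 × 50 matrices over 20 seeds (the asymmetry
of an eigenbasis estimated from 2,000 rows fluctuates ≈±20% seed to seed,
so recovery is asserted on the ensemble median); enumeration oracles use
N ≤ 12 exact and 500 random instances with N ≤ 9; the expression studies
use 4,109–6,200 entities with 10 normal/529 tumor (study) or 6/6 (cutoff
sweep) samples. These sizes keep every stage exact or well-converged
while the whole suite runs in well under a minute.
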