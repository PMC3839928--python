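# translen

Identification of transcript-length distribution functions from
gel-electrophoresis profile matrices, for transcriptomics researchers
studying how mRNA length relates to gene function and to tumor gene
expression.

When mRNA from a tissue is separated by length on an agarose gel and each
slice is assayed on a microarray, every transcript traces an abundance
profile across migration distances x (mm), with x decreasing roughly as
a − b·ln L in the transcript length L (nt). This package identifies the
length distribution function of any set or subset of transcripts from such
a profile matrix D (P transcripts × X slices) by singular value
decomposition, and attaches the finite-population statistics needed to
compare subset lengths.

**The model.** The SVD of D uncovers eigenvectors (right singular vectors)
and eigenvalues λ_q = ε_q². If the leading eigenvectors fit the series of
asymmetric Hermite functions

  ψ_q(x) = H_q(√K(x)·(x − x₀)) · exp(−K(x)(x − x₀)²/2),
  K(x) = k for x ≤ x₀,  k·s² for x > x₀,

and the eigenvalues fit a geometric series λ_q ∝ η^q, then the data sample
an *asymmetric generalized coherent state*: each transcript's profile is an
asymmetric Gaussian, and the profile peaks are themselves
asymmetric-Gaussian distributed around the equilibrium x₀. The fitted
(x₀, k, s, η) summarize the set: its typical transcript length (via the
migration↔length calibration), its spread, and the asymmetry of the
restoring-force-like constraint −K(x)(x − x₀) acting on lengths.

**The statistics.** Subset length comparisons use sampling-without-
replacement nulls with closed-form variances — subset-vs-set
(Var = σ²(N−M)/(M(N−1))), two independent subsets drawn from their union,
and an exclusive split (Var = σ_M²M²/(L(M−L)(M−1))) — each bounded by
Cantelli's inequality P ≤ Var/(Var + δ²). Overexpression subsets are
defined by top-X rank in ≥20% of a condition's samples, partitioned into
normal-only / tumor-only / both, and scanned for annotation-term
enrichment with the hypergeometric upper tail.

Everything runs on synthetic data the package generates itself (module
`translen.simulate`): coherent-state profile matrices, length tables with
planted subset shifts, and expression matrices with planted top-X
structure — see `docs/methods.md` for what the generators do and do not
emulate.

## Worked example

The numbered scripts under `analysis/` run the full study over synthetic
data and write tables under `results/`:

```
$ python analysis/02_identify_coherent_states.py --seed 1
human: equilibrium 84 mm (~1415+-37 nt), s = 1.24, eta = 0.71; mean eigenvector|Hermite correlation 0.99, eigenvalue|geometric correlation 0.999, overall-profile|Gaussian correlation 0.999
yeast: equilibrium 78 mm (~838+-39 nt), s = 1.22, eta = 0.58; mean eigenvector|Hermite correlation 0.99, eigenvalue|geometric correlation 1.000, overall-profile|Gaussian correlation 0.999
```

The human-scale set's five leading eigenvectors correlate 0.99 on average
with ψ₀..ψ₄, its eigenvalues follow a geometric series with η ≈ 0.71
(correlation > 0.99), and the equilibrium sits at 84 mm — about 1,400 nt
on the two-anchor endpoint calibration, with a ±37 nt half-slice
uncertainty.

```
$ python analysis/03_subset_length_statistics.py --seed 1
human_translation_vs_global: delta = -389 nt (shorter), P <= 0.0384 [significant]
human_ribosome_vs_global: delta = -1038 nt (shorter), P <= 0.0129 [significant]
...
yeast_mms_over_vs_under_split: delta = +346 nt (longer), P <= 0.0155 [significant]
```

Protein-synthesis and mitochondrial subsets come out significantly
shorter than the global set, glucose-metabolism subsets significantly
longer than the respiratory electron transport chain, and the
DNA-damage-overexpressed transcripts significantly longer than the
underexpressed ones — the planted structure, recovered with the Cantelli
bound below 0.05.

`analysis/01_simulate_datasets.py` writes the underlying tab-delimited
data sets (under `scratch/data/`), and
`analysis/04_overexpression_enrichment.py` runs the annotation →
partition → enrichment stage, verifying the planted overexpression
subsets are recovered exactly at every cutoff.

A `translen` command-line tool wraps the same library surface
(`translen simulate|fit|lengthstats|annotate|enrich|report --help`).

## Layout

```
src/translen/     model.py (asymmetric coherent-state math, calibration)
                  svd.py (decomposition + Hermite/geometric/Gaussian fits)
                  lengthstats.py (Cantelli statistics + null oracles)
                  enrichment.py (top-X annotation, partition, hypergeometric)
                  simulate.py (seeded generators)  study.py (study conditions)
                  io.py (tab-delimited dialects)   cli.py (click surface)
analysis/         numbered narrative drivers writing results/
tests/            pytest suite (unit, property-based, acceptance)
docs/methods.md   model, assumptions, parameter choices, limitations
```
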