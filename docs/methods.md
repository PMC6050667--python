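# Methods

## Scope and model

The package quantifies synonymous codon usage bias in a set of coding
sequences and attributes it to the two observable forces of the
mutation–selection balance: mutational (compositional) pressure, which
shifts base content at all or mostly third codon positions, and selection,
which concentrates usage on particular synonyms beyond what composition
predicts. Genetic drift is not separately identifiable from composition
data and is not modelled.

All statistics assume the standard nuclear genetic code (translation
table 1). Leucine, serine and arginine are treated as single six-fold
families (never split 2+4), isoleucine is the only three-fold family, and
methionine/tryptophan are singletons excluded from the 59 informative
codons. Internally sequences are DNA (T); all reported tables use RNA
codons (U), the transcriptome convention.

## Input validation

A candidate CDS is accepted when it is ≥ 300 nt (the usual transcriptome
quality floor; tunable), a whole number of codons, free of ambiguity
characters, and free of internal in-frame stops. Rejections report the
first failed rule in that fixed order. The internal-stop rule defaults to
"none tolerated" (`max_internal_stops = 0`): the RSCU/ENC machinery assumes
clean ORFs, and a permissive override exists for exploratory use. Length
divisibility by 3 is required because codon counting is otherwise
ill-defined. A single terminal stop is allowed and stripped from all
counting. No start-codon requirement is imposed — ORF discovery is assumed
upstream — and parsing is case-insensitive with U↔T normalization.

## Statistics

**RSCU.** `RSCU_c = n_c · k / Σ_family n` for a codon in a family of size
k; undefined (flagged absent) for unobserved families. Classification
thresholds are strict: preferred > 1, highly preferred > 1.25, avoided
< 0.75. Dataset-level RSCU is the RSCU of the summed count table, not the
mean of per-gene profiles, so long genes weigh in proportion to their
codon count.

**ENC.** Wright's estimator. Per amino acid with family total m ≥ 2,
`F̂ = (mΣp² − 1)/(m − 1)`; families with m ≤ 1 are skipped (F̂ undefined at
m = 1). Class means F̄₂, F̄₃, F̄₄, F̄₆ are averaged over observed amino
acids; a missing F̄₃ (no isoleucine) is imputed as (F̄₂ + F̄₄)/2; any other
missing class or a non-positive class mean leaves ENC undefined with a
machine-readable reason (`insufficient_families`,
`nonpositive_homozygosity`). Sums above 61 — a finite-sample artefact of
near-uniform usage, since F̂ < Σπ² in expectation of its reciprocal — are
clamped to 61 and flagged. Note that exact scale invariance does **not**
hold for this estimator: multiplying all counts by k moves ENC
monotonically *down* toward the plug-in value computed from Σp² directly
(the finite-sample correction (S−1)/(m−1) shrinks). The property suite
asserts that convergence rather than a false invariance.

**Expected ENC and deviation.** `ENC_exp(s) = 2 + s + 29/(s² + (1−s)²)`
with s = GC3, sampled on the conventional grid 0.001…1.000 (1000 points)
for the plot layer. This curve is a heuristic approximation to the
pure-compositional expectation, not an exact one; its maximum sits at
s ≈ 0.502 (the `+s` term), and neutral simulations scatter around it
closely enough that the mean deviation `(ENC_exp − ENC_obs)/ENC_exp` is
statistically indistinguishable from zero at the default generator
settings. GC3 for the curve includes third positions of *all* sense codons
(Met and Trp included); a `gc3s` variant excluding the singletons is
carried in the per-gene table for sensitivity checks.

**PR2.** `x = G3/(G3+C3)`, `y = A3/(A3+U3)` over all sense codons'
third positions (a `fourfold_only` switch restricts to the fourfold
families, the classical variant where third-position changes are always
synonymous). Points exactly on an 0.5 axis are "boundary", zero
denominators "undefined"; neither enters the quadrant tallies, so
Q1+Q2+Q3+Q4+boundary+undefined = n always.

**Neutrality.** OLS of GC12 on GC3 (GC12 as response). The slope × 100 is
reported as the mutation-pressure percentage and 100·(1 − slope) as the
selection percentage; both are emitted together with slope, intercept, r²
and n, since the two-percentage summary is only as good as the linearity
of the relation.

**Dinucleotides.** Four datasets: within-codon positions 1–2 and 2–3, the
codon-bridging 3–1 pair (within a record), and all overlapping pairs of
the sense sequence. An initial ATG and the terminal stop are removed first
(start/stop usage is constrained by non-synonymous signals). Observed
frequencies are pooled over records; ratios divide by the product of the
marginal base frequencies of the two positions each dataset actually
pairs, making the ratio a pure association measure (a `global_marginals`
switch uses whole-sequence content instead; `average_records` averages
per-record frequencies instead of pooling).

**Protein indices.** GRAVY is the mean Kyte–Doolittle hydropathy;
aromaticity the F+Y+W fraction; amino-acid proportions live on the
20-simplex.

**PCA.** Column-centered, unscaled (`scale` optional) via SVD; axis signs
fixed by forcing each axis's largest-magnitude loading positive, so scores
are reproducible across row orders. Gene-level RSCU matrices impute
unobserved families at 1.0 — the no-information value with correct family
mass; 0 would encode an avoidance signal short genes cannot support —
with flags per cell and `zero`/`drop-gene` alternatives. Codon-space PCA
labels the 59 codons by ending base (A:14, U:16, G:13, C:16) and reports
per-group dispersion in the first two axes. Amino-acid PCA requests 20
axes and reports the cumulative variance of the first six.

**Expression.** FPKM rows ≤ 1 are retained but excluded from expression
analyses (the threshold is strict). GC strata default to the dataset's
per-gene GC quartiles — published leech values 41.8%/50.8% are one
dataset's quartiles, not constants — with explicit override.

## Synthetic data

The generator emulates what the analyses measure and nothing more:
composition under mutation and selection, not substitution over time.
Defaults: 2000 genes; protein length lognormal with median 300 aa
(σ = 0.45), truncated at 100 aa, matching a ~1 kb-mean CDS pool; FPKM
lognormal with ln-mean 1 and ln-σ 2 (median ≈ 2.7, ~69% of genes above
the FPKM = 1 threshold); mutational GC bias m = 0.5 (neutral); selection
s = 0. Within each family the codon weight is
`(m if GC-ending else 1−m) · exp(s_g · 1[selected ending])`, normalized —
at m = 0.5, s = 0 every family is exactly uniform, so the pooled RSCU null
is flat by construction. The effective per-gene selection is
`s_g = max(0, s(1 + c·z))` with z the gene's log-FPKM z-score and c the
expression coupling. A per-gene bias range `m ~ U(low, high)` provides the
across-gene GC3 spread regression analyses need. With
`mutation_all_positions` the bias applies to every codon position (codons
drawn over all 61 sense codons), the regime where GC12 tracks GC3 and the
neutrality slope approaches 1; in the default third-position-only regime
the slope is ~0 because GC12 is compositionally neutral.

Because amino acids are drawn independently of the codon model,
amino-acid composition is uninformative by construction; selection toward
*both* G- and C-endings is deliberately indistinguishable from
compositional bias (it renormalizes to an effective m), so the
"points below the expected curve" signature requires asymmetric (e.g.
C-only) selection — which is also what makes the simulator's preferred
set C-dominated, mirroring the empirical leech pattern.

What the generator does not emulate: real length–composition
correlations, amino-acid usage structure, isochores, splice/UTR context,
or any time-resolved substitution process. Passing tests therefore show
the *estimators* recover known generative structure, not that real
transcriptomes satisfy the generative assumptions.

## Reference fixture

The packaged RSCU table reproduces a published genome-wide profile for
*Hirudinaria manillensis* (18,000 CDSs) exactly as printed, including its
rounding residues (the leucine family sums to 6.001). As printed, GGA
(1.544) carries the largest value even though prose summaries of the same
study single out GCC (1.39); the table is preserved verbatim and the
classification is computed from it, not from the prose. Its
threshold-derived preferred set has 30 codons (A=6, U=6, C=13, G=5 by
ending base) and seven highly preferred ones — summaries elsewhere citing
"four" highly preferred codons do not match the printed values, and the
package reports only what the thresholds yield.

## Numerical choices and limitations

- Half-open binning throughout ([lo, hi)); the GC histogram's five bins
  are <30, 30–42, 42–50, 50–60, ≥60%; deviation histogram bins align to
  zero with width 0.01. The "2500 permutations" sometimes attached to
  deviation histograms has no deterministic reading; the histogram here is
  exact, with an optional seeded gene-resampling bootstrap (default 2500
  replicates) for confidence bands.
- RSCU/ENC dual-route agreement is held to 1e-9 against brute-force
  oracles; family-sum identities to 1e-9; closed forms to machine
  precision.
- Undefined values (ENC on tiny genes, PR2 zero denominators, log10 of
  FPKM 0) propagate as NaN with reasons where structured, never as
  silent drops; CLI runs log all skips and warnings.
- Correlations are plain Pearson with two-sided p-values; no multiple-
  testing correction is applied to the small default pair list.
- The per-gene expected-ENC is computed from that gene's own GC3; genes
  with GC3 = 0 get an undefined expectation rather than an extrapolated
  one.
- Test and acceptance simulations use 2000 genes (a size at which all
  stochastic checks sit far from their thresholds); smaller sizes appear
  in unit tests where only structure, not precision, is at stake.
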