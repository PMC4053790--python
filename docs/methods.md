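# Methods

This note documents the models, conventions and design choices behind
`godiverge`, in the order the pipeline applies them.

## Substitution and site counting (`codon_counts`)

Per-gene inputs to the category statistic are the four quantities
(*a*, *A*, *s*, *S*): non-synonymous substitutions and sites, synonymous
substitutions and sites.  We count them on pairwise in-frame codon
alignments with an equal-weight (Nei–Gojobori-style) scheme:

- **Sites.** Each codon position contributes (number of synonymous
  single-base alternatives)/3 to *S* and the complement to *A*; changes to
  stop codons are non-synonymous.  The two components of a codon always sum
  to exactly 3.  Site counts are averaged over the two aligned sequences
  (symmetric in sequence order).
- **Substitutions.** For codon pairs differing at *d* > 1 positions, the
  *d*! orderings of single-base steps are enumerated; orderings passing
  through a stop codon are excluded from the average (if every ordering is
  blocked, all are used, with stop-touching steps classed non-synonymous).
  Fractional averages are carried unrounded into all aggregation.
- **Column filter.** Codon columns containing a gap, an N, or a stop codon
  in *either* sequence are skipped entirely (whole-codon skip, symmetric and
  conservative); `codons_used` records the retained columns and
  *A* + *S* = 3·`codons_used` holds to 1e−9.  Genes with zero retained
  columns are flagged unusable and excluded downstream with a logged count.

This estimator deliberately replaces codon maximum-likelihood fitting
(transition/transversion and codon-frequency parameters): the category
statistic consumes only (*a*, *A*, *s*, *S*), so the estimator is swappable —
`read_counts_table` imports externally estimated per-gene counts verbatim,
and such counts need not satisfy the 3-sites-per-codon identity
(`codons_used` is then unknown).  Known property of the counting scheme:
equal-weight site definitions are unbiased only when all single-base changes
are equally likely; under transition bias the synonymous rate is slightly
overestimated.  This cancels in the category test, which compares categories
against pooled rates from the same estimator, but matters when absolute
ka/ks values are interpreted.  A Jukes–Cantor correction
(−¾·ln(1 − 4p/3), defined for p < ¾) is provided for reporting corrected
per-gene distances; the category test itself uses raw counts.

## Annotation handling and the permutation contract (`annotation`)

Gene→GO-term annotations are read from a two-column TSV (optionally filtered
to one namespace, e.g. molecular_function), restricted to the ortholog
universe, and deduplicated; unannotated universe genes carry explicit empty
sets.  Terms are assumed ancestor-propagated upstream; the GO DAG itself is
never consumed.  Categories are terms with at least `min_genes` annotated
genes (default 20 — below that the binomial tail of the category total is
too granular to rank usefully).

The permutation null re-assigns **whole per-gene term sets** to genes,
uniformly over all permutations of the universe.  Moving sets atomically
preserves (i) every term's gene count, hence the size filter, and (ii) each
gene's term co-occurrence pattern, which is how the hierarchical structure
of GO enters the data.  Permutation runs over *all* universe genes,
including unannotated ones, so annotation can land on genes of any
substitution profile.  Genes without usable substitution counts are removed
from the universe once, before permuting: they could never contribute to a
category sum, so this is behaviourally identical to per-permutation dropping
while keeping term sizes permutation-invariant (which also makes the null
vectorizable — a sparse category-membership matrix times permuted count
vectors).

## The category divergence test (`category_test`)

Genome-wide rates are ratio-of-sums over the universe (equivalent to
counting on the concatenated gene set), **not** means of per-gene ratios;
per-gene ratios are noisy and undefined at *s*ᵢ = 0, while the pooled ratio
is stable.  The expected non-synonymous proportion of a category uses these
genome-wide rates with the category's own site sums —

P_A = ka·ΣA / (ka·ΣA + ks·ΣS)

— so a category is compared against how *its own sites* would accumulate
substitutions at genome-average rates.  When the category is the whole
universe, P_A reduces algebraically to Σa/(Σa+Σs).

Both binomial tails include the observed value: rapid = P(j ≥ a_C),
slow = P(j ≤ a_C), j ~ Binomial(a_C+s_C, P_A).  Upper-tail inclusion is
forced by "equal or more"; lower-tail inclusion was chosen for symmetry.
Tails are evaluated through the regularized incomplete beta identities
P(j ≥ a) = I_p(a, s+1) and P(j ≤ a) = I_{1−p}(s, a+1), which coincide with
the direct binomial sums at integer counts and extend them continuously to
the fractional counts that pathway averaging produces (no rounding).
Degenerate P_A ∈ {0, 1} yields the point-mass tail with a warning.

No multiple-testing correction is applied per category — memberships
overlap and genes within a category share constraint, so per-category tails
are not independent tests.  Error control is global: for each direction and
threshold in {0.05, 0.01, 0.001, 0.0001}, the observed number of categories
below threshold is compared with its permutation distribution
(default 10,000 re-annotations).  The mean permuted count is the expected
number of false positives among the observed outliers; the global p-value is
the add-one estimator (1 + #{permuted count ≥ observed})/(1 + N), with the
plain proportion also reported.  Genome-wide rates are permutation-invariant
under set-preserving re-annotation, so they are computed once.  An
`exhaustive=True` mode enumerates all n! assignments on tiny universes,
making expectations exact (used by the test suite's enumeration oracle).
The alternative reading of the global test — a per-category empirical p
against the permuted P_C distribution — is deliberately not implemented;
the count-based test matches the stated null (no more outliers than randomly
composed categories would give).

The public surface is a statsmodels-style pair: `CategoryDivergenceModel`
(data + configuration) whose `fit()` returns `CategoryDivergenceResults`
(per-category table, permutation summaries, `summary()` report, p-value
histogram, file export with run metadata including seed and input digests).

## Ortholog QC (`ortholog_qc`)

A transcript mapping passes iff (a) coverage ≥ 0.80, (b) low-quality
fraction ≤ 0.10 (both boundaries inclusive, taken literally), (c) every
frame-shift indel is compensated within 15 bases, and (d) no in-frame stop
and all splice sites conserved.  Criterion (c) is operationalized as
transitive clustering: indels whose start positions lie within 15 bases are
merged (start-to-start distance; chaining allowed), and each cluster's net
signed length must be ≡ 0 (mod 3).  Clustering is order-independent and
window=0 isolates every indel.  Coverage, low-quality fraction and the
stop/splice flags are upstream-computed fields (producing them requires
whole-genome alignments, out of scope here).  Criteria are recorded
independently, so a verdict lists every failed criterion.  Per gene, the
longest passing transcript is kept, ties broken by lexicographically
smallest transcript id; ortholog records can additionally be required to
contain a given species set.  Coordinates are 0-based half-open internally.

## Likelihood-ratio tests (`selection_lrt`)

Given per-gene log-likelihoods from two nested codon-model fits run
externally, the statistic is 2·(lnL_alt − lnL_null), clamped at 0 (negative
raw differences are optimizer artefacts and are flagged), and referred to a
chi-square upper tail.  Degrees of freedom are **caller-supplied with no
default** — the appropriate df depends on which nested pair was fitted, and
silently assuming one invites wrong p-values.  The plain chi-square
reference is the default; the 50:50 point-mass/chi-square boundary mixture
(appropriate when the null pins a parameter at its boundary) is available as
an option.  Batch mode sorts ascending by p-value and flags significance at
a supplied alpha.

## Synthetic data (`simulate`)

The generator emulates a scaled-down two-species ortholog comparison with
known ground truth.  Defaults (the study conditions for all calibration and
recovery tests): 2,000 gene pairs of 100–300 codons, per-lineage synonymous
divergence dS = 0.1 (pairwise ks ≈ 0.2, a typical congeneric passerine
scale), baseline ω = 0.2 (genome-average purifying selection), transition
bias κ = 2, categories of 20 genes.  Planted-effect experiments use 50
categories over a 2,000-gene universe (1,000 annotated + 1,000 unannotated
filler, so permutation over the full universe is exercised at genome scale).

Mechanism: the ancestor is uniform over sense codons; each lineage evolves
by single-base proposals (transitions κ-weighted), synonymous proposals
always accepted, non-synonymous accepted with probability min(1, ω),
stop-creating proposals rejected.  The stopping rule is explicit: each
lineage fixes Poisson(dS·S₀) synonymous substitutions, S₀ being the
ancestor's equal-weight synonymous site count.  A proposal–acceptance scheme
was preferred over matrix exponentiation for transparency: the generative
contract (what converges to what) is asserted by tests rather than assumed
by construction.  Per-gene ω is ω₀ times the product of the multipliers of
the gene's categories (>1 rapid, <1 slow); categories may be disjoint blocks
or overlapping random draws.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic codon frequencies (F3×4), indels and
alignment error, rate variation among sites and genes beyond the planted
structure, branch asymmetry, GO's actual nested term structure (planted
terms overlap only if configured), and annotation bias toward conserved
genes.  Two quantitative caveats are tested explicitly: realized pairwise ks
sits slightly below 2·dS (multiple hits at a site are observed once), and at
ω = 0 a small fractional non-synonymous count can still be *attributed* by
pathway averaging when both lineages hit the same codon (the event-level
count is exactly zero; the artifact is bounded in tests at ≤ 2% of the
synonymous count).

## Numerical and operational choices

- Tails via `scipy.special.betainc`; agreement with direct summation is
  ≤ 1e−10 over the tested grid (a, s ≤ 200).
- Outlier counting uses strict inequality (p < threshold).
- Thresholds are scanned at {0.05, 0.01, 0.001, 0.0001}; `min_genes`,
  thresholds and permutation count are configurable everywhere, seeds are
  mandatory for every stochastic stage, and identical config+seed reproduces
  outputs byte-for-byte (staged CLI runs equal the monolithic run).
- Problem sizes used by the test suite and the acceptance script — 2,000
  genes for null calibration, 20 replicates of the 50-category planted
  design, 1,000 permutations per fit — were chosen as the smallest sizes at
  which the calibration and recovery properties are stable across seeds.
- The planted-recovery power bound (all 5 planted categories in the top 10
  and global p < 0.05 in ≥ 80% of 20 replicates) was pre-registered from an
  independent 30-replicate pilot at the same conditions before being frozen
  into the acceptance test.

## Known limitations

- Pairwise counts conflate the two lineages; lineage-specific (branch)
  attribution would require an outgroup and is not implemented.
- The counting estimator ignores transition bias and codon frequencies in
  its site definitions; absolute ka/ks values are approximate even though
  the category comparison is internally calibrated.
- The permutation null preserves term sizes and per-gene set structure but
  not any correlation between annotation and gene length/divergence that
  real annotation pipelines can induce.
- Fractional substitution counts make the binomial model an approximation
  at the margins; the continuous-beta treatment is exact only at integer
  counts.
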