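# Methods

## The problem the package models

A de-novo GBS/RADseq assembly pipeline turns restriction-digested short
reads into per-locus alignments of diploid consensus sequences.  Every
parameter choice (clustering threshold, base-calling mode, minimum sample
coverage, minimum taxon coverage) shifts the balance between recovered data
and genotyping error.  The package quantifies both sides of that balance —
error rates measured on replicate pairs, and resolution/branch-length
metrics measured on trees — and automates the selection of the two extreme
configurations (MinError, MaxResol).  Because raw sequencing data are not
needed to exercise any of the statistics, a synthetic generator provides
assemblies with a known ground truth.

## Synthetic generator

**Species tree.** Pure-birth (Yule) process started at the crown with two
lineages; lineages split at per-lineage rate λ (default 1/Myr) until the
target tip count `n` is reached, then one further Exp(nλ) interval is
appended.  This makes the expected crown age `Σ_{k=2..n} 1/(kλ)`, the
classic Yule expectation, which the test suite checks by simulation.  Trees
are rooted, binary, ultrametric.

**Sequences.** Each locus evolves independently under Jukes–Cantor: the
probability a site changes along a branch of length `b` (time units) is
`(3/4)(1 − e^(−4μb/3))` for substitution rate μ.  Defaults of
μ = 0.01/site/Myr and 60-bp loci give the few-percent between-taxon
divergence typical of GBS loci in a recently diversified plant clade.
Diploidy is injected per taxon by mutating one allele copy at Bernoulli(het)
sites (default het = 0.01); genotypes collapse to IUPAC consensus characters
(e.g. {A,C} → M), which is what replicate-based error scripts consume.

**Corruption.** Each replicate copy is corrupted independently:

| process       | unit                           | effect                                        |
|---------------|--------------------------------|-----------------------------------------------|
| `dropout`     | per locus per copy             | locus missing from that copy                  |
| `seq_error`   | per locus per copy             | one random substitution at one random site    |
| `het_collapse`| per heterozygous site per copy | genotype collapses to one allele (het class)  |
| `geno_swap`   | per true SNP site per copy     | homozygote disjoint from the genotype (hard)  |

All events are logged.  Under dropout probability `d` each copy keeps a
locus with probability `1 − d` independently, so the expected locus error is
`2d(1−d)/(1−d²) = 2d/(1+d)` — the closed form used in the tests.  An
exact-count mode instead plants requested numbers of events
(`k_drop`, `k_allele`, `m_het`, `m_hard`) into the first pair's A copy only,
at distinct loci/sites, making every event observable exactly once.  One
consequence worth noting: a `seq_error` substitution always replaces the
consensus character with a base outside its allele set, so it is also one
hard-class SNP disagreement; exact recovery of `m_hard` alone therefore
requires `k_allele = 0`, and with both present the recovered hard count is
`m_hard + k_allele` (asserted in the tests).

Non-replicated taxa pass through uncorrupted, since the error statistics are
defined only on replicate pairs.  An optional `background_dropout` applies
locus dropout (never genotyping errors) to non-replicated samples so that
sweeps produce realistic coverage variation for the minimum-taxon-coverage
filter; it defaults to 0.

**What the generator does not emulate.** No read-level simulation
(restriction digestion, depth, PCR duplicates, quality profiles), no indels,
no paralogy/repeat collapse, no allele dropout from restriction-site
mutations, and no model of how clustering thresholds or base-calling modes
map onto error probabilities — configurations name their error
specifications directly.  Passing tests therefore validate the statistics
and their recovery logic, not the error magnitudes of any real pipeline.

## Error statistics

Locus error uses the union of the pair's loci as denominator, which makes
the rate symmetric, bounded and equal to 0/1 at the extremes.  Allele error
compares shared loci column-by-column as allele sets, ignoring columns where
either copy is N/`-`; a missing call is a coverage issue, not a genotyping
disagreement.  SNP errors are computed over assembly-wide SNP columns lying
in shared loci with both genotypes resolved: equal allele sets are
concordant, intersecting-but-unequal sets are heterozygous errors, disjoint
sets are hard errors; the three rates share one denominator so
`snp = hard + het` exactly.  Homology across replicates is co-occurrence in
the same locus block (assemblers cluster across samples); no re-alignment is
attempted.  Undefined rates (empty denominators) propagate as NaN and are
excluded from per-configuration means — reporting 0 would masquerade as
perfect replication.

## Assembly statistics

A SNP column has more than one distinct allele over all allele copies
(ambiguity codes contribute both alleles; N/`-` are missing).  A
parsimony-informative column has ≥ 2 alleles each carried by ≥ 2 samples;
a singleton column is variable with all but one present sample sharing one
genotype pattern.  Percent missing is cell-wise over the implied
concatenated matrix: roster size × total bp in the denominator, a cell
missing when the sample lacks the locus or carries N/`-`.  The coverage
filter keeps loci with (samples present)/(roster size) ≥ the threshold,
inclusive.  Internally, characters are encoded as 4-bit allele masks so
column classification is vectorized; coordinates are 0-based half-open
internally and 1-based inclusive in all emitted reports.

## Tree metrics

Trees are compared unrooted.  Bipartitions are keyed by the tip set not
containing a fixed reference taxon; a root bifurcation contributes a single
split whose length is the sum of the two root-child edges.  RF distance is
the symmetric difference of nontrivial bipartition sets, normalized by
`2(n − 3)`; the branch-score distance is the square root of summed squared
length differences over the bipartition union, terminal branches included
(the literature contains both squared and rooted variants; the rooted one is
used).  The resolution quotient counts internal branches with support
strictly above the threshold (BS > 70 or PP > 0.90 conventions) over
`n − 3`, so consensus polytomies depress it and a star tree scores 0; a
threshold above the declared support scale's maximum is rejected rather than
silently rescaled.  Branch-length summaries honor rooting and report medians
of terminal and internal branch lengths divided by total tree length.

The NJ surrogate computes p-distances with pairwise deletion of missing
cells, runs neighbor joining (scikit-bio), clamps the occasional small
negative NJ branch length to 0, and derives supports as bipartition
frequencies × 100 over bootstrap column resamples (replicates in which some
pair loses all overlap are skipped and excluded from the support
denominator).  It is deliberately simple plumbing: a stand-in for
likelihood/Bayesian/quartet inference so the workflow runs end-to-end at
desk scale, not a recommendation for real analyses.

## Diversification rates

The whole-clade estimators condition on clade survival: with relative
extinction ε = μ/λ, the crown form is

    r = (1/t) [ ln( n(1−ε²)/2 + 2ε + ((1−ε)/2)·√(n(nε² + 2nε − 8ε + n)) ) − ln 2 ]

which reduces to `r = (ln n − ln 2)/t` at ε = 0 (continuity at ε → 0⁺ is
verified to 1e-6 across a grid of n and t); the stem form is
`r = ln(n(1−ε) + ε)/t`.  ε defaults to 0, the setting that reproduces the
published Mediterranean comparison rates, and is exposed for sensitivity
analyses.  Qualitative classes use bins inferred from published labels —
Medium (r < 1), Fast (1 ≤ r < 2), Very fast (r ≥ 2) — and are a heuristic,
not part of the estimator.  Rounding to two decimals happens only at report
time.  One published row (the genus at n = 104, t = 7.80) computes to
0.5066, printed two-decimal value 0.51, where the source prints a truncated
0.50; two further comparison rows differ from the ε = 0 closed form by
≤ 0.05, consistent with different n, ε or rounding in their original
sources, and are not treated as reference values.

## Sweeps and selection

A sweep simulates one ground truth (sizes configurable; tests and examples
use 6–20 taxa, 30–500 loci of 40–60 bp — sizes chosen so a full sweep is a
desk-scale computation) and runs every grid configuration against it.  Each
configuration derives a child seed from the base seed and its own label
(CRC32 mix), so rows are independent: removing a configuration never changes
another row, and reports are byte-identical across reruns.  The
majority-rule axis only combines with minimum sample coverage in {5, 10},
giving the canonical 15-configuration / 30-assembly exploratory grid.
Because no mechanistic mapping from configuration to error process exists,
the sweep config names an error specification per configuration label (with
a default).  Selection rules: MinError is the lexicographic minimum on
(allele error, SNP error), tie-broken by lower locus error then more loci;
MaxResol is the maximum mean over the available resolution columns,
tie-broken by more parsimony-informative sites.  Both rules are stated
explicitly because published workflows describe the criteria only verbally.

## Numerical and degenerate-input conventions

Probabilities validated to [0, 1]; exact counts validated against available
loci/sites before injection.  Empty rate denominators raise
`UndefinedRateError` at the single-statistic level and become NaN in
reports.  Trees need ≥ 4 tips for resolution, ≥ 2 branches and nonzero
total length for branch summaries; a tree without internal branches yields
NaN for the internal median.  Normalized RF on ≤ 3 tips is defined as 0.
All randomness flows through explicitly seeded NumPy generators; config
files must set a seed (no wall-clock seeding).

## Known limitations

Error processes are independent across copies, loci and sites — no shared
library-preparation biases, no depth-dependent error, no correlation between
dropout and divergence (allele dropout in real GBS is biased toward divergent
taxa).  The NJ surrogate underestimates the resolution attainable by model-
based inference, so sweep resolutions are comparable within a sweep, not
across methods.  The estimators assume complete, accurate richness counts
and exact crown ages; uncertainty in either propagates directly into r and
is not modeled here.
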