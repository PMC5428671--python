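# Methods

## Data model

A community matrix holds non-negative abundances of S species across n
discrete resource states. The intended use case treats each sampled
spring outlet as one resource state ("natural sampling unit"), with the
number of individuals collected there as a proxy for the amount of that
resource used. When a long-format table with site × period replicates is
supplied, the reader pools the temporal replicates per site by default
(n = number of sites); keeping site × period combinations as separate
states is exposed as a reader option for sensitivity analysis, since
pooling level affects both overlap and C-score values. Abundances are
accepted as non-negative reals, not just integers, so that normalized or
simulated utilization matrices pass through the same code path.

Species whose total abundance in an assemblage is zero are excluded from
that assemblage's overlap and C-score computations (their utilization
profile is undefined); the exclusion is logged. Validation on ingest
requires at least 2 species and 2 resource states, unique identifiers,
and finite non-negative cells; programmatic subsetting may produce
smaller matrices, and the operations that need two species check for
themselves.

## Overlap

Pianka's index is computed on row-normalized utilization profiles. The
pairwise matrix has unit diagonal by construction, but the diagonal
never enters the per-species means O_sp or the assemblage mean, which
average over pairs only. All accumulation is in double precision; at
these problem sizes (tens of species, single-digit resource counts) no
compensated summation is warranted. The index is invariant to rescaling
any row and equivariant under a common permutation of the resource
columns; both properties are enforced by property-based tests.

When a category subset (e.g. stygobites only) is analysed, utilization
proportions are per-row and hence unchanged by subsetting; only the set
of pairs changes. In the cross-year comparison, a species' O_sp within a
year is deliberately computed over *all* partners present that year,
including partners that the all-years-present filter later removes from
the subject list — the filter selects subjects, not partners.

## Null models

The four randomization algorithms operate on the utilization
(row-proportion) scale:

* **RA1** — every entry replaced by an independent uniform(0,1) draw;
* **RA2** — zero entries kept at zero, nonzero entries replaced by
  uniform draws (guild structure retained, niche breadth relaxed);
* **RA3** — each row permuted uniformly across all n states (niche
  breadth retained, zero structure destroyed);
* **RA4** — each row's nonzero entries permuted among the nonzero
  positions only (both retained).

RA1/RA2 rows are re-normalized to sum 1 after replacement; because the
Pianka index is row-scale-invariant this is provably inconsequential and
done only for tidiness. Uniform draws live on the open interval (0,1),
so a nonzero cell can never become zero.

The Monte-Carlo test simulates (by default) 1000 null assemblages,
records each one's mean pairwise overlap, and reports the ensemble mean,
its population variance (divisor = iterations; the ensemble is treated
as a complete description of the null distribution, not a sample from a
larger one), and the upper tail probability p_ge = (# null means ≥
observed)/iterations. The raw-proportion convention mirrors the classic
EcoSim-style output; the (count+1)/(iterations+1) convention, which can
never report exactly 0 or 1, is available behind the `add_one` flag.
Randomness is driven by one seed: per-iteration substreams are derived
deterministically via `numpy` `SeedSequence.spawn`, so a fixed seed
yields bit-identical results regardless of execution order. Type-I
calibration of the RA3 test (p-values approximately uniform when the
data are themselves an RA3 draw) is verified at desk scale — 200
datasets of 20 species × 8 sites, 200 iterations each — in the
acceptance tests.

## C-score

Computed from the presence/absence thresholding (abundance > 0) of the
per-site pooled matrix, with species absent that year excluded by
default to mirror the overlap filtering; an option keeps empty rows,
which contribute C = 0 with every partner. The matrix-wide mean C-score
is reported purely descriptively; no checkerboard null-model test is
offered (deliberately out of scope — the statistic's null-model
behaviour is notoriously contentious, and the intended use is a
between-year comparison of the raw value).

## Repeated-measures ANOVA

`rm_anova` implements the univariate mixed-design decomposition with
Type III sums of squares. Effect SS are obtained by model comparison on
a sum-to-zero (deviation) coded cell-means design — full model versus
the model with the tested effect's columns removed — so that with
unequal group sizes each effect tests hypotheses about unweighted cell
means, matching R's `car::Anova(type = 3)` convention (the engine behind
the `ez` package); agreement with that reference was verified exactly on
an unbalanced mixed design, and the frozen values are kept as a test
oracle. Error strata are computed directly: subject-within-group SS
(tests the between factor, df = N − g) and the subject × time residual
(tests year and interaction, df = (N − g)(k − 1)). Under balance the
Type III SS coincide with the classical sequential decomposition, which
a brute-force cell-means oracle checks to 1e−8 relative.

Greenhouse–Geisser epsilon is estimated from the pooled within-group
covariance and reported alongside the table, but the headline P values
are the uncorrected univariate ones. Note that subjects in the pairwise-O
analysis are species *pairs*: pairs sharing a species are not
independent, a known feature of ANOVAs on pairwise indices that is
documented here rather than corrected.

Bonferroni post-hocs multiply each raw two-sided P by the number of
comparisons in its family (years, or pair types — families are adjusted
separately) and cap at 1; within-factor comparisons use paired t-tests
across subjects, between-factor comparisons use two-sample t-tests on
subject means. `paired_t` reports the degenerate zero-variance case
explicitly instead of propagating a NaN.

## Synthetic communities

The generator emulates the study design the pipeline assumes: 22
species, 9 of them stygobites (~40% obligate specialists), 8 sites, with
strongly overdispersed counts. Per species it draws a Dirichlet
utilization profile (concentration `breadth`; default 0.5, giving
specialist-leaning profiles), mixes it with a species-specific site
block according to `segregation` ∈ [0, 1], draws a negative-binomial
total (default mean 60 ≈ observed yearly totals spread over 22 species;
shape k = 1, matching the strong between-sample dispersion of real
spring counts — Poisson totals would understate it), and allocates the
total multinomially across sites. Blocks are contiguous site ranges by
default (random subsets optional); disjoint one-site blocks with
segregation 1 give exactly zero overlap, one small shared block gives a
strongly aggregated community.

The bundled three-year scenario keeps the roster fixed and varies
segregation (0.9 / 0.7 / 0.1) and mean abundance (45 / 125 / 41) across
years, mimicking a low-discharge, high-discharge, and post-disturbance
year: desegregation in the final year raises mean overlap. One
limitation is worth stating: in this generator site *occupancy* scales
with total abundance, so the presence/absence-based C-score responds to
the abundance trajectory as well as to segregation — with the default
unequal abundances the post-disturbance drop in mean C-score is not
reliably reproduced, whereas with comparable abundances across years (or
the sharper 0.9/0.9/0.1 segregation contrast) both directional
signatures — overlap up, C-score down — recover consistently. The
generator also omits temporal autocorrelation between replicates,
species-specific detectability, and any mechanistic hydrology; passing
tests therefore demonstrate the statistical machinery, not ecological
realism.

## Problem sizes and determinism

Default analyses (22 species × 8 sites, 1000 null iterations) run in
well under a second. Test-suite simulations use reduced but informative
sizes — 200 calibration datasets at 200 iterations, 20 seeds for the
directional checks — chosen so the whole suite completes in seconds
while keeping Monte-Carlo noise well inside the asserted margins. All
stochastic components accept explicit seeds and are bit-reproducible;
property-based tests run derandomized.
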