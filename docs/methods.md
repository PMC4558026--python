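# Methods

This note records the models implemented in `slavstrata`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
generators do and do not emulate.

## Data model

Populations carry a linguistic affiliation (branch → ethnic group →
language) and coordinates; haplogroup tables are populations × haplogroups
relative frequencies with optional integer counts (rows of a count table are
renormalised; a table whose cells are all integers and whose rows do not sum
to one is auto-detected as counts, since published frequency tables mix
percent, proportion and count conventions). Distance matrices are labelled,
symmetric, zero-diagonal; read-time asymmetries up to 1e-6 are averaged,
larger ones rejected. IBD segments live in genetic-map units as half-open
`[start_cM, end_cM)` intervals — physical positions are never needed because
every downstream statistic uses only cM lengths. Segments are read from a
fastIBD-style file whose marker endpoints are resolved through a PLINK-.map
style genetic map; segments shorter than a configurable minimum (default
1 cM, the practical resolution of array-based segment callers) are dropped
at read time with the count logged.

## Nei distance and geography

`nei_distance` implements the standard normalised-identity distance
`D = −ln(Jxy/√(Jx·Jy))`. The plug-in estimator is the default; an optional
flag applies the unbiased homozygosity correction `(nJ−1)/(n−1)` to Jx and
Jy. Two populations with disjoint haplogroup support have `I = 0` and an
infinite distance; the default behaviour caps the distance at 10 with a
warning (strict mode raises) so that downstream ordination and matrix tests
remain finite — small samples of highly drifted populations do produce such
pairs. Geographic distances are great-circle (haversine) with Earth radius
6371 km.

Group summaries average unordered within-group pairs, or all cross pairs
when two groups are given; a singleton group has no within-group pairs and
is rejected rather than reported as zero.

## Non-metric MDS

The embedding minimises Kruskal stress-1,
`√(Σ(d̂ᵢⱼ−δᵢⱼ)²/Σδᵢⱼ²)`, where δ are configuration distances and d̂ the
isotonic (monotone) regression of δ on the input dissimilarities. Ties are
treated by Kruskal's primary approach — within a tied block of
dissimilarities the disparities follow the configuration order — which is
implemented by breaking ties before the pool-adjacent-violators pass.
Optimisation is SMACOF with isotonic regression (scikit-learn's non-metric
`smacof`), with the first restart initialised by classical Torgerson scaling
and subsequent restarts by Gaussian configurations scaled to the mean
dissimilarity; the best configuration over restarts is returned, and the
reported stress is always the package's own `stress1` evaluated on the
returned coordinates (so the reported value is a pure function of the
output, independent of optimiser internals). Convergence uses a raw-stress
improvement threshold of 1e-9 with at most 300 iterations; restart seeds
are drawn sequentially from one generator, so the reported stress is
non-increasing in the number of restarts for a fixed seed.

## AMOVA

Individuals are haplogroup-labelled units with 0/1 mismatch distance, which
makes Φ_ST the haplogroup-frequency analogue of F_ST — appropriate for
binary-marker haplogroup data, where no molecular distance between
haplogroups is modelled. For any pooled set the sum of squared distances
over ordered pairs reduces to `n² − Σ_h c_h²`, so all sums of squares are
computed from count vectors; an individual-expanded brute-force
decomposition is kept in the test suite as the oracle.

Variance components follow the standard hierarchical scheme with
unequal-sample-size coefficients:

    σ_c = MS(within populations)
    σ_b = (MS(among populations within groups) − σ_c) / n′
    σ_a = (MS(among groups) − σ_c − n″·σ_b) / n‴

with `n′ = (N − Σ_g Σ_{p∈g} n_p²/n_g)/(P−G)`,
`n″ = (Σ_g Σ_{p∈g} n_p²/n_g − Σ_p n_p²/N)/(G−1)`,
`n‴ = (N − Σ_g n_g²/N)/(G−1)`. Raw (possibly negative) component estimates
are primary — negative values mean units are more similar than random
sampling predicts — and a zero-clamped view (`sigma_clamped`,
`phi_clamped`) is provided alongside, since both conventions are in use.
A stratum with a single unit is reported as not testable (NaN), never as
zero. Permutation p-values use (b+1)/(m+1); Φ_ST permutes individuals among
all populations, Φ_SC permutes individuals among populations within their
group, and Φ_CT permutes whole populations among groups. `amova_per_group`
runs one two-level AMOVA per unit of a chosen stratum (units with fewer
than two populations are skipped with a log entry) and reports the
across-unit average Φ_ST — the "differentiation among local populations
speaking the same language" summary.

Whether a published three-level table derives from one three-level run or
separate two-level runs is often unstated; both modes are provided.

## Mantel and partial Mantel

The statistic is the Pearson correlation over the n(n−1)/2 upper-triangle
entries after aligning labels. The null simultaneously permutes rows and
columns of the second matrix; tests are one-sided for positive association
by default (the associations of interest here are positive), with a
two-sided option. For n ≤ 8 an exact mode enumerates all n! permutations.
The first-order partial correlation
`r_AB·C = (r_AB − r_AC·r_BC)/√((1−r_AC²)(1−r_BC²))` is tested by permuting
the raw entries of B and recomputing the partial statistic (the most common
implementation lineage); residual permutation is available behind a flag.
Controls collinear with a tested matrix (|r| = 1) are rejected.

## The ibd-statistic

For two disjoint groups of individuals the statistic is the number of IBD
segments between the groups divided by the number of cross pairs, tabulated
by length class; pairs sharing nothing still count in the denominator, so
the per-class values sum exactly to the binning-free per-pair average. The
default ten classes have edges 1, 1.5, 2, 2.5, 3, 4, 5, 6, 8, 10 cM with an
open top class: half-cM resolution at the short end (where most segments
fall and where the detection threshold sits) and wider classes above,
configurable throughout.

Group comparisons test whether a focal group shares more with comparator c1
than c2 via Δ = ibd(focal,c1) − ibd(focal,c2) totalled over selected
classes. The null reassigns the individuals of c1 ∪ c2 to pseudo-groups of
the original sizes — individuals, not populations, are the exchangeable
units, because the statistic is defined per pair of individuals — and the
two-sided p-value is (b+1)/(m+1). This label-permutation design targets
exactly the claim "focal shares more with c1 than with c2"; it is this
package's choice of test, not a reconstruction of any particular published
procedure.

## Lexicostatistics

Wordlist cells hold sets of cognate-class ids (synonyms allowed; empty =
missing). Two lects match on an item when their sets intersect, so adding a
synonym that duplicates an existing class never changes a distance. The
share is weight-averaged over items non-missing in both lects (per-item
stability weights default to 1; a weights file can supply externally
estimated stability indices), and distance is `1 − share`. A pair with no
jointly attested items is an error naming the pair.

Dating laws (`t` in millennia, λ per millennium², default λ = 0.05):

* `starostin` (default): `t = √(−ln c / (2λc))` — quadratically
  accelerated loss with the share-dependent correction;
* `sqrt`: `t = √(−ln c / (2λ))` — the uncorrected accelerated law;
* `linear`: `t = −ln c / (2λ)` (λ per millennium) — the inverse of a
  constant-rate Poisson replacement clock.

Tree building ("StarlingNJ" style): neighbor-joining on the distance matrix
(scikit-bio), midpoint-rooted; each internal node is dated from the mean
cognate share between the leaf sets of its child clusters (the mean-share
choice is this package's documented assumption) and dates are monotonised
root-ward with a running maximum, so a parent is never younger than a
child. A cross-cluster share of zero would date to infinity and is floored
at `min_share` (default 0.01). Slovenian is excluded from tree building by
default — its vocabulary mixes West and South Slavic strata — via an
`exclude_lects` parameter that is a no-op when the lect is absent.
Consensus collapsing contracts internal edges whose parent–child date gap
is ≤ 300 years (configurable) into multifurcations, the contracted node
keeping the parent's date; gaps are evaluated top-down on the partly
collapsed tree, which makes the operation idempotent. Newick export writes
branch lengths in years (parent date − child date); the reader reconstructs
dates from path lengths and assumes an ultrametric tree with leaves at
0 YBP.

Because the wordlist simulator's default clock is constant-rate while the
default dating law assumes accelerated loss, recovery experiments pair each
clock with its inverse law (`constant` ↔ `linear`; `accelerated` ↔
`sqrt`/`starostin`). Mixing them systematically compresses or stretches
deep dates, which is precisely the dating-law ambiguity that motivates
reporting split dates with generous uncertainty.

## Synthetic generators

All generators are pure functions of a config and a seed, and their outputs
round-trip through the package's readers.

**Haplogroup tables.** A global frequency vector is drawn once
(symmetric Dirichlet); branch frequencies follow a Dirichlet random walk
from geographic neighbour to neighbour (isolation by distance at the branch
scale), group and population frequencies are Dirichlet draws centred on
their parent with concentrations `tau_group`, `tau_pop`, and counts are
multinomial. Defaults — 4 branches × 3 groups × 2 populations of 100
samples over 15 haplogroups, `tau_branch = 20`, `tau_group = 30`,
`tau_pop = 150` — were chosen so the implied differentiation profile sits
at the level observed in Balto-Slavic NRY data: Φ_CT ≈ 0.06 among branches,
Φ_SC ≈ 0.03 among ethnic groups, and ≈ 0.01 among local populations of one
language. Populations of a branch occupy one latitude band (contiguous
geography), and an optional Gaussian-kernel-correlated logit perturbation
(`spatial_rho` in km) adds tunable spatially autocorrelated drift; the full
synthetic study uses `spatial_rho = 1000` km at s.d. 0.8 to produce a
clearly positive genetics–geography Mantel signal.

**IBD segments.** For a group pair with ancestry `g` generations back, a
pair of individuals receives a raw Poisson(μ) number of segments with
Exponential(mean 100/(2g) cM) lengths; segments below the detection
threshold are discarded (sampled by the shifted-exponential identity, which
is exact), so observed counts are Poisson(μ·e^(−2g·min/100)) and the
expected count in class [a,b) is `μ(e^(−2ga/100) − e^(−2gb/100))`, exposed
as a closed form and verified against simulation within Monte-Carlo error.
Keeping the truncation thinning in the expectation (rather than
renormalising counts to a constant) is what makes sharing depth observable:
deeper ancestry yields both fewer and shorter detectable segments. The
default study design uses five groups of 25 individuals with depths 30–90
generations arranged so that a focal group shares most with a
"north-eastern" group, equally with "southern" and "inter-lying" groups,
and least with a "Volga" group — the sharing topology reported for
East-West Slavs.

**Wordlists.** Cognate classes are replaced along the true tree by a
Poisson process (rate per item per millennium, default 110 items at 0.05 —
the canonical basic-vocabulary scale); every replacement draws a globally
novel class, and with probability `synonym_prob` (default 0.05) it is added
as a synonym instead of replacing. Under the constant clock the expected
share of lects separated by total time T is `e^(−rate·T)` per item; the
`accelerated` clock uses hazard 2λt in absolute time (survival `e^(−λt²)`
per lineage). The default true tree mirrors the consensus shape of the
Balto-Slavic tree: a deep split at 3400 YBP, one side splitting ternary
fashion at 1900 YBP into three clades that diversify 1400–600 YBP.

**What the generators do not emulate.** Haplogroup counts are multinomial
with no within-lineage phylogenetic structure, no sex-biased or
cluster-sampling effects, and no missing data; IBD segments are independent
across pairs with no linkage to a shared pedigree (no transitivity of
sharing), a single genome-wide map length scale and no genotyping error;
wordlists have no borrowing, no semantic drift and no correlated rates
between items. Passing recovery tests therefore demonstrates correctness of
the estimators under their own model assumptions, not robustness to these
real-data complications.

## Problem sizes and test design

The test suite runs entirely on desk-scale data: brute-force AMOVA oracles
on ≤ 30 individuals, exact Mantel enumeration at n = 4, generator
closed-form checks at ~2000 pairs or ~2400 samples. Stochastic recovery
experiments use 50 seeds (AMOVA component ordering, both orderings), one
999-permutation sharing comparison at 25 individuals per group, 60 seeds of
200-item wordlists for topology (≥95% of seeds) and dating (the
seed-averaged date of every internal node within 15% of truth — individual
seeds carry ~15–20% binomial noise at this list length, so accuracy is
assessed on the seed average while topology is assessed per seed), a
300-run Mantel type-I calibration at α = 0.05 ± 0.02 and a 200-run
AMOVA p-value uniformity check. The acceptance script regenerates the full
synthetic study (24 populations × 100 samples, five IBD groups × 25
individuals, 11 lects × 110 items) and completes in seconds.

## Known limitations

* AMOVA is haplogroup-identity based only; sequence-based molecular
  distances (and hence haplotype AMOVA) are out of scope.
* The Mantel permutation count and sidedness used in any given published
  table are often unstated; defaults here (999 permutations, one-sided)
  are documented choices, not reconstructions.
* MDS stress values are comparable across programs only approximately:
  optimiser, tie handling and convergence settings all shift the third
  decimal.
* `read_newick` assumes ultrametric trees (leaves at the present); it is
  the inverse of `write_newick`, not a general Newick ingester.
* Reproduction of published group-level values requires the deposited
  supplementary tables, which are not redistributed with the package.
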