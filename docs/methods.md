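# Methods

`crcland` implements a cohort-level analysis of somatic mutation profiles
in metastatic colorectal cancer: per-variant quality filtering, a
VAF-based clonality call, tumor mutational burden (TMB) and microsatellite
instability (MSI) calling, the Schell APC/TP53/KRAS mutational
classification with its two-level risk stratification, a binary
gene-instance encoding of clonal profiles analysed by PCA and a
median-joining network, and nonparametric survival and contingency
comparisons between strata. A synthetic cohort generator reproduces the
statistical structure these analyses assume so that every stage is
testable without access to patient-level data.

## Variant filtering

A call is kept iff it passes every enabled rule: alt-supporting depth
>= 7 reads, mean base quality >= 30 (phred), VAF >= 0.003, total depth
>= 10 in the tumor **or** the matched normal, population allele frequency
<= 0.01% (fraction 0.0001), and no caller-set strand-bias or DNA-damage
flag. "Minimal X" rules use >= (a value exactly at the threshold passes);
every removed record carries the list of rules it failed. The strand-bias
and damage filters consume upstream boolean flags rather than
re-implementing the caller's internal tests, which keeps the pipeline
contract while leaving the statistical test to the tool that has the read
evidence. An optional joint rule (VAF < a AND tumor depth < b, suggested
a=0.05, b=30) guards against low-frequency noise at thin coverage; it is
off by default because its parameters are pipeline folklore rather than a
published constant. A threshold set to 0 (or an AF cap of 1) disables the
corresponding rule; a missing field only errors when its rule can bite.

## Clonality

With `vmax` the sample's maximum tumor VAF, a variant is **clonal** when
`vaf >= 0.25 * vmax`. Non-clonal variants are **excluded** (ignored by
every downstream count) when `vaf < vmax / 10` or `vaf < 0.03` absolute,
and **subclonal** otherwise. The clonal test is applied first: the
exclusion rules describe which *subclonal* mutations are not counted, so
the maximum-VAF variant is clonal by construction even in a sample whose
maximum VAF is below 3%. The fraction-of-max rules are invariant under a
uniform rescaling of a sample's VAFs; the 3% absolute floor deliberately
is not (it encodes assay sensitivity, not tumor architecture).

## TMB and MSI

TMB = mutations / panel megabase, rounded half-away-from-zero to one
decimal (exact decimal arithmetic, so 7/0.8 = 8.75 reports as 8.8). By
default the count is all post-filter non-synonymous variants; synonymous
inclusion is a flag. With a matched normal the MSIsensor-style score maps
to MSS (< 10), MSI-L (10–30 inclusive) or MSI-H (> 30); tumor-only mode
uses the single cutoff 25 (MSI iff score > 25, a score exactly at the
cutoff is MSS). When a score falls strictly within `adjudication_delta`
(default 5) of a cutoff, the sample's TMB adjudicates: TMB >=
`tmb_high` (default 20 mut/Mb, the common hypermutation convention —
configurable because no published constant pins it) pushes the call to
the more-instable side of that cutoff, lower TMB to the less-instable
side, and the call is flagged as adjudicated. The window is strict, so
`delta=0` makes the adjudication layer exactly the identity; when a score
is within delta of both cutoffs the nearer one wins, ties to the lower.
With TMB fixed, the call is monotone in the score.

## Schell classification and risk

Class 0: no clonal truncating APC mutation (nonsense, frameshift, splice
site). Classes 1/2: one / two-or-more truncating APC with exactly one of
TP53, KRAS mutated. Classes 3/4: one / two-or-more truncating APC with
both mutated. TP53/KRAS count as mutated on any clonal non-synonymous
variant; NRAS never substitutes for KRAS. Risk is high for classes 0 and
4, low for 1–3. The published enumeration is silent on truncating-APC
tumors with *neither* TP53 nor KRAS mutated; such samples get the
corresponding low-risk class (1 or 2) with `fallback_applied=True`
surfaced in every output, the conservative choice that preserves the
high-risk = {0, 4} semantics without inventing risk.

## Binary encoding, PCA, median-joining network

Clonal mutations restricted to the shared panel gene set are encoded as a
samples x gene-instance 0/1 matrix: a gene hit up to m times anywhere in
the cohort contributes columns GENE, GENE_1, ..., GENE_{m-1}, and a
sample with k hits sets the first k to 1. Instance columns are assigned
by count, not by variant identity — mutations within a gene are
unordered — which makes row-wise Hamming distance equal the summed
per-gene count difference. Samples with no shared-set mutations are
dropped and reported. Columns sort alphabetically with instances
ascending, so output is deterministic.

PCA is a centered, unscaled SVD (binary columns share a scale); explained
fractions are shares of total variance; each component is oriented so its
largest-magnitude loading is positive (first index on ties).

The median-joining network starts from the epsilon-relaxed minimum
spanning network of the unique observed vectors under Hamming distance
(an edge is feasible iff its length is within epsilon of the pair's
minimax/bottleneck distance; epsilon=0, the default and most parsimonious
choice, yields the union of all minimum spanning trees). For every pair
of links sharing a node, the per-column majority of the three endpoint
vectors — the unique binary Steiner point of the triplet — becomes a
candidate; candidates are added greedily (best first, lexicographic
tie-break) while they strictly reduce the minimum spanning cost of the
vector set, then the network is rebuilt. Finally, median vectors that do
not lie on any shortest path between observed vectors, or whose degree
falls below 3 (a Steiner point of degree <= 2 never shortens a network),
are pruned iteratively. The all-zero "healthy" profile is injected as an
explicit observed root node by default. Tie-breaking is lexicographic
throughout, so construction is deterministic.

## Survival and contingency

Kaplan–Meier curves come from lifelines (Greenwood variance, log(−log)
95% bands); median OS is the smallest t with S(t) <= 0.5, undefined when
the curve plateaus above it. The two-group comparison is the
Mantel–Haenszel log-rank test with the O/E tally computed in-house (it
also yields the hazard ratio (O1/E1)/(O2/E2) with a log-scale 95%
interval); lifelines' log-rank and a permutation null serve as
cross-checks in the test suite. Multivariate Cox adjustment is
deliberately out of scope — use lifelines' `CoxPHFitter` on the clinical
table directly.

Fisher exact p-values are two-sided by the minimum-likelihood definition
(sum of probabilities of margin-preserving tables no more likely than the
observed one, with a 1e-7 relative tie tolerance — the convention of the
major statistical packages, chosen over tail-doubling). The 2x2 case
delegates to scipy; the r x c case enumerates all margin-preserving
tables depth-first (refusing beyond a configurable ~1e7-table bound) or
estimates the tail by seeded Patefield sampling with a reported binomial
standard error. Records with missing categories are excluded from every
comparison table.

## Synthetic cohort generator

The generator draws, per patient and in a fixed documented order: MSI
status (10%), a Schell class from the stage-IV margins 23:24:16:11:14
(MSI forces class 0 — MSI colorectal tumors essentially never carry
truncating APC), a treatment arm (Germany always SOC; USA individualized
after SOC with probability 35/54), an exponential survival time with rate
ln 2 / median for the (risk, country, treatment) stratum, independent
Uniform(0, c) censoring with c solved numerically so the censoring
fraction hits its target (default 20%), demographics, an MSI score clear
of the cutoffs (MSS ~ U(0, 8), MSI ~ U(32, 80)), and finally the
mutations: the drivers its class implies (APC truncating consequences
drawn 45/45/10 nonsense/frameshift/splice; classes 1/2 choose TP53 vs
KRAS proportional to their marginal rates 0.60/0.45; MSI adds BRAF with
probability 0.73), plus Poisson-count passengers (mean 8 MSS / 40 MSI)
over a background gene table of plausible colorectal frequencies — the
real cohorts' per-gene rates are not published, so these are documented
placeholders. Default stratum medians follow the reported curves:
high-risk USA 29 (SOC+IND) vs 13 (SOC), low-risk USA 33/34, Germany 19.5.

VAFs are laid out so the clonality rules provably recover the design: a
clonal peak `vmax ~ Beta(8, 12)` (re-drawn below 0.10), clonal variants
at `vmax * U(0.3, 1)`, subclonal passengers at `vmax * (0.105 + 0.14 *
Beta(2, 2))` — strictly inside the subclonal band, with a safety margin
exceeding the 4-decimal rounding of written VAFs. QC fields are drawn to
pass the technical filters (depth ~ 100 + Poisson(450), base quality
U(30, 40), zero population AF).

What the generator does **not** emulate: real genomic positions or
mutational signatures, gene–gene co-occurrence beyond the class
definitions, panel differences between cohorts, non-exponential survival
(the published data give only medians, so the one-parameter memoryless
family is the least-assuming choice), or informative censoring. Passing
tests therefore demonstrate that the pipeline's rules and estimators are
correct and internally consistent — not that the generator's margins
match any particular patient population.

## Numerical choices and problem sizes

TMB rounding is exact-decimal; Fisher tie tolerance 1e-7 relative; PCA
oracle agreement asserted at 1e-8; MST/network tie-breaks lexicographic.
Test simulations use 2,000 draws per arm for parameter-recovery checks
(KM medians recovered within ±1 month uncensored, ±1.5 under ~30%
censoring) and cohorts of 15–1,000 patients per country elsewhere; the
end-to-end demonstration uses 12 per country, sizes at which the full
pipeline runs in seconds while leaving the binomial checks adequately
powered. The acceptance script simulates the two country arms with a
shared seed (common random numbers), the standard variance-reduction
design when the estimand is a difference of medians.

## Known limitations

The clonality proxy ignores copy number and purity; TMB uses a single
panel size for all samples; the median-joining search is greedy (median
joining is itself a heuristic for the NP-hard Steiner problem, and the
greedy ordering may differ from other implementations on ties); the r x c
exact test is exponential in table size by nature; and the high-risk
fallback class is this package's documented convention, not a published
rule.
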