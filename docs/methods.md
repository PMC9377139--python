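# Methods

This note documents the models, conventions and numerical choices behind
`phindex`, and what the synthetic-data tests do and do not demonstrate
about real metagenome data.

## Abundance model and CPM normalization

Read counts per genome are normalized to genome counts per million (CPM):
counts are divided by genome length (bp) and each sample column rescaled
to sum to 10⁶. CPM therefore estimates the *genome-copy* composition of
the community rather than the read composition, and converts to percent by
dividing by 10,000. CPM is invariant to sequencing depth: scaling a
sample's counts by any positive constant leaves it unchanged.

Condition responses are log₂ ratios of CPM against a reference — the mean
across conditions, a control sample, or the inoculum. A pseudocount of
0.5 CPM (configurable, `pseudocount=`) is added to numerator and
denominator so that genomes absent from one sample still yield finite
ratios; at the abundances where responses are biologically interpretable
(hundreds to thousands of CPM) its effect is below 10⁻³ log₂ units.
The base is 2, so +1 means doubling relative to reference. The
coefficient of variation uses the population standard deviation
(`ddof=0`, configurable). Genome rankings ("top 50") are by mean CPM over
a caller-specified sample subset — by convention supernatant samples for
viral genomes and pellet samples for prokaryotes, since each fraction
enriches the respective community — with lexicographic tie-breaking for
reproducibility.

Spearman correlations between condition responses use average ranks for
ties; the two-sided p-value is computed by exhaustive enumeration of all
n! pairings for n ≤ 10 and by the t approximation above that. Response
profiles are clustered by average linkage (UPGMA) on Euclidean distances
between log-ratio row vectors; trees are serialized as Newick with branch
lengths equal to merge-height differences.

## Consensus viral calling and triage

Per-tool filters: PPR-Meta viral score ≥ 0.75 (boundary inclusive);
CheckV calls suppressed only when the quality tier is "not determined"
AND no viral genes were detected (the conjunctive reading of the
exclusion rule — a disjunctive variant would also drop determined-quality
calls without viral genes, which contradicts CheckV's own semantics);
VIBRANT and PHASTER pass unfiltered. The consensus is
`PHASTER ∨ (#{CheckV, PPR-Meta, VIBRANT votes} ≥ 2)`, which is monotone:
adding a positive vote can never revoke a viral call.

Triage discards bins under 10,000 bp, then classes a bin as viral when
more than 50 % of its *length* lies in consensus-viral contigs
(length-weighted majority; a contig-count majority would let many short
non-viral fragments outvote one long viral contig). Viral bins over
200,000 bp are dissolved into single-contig viral genomes — bins that
size exceed the realistic genome span of tailed phages and in practice
show low completeness and high contamination. Non-viral bins with
CheckM-style quality metrics become MAGs; the rest stay unclassified.
Quality tiers follow the published MIMAG and MIUViG standards (MAG high:
completeness > 90 ∧ contamination < 5; medium: ≥ 50 ∧ < 10; virMAG
complete: 100; high: ≥ 90); thresholds are arguments for sensitivity
analyses.

## Compositional correlation

Counts are compositional: correlations computed directly on fractions are
biased by the closure to a constant sum. The estimator works on log-ratio
variances T_ij = var(log x_i/x_j), which are closure-free, and solves for
basis variances ω_i² under a sparsity assumption (most pairs
uncorrelated), giving r_ij = (ω_i² + ω_j² − T_ij) / (2 ω_i ω_j), clipped
to [−1, 1]. Pairs with |r| above an exclusion threshold (default 0.1)
visibly violate sparsity; the single strongest such pair is removed from
the linear system and the system re-solved, for up to 20 rounds (both
defaults are the reference algorithm's canonical values), keeping every
genome attached to at least two pairs so the system stays well-posed.
Fractions are drawn from a per-sample Dirichlet(counts + 1) posterior and
the estimate averaged over 10 resamples; `n_resamples=0` instead uses the
posterior-mean fractions once, which is fully deterministic and exactly
invariant to sample order (used by the exchangeability tests).

Significance: each bootstrap permutes every genome's counts across
samples independently — destroying all between-genome dependence while
preserving marginals — and re-estimates the matrix. The two-sided pseudo
p-value is (1 + #{|r_boot| ≥ |r_obs|}) / (B + 1); the add-one form keeps
p ≥ 1/(B+1) and avoids zero p-values. The conventional B is 1000.

## Induction detection

A prophage-carrying genome is split at its 0-based half-open prophage
intervals into a viral and a host part; interval arithmetic conserves
length exactly. For coverage aggregation each contig is assigned to the
part holding the majority of its length (in the supported data layouts
prophages occupy dedicated contigs, making the assignment exact). Part
coverage is the *unweighted* mean of per-contig coverage values — each
contig contributes one value regardless of size, matching how per-contig
coverage tables are produced upstream.

Presence requires mean coverage ≥ 0.01× (inclusive boundary). The
induction statistic is the raw virus/host coverage ratio with a strict
cutoff of 10 — a value chosen where empirical ratio distributions
plateau, i.e. beyond what coverage noise produces. (The statistic is the
ratio itself, not its logarithm: observed induced ratios of ~13 to
several thousand are only consistent with a cutoff on the raw scale.)
Host-absent, virus-present cases are excluded from induction calling and
reported as a separate presence class: the parsimonious explanation is an
alternative host, not induction. For clustering, ratios are
log₂-transformed with the presence threshold (0.01) as pseudocount on
both coverages, bounding the dynamic range.

Group comparisons (e.g. mesophilic vs thermophilic samples) use the
two-sided Mann-Whitney U test with tie correction (exact for small
untied samples, normal approximation otherwise), with direction taken
from mean ranks and significance at α = 0.05. FASTQ subsampling uses
single-pass reservoir sampling — uniform without replacement, exactly
min(n, total) reads, deterministic per seed, paired files in lockstep —
with a default of 10⁷ reads to put samples on a common footing before
mapping.

## Annotation statistics

Consensus taxonomy walks ranks from order downward; at each rank the
vote is taken among ORFs that carry an assignment at that rank and whose
higher ranks match the consensus so far (shallower hits abstain rather
than dilute), requiring a strict > 0.5 share; the walk stops at the first
rank without a majority. Gene-family enrichment counts annotated ORFs
(not genomes) in a 2×2 table of family vs other hits in viral vs
prokaryotic genomes; the two-sided Fisher exact p sums hypergeometric
point probabilities no larger than the observed table's, and the odds
ratio is the conditional maximum-likelihood estimate. An HMM profile is
cluster-specific when all genomes hitting it share one response-cluster
label.

## The synthetic-data generator

The generator emulates the statistical structure the analysis relies on,
not sequence content: genome records with contigs and lengths (prokaryote
contigs 2–6 per genome; each prophage on a dedicated contig fully covered
by its interval, so splitting is exact), a skewed lognormal community
composition, per-condition log₂ effects, one sample per condition.
Defaults mirror a stress-perturbation digester experiment: a control plus
four stresses, half the prokaryotes carrying one prophage, viral lengths
5–150 kbp (inside the 1.5–200 kbp span of tailed phages), effect sd 0.5
log₂ units, 10⁶ reads per sample, coverage noise CV 0.2, induction
probability 0.1 per (sample, prophage) with fold elevations of 20–200×.

Counts are multinomial with probability ∝ abundance × 2^effect × length
(longer genomes attract proportionally more reads); columns sum exactly
to the requested depth. Coverage is relative abundance × a depth scale,
times lognormal noise parameterized by its CV (σ² = ln(1+CV²),
μ = −σ²/2, unit mean) — positive and multiplicative, as coverage noise
is; induced prophage contigs are multiplied by the planted fold.
Predictor evidence reports the true class per tool with probability
1 − error_rate, with tool-appropriate score/quality fields.

Condition effects are identifiable from compositional data only up to a
per-sample offset. The generator therefore recentres the drawn effects so
the community abundance total is equal across conditions (and the control
effect is zero); the stored truth is the identifiable parameter, and
noise-free log ratios recover it to machine precision. Without this
convention no estimator could recover the raw draws.

What passing tests do **not** show about real data: no read-level
simulation, assembly artefacts, chimeric bins, strain heterogeneity,
mapping ambiguity between prophage and related free phages, or
compositional effects of unclassified contigs. Recovery results bound
what the pipeline can do when its input tables are right; they do not
validate the upstream tools that produce those tables.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which the estimators' asymptotics are visible: induction
recovery on 500 planted (sample, prophage) pairs (50 prokaryotes, half
carriers, 20 samples, fold ≥ 50, noise CV 0.3); correlation recovery on
20 genomes × 200 samples at depth 10⁵; bootstrap power checks at 10
genomes × 100 samples with ~200 bootstraps. Exact-test oracles
(hypergeometric enumeration, permutation enumeration, brute-force UPGMA)
are kept in the test suite, independent of the implementation paths they
check. Degenerate inputs fail loudly and specifically: all-zero count
columns, zero-mean CVs, constant correlation vectors, empty coverage
lists, overlapping or out-of-bounds prophage intervals, contigs claimed
by two bins.

## Known limitations

* The triage step consumes predictor and quality *tables*; native output
  formats of the upstream tools are out of scope.
* The correlation estimator assumes sparsity of true correlations; dense
  correlation structure biases basis variances (inherent to the method).
* Induction calling conflates genuine induction with any process that
  elevates prophage-region coverage (e.g. cross-mapping from related free
  phages); the virus-only flag catches only the host-absent extreme.
* One sample per condition in the generator: condition effects and sample
  effects are confounded by design, as in small real studies.
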