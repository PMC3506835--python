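# Methods

## Scope and data model

The pipeline consumes MAS5-style microarray output: a probesets × samples
matrix of nonnegative linear-scale intensities and an identically shaped
matrix of detection calls (P/M/A), plus a sample design table, a
probeset→gene map and a gene→GO annotation with a term parent table. All
artifacts are TSV; intensities are written with 6 significant digits.
Upstream steps (probe-level signal computation, normalization across
arrays) are out of scope — the analysis starts where those algorithms
end.

Probesets mapping to more than one gene are rejected at read time:
many-probesets-to-one-gene averaging is well defined, one-to-many is
not, and silently expanding it would double-count probesets.

## Preprocessing

A probeset is *consistently detected* when every hybridization of at
least one condition of its experiment calls it P or M. The rule is
applied per experiment, per condition label, before gene collapsing. A
gene's expression is the log2 of the arithmetic mean of its retained
probesets' linear intensities — averaging strictly precedes the log
transform, so by Jensen's inequality the gene value is at least the mean
of the probeset log intensities. A gene is kept when at least one of its
probesets survives filtering; requiring all probesets would discard
genes whose weaker probesets drop out near the detection limit.

## Differential testing

Per gene, on the log2 scale:

* Welch two-sample *t* with Welch–Satterthwaite degrees of freedom for
  the unpaired in vivo contrasts (S vs M, M vs F), oriented so Δ and *t*
  are positive when the second-named condition is higher;
* paired *t* on per-preparation differences for the in vitro contrast;
* classical one-way fixed-effects ANOVA as the three-group screen.

All p-values are two-sided. Zero-variance genes yield logged sentinel
values (p = 1 when means agree, the smallest positive double when they
do not) instead of exceptions, so one flat gene never aborts a
full-matrix run.

False-discovery control uses Storey q-values: π₀(λ) = #{p > λ}/(m(1−λ))
on the grid λ = 0.05, 0.10, …, 0.90, smoothed by a cubic least-squares
fit and evaluated at λ = 0.90, clamped to (0, 1]; then
q_i = min_{p_j ≥ p_i} π₀ m p_j / rank(p_j). Below 100 p-values the
smoother is too noisy and π₀ is fixed at 1, which makes the q-values
equal Benjamini–Hochberg adjusted p-values exactly (the identity also
serves as a test oracle). The smoother choice (polynomial cubic fit
rather than a spline) is pinned by a simulation check: on
0.8·U(0,1) + 0.2·Beta(0.5, 8) mixtures of 10,000 p-values the π₀
estimate recovers 0.8 within ±0.05 averaged over 20 seeds.

The Fisher exact test sums hypergeometric probabilities (computed via
log-gamma, so counts in the hundreds do not overflow) of all tables
sharing the observed margins whose probability does not exceed the
observed table's, with a 1e-7 relative tolerance at the boundary. Any
zero margin returns p = 1.

## Rank-based GO association

Genes with p < α are ranked on Δ descending (rank 1 = strongest
increase; ties get average ranks, and tied genes are interchangeable by
construction). Each term with an in-list membership of at least 2 and at
most (list − 2) genes is scored by comparing in-term vs out-of-term rank
sums. For lists of ≤ 12 genes the exact permutation null is computed by
dynamic programming over the rank multiset; otherwise a normal
approximation with tie correction and a 0.5 continuity correction is
used. The reported p is two-sided (probability of a rank-sum deviation
at least as large as observed); the smaller one-sided tail is also
returned. The sign is +1 when the in-term mean rank sits toward the
increased-expression end (+1 on exact ties). Benjamini–Hochberg
adjustment runs across the tested terms of one ranked list — each
contrast is its own family. Signed scores floor the adjusted p at
1e-300 before the log10 transform.

The term-size bounds are this package's choice (the underlying
requirement is only that both groups be nonempty); they guarantee both
rank groups have at least two members.

## Concordance and attenuation

The common-gene set holds genes with p < α in *both* systems, carrying
both Δs. Quadrant assignment uses strict sign comparisons; Δ = 0 genes
(measure-zero in real data, constructible in tests) are excluded and
counted. Sensitivity and specificity treat in vitro induction as the
classifier and in vivo induction as the state — an undefined denominator
reports a missing value, never 0. The restricted analysis recomputes all
metrics on the subset of common genes annotated to one configured term.

Attenuation considers genes significantly induced by the insult
(p < α and Δ_MS > 0) and reports the fraction whose Δ_FM < 0, the count
of drug-significant genes, and r(Δ_MS, Δ_FM).

## Synthetic data generator

The generator emulates the two-system design: in vivo S/M/F with n = 3
per group; in vitro control/LPS with 4 matched pairs. Gene-level log2
means are baseline + condition effect; observations are
2^(mean + probeset affinity + pair intercept + N(0, σ)) — i.e. log2-normal
intensity noise with additive effects, matching the analysis's log2
workspace (no noise model is implied by the consumed data format, so the
simplest model consistent with the analysis scale is used).

Defaults, which are the designed study conditions: 10,000 genes; 400
shared program genes induced in both systems; program effect s = 1.5
log2 units applied *exactly* (s is defined as the mean induction, and a
constant effect is the simplest distribution with that mean — it also
keeps the generator's power properties transparent); drug attenuation
λ = 0.8, i.e. F retains (1−λ)·s of the insult effect, applied to program
genes only (system-specific in vivo responders keep their full effect
under the drug); 150 responder genes specific to each system with
effect ±s; baseline log2 ~ N(8, 1.5²); residual noise σ = 0.25; probeset
count per gene uniform on {1, 2, 3} with affinity offsets N(0, 0.3²);
per-preparation random intercepts N(0, 0.3²) shared between the control
and LPS sample of a pair, which is what makes the paired test's
advantage real in the synthetic world; detection calls drawn from a
logistic model in observed log2 intensity with 50% Absent at log2
intensity 5 and unit slope, plus a 5% Marginal rate among detected
cells. Everything is reproducible bit-for-bit from the seed.

The program genes are annotated to a designated inflammatory-response
term whose ancestors (response to wounding → response to external
stimulus → root, plus immune system process) carry additional random
direct annotations so the hierarchy behaves like a real ontology
(ancestors are strict supersets); background terms of random size
complete the annotation.

What the generator does **not** emulate: probe-level MAS5 behavior,
spatial or batch artifacts, array-wide normalization errors,
heavy-tailed or intensity-dependent variance, and correlated gene
modules beyond the single shared program. Passing tests therefore
demonstrate correctness of the analysis machinery and its power under
idealized noise, not robustness to real-array artifacts.

## Numerical and design notes

* Tests never compare floats for equality except where values are exact
  by construction; table sorts break ties by gene or term identifier so
  outputs are byte-deterministic for a fixed seed.
* Welch's test at n = 3 per group is conservative by nature: its true
  two-sided size at α = 0.05 is ≈ 0.035 on ideal normal data (any
  correct implementation, including reference libraries, measures the
  same). Calibration checks on the paired t and ANOVA stages land within
  binomial error of α at the same group sizes.
* The rank-based term test is a rank-sum (two-sample) comparison of a
  category against its complement on one ranked list; the historical
  label "signed rank" attached to this style of GO analysis describes
  the signed output score, not a one-sample signed-rank statistic.
* Monotonicity and null checks of cross-system correlation are run at
  the full default scale: at a few thousand genes the s = 0 common set
  contains only a handful of false positives and single-run r estimates
  are too heavy-tailed to average meaningfully.
* Simulation-based checks use 2,000-gene scaled configurations with 20
  seeds where the quantity under test is a per-gene rate (type-I error,
  reversal fractions), and full-scale runs where it is a set-level
  statistic (correlation, GO ranking).

## Limitations

* The paired in vitro test requires explicit pair identifiers; samples
  without a partner are excluded from that contrast (logged).
* No moderated/shrinkage variance estimation; with n = 3 the per-gene
  variance estimates are noisy and power is limited at small effects.
* GO analysis treats terms independently — no elim/weight-style
  decorrelation of nested terms, so ancestors of a strongly associated
  term also score highly.
* The Fisher test and quadrant metrics condition on the significant-in-
  both gene set; they quantify directional agreement, not an unbiased
  population-level association.
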