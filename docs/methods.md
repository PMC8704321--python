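# Methods

## The ternary relation model

A thresholded bioactivity dataset over ligands L (n = |L|) and targets T
(m = |T|) is modelled as a total map from the L × T grid to the state set
{active, inactive, null}. Totality is an invariant, not an assumption: a
pair absent from the input *is* the null state, so construction fills
unmentioned cells with null and refuses duplicate (ligand, target) entries
outright (resolving duplicates is the thresholding step's job, where the
domain semantics — conflicting assay calls — are known).

The abstract three-dimensional relation is never materialised. The dense
n × m state-code matrix is the relation; the projection to a per-state
binary incidence is a state-equality mask, and the per-ligand (or
per-target) profile is the row (column) split into the three subsets
S+, S−, S∅. Faithfulness is enforced by tests: incidence cardinalities
equal class cardinalities, the three incidences sum to the all-ones matrix,
and rebuilding the relation from its projections is the identity.

Profile subsets carry their reference set and implement intersection/union
as elementwise min/max of characteristic vectors; operations across
different reference sets are refused rather than silently aligned by name.

## Completeness

GDC = (#active + #inactive)/(n·m); LDC(l) and LDC(t) are the row and column
restrictions. Since all rows have length m, mean_l LDC(l) = GDC = mean_t
LDC(t) holds algebraically; `completeness_report` asserts it to 1e-12
relative tolerance as an internal-consistency guard. Distribution summaries
use the exact empirical step CDF over observed values (no binning, no
interpolation) and the midpoint convention for even-count medians — both
chosen so the report is a pure function of the data with no presentation
parameters.

`check_summary_counts` validates externally supplied summary tables (grid
size vs class counts vs printed totals) and *reports* inconsistencies
instead of reconciling them; published panel summaries do contain such
off-by-a-few internal contradictions and silently "fixing" them would hide
a data-quality signal.

## Simple polypharmacology

For ligand l with profile (S+, S−, S∅):

- Pmin = |S+|, Pmax = |S+| + |S∅|; the true target count P(l) lies in
  [Pmin, Pmax] whenever the observed states are correct (a structural
  guarantee, tested as such on synthetic data).
- The urn-model rate p̂ = |S+|/(|S+| + |S−|) estimates the probability that
  a null pair is active, conditioning only on the ligand's own measured
  pairs. The shrunken upper bound P̃max = |S+| + p̂·|S∅| is an expectation
  value and is deliberately kept real-valued, never rounded.
- Error terms: ΔEmax = Pmax − Pmin = |S∅| and ΔẼ = p̂·|S∅| = P̃max − Pmin.

**Zero-denominator policy.** A ligand with no measured pairs has no
ligand-specific rate. The default fallback is the dataset-wide active
fraction among known pairs, always flagged `global-fallback` in output; a
strict mode emits flagged undefined values instead. The fallback is a
pragmatic prior — per-ligand rates in real panels vary widely, so the flag
matters more than the value.

**Confidence intervals.** p̂ is a binomial proportion with k = |S+|
successes in n = |S+| + |S−| trials. The Jeffreys Bayesian interval — the
central alpha/2, 1−alpha/2 quantiles of the Beta(k + 1/2, n − k + 1/2)
posterior, with the standard boundary conventions low = 0 at k = 0 and
high = 1 at k = n — is mapped affinely through the estimator:
CI endpoint = |S+| + q·|S∅|. Affinity and monotonicity make this exactly a
confidence interval for the mapped rate value |S+| + p·|S∅|. It is *not* a
prediction interval for the realised number of active null pairs: that
count carries additional binomial spread around p·|S∅| which the rate
interval does not model. The recovery harness reports both coverages
(`ci_coverage` for the mapped parameter, ≈ 1 − alpha under MCAR;
`ci_coverage_realized`, expectedly lower). alpha defaults to 0.05. n = 0
yields the flagged trivial interval (0, 1), which maps to [Pmin, Pmax].

## Joint polypharmacology

For a pair (l, l′) the 3 × 3 cross-tabulation of states over T partitions
the target set (nine disjoint cells summing to m). Then

- Pmin(l,l′) = |S+,+|; Pmax(l,l′) = |S+,+| + |S+,∅| + |S∅,+| + |S∅,∅|
  (the four cells in which neither ligand is known inactive);
- Pmin(l,l′) ≤ min[Pmin(l), Pmin(l′)] always (the (+,+) cell is contained
  in each ligand's active set);
- the shrunken bound is P̃max = |S+,+| + Pr(+,∅+)·|S+,∅| +
  Pr(∅+,+)·|S∅,+| + Pr(∅+,∅+)·|S∅,∅| with two probability modes:
  - **joint** mode conditions on doubly measured targets:
    Pr(+,∅+) = |S+,+|/(|S+,+| + |S+,−|), symmetrically for (∅+,+), and
    Pr(∅+,∅+) = |S+,+| over all four doubly measured cells;
  - **independence** mode factorises over the marginal urn rates:
    Pr(+,∅+) = p̂(l′), Pr(∅+,+) = p̂(l), Pr(∅+,∅+) = p̂(l)·p̂(l′). The
    marginals are recovered from the partition's row/column sums.

  Zero denominators follow the same flagged-fallback policy as the simple
  case; an empty cell contributes nothing regardless of its (possibly
  undefined) probability.

Self-pairs are permitted and reduce to the simple quantities (the partition
is diagonal). Pair reports enumerate unordered pairs l < l′ in reference
order, n(n−1)/2 rows; the one-ligand-vs-all mode emits n − 1 rows.

**Joint confidence intervals.** No closed form exists for the distribution
of the joint estimator, so the interval is propagated by Monte Carlo: each
underlying proportion is sampled from its Jeffreys Beta posterior (joint
mode: the three cell estimators' k, n; independence mode: the two marginal
posteriors, with the product term sampled coherently as the product of the
same draws), the estimator is evaluated per draw, and the empirical
alpha/2, 1−alpha/2 quantiles are reported. Draws are seeded and
deterministic; per-pair seeds in reports are spawned from the run seed via
`SeedSequence`, so reports are byte-reproducible. Default 4,000 draws
(quantile Monte Carlo error well under the count scale's resolution; a
minimum of 1,000 is enforced). A proportion with an empty denominator and
no fallback is sampled from the Jeffreys prior Beta(1/2, 1/2) itself.

## Thresholding protocol

Quantitative Kd/Ki records are normalised to molar (accepted unit tokens:
M, mM, uM/µM, nM, pM) and called inactive when *strictly larger* than the
3 µM default cutoff, so a pair at exactly 3 µM is active; pKd/pKi records
are called inactive below 5.5 (≥ 5.5 active). The two scales are treated as
independent thresholds: 3 µM corresponds to pK ≈ 5.52, so a pair measured
both ways can in edge cases disagree — and then falls under the conflict
rule like any other disagreement. Qualitative "not active" annotations are
inactive. All calls for a pair must agree; any mix of active and inactive
yields null. The rule is idempotent and order-independent (tested
exhaustively over call multisets), and it never invents a consensus.
IC50 and other measure types are rejected — the cutoff semantics are
defined for binding constants only.

## Synthetic data

The generator emulates the structure of real kinase panels: each (l, t)
pair is truly active with a per-ligand probability (scalar or vector;
default 0.1, a realistic kinase-panel hit rate at a 3 µM cutoff), and each
cell is observed independently with probability given by the observation
model — uniform MCAR at a default completeness of 0.685 (the reference
panel's GDC), or a block model of rectangular "islands of data" with
per-block completeness over a sparse sea, mimicking the union of dense
panel assays. An optional bias parameter makes active pairs more likely to
be observed (observation probability min(1, c·(1 + bias))), emulating
under-reporting of inactives; under bias the urn rate is upwardly biased
and CI coverage is expected to degrade — documented behaviour, not an
asserted guarantee. One seeded generator drives truth and mask; identical
spec + seed reproduce the dataset bit-for-bit.

What the generator does *not* emulate: correlation between chemically
similar ligands, target-specific activity rates, and measurement error in
the observed states. Passing recovery tests therefore demonstrate the
estimators' arithmetic and their MCAR calibration, not robustness to
informative missingness or assay noise in real panels.

The recovery harness (`recovery_trial`) regenerates the dataset across
replicates and reports structural containment of the true polypharmacology
in [Pmin, Pmax] (1.0 by construction), both CI coverage readings (see
above), and the bias/MAE of the urn rate. Test problem sizes: the
calibration check runs 5 ligands × 433 targets × 200 replicates
(1,000 ligand-level checks, binomial SE ≈ 0.007 at 95% coverage); the
identity suite runs 1,000 random relations up to 50 × 100; oracle
equivalence runs 500 random relations up to 6 × 6 against an
explicit-triple enumeration.

## Numerical and design choices

- State codes are int8 (0 active, 1 inactive, 2 null) in a read-only dense
  matrix; identifiers are opaque, case-sensitive, whitespace-trimmed
  strings; internal indexing is 0-based with external outputs always on
  string ids.
- Expectation values and CI endpoints are reported to 10 significant
  digits in TSV; empty fields denote flagged-undefined values.
- The dense-grid serialisation uses "1"/"0"/"." so sparsity is visually
  obvious and null cannot be confused with inactive; both serialisations
  round-trip exactly.
- Ligand subsampling (`--sample-ligands`) draws without replacement from a
  seeded generator and keeps reference order, so subsampled runs are
  reproducible.

## Known limitations

- Single activity cutoff; no multi-threshold or concentration-dependent
  partitioning, and no weak/strong activity stratification.
- The urn model conditions on the ligand alone; with informative
  missingness (publication bias) its rate estimate is optimistic, and the
  package only flags, not corrects, this.
- Joint-mode probabilities are undefined for pairs with no doubly measured
  targets (fallback applies); the independence mode ignores any real
  correlation between the two ligands' activity profiles.
- The joint CI is a Monte Carlo construction over independent cell
  posteriors; it does not model the multinomial coupling between cells of
  one partition.
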