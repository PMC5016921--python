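# Methods

## Model

A criterion hierarchy is a tree with the decision goal at level 1. In the
packaged study hierarchy the goal splits into four *information fields*
(medical questions, research, current events, social counselling and
assistance services); three of the fields split further into three
*information types* each, while *current events* has no subdivisions and is
treated as a leaf criterion whose global weight is simply its field weight.
This gives 13 criteria, 10 leaves, and 15 pairwise comparisons per
questionnaire (6 among the fields, 3 × 3 among the types).

Respondents judge each pair of siblings on the 9-point ratio scale
{1/9 … 1/2, 1, 2 … 9}. Judgements below 1 are stored as exact rational
reciprocals so that the comparison matrix obeys a_ij · a_ji = 1 bit-exactly;
floating point enters only at eigencomputation.

Local priorities are the normalized principal right eigenvector of the
comparison matrix, computed by power iteration from the uniform vector to a
componentwise relative tolerance of 1e−12 (at most 10,000 iterations; for a
positive matrix the Perron eigenvector is unique, and non-convergence is
practically unreachable). The eigenvalue estimate at a normalized iterate w
is Σ(Aw). A dense general-purpose eigensolver serves as the independent
cross-check in the tests, never as the implementation. Global leaf weights
are products of local weights along the root-to-leaf path and sum to 1 by
construction.

Consistency is measured by CI = (λ_max − n)/(n − 1) (floored at 0 against
roundoff; λ_max ≥ n holds for every positive reciprocal matrix) and
CR = CI/RI(n). The RI constants for n = 2…10 are the classic Saaty values
(0.00, 0.58, 0.90, 1.12, …), kept as configuration because variant tables
exist in the literature. An RI can also be estimated by simulation — the
mean CI of random reciprocal matrices with uniform scale-valued upper
triangles. Note that this estimator concentrates near 0.52 for n = 3, not
at the classic table constant 0.58; the table remains the default because
CR thresholds in the applied literature are calibrated against it. For
n = 2 a reciprocal matrix is always consistent and CR is defined as 0
rather than dividing by RI = 0.

## Screening

A respondent is included if every comparison matrix at each required
hierarchy level has CR ≤ threshold; the study convention is threshold 0.2
required at level 2 only (the single fields matrix), with ties at the
threshold included. A matrix's level is the level of the children it
compares. Requiring level 3 as well means every type matrix must also pass;
both variants are exposed via `ScreenPolicy` and tabulated by
`sample_size_curve`.

## Aggregation

Aggregation operates on priority vectors (aggregation of individual
priorities), not on raw judgements: the componentwise arithmetic mean,
geometric mean, or median of the included respondents' global weight
vectors, and likewise per node for local weights. Geometric-mean and median
aggregates do not generally sum to 1 and are renormalized (globally over
leaves; per node for locals); ranking is invariant to that rescaling. Ranks
are competition-style ("1224"): descending weight, ties share the smallest
rank of their group and are broken for display by leaf id; tie occurrence
is reported via `AggregateReport.has_ties`.

`outlier_sensitivity` reports the L1 distance each method's aggregate moves
when one additional respondent joins the cohort. The arithmetic mean always
moves; the median of a constant-majority sample does not. One caveat worth
knowing: for a *maximally* adversarial outlier (every comparison reversed at
strength 9) the renormalized geometric aggregate can move farther than the
arithmetic one, because a single near-zero weight shifts the log-space mean
strongly. For realistic outliers — e.g. a respondent who rates one field 9×
against the cohort consensus — the familiar ordering
arithmetic > geometric > median holds, and that is the configuration the
tests pin.

## Individual-vs-group analytics

Local rank comparison reports, per internal node, the ordering of children
under each of two aggregate reports and whether the orderings coincide.
Priority distributions are summarized per leaf and source as
min/Q1/median/Q3/max with type-7 (linear interpolation) quartiles — stated
because box-plot statistics depend on the convention. Answer distributions
fold each judgement to its magnitude max(v, 1/v) and report the cumulative
relative frequency at scale steps 1…9, so a cohort that uses the scale
uniformly lies on the diagonal.

The response-behaviour test is a two-sample t-test on pooled judgement
magnitudes, Welch's by default (the two pools have very unequal sizes and
variances); Student's pooled-variance variant is available. The unit of
analysis is the individual judgement, not the respondent: answers are pooled
across respondents and slots, so within-respondent clustering is ignored —
a known limitation that inflates effective sample size.

## Synthetic respondents

The generator emulates the study's data-collection design. Each respondent
shares latent local weights per internal node; an answered comparison is the
latent ratio w_left/w_right times a log-normal factor exp(ε),
ε ~ N(0, σ²) independent per slot, snapped to the nearest scale value in
log space (log-space snapping keeps 2 and 1/2 symmetric). Each respondent
draws from an RNG stream derived from (seed, stream index), so a cohort can
grow without reshuffling existing respondents.

Defaults mirror the study shape: 40 individual interviews and three
consensus groups of sizes (3, 4, 4). The default noise σ = 0.6 (log-ratio
scale) makes a minority of a 40-respondent cohort fail the CR ≤ 0.2 screen
at level 2 — around 5–8 respondents at typical seeds — matching the kind of
attrition real AHP interviews show. The default latent weights favour
medical questions, then social counselling, with diagnostics the top type,
mirroring the qualitative ranking such surveys report; they are
configuration, not an empirical claim.

Consensus groups answer jointly: members perturb the latent ratio
independently, the consensus is the geometric mean of the members' ratios,
clamped to answer magnitude ≤ 5 by default before snapping. The clamp is an
explicit model knob reproducing the observation that consensus judgements
avoid the strong end of the scale; geometric-mean averaging alone already
compresses group answers. This consensus rule can never produce a judgement
outside the members' range; modelling the occasional out-of-range group
consensus seen in real discussions would need a different rule and is a
documented extension point, as is any model of discussion dynamics or
demographic covariates.

What passing tests show — and do not show — about real data: the simulator
reproduces the *statistical shape* of such a study (consistency attrition,
compressed group answers, recoverable latent ranking), so the pipeline's
correctness and power properties are demonstrated on that shape. It does not
reproduce any real cohort's judgements, demographic structure, or the
clustering of answers within respondents.

Two power facts measured with this generator at the study's own shape:
(i) with σ = 0.3 and 40 respondents, arithmetic aggregation recovers the
latent top criterion in ≥ 95% of replicates (the suite runs 200); (ii) the
Welch test on a *single* cohort's pooled magnitudes (600 individual vs 45
group judgements) detects the group compression only part of the time —
three groups contribute little data — so the test-suite check pools ten
seeded cohorts, where the effect is unambiguous. A real study reporting a
strongly significant single-cohort difference reflects a larger
individual-group contrast than the generator's default σ and cap produce.

## Numerical conventions and problem sizes

- Eigenvector tolerance 1e−12 relative, componentwise; weights and global
  weights sum to 1 within 1e−10.
- Quartiles: type-7. Ranks: competition ("1224"). Scale parsing is exact
  (`Fraction`); CSV values are integers or `1/k` strings.
- CI floored at 0; CR defined as 0 for n = 2; λ_max below n − 1e−9 raises.
- The test suite's simulation sizes (cohorts of 5–100 respondents, 200
  recovery replicates, RI simulation at 20,000 matrices) were chosen to make
  the statistical assertions stable at conventional seeds while keeping the
  suite fast on a single CPU.
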