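# Methods

## The analysis

`symptomnet` implements cross-sectional symptom-network analysis for a
40-item mental-health questionnaire scored 0–3 per item (higher = more
severe), as used with persons living with HIV (PLWH). The instrument groups
36 items into six clusters — somatization (7 items), cognitive function (5),
negative affect (10), interpersonal communication (4), cognitive processes
(7), social adaptation (3) — with four standalone symptoms (sleep
disturbance, loneliness, sadness, anger).

The pipeline is:

1. **Exclusion.** Listwise deletion: any record with at least one missing
   item is dropped; the exclusion percentage is reported to one decimal.
2. **Scoring.** Per-item prevalence (share of participants scoring ≥ 1),
   severity (mean ± sample SD of the 0–3 score), cluster sum composites,
   cluster prevalence (any member item ≥ 1) and Cronbach's α per cluster,
   α = k/(k−1) · (1 − Σ item variances / variance of the item sum), all
   variances with denominator N−1.
3. **Network estimation.** Pairwise Spearman rank correlations (mid-ranks
   for ties) on raw ordinal scores give a weighted, fully connected
   undirected graph: a 40-node single-symptom network and a 10-node network
   over the six cluster composites plus the four standalone items. No
   thresholding, regularization or significance filtering is applied at
   estimation time; an optional `min_abs_weight` exists for display only.
4. **Centrality.** Strength (sum of absolute incident weights), closeness
   and betweenness on shortest-path distances with edge length d = 1/|r|,
   standardized to the [0, 1] reporting scale (r_S, r_C, r_B).
5. **Layout.** A weighted Fruchterman–Reingold embedding that pulls
   strongly correlated nodes toward the centre of the figure.

## Design choices where the convention was open

* **Prevalence threshold.** "Symptom present" is score ≥ 1. It is the only
  rule that reproduces the published count/percentage pairs (e.g. 358 of
  503 → 71.2%) under 0–3 scoring.
* **Cluster composite = sum, not mean.** Published cluster means (e.g. 7.25
  for the 10-item negative-affect cluster) exceed the per-item maximum of 3,
  which identifies the composite as a sum.
* **Rounding.** Percentages are rounded half-away-from-zero to one decimal;
  this mode reproduces every verifiable published percentage. One published
  row is internally inconsistent (somatization count 394 of 503 prints as
  78.5%, though 394/503 = 78.3%); the package always reports percentages
  computed from counts and treats the printed 78.5 as a typo.
* **SD denominator.** Sample SD (N−1), the convention of the instruments'
  psychometric literature.
* **Distance for closeness/betweenness.** d = 1/|r|, the dominant convention
  for correlation networks: stronger association = shorter path, and |r| ≤ 1
  bounds every finite distance below by 1.
* **Absolute weights for strength.** Sign handling of negative correlations
  is not standardized in the reporting convention; |·| keeps strength
  monotone in association magnitude.
* **Closeness on disconnected graphs.** Classic closeness times the
  reachable-fraction penalty (n_reachable − 1)/(n − 1) (Wasserman–Faust),
  which keeps r_C in [0, 1] without dropping nodes; an isolated node scores 0.
* **Betweenness ties.** Fractional (Brandes) credit over tied geodesics,
  normalized by (n−1)(n−2)/2.
* **Standardization modes.** Published values are ambiguous between two
  readings: cluster-network values (top node r_S = 1) imply division by the
  observed maximum, while symptom-network values (top r_S = 0.59 < 1) imply
  a theoretical maximum. Both are implemented — `theoretical-max` (default):
  r_S = strength/(n−1), r_C and r_B already ≤ 1; `observed-max`: each index
  divided by its maximum over nodes. Every output records the mode used.
* **Consensus ranking.** Per-index competition ranks (ties broken
  lexicographically by node id), consensus = mean of the three ranks.

## The synthetic-data generator

The raw study data are not deposited, so the generator supplies cohorts with
the statistical structure the analysis assumes. It is a Gaussian copula:
z ~ N(0, R) with R a latent correlation matrix; item j's score is the number
of cutpoints below z_j, the cutpoints being standard-normal quantiles of the
item's cumulative category probabilities. This controls marginals and
association independently.

* **Calibration.** Default marginals are fitted to the published per-item
  prevalence/mean-severity pairs of the N = 503 reference cohort. Matching
  two moments leaves one degree of freedom over the three positive
  categories; it is resolved by a geometric allocation
  p1 : p2 : p3 = w : w² : w³ with w > 0 solving the mean constraint
  (deterministic, smooth, spans the whole feasible range; a two-point {1, 3}
  split is the fallback at the boundary).
* **Latent structure.** Default is dense and positive — 0.6 within clusters,
  0.3 between (standalone items behave as singleton blocks) — emulating the
  high network density the analysis context reports. This decomposes into a
  sum of PSD terms, so it needs no repair.
* **Planted hubs.** `plant_hub` sets one item's latent correlations to a
  hub value (default experiments: 0.7) against an exchangeable background
  (0.2). Such designs are indefinite for more than a few items; the matrix
  is projected to the nearest PSD correlation matrix (eigenvalue clipping +
  diagonal renormalization, warning with the Frobenius distance). The
  projection shrinks the realized hub correlation (≈ 0.47 at 40 items) but
  preserves the hub's dominance, which is the property the recovery
  experiments measure.
* **Reproducibility.** One `numpy.random.default_rng(seed)` stream per
  `generate_responses` call; identical specs give byte-identical matrices.

What the generator does **not** emulate: the real items' inter-item
correlation matrix (unpublished), demographic covariates and subgroup
structure, differential item functioning, and any missingness mechanism
beyond complete/incomplete. Passing recovery tests therefore shows the
pipeline identifies structure correctly when the generative assumptions
hold, not that the published substantive findings are confirmed.

## Layout

Weighted Fruchterman–Reingold with repulsion k²/d, attraction w·d²/k
(k = √(area/n), w = |r|), seeded uniform initial positions, linear cooling
from t₀ = 0.1·√area over 500 iterations (both configurable; the temperature
schedule accepts a callable). The final configuration is centred and
uniformly rescaled so the maximum distance from the centroid is 1, which
fits the layout in [−1, 1]² while keeping pairwise distances equivariant
under rotations of the initial placement (per-axis bounding-box scaling
would not be). Figures are qualitative; no numeric check depends on layout
output.

## Numerical conventions

* Symmetry tolerance 1e−12 and eigenvalue tolerance −1e−10 for latent
  correlation matrices; category probabilities must sum to 1 within 1e−9.
* Geodesic ties are detected at 1e−12 relative tolerance.
* CSV output uses 17 significant digits and readers parse with round-trip
  float precision, so write/read reproduces matrices exactly.
* Constant columns (impossible in real complete data, possible in small
  simulations) have undefined rank correlations: the estimator either
  raises or, on request, drops and records the node.

## Problem sizes used by the test suite and acceptance script

Simulated cohorts use n = 503 (the reference cohort size) for pipeline and
recovery runs; marginal-recovery checks use n = 50,000 and association
monotonicity n = 20,000 per grid point; the Monte-Carlo copula oracle uses
10⁶ draws; exhaustive centrality oracles run on 50 random graphs of at most
8 nodes, where path enumeration is exact. Hub-recovery experiments use 20
seeded replicates at n = 503 (40 items) and n = 2,000 (10 items).

## Known limitations

* The exact published results — specific edge weights (r = 0.85, 0.84,
  0.81), centrality values (e.g. r_S = 0.59 for sadness), severity means/SDs
  and subscale α values — are **not** reproducible without the undeposited
  raw data: correlations cannot be derived from published marginals alone.
  The package therefore validates those stages with oracle-equivalence and
  parameter-recovery experiments on calibrated synthetic cohorts instead,
  and ships the published table only as calibration targets and rounding
  fixtures, never as asserted outputs.
* Cross-sectional networks only: no longitudinal/dynamic modelling, no
  causal claims, no regularized partial-correlation estimation, no
  bootstrap stability analysis.
* The instrument description lists the sleep item once as "sleep
  satisfaction"; the symptom table and figures use "sleep disturbance"
  (consistent with higher-is-worse scoring), which this package follows.
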