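# Methods

## Scope and model

`stromanet` analyses compartment-resolved RPPA data from a two-group cohort
design: cases are stratified by an ordinal IHC expression-ratio rule, and the
two strata's signaling architectures are contrasted as thresholded Spearman
correlation networks. The analysis assumes (i) one abundance value per
case × compartment × endpoint after dilution-series reduction, (ii) that
rank correlations at ρ ≥ 0.75 with p ≤ 0.01 mark biologically meaningful
co-variation at n ≈ 9 per group, and (iii) that the difference between the
groups is captured by *set algebra on edges* — shared edges are background,
exclusive edges are the differential signal. No multiple-testing correction
is applied across the 435 pairs or the 30 endpoint comparisons; that is a
property of the method being implemented, documented rather than "fixed".

## IHC ratio classification

Scores are integers 0–3 per compartment. The classifier is the signed rule
`high ⇔ epithelium − stroma ≥ 2`. The signed (not absolute) difference is a
deliberate choice: a *high epithelium:stroma ratio* semantically means
stroma-low, so stroma-dominant cases classify low. The packaged 19-case
reference cohort enumerates the ten high-ratio pairs directly
((3,0)×1, (3,1)×6, (2,0)×3) and completes the nine low-ratio pairs uniquely
from the cohort's epithelial (8 strong / 9 moderate / 2 weak) and stromal
(2 moderate / 12 weak / 5 absent) score marginals together with the two
individually described low-ratio cases (3,2) and (1,0); the completion is a
documented reconstruction of the published distribution, not a per-case
record.

## RPPA quantification

* **Replicates** are arithmetically averaged before normalization.
* **Normalization** divides each endpoint spot by the ssDNA spot of the same
  case, compartment and dilution step (nearest step as fallback, logged).
  ssDNA staining scales with cell number, so the ratio corrects loading.
* **Detection floor** defaults to 2× the median negative-control intensity;
  spots at or below it are dropped before reduction.
* **Reduction**: the published pipeline delegates this step to an
  unpublished spreadsheet macro, so the reducer here is this package's own
  documented procedure: the geometric mean of dilution-corrected values
  `d · I(d)` over usable spots. Under the ideal dilution law `I = A/d` every
  term equals the undiluted abundance A, so the reducer is exact on ideal
  data; the geometric mean makes multiplicative noise average in log space.
  A **linearity flag** records whether the least-squares slope of
  log2 I vs −log2 d is within `slope_tolerance` (default 0.3) of 1; flat
  (saturated) or erratic series are flagged but still reported. Fewer than
  two usable points ⇒ the endpoint is missing for that case and downstream
  correlations use pairwise-complete observations.
* **QC**: per case × compartment, a one-sided Welch t-test of the 30
  undiluted endpoint spot intensities against all negative-control spot
  intensities; a case passes iff p < 0.05 *and* its mean exceeds the control
  mean. Welch was chosen because the criterion "not significantly different
  from the negative control" implies a location test and unequal variances
  are expected between antibody signal and background. A case failing in
  either compartment is excluded from all network analysis. Degenerate
  (constant, identical) inputs fail with the p = 1 convention.

## Correlation networks

Spearman ρ uses average ranks; p-values use the two-sided t approximation on
n−2 df (the default of the commercial packages this analysis style was
developed in), with |ρ| = 1 reported at the exact permutation value 2/n!.
An exact full-enumeration permutation p (n ≤ 8) is available and is the test
oracle at n = 5. Pairs with fewer than four complete observations or zero
rank variance are skipped and counted. The significance filter applies
**both** conditions; this matters because at n = 9 the t approximation gives
p ≈ 0.017–0.019 at ρ = 0.76, so p ≤ 0.01 is strictly stricter than ρ ≥ 0.75.
The ρ threshold is one-sided positive by default (the rule is stated as
ρ ≥ 0.75, not |ρ|); `abs_rho=True` selects the absolute variant.

Shared/exclusive partitioning is set algebra on canonical (lexicographic)
endpoint pairs within one compartment; exclusive edges retain their own
group's ρ and p. The partition identity
|shared| + |exclusive_high| + |exclusive_low| = |union| holds by
construction and is property-tested.

Subgroup detection uses seeded Louvain modularity maximization (networkx) at
resolution 1.0 with ρ as edge weight — the closest documented analogue of
the modularity grouping that graph-visualization tools perform. Community
ids are relabelled contiguously by each community's lexicographically
smallest member, so labels are reproducible for a fixed seed.

## Group comparisons

Welch's t-test by default (robust at n ≈ 9–10), with a pooled-variance flag
for emulating either convention; two-sided, α = 0.05. Epithelium and stroma
come from the same cases, yet the comparison is implemented as an
*independent-samples* test because that is the specified procedure; a paired
test would be the statistically natural alternative and this discrepancy is
deliberate. Box-plot summaries use linear interpolation between order
statistics for quartiles (conventions differ across packages; this one is
fixed and tested against a brute-force oracle).

## Synthetic cohort generator

The generator emulates the study conditions: 10 + 9 cases whose IHC pairs
follow the reference distribution, 30 endpoints, 2-fold 4-point dilution
series, per-case×compartment loading factors (uniform 0.7–1.3), a
negative-control floor (Normal(50, 10) clipped at 0.1 scanner units, giving
a detection floor ≈ 100), and one case generated entirely at the floor so it
fails QC, leaving 9 + 9 for network analysis.

Endpoint abundances come from a Gaussian copula: per group × compartment a
correlation matrix embeds the planted blocks (shared blocks in both groups,
exclusive blocks in one), with the target Spearman ρ converted to the latent
Pearson correlation via r = 2·sin(πρ/6) (exact for Gaussian copulas).
Latents map to log-normal intensities: per-endpoint base intensities are
log-uniform in 1000–5000 scanner units, biological spread `latent_sd_log` =
1.0 (tumor protein levels commonly vary by an e-fold or more across cases),
spot noise `noise_sd_log` = 0.15. ssDNA spots are the loading factor times
its own multiplicative noise, constant in expectation across dilution steps,
which makes the normalized endpoint signal follow the 1/d law the reducer
assumes. The default plants six 4-endpoint blocks at target Spearman 0.9:
one shared, one high-exclusive and one low-exclusive block per compartment.

What the generator does **not** emulate: spatial array artifacts, antibody
cross-reactivity, heteroscedastic scanner saturation, the empirical edge
density of real cohorts (planted blocks are much sparser than the dozens of
significant correlations real tissue shows), and any per-case coupling
between IHC scores and RPPA values beyond the group label. Passing tests
therefore demonstrate correctness of the *procedure* under a faithful noise
and correlation model, not biological replication.

## Statistical power at the study's sample size, and frozen test thresholds

At nine cases per group the joint rule requires sample ρ ≥ ~0.798, and a
pre-build Monte-Carlo power calculation (bivariate Gaussian copula at target
Spearman 0.9, measurement noise as above) puts per-pair detection at ≈ 0.70;
through the full pipeline (floor dropouts, normalization noise) the measured
per-pair recovery of planted exclusive pairs is ≈ 0.68, and a *shared* pair
must be detected in both groups independently (≈ 0.5). Recovery thresholds
in the test suite were frozen from that calculation, before the tests were
written, at levels the study conditions can meet: mean exclusive per-pair
recovery ≥ 0.55, shared ≥ 0.30, correct-set assignment of detected exclusive
pairs ≥ 0.80 (measured ≈ 0.99 — partitioning errors require the same pair to
cross the threshold spuriously in the other group), and unplanted pairs
significant in ≤ 2% of slots. Power, not partitioning, is the binding
constraint at this sample size.

## Numerical and design choices

* Edge identity: unordered lexicographic pair, so set algebra is
  well-defined across groups.
* Ties in ranks: average ranks (deterministic, standard).
* All randomness flows from one root seed (`numpy.random.default_rng`);
  pipeline reruns with the same config and seed produce byte-identical
  reports and edge tables.
* Test problem sizes: planted-recovery statistics use 100 seeded end-to-end
  cohorts; the null false-positive check uses 500 seeded 9 × 30 matrices;
  Welch calibration uses 5000 replicates; large-n generator consistency uses
  201-case cohorts. These sizes give Monte-Carlo standard errors well inside
  the asserted margins.

## Known limitations

* The dilution-series reducer is this package's own construction; the
  original study's reduction algorithm is not publicly described, so
  numerical equality with the original pipeline on real data is not claimed.
* The published headline edge counts depend on the study's raw intensity
  tables, which are not deposited; they are therefore not reproduced here —
  the properties of the procedure (denominator, thresholds, partition
  identity, calibration, recovery) are tested instead.
* Whether the original QC was applied per case or per case × compartment is
  not stated; this implementation tests per case × compartment and excludes
  the whole case if either fails.
* One- vs two-sided Spearman p in the original analysis is unknown; the
  default here is two-sided, and the one-sided variant is obtainable by
  doubling p_max.
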