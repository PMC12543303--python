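# Methods

## Data model

A cohort is a set of participants, each carrying five symmetric weighted
adjacency matrices over one fixed atlas (119 nodes at the reference
scale: 100 cortical parcels across seven resting-state networks, of which
24 form the default mode network, plus 19 subcortical parcels).  Four
structural weightings come from fixel-based analysis over a template
tractogram — average fiber density (FD), average log fiber-bundle
cross-section (logFbC), combined fiber density-and-cross-section (FDC),
each multiplied by the edge's streamline count — plus a plain per-subject
streamline count.  The functional matrix holds signed Fisher-Z
transformed BOLD correlations and is dense off the diagonal; matrices
are stored already in Z space and no r-to-z transform is applied on load.

Missing structural edges (no streamline support) are carried as an
explicit boolean mask.  A zero weight and an absent edge are different
things: absent edges are excluded from every mean, correlation and
strength, never imputed as zero.  On disk the missing token is `NA`.
Edge vectors are the strict upper triangle in row-major order
(N(N−1)/2 = 7,021 entries at N = 119); vectorization and file I/O are
exact inverses, with `float_precision="round_trip"` on read and 17
significant digits on write.

The fixel edge weight is the mean of the *nonzero* fixel values along a
connection multiplied by its streamline count; an edge whose fixel values
are all zero has no usable fixel support and is missing.  The weight is
linear in the streamline count and invariant to fixel ordering.

## Coupling statistics

Coupling is a Pearson correlation between matched SC and FC quantities.
Only direct connections enter: FC edges without a structural counterpart
are dropped from edge-level couplings.  Four levels:

- **Subject-overall** — within one participant across edges (whole
  connectome, within-network, or within-DMN), optionally restricted to
  positive-only or negative-only FC edges; FC values exactly zero are
  excluded from the signed variants because their sign is undefined.
- **Group-average** — each edge averaged over the group's participants
  (pairwise deletion per edge), then one correlation over edges.  The
  edge is the sampling unit of this correlation, so the Fisher r-to-Z
  comparison of two groups uses the edge counts as the effective n (the
  subject counts are also surfaced for sensitivity checks).
- **Edge-wise** — r across participants per edge, per group.
- **Node-wise** — r across participants per node using nodal strengths.
  Strength is the plain signed sum of present incident edge weights
  (negative FC included as-is, no normalization).  FC strength sums
  *all* functional edges of the node, not only those with SC support;
  the same whole-brain convention is applied to SC strength.

Correlations need at least 3 pairs; edge-wise and node-wise correlations
additionally require 10 contributing subjects (tiny-n correlations are
unstable and would dominate permutation tails — the threshold is a
package choice, configurable per call).  Deletion is pairwise throughout:
across edges within a subject and across subjects within an edge.
Per-subject DMN coupling yields two values: the within-DMN edge coupling
and the correlation of SC vs FC strengths over the 24 DMN nodes.

## Inference

**Permutation tests.**  The exchangeable unit is the participant: each of
the 5,000 permutations (configurable) reassigns the pooled subjects of
the two groups to pseudo-groups of the original sizes with each subject's
SC and FC kept paired, and recomputes every per-key coupling difference.
Two-tailed p uses the add-one estimator (1 + #{|null| ≥ |obs|}) / (1 + B),
which is exchangeability-valid and never zero.  Each key is compared with
its own null (no pooled max-statistic), because FDR is applied afterwards
and needs per-key p values.  An exhaustive mode enumerates every
assignment for small pools and reports the exact proportion.  Null
distributions are also validated empirically: under the null generator
the p values are uniform (Kolmogorov–Smirnov) and the false-positive
fraction at 0.05 sits in its binomial band.

**Multiplicity.**  Significance threshold p < 0.01 Bonferroni-corrected
across the four SC weightings → 0.0025.  Benjamini–Hochberg FDR is
implemented directly (step-up, capped, monotone) and pooled across all
edges of all comparisons when runs are combined.  Note BH adjusted values
are *not* idempotent in general (p = [0.25, 1.0] → q = [0.5, 1.0], which
re-adjusts to [1.0, 1.0]); the tested invariants are order invariance,
domination of the raw p and rank monotonicity.

**ANCOVA.**  Subject-level couplings are modeled as
`coupling ~ group + age + sex` (Type II F for group).  Post hoc group
contrasts are estimated-marginal-means differences: design rows evaluated
at the covariate means, averaged with equal weight over sex levels, with
t statistics on the model residual df (387 at the reference size:
392 subjects, 3 group levels, age, sex — 5 parameters).

**Demographics and outcomes.**  Sex-by-group uses the chi-square
independence test (no continuity correction) with adjusted standardized
residuals (O − E)/√(E(1 − row/N)(1 − col/N)).  Cognitive outcomes use
one-way ANOVA with df = (groups − 1, N − groups), Tukey HSD (validated
against a direct studentized-range computation), and pairwise Wilcoxon
rank-sums with FDR over pairs.

## Memory composite (one-factor CFA)

The four RAVLT scores (learning, immediate, 30-min delay, recognition)
are min-max scaled to [0, 1] and fit with a single latent factor:
x_k = λ_k η + e_k, η ~ N(0, 1), uncorrelated residuals.  The factor is
identified by fixing the latent variance (all loadings free), which keeps
loadings comparable and makes recovery tests clean.  Complete cases only
(the reference cohort has 349 completers of 392); at least 50 required.

Estimation minimizes the ML discrepancy
F = log|Σ(θ)| + tr(SΣ⁻¹) − log|S| − p with analytic gradient, on the
correlation matrix (F is invariant under diagonal rescaling, and the
correlation scale is well-conditioned regardless of the 0–1 scaling),
in two passes: first with residual variances parameterized as exp(θ) so
Σ stays positive definite, then a free-ψ refinement from that optimum so
a Heywood case (negative residual variance) can be reached — it is
reported via a flag, never clipped.  S uses the n−1 denominator and
χ² = (n−1)·F at the optimum; df = 10 moments − 8 parameters = 2.
CFI compares against the independence baseline; RMSEA is
√(max(0, (χ²−df)/(df(n−1)))) with a 90% interval from the noncentral
chi-square; SRMR averages squared standardized residual moments over the
p(p+1)/2 unique entries.  Factor scores use the regression method and
are min-max scaled to [0, 1], with the scaling minima/maxima recorded so
held-out scoring is reproducible.  Standard ML is used throughout (no
robust corrections).

## Coupling-on-cognition regressions

One model per SC weighting and outcome (MMSE, memory composite):
`outcome ~ dmn_edge_coupling + dmn_node_coupling + age + sex + icv`.
The response and continuous predictors are z-scored (betas are
standardized); sex stays 0/1.  Diagnostics per model: VIF, tolerance
(= 1/VIF) and the maximum pairwise predictor correlation, flagged at
VIF > 10, tolerance < 0.02 and |r| > 0.8.  The FDR family is the set of
coupling coefficients across all models (4 weightings × 2 outcomes ×
2 terms = 16 tests); covariates are excluded from the family.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes;
it starts at the connectome level and simulates no BOLD series,
tractography or fixel images.  Defaults are the reference study
conditions: 225 CN / 142 MCI / 25 AD, 119 nodes with 24 DMN nodes,
5,922 fixel-SC edges of 7,021, ~349 RAVLT completers.

- **Masks.**  One fixel-SC mask shared by the whole cohort (edges derive
  from a single template tractogram), drawn once at exactly
  round(density × 7,021) edges.  Streamline SC gets per-subject masks
  (per-subject tractography): each edge present independently at the
  mean density.  The reference streamline edge count (11,676 in the
  119×119 matrix) exceeds the 7,021 undirected pairs and is therefore
  read as a directed-cell count; the generator uses 11,676/2 ≈ 0.83
  density.
- **SC weights.**  Per-edge log-normal FD and FbC values around cohort
  edge profiles (log-scale SD 0.30 within edge, 0.30–0.35 across edges);
  FDC = FD × FbC at the fixel-value level; every fixel weight is the
  fixel value times the edge's template streamline count; streamline SC
  draws dispersed counts around per-edge log-normal means.  The
  log-normal forms are a modeling choice recorded in the ground-truth
  output, not a claim about any real cohort's distributions.
- **FC.**  FC_e = ρ_g·z(SC_e) + b_{g,e}·w(SC_e) + √(1−ρ²)·(baseline + noise),
  where z standardizes the subject's own FD edge weights within subject
  — so the expected subject-overall coupling equals ρ_g *exactly*,
  with no noise calibration — and w standardizes each edge across
  subjects via the analytic log-normal moments, so planted slopes
  b_{g,e} (nonzero only on designated edges, optionally all edges
  incident to planted nodes) drive edge-wise and node-wise group
  differences with known sign.  Half the noise variance is a shared edge
  baseline, giving FC a stable profile across subjects.  FC is dense and
  signed, scaled so |FC| stays mostly below 1.5 (Fisher-Z realism).
- **Cognition.**  Latent memory M = group shift + effect·z(DMN nodal
  coupling) + noise; four RAVLT indicators load on standardized M with
  loadings (.9, .9, .8, .7) and unit-total variance, mapped to plausible
  RAVLT scales; MMSE is an integer-rounded linear map of standardized M
  clipped to 0–30.  Group shifts (CN +0.5, MCI −0.4, AD −1.6 SD) produce
  the CN > MCI > AD ordering; per-group RAVLT missingness reproduces the
  completer counts.  Covariates roughly match the reference means/SDs,
  including the female excess in CN.

All randomness flows from one integer seed; a fixed config is
bit-reproducible.  Planted parameters are echoed in
`Cohort.ground_truth`.

What passing tests show — and don't: the generator plants effects in
exactly the functional form the estimators assume (linear coupling,
normal noise, one-factor cognition), so recovery tests validate the
*statistical machinery*, not the realism of fixel metrics, spatial
autocorrelation, site effects or head-motion confounds, none of which
are simulated.

## Problem sizes and numerical choices

Validation runs use scaled-down cohorts chosen to keep Monte Carlo error
well inside each acceptance band: permutation calibration uses 2×50
subjects, 200 edges and 500 permutations averaged over 5 replicate
cohorts (binomial SE of the mean false-positive fraction ≈ 0.007);
coupling recovery uses 200 subjects (SE of the mean subject coupling
< 0.01); CFA recovery reports the median over 5 replicate cohorts of
392 subjects (per-fit max-loading error has sampling SD ≈ 0.02 at
n ≈ 350, so a single draw occasionally exceeds 0.05 by chance while the
median is stable near 0.03).  Symmetry tolerance on foreign files is
1e-8 relative (files written by this package are exactly symmetric).
Pearson correlations guard zero variance at 1e-14 and clip to [−1, 1]
against rounding.

## Known limitations

- Edge- and node-level coupling is cross-sectional: one (SC, FC) pair
  per subject per key, so per-subject edge-specific coupling is not
  identifiable — only group-level per-key correlations.
- No indirect/communication-model SC–FC measures (shortest paths,
  diffusion); only direct connections are kept.
- No spatial-autocorrelation-preserving nulls and no cluster/NBS
  enhancement; the permutation null is pure label exchange.
- The CFA is standard ML; robust (scaled) fit statistics are not
  implemented, which can matter for strongly non-normal indicators.
- The generator's streamline SC is independent of its fixel SC given the
  masks, which understates the correlation between SC weightings seen in
  real data.
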