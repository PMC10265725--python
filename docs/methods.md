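# Methods

This note documents the models the package implements, the defaults it
ships, the numerical choices behind them, and what the synthetic cohort
does and does not emulate.

## Network construction

A scan's connectome is the symmetric 90×90 matrix whose entry (i, j) is
the arithmetic mean FA of all fibres assigned to the unordered region pair
{i, j} of the AAL-90 parcellation; pairs without fibres get weight 0.
Self-loops in a fibre table indicate an upstream assignment bug and are
rejected rather than dropped. Edges are defined by weight > 0 exactly; no
minimum-streamline or weight threshold is applied. Node indexing is
1-based in files and 0-based internally; in atlas order, homologous
regions alternate left/right, so odd 1-based indices are left-hemisphere.
Scans whose positive-weight graph does not form a single component over
all 90 nodes are excluded before any path-based metric is computed, with
the reason logged per scan.

## Graph metrics

All path-based metrics convert weights to lengths as ℓ = 1/w, the
standard convention for FA-weighted connectomes (stronger = shorter).
Distances come from Dijkstra's algorithm (`scipy.sparse.csgraph`);
betweenness uses Brandes' accumulation with tied shortest paths
(tolerance 10⁻¹² relative) splitting counts proportionally, and each
unordered source–target pair counted once.

Weighted clustering is the Onnela geometric-mean-of-triangles form on
weights normalized by the network-wide maximum:

    NCp(i) = (2 / (k_i (k_i − 1))) Σ_{j<h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3},  ŵ = w / max(w)

Nodes of degree < 2 contribute NCp = 0, and the global Cp averages over
all 90 nodes so that denominators are constant across scans. The field
uses several weighted clustering variants; this one is scale-free in the
weights and matches the networkx convention, which the tests exploit as a
cross-check. It is a documented default, not asserted to match any
particular toolbox.

Small-worldness standardizes the empirical Cp and Lp against random
networks: each null is produced by degree-preserving double-edge swaps
(10 × edge-count accepted swaps; proposals creating self-loops or
duplicate edges are rejected), with edges carrying their weights, so every
null preserves both the degree sequence and the edge-weight multiset.
Nulls that come out disconnected are resampled from the original (bounded
retries) so the null path length is always finite, matching the
fully-connected analysis set. Then γ = Cp/⟨Cp_null⟩, λ = Lp/⟨Lp_null⟩,
σ = γ/λ. The production default is 1000 nulls per scan; demo runs and
tests use 50 or fewer, which changes ⟨·⟩ estimates by well under the
between-scan variability of γ and λ.

## Scanner harmonization

The metric table (scans × all global and nodal features in one pooled
run, so empirical-Bayes priors borrow strength across features) is
adjusted with the parametric ComBat location/scale model. Per feature v
and site i:

    y_ivj = α_v + x_j'β_v + γ_iv + δ_iv ε_ivj

The covariate matrix preserves group, days post-injury and days², age at
injury and sex. Site locations and scales are estimated on standardized
residuals and shrunk with a normal (location) / inverse-gamma (scale)
prior via the standard iterative conditional updates (tolerance 10⁻⁶, max
100 iterations). Conventions match the reference R implementation
(`sva::ComBat` with a model matrix): pooled variance with denominator N,
per-site scale with n_i − 1; the test suite verifies agreement to 10⁻⁶ on
a fixture. Choices worth noting:

- A single-site table is returned unchanged (zero location, unit scale):
  there is no second batch to harmonize against.
- Features that are constant across scans (e.g. degree under a fixed
  synthetic topology) carry no site signal and are passed through with a
  warning rather than degenerating the standardization.
- Repeated scans of a participant are treated as independent observations
  during harmonization; the longitudinal structure is handled downstream
  by the mixed model.
- The multiplicative site effect is modelled on the *unexplained*
  component, as in the generating model above. A scanner that rescaled
  biological effects themselves (a site × age interaction, say) is
  outside this model class and would survive adjustment.

## Reliable change index

For each rater (parent, child), 1-month post-injury symptom totals are
regressed on parent-rated premorbid totals by OLS over the reference
sample (all complete pairs by default; an OI-only reference is a config
option). SEE = √(Σe²/(n−2)). A participant's standardized change score is
z = (post − predicted)/SEE, and z ≥ 1.645 (one-tailed 5%; "persistent"
is a directional increase; config-exposed) labels persistent symptoms.
TBI participants split into persistent / non-persistent per rater; OI
participants are never reclassified; TBI participants missing a rating
are excluded from that rater's symptom-group analyses and logged. Under
the null generating model the persistent rate converges to the upper-tail
probability of the cutoff, which the tests verify at n = 10,000.

## Mixed-effects inference

Global metrics: `metric ~ Group × (Time + Time²) × (Age + Sex) +
(1 | participant)`. Nodal metrics add a Hemisphere main effect and use one
row per scan × hemisphere for the region's homologous node pair (the
hemisphere-moderation pre-check is available as a diagnostic, not a gate).
Codings are fixed: Group reference OI, Sex reference M, Hemisphere
reference L; days post-injury are centred and scaled by the sample SD
*before* squaring (conditioning of Time² over a 2–180 day range); age is
centred. The grouping is either 2-level injury (TBI indicator) or 3-level
symptom status (persistent and non-persistent indicators, OI reference,
per rater), with the persistent vs non-persistent comparison available as
a coefficient contrast.

Estimation is REML with a participant random intercept (statsmodels
MixedLM, fitted on the z-scored outcome for numerical conditioning and
mapped back). Degrees of freedom are Satterthwaite-type: for a contrast c,
df = 2f²/(g'Ag) with f = c'C(θ)c, g its gradient in the two variance
components (central differences), and A the inverse observed information
of the restricted likelihood. The suite checks estimates, SEs, df and
p-values against lmerTest on identical frames (df to ~0.002%). A
"residual" df mode exists as a cross-check. Optimizer fits that stop at
the σ²_participant = 0 boundary are accepted (the GLS solution is still
valid there; the df then fall back to residual df); only fits with no
finite solution are flagged non-converged and excluded from the FDR
family with a log entry. Outcomes that are constant across scans are
skipped.

FDR is Benjamini–Hochberg within a family defined as all group-involving
terms across the 45 regions for a given metric and grouping (the single
model for global metrics), at α = 0.05 for the injury grouping and
α = 0.025 for the symptom grouping (two raters). The family definition is
a documented default; the underlying procedure is `statsmodels
multipletests`, test-verified against the literal step-up definition.

Cohen's d divides an estimate or contrast by the total random SD
√(σ²_participant + σ²_residual); its 95% CI is the Wald interval mapped to
the d scale; effects are "robust" iff the CI excludes 0; bands are
negligible/small/medium/large at |0.20|, |0.50|, |0.80|. Significant
group-involving interactions are probed as group-difference contrasts on
the grid implied by which interactions are significant: mean days
post-injury of each visit (time), both sexes (sex), 10th/90th percentile
of age over unique participants (age); unprobed dimensions stay at the
reference/mean.

## Synthetic cohort generator

The generator's defaults encode the study conditions the pipeline is
designed for: 65/35 TBI/OI split, five sites, 60% male, ages uniform on
[8, 16.99] years, a post-acute scan at 2–33 days (truncated normal around
day 11), a second scan randomly assigned to ~90 or ~180 days (jitter SD 7
days) with 25% chronic attrition, and a latent persistent-symptom rate of
0.25 among TBI.

Connectomes derive from a single cohort-wide template: a Watts–Strogatz
ring lattice over 90 nodes (mean degree 12, rewiring probability 0.1 —
connected and small-world) with edge weights drawn once from Beta(8, 8)
scaled to [0.2, 0.8], an FA-plausible range. Per scan, in order: a linear
age trend on every edge (default 0.003 FA/yr, centred at 12.5 y), injected
ground-truth effects (a signed delta on all edges incident to target
regions when the participant/visit matches the effect's condition), site
effects applied to edge weights as w → scale·w + shift (defaults: shifts
0/±0.02/±0.01, scales 1/1.05/0.95/1.02/0.98) so harmonization is tested
against realistic propagation through the metrics rather than additive
noise on metrics, then i.i.d. symmetric Gaussian edge noise (SD 0.02),
and clipping to (0.01, 1] so FA stays bounded and no edge is deleted.
Symptom totals follow the regression structure the RCI assumes:
premorbid ~ rounded Gamma(2, 2.5); post = 1.0 + 0.8·premorbid + 1.0·TBI
(+ 2·SEE for latent-persistent) + N(0, 3), floored at 0.

What this emulates well: the data structure, seed-determinism, site
confounding at the edge level, covariate-linked baseline variation, and
localized group × time × sex/age effects with known ground truth. What it
does not: real FA edge-weight distributions and topology (unknown for any
specific cohort; all template choices are config-exposed), scan-to-scan
topology variation (the template is shared, so degree metrics are
constant by construction and their models are skipped), motion/artefact
processes, and item-level symptom questionnaires. Passing tests therefore
demonstrate correctness of the machinery and calibration under the
generating model, not claims about real cohorts.

## Simulation sizes used in the tests

Monte-Carlo tests fix their seeds and use sizes chosen so the sampling
error of the checked quantity is small against its tolerance: metric
oracles on 100 random graphs of ≤ 10 nodes; harmonization recovery at 200
scans/site; RCI calibration at n = 10,000; mixed-model type-I error over
25 replicates of 300 participants (rates pooled over the nine
group-involving terms); three-way-interaction recovery over 25 replicates
of 550 scans with intraclass correlation 0.95 (FA-derived global metrics
are highly reliable within person, and a high ICC makes the
within-participant interaction estimate precise enough that a 10% bias
bound is meaningful); FDR control over 1000 45-feature null families; and
end-to-end determinism at 90 participants with 50 nulls per scan.

## Known limitations

- Binary-matrix variants, streamline-count weighting, thresholded
  networks, rich-club and modularity analyses are out of scope.
- Non-parametric ComBat priors and longitudinal/GAM ComBat variants are
  not implemented.
- The random-effects structure is a single participant intercept; random
  slopes over time are not supported.
- The null-rewiring scheme preserves degrees and the weight multiset but
  not the weight-degree correlation structure; alternative null models
  (e.g. weight-shuffle-only) are not provided.
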