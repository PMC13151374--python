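# Methods

## The problem setting

Synovial fluid from patients with failing joint replacements carries an
immune-cell signature of the failure mode: infection (including indolent,
culture-negative "low-grade" infection) skews the CD45⁺ compartment
towards neutrophils and innate activation, whereas aseptic wear-particle
disease preserves a more adaptive profile. `synovnet` treats each patient
as a vector of such markers and asks which patients are similar overall,
rather than thresholding any single biomarker.

## Synthetic cohort generator

Only group-level summaries of the clinical cohort are public: per group
and marker, a mean, the 95% confidence interval of the mean, and the
observed [min, max]. The generator turns these four numbers into a
sampling distribution:

- **Distribution.** A normal truncated to [min, max]. The scale is
  `sd = ci_half·√n / 1.96` (inverting the CI of a mean over the group's
  n patients; 1.96 is the conventional normal quantile the summaries were
  built with). The location parameter is then solved by root-finding so
  that the *truncated* distribution's mean equals the printed mean
  exactly. This respects all four printed statistics simultaneously; a
  plain clipped normal would bias the mean whenever the printed mean sits
  asymmetrically in the range.
- **Interpretation of the CI.** The printed "mean ± x" is assumed to be a
  CI of the mean, not a predictive interval of the distribution; this is
  an assumption, not a documented fact about the source summaries.
- **Group structure.** Five disjoint groups are generated — PJI (n=16),
  LG-PJI (n=8), OL/AL (n=20), OA-INF (n=28), OA (n=36), 108 patients in
  total — each from its own published column. The "PJI-all" contrast
  group (n=24) is the union of PJI and LG-PJI. The four default markers
  are the absolute CD45⁺ count (×10⁹ cells/l) and the lymphocyte,
  monocyte–macrophage and neutrophil percentages of CD45⁺ cells.
- **Composition.** The three percentage markers are sampled marginally
  (the marginals are the only published constraint) and any patient whose
  LYM+MON+NEU sum exceeds 100% is rescaled proportionally to sum to 100,
  with a `composition_rescaled` flag kept per row. The calibration tests
  bypass this step by drawing from the sampler directly, so marginal mean
  recovery is assessed un-rescaled.
- **Seeding.** One master seed; each group × marker draws from its own
  substream keyed by CRC32 hashes of the group and marker names, so
  adding a marker never perturbs another marker's draws and identical
  seeds give bit-identical tables.
- **Soluble markers** (CRP, PTX3, α-defensins, sCD14, sTREM1, PCT,
  CXCL13) use the same calibration schema, but no default calibrations
  ship because their group summaries are not in the public main-text
  table; users supply them via the YAML config. The α-defensin
  positivity thresholds ship as presets: 156 pg/ml (ELISA limit of
  detection) and 1,560 ng/ml (lateral-flow cut-off), both stored in
  pg/ml so comparisons are unit-consistent.

### Archetype mode

For cluster-recovery validation the generator can plant known structure:
an archetype is a centroid on the rescaled [0, 1] scale, built by mapping
qualitative levels high/mid/low to 0.8/0.5/0.2, plus isotropic Gaussian
noise (default sd 0.08), clipped to [0, 1]. The defaults define four
archetypes over the six network markers (cDC2%, LYM%, NK%, HLA-DR⁺ NK%,
CD88⁺ cDC1%, HLA-DR on MON–Mϕ) in a 44-patient implant cohort (24
infected + 20 aseptic), with the infection archetypes low in cDC2, LYM
and HLA-DR and high in CD88⁺ cDC1 and NK. The level patterns were chosen
so every pairwise centroid distance is at least six noise-sd (minimum
0.3·√3 ≈ 0.52 vs 0.48), which is what makes "the pipeline should find
exactly these four clusters" a well-posed requirement. Only separation
ratios matter; the particular level values are arbitrary but fixed.

What the generator does *not* emulate: flow-cytometry event-level data,
gating, spillover, measurement error correlated across markers,
inter-marker clinical correlations beyond the composition constraint, and
covariates (age, sex, implant type). Passing recovery tests therefore
show that the network machinery behaves correctly on data with the
published marginal structure — not that the published clustering itself
is reproduced, which would require the unpublished per-patient data.

## Similarity network

- **Rescaling.** Per-feature min–max to [0, 1]; a constant feature maps
  to 0 everywhere (it carries no information and must not contribute
  distance). Missing values are a hard error.
- **Kernel.** `s = exp(−d²/2σ²)` on Euclidean distance. σ defaults to
  the median pairwise distance of the rescaled matrix (scale-adaptive and
  deterministic); mean-distance and fixed-σ rules are available. If all
  patients coincide, σ falls back to 1 with a warning.
- **Degree rule.** Representativeness `rep(v)` is the number of patients
  whose single nearest neighbour is `v` (votes sum to n). Each vertex
  links to its `k(v) = min(cap, max(rep(v), floor))` nearest neighbours,
  cap `⌈√n⌉`, floor `⌈log₂ n⌉`; the edge set is the deduplicated union
  over both endpoints. The floor is the package's own choice: the union
  of pure reverse-nearest-neighbour links is a forest of small stars, and
  modularity optimisation on a disconnected graph returns its connected
  components, fragmenting genuinely homogeneous patient groups. A
  logarithmic floor is the classic connectivity scale of nearest-
  neighbour graphs and keeps each similarity neighbourhood connected
  while representativeness still widens local hubs up to the cap. Both
  cap and floor are configurable.
- **Ties.** All nearest-neighbour ties break by ascending patient id, so
  runs are bit-reproducible even on degenerate data.

## Clustering and quality

- **Louvain.** Weighted modularity optimisation at resolution 1.0,
  20 restarts with derived seeds; the restart with the highest modularity
  wins (ties keep the earliest). Cluster ids are relabelled 1..K ordered
  by each cluster's smallest patient id, so output is deterministic.
- **Modularity** is the weighted Newman form
  `Q = Σ_c (w_c/W − (s_c/2W)²)`.
- **Silhouette and centroids** operate in the rescaled feature space, not
  on graph distances: within-cluster spread and "average patients" are
  statements about marker values. Singleton-cluster members score 0.
- **Centroid reliability** has no canonical formula in the field; it is
  operationalised as the fraction of patients whose nearest cluster
  centroid (per-cluster feature mean) is their own — bounded, unitless,
  and 0.5 at chance for two interchangeable clusters.
- **Within-cluster variance** is the population sd per cluster × feature;
  its grand mean is the scalar criterion (lower is better).
- **Balanced selection.** Across candidate feature subsets (exhaustive
  within the configured size range, guarded by a candidate cap), each
  metric is min–max normalised over candidates, the variance criterion
  inverted, and a candidate's balance score is its *worst* normalised
  metric (maximin): the most balanced network is the one whose weakest
  property is strongest. Ties break by the normalised-metric sum, then
  by the subset name tuple. A metric that is constant across candidates
  normalises to 1 so it cannot dominate the maximin.
- **Boundary score.** The fraction of a patient's incident edge weight
  that crosses cluster borders (0 interior, 1 fully boundary). This is a
  deliberately transparent stand-in for the looser notion of "patients at
  the cluster boundary"; graph-theoretic eccentricity is *maximal*, not
  minimal, at a periphery, so that term is avoided.

## Biomarker statistics

- Shapiro–Wilk per group is descriptive; inference is nonparametric
  throughout (Mann–Whitney pairwise, Kruskal–Wallis omnibus for >2
  groups). Mann–Whitney uses the exact null distribution for tie-free
  samples with both n ≤ 12, otherwise the tie-corrected normal
  approximation. Bonferroni multiplies by the number of pairwise
  comparisons, capped at 1. Significance tiers: *** ≤ 0.001,
  ** ≤ 0.01, * ≤ 0.05, NS otherwise; α = 0.050.
- **AUC** is computed as the midrank Mann–Whitney probability, so ties
  count one half and the value is exactly the probability a random
  positive outranks a random negative.
- **DeLong.** Placement values per positive (fraction of negatives
  outranked) and per negative; `var(AUC) = S₁₀/m + S₀₁/n` with sample
  variances (ddof 1); normal-approximation CI clipped to [0, 1]. Perfect
  separation gives variance 0 and a point CI, flagged by construction.
- **Youden cut-offs** scan the midpoints between adjacent distinct scores
  plus one extrapolated threshold below the minimum and one above the
  maximum (so "call everyone" and "call no one" are always candidates);
  prediction is positive at score ≥ cut-off. Ties resolve to the lowest
  cut-off achieving maximal J, favouring sensitivity. Markers where low
  values indicate infection are handled by an orientation flag; the
  reported cut-off is then on the negated scale and the flag says so.
- **Combined panels.** Features are z-standardised (so the score and its
  AUC are invariant to affine rescaling of any marker); the L2 penalty is
  chosen by stratified cross-validated log-loss over a 13-point
  logarithmic grid spanning 10⁻³–10³ (fold count shrinks to the minority
  class when needed), and the final model is refit on all patients. The
  penalty grid excludes 0, so complete separation cannot blow up the
  coefficients. Both the in-sample AUC of the refit score and the
  out-of-fold AUC at the chosen penalty are reported, since it is not
  always knowable which convention an external study used.

## Problem sizes and numerical choices

The validation suite exercises the stack at desk scale: exhaustive
reference implementations act as oracles for graphs and partitions up to
n ≈ 8–12, Monte-Carlo calibration checks use 10,000 draws per group ×
marker, and planted-structure recovery uses the default 44-patient
archetype cohort over 50 seeds (recovery is declared when Louvain finds
exactly 4 clusters with adjusted Rand ≥ 0.9). Root-finding for the
truncated-normal location uses Brent's method to 10⁻¹² on an adaptively
widened bracket; degenerate calibrations (zero CI, zero-width range)
short-circuit to constants.

## Known limitations

- The published clustering itself cannot be reproduced or refuted without
  the unpublished per-patient table; all cluster-level claims here are
  about synthetic data with the published marginal structure.
- The original local-representativeness construction is described only
  qualitatively in the sources available to this package; the degree rule
  above is a documented, configurable interpretation, not a re-derivation
  of the original parameterisation.
- The truncated-normal choice is one of many distributions consistent
  with four summary statistics; heavy-tailed or multimodal within-group
  structure (plausible for, e.g., absolute cell counts) is not modelled.
- Ridge-combined AUCs are in-sample unless the cross-validated figure is
  used; neither is an external validation.
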