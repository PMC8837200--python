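# Methods

This note documents the models, algorithms, defaults and design choices in
`stressg`, in the package's own words. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Study design being emulated

The synthetic generator reproduces the statistical structure of a pedigreed
captive study of stress-response integration in a small livebearing fish:

- **Pedigree.** Maternal full-sib families nested within paternal half-sib
  groups, built over up to five generations of breeding rounds (defaults:
  2 measured generations, 25 sires × 3 dams × 4 offspring ⇒ ~600
  phenotype-eligible fish). A configurable fraction of offspring has unknown
  paternity (broods conceived before the designated pairing). Unknown
  parents are treated as unrelated, non-inbred founders.
- **Housing.** Mixed-family groups of 16–20 adults with sexes balanced to
  ±1; families are dispersed across groups by round-robin allocation so
  common-environment effects are not confounded with family.
- **Assays.** 2–4 open-field trials (OFT; four traits recorded per trial),
  2 emergence trials, 2 shoaling trials, and cortisol after the 1st and 3rd
  of three handling/confinement stressors. Per-assay inclusion is
  independent per fish, with probabilities calibrated to the reported
  phenotyping counts (OFT 1365/1384, emergence 806/1384, shoaling 532/1384,
  cortisol 629/1384).
- **Covariates.** Assay repeat, order caught within group (an exact
  permutation), water temperature, time of day, age, sex, generation, body
  mass. The study's empirical covariate distributions are unknown, so the
  generator uses documented placeholders (temperature N(24, 0.4²) clipped to
  23–25 °C; behavioural testing 09:00–17:00 and cortisol sampling
  12:00–14:00; age uniform 180–350 d; mass lognormal around 0.25 g) and
  emits raw plus centred/scaled versions.

Traits are simulated directly on their transformed analysis scales
(√freezings, ln emergence time, ln cortisol in ng/hr); `to_raw_scale`
inverts the transformations (censoring emergence at 900 s) to produce
raw-scale fixtures for the transformation code path. Default generating
values are the published point estimates: univariate variance components per
trait, the standardised 6-trait **G** (correlation structure also used, with
univariate Va, for the raw-scale generator), and the two-context cortisol
model (means 8.47/8.02; Va 0.081/0.041; cross-context genetic correlation
0.83; group 0.038/0.032; residual 0.164/0.237). The PE/GROUP/residual
covariance *matrices* of the source study are not reproduced in the text
available here, so their defaults are diagonal — a known simplification;
recovery tests therefore target G's structure and the univariate components,
not PE/GROUP correlation structure.

Under the GxE option, cortisol's context-specific genetic effects are built
as u_c = √(r·Va_c)·z + √((1−r)·Va_c)·w_c, where z is the (standardised)
joint-G cortisol merit and w_c are independent pedigree-structured factors.
This reproduces Va_1, Va_3 and the cross-context correlation r exactly while
preserving genetic integration with behaviour up to a factor √r — a
deliberate compromise, since a single generator cannot match both the
single-trait G parameterisation and the character-state parameterisation at
once.

## Trajectory traits

- **Arena.** 20 × 30 cm, 1 cm analysis grid. The middle zone is the centred
  rectangle similar to the arena scaled by 1/√2 — the only similar rectangle
  whose inside and outside areas are equal. Shoaling thirds split the long
  axis; the shoal-adjacent end is configurable.
- **Area covered.** Cells are half-open [i, i+1) × [j, j+1), with far-edge
  points assigned to the last cell. Cell membership along a segment is
  computed exactly by locating every grid-line crossing and taking the cell
  containing each inter-crossing midpoint (corner touches are resolved by
  clamping). This exact traversal replaced fixed-step subdivision because no
  finite subdivision step can guarantee agreement with a dense supersampling
  oracle near cell corners; the oracle test demands exact cell-set equality.
- **Freezing bouts.** Instantaneous velocity is inter-frame displacement ×
  fps with no smoothing (a smoothing window can be added upstream by
  resampling); a bout is a maximal run of sub-threshold (default 4 cm/s)
  intervals lasting ≥ 2.5 s, counted even if truncated by trial end.
- **Random-swim null model.** Step vectors are drawn i.i.d. from a pool of
  per-frame displacements; draws that would exit the arena are rejected and
  redrawn (error after 10⁵ consecutive rejections); steps longer than 1 cm
  are recorded as subdivided parts; the walk starts at the arena centre and
  stops on the step that reaches the target length. Simulated area covered
  is regressed on track length with a fourth-order polynomial over a grid of
  100 lengths × 5 replicates spanning 100–8000 cm; *relative area* is
  observed minus predicted coverage, with extrapolation outside the fitted
  range allowed but warned about.
- **Synthetic step pool.** The empirical pool (coordinates of real trials)
  is not available, so the default pool is a labelled synthetic stand-in:
  distances are gamma (shape 2) from a three-component mixture — freeze-like
  (mean 0.1 cm/frame, weight 0.30), cruise (0.8 cm/frame, 0.55) and dart
  (2.0 cm/frame ≈ 50 cm/s at 25 fps, 0.15) — with uniform headings. The dart
  component matters: the coverage of a confined random walk at fixed path
  length fluctuates on the scale of the walk's mixing length (∝ arena² /
  step), and without a fast tail the area–track-length relationship is too
  noisy for a quartic to explain > 90% of variance. Burst swimming is a real
  feature of flight-type open-field responses, which is why the stand-in
  includes it; all pool parameters are configurable. With these defaults the
  null-model fit's R² is ≈ 0.93–0.95 across seeds (measured by the test
  suite); the R² obtained with the original empirical pool is not claimed.

## REML animal models

The mixed model is y = Xb + Σ_j Z_j u_j + e with u_j ~ N(0, Σ_j ⊗ K_j):
K_j is **A** for the genetic term (reduced to phenotyped individuals, which
marginalises correctly) and identity for permanent-environment and group
terms. Residuals are block-correlated within *residual units* (a trial);
covariances between traits never co-observed in a unit are structural zeros
(block-diagonal residual structure: the four OFT traits form one block;
emergence and cortisol are their own blocks).

The restricted likelihood is evaluated through the mixed-model equations:
−2 l_R = log|R| + Σ log|Σ_j ⊗ K_j| + log|C| + y′Py + (n−p)·log 2π.
Estimation is average-information (AI) REML:

- 3 initial EM steps stabilise the search from a crude equal-split start
  (EM updates for unstructured/diagonal terms and the residual, using
  Var(e|y) = W C⁻¹ W′ restricted to within-unit blocks).
- AI iterations update covariance elements directly, with scores from the
  standard Z′PZ identities and the AI matrix from 0.5·h′Ph, h = ∂V·Py.
- Step control is Levenberg–Marquardt on the AI matrix: a persistent ridge
  grows until a step improves the restricted likelihood (with per-component
  caps and limited step-halving), and decays after successes. If no uphill
  AI step is found the iteration falls back to EM.
- Positive-semidefiniteness is enforced by eigenvalue bending with a floor
  of 1e-8 × mean phenotypic variance; boundary components (e.g. a trait with
  no genetic variance) sit at the floor.
- Convergence: relative change in −2 l_R below 1e-9 on a full step, or a
  plateau (three consecutive near-zero improvements — the typical signature
  of an estimate pinned to the PSD boundary). On well-conditioned problems
  (e.g. balanced designs) the optimum is reached to ~1e-12 relative, which
  is what the ANOVA-equivalence oracle requires.

This AI-REML design was chosen over a generic quasi-Newton on a log-Cholesky
parameterisation: it is the field-standard algorithm for these models, it
converges quadratically near the optimum, and its information matrix
provides parameter standard errors directly. Jittered restarts remain
available (`n_restarts`).

Constraints used by the model ladder: a genetic correlation fixed at one is
implemented as a *shared factor with axis loadings carried in the design
matrix* (a rank-1 trait covariance cannot be inverted in the MME); equal
variances + unit correlation collapse to a single shared effect; covariances
fixed at zero use diagonal/block-diagonal structures.

Derived quantities: h² = Va/(Va+Vpe+Vgroup+Vr) and R = (Va+Vpe)/(·) with
delta-method standard errors from the inverse AI matrix; confidence
intervals for variance parameters are symmetric on the log scale (the usual
remedy for the right-skew of variance estimators — plain Wald intervals
under-cover for terms with few levels, such as ~35 housing groups). Wald F
statistics for fixed-effect contrasts use a Satterthwaite-type denominator
df: ddf = 2(c′V_b c)²/Var(c′V_b c), the variance by delta method with a
finite-difference gradient; exact agreement with other software's df
algorithms is not promised. BLUPs come from the MME solutions; unphenotyped
relatives are predicted via A_cross A_obs⁻¹ û.

### Character-state (GxE) cortisol ladder

Cortisol after 1st and 3rd stressor exposures is modelled as two traits.
Each fish contributes at most one observation per context, so no PE term is
fitted and the *individual* is the residual unit — the cross-context
residual covariance absorbs non-genetic among-individual covariance. The
nested sequence (no genetics → shared genetic effect → context-specific
variances with r = 1 → free r) is compared with boundary χ²₀,₁ tests for
variances (p = 0.5·P(χ²₁ ≥ x), exactly 0.5 at x = 0) and a plain χ²₁ test
for r < 1. Context-specific h² uses Va_c/(Va_c + Vgroup_c + Vr_c).

### Multivariate G

Six response traits (relative area, time in middle, track length,
√freezings, −ln emergence, ln cortisol as a single repeated trait with a
context fixed effect), standardised to SD units before fitting; fixed
effects per trait as in the univariate models. Integration is tested by
comparing the full model to one with G diagonal (15 df). Eigenvectors are
reported with the largest-magnitude loading positive; proportions use
positive-part eigenvalues (raw eigenvalues are reported unchanged).

### Parametric bootstrap

Full simulate-and-refit: each replicate draws every random term and the
residual from the fitted covariances over the same pedigree/design, refits
(warm-started at the point estimate), and stores its G. Replicate axes are
matched to the point estimate by rank and sign-aligned by dot product —
a documented limitation when eigenvalues are near-degenerate. Failed refits
are flagged and excluded from percentile intervals, never silently dropped.
Desk-scale default is 200 replicates (a config knob; a full-scale analysis
would use thousands).

## Problem sizes and runtimes

Chosen so the full pipeline and test suite run comfortably on one CPU:
univariate fits use the full ~600-fish design (~1–2 s each; the recovery
experiment fits 100 such studies); the GxE calibration fits the two models
it compares at the same design; the multivariate G stage runs at a few
hundred fish (one to several minutes per fit — the analysis scripts use
~290 fish with 30 bootstrap replicates, which takes tens of minutes
end-to-end; the pipeline default is ~190 fish with 50 replicates).
Full-size multivariate runs are one config change away
(`PipelineConfig.multivariate_n_sires`, `bootstrap_reps`).

## What passing tests do and do not show

The synthetic generator draws Gaussian effects on the transformed scales,
with missingness independent per assay and no selection, maternal effects,
inbreeding depression, or temporal drift. Recovery results therefore
validate the *estimators and pipeline plumbing* under the assumed model —
they cannot validate the transformations' adequacy for raw field data, the
independence assumptions, or the biological interpretation of g_max.
Published full-data values (raw variance components, LRT statistics on the
real fish) are used only as generating parameters and for derived-quantity
arithmetic; reproducing them from data requires the original dataset.

## Known limitations

- PE/GROUP/residual cross-trait covariances default to zero in the
  generator (see above), so the multivariate model's non-genetic covariance
  structure is estimated but its recovery is not benchmarked.
- AI-REML reports "converged" on PSD-boundary plateaus; near-singular G
  estimates can make nested-model log-likelihoods agree only to ~1e-3,
  which occasionally produces tiny negative LRT statistics (clipped to 0,
  with a warning).
- The Satterthwaite ddf and the bootstrap axis-matching are approximations,
  both documented where used.
- Housing-group assignment balances sexes and disperses families but does
  not model the sequential group formation of the real husbandry workflow.
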