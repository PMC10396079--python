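# Methods

## The problem

Crop nitrogen diagnosis rests on the critical N concentration: the minimum
plant N concentration (% dry mass) that still permits maximal growth at a
given crop size. As the crop accumulates biomass, structural tissue dilutes
the metabolically active N pool, so the critical concentration falls with
biomass following a power law

    Nc(W) = A1 · W^(−A2),

where `W` is biomass (t ha⁻¹) or leaf area index, `A1` is the critical
concentration at `W = 1`, and `A2` is the dimensionless dilution exponent.
`critnc` estimates `(A1, A2)` per organ basis — leaf biomass, stem biomass,
shoot biomass, and LAI — from multi-date wheat N-response trials, and uses
the fitted curves for nitrogen nutrition index (NNI = Nt / Nc) diagnosis.

## The hierarchical change-point model

Within one sampling date, biomass responds to N concentration as a
linear-plus-plateau function: below the date's critical concentration
`Nc_i`, expected biomass is `Bmax_i · (1 − beta_i · (Nc_i − N))`, clipped at
zero; at or above it, the plateau `Bmax_i`. The hierarchy ties the per-date
critical points to the shared curve through `Nc_i = A1 · Bmax_i^(−A2)`, so
one MCMC run estimates the dilution curve jointly with the per-date
nuisances `(Bmax_i, beta_i)` rather than in a two-stage ANOVA-then-regress
procedure. The two-stage classical approach yields no uncertainty statement
for the final curve; here the posterior of `(A1, A2)` carries it directly.

Observation error is Gaussian on `W` with standard deviation
`sigma · Bmax_i`. The relative parameterization reflects that biomass
sampling error scales with crop size; with an absolute common sigma the
late-season scatter (plateaus of 10–14 t ha⁻¹) would dominate the fit and
wash out the early dates that anchor `A1`.

Priors are uniform: `A1 ∈ [0, 12]`, `A2 ∈ [0, 5]` (weak ranges comfortably
containing published wheat curves), `Bmax_i ∈ (0, 2·max W in group)`,
`beta_i ∈ (0, 5)`, `sigma ∈ (0, 0.5)`.

### Sampling and convergence

Sampling uses the affine-invariant ensemble sampler (`emcee`) with a
0.8/0.2 mixture of differential-evolution and snooker moves; the default
stretch move mixes poorly once the per-date nuisances push the dimension
past ~20 (hybrid fits pool many dates). A "chain" is an independently
seeded and independently initialized ensemble; `n_burn` and `n_keep` count
draws per chain flattened across walkers, with an internal thinning factor
(default 10 ensemble steps per retained step) so retained draws are nearly
uncorrelated. Burn-in never drops below ~30 steps per parameter regardless
of the requested budget. Walkers start in a small ball around a data-driven
point (per-group plateau = max observed W; crude critical points from the
most-deficient treatments; log–log regression for `A1`, `A2`).

Defaults are test scale — 4 chains, 5,000 burn-in + 3,000 retained per
chain — which converges in seconds per fit; the large-sample configuration
(100,000 burn-in, 30,000 retained) is available by passing those counts.
Convergence is screened on `A1` and `A2` with split-R̂ < 1.1 and effective
sample size ≥ 400 (via `arviz`); fits failing the screen are flagged and
excluded from every downstream comparison. R̂ across ensembles detects
disagreement between independently initialized runs; because walkers within
an ensemble interact, the per-chain draws are treated as exchangeable
samples rather than a single autocorrelated trajectory.

### The grid oracle

Sampler correctness is certified against a brute-force 2-D grid posterior
over `(A1, A2)` with the nuisances pinned at known values: cell-center
evaluation over the full prior box, normalization by direct summation,
quantiles by interpolating the marginal CDF. The oracle raises an error if
the posterior mode lands on a boundary cell (grid too coarse). MCMC and
grid medians agree within 2% and interval endpoints within 5% on reduced
models; doubling the grid resolution moves the medians by <0.5%.

## Synthetic trials

Field observations from the kind of G × E × M experiment this methodology
targets are not publicly deposited, so the package ships a generator whose
output has known ground truth; every downstream claim is validated against
that truth. One simulated trial mirrors a wheat N-rate experiment:

- 5–8 sampling dates before flowering, 4–8 N treatments (13 in the densest
  published designs), 3 replicate plots; defaults 7 dates × 6 rates × 3 reps.
- `Bmax_i` grows geometrically from ~1.5 to ~12 t ha⁻¹ over dates; `beta_i`
  constant per trial in 0.35–0.6 per %N.
- Treatments place the achieved shoot N concentration at fixed multiples of
  the date's critical concentration — defaults (0.6, 0.8, 0.95, 1.05, 1.2,
  1.4) × Nc_i — so both limbs of the change-point response are populated at
  every date and the N ladder is monotone in applied rate.
- Noise is additive Gaussian on shoot biomass with sd = 5% of `Bmax_i`.
- Organ accounting: leaf fraction of shoot biomass declines linearly from
  0.55 to 0.30 over dates (stem dominates late); leaf N sits 0.5 %N above
  shoot N and stem N is solved so the biomass-weighted organ mean equals
  shoot N exactly; LAI = 2.0 × leaf biomass (specific leaf area,
  LAI units per t ha⁻¹).
- Daily weather (Tmax/Tmin with a mid-winter dip, intermittent gamma
  rainfall) spans sowing (Oct 15) to flowering (Apr 20) for the AGDD and
  rainfall covariates.

What the generator does **not** emulate: spatial field heterogeneity and
block effects, correlated (systematic) measurement error, organ-specific
dilution laws that are themselves exact power laws (leaf/stem/LAI curves
emerge from the organ split, not from independent truths), lodging,
disease, or water stress. Passing tests therefore demonstrate that the
estimation machinery is correct and well calibrated under the stated error
model — not that any particular field dataset satisfies that model.

Determinism: every random quantity flows from explicit seeds; suite
sub-seeds are CRC32 hashes keyed by `(master seed, experiment id)`, so
reordering or extending a suite never perturbs an existing experiment.

## Observation selection

- Samples taken while shoot biomass < 1 t ha⁻¹ are excluded before fitting:
  N concentration barely dilutes during establishment and those points
  distort the early curve. The boundary value is retained (`≥`), and the
  gate is shoot biomass for all four bases — one consistent developmental
  criterion.
- A date group needs ≥ 3 (W, N%) pairs: a slope, a plateau, and their
  intersection are not identifiable from fewer distinct N levels. Smaller
  groups are dropped with a warning.
- Basis pairing: leaf↔leaf N, stem↔stem N, shoot↔shoot N, LAI↔shoot N.
- Replicate plots enter the fit as individual observations; fitting
  treatment means instead is possible by averaging upstream.

## Curve comparison across conditions

Fitted parameters are compared across G × E × M conditions with a
posterior-difference rule: two fits differ at level α when the central
(1−α) interval of the difference of their posterior draws (independently
permuted and paired, fixed permutation seed) excludes zero. A classical
Tukey HSD on the fitted parameters would need replicate-level structure
that a Bayesian per-condition fit does not expose; the difference-interval
rule is the self-contained Bayesian analogue. Compact letters come from
the maximal cliques of the resulting non-difference graph (deterministic
ordering by experiment id); fits sharing a letter are pairwise
indistinguishable. Cross-condition variability is summarized as the CV
(sample SD / mean × 100) of the posterior medians.

## NNI and agreement statistics

NNI is computed per observation (never per-treatment means):
`NNI = Nt / Nc(W)` with the curve evaluated at the observation's own W.
Agreement between two NNI series uses RMSE and
n-RMSE = RMSE / mean(reference) × 100%. The normalizing mean is always the
*reference* series (hybrid-derived NNI when comparing hybrid to specific
curves; shoot-basis NNI in organ crosswalks), so n-RMSE is deliberately
asymmetric. The biomass-weighted mean NNI of leaf and stem,
`(NNI_l·W_l + NNI_s·W_s)/(W_l + W_s)`, is compared against shoot NNI in the
crosswalk; on synthetic data it tracks shoot NNI more closely than either
organ alone, because the simulator distributes shoot N between organs by
exactly that weighting.

## Covariates and drivers

Per experiment: DMmax (max shoot biomass before flowering), Nmax (max shoot
N concentration), VPD (vegetative period duration, sowing→flowering, days),
AGDD (accumulated growing degree days, `Σ max(0, (Tmax+Tmin)/2 − Tbase)`,
Tbase = 0 °C), mean daily GDD = AGDD/VPD, total rainfall, sowing density.
Sub-zero daily means are clamped to zero — the standard agronomic
convention for wheat with a 0 °C base; the literal unclamped sum is a flag
away (`clamp_negative=False`). "Vegetative period" is operationalized as
sowing→flowering; rainfall is precipitation only (irrigation is not
modelled). Correlations are Pearson r with two-sided t-test p-values
(Spearman behind a flag), flagged at the 0.1/0.05/0.01/0.001 tiers, with
constant variables reported as undefined rather than failing the matrix.
Curve parameters enter as posterior medians, one value per experiment; at
least 4 matched experiments are required for a p-value.

## Numerical choices and edge cases

- Low-biomass filter boundary kept (`shoot_W ≥ threshold`).
- Date index is the chronological rank of the calendar date (1-based).
- Grid oracle uses cell centers; quantiles interpolate the discrete CDF.
- `compare_parameters` sorts fits by id before any pairwise work, making
  letters and CVs invariant to input order.
- The hybrid fit pools every experiment-date as its own group with its own
  nuisances; only `(A1, A2)` are shared. Pooling a single experiment is
  bit-identical to the specific fit under the same seed.
- Degenerate posteriors (all draws equal) yield zero-width intervals and
  CV 0 rather than errors.
- Problem sizes used in the validation suite — 10 recovery seeds at the
  reference design (8 dates × 6 rates × 3 reps), 50 calibration simulations
  at 5 dates × 2 reps with the default 6-treatment ladder, 14-condition
  suites at 2-chain MCMC — were chosen to give stable statistics at
  desk-scale runtimes. Calibration keeps the default treatment ladder
  because its quantiles straddle the change point without sitting on it;
  placing a treatment exactly at the critical concentration weakens the
  identification of the kink and (verified against long-chain runs) the
  honest posterior then undercovers on very small designs.

## Known limitations

- The pooling across dates uses independent per-date nuisances with shared
  `(A1, A2)`; a hyperprior on `(Bmax_i, beta_i)` is a config stub, not
  implemented.
- Convergence screening on `(A1, A2)` only; a pathological nuisance could
  in principle pass the screen.
- The organ-level curves on synthetic data are induced by the organ split
  and are not exact power laws, so organ-basis "truth" is defined only
  through reconstruction, not closed form.
- No multiple-testing correction on the correlation matrix (raw tiers are
  reported, as is conventional for this analysis).
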