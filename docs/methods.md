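# Methods

## Problem and model

Dynamic viscosity μ of a small-molecule liquid depends jointly on
chemical structure and temperature. We model log₁₀ μ (μ in centipoise)
because raw viscosities are right-skewed over orders of magnitude, and we
feed models the inverse temperature 1/T because empirical
viscosity–temperature laws of the Vogel form,

    log₁₀ μ(T) = A + B / (T − C),

make log-viscosity approximately linear in reciprocal temperature far
from the divergence temperature C. Structure enters through three
descriptor blocks computed from SMILES only (no 3D conformers):

- **2D block** — the full RDKit 2D descriptor list (~210
  physicochemical/topological indices, prefixed `RD_`);
- **FP block** — a hashed circular (Morgan) fingerprint, radius 2,
  1000 binary bits (radius and width configurable);
- **COMP block** — element-composition statistics: for each of seven
  tabulated elemental properties (mass, electronegativity, covalent and
  van der Waals radii, ionization energy, electron affinity, valence
  electrons) the mean/min/max/range/std over all atoms including
  hydrogens, plus per-element atom fractions and atom counts. The exact
  composition list is configurable; only the construction, not a
  particular feature count, is asserted anywhere.

## Curation

Three filters run in a fixed order, each recorded in an auditable report:

1. **Structure** — keep single-fragment molecules containing at least one
   carbon and only {H, C, N, O, F, Si, P, S, Cl, Br, I}. "Organic" is
   operationalized as "contains carbon", so e.g. water is excluded.
2. **Range** — a record is dropped when its viscosity *or* temperature
   falls outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] of that variable. Quantiles
   use linear interpolation between order statistics. The filter is a
   single pass with fences from the pre-filter distribution; it is
   therefore *not* idempotent on arbitrary data (removing tails shrinks
   the fences), though datasets whose values sit well inside the fences
   are fixed points.
3. **Positive temperature deviation** — within each compound (canonical
   SMILES identity), scanning by ascending temperature, a point whose
   viscosity exceeds the *last retained* point's by strictly more than
   0.02 cP is removed (with a 1e-12 epsilon so an exact 0.02 cP step
   survives float representation). Comparing against the last retained
   point preserves each curve's low-temperature anchor and makes a single
   forward pass convergent.

Units are fixed at the reader boundary (K, cP; Celsius input converted by
+273.15); everything downstream is unit-consistent.

## Preprocessing

Fit on training rows only and then frozen: (1) greedy keep-first
correlation pruning in column order at |r| ≥ 0.90 (the scan order is
documented here because any tie-break is arbitrary);
(2) zero-variance removal, where "zero" means below 1e-12 of the column's
magnitude to absorb float roundoff in constant columns; (3)
standardization by training mean and standard deviation, applied
identically to validation/test rows. Inverse temperature is standardized
with everything else.

## Evaluation protocol

All splits are compound-disjoint: shuffled compounds accumulate into
training until the first crossing of 80% of rows (slight overshoot
allowed). Grouped 5-fold CV partitions training compounds into
row-balanced folds by greedy largest-first assignment. CV metrics are
computed on the pooled left-out predictions, not averaged per fold — the
two differ, and the pooled version weights every row equally.
Hyperparameter tuning evaluates small default grids with single
(un-bagged) fits per fold, selecting by pooled CV R² (ties: lower RMSE,
then first in grid); the winning configuration is refit as a 20-member
bagged ensemble on the full training split. Negative R² values are
reported as-is and Score_M is evaluated on them unchanged. The benchmark
repeats everything over five split seeds and ranks families by mean
Score_M.

Bagging details: each member trains on a with-replacement resample of the
training rows (same size as the training set); member seeds derive from a
master seed, so replays are bit-stable for deterministic families. The
90% prediction band is the 5th/95th percentile (linear interpolation) of
the member predictions.

The learning-curve experiment holds out a fixed 20% compound-disjoint
test set per split, draws nested compound-wise training subsets at each
requested size (nesting reduces between-size variance), trains the same
bagged LGBM configuration at every size without re-tuning, and contrasts
featurizations — e.g. 2D-only vs 2D plus external descriptors.

## Shapley attribution

The attribution target is the interventional Shapley value: a coalition's
value is the mean model output with out-of-coalition features replaced by
background rows. The exact enumerator (≤ 15 features) is the oracle; the
permutation-sampling estimator averages every waypoint over the full
background so efficiency holds exactly per sampled permutation; for
LightGBM/XGBoost members the native `pred_contrib` TreeSHAP is used as a
fast path (path-dependent TreeSHAP has a subtly different implicit
background; tests bound the discrepancy on small fixtures). Reporting
follows the Mean|SHAP| convention: mean absolute Shapley value over (test
instances × bag members), uncertainty as the std over per-member means,
sign from the Pearson correlation between Shapley and feature values
(undefined for constant features and reported as such), and for top
features a bracket of other features correlated at |r| ≥ 0.90. The test
set serves as both explained instances and background.

## MD descriptors

Eight descriptors per (compound, temperature) from an orthorhombic-box
trajectory, ensemble-averaged over the trailing half of the run (the
portion assumed equilibrated; the fraction is a parameter):

| descriptor | definition | units |
|---|---|---|
| MD_density | Σmᵢ / V | g/cm³ |
| MD_FV | % of grid points farther than r_vdW + r_probe from every atom (periodic minimum image; probe default 0 Å, grid 0.5 Å) | % |
| MD_Rg | mean over molecules of mass-weighted radius of gyration, molecules unwrapped by minimum image | Å |
| MD_SP | √(−⟨E_inter⟩/⟨V⟩), converted kcal·mol⁻¹·Å⁻³ → MPa | MPa^1/2 |
| MD_SP_E, MD_SP_V | same from the electrostatic / van-der-Waals energy shares; a non-cohesive (positive) share clamps to 0 with a warning | MPa^1/2 |
| MD_HV | −⟨E_inter⟩/n_molecules + RT (ideal-vapor limit) | kcal/mol |
| MD_RMSD | mean over window frames of √(mean over atoms |r_t − r_ref|²), unwrapped, no superposition, reference = window's first frame | Å |

These are the standard definitions of each quantity; they are the
package's own formulas, stated here precisely so users can compare
against whatever convention their MD engine reports. Trajectories are an
extended-XYZ dialect (comment line carries `box="lx ly lz"`, `time`, and
optional `e_total`/`e_inter`/`e_elec`/`e_vdw` in kcal/mol of cell) with a
JSON topology sidecar (masses, vdW radii, molecule membership; masses and
radii default to a bundled Bondi-type element table). Running simulations
is out of scope — trajectories are inputs.

Numerical constants: 1 u = 1.66053907×10⁻²⁴ g; 1 kcal·mol⁻¹·Å⁻³ =
6947.695 MPa; R = 1.98720×10⁻³ kcal·mol⁻¹·K⁻¹.

## Synthetic data generator

The generator emulates the statistical structure of curated experimental
viscosity data — it is the test bed, not a claim about any particular
dataset:

- **Compounds**: a fragment grammar over linear/branched alkyls builds
  esters, carbonates, ethers, alcohols and alkanes (~430 distinct
  structures); a "battery" preset returns six electrolyte solvents
  (methyl/ethyl acetate, methyl butyrate/propionate, dimethyl and ethyl
  methyl carbonate).
- **Law**: per compound, log₁₀ μ(T) = A + B/(T − C) with A ~ N(−1.4,
  0.05); B = 130 + 6·(heavy−3) + 80·donors + 90·σ(heavy) + N(0, 10) K;
  C = clip(N(75 + 45·σ(heavy), 6), 50, 160) K, where σ is a logistic
  crossover centred at 12 heavy atoms. The crossover in both B and C
  emulates the regime change from small-molecule flow to the more
  cooperative dynamics of larger liquids; it makes the structure–
  temperature response genuinely non-additive, which is what lets
  interaction-capable models (gradient-boosted trees) out-generalize
  additive linear baselines, and it gives log-viscosity its right tail.
  Parameters are deterministic per (canonical SMILES, seed).
- **Sampling**: temperatures Beta(2, 4)-skewed inside 227–404 K (more
  measurements at moderate temperatures); log-scale Gaussian noise
  (default sd 0.02); viscosities clipped to 0.10–26.52 cP with clipping
  flagged in the ground truth.
- **Injected violations** (for filter tests): element-rule breakers,
  gross range outliers (300–1500 cP), and positive-deviation points
  (+0.05 to +0.5 cP above the previous retained point — comfortably above
  the 0.02 cP threshold). The dedicated curation fixture freezes the
  Vogel parameters of two small esters and uses an even temperature grid
  so that, for any seed, each injected row trips exactly its own filter
  and no clean row sits near an IQR fence.
- **Surrogate external descriptors**: eight columns named like the MD
  descriptors, each a monotone transform of the row's noiseless
  log-viscosity blended with seeded noise by an informativeness weight in
  [0, 1]; the FV- and RMSD-analogs are negatively related to viscosity
  (thinner liquids have more free volume and mobility).

What passing tests on this generator do **not** show: real experimental
scatter is not i.i.d. log-normal, real structure–property relations are
far richer than a two-summary crossover, inter-laboratory offsets and
measurement-protocol biases are absent, and stereochemistry is ignored.
Results on synthetic data demonstrate that the machinery is correct and
statistically powered under its stated assumptions, not that any model
will reach the same accuracy on laboratory data.

## Problem sizes and numerical choices

Default study conditions: 200 compounds × 5 temperatures, noise sd 0.02,
five split seeds for benchmarks and twenty for learning curves; the
benchmark in the acceptance script contrasts the strongest tree family
(LGBM) with the L1-linear baseline — all eight families are implemented
and unit-tested, and can be benchmarked by listing them. Default
hyperparameter grids are small (1–3 knobs, 1–4 values; LGBM: 300
trees/lr 0.05/31 leaves/column-subsample 0.6 vs 600/0.04/63/0.4) and
user-replaceable. Degenerate inputs fail loudly: non-positive
temperatures/viscosities, constant targets in R², empty grids, fewer
compounds than folds, missing external rows under the strict join policy.

## Known limitations

- Exact curation idempotence cannot hold for arbitrary inputs with a
  single-pass IQR filter (see Curation); the report makes every removal
  auditable instead.
- TreeSHAP fast-path values are not identical to interventional sampling
  values; rankings agree on tested fixtures.
- Free-volume estimates carry grid discretization error (≲0.5% at 0.25 Å
  spacing on 10 Å boxes); the Monte-Carlo cross-check in the tests bounds
  it.
- The MD descriptor set assumes orthorhombic boxes and molecules smaller
  than half the box (minimum-image unwrapping).
- Stereoisomerism is not modeled anywhere (canonical SMILES identity).
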