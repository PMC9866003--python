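# Methods

This note documents the statistical model, the data-conditioning rules,
the numerical choices and the synthetic-data assumptions behind
`pmfsa`, and states what the test suite does and does not demonstrate.

## Receptor model and objective

PM2.5 source apportionment treats the measured concentration table
X (n samples × m species) as a nonnegative mixture X = G F + E of p
sources: G holds per-sample source contributions, F per-source chemical
fingerprints.  Both factors are constrained nonnegative — a source
cannot emit a negative concentration nor contribute negative mass —
which is what distinguishes positive matrix factorization from
rotation-based factor analysis and makes the factors physically
interpretable.  The fit minimizes

Q = Σᵢⱼ (eᵢⱼ/σᵢⱼ)²,  eᵢⱼ = xᵢⱼ − Σₖ gᵢₖ fₖⱼ,

so each cell is weighted by its own measurement uncertainty σᵢⱼ: noisy
species, below-detection values and the redundant total-mass column are
down-weighted rather than discarded.  When the uncertainty model is
correct, Q behaves like a χ² statistic with roughly
dof = n·m − p(n+m) degrees of freedom; Q/dof near 1 indicates neither
over- nor under-fitting.  On synthetic data with correctly specified
uncertainties the suite measures Q/dof ≈ 0.83–0.91 (n=200, m=21, p=4):
slightly below 1 because the deliberately down-weighted cells (mass
column at 4× uncertainty, BDL substitutions at (5/6)·MDL, imputed cells
at 4× the geometric mean) contribute near-zero scaled residuals while
still being counted in dof.

## Data conditioning

Applied in this order (each removal is logged with its triggering rule):

1. **Mass closure** (`closure_tol`, default 0.50): samples where
   |mass − Σ species| / mass > 50% are excluded.  The species sum uses
   measured values, counts BDL cells at MDL/2 and skips missing cells;
   samples with missing or non-positive mass are excluded under a
   distinct rule rather than divided by.  Imputed values never rescue a
   bad sample, because imputation happens later.
2. **Species screening** (`bdl_missing_frac`, default 0.90): species
   BDL-or-missing in ≥90% of samples are dropped, as are species on the
   analyst's `drop_list` (chemically unreliable columns).  Whether the
   90% rule is strict or weak is a convention; ≥ is used here.
3. **Imputation and uncertainties** (`error_fraction`, default 0.1):
   - measured x > 0: X = x, U = √((0.1·x)² + (0.5·MDL)²);
   - BDL or measured 0: X = MDL/2, U = (5/6)·MDL (a reported zero
     carries no more information than "below detection");
   - missing: X = geometric mean of the species' measured positive
     values, U = 4× that mean (kept, but nearly ignored by the fit);
   - total-mass column: U = 4× the mass value, so the mass is present
     for scaling but does not dominate the factorization.
   A species with no measured positive value has no defined geometric
   mean; the error message instructs excluding it first.

The per-species signal-to-noise ratio is reported as the mean over
non-missing cells of max(0, (x − MDL)/MDL) — the convention of the
widely used desktop PMF tool — with BDL cells contributing zero.

## Solver

Alternating multiplicative (Lee–Seung-type) updates generalized to
per-cell weights 1/σ², with an ε = 10⁻¹² floor preventing division by
zero and keeping iterates strictly positive.  These updates decrease Q
monotonically and preserve nonnegativity by construction; the suite
asserts monotonicity to 10⁻⁹ relative tolerance.  Convergence is
declared after 10 consecutive iterations with relative ΔQ < 10⁻⁸
(`rel_tol`), capped at `max_iter` = 5000.  Multiplicative updates
converge slowly near a minimum, so long runs on well-fitting data may
hit the cap with the solution already stable to ~6 significant digits;
`converged` records which happened.

NMF objectives are multimodal, so the solver restarts from `n_starts`
(default 20) random initializations whose generators are spawned
deterministically from the master seed; the lowest-Q run is kept and
the per-start Q spread is reported as a stability diagnostic.  Identical
input + config reproduce results bit for bit.

**Robust mode** (off by default): cells with |scaled residual| > α = 4
are down-weighted by α/|r| (Huber), and Q_robust replaces Q_true both in
the objective's reweighting and in start selection.  Both Q values are
always reported.

**Rotational ambiguity / Fpeak.**  Any invertible T with GT ≥ 0 and
T⁻¹F ≥ 0 yields an equally good solution; the Fpeak parameter φ walks
this family.  The implementation applies elementary pairwise transforms
T = I + φ·E_kl to unit-mean-normalized G columns — φ < 0 sparsifies
contributions, φ > 0 profiles — choosing the factor pair greedily: among
pairs whose post-rotation Q stays within a 10% budget of the base Q,
the one pushing the most mass against the nonnegativity boundary is
taken (the most "rotating" feasible move), then negatives are clipped
and the free matrix refit.  φ = 0 is the identity; the Q increase paid
for each rotation is reported and never negative.  The exact rotation
algorithm of the proprietary multilinear-engine tools is unpublished;
this scheme satisfies the same contract (identity at 0, nonnegativity,
bounded and reported dQ) but is not claimed to be numerically
equivalent.  `fpeak_scan` tabulates the default 21-point grid
(−1.0 … 1.0 in 0.1 steps) and deliberately makes no automatic choice.

**Mass scaling and ordering.**  `normalize_factors` rescales each
factor by its profile's mass loading so G columns are in μg/m³ of
PM2.5; factors with (numerically) zero mass loading are flagged and
left unscaled rather than divided by zero.  Factors are ordered by
descending mean contribution purely for reporting reproducibility.

## Diagnostics

* **Coverage**: fraction of scaled residuals in [−3, +3]; ≥80% is the
  conventional adequacy bar.  Raw (not robust-capped) residuals are
  used.
* **IM / IS**: maximum over species of the mean and of the sample
  standard deviation (n−1 divisor; the divisor is a convention) of that
  species' scaled residuals.  IM is taken literally as the maximum
  *signed* column mean; the maximum absolute mean is reported alongside
  since a strong negative bias is equally diagnostic.  Both statistics
  drop sharply once the factor count reaches the true complexity; the
  advisory knee is the largest relative successive drop in IS.  The
  suggestion is never auto-final — factor count is ultimately a
  physical-plausibility judgement.
* **Mass R²**: ordinary least-squares R² between measured total mass
  and the sum of mass-scaled contributions (flagged zero-mass factors
  excluded).  Study-scale synthetic runs land around 0.85–0.90.

## CPF

For one source with daily contributions c and wind records (θ, v):
CPF(Δθ) = mΔθ/nΔθ over 16 north-centered, clockwise, half-open 22.5°
sectors, where n counts non-calm winds (v > 1 m/s) from the sector and
m those whose day's contribution strictly exceeds the 80th-percentile
threshold (linear-interpolation empirical quantile over all paired
non-calm records; both the percentile and the quantile rule are
conventions).  Sub-daily winds inherit their calendar day's
contribution; duplicate sample dates (co-located samplers) are averaged.
Sectors never visited get NaN, not 0/0; an all-calm record set is an
error; a constant contribution series yields threshold = constant and
all-zero CPF with a warning — the realistic outcome for a source that
never exceeds its own threshold.

## Synthetic data generator

The generator emulates the statistical structure the method assumes,
not atmospheric chemistry:

* **Fingerprints**: sparse Dirichlet compositions (concentration 0.15)
  tilted toward realistic per-species scales — major ions and carbon
  carry most mass, trace metals sit orders of magnitude lower — and
  row-normalized so one activity unit contributes 1 μg/m³ of mass.
  Rows are resampled until all pairwise cosine similarities are < 0.9,
  making factors identifiable.
* **Activities**: lognormal (σ = 0.6) around geometrically decreasing
  factor means normalized to a mean total mass of 18 μg/m³, with a
  ±30% factor-specific monthly modulation.
* **Noise**: ε ~ N(0, σᵢⱼ), σᵢⱼ = √((0.1·x_true)² + (0.5·MDLⱼ)²),
  truncated at zero (concentrations are physical quantities).
* **Censoring**: per-species MDLs are the fixed point of
  σ(MDL) → observed values → their `bdl_target_rate` quantile, computed
  with a fixed noise draw, so the generating σ, the censoring threshold
  and the conditioning-side U are mutually consistent and the empirical
  BDL fraction matches the target.  Missing cells are restricted to
  species contributing <5% of mass, since losing a dominant species
  would spuriously fail the closure screen (as a lab would re-analyze
  rather than report such a sample).
* **Mass**: row sums of true contributions plus its own 10% noise, so
  closure holds up to noise; planted closure violations multiply the
  observed mass by 3, decisively breaking the ±50% rule.
* **Winds**: 24 hourly records per day; on days where a directional
  source exceeds its 70th activity percentile, directions are von Mises
  around the planted bearing (κ = 12 in the strong-signal tests, where
  the planted sector is recovered in ≥ 18/20 replicates), otherwise
  uniform; speeds are Gamma(2, 1.2) m/s, leaving ~20% calm.

The `study_scale` preset mirrors an urban spring–summer filter
campaign: 74 daily samples from late April, 9 sources, 24 retained
species plus 3 low-reliability and 2 nearly-always-BDL columns and one
closure-violating sample, so conditioning yields a 73 × 25 matrix.

**What passing tests show** — that the estimator is correctly
implemented and well calibrated *under its own assumptions*: exact
low-rank structure plus independent Gaussian noise with known scale.
Real speciated data add profile drift, correlated sampling artifacts,
systematically mis-stated uncertainties and collinear sources (e.g.
secondary sulfate vs. nitrate seasonality); recovery there is known to
be harder, and nothing here quantifies that gap.

## Problem sizes and tolerances in the suite

Simulation-backed tests use deliberately modest sizes chosen to make
their statistical assertions stable: residual calibration at
n=100 × m=21 × p=4 over 10 replicates, recovery and χ² calibration at
n=200 over 20 replicates (mean cosine > 0.95, mean contribution r >
0.9, Q/dof ∈ [0.75, 1.25]), factor-count knee at n=60, m=16, p₀=4 over
10 replicates, CPF bearing recovery over 20 replicates.  Oracle
equivalence tests (brute-force double loops for Q, IM/IS, CPF counts;
exhaustive 3! search for factor matching) run at ≤ 10×10 instances
where enumeration is exact.  Numerical tie-breaks: stable sort for
factor ordering, lexicographic pair choice in the Fpeak greedy step,
strict `>` for CPF exceedance, half-open sector boundaries.

## Known limitations

* No bootstrap/displacement uncertainty estimates on G and F, and no
  constrained (target-profile) runs.
* The Fpeak scheme explores one-pair elementary rotations per call;
  compound rotations are reachable only by repeated application.
* Multiplicative updates are first-order; for matrices much larger than
  a few hundred samples a dedicated weighted-ALS or second-order solver
  would converge faster.
* The weekday/weekend split uses the local calendar of the sample date;
  holidays are not treated specially.
* CPF assumes the day's mean contribution is representative of every
  hour of that day; sub-daily source dynamics are invisible at 24-h
  filter resolution.
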