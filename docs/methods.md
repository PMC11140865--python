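# Methods

## Model

All endpoints are poly-parameter linear free energy relationships (PPLFERs)
in the Goss single-form convention, which uses both the V/L (cavity/van der
Waals) and S/A/B (polar/H-bond) descriptor blocks:

    log K          = s·S + a·A + b·B + v·V + l·L + c
    log {S_W, S_O, VP} = s·S + a·A + b·B + d·(A·B)^0.5 + v·V + l·L + c

Using one functional form for every endpoint is what makes thermodynamic
property cycles applicable at the level of the coefficients, not just the
predictions. The d·(A·B)^0.5 term appears only for pure-phase endpoints: it
captures hydrogen bonding between molecules of the chemical acting as both
solute and solvent. For partition endpoints d is stored as 0 with zero
standard error so a single evaluation path serves all nine endpoints. All
system parameters refer to 25 °C; no temperature dependence is modelled.

Wet vs dry octanol matters: most K_OW measurements use water-saturated
octanol while K_OA measurements use dry octanol, and the dissolved water
changes the phase's polarity and H-bond behaviour. The package therefore
carries both conventions plus the hypothetical wet/dry octanol partition
ratio K_OO that links them.

### Cycle derivation and uncertainty propagation

Four parameter rows are never calibrated directly but derived:

    KOW_dry       = KOA + KAW
    KOO           = KOW_wet − KOW_dry
    SO_dry_liquid = SW_liquid + KOW_dry
    SO_wet_liquid = SW_liquid + KOW_wet

Derivations chain through **unrounded** intermediates (KOW_dry is reused at
full precision for KOO and SO_dry), and each coefficient's standard error
propagates in quadrature, for differences as well as sums, treating the
calibrated equations as independent. The bundled registry stores the
published 2-decimal values; `check_cycle_consistency` recomputes the
derived rows and reports |stored − recomputed| per coefficient and for the
total s.e., passing at ≤ 0.005 (print rounding). Per-coefficient standard
errors are reported in the audit table but excluded from the pass
criterion: quadrature on rounded inputs can land on the opposite side of a
rounding boundary from a value computed on unrounded inputs (two cells in
the bundled registry differ by ~0.01 for exactly this reason), whereas the
coefficients and totals close exactly.

### Calibration

`calibrate_system_parameters` is unweighted ordinary least squares
(statsmodels OLS) of the observed log property on the descriptor columns
(plus sqrt(A·B) for the pure-phase form). Per-coefficient standard errors
come from the OLS covariance matrix; the total standard error is the
residual standard deviation sqrt(SSR/(n−p)). A weighting hook is
deliberately absent: unweighted OLS is the documented default, and rank
deficiency or n ≤ p abort with the offending columns named. Parameter
recovery from synthetic data generated under the model is the module's core
correctness property and is exercised for every bundled endpoint.

## State handling

The state classifier is a transparent threshold rule (system temperature T,
default 298.15 K; margin m, default 10 K):

* gas if T_B ≤ T;
* solid if T_M ≥ T + m;
* maybe_solid if |T_M − T| < m;
* liquid if T_M ≤ T − m and T_B is known to exceed T;
* unknown whenever the deciding inputs are missing.

The maybe-solid band exists because melting-point data and predictions near
ambient temperature are uncertain; downstream, the solid adjustment factors
key on {maybe_solid, solid}. The rule never raises for valid inputs.

The Van't Hoff (Walden) approximation converts supercooled-liquid values to
solid-phase values for T_M > T:

    log X_solid = log X_liquid − ΔS_M·(T_M − T)/(ln10 · R · T)

with R = 8.314 J/(mol·K). When ΔS_M is missing, Walden's rule
(56.5 J/(mol·K)) is used and flagged. Polymorphism and full
Clausius–Clapeyron integration are out of scope.

Boundary caps: a solubility cannot exceed the molarity of the pure liquid,
log10(1/MV) (MV in L/mol), and an environmentally meaningful vapor pressure
cannot exceed atmospheric pressure, log10(101325 Pa) ≈ 5.006. A capped
prediction keeps the RMSEP of the UL it originally received (the interval
is re-centred on the cap), is flagged `capped` and assigned UL 6. MV is a
user input; an optional fallback MV ≈ 1.27·V L/mol (McGowan-volume scaling)
can be enabled and is always flagged. In batch prediction, solubility
capping is skipped (not an error) when MV is absent and the fallback is
disabled, since the cap is then undefined.

## Applicability domain and uncertainty

Three complementary AD diagnostics grade each prediction:

* **leverage** h = xᵀ(XᵀX)⁻¹x against the training design (pseudo-inverse,
  so rank-deficient designs degrade gracefully) — a measure of
  extrapolation;
* **chemical similarity score (CSS)** — mean similarity of the k nearest
  training rows (default k = 3) under the count-vector Tanimoto
  Σmin/Σmax (cosine selectable) — less sensitive to extrapolation;
* **negative-domain check** — substructure codes present in the query but
  absent from the entire training set.

UL assignment precedence: unseen substructures → UL 5; all fragment counts
zero (intercept-only) → UL 4; egregious leverage → UL 3; leverage/CSS
out-of-AD → UL 2; borderline warning → UL 1; else UL 0. UL 6 is reserved
for boundary-cap violations and applied only by the capping step. The
cut-offs are configuration with defaults 1.5p/n / 3p/n / 10p/n for leverage
(warn/out/egregious — multiples of the mean training leverage p/n) and
0.5 / 0.25 for CSS: the grading scheme is fixed, the numbers are documented
stand-ins chosen from common leverage-diagnostic practice.

Meta-model aggregation combines component RMSEPs (and fixed extra standard
errors such as those of the system parameters written into the model) in
quadrature and component ULs by maximum; an intercept-only component (UL 4)
counts as in-AD by default for PPLFER endpoints — the intercept is the
property of an interaction-free solute, a physically meaningful baseline —
with a per-call override.

The 95% prediction interval is M ± 1.96 × adjusted RMSEP. The adjustment
ladder multiplies the estimated RMSEP by 1.25 globally, by 1.67 (VP) or
1.25 (S_W) for maybe/likely solids, and by a further 1.25 for VP at UL 2, 3
or 5. Adjustments only widen intervals. When no per-UL RMSEP table is
supplied, batch prediction falls back to each endpoint's total calibration
standard error as the baseline RMSEP estimate — a lower bound on true
prediction error, which the global 1.25 factor partially offsets.

Evaluation statistics use the population RMSEP (divide by n, as the
external-validation formula is defined), closed-interval membership for
%-within-PI (boundary counts as inside), and a deterministic geometric
ladder {1, 1.25, 1.25², …} for coverage calibration: the smallest factor
whose intervals reach the target coverage.

## Synthetic data

The generator emulates a population of neutral organics spanning small
volatiles to large, complex chemicals: V ~ Uniform(0.3, 4.0);
S ~ Uniform(0, 2.5); A ~ Exp(mean 0.25) truncated at 1.5 and B ~ Exp(mean
0.45) truncated at 2.5 (donors rarer and weaker than acceptors, as in real
neutral organics); L = 3.5·V + N(0, 0.8) (size–van der Waals correlation);
T_B rising with V and T_M 60–160 K below T_B, so gases, liquids,
borderline and clear solids all occur at 25 °C; MV = 1.27·V with 10% noise.
Property datasets are exact PPLFER values plus i.i.d. N(0, σ) noise — the
generating model that OLS assumes.

What passing these tests shows, and does not: the synthetic population has
no correlated descriptor-measurement error, no curated-database biases, no
ionizable or inorganic chemicals, and its noise is homoscedastic Gaussian.
Recovery and coverage results therefore validate the *machinery*
(estimation, propagation, interval construction), not the real-data error
magnitudes, which depend on external experimental datasets.

The coverage-calibration check uses a *constructed* miscalibrated stratum:
residuals are exact normal quantiles on the (i−0.5)/n grid, scaled by
1.25× the assumed RMSEP and randomly permuted. With i.i.d. draws the
empirical coverage of a nominal-95% interval sits exactly on the 95%
boundary and the recovered ladder step would flip with the seed; the
quantile construction makes the recovered factor a property of the method
rather than of sampling luck, at the cost of slightly understating
real-data sampling variability.

## Numerical choices and problem sizes

* Published coefficients are stored at 2-decimal precision; comparisons to
  print use half-even rounding.
* Zero-descriptor (all-zero) solutes are admitted as the degenerate
  intercept-only case even though any real solute has V > 0.
* Parameter-recovery runs use n = 500 rows with σ = 0.2 per endpoint;
  coverage runs use n = 2000 per stratum — sizes at which the sampling
  error of the checked quantities is comfortably below the assertion
  tolerances while the full suite runs in seconds.
* The indirect Raoult's-law VP route (log VP = log(RT/(γ·K_kAk·MV)),
  γ = 1 in the pure phase) accepts caller-supplied per-solute K_kAk
  coefficients; it is restricted to predicted liquids and emits a warning
  for solids, where the approach is known to perform poorly. No identity is
  asserted between the independently calibrated VP and S_W equations via
  S_A: their intercepts were calibrated on different experimental datasets
  and differ by ~0.08 log units from exact three-solubility closure.

## Known limitations

Ionic and ionizable species are out of scope (strong acids pKa < 4 and
bases pKa > 10 are filtered from evaluation data); system parameters are
fixed at 25 °C; the solute-descriptor QSPRs that would predict S, A, B, V,
L from structure are not part of this package — descriptors are inputs;
absolute external-validation RMSEPs depend on proprietary/curated
experimental datasets and are not reproduced here, only the statistics
machinery that computes them.
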