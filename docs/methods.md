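# Methods

## Model and assumptions

The package implements an empirical carbon-ion RBE model built on the
observation that radiosensitivity endpoints D_SF — the dose at which the
surviving fraction reaches SF — are linearly correlated between photon and
carbon-ion exposures, with slope and intercept that vary smoothly with
dose-weighted LET. Two endpoints are modeled, D at e⁻³ (~5% survival) and
D at e⁻¹ (~37%):

- slope(LET) = (1 + f·LET)⁻¹ for both endpoints (one parameter each:
  f₁, f₂);
- intercept(LET) = q₁·LET² + m₁ for the e⁻³ endpoint only; the e⁻¹
  intercept is identically zero.

The predicted endpoints convert to a linear-quadratic curve through the
exact two-point interpolation formulas, with non-negativity constraints:
a negative raw β (exactly when D₃ > 3D₁) pins β = 0 and refits α alone by
least squares over the two endpoints, and symmetrically for a negative raw
α (exactly when D₃ < √3·D₁). The two conditions are mutually exclusive.
These constraints are part of the model — they are applied identically
during training, validation, and inference.

Assumptions worth keeping in view: the LQ form holds over 0–10 Gy; LET_d
alone characterizes beam quality (no track-structure detail); the photon
reference is a high-energy (≥ 200 kVp-equivalent) source; and the
endpoint-space error structure is multiplicative.

## Parameters

| name | units | packaged value | role |
|------|-------|----------------|------|
| f₁ | (keV/µm)⁻¹ | 2.095070×10⁻² | e⁻³ slope decay |
| m₁ | Gy | 5.955453×10⁻¹ | e⁻³ intercept offset |
| q₁ | (keV/µm)⁻² | 2.133918×10⁻⁵ | e⁻³ intercept curvature |
| f₂ | (keV/µm)⁻¹ | 2.230798×10⁻² | e⁻¹ slope decay |

The packaged JSON resource also carries the four standard uncertainties and
all six covariances; the assembled 4×4 covariance is positive semi-definite
(smallest eigenvalue ≈ 5×10⁻¹¹). Dose is always Gy, LET always keV/µm;
there is no unit-conversion layer. Photon sources quoted in MV are stored
as kVp-equivalent = 1000×MV so the curation threshold is one number.

## Fitting

The curve-level objective is the normalized L2 distance of Eq.-style form
√(∫(SF_meas − SF_pred)² dD) / ∫SF_pred dD over the clinically relevant
window 0.5–4 Gy, evaluated on a fixed 513-point composite-Simpson grid
(changing to a 10× finer grid moves distances by < 10⁻⁶; asserted in
tests). Note the normalization uses the predicted curve only, so the
distance is deliberately asymmetric.

The global fit minimizes the sum of squared per-record L2 distances over
(f₁, m₁, q₁, f₂) with non-negativity bounds, via bounded trust-region
least squares with an analytic Jacobian (validated against central finite
differences). Multi-start: the center is the pair of per-endpoint trend
fits (e⁻³: inverse-linear slope + quadratic intercept; e⁻¹: inverse-linear
slope, no intercept), and each start jitters the center uniformly within
±10% per parameter. The default budget is 10 000 starts as in the original
procedure, but the optimum is found reliably with far fewer on synthetic
data; tests and cross-validation use 3–100 starts. Convergence tolerances:
1×10⁻¹⁰ on the objective, 1×10⁻⁸ on parameters. Records whose predicted
endpoints would invert (D₃ ≤ D₁, possible only for pathological parameter
values) contribute a smooth penalty residual that steers the optimizer
back. Fits are deterministic given the seed and invariant under record
reordering (records are canonically sorted internally).

Model selection uses the Gaussian concentrated-likelihood conventions
BIC = n·ln(RSS/n) + k·ln(n) and AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1),
with additive constants dropped (only differences are ever compared).
RSS/n is floored at 10⁻¹⁶ so that noiseless data — RSS at machine zero —
degrade gracefully: ties are then broken purely by the parameter-count
penalty. The slope/intercept family registry ships the named families and
accepts user-registered ones.

Parameter covariance is the Gauss–Newton estimate σ̂²(JᵀJ)⁻¹ with
σ̂² = RSS/(n−4) on the per-record L2 residuals. Two caveats, both verified
by simulation in the test suite: a perfect (noiseless) fit returns a zero
matrix (the √RSS Jacobian is singular there), and because the estimate
treats per-record residuals as independent scalars it understates
cross-correlations between f₂ and the (f₁, m₁, q₁) block that replicate
refit scatter reveals; within-block correlation signs agree with the
scatter oracle.

## Uncertainty propagation

Measured-curve bands propagate the (α, β) fit covariance exactly on the
log-survival scale: var(ln SF) = D²·var(α) + D⁴·var(β) + 2D³·cov(α, β).
Predicted-curve bands propagate the 4×4 model covariance by central finite
differences of ln SF (relative step 10⁻⁵ per parameter) through the full
prediction chain with the central constraint branch held fixed; parameter
draws that would cross the branch are detected and logged. Bands are
formed as exp(ln SF ± z·SE) — positive by construction — with z = 1.96 at
95% coverage and z = 1.0 at 68.3%, exactly.

Validity: the delta method is first-order. Where the central branch is
stable under parameter sampling, band half-widths agree with 10⁴-draw
Monte-Carlo sampling to within 5% (tested at LET 60.5 keV/µm). In the
β-zeroed regime the prediction is strongly convex in f₁ (whose relative
uncertainty is ~41%), and the linearized band understates the sampled
spread by ~20%; the direction of this bias is itself asserted in a test.

## Validation

LOOCV refits the model with each record held out (scaled-down default
budget of 50 starts per refit; per-record seeds derive from a stable
content hash, so results are independent of record order) and predicts the
held-out record. Accuracy is summarized as relative RBE deviations at the
0.5, 1, 2 and 4 Gy dose levels. "RBE at a dose level" fixes the carbon-ion
dose and takes the iso-survival photon dose ratio — the standard
iso-effect convention for ion survival work; the photon-dose-fixed variant
is available behind a flag since the convention is not uniquely
standardized. Bootstrap prediction intervals use the percentile method per
dose level (deviations are resampled within, not across, dose levels),
n_boot = 2000 by default; interval endpoints stabilize to < 2% when n_boot
doubles. LET-bin summaries use the fixed clinical bins [0, 20), [20, 40),
[40, 70), [70, 100), [100, 200), [200, ∞) keV/µm — entrance through
very-high-LET — left-closed so the boundary conventions are exact.
Comparison metrics report mean |relative deviation| (with SEM) for D10%,
D50%, and RBE at 1, 2, 4 Gy, computed on held-out predictions; the test
suite asserts these differ from train-on-all predictions on noisy data
(leakage check). Measured RBE always uses the record's stored C-ion LQ
parameters.

## Synthetic data

The generator emulates the structure of a curated survival compilation.
Defaults state the reference experimental design: 8 cell lines at LET_d =
13.5, 27.9 and 60.5 keV/µm with a 6 MV photon reference, photon
radiosensitivity spanning α_X ∈ [0.05, 0.8] Gy⁻¹ and β_X ∈ [0.005, 0.1]
Gy⁻² (covering the observed D10%,X range of roughly 1.4–8.6 Gy). C-ion
responses derive from the packaged ground-truth constants; each true
endpoint is multiplied by an independent unit-mean lognormal factor with
CV = 5% by default — noise lives in endpoint space because that is where
the model's error structure is defined. Draws violating the endpoint
ordering are resampled (never clamped, to avoid distributional
distortion), with a hard cap of 100 attempts.

What a green synthetic test does not establish: real compilations have
heteroscedastic, inter-laboratory noise, correlated endpoint errors within
a record, uneven LET coverage, and model misspecification — none of which
the generator emulates. Synthetic recovery tests validate the machinery,
not the biological accuracy of the published constants.

One structural subtlety: stored (α_C, β_C) pass through the same
non-negativity constraints as inference, so on the β-zeroed branch the
stored curve is a least-squares fit, not an interpolant, of the generating
endpoints. Endpoint-space trend relations are therefore exact only on the
unconstrained branch, and trend-level tests restrict to it; the global
fit, which applies identical constraints, recovers the generating
parameters exactly from mixed-branch noiseless data.

## Numerical choices

- Dose inversion uses the cancellation-free root
  D = 2L/(α + √(α² + 4βL)), L = −ln SF, which degrades to L/α at β = 0 and
  √(L/β) at α = 0 with no branch switch or precision loss.
- Endpoint ordering D₃ > D₁ is enforced as an error, not a clamp: any
  LQ-derived endpoint pair satisfies it, so a violation indicates a
  pathological parameterization and should be loud.
- Photon inputs with β_X < 0 are rejected outright (mirroring the training
  curation); α_X = 0 with β_X > 0 is accepted.
- CLI configs are flat key-value JSON; explicit flags override config
  values; outputs are never overwritten without `--force`; every artifact
  carries a provenance block (seed, config hash, package version).

## Known limitations

- Purely empirical: the fitted functions characterize, not explain, the
  LET response; no oxygenation, cell-cycle, or track-structure effects.
- Accuracy degrades above ~200 keV/µm, where training compilations are
  sparse and survival measurements carry larger dosimetric uncertainty.
- First-order confidence bands understate uncertainty in the β-zeroed
  regime (see above).
- The Gauss–Newton covariance misses cross-endpoint parameter
  correlations; treat the packaged covariance as approximate when
  propagating through derived quantities dominated by f₂ interactions.
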