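# Methods

This note documents the models, parameter conventions, numerical choices and
validation design of `qmrifit`, and states what the synthetic phantoms do and
do not demonstrate about real data.

## Units and conventions

All internal times are seconds. Rate constants are reported in the
field-standard min⁻¹ (Ktrans, kep, PS), plasma flow Fp in mL/min/100mL,
diffusivities in mm²/s, concentrations in mM, relaxation rates in s⁻¹;
conversion happens at the model boundary against the frame clock. Voxel
indexing is 0-based; spatial orientation is taken from the NIfTI affine and
never reordered; ROI masks that do not match the parent grid (shape or
affine) are rejected, never silently resampled.

Every mapping routine is an sklearn-style estimator: acquisition grid,
bounds and solver options are constructor parameters; `fit(X)` consumes
`(n_voxels, n_frames)` curves; per-voxel results land in trailing-underscore
attributes together with a goodness-of-fit bundle (RSS, R², AIC, AICc, BIC,
convergence flag). Voxels are fitted independently, so any execution order
gives identical results.

## DCE pharmacokinetic modeling

### Signal → concentration

The SPGR steady-state signal is S = S0·sin α·(1−E1)/(1−cos α·E1) with
E1 = exp(−TR·R1). Conversion is baseline-anchored: the mean of the
pre-contrast frames serves as the S(R10) reference, each frame's signal
ratio is inverted for R1(t), and Ct = (R1(t) − R10)/r1. Because only the
ratio enters, the conversion is invariant to a global scanner gain. Default
relaxivity r1 = 4.5 mM⁻¹s⁻¹ (gadolinium agents at 3 T); it is a parameter
everywhere.

Inversions that leave the attainable domain (noise pushing the signal above
the SPGR maximum) are clamped to R1 ∈ [1e-4, 100] s⁻¹ and flagged per frame
rather than set to NaN: maps stay continuous and the QC flag records
unreliability.

The number of baseline frames matters more than is commonly appreciated:
with a short anchor, baseline noise induces a *correlated*, curve-shaped
error across the whole time course that a richer model (e.g. ETM's vp term)
can partially absorb, biasing both parameters and model selection. The
selection study therefore anchors on (nearly) the whole pre-bolus window,
and we recommend the same on real data.

### Arterial input function

Three sources: (i) a population curve — zero before bolus arrival
(default 60 s), linear upslope (4 s) to the peak, then biexponential
washout `a1·e^(−m1 t') + a2·e^(−m2 t')` with defaults
a1 = 4.5 mM, m1 = 4e-3 s⁻¹, a2 = 1.5 mM, m2 = 1.7e-4 s⁻¹ (peak 6 mM — a
typical post-dispersion plasma peak for a standard single dose; every
constant is overridable); (ii) automated detection; (iii) a user CSV.

Automated detection scores every voxel by its maximal normalised
cross-correlation against an idealised bolus — a peak-normalised
gamma-variate (α = 3, tp = 6 s) plus a recirculation plateau rising to 0.4
of the peak with a 15 s time constant — swept over candidate onset times.
The plateau term matters: real arterial curves do not return to baseline,
and a pure gamma-variate template lets slowly enhancing tissue outrank the
artery. Top-decile correlations are filtered for early peak time (no later
than the median candidate) and high amplitude (upper quartile); the mean
signal of the top n voxels (default 10) is converted to whole-blood
concentration via the blood-T10 SPGR inversion and to plasma concentration
by 1/(1−Hct), hematocrit default 0.45.

### Forward models and convolution

TM/ETM/PM are as in the README table. CTUM uses the compartment-uptake
impulse response Fp·[(1−E)e^(−t/Tp) + E]; the 2CXM impulse response is
obtained by eigendecomposition of the 2×2 exchange system

    vp·dC1/dt = Fp(Ca − C1) + PS(C2 − C1),   ve·dC2/dt = PS(C1 − C2)

giving a biexponential with analytically computed amplitudes and rates
(PS = 0 decouples the compartments and is handled exactly; a defective
double root is split by a 1e-14 relative perturbation). The implementation
is verified against a direct ODE integration oracle and against CTUM in the
ve → ∞ limit.

All convolutions use an exponential integrator: Cp is taken piecewise
linear between frames, for which ∫Cp(s)e^(−k(t−s))ds has a closed form per
interval; the recursion is evaluated as a first-order IIR filter on uniform
grids and by a direct loop on non-uniform ones. This is exact for the
kernel class (no quadrature error beyond the piecewise-linear Cp
assumption), robust to non-uniform timing, and — unlike FFT convolution —
free of wrap-around and resampling artifacts. Rate 0 reduces exactly to the
running trapezoid, which is why the Patlak model and the kep→0 limit of ETM
agree to machine precision. Terms with kΔt < 1e-4 use series expansions to
avoid cancellation.

### Shutter-speed model (FXR)

Water exchange between intracellular space (ICS, population pi = 1 − ve)
and EES (pe = ve) is finite; R1(t) is the smaller eigenvalue of the
two-site exchange system with EES concentration Ce = Ct/ve taken from the
Tofts model. Exchange rates: kie = 1/τi; kei from population balance
pi·kie = pe·kei (vascular water ignored — the model is two-site).
Pre-contrast R1 of both sites defaults to the tissue R10; both are
configurable. The model is fitted in *signal* space (the baseline-normalised
SPGR transform of R1(t)) because R1 is intrinsically nonlinear in Ce; τi is
fitted within [0.05, 3] s.

Fast-exchange behaviour: R1 → pi·R1i + pe·(R10e + r1·Ce), i.e. the linear
single-compartment form, with a leading correction
≈ pi·pe·(r1·Ce)²/kex, kex = kie/pe. At kie = 100 s⁻¹ this correction is
below 0.5% only for modest enhancement (r1·Ct ≲ 1 s⁻¹); the validation
therefore demonstrates the limit on a weakly enhancing reference tissue
(Ktrans = 0.015 min⁻¹, ve = 0.2, Ct peak ≈ 0.22 mM) and separately asserts
monotone convergence as kie → ∞ on a strongly enhancing curve, where the
deviation at kie = 100 s⁻¹ is still 2–3% — physically real shutter-speed
behaviour, not numerical error.

### Fitting

Bounded trust-region-reflective least squares throughout. Default bounds:
Ktrans ∈ [0, 5] min⁻¹, ve ∈ [1e-3, 1], vp ∈ [0, 0.5], Fp ∈ [0, 500]
mL/min/100mL, PS ∈ [0, 5] min⁻¹, τi ∈ [0.05, 3] s; organ presets
(brain, head-and-neck, thyroid, prostate, pancreas, bladder) ship as
editable YAML. Initialisation: a Patlak linear regression seeds
Ktrans (and vp) for TM/ETM/PM; CTUM/2CXM/FXR start from physiological
midpoints with a deterministic seeded multi-start (default 5 starts) for
2CXM and FXR. Zero-enhancement voxels return Ktrans at the lower bound,
flagged non-converged.

## Diffusion modeling

Model equations as in the README. ADC comes from the log-linear regression
of ln S on b (non-positive signals excluded; fewer than two usable points
flags the voxel invalid). DKI is a bounded nonlinear fit initialised from
the quadratic polynomial in b of ln S; Kapp is capped at 3 by default to
suppress non-physiological high-b fits, and a warning is issued when the
grid lacks b ≥ 1000 s/mm². IVIM defaults to segmented fitting with
b-threshold 200 s/mm²: mono fit of D above the threshold, then (S0, f, D\*)
with D fixed, iterated three times with the residual pseudo-diffusion
signal subtracted from the high-b segment before each D re-fit — one pass
leaves a D bias of a few percent when D\* is slow (f·e^(−b·D\*) leaking into
b ≥ 200), three passes reduce it below 0.3% on the phantom grid. A
simultaneous four-parameter option exists. NG-IVIM is staged (kurtosis
branch on high b, perfusion branch, joint bounded refinement of all five
parameters). Rician-bias correction is deliberately off by default — the
fits implement the model equations as stated; the noise-floor effect is
characterised by the DRO tests instead.

## Optimal model mapping

Criteria use the Gaussian-likelihood forms AIC = n·ln(RSS/n) + 2k,
AICc = AIC + 2k(k+1)/(n−k−1), BIC = n·ln(RSS/n) + k·ln n, R² = 1 − RSS/TSS,
χ² = RSS/σ² (σ estimated robustly from residual MAD when not given). AICc
is the default: DW fits have n ≤ 10 points, where the small-sample
correction matters. The F-test cascade walks up a statically declared
nesting lattice (PM, TM ⊂ ETM ⊂ 2CXM; CTUM ⊂ 2CXM;
mono ⊂ {DKI, IVIM} ⊂ NG-IVIM) from the most parsimonious candidate.

Two numerical decisions guard degenerate voxels: residual sums below
(1e-6 × signal RMS)² per point are treated as machine-identical before
criterion evaluation — on noise-free data both of two nested models reach
the optimizer's convergence floor and the log-RSS difference would
otherwise be decided by terminal iterates a few ulps apart; and criterion
ties within 1e-9 go to the model with fewest parameters. Voxels where every
candidate failed to converge are masked (index −1). Parameters absent from
a voxel's winning model are masked (NaN) in the combined optimal maps
rather than zero-filled; zero-filling vp where TM wins would be a
defensible alternative but conflates "not modelled" with "estimated zero".

At SNR 50 the residual TM-half misassignment (~9%) matches the irreducible
AICc false-selection rate for one bound-constrained extra parameter
(½·P(χ²₁ > 2) ≈ 8%): this is a property of AICc, not of the
implementation.

## Digital reference objects

The DCE phantom tiles patches over Ktrans ∈ {0.01, 0.02, 0.05, 0.1, 0.2,
0.35} min⁻¹ × ve ∈ {0.01, 0.05, 0.1, 0.2, 0.5} (vp = 0.05 for ETM), renders
them through the chosen forward model to SPGR signal (TR 5 ms, FA 25°,
tissue T10 1 s, blood T10 1.44 s, S0 1000), appends an arterial strip
carrying the blood signal, and uses 661 frames at 0.5 s by default. These
lattice values emulate the public QIBA-style perfusion phantom layout; they
are this package's documented defaults, not a replication of any external
object. The DW phantom renders the grid D ∈ {0.6, 1.0, 1.6}·10⁻³ mm²/s ×
f ∈ {0.05, 0.12, 0.25} × D\* ∈ {10, 20}·10⁻³ × K ∈ {0.5, 0.9, 1.5} through
the NG-IVIM equation over b = {0, 30, 80, 200, 500, 800, 1500, 2000} s/mm²,
spanning the low-b perfusion and high-b kurtosis regimes. Gaussian or
Rician (magnitude) noise and optional 12-bit DICOM-style integer scaling
(stored slope/intercept) are applied last; a fixed seed makes output
bit-reproducible.

`score_maps` is the universal harness: per-parameter bias, RMSE and — on
paired seeded noise replicates (synthetic test–retest) — the repeatability
coefficient RC = 1.96·√2·wSD with wSD = √(mean(d²)/2).

### What the phantoms do and do not show

Patches are internally homogeneous, noise is spatially white, the AIF is
known exactly, and there is no motion, B1 inhomogeneity, partial-volume
mixing, or T2\* saturation of the bolus peak. Passing the recovery tests
demonstrates that the forward models, conversions and optimizers are
correct and unbiased under the stated noise model — it does not bound
errors on real data, where AIF inaccuracy and B1 error typically dominate
the Ktrans budget. The selection study's SNR and voxel counts (SNR 50,
750 voxels/half, 661 frames) are the package's chosen study conditions.

## Validation problem sizes

The shipped validation uses patch size 2 (DCE, 120 tissue voxels × 661
frames), patch size 2 per DW grid (12–216 voxels × 8 b-values), and patch
size 5 for the selection study (1500 voxels); these sizes were chosen so
the whole suite completes in minutes on one CPU while still covering every
lattice point.

## Known limitations

No inversion-recovery T1, B1 correction, DTI/directional diffusion,
three-site water exchange, Bayesian model averaging, spatial regularisation
of the OMM index map, dispersion/delay correction of the AIF, or DICOM
pixel-data conversion (metadata extraction only; image conversion is
delegated to an external converter). The DICOM b-value reader supports the
public tag (0018,9087) plus the Siemens (0019,100C), GE (0043,1039;
1e9-offset convention) and Philips (2001,1003) private tags.
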