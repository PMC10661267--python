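# qmrifit

Quantitative multiparametric MRI analysis for oncology imaging: voxel-wise
parametric mapping from dynamic contrast-enhanced (DCE) MRI, multi-b-value
diffusion-weighted (DW) MRI and T1/T2 relaxometry, with voxel-wise **optimal
model mapping** (OMM) and digital-reference-object (DRO) synthesis for
ground-truth validation.

It is aimed at imaging scientists who need reproducible quantitative
biomarkers — permeability (Ktrans, ve, vp, Fp, PS), cellularity (ADC, D, f,
D\*, K) and relaxation times (T1, T2) — from NIfTI image series, either
through the Python API (scikit-learn-style estimators) or the `qmri` command
line.

## Models

**DCE pharmacokinetics** (tissue concentration Ct driven by the arterial
plasma concentration Cp):

| model | parameters | form |
|---|---|---|
| TM    | Ktrans, ve | Ct = Ktrans·e^(−kep·t) ⊗ Cp, kep = Ktrans/ve |
| ETM   | Ktrans, ve, vp | TM + vp·Cp |
| PM    | Ktrans, vp | Ktrans·∫Cp dt + vp·Cp |
| FXR (shutter-speed) | Ktrans, ve, τi | two-site water-exchange R1(t), fitted in signal space |
| CTUM  | Fp, PS, vp | Fp·[(1−E)e^(−t/Tp) + E] ⊗ Cp, E = PS/(PS+Fp), Tp = vp/(Fp+PS) |
| 2CXM  | Fp, PS, ve, vp | biexponential exchange impulse response ⊗ Cp |

Signal→concentration conversion inverts the SPGR steady-state equation
against a pre-contrast baseline anchor: ΔR1(t) = R1(t) − R10, Ct = ΔR1/r1.
The AIF can be a configurable population curve, auto-detected from the
image (cross-correlation against an idealized bolus), or supplied as CSV.

**Diffusion** (signal vs b-value): mono-exponential ADC, IVIM
(f, D\*, D; segmented or simultaneous fitting), DKI (Dapp, Kapp) and
NG-IVIM (f, D\*, D, K), which nest as
mono ⊂ {IVIM, DKI} ⊂ NG-IVIM.

**Relaxometry**: variable-flip-angle SPGR T1 (DESPOT1 initialisation +
bounded nonlinear refinement) and multi-echo T2 (S = S0·e^(−TE/T2)).

**OMM** arbitrates fitted candidate models per voxel by AICc (default),
BIC, χ², R² or a nested F-test cascade, and assembles a best-model index
map plus optimal parameter maps.

## Worked example

Fit the extended Tofts model to a noise-free 661-frame DCE phantom with
known ground truth:

```python
import numpy as np
from qmrifit import DROSpec, generate_dce_dro, DCEFitter

bundle = generate_dce_dro(DROSpec(kind="dce", patch_size=2, frames=661,
                                  model="etm", seed=42))
ct, truth = bundle.tissue_concentration(baseline_frames=100)
est = DCEFitter(model="etm", aif=bundle.aif).fit(ct)
for p in ("ktrans", "ve", "vp"):
    rel = np.abs(est.params_[p] - truth[p]) / truth[p]
    print(f"{p:6s} max relative error {100 * rel.max():.2e} %")
```

prints

```
ktrans max relative error 2.59e-07 %
ve     max relative error 8.90e-08 %
vp     max relative error 1.78e-08 %
```

i.e. the fit returns the generating Ktrans (min⁻¹), ve and vp of every
phantom patch to ~1e-7 % — machine-precision recovery through the full
pipeline (forward model → SPGR signal → concentration inversion → bounded
least squares).

The same workflow from the shell:

```bash
qmri dro --kind dce --seed 42 --out dro/
qmri aif --population --dt 0.5 --frames 661 --out aif/
qmri dce --model etm --series dro/series.nii.gz --aif aif/aif.csv \
     --t10 1.0 --fa 25 --tr 0.005 --dt 0.5 --baseline-frames 100 --out maps/
qmri score --fitted maps/etm_ktrans.nii.gz --truth dro/truth_ktrans.nii.gz
```

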