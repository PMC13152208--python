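# npwmf — nonprewhitening matched-filter model observer for CT

`npwmf` computes task-based low-contrast detectability for CT images with
the nonprewhitening matched filter (NPWMF) model observer, in both the
**Fourier domain** (the route used by most CT quality-assurance tools) and
the **spatial domain** (the route that remains valid when iterative or
deep-learning reconstruction makes the noise nonstationary).  It is aimed
at medical physicists assessing scanner protocols and reconstruction
algorithms with repeat-scanned phantoms, and at anyone who wants to check
how far a Fourier NPS/TTF analysis can be trusted for a given denoising
algorithm.

## The observer

For an image (column vector) **i**, the NPWMF decision variable is

    L = Δī^T i,

where the template Δī = E[i_present − i_absent] is the expected
signal-present minus signal-absent image (estimated from a repeat-scan
ensemble, or rendered analytically when the ground truth is known).  From
the decision variables of n₁ signal-absent and n₂ signal-present images
the package computes, per feature:

- **method 1 (Fourier)** — d′² = [∫|ΔF|²|T|² dν]² / ∫|ΔF|²|T|² N dν, from
  the radial noise power spectrum N(ν) (windowed-periodogram estimate over
  background ROIs of the repeat scans), the task transfer function T(ν)
  (circular-edge measurement on a high-contrast disk) and the analytic
  disk task spectrum ΔF(ν) = C·π(D/2)²·2J₁(πDρ)/(πDρ);
- **method 2 (spatial, Gaussian responses)** —
  d′² = (E[L₂]−E[L₁])² / (½(Var[L₁]+Var[L₂])), converted to AUC through
  AUC = Φ(d′/√(1+β)/√2) with internal-noise parameter β;
- **method 3 (spatial, nonparametric)** — the pairwise (Mann-Whitney)
  AUC = (1/n₁n₂)ΣΣ H(L₂−L₁), optionally convolved with Gaussian internal
  noise of variance σ² = β(Var[L₁]+Var[L₂]).

Uncertainties: analytic relative d′ uncertainty
u = 100·√(1/(nm·d′²) + 1/(4(n−1)m)) for n repeats × m slices (method 2),
per-slice standard error of the AUC mean (method 3), and a percentile
bootstrap over TTF/NPS replicates (method 1).  A synthetic phantom
simulator (disks blurred by a Gaussian PSF in correlated Gaussian noise
with a parametric radial NPS, plus an edge-preserving denoiser surrogate)
provides ground truth for every estimator.

## Worked example

`examples/02_spatial_observer.py` simulates 110 repeat scans × 5 slices of
the default scene (6 mm / 10 HU disk in 20 HU ramp-spectrum noise) and
runs both spatial routes at β = 3:

```
feature: 6.0 mm, 10.0 HU
method 2 (Gaussian responses): d' = 2.842, AUC = 0.843 (95% CI 0.830-0.855)
method 3 (nonparametric):      AUC = 0.843 (95% CI 0.836-0.850, per-slice SEM 0.0035)
```

The two spatial routes agree to the third decimal — the Gaussian-response
assumption costs nothing here.  `examples/04_denoising_divergence.py` adds
the edge-preserving denoiser surrogate and repeats the comparison against
the Fourier route:

```
condition              AUC_Fourier  (change)   AUC_spatial  (change)
stationary                  0.848  (+0.000)        0.855  (+0.000)
denoised (s=0.5)            0.855  (+0.007)        0.857  (+0.003)
denoised (s=0.9)            0.861  (+0.013)        0.858  (+0.003)
```

The Fourier route credits the denoiser with several times the benefit the
spatial observer actually experiences: the background NPS drops, but the
faint feature is smoothed along with the noise — exactly the failure mode
of stationarity-assuming analyses of nonlinear reconstruction.

The other examples cover ensemble simulation and I/O (`01`), the Fourier
pipeline with its bootstrap CI (`03`), and the d′/AUC/percent-correct
conversion chain (`05`).  A thin CLI wraps the same pipeline:
`npwmf simulate`, `npwmf analyze --config cfg.yaml`, `npwmf compare`.

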