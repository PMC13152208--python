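"""The central comparison: Fourier vs spatial observer under denoising.

Runs both calculation routes on the same scene, first with stationary
correlated noise, then with an edge-preserving denoiser surrogate (the
stand-in for iterative / deep-learning reconstruction).  With stationary
noise the routes agree; with denoising the Fourier route overestimates
detectability because the background NPS drops while the faint feature
is smoothed along with the noise.
"""

from npwmf import (
    NoiseSpec,
    auc_from_dprime,
    background_roi_grid,
    decision_variables,
    disk_spectrum,
    dprime_fourier,
    dprime_spatial,
    estimate_nps,
    estimate_template,
    estimate_ttf,
    extract_samples,
    layout_from_spec,
    place_rois,
    simulate_ensemble,
)
from npwmf.pipeline import default_phantom

BETA = 3.0
spec, base = default_phantom()
geoms = place_rois(layout_from_spec(spec), spec.pixel_size, spec.grid_shape)
exclude = [g.roi_mask | g.absent_roi_mask for g in geoms]
corners = background_roi_grid(spec.grid_shape, 128, exclude)
task = disk_spectrum(geoms[0].feature)

rows = []
for label, denoiser in [("stationary", None),
                        ("denoised (s=0.5)", ("edge_preserving", 0.5)),
                        ("denoised (s=0.9)", ("edge_preserving", 0.9))]:
    noise = NoiseSpec(model=base.model, target_std=base.target_std,
                      denoiser=denoiser)
    ens = simulate_ensemble(spec, noise, 110, 5, seed=13)
    d_f = dprime_fourier(estimate_nps(ens, 128, corners),
                         estimate_ttf(ens, geoms[1].feature), task)
    samples = extract_samples(ens, geoms[0])
    d_s = dprime_spatial(decision_variables(samples, estimate_template(samples)))
    rows.append((label, auc_from_dprime(d_f, BETA), auc_from_dprime(d_s, BETA)))

print("condition              AUC_Fourier  (change)   AUC_spatial  (change)")
for label, af, asp in rows:
    print(f"{label:22s} {af:10.3f}  ({af - rows[0][1]:+.3f}) "
          f"{asp:12.3f}  ({asp - rows[0][2]:+.3f})")
print("the Fourier route credits the denoiser with a benefit several times "
      "larger than the spatial observer actually experiences — the "
      "inflation a stationarity-assuming analysis reports for nonlinear "
      "denoising")
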