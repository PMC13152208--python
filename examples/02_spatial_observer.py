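"""Spatial-domain NPWMF: template, decision variables, d' and AUC.

Extracts background-corrected feature-present and feature-absent ROI
vectors, forms the empirical matched-filter template, and evaluates both
spatial routes: the Gaussian-response detectability index d' (method 2)
and the nonparametric pairwise AUC with internal noise (method 3).
"""

from npwmf import (
    InternalNoiseModel,
    auc_ci_from_dprime,
    auc_from_dprime,
    auc_sem_method3,
    decision_variables,
    dprime_spatial,
    estimate_template,
    extract_samples,
    layout_from_spec,
    place_rois,
    simulate_ensemble,
)
from npwmf.pipeline import default_phantom

BETA = 3.0  # internal noise degrading the ideal observer to human efficiency

spec, noise = default_phantom()
n, m = 110, 5
ensemble = simulate_ensemble(spec, noise, n, m, seed=7)
geom = place_rois(layout_from_spec(spec), spec.pixel_size, spec.grid_shape)[0]
samples = extract_samples(ensemble, geom)
template = estimate_template(samples)
decisions = decision_variables(samples, template)

d = dprime_spatial(decisions)
auc2 = auc_from_dprime(d, BETA)
lo2, hi2 = auc_ci_from_dprime(d, BETA, n, m)
auc3, sem3, (lo3, hi3) = auc_sem_method3(decisions, InternalNoiseModel(beta=BETA))

print(f"feature: {geom.feature.diameter_mm} mm, {geom.feature.contrast_hu} HU")
print(f"method 2 (Gaussian responses): d' = {d:.3f}, "
      f"AUC = {auc2:.3f} (95% CI {lo2:.3f}-{hi2:.3f})")
print(f"method 3 (nonparametric):      AUC = {auc3:.3f} "
      f"(95% CI {lo3:.3f}-{hi3:.3f}, per-slice SEM {sem3:.4f})")
print("the two spatial routes agree within their uncertainties when the "
      "decision variables are close to Gaussian")
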