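"""Conversions and uncertainties: d' <-> AUC, analytic CIs, M-AFC percent correct.

Shows the closed-form chain used for the published confidence intervals
(invert the Gaussian-response AUC relation, apply the analytic relative
uncertainty of a repeat-scan d' estimate, map back), and the conversion
of forced-choice percent correct to AUC by numerical integration of the
Gaussian M-AFC psychometric function.
"""

from npwmf import (
    auc_ci_method2,
    auc_from_dprime,
    dprime_from_auc,
    dprime_rel_uncertainty,
    mafc_pc_to_auc,
)

beta, n, m = 3.0, 110, 5
for point in (0.838, 0.832, 0.818, 0.847, 0.849, 0.851):
    d = dprime_from_auc(point, beta)
    u = dprime_rel_uncertainty(d, n, m)
    lo, hi = auc_ci_method2(point, beta, n, m)
    print(f"AUC {point:.3f}: d' = {d:.3f}, u = {u:.2f}%  ->  "
          f"95% CI ({lo:.3f}, {hi:.3f})")

print()
for pc in (0.45, 0.65, 0.85):
    auc = mafc_pc_to_auc(pc, m_alternatives=4)
    print(f"4-AFC percent correct {pc:.2f} -> AUC {auc:.3f}")
print("a 4-AFC score converts to a higher AUC than the raw proportion "
      "because beating 3 distractors is harder than a paired comparison")
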