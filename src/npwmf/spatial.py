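"""Spatial-domain nonprewhitening matched filter.

The NPWMF decision variable for an image vector i is L = t^T i, where the
template t is the expected signal-present minus signal-absent image.  From
the two sets of decision variables the observer yields either a
detectability index d' under a Gaussian-response assumption, or a
nonparametric AUC by pairwise comparison (the Mann-Whitney statistic),
optionally degraded by Gaussian internal noise of standard deviation
sigma on the decision axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .phantom import PhantomSpec, disk_image
from .roi import RoiGeometry, RoiSamples

__all__ = [
    "Template",
    "DecisionSet",
    "InternalNoiseModel",
    "estimate_template",
    "analytic_template",
    "decision_variables",
    "dprime_spatial",
    "dprime_roi_route",
    "auc_empirical",
    "internal_noise_sigma",
]


@dataclass
class Template:
    """Matched-filter weights over the ROI pixels (HU units)."""

    values: np.ndarray
    source: str  # "empirical" | "analytic"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("template contains non-finite values")
        if np.all(self.values == 0):
            warnings.warn("template is identically zero (degenerate)", stacklevel=2)


@dataclass
class DecisionSet:
    """Decision variables for n1 signal-absent and n2 signal-present images."""

    L_absent: np.ndarray
    L_present: np.ndarray
    slice_index: np.ndarray | None = None

    def __post_init__(self):
        self.L_absent = np.asarray(self.L_absent, dtype=float).ravel()
        self.L_present = np.asarray(self.L_present, dtype=float).ravel()
        if len(self.L_absent) < 1 or len(self.L_present) < 1:
            raise ValueError("both classes need at least one observation")
        if not (
            np.all(np.isfinite(self.L_absent)) and np.all(np.isfinite(self.L_present))
        ):
            raise ValueError("non-finite decision variables")
        if self.slice_index is not None:
            self.slice_index = np.asarray(self.slice_index)
            if not (len(self.slice_index) == self.n1 == self.n2):
                raise ValueError(
                    "slice_index labels require equally sized classes"
                )

    @property
    def n1(self) -> int:
        return len(self.L_absent)

    @property
    def n2(self) -> int:
        return len(self.L_present)


@dataclass
class InternalNoiseModel:
    """Internal decision noise: beta (dimensionless) and/or sigma (L units).

    The two parameterisations are linked through the class variances:
    sigma^2 = beta * (Var[L_absent] + Var[L_present]).
    """

    beta: float | None = None
    sigma: float | None = None

    def __post_init__(self):
        if self.beta is not None and self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def estimate_template(samples: RoiSamples) -> Template:
    """Empirical template: mean(present) - mean(absent) over all observations."""
    if samples.present.shape[0] < 2:
        raise ValueError("need at least 2 observations per class")
    return Template(
        values=samples.present.mean(axis=0) - samples.absent.mean(axis=0),
        source="empirical",
    )


def analytic_template(spec: PhantomSpec, geom: RoiGeometry, feature_index: int = 0
                      ) -> Template:
    """Ground-truth template from a simulated scene.

    Renders the PSF-blurred disk alone (no noise, zero background) and
    reads off the ROI pixels — available only when the scene and transfer
    are known, i.e. for simulations.
    """
    feat = spec.features[feature_index]
    solo = PhantomSpec(
        grid_shape=spec.grid_shape,
        pixel_size=spec.pixel_size,
        background_level=0.0,
        features=(feat,),
        psf_sigma=spec.psf_sigma,
    )
    return Template(values=disk_image(solo)[geom.roi_mask], source="analytic")


def decision_variables(samples: RoiSamples, template: Template) -> DecisionSet:
    """Inner product of the template with every present/absent pixel vector."""
    if template.values.shape[0] != samples.present.shape[1]:
        raise ValueError(
            f"template length {template.values.shape[0]} != ROI pixel count "
            f"{samples.present.shape[1]}"
        )
    L2 = samples.present @ template.values
    L1 = samples.absent @ template.values
    if not (np.all(np.isfinite(L1)) and np.all(np.isfinite(L2))):
        raise ValueError("non-finite decision variable")
    return DecisionSet(L_absent=L1, L_present=L2, slice_index=samples.slice_index)


def dprime_spatial(decisions: DecisionSet) -> float:
    """Detectability index from decision-variable means and variances.

    d'^2 = (E[L2] - E[L1])^2 / (0.5 (Var[L1] + Var[L2])), with unbiased
    sample variances.  The returned d' is non-negative; a negative mean
    difference (perverse observer) is reported via warning.
    """
    if decisions.n1 < 2 or decisions.n2 < 2:
        raise ValueError("need at least 2 observations per class")
    diff = decisions.L_present.mean() - decisions.L_absent.mean()
    pooled = 0.5 * (
        decisions.L_absent.var(ddof=1) + decisions.L_present.var(ddof=1)
    )
    scale = max(
        np.abs(decisions.L_absent).max(), np.abs(decisions.L_present).max(), 1.0
    )
    if pooled <= (1e-10 * scale) ** 2:
        raise ValueError("zero pooled variance: decision variables degenerate")
    if diff < 0:
        warnings.warn("mean(L_present) < mean(L_absent); returning |d'|", stacklevel=2)
    return float(abs(diff) / np.sqrt(pooled))


def dprime_roi_route(decisions: DecisionSet) -> float:
    """Detectability index with the repeat-scan ROI estimation structure.

    Variant of :func:`dprime_spatial` matching the repeat-imaging ROI
    procedure whose analytic uncertainty is
    :func:`npwmf.stats.dprime_rel_uncertainty`: the background-corrected
    absent class has zero expectation by construction, so the numerator
    is the present-class mean alone, and the class variances are
    estimated per slice position across repeats (pooled over both
    classes and slices, 2(n-1)m degrees of freedom).
    """
    if decisions.slice_index is None:
        raise ValueError("ROI-route d' needs slice labels")
    slices = np.unique(decisions.slice_index)
    n_per = [np.sum(decisions.slice_index == s) for s in slices]
    if min(n_per) < 2:
        raise ValueError("need at least 2 repeats per slice")
    if len(set(n_per)) != 1:
        raise ValueError("unbalanced slices: equal repeats per slice required")
    mean_abs = decisions.L_absent.mean()
    sem_abs = decisions.L_absent.std(ddof=1) / np.sqrt(decisions.n1)
    if abs(mean_abs) > 5 * sem_abs:
        warnings.warn(
            "absent-class mean is far from zero; background correction "
            "may be inadequate for the ROI-route estimator",
            stacklevel=2,
        )
    diff = decisions.L_present.mean()
    pieces = []
    for s in slices:
        sel = decisions.slice_index == s
        pieces.append(decisions.L_absent[sel].var(ddof=1))
        pieces.append(decisions.L_present[sel].var(ddof=1))
    pooled = float(np.mean(pieces))
    scale = max(abs(decisions.L_present).max(), abs(decisions.L_absent).max(), 1.0)
    if pooled <= (1e-10 * scale) ** 2:
        raise ValueError("zero pooled variance: decision variables degenerate")
    if diff < 0:
        warnings.warn("mean(L_present) < 0; returning |d'|", stacklevel=2)
    return float(abs(diff) / np.sqrt(pooled))


def auc_empirical(
    decisions: DecisionSet, internal: InternalNoiseModel | None = None
) -> float:
    """Empirical AUC by pairwise comparison of all n1*n2 decision pairs.

    Without internal noise this is the Mann-Whitney statistic with the
    standard tie convention H(0) = 1/2.  With internal noise sigma > 0,
    each Heaviside comparison is convolved with the Gaussian noise,
    becoming Phi((L2 - L1)/sigma); as sigma -> 0 this reduces to the
    step-function form.
    """
    sigma = 0.0
    if internal is not None:
        if internal.sigma is not None:
            sigma = internal.sigma
        elif internal.beta is not None:
            sigma = internal_noise_sigma(decisions, internal.beta)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    diffs = decisions.L_present[:, None] - decisions.L_absent[None, :]
    if sigma == 0:
        comp = np.where(diffs > 0, 1.0, np.where(diffs < 0, 0.0, 0.5))
    else:
        comp = norm.cdf(diffs / sigma)
    return float(comp.mean())


def internal_noise_sigma(decisions: DecisionSet, beta: float) -> float:
    """Internal-noise sigma equivalent to a given beta.

    sigma^2 = beta * (Var[L_absent] + Var[L_present]).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if beta == 0:
        return 0.0
    v = decisions.L_absent.var(ddof=1) + decisions.L_present.var(ddof=1)
    scale = max(
        np.abs(decisions.L_absent).max(), np.abs(decisions.L_present).max(), 1.0
    )
    if v <= (1e-10 * scale) ** 2:
        raise ValueError("degenerate decision-variable variance")
    return float(np.sqrt(beta * v))
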