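"""Conversions between d', AUC and percent correct, and uncertainty estimates.

Under the Gaussian independent-response assumption,

    AUC = Phi( d' / sqrt(1 + beta) / sqrt(2) ),

where beta is the internal-noise parameter degrading the ideal template
observer to human efficiency.  The relative uncertainty (one standard
deviation, percent) of an ROI-based d' estimate from n repeat scans with
m usable slices, one present and one absent ROI per slice, is

    u = 100 * sqrt( 1/(n m d'^2) + 1/(4 (n-1) m) ).

Confidence intervals for the three observer calculation methods:
method 1 (Fourier) by percentile bootstrap over TTF and NPS replicates,
method 2 (spatial, Gaussian response) analytically through u on the d'
scale, method 3 (spatial, nonparametric) by the standard error of the
per-slice AUC mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import norm

from .fourier import DiskTaskSpectrum, NoisePowerSpectrum, TaskTransferFunction, dprime_fourier
from .spatial import DecisionSet, InternalNoiseModel, auc_empirical

__all__ = [
    "ObserverOutcome",
    "AfcResult",
    "Z_95",
    "auc_from_dprime",
    "dprime_from_auc",
    "dprime_rel_uncertainty",
    "auc_ci_method2",
    "auc_ci_from_dprime",
    "auc_sem_method3",
    "bootstrap_ci_fourier",
    "mafc_pc_to_auc",
]

Z_95 = 1.959964


@dataclass
class ObserverOutcome:
    """One observer result: method, d', AUC and its confidence interval."""

    method: str  # "fourier" | "spatial_gaussian" | "spatial_general"
    auc: float
    ci_low: float
    ci_high: float
    d_prime: float | None = None
    u_percent: float | None = None
    beta: float = 0.0
    n_repeats: int | None = None
    m_slices: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("CI must bracket the AUC point estimate")


@dataclass
class AfcResult:
    """Outcome of an M-alternative forced-choice experiment."""

    pc: float
    m_alternatives: int
    auc: float

    def __post_init__(self):
        if self.m_alternatives < 2:
            raise ValueError("need at least 2 alternatives")
        if not 0.0 < self.pc <= 1.0:
            raise ValueError("pc must be in (0, 1]")
        if self.pc < 1.0 / self.m_alternatives:
            warnings.warn(
                f"pc={self.pc} below chance (1/{self.m_alternatives})", stacklevel=2
            )


def auc_from_dprime(d_prime: float, beta: float = 0.0) -> float:
    """AUC under Gaussian independent responses with internal noise beta."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return float(norm.cdf(d_prime / np.sqrt(1.0 + beta) / np.sqrt(2.0)))


def dprime_from_auc(auc: float, beta: float = 0.0) -> float:
    """Exact inverse of :func:`auc_from_dprime`."""
    if not 0.0 < auc < 1.0:
        raise ValueError("auc must be in (0, 1)")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    return float(norm.ppf(auc) * np.sqrt(2.0 * (1.0 + beta)))


def dprime_rel_uncertainty(d_prime: float, n_repeats: int, m_slices: int) -> float:
    """Analytic one-sigma relative uncertainty of an ROI-based d' estimate, percent."""
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    if m_slices < 1:
        raise ValueError("m_slices must be >= 1")
    if d_prime <= 0:
        raise ValueError("d_prime must be > 0")
    n, m = n_repeats, m_slices
    return float(
        100.0 * np.sqrt(1.0 / (n * m * d_prime**2) + 0.25 / ((n - 1) * m))
    )


def auc_ci_method2(
    auc_point: float,
    beta: float,
    n_repeats: int,
    m_slices: int,
    level: float = 0.95,
) -> tuple[float, float]:
    """Analytic confidence interval for the spatial Gaussian-response AUC.

    The interval is built on the d' scale — d' from inverting the AUC,
    one sigma from the analytic relative uncertainty, a +/- z interval —
    and mapped back to the AUC scale.
    """
    d = dprime_from_auc(auc_point, beta)
    return auc_ci_from_dprime(d, beta, n_repeats, m_slices, level)


def auc_ci_from_dprime(
    d_prime: float,
    beta: float,
    n_repeats: int,
    m_slices: int,
    level: float = 0.95,
) -> tuple[float, float]:
    """Same analytic interval as :func:`auc_ci_method2`, but starting from
    d' itself — usable when the AUC point estimate saturates at 1."""
    z = float(norm.ppf(0.5 + level / 2.0))
    sigma_d = dprime_rel_uncertainty(d_prime, n_repeats, m_slices) / 100.0 * d_prime
    lo = auc_from_dprime(d_prime - z * sigma_d, beta)
    hi = auc_from_dprime(d_prime + z * sigma_d, beta)
    return lo, hi


def auc_sem_method3(
    decisions: DecisionSet,
    internal: InternalNoiseModel | None = None,
    level: float = 0.95,
) -> tuple[float, float, tuple[float, float]]:
    """Per-slice AUC mean and its standard error (spatial nonparametric route).

    The AUC is computed for each slice position from that slice's
    decision variables; the reported value is the mean across slices and
    the uncertainty its standard error.  Returns (auc, sem, (ci_low,
    ci_high)) with the CI clipped to [0, 1].
    """
    if decisions.slice_index is None:
        raise ValueError("decision set carries no slice labels")
    slices = np.unique(decisions.slice_index)
    if len(slices) < 2:
        raise ValueError(
            "need >= 2 slice positions; use the analytic d' uncertainty instead"
        )
    per_slice = []
    for s in slices:
        sub = DecisionSet(
            L_absent=decisions.L_absent[decisions.slice_index == s],
            L_present=decisions.L_present[decisions.slice_index == s],
        )
        per_slice.append(auc_empirical(sub, internal))
    per_slice = np.asarray(per_slice)
    auc = float(per_slice.mean())
    sem = float(per_slice.std(ddof=1) / np.sqrt(len(per_slice)))
    z = float(norm.ppf(0.5 + level / 2.0))
    ci = (max(0.0, auc - z * sem), min(1.0, auc + z * sem))
    return auc, sem, ci


def bootstrap_ci_fourier(
    ttf_replicates: np.ndarray,
    nps_replicates: np.ndarray,
    ttf_freq: np.ndarray,
    nps_freq: np.ndarray,
    task: DiskTaskSpectrum,
    beta: float,
    pixel_size: float,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the Fourier-domain AUC.

    Resamples the per-slice TTF curves and per-repeat NPS curves with
    replacement, recomputes the average curves, d' and AUC for each of
    ``n_boot`` resamples, and returns the percentile interval.
    """
    ttf_replicates = np.atleast_2d(np.asarray(ttf_replicates, dtype=float))
    nps_replicates = np.atleast_2d(np.asarray(nps_replicates, dtype=float))
    if ttf_replicates.shape[0] < 2 or nps_replicates.shape[0] < 2:
        raise ValueError("need >= 2 replicates of both TTF and NPS")
    if np.allclose(ttf_replicates.var(axis=0), 0) and np.allclose(
        nps_replicates.var(axis=0), 0
    ):
        # all replicates identical: zero-width interval
        t = TaskTransferFunction(ttf_freq, _renorm(ttf_replicates.mean(axis=0)))
        n = NoisePowerSpectrum(
            nps_freq, nps_replicates.mean(axis=0), pixel_size, n_rois=0
        )
        a = auc_from_dprime(dprime_fourier(n, t, task), beta)
        return a, a
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small for a percentile CI", stacklevel=2)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ti = rng.integers(0, ttf_replicates.shape[0], ttf_replicates.shape[0])
        ni = rng.integers(0, nps_replicates.shape[0], nps_replicates.shape[0])
        tv = _renorm(ttf_replicates[ti].mean(axis=0))
        nv = np.clip(nps_replicates[ni].mean(axis=0), 0.0, None)
        t = TaskTransferFunction(ttf_freq, tv)
        n = NoisePowerSpectrum(nps_freq, nv, pixel_size, n_rois=0)
        aucs[b] = auc_from_dprime(dprime_fourier(n, t, task), beta)
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(aucs, alpha)), float(np.quantile(aucs, 1.0 - alpha))


def _renorm(ttf_values: np.ndarray) -> np.ndarray:
    if ttf_values[0] <= 0:
        raise ValueError("degenerate TTF replicate (non-positive DC)")
    return ttf_values / ttf_values[0]


def mafc_pc_proportion(d_prime: float, m_alternatives: int) -> float:
    """Expected proportion correct in an M-AFC task at detectability d'.

    PC(d') = int phi(x - d') Phi(x)^(M-1) dx for Gaussian independent
    responses: the signal response must exceed all M-1 noise responses.
    """
    if m_alternatives == 2:
        return float(norm.cdf(d_prime / np.sqrt(2.0)))
    val, _ = quad(
        lambda x: norm.pdf(x - d_prime) * norm.cdf(x) ** (m_alternatives - 1),
        -8.0 + min(0.0, d_prime),
        8.0 + max(0.0, d_prime),
        epsabs=1e-10,
        epsrel=1e-10,
    )
    return float(val)


def mafc_pc_to_auc(pc: float, m_alternatives: int) -> float:
    """AUC from M-AFC percent correct under Gaussian independent responses.

    Solves PC(d') = pc for d' by bracketed root finding on the monotone
    Gaussian M-AFC psychometric function, then AUC = Phi(d'/sqrt(2)).
    For M = 2 the identity AUC = pc holds exactly.  Below-chance pc gives
    d' < 0 and AUC < 0.5 with a warning.
    """
    m = int(m_alternatives)
    if m < 2:
        raise ValueError("m_alternatives must be >= 2")
    if not 0.0 < pc < 1.0:
        raise ValueError("pc must be in (0, 1)")
    if m == 2:
        return float(pc)
    chance = 1.0 / m
    if abs(pc - chance) < 1e-12:
        return 0.5
    if pc < chance:
        warnings.warn("pc below chance: returning AUC < 0.5", stacklevel=2)
    d = brentq(lambda dd: mafc_pc_proportion(dd, m) - pc, -10.0, 15.0, xtol=1e-10)
    return float(norm.cdf(d / np.sqrt(2.0)))
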