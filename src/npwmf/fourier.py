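"""Fourier-domain nonprewhitening matched filter.

Under quasi-stationary noise and a shift-invariant transfer, the NPWMF
detectability index can be computed from three radial curves: the task
spectrum of the feature |dF(rho)| (analytic for a disk), the task
transfer function T(rho) measured from a circular edge, and the noise
power spectrum N(rho) measured from repeat-scan noise realisations:

    d'^2 = [ int |dF|^2 T^2 dnu ]^2  /  int |dF|^2 T^2 N dnu

with the 2-D frequency integrals evaluated as 1-D radial integrals with
2*pi*rho weighting.  This is the calculation route most commonly used in
CT quality assurance; it is exact only for stationary noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import j1

from .phantom import DiskFeature, ImageEnsemble

__all__ = [
    "NoisePowerSpectrum",
    "TaskTransferFunction",
    "DiskTaskSpectrum",
    "estimate_nps",
    "estimate_ttf",
    "disk_spectrum",
    "dprime_fourier",
    "background_roi_grid",
]


@dataclass
class NoisePowerSpectrum:
    """Radially binned 2-D NPS.

    ``values`` are in HU^2 mm^2 per radial-frequency bin (mm^-1);
    ``bin_counts`` are the number of 2-D frequency samples per bin, kept
    so the Parseval integral can be evaluated on the binned curve.
    """

    radial_freq: np.ndarray
    values: np.ndarray
    pixel_size: float
    n_rois: int
    bin_counts: np.ndarray | None = None
    df: float | None = None  # 2-D frequency sample spacing, mm^-1
    replicates: np.ndarray | None = None  # per-repeat radial curves

    def __post_init__(self):
        self.radial_freq = np.asarray(self.radial_freq, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("NPS values must be >= 0")

    def integral(self) -> float:
        """2-D integral of the NPS over frequency = pixel variance (Parseval)."""
        if self.bin_counts is None or self.df is None:
            raise ValueError("bin counts unavailable for this NPS")
        return float(np.sum(self.values * self.bin_counts) * self.df**2)

    def to_csv(self, path):
        pd.DataFrame(
            {"freq_mm^-1": self.radial_freq, "nps_hu2mm2": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, pixel_size: float):
        df = pd.read_csv(path)
        return cls(
            radial_freq=df.iloc[:, 0].to_numpy(),
            values=df.iloc[:, 1].to_numpy(),
            pixel_size=pixel_size,
            n_rois=0,
        )


@dataclass
class TaskTransferFunction:
    """Radial transfer function, normalised to 1 at zero frequency."""

    radial_freq: np.ndarray
    values: np.ndarray
    replicates: np.ndarray | None = None  # per-slice curves

    def __post_init__(self):
        self.radial_freq = np.asarray(self.radial_freq, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TTF contains non-finite values")
        if abs(self.values[0] - 1.0) > 1e-6:
            raise ValueError("TTF must equal 1 at zero frequency")

    def to_csv(self, path):
        pd.DataFrame({"freq_mm^-1": self.radial_freq, "ttf": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        return cls(
            radial_freq=df.iloc[:, 0].to_numpy(), values=df.iloc[:, 1].to_numpy()
        )


@dataclass
class DiskTaskSpectrum:
    """Analytic task spectrum of a uniform disk (jinc profile).

    dF(rho) = C * pi * (D/2)^2 * 2 J1(pi D rho) / (pi D rho), with the
    rho -> 0 limit C * pi * (D/2)^2.
    """

    contrast: float
    diameter: float

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")

    def __call__(self, rho) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        area = np.pi * (self.diameter / 2.0) ** 2
        x = np.pi * self.diameter * rho
        with np.errstate(invalid="ignore", divide="ignore"):
            jinc = np.where(x > 1e-12, 2.0 * j1(x) / np.where(x > 1e-12, x, 1.0), 1.0)
        return self.contrast * area * jinc


def disk_spectrum(feature: DiskFeature) -> DiskTaskSpectrum:
    """Analytic radial task spectrum for a disk feature."""
    return DiskTaskSpectrum(contrast=feature.contrast_hu, diameter=feature.diameter_mm)


def background_roi_grid(
    grid_shape: tuple[int, int],
    roi_size: int,
    exclusion_masks: list[np.ndarray] | None = None,
    overlap: float = 0.5,
) -> list[tuple[int, int]]:
    """Top-left corners of square NPS ROIs tiling the background.

    ROIs are laid on a grid with the given fractional overlap and dropped
    if they intersect any exclusion mask (feature ROIs).
    """
    step = max(1, int(roi_size * (1 - overlap)))
    excl = None
    free = None
    if exclusion_masks:
        excl = np.zeros(grid_shape, dtype=bool)
        for m in exclusion_masks:
            excl |= m
        # free[r, c] == True iff the roi_size square at (r, c) avoids excl
        csum = np.zeros((grid_shape[0] + 1, grid_shape[1] + 1))
        csum[1:, 1:] = np.cumsum(np.cumsum(excl, axis=0), axis=1)
        nr = grid_shape[0] - roi_size + 1
        nc = grid_shape[1] - roi_size + 1
        free = (
            csum[roi_size:, roi_size:]
            - csum[roi_size:, :nc]
            - csum[:nr, roi_size:]
            + csum[:nr, :nc]
        ) == 0
    # fine candidate scan, greedily thinned to the overlap step, so free
    # pockets that do not start at a multiple of the step are still found
    fine = max(1, step // 4)
    corners: list[tuple[int, int]] = []
    for r in range(0, grid_shape[0] - roi_size + 1, fine):
        for c in range(0, grid_shape[1] - roi_size + 1, fine):
            if free is not None and not free[r, c]:
                continue
            if any(max(abs(r - r0), abs(c - c0)) < step for r0, c0 in corners):
                continue
            corners.append((r, c))
    return corners


def estimate_nps(
    ensemble: ImageEnsemble,
    roi_size: int = 64,
    roi_corners: list[tuple[int, int]] | None = None,
    exclusion_masks: list[np.ndarray] | None = None,
    keep_replicates: bool = False,
    window: str = "hann",
) -> NoisePowerSpectrum:
    """Noise power spectrum from repeat-scan noise realisations.

    Noise realisations are each image minus the across-repeat mean of its
    slice, which removes the deterministic scene; the resulting variance
    deficit is undone by the n/(n-1) factor.  Each square ROI has its own
    mean removed, its windowed periodogram (dx*dy / sum(w^2)) |DFT(w*roi)|^2
    computed, and the ensemble-averaged 2-D NPS is binned radially with bin
    width 1/(roi_size * dx).  The default Hann taper suppresses the boxcar
    sidelobe leakage that otherwise fills in deep spectral minima of
    strongly coloured (e.g. ramp-shaped) noise; ``window="boxcar"`` gives
    the plain periodogram.
    """
    if ensemble.n_repeats < 2:
        raise ValueError("NPS estimation needs at least 2 repeats")
    if roi_corners is None:
        roi_corners = background_roi_grid(
            ensemble.grid_shape, roi_size, exclusion_masks
        )
    elif exclusion_masks:
        excl = np.zeros(ensemble.grid_shape, dtype=bool)
        for m in exclusion_masks:
            excl |= m
        for r, c in roi_corners:
            if excl[r : r + roi_size, c : c + roi_size].any():
                raise ValueError(f"NPS ROI at {(r, c)} touches a feature ROI")
    if not roi_corners:
        raise ValueError("no background ROIs available for NPS estimation")

    n, m = ensemble.n_repeats, ensemble.m_slices
    dx = ensemble.pixel_size
    noise = ensemble.pixels - ensemble.pixels.mean(axis=0, keepdims=True)
    bias = n / (n - 1)
    if window == "hann":
        w1 = np.hanning(roi_size)
        w2d = w1[:, None] * w1[None, :]
    elif window == "boxcar":
        w2d = np.ones((roi_size, roi_size))
    else:
        raise ValueError(f"unknown window {window!r}")
    wnorm = float(np.sum(w2d**2))

    fr = np.fft.fftfreq(roi_size, d=dx)
    rho = np.sqrt(fr[:, None] ** 2 + fr[None, :] ** 2)
    dfreq = 1.0 / (roi_size * dx)
    nbins = roi_size // 2 + 1
    bin_idx = np.minimum((rho / dfreq + 0.5).astype(int), nbins - 1)
    counts = np.bincount(bin_idx.ravel(), minlength=nbins)

    scale = dx * dx / wnorm
    per_repeat = np.zeros((n, nbins))
    n_rois = 0
    for i in range(n):
        acc2d = np.zeros((roi_size, roi_size))
        cnt = 0
        for j in range(m):
            for r, c in roi_corners:
                roi = noise[i, j, r : r + roi_size, c : c + roi_size]
                roi = (roi - roi.mean()) * w2d
                acc2d += np.abs(np.fft.fft2(roi)) ** 2
                cnt += 1
        acc2d *= scale * bias / cnt
        per_repeat[i] = np.bincount(
            bin_idx.ravel(), weights=acc2d.ravel(), minlength=nbins
        ) / counts
        n_rois += cnt
    # The DC bin is destroyed by per-ROI detrending and the first radial
    # bin is contaminated by the window mainlobe; both are replaced by a
    # linear extrapolation from the next bins (exact for flat spectra).
    if nbins >= 6:
        fit_idx = np.arange(2, 6)
        for curve in (*per_repeat, ):
            a, b = np.polyfit(fit_idx, curve[fit_idx], 1)
            curve[0] = max(b, 0.0)
            curve[1] = max(a + b, 0.0)
    radial = per_repeat.mean(axis=0)
    # report the occupancy-weighted mean frequency of each annular bin
    # (not the nominal centre): halves interpolation error for curved spectra
    fsum = np.bincount(bin_idx.ravel(), weights=rho.ravel(), minlength=nbins)
    freqs = fsum / counts
    freqs[0] = 0.0
    return NoisePowerSpectrum(
        radial_freq=freqs,
        values=radial,
        pixel_size=dx,
        n_rois=n_rois,
        bin_counts=counts,
        df=dfreq,
        replicates=per_repeat if keep_replicates else None,
    )


def _radial_edge_mtf(
    mean_img: np.ndarray,
    pixel_size: float,
    nominal_center_px: tuple[float, float],
    disk_radius_px: float,
    bin_width_px: float,
) -> tuple[np.ndarray, np.ndarray]:
    """MTF from the radial edge-spread function of one disk image."""
    nr, nc = mean_img.shape
    r_max = disk_radius_px * 2.5
    # intensity-weighted centroid of the thresholded disk
    rows = np.arange(nr)[:, None]
    cols = np.arange(nc)[None, :]
    d2 = (rows - nominal_center_px[0]) ** 2 + (cols - nominal_center_px[1]) ** 2
    near = d2 <= (disk_radius_px * 1.5) ** 2
    local = mean_img.copy()
    bg = np.median(local[(d2 > (disk_radius_px * 1.8) ** 2) & (d2 < r_max**2)])
    local = local - bg
    peak = local[d2 <= (disk_radius_px * 0.5) ** 2].mean()
    thresh = near & (np.sign(peak) * local > abs(peak) / 2)
    w = np.abs(local[thresh])
    cr = float((rows * np.ones_like(cols) * 1.0)[thresh] @ w / w.sum())
    cc = float((np.ones_like(rows) * cols * 1.0)[thresh] @ w / w.sum())

    # subpixel radial binning of the edge-spread function
    rr = np.sqrt((rows - cr) ** 2 + (cols - cc) ** 2)
    sel = rr <= r_max
    r = rr[sel].ravel()
    v = (mean_img - bg)[sel].ravel()
    nb = int(np.ceil(r_max / bin_width_px))
    idx = np.minimum((r / bin_width_px).astype(int), nb - 1)
    sums = np.bincount(idx, weights=v, minlength=nb)
    cnts = np.bincount(idx, minlength=nb)
    centers = (np.arange(nb) + 0.5) * bin_width_px
    filled = cnts > 0
    esf = np.interp(centers, centers[filled], sums[filled] / cnts[filled])

    # LSF = -dESF/dr, windowed about the edge
    lsf = -np.gradient(esf, centers)
    if peak < 0:
        lsf = -lsf
    edge_pos = centers[np.argmax(lsf)]
    win = np.hanning(2 * nb + 1)
    widx = np.clip(
        ((centers - edge_pos) / r_max * nb + nb).astype(int), 0, 2 * nb
    )
    lsf = lsf * win[widx]

    h = bin_width_px * pixel_size  # mm
    nyq = 1.0 / (2.0 * pixel_size)
    freqs = np.linspace(0.0, nyq, 128)
    rad = centers * pixel_size
    # modulus of the continuous FT (edge position shifts only the phase)
    kern = np.exp(-2j * np.pi * freqs[:, None] * rad[None, :])
    mtf = np.abs(np.trapezoid(lsf[None, :] * kern, dx=h, axis=1))
    if mtf[0] <= 0:
        raise ValueError("degenerate edge: zero area under the LSF")
    mtf = mtf / mtf[0]
    return freqs, mtf


def estimate_ttf(
    ensemble: ImageEnsemble,
    feature: DiskFeature,
    center_mm: tuple[float, float] | None = None,
    bin_width_px: float = 0.1,
    min_cnr: float = 15.0,
    keep_replicates: bool = False,
) -> TaskTransferFunction:
    """Task transfer function from the circular edge of a disk feature.

    Uses the across-repeat mean image: the radial edge-spread function
    about the disk centre (subpixel radial binning), differentiated to a
    line-spread function, windowed, and Fourier-transformed; normalised
    to 1 at zero frequency.  Beyond the first zero crossing the curve is
    truncated to a monotone noise floor of zero.
    """
    dx = ensemble.pixel_size
    radius_px = (feature.diameter_mm / 2.0) / dx
    if 2 * radius_px < 15:
        raise ValueError(
            "disk too small for circular-edge analysis (needs >= ~15 px diameter)"
        )
    if center_mm is None:
        center_mm = feature.center_mm
    center_px = (center_mm[0] / dx, center_mm[1] / dx)

    mean_all = ensemble.mean_image()
    n_eff = ensemble.n_repeats * ensemble.m_slices
    sigma_mean = (
        ensemble.pixels.std(axis=(0, 1)).mean() / np.sqrt(n_eff)
    )
    cnr = abs(feature.contrast_hu) / max(sigma_mean, 1e-12)
    if cnr < min_cnr:
        raise ValueError(
            f"contrast-to-noise of the mean image ({cnr:.1f}) below {min_cnr}; "
            "acquire more repeats for a reliable TTF"
        )

    def one_mtf(img):
        f, v = _radial_edge_mtf(img, dx, center_px, radius_px, bin_width_px)
        # monotone noise-floor truncation beyond the first zero crossing
        zero = np.argmax(v <= 0) if np.any(v <= 0) else len(v)
        v = v.copy()
        v[zero:] = 0.0
        return f, v

    freqs, values = one_mtf(mean_all)
    reps = None
    if keep_replicates:
        reps = np.array(
            [one_mtf(ensemble.mean_image(j))[1] for j in range(ensemble.m_slices)]
        )
    return TaskTransferFunction(radial_freq=freqs, values=values, replicates=reps)


def dprime_fourier(
    nps: NoisePowerSpectrum,
    ttf: TaskTransferFunction,
    task: DiskTaskSpectrum,
    n_grid: int = 2048,
) -> float:
    """Detectability index from the radial NPS, TTF, and task spectrum.

    Integrates d'^2 = [int |dF|^2 T^2 dnu]^2 / int |dF|^2 T^2 N dnu as
    1-D radial trapezoids with 2*pi*rho weighting on a common grid up to
    the Nyquist frequency of the coarser input; the TTF is interpolated
    linearly (zero outside its support) and the NPS with edge-value
    extension.
    """
    fmax = min(nps.radial_freq[-1], ttf.radial_freq[-1])
    if fmax <= 0:
        raise ValueError("frequency supports do not overlap")
    rho = np.linspace(0.0, fmax, n_grid)
    t = np.interp(rho, ttf.radial_freq, ttf.values, left=ttf.values[0], right=0.0)
    npsv = np.interp(
        rho, nps.radial_freq, nps.values, left=nps.values[0], right=nps.values[-1]
    )
    f2t2 = task(rho) ** 2 * t**2 * 2 * np.pi * rho
    num = np.trapezoid(f2t2, rho) ** 2
    den = np.trapezoid(f2t2 * npsv, rho)
    if den <= 0:
        raise ValueError("non-positive noise integral; NPS degenerate")
    return float(np.sqrt(num / den))
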