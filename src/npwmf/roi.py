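"""Region-of-interest placement and background-corrected sample extraction.

The spatial-domain observer operates on pixel vectors drawn from a
feature-present ROI and an identically shaped feature-absent ROI.  The
feature ROI is the feature's physical radius (in pixels) expanded by
``n_exp`` pixels; the local background is the mean of an annulus
``n_ann`` pixels wide starting ``n_gap`` pixels beyond the ROI, averaged
over all repeat scans.  Annulus pixels falling inside a neighbouring
feature's ROI are excluded.  Coordinates are 0-based (row, col) with
pixel centres at integer positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import DiskFeature, ImageEnsemble, PhantomSpec

__all__ = [
    "RoiGeometry",
    "RoiSamples",
    "circle_mask",
    "place_rois",
    "extract_samples",
    "read_layout",
]


def circle_mask(
    center: tuple[float, float], radius: float, grid_shape: tuple[int, int]
) -> np.ndarray:
    """Boolean mask of pixels whose centres lie within ``radius`` of ``center``.

    Distances are Euclidean in pixel units; the boundary is inclusive, so
    an integer centre with radius 2 selects the 13 lattice points with
    r^2 + c^2 <= 4.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    rows = np.arange(grid_shape[0])[:, None] - center[0]
    cols = np.arange(grid_shape[1])[None, :] - center[1]
    mask = rows**2 + cols**2 <= radius**2 + 1e-9
    if not mask.any():
        raise ValueError(f"circle mask at {center} radius {radius} is empty")
    return mask


@dataclass
class RoiGeometry:
    """Present/absent ROI masks and the background annuli for one feature.

    ``excluded_pixels`` records annulus pixels removed because they
    overlapped a neighbouring feature's ROI (already absent from
    ``annulus_mask``).
    """

    feature: DiskFeature
    feature_center_px: tuple[float, float]
    roi_radius_px: float
    gap_px: float
    annulus_px: float
    absent_center_px: tuple[float, float]
    roi_mask: np.ndarray
    annulus_mask: np.ndarray
    absent_roi_mask: np.ndarray
    absent_annulus_mask: np.ndarray
    excluded_pixels: set = field(default_factory=set)

    def __post_init__(self):
        if (self.roi_mask & self.annulus_mask).any():
            raise ValueError("feature ROI and annulus overlap")
        if self.roi_mask.sum() != self.absent_roi_mask.sum():
            raise ValueError("present and absent ROIs differ in pixel count")

    @property
    def n_pixels(self) -> int:
        return int(self.roi_mask.sum())


def _annulus(center, r_in, r_out, grid_shape):
    outer = circle_mask(center, r_out, grid_shape)
    inner = circle_mask(center, r_in, grid_shape)
    return outer & ~inner


def place_rois(
    layout,
    pixel_size: float,
    grid_shape: tuple[int, int],
    n_exp: int = 4,
    n_ann: int = 4,
    n_gap: int = 4,
    absent_rule: str | list[tuple[float, float]] = "mirror",
) -> list[RoiGeometry]:
    """Build ROI geometry for every feature in a layout table.

    ``layout`` is a DataFrame (or path handled by :func:`read_layout`)
    with columns center_row_mm, center_col_mm, diameter_mm, contrast_hu.
    The ROI radius is the feature's physical radius in pixels (not
    rounded) plus ``n_exp``.  ``absent_rule`` is ``"mirror"`` (left-right
    mirror about the vertical midline) or an explicit list of absent-ROI
    centres in mm, one per feature.
    """
    if min(n_exp, n_ann, n_gap) < 0:
        raise ValueError("n_exp, n_ann, n_gap must be >= 0")
    if n_ann == 0:
        raise ValueError("annulus width must be positive")
    layout = layout.reset_index(drop=True)
    centers_px = [
        (row.center_row_mm / pixel_size, row.center_col_mm / pixel_size)
        for row in layout.itertuples()
    ]
    roi_radii = [
        (row.diameter_mm / 2.0) / pixel_size + n_exp for row in layout.itertuples()
    ]
    if absent_rule == "mirror":
        absent_px = [(r, grid_shape[1] - 1 - c) for r, c in centers_px]
    else:
        if len(absent_rule) != len(layout):
            raise ValueError("need one absent-ROI centre per feature")
        absent_px = [(r / pixel_size, c / pixel_size) for r, c in absent_rule]

    all_roi_masks = [
        circle_mask(c, rad, grid_shape) for c, rad in zip(centers_px, roi_radii)
    ]
    geoms = []
    for k, row in enumerate(layout.itertuples()):
        feat = DiskFeature(
            center_mm=(row.center_row_mm, row.center_col_mm),
            diameter_mm=row.diameter_mm,
            contrast_hu=row.contrast_hu,
        )
        r_roi = roi_radii[k]
        ann = _annulus(centers_px[k], r_roi + n_gap, r_roi + n_gap + n_ann, grid_shape)
        abs_ann = _annulus(
            absent_px[k], r_roi + n_gap, r_roi + n_gap + n_ann, grid_shape
        )
        excluded = set()
        for j, other in enumerate(all_roi_masks):
            if j == k:
                continue
            clash = ann & other
            if clash.any():
                excluded.update(map(tuple, np.argwhere(clash)))
                ann &= ~other
            abs_ann &= ~other
        if not ann.any():
            raise ValueError(
                f"annulus of feature {k} fully excluded by neighbouring ROIs"
            )
        absent_mask = circle_mask(absent_px[k], r_roi, grid_shape)
        for j, other in enumerate(all_roi_masks):
            if (absent_mask & other).any():
                raise ValueError(
                    f"absent ROI of feature {k} overlaps feature ROI {j}; "
                    "supply explicit absent-ROI centres"
                )
        geoms.append(
            RoiGeometry(
                feature=feat,
                feature_center_px=centers_px[k],
                roi_radius_px=r_roi,
                gap_px=n_gap,
                annulus_px=n_ann,
                absent_center_px=absent_px[k],
                roi_mask=all_roi_masks[k],
                annulus_mask=ann,
                absent_roi_mask=absent_mask,
                absent_annulus_mask=abs_ann,
                excluded_pixels=excluded,
            )
        )
    return geoms


def layout_from_spec(spec: PhantomSpec) -> pd.DataFrame:
    """Layout table for a simulated phantom (one row per disk feature)."""
    return pd.DataFrame(
        {
            "center_row_mm": [f.center_mm[0] for f in spec.features],
            "center_col_mm": [f.center_mm[1] for f in spec.features],
            "diameter_mm": [f.diameter_mm for f in spec.features],
            "contrast_hu": [f.contrast_hu for f in spec.features],
        }
    )


def read_layout(path) -> pd.DataFrame:
    """Read a feature layout CSV.

    Accepts either (center_row_mm, center_col_mm) or image-frame
    (center_x_mm = column, center_y_mm = row) coordinate columns, plus
    diameter_mm and contrast_hu.
    """
    layout = pd.read_csv(path)
    if "center_x_mm" in layout.columns:
        layout = layout.rename(
            columns={"center_y_mm": "center_row_mm", "center_x_mm": "center_col_mm"}
        )
    required = {"center_row_mm", "center_col_mm", "diameter_mm", "contrast_hu"}
    missing = required - set(layout.columns)
    if missing:
        raise ValueError(f"layout file missing columns: {sorted(missing)}")
    return layout


@dataclass
class RoiSamples:
    """Background-subtracted pixel vectors for one feature.

    ``present`` and ``absent`` are (n_repeats * m_slices, p) matrices in
    repeat-major order; ``slice_index`` labels each row with its slice.
    """

    present: np.ndarray
    absent: np.ndarray
    slice_index: np.ndarray
    geometry: RoiGeometry

    def __post_init__(self):
        if self.present.shape != self.absent.shape:
            raise ValueError("present/absent sample matrices differ in shape")
        if len(self.slice_index) != self.present.shape[0]:
            raise ValueError("slice_index length mismatch")


def extract_samples(ensemble: ImageEnsemble, geom: RoiGeometry) -> RoiSamples:
    """Extract background-corrected present/absent vectors for every image.

    The background of each ROI is the mean over its annulus pixels,
    averaged over all repeat scans, computed per slice position, so
    slice-to-slice level differences are removed but per-image noise in
    the background estimate is suppressed by the repeat average.
    """
    px = ensemble.pixels
    if not np.all(np.isfinite(px)):
        bad = np.argwhere(~np.isfinite(px).all(axis=(2, 3)))[0]
        raise ValueError(f"non-finite pixels in repeat {bad[0]}, slice {bad[1]}")
    n, m = ensemble.n_repeats, ensemble.m_slices
    # (n, m, p) stacks of ROI pixels
    pres = px[:, :, geom.roi_mask]
    absn = px[:, :, geom.absent_roi_mask]
    # per-slice backgrounds, averaged over repeats: shape (m,)
    bg_pres = px[:, :, geom.annulus_mask].mean(axis=(0, 2))
    bg_absn = px[:, :, geom.absent_annulus_mask].mean(axis=(0, 2))
    pres = pres - bg_pres[None, :, None]
    absn = absn - bg_absn[None, :, None]
    slice_index = np.tile(np.arange(m), n)
    return RoiSamples(
        present=pres.reshape(n * m, -1),
        absent=absn.reshape(n * m, -1),
        slice_index=slice_index,
        geometry=geom,
    )
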