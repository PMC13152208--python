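"""Reading and writing image ensembles.

Ensembles travel as multi-page TIFF stacks (pages ordered repeat-major)
with a plain-text sidecar carrying pixel size and stack dimensions, or
are assembled from a directory of DICOM slices with pixel spacing and
rescale slope/intercept honoured.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .phantom import ImageEnsemble

__all__ = ["write_ensemble", "read_ensemble", "read_dicom_series"]

_SIDECAR_SUFFIX = ".meta.txt"


def write_ensemble(ensemble: ImageEnsemble, path) -> Path:
    """Write a multi-page TIFF plus a key-value sidecar next to it."""
    path = Path(path)
    n, m = ensemble.n_repeats, ensemble.m_slices
    pages = ensemble.pixels.reshape(n * m, *ensemble.grid_shape).astype(np.float32)
    tifffile.imwrite(path, pages)
    meta = {
        "pixel_size_mm": ensemble.pixel_size,
        "n_repeats": n,
        "m_slices": m,
        **{k: v for k, v in ensemble.provenance.items() if np.isscalar(v)},
    }
    sidecar = path.with_suffix(path.suffix + _SIDECAR_SUFFIX)
    sidecar.write_text("".join(f"{k}: {v}\n" for k, v in meta.items()))
    return path


def read_ensemble(path) -> ImageEnsemble:
    """Read an ensemble written by :func:`write_ensemble`."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + _SIDECAR_SUFFIX)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {sidecar}")
    meta = {}
    for line in sidecar.read_text().splitlines():
        if ":" in line:
            k, v = line.split(":", 1)
            meta[k.strip()] = v.strip()
    pages = tifffile.imread(path).astype(float)
    n = int(meta["n_repeats"])
    m = int(meta["m_slices"])
    if pages.shape[0] != n * m:
        raise ValueError(
            f"TIFF has {pages.shape[0]} pages but sidecar says {n} x {m}"
        )
    return ImageEnsemble(
        pixels=pages.reshape(n, m, *pages.shape[1:]),
        pixel_size=float(meta["pixel_size_mm"]),
        provenance={k: v for k, v in meta.items() if k not in
                    ("pixel_size_mm", "n_repeats", "m_slices")},
    )


def read_dicom_series(directory, n_repeats: int, m_slices: int) -> ImageEnsemble:
    """Assemble an ensemble from a directory of DICOM files.

    Files are sorted by (AcquisitionNumber, InstanceNumber) and reshaped
    repeat-major; pixel values are converted to HU via RescaleSlope and
    RescaleIntercept, and PixelSpacing provides the pixel size.
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files in {directory}")
    if len(files) != n_repeats * m_slices:
        raise ValueError(
            f"{len(files)} DICOM files cannot form {n_repeats} x {m_slices}"
        )
    datasets = [pydicom.dcmread(f) for f in files]
    datasets.sort(
        key=lambda d: (
            int(getattr(d, "AcquisitionNumber", 0) or 0),
            int(getattr(d, "InstanceNumber", 0) or 0),
        )
    )
    spacing = [float(s) for s in datasets[0].PixelSpacing]
    if abs(spacing[0] - spacing[1]) > 1e-6:
        raise ValueError("anisotropic pixel spacing is not supported")
    stack = []
    for d in datasets:
        slope = float(getattr(d, "RescaleSlope", 1.0))
        intercept = float(getattr(d, "RescaleIntercept", 0.0))
        stack.append(d.pixel_array.astype(float) * slope + intercept)
    pixels = np.stack(stack).reshape(n_repeats, m_slices, *stack[0].shape)
    return ImageEnsemble(
        pixels=pixels, pixel_size=spacing[0], provenance={"source": str(directory)}
    )
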