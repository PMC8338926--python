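"""Binary vessel masking by global Otsu thresholding.

The angiogram (or the vesselness response) is reduced to a binary vessel
map with a single global threshold chosen to minimize the intra-class
intensity variance — equivalently, to maximize the between-class variance
of the histogram split. A global criterion adapts to the per-scan noise
floor, unlike a fixed threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hessian import VesselnessResult
from .image import ScalarImage2D

__all__ = ["BinaryMask", "otsu_threshold", "make_vessel_mask"]

MASK_MODES = ("intensity", "vesselness", "and")


@dataclass(frozen=True)
class BinaryMask:
    """Boolean vessel map plus the threshold(s) that produced it."""

    pixels: np.ndarray
    threshold_used: float | tuple[float, float]
    mode: str = "intensity"

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def otsu_threshold(values: ScalarImage2D | np.ndarray, n_bins: int = 256) -> float:
    """Otsu's global threshold over an ``n_bins`` histogram of the data.

    Candidate thresholds are the interior bin edges; the edge maximizing
    the between-class variance (ties broken toward the lower threshold) is
    returned. Pixels strictly above the threshold are foreground.

    Raises
    ------
    ValueError
        If the input has fewer than two distinct values (no split exists).
    """
    v = values.pixels if isinstance(values, ScalarImage2D) else np.asarray(values, dtype=np.float64)
    v = v.ravel()
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise ValueError("degenerate input: constant image has no Otsu threshold")
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    counts = counts.astype(np.float64)
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(counts)                     # pixels in bins 0..k
    total = w0[-1]
    m0 = np.cumsum(counts * centers)           # cumulative first moment
    mtot = m0[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mtot - m0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.where((w0 > 0) & (w1 > 0), between, -np.inf)
    k = int(np.argmax(between[:-1]))           # split after bin k; argmax takes lowest tie
    return float(edges[k + 1])


def make_vessel_mask(image: ScalarImage2D, vesselness: VesselnessResult | None = None,
                     mode: str = "and", n_bins: int = 256) -> BinaryMask:
    """Threshold the scan into a binary vessel map.

    mode "intensity": Otsu on the raw image. mode "vesselness": Otsu on
    the filter response ρ. mode "and" (default): conjunction of both —
    a pixel is vessel only if it is bright *and* tube-like.
    """
    if mode not in MASK_MODES:
        raise ValueError(f"mode must be one of {MASK_MODES}")
    if mode in ("vesselness", "and"):
        if vesselness is None:
            raise ValueError(f"mode {mode!r} requires a vesselness result")
        if vesselness.shape != image.shape:
            raise ValueError(f"shape mismatch: image {image.shape} vs vesselness {vesselness.shape}")

    if mode == "intensity":
        t = otsu_threshold(image, n_bins)
        return BinaryMask(image.pixels > t, t, mode)
    if mode == "vesselness":
        t = otsu_threshold(vesselness.rho, n_bins)
        return BinaryMask(vesselness.rho > t, t, mode)
    ti = otsu_threshold(image, n_bins)
    tv = otsu_threshold(vesselness.rho, n_bins)
    return BinaryMask((image.pixels > ti) & (vesselness.rho > tv), (ti, tv), mode)
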