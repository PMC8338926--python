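"""Core in-memory image container shared by every processing stage.

Images are stored row-major (row index increases downward) but all angles
reported by this package follow the display convention: degrees measured
counter-clockwise from the +x (rightward) axis with y pointing up, folded
axially into [0°, 180°).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScalarImage2D", "fold_axial", "axial_distance"]

MIN_SIDE = 16


@dataclass(frozen=True)
class ScalarImage2D:
    """A single-channel image with intensities normalized to [0, 1].

    Parameters
    ----------
    pixels
        2-D float array of intensities in [0, 1].
    px_per_mm
        Pixel pitch of the acquisition (pixels per millimetre). Optional:
        only geometry-aware stages (disk ROI construction) require it.
        A 6 mm scan sampled at 512 positions gives 512/6 ≈ 85.33 px/mm.
    """

    pixels: np.ndarray
    px_per_mm: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D array, got ndim={px.ndim}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise ValueError(f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        if self.px_per_mm is not None and not self.px_per_mm > 0:
            raise ValueError("px_per_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def fold_axial(theta_deg: np.ndarray | float) -> np.ndarray | float:
    """Fold angles (degrees) into the axial range [0, 180).

    Head-tail symmetric data identify θ with θ+180°.
    """
    return np.mod(theta_deg, 180.0)


def axial_distance(a_deg, b_deg):
    """Axial angular distance in degrees: min(|a−b|, 180−|a−b|), in [0, 90]."""
    d = np.abs(np.mod(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float), 180.0))
    return np.minimum(d, 180.0 - d)
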