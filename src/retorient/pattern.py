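"""Orientation-distribution ("rose plot") metrics for a region of interest.

For every vessel pixel inside an ROI the axial orientation θ ∈ [0°, 180°)
contributes to an angular histogram over [0°, 360°) at both θ and θ+180°
(vessel direction is head–tail symmetric). Plotted as a polar curve with
radius = pixel count per bin, the distribution traces a roughly elliptical
shape summarized by three metrics:

* preferred orientation — angle of the major axis of the moment-equivalent
  ellipse of the filled curve, in [0°, 180°);
* vessel anisotropy — major/minor axis-length ratio (1 = isotropic);
* vessel area — area (pixel²) enclosed by the closed curve, computed by
  the shoelace formula on the 360/bin_width-vertex polygon.

Vessel density (vessel-pixel fraction of the ROI) is computed alongside as
the conventional reference metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .image import fold_axial
from .mask import BinaryMask

__all__ = [
    "OrientationDistribution",
    "PatternMetrics",
    "orientation_histogram",
    "pattern_metrics",
    "vessel_density",
    "polygon_vertices",
]

# relative area below which the polygon is treated as degenerate (all mass
# on one axis) and metrics fall back to point-mass moments
_DEGENERATE_AREA_RTOL = 1e-9
# relative eigenvalue gap below which the distribution is isotropic and the
# preferred orientation is undefined
_ISO_RTOL = 1e-9


@dataclass(frozen=True)
class OrientationDistribution:
    """Axially symmetric angular histogram of vessel-pixel orientations.

    counts[k] is the number of vessel pixels in bin
    [k·bin_width, (k+1)·bin_width); counts[k] == counts[k + 180°/bin_width]
    exactly by head–tail duplication. ``empty`` flags a distribution built
    from an empty mask∩sector.
    """

    bin_width: float
    counts: np.ndarray
    empty: bool = False

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def n_pixels(self) -> int:
        """Number of contributing pixels (half the histogram mass)."""
        return int(self.counts.sum()) // 2

    def bin_angles(self) -> np.ndarray:
        """Left edge of each bin, degrees."""
        return self.bin_width * np.arange(self.n_bins)


@dataclass(frozen=True)
class PatternMetrics:
    """Summary of one ROI's orientation pattern.

    ``preferred_orientation_deg`` is NaN for an exactly isotropic
    distribution; ``anisotropy`` is ≥ 1 (inf when all mass lies on a single
    axis); ``vessel_density`` is filled by the caller that knows the ROI.
    """

    preferred_orientation_deg: float
    anisotropy: float
    vessel_area_px2: float
    vessel_density: float = float("nan")

    def with_density(self, density: float) -> "PatternMetrics":
        return replace(self, vessel_density=density)


def orientation_histogram(theta0: np.ndarray, mask: BinaryMask | np.ndarray,
                          sector: np.ndarray | None = None,
                          bin_width: float = 1.0) -> OrientationDistribution:
    """Histogram masked in-sector orientations over [0°, 360°).

    Each pixel with a defined (finite) orientation θ increments the bins
    containing θ and θ+180°, so the total mass is twice the number of
    contributing pixels. ``bin_width`` must divide 180.
    """
    n_half = 180.0 / bin_width
    if abs(n_half - round(n_half)) > 1e-9:
        raise ValueError("bin_width must divide 180")
    m = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if m.shape != theta0.shape:
        raise ValueError(f"shape mismatch: theta {theta0.shape} vs mask {m.shape}")
    if sector is not None:
        if sector.shape != theta0.shape:
            raise ValueError(f"shape mismatch: theta {theta0.shape} vs sector {sector.shape}")
        m = m & sector

    n_bins = 2 * int(round(n_half))
    theta = fold_axial(theta0[m & np.isfinite(theta0)])
    idx = np.floor_divide(theta, bin_width).astype(int) % (n_bins // 2)
    counts = np.bincount(idx, minlength=n_bins // 2).astype(np.int64)
    counts = np.concatenate([counts, counts])  # head–tail duplication
    if counts.sum() == 0:
        warnings.warn("empty mask∩sector: all-zero orientation distribution", stacklevel=2)
        return OrientationDistribution(bin_width, counts, empty=True)
    return OrientationDistribution(bin_width, counts)


def polygon_vertices(dist: OrientationDistribution) -> np.ndarray:
    """Cartesian vertices (n_bins, 2) of the closed polar curve r(θk) = counts[k]."""
    ang = np.radians(dist.bin_angles())
    r = dist.counts.astype(np.float64)
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def _polygon_moments(v: np.ndarray) -> tuple[float, float, float, float]:
    """Signed area and origin-referenced second moments of a closed polygon.

    Green's-theorem formulas; vertices need not be closed explicitly.
    Returns (area, ∫x²dA, ∫xy dA, ∫y²dA), all signed consistently.
    """
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    mxx = (cross * (x * x + x * x1 + x1 * x1)).sum() / 12.0
    myy = (cross * (y * y + y * y1 + y1 * y1)).sum() / 12.0
    mxy = (cross * (x * y1 + 2.0 * x * y + 2.0 * x1 * y1 + x1 * y)).sum() / 24.0
    return area, mxx, mxy, myy


def _axes_from_cov(cov: np.ndarray) -> tuple[float, float]:
    """(preferred angle deg in [0,180) or NaN, anisotropy ≥ 1) from a 2×2 covariance."""
    a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
    m = 0.5 * (a + c)
    r = float(np.hypot(0.5 * (a - c), b))
    lam_max, lam_min = m + r, m - r
    if r <= _ISO_RTOL * max(lam_max, 1e-300):
        return float("nan"), 1.0
    angle = fold_axial(0.5 * np.degrees(np.arctan2(2.0 * b, a - c)))
    aniso = float(np.sqrt(lam_max / lam_min)) if lam_min > 0 else float("inf")
    return float(angle), aniso


def pattern_metrics(dist: OrientationDistribution) -> PatternMetrics:
    """Preferred orientation, anisotropy and enclosed area of the rose curve.

    The closed polygon of the polar curve is filled; its second central
    moments define the moment-equivalent ellipse whose major-axis angle is
    the preferred orientation and whose axis-length ratio is the
    anisotropy. The enclosed area (pixel²) comes from the shoelace formula.
    Distributions whose mass lies entirely on one axis have zero enclosed
    area; the axis direction is then taken from point-mass moments of the
    vertices and the anisotropy is infinite.
    """
    counts = dist.counts
    if counts.sum() == 0:
        raise ValueError("undefined metrics: all-zero orientation distribution")
    v = polygon_vertices(dist)
    area, mxx, mxy, myy = _polygon_moments(v)
    scale = float(counts.max()) ** 2
    if abs(area) > _DEGENERATE_AREA_RTOL * scale:
        # axial symmetry makes the polygon centrally symmetric -> centroid at
        # the origin; normalize the signed moments into a covariance
        cov = np.array([[mxx, mxy], [mxy, myy]]) / area
        angle, aniso = _axes_from_cov(cov)
        return PatternMetrics(angle, aniso, abs(area))
    # degenerate: collinear spike — use point masses at the vertices
    w = counts.astype(np.float64)
    cov = (v.T * w) @ v / w.sum()
    angle, _ = _axes_from_cov(cov)
    return PatternMetrics(angle, float("inf"), 0.0)


def vessel_density(mask: BinaryMask | np.ndarray, sector: np.ndarray) -> float:
    """Vessel-pixel fraction of the ROI: |mask ∩ sector| / |sector|."""
    m = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if m.shape != sector.shape:
        raise ValueError(f"shape mismatch: mask {m.shape} vs sector {sector.shape}")
    n_sector = int(sector.sum())
    if n_sector == 0:
        raise ValueError("empty sector has no vessel density")
    return float((m & sector).sum()) / n_sector
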