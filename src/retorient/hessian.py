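"""Gaussian scale-space Hessian analysis and the multiscale vesselness filter.

The filter follows the classic Hessian-eigenvalue recipe for enhancing
tubular structures in angiography: at each scale σ the image is convolved
with second-derivative-of-Gaussian kernels, the 2×2 Hessian is
eigen-decomposed per pixel, and a response

    ρ(t, σ) = exp(−R²/2β²) · (1 − exp(−S²/2γ²))

combines the line-similarity ratio R = |λ1|/|λ2| with the structure-ness
S = sqrt(λ1² + λ2²). The response is maximized over a scale grid; the
winning scale σ0 estimates the local vessel width and the eigenvector of
the smallest-magnitude eigenvalue at σ0 gives the local vessel orientation.

Scale normalization: derivatives are multiplied by σ^(2·ridge_norm_gamma).
The default exponent 0.75 is the γ-normalization for ridge detection; it
makes the selected scale equal the Gaussian half-width s of an ideal tube
profile (with exponent 1.0 the argmax sits at √2·s instead).

Coordinate/angle convention: images are stored row-major with the row index
increasing downward, but all angles are reported in display coordinates
(counter-clockwise from +x, y up), folded axially into [0°, 180°).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import ScalarImage2D, fold_axial

__all__ = [
    "FilterParams",
    "HessianField",
    "EigenField",
    "VesselnessResult",
    "make_gaussian_kernel",
    "hessian_at_scale",
    "eigen_field",
    "vesselness_at_scale",
    "multiscale_vesselness",
]

BRIGHT = "bright-on-dark"
DARK = "dark-on-bright"

# Relative tolerance used to flag |λ1| ≈ |λ2| ties, where the orientation of
# the local structure is meaningless (isotropic point).
_TIE_RTOL = 1e-9

_MIN_SIGMA = 0.5  # below this the sampled derivative kernels alias


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the multiscale vesselness filter.

    Attributes
    ----------
    sigma_min, sigma_max, sigma_step
        Scale grid in pixels: σ = sigma_min, sigma_min+step, … ≤ sigma_max.
        The grid should bracket the Gaussian half-width of the vessels of
        interest (capillaries ≈ 1 px, arterioles/venules ≈ 3–4 px at
        ~85 px/mm).
    beta
        Suppression index of the line-similarity term R (unitless).
    gamma
        Suppression index of the structure-ness term S, or "auto" to use
        half the maximum Frobenius norm of the scale-normalized Hessian
        over the image and the whole scale grid.
    polarity
        "bright-on-dark" (vessels brighter than background; requires
        λ2 < 0) or "dark-on-bright" (λ2 > 0).
    ridge_norm_gamma
        Exponent of the scale normalization σ^(2·ridge_norm_gamma) applied
        to the second derivatives. 0.75 calibrates scale selection so that
        σ0 equals the tube half-width s.
    truncate
        Kernel support radius in units of σ.
    """

    sigma_min: float = 1.0
    sigma_max: float = 4.0
    sigma_step: float = 0.5
    beta: float = 0.5
    gamma: float | str = "auto"
    polarity: str = BRIGHT
    ridge_norm_gamma: float = 0.75
    truncate: float = 4.0

    def __post_init__(self) -> None:
        if not (self.sigma_min > 0 and self.sigma_max > 0 and self.sigma_step > 0):
            raise ValueError("sigma_min, sigma_max and sigma_step must be positive")
        if self.sigma_min > self.sigma_max:
            raise ValueError("sigma_min must not exceed sigma_max")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.gamma != "auto" and not (isinstance(self.gamma, (int, float)) and self.gamma > 0):
            raise ValueError('gamma must be positive or "auto"')
        if self.polarity not in (BRIGHT, DARK):
            raise ValueError(f"polarity must be {BRIGHT!r} or {DARK!r}")
        if len(self.sigma_grid()) == 0:
            raise ValueError("scale grid is empty")

    def sigma_grid(self) -> np.ndarray:
        n = int(np.floor((self.sigma_max - self.sigma_min) / self.sigma_step + 1e-9)) + 1
        return self.sigma_min + self.sigma_step * np.arange(n)


@dataclass(frozen=True)
class HessianField:
    """Scale-normalized second derivatives of a smoothed image.

    ``ixy`` is stored in display coordinates (y up); it is the negative of
    the raw row/column mixed derivative.
    """

    ixx: np.ndarray
    ixy: np.ndarray
    iyy: np.ndarray
    sigma: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.ixx.shape


@dataclass(frozen=True)
class EigenField:
    """Per-pixel eigen-decomposition of a Hessian field.

    ``lambda1`` is the smallest-magnitude eigenvalue (|λ1| ≤ |λ2|) and
    ``theta`` the display-convention angle of its eigenvector in
    [0°, 180°); NaN where the orientation is undefined (|λ1| = |λ2| ties,
    zero Hessian, or non-finite input).
    """

    lambda1: np.ndarray
    lambda2: np.ndarray
    theta: np.ndarray
    sigma: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.lambda1.shape


@dataclass(frozen=True)
class VesselnessResult:
    """Output of the multiscale filter.

    Attributes
    ----------
    rho
        Maximum response over the scale grid, in [0, 1].
    sigma0
        Scale (px) attaining the maximum — the local vessel width estimate.
    theta0
        Vessel orientation at σ0, degrees in [0°, 180°); NaN where
        undefined.
    r0, s0
        Diagnostics: line-similarity R and structure-ness S at σ0.
    sigma_grid
        The scale grid used.
    gamma_used
        The resolved γ (after "auto").
    border_px
        Width of the image border where reflection padding makes the
        response unreliable: ceil(3·sigma_max).
    """

    rho: np.ndarray
    sigma0: np.ndarray
    theta0: np.ndarray
    r0: np.ndarray
    s0: np.ndarray
    sigma_grid: np.ndarray
    gamma_used: float
    border_px: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.rho.shape


def make_gaussian_kernel(sigma: float, truncate_radius: float | None = None,
                         normalize: bool = True) -> np.ndarray:
    """Sample the isotropic 2-D Gaussian G(t, σ) on an integer grid.

    G(t, σ) = exp(−‖t‖²/2σ²) / (2πσ²), sampled at integer offsets within
    ``truncate_radius`` (defaults to 4σ, must be ≥ 3σ) of the center, then
    renormalized to unit sum when ``normalize``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if truncate_radius is None:
        truncate_radius = 4.0 * sigma
    if truncate_radius < 3.0 * sigma:
        raise ValueError("truncate_radius must be at least 3*sigma")
    r = int(np.ceil(truncate_radius))
    ax = np.arange(-r, r + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2)) / (2.0 * np.pi * sigma**2)
    if normalize:
        k = k / k.sum()
    return k


def hessian_at_scale(image: ScalarImage2D | np.ndarray, sigma: float,
                     ridge_norm_gamma: float = 0.75,
                     truncate: float = 4.0) -> HessianField:
    """Scale-normalized Hessian of the image at scale σ.

    Second derivatives are computed by separable convolution with sampled
    derivative-of-Gaussian kernels (reflection boundary) and multiplied by
    σ^(2·ridge_norm_gamma) so responses are comparable across scales.
    """
    if sigma < _MIN_SIGMA:
        raise ValueError(f"sigma must be >= {_MIN_SIGMA} px (got {sigma})")
    px = image.pixels if isinstance(image, ScalarImage2D) else np.asarray(image, dtype=np.float64)
    norm = float(sigma) ** (2.0 * ridge_norm_gamma)

    # the truncated second-derivative kernel does not sum exactly to zero;
    # subtract the residual (kernel sum x smoothed image) so that constant
    # images have an exactly zero Hessian
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-x**2 / (2.0 * sigma**2))
    g /= g.sum()
    s2 = float((g * (x**2 - sigma**2) / sigma**4).sum())

    # axis 0 = row (storage y, pointing down), axis 1 = column (x)
    smooth = ndimage.gaussian_filter(px, sigma, mode="reflect", truncate=truncate)
    ixx = (ndimage.gaussian_filter(px, sigma, order=(0, 2), mode="reflect",
                                   truncate=truncate) - s2 * smooth) * norm
    iyy = (ndimage.gaussian_filter(px, sigma, order=(2, 0), mode="reflect",
                                   truncate=truncate) - s2 * smooth) * norm
    # the first-derivative kernel is antisymmetric (exact zero sum): no correction
    ixy_storage = ndimage.gaussian_filter(px, sigma, order=(1, 1), mode="reflect",
                                          truncate=truncate) * norm
    # flipping y (row down -> y up) negates the mixed derivative only
    return HessianField(ixx=ixx, ixy=-ixy_storage, iyy=iyy, sigma=float(sigma))


def eigen_field(h: HessianField) -> EigenField:
    """Closed-form per-pixel eigen-decomposition of a symmetric 2×2 field.

    Eigenvalues of [[a, b], [b, c]] are m ± r with m = (a+c)/2 and
    r = sqrt(((a−c)/2)² + b²); they are ordered by absolute value. θ is the
    angle of the eigenvector of λ1, folded into [0°, 180°), NaN at
    isotropic points (|λ1| = |λ2|) where orientation is undefined.
    """
    a, b, c = h.ixx, h.ixy, h.iyy
    m = 0.5 * (a + c)
    r = np.hypot(0.5 * (a - c), b)
    lam_plus = m + r
    lam_minus = m - r
    plus_is_small = np.abs(lam_plus) <= np.abs(lam_minus)
    lam1 = np.where(plus_is_small, lam_plus, lam_minus)
    lam2 = np.where(plus_is_small, lam_minus, lam_plus)

    # angle of the eigenvector of lam_plus; the lam_minus vector is orthogonal
    phi_plus = 0.5 * np.degrees(np.arctan2(2.0 * b, a - c))
    theta = fold_axial(np.where(plus_is_small, phi_plus, phi_plus + 90.0))

    bad = ~np.isfinite(a) | ~np.isfinite(b) | ~np.isfinite(c)
    tie = np.abs(np.abs(lam2) - np.abs(lam1)) <= _TIE_RTOL * np.abs(lam2)
    zero = lam2 == 0.0  # covers the all-zero Hessian
    theta = np.where(bad | tie | zero, np.nan, theta)
    return EigenField(lambda1=lam1, lambda2=lam2, theta=theta, sigma=h.sigma)


def _structureness(e: EigenField) -> np.ndarray:
    return np.hypot(e.lambda1, e.lambda2)


def _line_ratio(e: EigenField) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.abs(e.lambda1) / np.abs(e.lambda2)
    return np.where(e.lambda2 == 0.0, 0.0, r)


def _polarity_ok(e: EigenField, polarity: str) -> np.ndarray:
    if polarity == BRIGHT:
        return e.lambda2 < 0.0
    return e.lambda2 > 0.0


def vesselness_at_scale(e: EigenField, beta: float, gamma: float,
                        polarity: str = BRIGHT) -> np.ndarray:
    """Single-scale filter response ρ = exp(−R²/2β²)·(1 − exp(−S²/2γ²)).

    The response is forced to zero where the sign of λ2 contradicts the
    requested polarity (a bright vessel on a dark background has λ2 < 0)
    and at non-finite pixels.
    """
    if beta <= 0 or gamma <= 0:
        raise ValueError("beta and gamma must be positive")
    if polarity not in (BRIGHT, DARK):
        raise ValueError(f"polarity must be {BRIGHT!r} or {DARK!r}")
    R = _line_ratio(e)
    S = _structureness(e)
    rho = np.exp(-(R**2) / (2.0 * beta**2)) * (1.0 - np.exp(-(S**2) / (2.0 * gamma**2)))
    rho = np.where(_polarity_ok(e, polarity), rho, 0.0)
    return np.where(np.isfinite(rho), rho, 0.0)


def multiscale_vesselness(image: ScalarImage2D | np.ndarray,
                          params: FilterParams | None = None) -> VesselnessResult:
    """Maximize the vesselness response over the scale grid (per pixel).

    Returns the maximal response ρ, the argmax scale σ0 (vessel width
    estimate) and the orientation θ0 of the eigenvector of the
    smallest-magnitude eigenvalue at σ0. With γ = "auto", γ is half the
    maximum structure-ness observed over the image across the whole grid,
    so responses remain comparable between scales.
    """
    params = params or FilterParams()
    sigmas = params.sigma_grid()

    eigens = [eigen_field(hessian_at_scale(image, s, params.ridge_norm_gamma, params.truncate))
              for s in sigmas]
    S_stack = np.stack([_structureness(e) for e in eigens])

    if params.gamma == "auto":
        # floor guards against floating-point dust on structureless images
        smax = float(S_stack.max())
        gamma = 0.5 * smax if smax > 1e-12 else 1.0
    else:
        gamma = float(params.gamma)

    rho_stack = np.stack([vesselness_at_scale(e, params.beta, gamma, params.polarity)
                          for e in eigens])
    best = np.argmax(rho_stack, axis=0)
    ii, jj = np.indices(best.shape)
    rho = rho_stack[best, ii, jj]
    theta_stack = np.stack([e.theta for e in eigens])
    R_stack = np.stack([_line_ratio(e) for e in eigens])
    return VesselnessResult(
        rho=rho,
        sigma0=sigmas[best].astype(np.float64),
        theta0=theta_stack[best, ii, jj],
        r0=R_stack[best, ii, jj],
        s0=S_stack[best, ii, jj],
        sigma_grid=sigmas,
        gamma_used=gamma,
        border_px=int(np.ceil(3.0 * params.sigma_max)),
    )
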