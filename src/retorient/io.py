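"""Image readers/writers and the orientation color map.

Input angiograms are single-channel 8- or 16-bit PNG or TIFF; intensities
are normalized to [0, 1] by the bit-depth maximum. Orientation maps are
visualized with a cyclic-over-180° hue encoding (0° and 180° share the same
color, 90° is green) on masked vessel pixels, black elsewhere, with a hue
legend bar appended below the image.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .hessian import VesselnessResult
from .image import ScalarImage2D
from .mask import BinaryMask

__all__ = [
    "load_image",
    "save_image",
    "save_float_tiff",
    "save_mask_png",
    "orientation_rgb",
    "save_orientation_colormap",
]


def _normalize(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel image, got shape {arr.shape}; "
            "convert RGB/multi-channel input to grayscale first")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float64)
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError(f"{path}: float image intensities must already lie in [0, 1]")
        return arr
    raise ValueError(f"{path}: unsupported dtype {arr.dtype}; use 8- or 16-bit grayscale")


def load_image(path: str | Path, px_per_mm: float | None = None) -> ScalarImage2D:
    """Load an 8/16-bit single-channel PNG or TIFF as a normalized image."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such image file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as im:
            if im.mode in ("I;16", "I;16B", "I;16L"):
                arr = np.asarray(im, dtype=np.uint16)
            elif im.mode == "L":
                arr = np.asarray(im, dtype=np.uint8)
            elif im.mode == "I":
                arr = np.asarray(im).astype(np.uint16)
            else:
                raise ValueError(
                    f"{path}: mode {im.mode!r} is not single-channel grayscale; "
                    "convert RGB/multi-channel input to grayscale first")
    return ScalarImage2D(_normalize(np.asarray(arr), path), px_per_mm=px_per_mm)


def save_image(image: ScalarImage2D, path: str | Path, bit_depth: int = 16) -> None:
    """Write a normalized image as 8- or 16-bit grayscale PNG/TIFF."""
    path = Path(path)
    if bit_depth == 8:
        arr = np.round(image.pixels * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.round(image.pixels * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def save_float_tiff(arr: np.ndarray, path: str | Path) -> None:
    """Diagnostic dump of a float field (ρ, σ0, θ0, ground truth) as 32-bit TIFF."""
    tifffile.imwrite(Path(path), arr.astype(np.float32))


def save_mask_png(mask: BinaryMask | np.ndarray, path: str | Path) -> None:
    """Write a binary mask as a 1-bit PNG."""
    m = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    Image.fromarray(m).convert("1").save(Path(path))


def orientation_rgb(theta0: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Map axial orientations to RGB hues (cyclic over 180°), black off-mask.

    0° and 180° are the same line direction and map to the same color
    (red); 90° maps to green. The hue runs red → yellow → green over
    [0°, 90°] and green → blue → red over [90°, 180°), closing the hue
    circle so the encoding has no axial seam.
    """
    from matplotlib import colormaps

    hsv = colormaps["hsv"]
    x = np.where(np.isfinite(theta0), np.mod(theta0, 180.0) / 180.0, 0.0)
    hue = np.where(x <= 0.5, (2.0 / 3.0) * x, 1.0 / 3.0 + (4.0 / 3.0) * (x - 0.5))
    rgb = hsv(hue)[..., :3]
    on = mask & np.isfinite(theta0)
    rgb[~on] = 0.0
    return (rgb * 255).astype(np.uint8)


def save_orientation_colormap(result: VesselnessResult, mask: BinaryMask | np.ndarray,
                              path: str | Path, legend_height: int = 12) -> None:
    """Write the orientation color map with a 0°–180° hue legend bar below."""
    m = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if m.shape != result.theta0.shape:
        raise ValueError(f"shape mismatch: mask {m.shape} vs theta {result.theta0.shape}")
    rgb = orientation_rgb(result.theta0, m)
    h, w = m.shape
    ramp = np.linspace(0.0, 180.0, w, endpoint=False)
    legend = orientation_rgb(np.tile(ramp, (legend_height, 1)),
                             np.ones((legend_height, w), dtype=bool))
    out = np.concatenate([rgb, np.zeros((2, w, 3), dtype=np.uint8), legend], axis=0)
    Image.fromarray(out).save(Path(path))
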