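"""Macular disk ROI and its eight 45° anatomical sectors.

The region of interest is a disk centered at the macula (default diameter
5 mm) divided into eight equal-area 45° wedges labeled by the anatomical
quadrants they straddle: N = nasal, S = superior, T = temporal,
I = inferior. Going counter-clockwise from the nasal axis the labels are
NS, SN, ST, TS, TI, IT, IN, NI. Nasal is toward the nose, so it maps to
image right for a right eye (OD) and image left for a left eye (OS);
superior is always image up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SectorROI", "SECTOR_LABELS", "disk_mask", "sector_masks"]

SECTOR_LABELS = ("NS", "SN", "ST", "TS", "TI", "IT", "IN", "NI")

EYES = ("OD", "OS")


@dataclass(frozen=True)
class SectorROI:
    """Disk-and-octant geometry with anatomical labels.

    ``sectors`` maps each label to a boolean mask; the masks are pairwise
    disjoint and their union is the disk. ``angular_ranges`` gives the
    half-open anatomical angle interval [lo, hi) of each wedge in degrees
    counter-clockwise from the nasal axis.
    """

    center: tuple[float, float]
    radius_px: float
    eye: str
    disk: np.ndarray
    sectors: dict[str, np.ndarray]
    angular_ranges: dict[str, tuple[float, float]]


def disk_mask(center: tuple[float, float], diameter_mm: float, px_per_mm: float,
              image_shape: tuple[int, int]) -> tuple[np.ndarray, float]:
    """Boolean disk of the given physical diameter centered at (row, col).

    A pixel belongs to the disk iff its center lies within
    radius = diameter_mm·px_per_mm/2 of the given center. The disk must
    fit entirely inside the image.
    """
    if diameter_mm <= 0 or px_per_mm <= 0:
        raise ValueError("diameter_mm and px_per_mm must be positive")
    radius = 0.5 * diameter_mm * px_per_mm
    r0, c0 = center
    h, w = image_shape
    if (r0 - radius < -0.5 or r0 + radius > h - 0.5
            or c0 - radius < -0.5 or c0 + radius > w - 0.5):
        raise ValueError(
            f"disk of radius {radius:.1f} px at ({r0}, {c0}) exceeds image bounds {image_shape}")
    rows = np.arange(h)[:, None] - r0
    cols = np.arange(w)[None, :] - c0
    return (rows**2 + cols**2) <= radius**2, radius


def sector_masks(disk: np.ndarray, center: tuple[float, float], eye: str,
                 radius_px: float | None = None) -> SectorROI:
    """Split a disk into the eight labeled 45° anatomical wedges.

    Each pixel is assigned by the display-convention polar angle of its
    center about the disk center (counter-clockwise, y up), converted to an
    anatomical angle measured counter-clockwise from the nasal axis. Wedges
    are half-open ([0°, 45°) is NS, etc.) so no pixel is double-assigned.
    """
    if eye not in EYES:
        raise ValueError(f"eye must be one of {EYES}")
    h, w = disk.shape
    r0, c0 = center
    dx = np.arange(w)[None, :] - c0
    dy = r0 - np.arange(h)[:, None]  # y up in display coordinates
    theta = np.degrees(np.arctan2(dy, dx))  # CCW from image right
    # anatomical angle: CCW from the nasal axis (nasal = right for OD, left for OS;
    # the OS frame is the left-right mirror of the OD frame, so CCW flips too)
    alpha = np.mod(theta if eye == "OD" else 180.0 - theta, 360.0)
    wedge = np.floor_divide(alpha, 45.0).astype(int) % 8

    sectors: dict[str, np.ndarray] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for k, label in enumerate(SECTOR_LABELS):
        sectors[label] = disk & (wedge == k)
        ranges[label] = (45.0 * k, 45.0 * (k + 1))
    # if not given, recover the radius from the disk area
    radius = float(radius_px) if radius_px is not None else float(np.sqrt(disk.sum() / np.pi))
    return SectorROI(center=(float(r0), float(c0)), radius_px=radius, eye=eye,
                     disk=disk, sectors=sectors, angular_ranges=ranges)
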