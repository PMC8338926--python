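"""Shared fixtures: small synthetic scenes and default parameters."""

from __future__ import annotations

import numpy as np
import pytest

from retorient.synthetic import SceneSpec, SyntheticTube, render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def single_tube_scene(angle_deg: float, s: float = 1.0, size: int = 96,
                      amplitude: float = 0.6, noise: float = 0.0,
                      background: float = 0.1, seed: int = 0) -> SceneSpec:
    c = (size - 1) / 2.0
    return SceneSpec(
        shape=(size, size),
        tubes=(SyntheticTube(s=s, amplitude=amplitude, point=(c, c), angle_deg=angle_deg),),
        background=background,
        noise_sigma=noise,
        seed=seed,
    )


@pytest.fixture
def vertical_tube():
    """Noiseless vertical (90°) tube with s=1 through the image center."""
    return render_scene(single_tube_scene(90.0, s=1.0, size=64, amplitude=0.8,
                                          background=0.0))


def centerline_mask(angle_deg: float, size: int, half_width: float = 0.7,
                    margin: int = 13) -> np.ndarray:
    """Pixels within half_width of the central tube axis, away from borders."""
    c = (size - 1) / 2.0
    rows = np.arange(size)[:, None]
    cols = np.arange(size)[None, :]
    th = np.radians(angle_deg)
    d = np.abs(-np.sin(th) * (cols - c) + np.cos(th) * (c - rows))
    m = d <= half_width
    m[:margin, :] = False
    m[-margin:, :] = False
    m[:, :margin] = False
    m[:, -margin:] = False
    return m
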