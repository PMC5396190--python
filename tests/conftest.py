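"""Shared fixtures: independent rasterizers and small synthetic builders.

The rasterizer here is deliberately written from scratch (point-in-shape on
pixel centres in anatomical coordinates) so geometry tests have an oracle
that does not share code with the package's phantom generator.
"""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest

from discload.relaxometry import DEFAULT_ECHO_TIMES_MS, EchoStack


def rasterize_rect(angle_deg, length_px, height_px, shape=(120, 120), center=None):
    """Rotated rectangle mask; positive angle lifts the anterior (left) end."""
    if center is None:
        center = (shape[0] / 2, shape[1] / 2)
    rows, cols = np.indices(shape, dtype=float)
    x = cols - center[1]
    y = -(rows - center[0])
    th = np.radians(angle_deg)
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    return (np.abs(u) <= length_px / 2) & (np.abs(v) <= height_px / 2)


def rasterize_ellipse(angle_deg, a_px, b_px, shape=(120, 120), center=None):
    if center is None:
        center = (shape[0] / 2, shape[1] / 2)
    rows, cols = np.indices(shape, dtype=float)
    x = cols - center[1]
    y = -(rows - center[0])
    th = np.radians(angle_deg)
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def day_start():
    return datetime(2020, 1, 6, 6, 0, 0)


def decay_stack(t2_by_region, shape=(1, 24, 24), s0=1000.0, pixel_size=0.366,
                spacing=4.5, echo_times=DEFAULT_ECHO_TIMES_MS):
    """Noiseless stack from {mask: t2} region map (masks are (s,r,c) bool)."""
    tes = np.asarray(echo_times, dtype=float)
    images = np.zeros((tes.size,) + shape)
    for mask, t2 in t2_by_region:
        decay = s0 * np.exp(-tes / t2)
        images[:, mask] = decay[:, None]
    return EchoStack(images=images, echo_times_ms=tes,
                     pixel_size_mm=pixel_size, slice_spacing_mm=spacing)
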