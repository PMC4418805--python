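"""Shared fixtures: small noise-free phantom scenes and fitted fiber axes."""

import numpy as np
import pytest

from fiberwrap import fibergeom as fg
from fiberwrap import synthgen as sg

VOX = (0.4, 0.4, 0.4)


def make_fiber_scene(bands=(), stress_fibers=(), nuclei=(), membrane_gaps=(),
                     radius=3.0, length=36.0, shape=(40, 40, 100), seed=0,
                     noise=False):
    """One straight fiber along x (anchor (8, 8, 2) μm) plus passed objects."""
    cfg = sg.SceneConfig(
        shape=shape,
        voxel_size=VOX,
        fibers=[sg.Fiber(anchor=(8.0, 8.0, 2.0), direction=(0, 0, 1),
                         radius=radius, length=length)],
        bands=list(bands),
        stress_fibers=list(stress_fibers),
        nuclei=list(nuclei),
        membrane_gaps=list(membrane_gaps),
        seed=seed,
    )
    if not noise:
        cfg = cfg.noise_free()
    return cfg


def fitted_axis(stack, threshold=0.5, label=1):
    labels = fg.segment_fibers(stack, threshold=threshold)
    axis = fg.extract_axis(labels == label, stack.voxel_size, fiber_id=label)
    return fg.fit_local_diameter(labels == label, axis,
                                 voxel_size=stack.voxel_size), labels


@pytest.fixture(scope="session")
def ringed_fiber():
    """Noise-free fiber with a full 360° band, a 120° arc crossing θ=0, and a
    longitudinal stress fiber; returns (stack, truth, axis)."""
    cfg = make_fiber_scene(
        bands=[sg.Band(fiber=0, axial_center=18.0, axial_width=2.0,
                       coverage_deg=360.0),
               sg.Band(fiber=0, axial_center=8.0, axial_width=2.0,
                       coverage_deg=120.0, offset_deg=300.0)],
        stress_fibers=[sg.StressFiber(fiber=0, azimuth_deg=90.0,
                                      axial_span=(24.0, 34.0))],
    )
    stack, truth = sg.render_scene(cfg)
    axis, _ = fitted_axis(stack)
    return stack, truth, axis
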