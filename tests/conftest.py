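import numpy as np
import pytest

from tilt3d import image_cues, stereo_synth, surface_truth


@pytest.fixture(scope="session")
def geom():
    return stereo_synth.ViewingGeometry()


@pytest.fixture(scope="session")
def truth_cfg(geom):
    return surface_truth.TruthConfig(pixels_per_degree=geom.pixels_per_degree)


@pytest.fixture(scope="session")
def cue_cfg(geom):
    return image_cues.CueConfig(pixels_per_degree=geom.pixels_per_degree)


@pytest.fixture(scope="session")
def ground_patch(geom):
    """Planar patch, tilt 90 (ground-plane-like), slant 45, 10 m."""
    spec = stereo_synth.SceneSpec(tilt=90.0, slant=45.0, distance=10.0, seed=2)
    return stereo_synth.render_stereo(spec, geom)


@pytest.fixture(scope="session")
def fronto_patch(geom):
    spec = stereo_synth.SceneSpec(tilt=0.0, slant=0.0, distance=10.0, seed=1)
    return stereo_synth.render_stereo(spec, geom)


def center_tilt_slant(patch):
    """Recomputed (signed tilt, slant) at the center of a rendered patch."""
    cfg = surface_truth.TruthConfig(pixels_per_degree=patch.geom.pixels_per_degree)
    dx, dy = surface_truth.range_gradient(patch.range_map, cfg)
    tm = surface_truth.groundtruth_tilt(dx, dy)
    cy, cx = patch.range_map.shape[0] // 2, patch.range_map.shape[1] // 2
    slant = surface_truth.groundtruth_slant(patch.range_map, cfg)[cy, cx]
    return float(tm.signed_tilt[cy, cx]), float(slant)
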