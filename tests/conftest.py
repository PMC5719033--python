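"""Shared fixtures: instrument geometry and small simulated scenes.

Scene-processing fixtures are session-scoped; rendering a cube and
running the correction chain are the expensive steps and every module
reads from them without mutating.
"""

import numpy as np
import pytest

import topotof as tt
from topotof.simulate import GLOBAL_SPECIES, ROOT_SPECIES, SUBSTRATE_SPECIES


def all_species():
    return [s for s, _ in ROOT_SPECIES + SUBSTRATE_SPECIES + GLOBAL_SPECIES]


@pytest.fixture(scope="session")
def geom():
    return tt.InstrumentGeometry()


@pytest.fixture(scope="session")
def root_scene32(geom):
    """32×32 root scene: half-cylinder 200 µm tall on a flat substrate."""
    return tt.make_root_scene(height=200e-6, nx=32, ny=32, seed=7)


@pytest.fixture(scope="session")
def raw_delta32(root_scene32, geom):
    """Noiseless delta-line render (exact integer bookkeeping)."""
    return tt.render(root_scene32, geom, noiseless=True)


@pytest.fixture(scope="session")
def comp_delta32(raw_delta32, geom):
    total = tt.sum_spectrum(raw_delta32)
    segs = tt.find_segments(total, threshold=500)
    segs = tt.assign_labels(segs, all_species(), geom)
    return tt.compress_cube(raw_delta32, segs)


@pytest.fixture(scope="session")
def corrected_gauss32(root_scene32, geom):
    """Cs+-referenced correction chain on a 32×32 expectation cube."""
    raw = tt.render(root_scene32, geom, noiseless=True, lineshape="gaussian")
    segs = tt.assign_labels(tt.find_segments(tt.sum_spectrum(raw), threshold=500),
                            all_species(), geom)
    comp = tt.compress_cube(raw, segs)
    track = tt.track_reference(comp, comp.segment_by_label("Cs+"))
    fld = tt.correction_field(track, tt.estimate_substrate_tof(track))
    return tt.apply_correction(comp, fld)


@pytest.fixture(scope="session")
def root_scene64(geom):
    """64×64 root scene used for correction-accuracy checks."""
    return tt.make_root_scene(height=200e-6, nx=64, ny=64, seed=1)


@pytest.fixture(scope="session")
def comp_gauss64(root_scene64, geom):
    """Compressed expectation render (Gaussian lines at m/Δm = 7000)."""
    raw = tt.render(root_scene64, geom, noiseless=True, lineshape="gaussian")
    total = tt.sum_spectrum(raw)
    segs = tt.assign_labels(tt.find_segments(total, threshold=1000),
                            all_species(), geom)
    return tt.compress_cube(raw, segs)


@pytest.fixture(scope="session")
def corrected_gauss64(comp_gauss64):
    """Cs+-referenced correction chain on the 64×64 expectation cube."""
    ref = comp_gauss64.segment_by_label("Cs+")
    track = tt.track_reference(comp_gauss64, ref)
    t_sub = tt.estimate_substrate_tof(track)
    fld = tt.correction_field(track, t_sub)
    corrected = tt.apply_correction(comp_gauss64, fld)
    return {"track": track, "t_sub": t_sub, "field": fld, "corrected": corrected}
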