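"""Shared fixtures: phantoms and pipeline stages are expensive, so the
default phantom and its processed stages are built once per session."""

import numpy as np
import pytest

import mrpi2
from mrpi2.midsagittal import build_axial_slab, detect_landmarks, fit_midsagittal
from mrpi2.preprocessing import normalize_intensity, register_rigid


@pytest.fixture(scope="session")
def default_spec():
    return mrpi2.PhantomSpec(v3_width_mm=8.61, fh_width_mm=39.1)


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    return mrpi2.generate_phantom(default_spec)


@pytest.fixture(scope="session")
def canonical(default_phantom):
    vol, _ = default_phantom
    return normalize_intensity(register_rigid(vol, vol, mode="passthrough"))


@pytest.fixture(scope="session")
def landmarks(canonical):
    return detect_landmarks(canonical)


@pytest.fixture(scope="session")
def msp(canonical, landmarks):
    return fit_midsagittal(canonical, landmarks)


@pytest.fixture(scope="session")
def slab(canonical, landmarks, msp):
    return build_axial_slab(canonical, landmarks, msp)


@pytest.fixture(scope="session")
def default_result(default_phantom):
    vol, _ = default_phantom
    return mrpi2.run_subject(vol)


@pytest.fixture(scope="session")
def v3_sweep_results():
    """Pipeline results for three third-ventricle widths (other dims fixed)."""
    out = {}
    for v3 in (4.3, 5.2, 8.6):
        vol, gt = mrpi2.generate_phantom(mrpi2.PhantomSpec(v3_width_mm=v3))
        out[v3] = (mrpi2.run_subject(vol), gt)
    return out


@pytest.fixture(scope="session")
def fh_sweep_results():
    """Pipeline results for three frontal-horn spans (other dims fixed)."""
    out = {}
    for fh in (30.0, 36.0, 42.0):
        vol, gt = mrpi2.generate_phantom(mrpi2.PhantomSpec(fh_width_mm=fh))
        out[fh] = (mrpi2.run_subject(vol), gt)
    return out
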