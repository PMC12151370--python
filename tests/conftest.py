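"""Shared fixtures: synthetic subjects, calibrations and model variants.

Session-scoped because calibration sessions are reused by many tests; all
randomness is seeded so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

import funkam as fk
from funkam.calibration import calibrate
from funkam.markers import reconstruct_virtual_markers
from funkam.model import integrate_far_fun1, integrate_far_fun2, make_generic_model, scale_model

RATE = 50.0  # Hz used for fixture trials (cheap but well-resolved)


def build_session(seed, knee_tilt=0.0, ankle_tilt=0.0, noise=fk.NoiseSpec(), rng_offset=1000):
    """Subject + reference movements + static + calibration + model variants."""
    sub = fk.make_subject(seed, knee_tilt, ankle_tilt)
    rng = np.random.default_rng(seed + rng_offset)
    refs = {
        "stararc": fk.simulate_stararc(sub, duration=6, rate=RATE, noise=noise, rng=rng),
        "knee": fk.simulate_flexion_reference(sub, "knee", duration=4, rate=RATE, noise=noise, rng=rng),
        "ankle": fk.simulate_flexion_reference(sub, "ankle", duration=4, rate=RATE, noise=noise, rng=rng),
    }
    static = fk.simulate_static(sub, duration=0.3, rate=RATE)
    cal = calibrate(refs, static)
    generic = make_generic_model()
    con = scale_model(generic, cal.hjc, cal.kjc, cal.ajc, static, sub.anthro)
    return {
        "subject": sub,
        "refs": refs,
        "static": static,
        "cal": cal,
        "generic": generic,
        "con": con,
        "fun1": integrate_far_fun1(generic, cal, static, sub.anthro),
        "fun2": integrate_far_fun2(con, cal, static),
    }


def conditioned_legpress(session, condition="static", foot="neutral", rate=RATE, **kw):
    """Simulate a leg-press trial and reconstruct the removed PSIS markers."""
    sub = session["subject"]
    trial = fk.simulate_legpress(sub, condition, foot, rate=rate, **kw)
    markers = reconstruct_virtual_markers(
        trial.markers,
        session["static"],
        list(sub.layout.pelvis_donors),
        list(sub.layout.psis_markers),
    )
    return trial, markers


@pytest.fixture(scope="session")
def tilted_session():
    """Subject whose functional knee/ankle axes are tilted from generic."""
    return build_session(5, knee_tilt=(8.0, 6.0), ankle_tilt=5.0)


@pytest.fixture(scope="session")
def neutral_session():
    """Subject whose functional axes coincide with the generic model."""
    return build_session(11)


@pytest.fixture(scope="session")
def generic_model():
    return make_generic_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
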