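"""Shared fixtures: quiet phantoms and hand-built index objects."""

from __future__ import annotations


import numpy as np
import pytest

from eitsbt.indices import SessionIndices
from eitsbt.prediction import PatientRecord
from eitsbt.synthetic import default_phantom_spec, generate_phantom, lung_ellipse_map


@pytest.fixture(scope="session")
def amp_map():
    return lung_ellipse_map((32, 32))


@pytest.fixture(scope="session")
def quiet_spec(amp_map):
    """Noise-free, cardiac-free uniform phantom at the baseline rate."""
    return default_phantom_spec(
        lung_amplitude_map=amp_map,
        delay_map=np.zeros_like(amp_map),
        respiratory_rate=23.5,
        noise_sd=0.0,
        cardiac_amplitude=0.0,
    )


@pytest.fixture(scope="session")
def quiet_phantom(quiet_spec):
    return generate_phantom(quiet_spec)


def make_session_indices(subject="p", session="t0", **over) -> SessionIndices:
    """A SessionIndices with plausible defaults, overridable per field."""
    base = dict(
        subject_id=subject,
        session_label=session,
        rr=23.5,
        tiv_au=100.0,
        tiv_percent=100.0,
        eeli_au=0.0,
        delta_eeli_percent=0.0,
        ir=1.0,
        ir_adapt=1.0,
        gi=40.0,
        gi_raw=0.40,
        sp_rvd={40: 12.0, 60: 12.0, 80: 12.0},
        sp_rvd_sd={40: 12.0, 60: 12.0, 80: 12.0},
        sp_rvd_mean={40: 40.0, 60: 55.0, 80: 70.0},
        rsbi_eit=23.5,
        n_breaths_selected=12,
        rvd_unreached=0,
    )
    base.update(over)
    return SessionIndices(**base)


def make_record(subject="p", vt_t0=500.0, vt_t2=500.0, **indices_over) -> PatientRecord:
    return PatientRecord(
        subject_id=subject,
        indices_t0=make_session_indices(subject, "t0", **indices_over),
        indices_t1=make_session_indices(subject, "t1", **indices_over),
        indices_t2=make_session_indices(subject, "t2", **indices_over),
        vt_t0=vt_t0,
        vt_t2=vt_t2,
    )


@pytest.fixture
def record_factory():
    return make_record
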