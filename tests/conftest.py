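"""Shared fixtures: toy grids and the reference virtual patient.

Heavy artifacts (reference patient, reduced model, calibrated ensemble)
are session-scoped so the calibration- and optimization-level tests
share one twin.
"""

from __future__ import annotations

import numpy as np
import pytest

import tumortwin as tt
from tumortwin.calibrate import PatientData, abc_smc, default_priors, epsilon_floor, lm_fit
from tumortwin.synth import measured_cellularity


@pytest.fixture()
def toy_grid():
    """Fully masked 6x6x1 grid, small enough for dense linear algebra."""
    return tt.VoxelGrid(spacing=(1.0, 1.0, 1.0), breast_mask=np.ones((6, 6, 1), bool))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def responder():
    """Reference zero-noise responder virtual patient."""
    return tt.generate_virtual_patient(tt.responder_spec(seed=3, noise_sd_frac=0.0))


@pytest.fixture(scope="session")
def responder_fields(responder):
    g = responder.grid
    theta = responder.theta_cap
    n_v1 = g.flatten(measured_cellularity(responder, "V1")) / theta
    n_v2 = g.flatten(measured_cellularity(responder, "V2")) / theta
    return n_v1, n_v2


@pytest.fixture(scope="session")
def reference_rom(responder, responder_fields):
    n_v1, n_v2 = responder_fields
    return tt.build_reduced_model(
        responder.grid, responder.theta_cap, n_v1, n_v2, responder.auc_list(), (0.0, 28.0)
    )


@pytest.fixture(scope="session")
def reference_data(responder, responder_fields, reference_rom):
    n_v1, n_v2 = responder_fields
    return PatientData(
        u0=reference_rom.reduce(n_v1),
        data_v2=reference_rom.reduce(n_v2),
        visit_days=(0.0, 28.0),
        regimen=responder.regimen,
        auc_assign=responder.auc_assign(),
    )


@pytest.fixture(scope="session")
def reference_priors(reference_rom):
    return default_priors(reference_rom.k_map)


@pytest.fixture(scope="session")
def reference_ensemble(reference_rom, reference_data, reference_priors):
    """Calibrated digital state of the reference responder (500 samples)."""
    _, eps_lm, _ = lm_fit(reference_rom, reference_data, reference_priors, seed=0)
    eps = max(eps_lm, epsilon_floor(reference_data))
    return abc_smc(reference_rom, reference_data, reference_priors, eps, n_accept=500, seed=0)


@pytest.fixture(scope="session")
def small_patient(tmp_path_factory):
    """A coarse, fast virtual patient written to disk (for IO/pipeline tests)."""
    spec = tt.responder_spec(seed=7, shape=(16, 16, 8), tumor_radii=(6.0, 6.0, 6.0), noise_sd_frac=0.02)
    patient = tt.generate_virtual_patient(spec)
    path = tmp_path_factory.mktemp("patient") / "p07"
    tt.write_patient(patient, path)
    return patient, path
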