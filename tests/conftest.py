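"""Shared fixtures.

The expensive objects — the packaged default patient, the sinus-LBBB and
CRT simulations and the three-stage calibration — are session-scoped so the
whole suite runs them once.
"""

import numpy as np
import pytest

from crtwork import default_model_params, default_patient, simulate_protocol
from crtwork.virtual_patient import NoiseSettings, synthesize_measurements


@pytest.fixture(scope="session")
def patient():
    return default_patient()


@pytest.fixture(scope="session")
def model_params():
    return default_model_params()


@pytest.fixture(scope="session")
def sinus_result(patient, model_params):
    return simulate_protocol(patient, "sinus", model_params)


@pytest.fixture(scope="session")
def crt_result(patient, model_params, sinus_result):
    return simulate_protocol(patient, "crt", model_params,
                             conduction=sinus_result.conduction,
                             graph=sinus_result.graph)


@pytest.fixture(scope="session")
def noise_free_measurements(patient, model_params, sinus_result):
    return synthesize_measurements(
        patient, model_params, NoiseSettings(0.0, 0.0, 0.0, 0.0), seed=11,
        base_trace=sinus_result.trace, activation_map=sinus_result.activation)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def calibrated_fits(patient, model_params, sinus_result, noise_free_measurements):
    """Full three-stage personalisation against noise-free synthetic data.

    Returns (passive_fit, windkessel_fit, active_fit, calibrated_params).
    """
    from crtwork.calibration import fit_active, fit_passive, fit_windkessel
    from crtwork.units import KPA_PER_MMHG

    ms = noise_free_measurements
    tr = sinus_result.trace
    fp = fit_passive(ms.atrial_filling_pv, patient, model_params)
    ej = tr.phase_lv == 1
    fw = fit_windkessel(tr.time[ej], tr.p_lv[ej], tr.v_lv[ej],
                        venous_pressure=model_params.wk_sys.venous_pressure)
    conditioned = model_params.replace(
        passive=fp.parameters,
        wk_sys=model_params.wk_sys.replace(
            proximal_resistance=fw.parameters.proximal_resistance,
            peripheral_resistance=fw.parameters.peripheral_resistance,
            compliance=fw.parameters.compliance))
    fa = fit_active(ms.lv_pressure_time_ms, ms.lv_pressure_mmhg * KPA_PER_MMHG,
                    patient, conditioned, sinus_result.activation)
    calibrated = conditioned.replace(active=fa.parameters)
    return fp, fw, fa, calibrated
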