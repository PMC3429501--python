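"""Coupled simulator: cap geometry, Windkessel, phase logic, equilibrium."""

import math

import numpy as np
import pytest

from crtwork.activation import ActivationMap
from crtwork.hemodynamics import (PHASE_EJECTION, PHASE_IVC, PHASE_POST,
                                  WindkesselParams, cap_geometry,
                                  default_model_params, equilibrium_residual,
                                  run_simulation, shell_diagnostics,
                                  solve_static_state, windkessel_step)
from crtwork.virtual_patient import (PatientConfig, ScarDescriptor,
                                     generate_patient)


class TestCapGeometry:
    def test_hemisphere_closed_form(self):
        x, v, c = cap_geometry(midwall_area=8.0 * math.pi, junction_radius=2.0)
        assert x == pytest.approx(2.0)
        assert v == pytest.approx(16.0 * math.pi / 3.0)
        assert c == pytest.approx(0.5)

    def test_flat_cap(self):
        x, v, c = cap_geometry(midwall_area=math.pi * 9.0, junction_radius=3.0)
        assert x == 0.0 and v == 0.0 and c == 0.0

    def test_round_trip(self):
        for area, y in ((40.0, 3.0), (120.0, 3.6), (60.0, 4.2)):
            x, _, _ = cap_geometry(area, y)
            assert math.pi * (x * x + y * y) == pytest.approx(area, rel=1e-10)

    def test_infeasible_area(self):
        with pytest.raises(ValueError, match="infeasible"):
            cap_geometry(midwall_area=1.0, junction_radius=3.0)


class TestWindkessel:
    WK = WindkesselParams(proximal_resistance=6.0, peripheral_resistance=135.0,
                          compliance=11.0, venous_pressure=0.4)

    def test_zero_flow_decay_matches_closed_form(self):
        """Small implicit steps reproduce P_ven + (P0−P_ven)·exp(−t/RpC)."""
        tau = self.WK.peripheral_resistance * self.WK.compliance
        p, dt = 9.5, 0.01
        p = windkessel_step(p, 0.0, dt, self.WK)
        exact = 0.4 + (9.5 - 0.4) * math.exp(-dt / tau)
        assert p == pytest.approx(exact, abs=1e-8)

    def test_constant_flow_steady_state(self):
        p, q = 5.0, 0.08
        for _ in range(40000):
            p = windkessel_step(p, q, 1.0, self.WK)
        assert p == pytest.approx(
            self.WK.venous_pressure + q * self.WK.peripheral_resistance, rel=1e-6)

    def test_step_halving_convergence(self):
        def run(dt):
            p = 9.5
            t = 0.0
            while t < 400.0 - 1e-9:
                p = windkessel_step(p, 0.1 * math.sin(t / 60.0), dt, self.WK)
                t += dt
            return p
        assert abs(run(0.5) - run(1.0)) / abs(run(1.0)) < 1e-3


class TestRunSimulation:
    def test_isovolumetric_volumes_held(self, sinus_result):
        tr = sinus_result.trace
        ivc = tr.phase_lv == PHASE_IVC
        assert np.max(np.abs(tr.v_lv[ivc] - tr.v_lv[0])) / tr.v_lv[0] < 1e-6
        ivc_rv = tr.phase_rv == PHASE_IVC
        assert np.max(np.abs(tr.v_rv[ivc_rv] - tr.v_rv[0])) / tr.v_rv[0] < 1e-6

    def test_phase_machine_monotone(self, sinus_result, crt_result):
        for tr in (sinus_result.trace, crt_result.trace):
            for phase in (tr.phase_lv, tr.phase_rv):
                assert np.all(np.diff(phase) >= 0)
                assert set(np.unique(phase)) <= {PHASE_IVC, PHASE_EJECTION,
                                                 PHASE_POST}

    def test_quiescent_heart_stays_near_end_diastole(self, patient, model_params):
        tr = run_simulation(patient, None, model_params, disable_active=True)
        assert np.all(tr.phase_lv == PHASE_IVC)
        assert np.all(tr.phase_rv == PHASE_IVC)
        assert np.max(np.abs(tr.p_lv - tr.p_lv[0])) <= 0.05 * tr.p_lv[0]
        assert np.all(tr.sigma_a == 0.0)

    def test_time_step_convergence(self, patient, model_params, sinus_result):
        fine = run_simulation(patient, sinus_result.activation, model_params,
                              dt=0.5)
        coarse = sinus_result.trace
        assert abs(fine.p_lv.max() - coarse.p_lv.max()) / coarse.p_lv.max() < 0.01

    def test_homogeneous_wall_strains_identical(self, model_params):
        """Identical segments + simultaneous activation: one strain per wall."""
        p = generate_patient(PatientConfig(
            jitter=0.0, scar=ScarDescriptor(fraction=0.0)), seed=1)
        ids = np.array(sorted(s.id for s in p.segments))
        amap = ActivationMap(segment_ids=ids, t_act=np.zeros(len(ids)))
        tr = run_simulation(p, amap, model_params, dt=1.0, duration=150.0)
        lvfw = np.array([k for k, sid in enumerate(ids)
                         if {s.id: s for s in p.segments}[sid].wall == "LV_free_wall"])
        spread = np.ptp(tr.E[:, lvfw], axis=1)
        assert np.max(spread) < 1e-10


class TestEquilibrium:
    def test_converged_states_satisfy_force_balance(self, patient, model_params,
                                                    sinus_result):
        """Laplace per wall, the radial junction balance and the
        area/volume compatibilities all vanish along the trace."""
        tr = sinus_result.trace
        for step in (0, 50, 150, 250, 399):
            res = shell_diagnostics(tr, patient, model_params, step)
            assert res.max_equilibrium_residual() < 1e-7

    def test_pressure_perturbation_shifts_laplace_residual(self, patient,
                                                           model_params,
                                                           sinus_result):
        """∂(LVFW Laplace residual)/∂P_LV = −1 exactly."""
        tr = sinus_result.trace
        step = 200
        sigma = (tr.sigma_p[step] + tr.sigma_a[step]
                 + (model_params.active.eta
                    + model_params.active.a_v * tr.sigma_a[step]) * tr.Edot[step])
        x_l, x_s, x_r, y = tr.geometry[step]
        base = equilibrium_residual((x_l, x_s, x_r, y, tr.p_lv[step], tr.p_rv[step]),
                                    tr.E[step], sigma, patient,
                                    (tr.v_lv[step], tr.v_rv[step]))
        bumped = equilibrium_residual(
            (x_l, x_s, x_r, y, tr.p_lv[step] + 1.0, tr.p_rv[step]),
            tr.E[step], sigma, patient, (tr.v_lv[step], tr.v_rv[step]))
        assert bumped.laplace[0] - base.laplace[0] == pytest.approx(-1.0)
        assert bumped.laplace[2] == base.laplace[2]

    def test_mirror_symmetry_zeroes_axial_reaction(self, patient):
        """Identical free walls, flat septum, equal pressures: the axial
        junction component vanishes by symmetry."""
        segs = sorted(patient.segments, key=lambda s: s.id)
        h = np.array([s.wall_volume / s.ref_midwall_area for s in segs])
        sigma = 1.0 / h    # uniform referential tension in every wall
        res = equilibrium_residual((-2.5, 0.0, 2.5, 3.5, 1.0, 1.0),
                                   np.zeros(len(segs)), sigma, patient,
                                   (100.0, 100.0))
        assert res.junction_axial == pytest.approx(0.0, abs=1e-12)

    def test_end_diastolic_state_matches_prescribed_volumes(self, patient,
                                                            model_params):
        u, strains = solve_static_state(patient, model_params,
                                        patient.lv_edv, patient.rv_edv)
        from crtwork.hemodynamics import _volumes_from_u
        v_lv, v_rv = _volumes_from_u(u)
        assert v_lv == pytest.approx(patient.lv_edv, rel=1e-8)
        assert v_rv == pytest.approx(patient.rv_edv, rel=1e-8)
        assert np.all(strains > 0)      # end diastole stretches every segment
        assert u[7] > u[8] > 0          # LV EDP above RV EDP
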