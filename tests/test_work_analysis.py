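"""Work rates, modes, regional aggregation, conservation, swaps, summary."""

import numpy as np
import pytest

from crtwork.hemodynamics import SimulationTrace, run_simulation
from crtwork.virtual_patient import Segment, VirtualPatient
from crtwork import work_analysis as wa


def _toy_trace(time, E, sigma_a, p_lv=None, phase_lv=None):
    """Minimal hand-built trace: two segments, prescribed strain/tension."""
    time = np.asarray(time, dtype=float)
    E = np.asarray(E, dtype=float)
    nt, ns = E.shape
    dt = time[1] - time[0]
    edot = np.zeros_like(E)
    edot[1:] = np.diff(E, axis=0) / dt
    z = np.zeros(nt)
    return SimulationTrace(
        time=time, segment_ids=np.arange(ns),
        E=E, Edot=edot, sigma_a=np.asarray(sigma_a, dtype=float),
        sigma_p=np.zeros_like(E),
        p_lv=z if p_lv is None else p_lv, v_lv=np.full(nt, 100.0),
        phase_lv=np.zeros(nt, np.int8) if phase_lv is None else phase_lv,
        p_rv=z, v_rv=np.full(nt, 80.0), phase_rv=np.zeros(nt, np.int8),
        p_art_sys=z, p_art_pul=z, q_sys=z, q_pul=z,
        geometry=np.zeros((nt, 4)))


def _toy_patient(volumes=(2.0, 1.0), scars=(0.0, 0.0)):
    segs = (
        Segment(0, "septum", "septum", volumes[0], 10.0, volumes[0] / 10.0,
                scars[0], (0.0, 0.0, 0.0), "septum", 0),
        Segment(1, "LV_free_wall", "LV_lateral", volumes[1], 10.0,
                volumes[1] / 10.0, scars[1], (1.0, 0.0, 0.0), "LV_lateral", 0),
    )
    return VirtualPatient(segments=segs, lv_edv=100.0, rv_edv=80.0,
                          end_diastolic_pressure_lv=1.0,
                          end_diastolic_pressure_rv=0.5,
                          sinus_rate=69.0, paced_rate=100.0, av_delay=100.0,
                          seed=0)


class TestWorkRate:
    def test_direct_product(self):
        tr = _toy_trace([0.0, 1.0], [[0.0, 0.0], [-0.001, 0.0]],
                        [[70.0, 0.0], [70.0, 0.0]])
        wt = wa.work_rate(tr)
        assert wt.w[1, 0] == pytest.approx(-0.070)

    def test_scar_segment_no_work(self, patient, sinus_result):
        """Full-scar tissue generates no tension, hence exactly zero work."""
        tr = sinus_result.trace
        wt = wa.work_rate(tr)
        scar = np.array([s.scar_fraction for s in
                         sorted(patient.segments, key=lambda s: s.id)])
        full = scar >= 1.0
        if full.any():
            assert np.all(wt.w[:, full] == 0.0)
        # the partial-scar segment's work scales with its viable fraction
        part = (scar > 0) & (scar < 1)
        assert part.any()
        assert np.any(wt.w[:, part] != 0.0)

    def test_sign_is_product_of_signs(self, rng):
        sa = rng.uniform(0.0, 100.0, 1000)
        edot = rng.uniform(-0.01, 0.01, 1000)
        w = sa * edot
        assert np.all(np.sign(w) == np.sign(sa) * np.sign(edot))


class TestClassifyModes:
    def test_examples(self):
        tr = _toy_trace(
            [0.0, 1.0],
            [[0.0, 0.0], [-0.001, 0.001]],      # seg0 shortens, seg1 stretched
            [[50.0, 50.0], [50.0, 50.0]])
        mode = wa.classify_modes(tr, eps_strain_rate=0.0)
        assert mode[1, 0] == wa.MODE_POSITIVE
        assert mode[1, 1] == wa.MODE_NEGATIVE
        zero = wa.classify_modes(_toy_trace([0.0, 1.0],
                                            [[0.0, 0.0], [-0.001, 0.001]],
                                            [[0.0, 0.0], [0.0, 0.0]]))
        assert np.all(zero == wa.MODE_NON_WORKING)

    def test_deadband_absorbs_micro_stretch(self):
        tr = _toy_trace([0.0, 1.0], [[0.0, 0.0], [1e-6, 1e-3]],
                        [[50.0, 50.0], [50.0, 50.0]])
        mode = wa.classify_modes(tr)    # default deadband 2e-5 ms⁻¹
        assert mode[1, 0] == wa.MODE_POSITIVE
        assert mode[1, 1] == wa.MODE_NEGATIVE


class TestRegionalAverage:
    def test_uniform_field_identity(self, patient):
        field = np.full(len(patient.segments), 3.25)
        for region in ("LV", "RV", "septum", "whole_heart"):
            assert wa.regional_average(field, region, patient) == pytest.approx(3.25)

    def test_volume_weighting_arithmetic(self):
        p = _toy_patient(volumes=(2.0, 1.0))
        field = np.array([3.0, 0.0])
        assert wa.regional_average(field, "whole_heart", p) == pytest.approx(2.0)

    def test_partition_identity(self, patient, sinus_result):
        """Whole-heart average = volume-weighted combination of the regions."""
        tr = sinus_result.trace
        w = wa.work_rate(tr).w
        vols = {r: sum(s.wall_volume for s in patient.segments
                       if s.id in set(wa.region_member_ids(patient, r)))
                for r in ("LV", "RV", "septum")}
        total = sum(vols.values())
        combo = sum(vols[r] * wa.regional_average(w, r, patient, tr.segment_ids)
                    for r in vols) / total
        whole = wa.regional_average(w, "whole_heart", patient, tr.segment_ids)
        np.testing.assert_allclose(whole, combo, atol=1e-12)

    def test_empty_region_rejected(self, patient):
        with pytest.raises(ValueError):
            wa.regional_average(np.zeros(24), "LA", patient)


class TestModeFractions:
    def test_partition_exact(self, patient, sinus_result, crt_result):
        for res in (sinus_result, crt_result):
            mode = wa.classify_modes(res.trace)
            mf = wa.mode_fractions(mode, patient,
                                   ("LV", "RV", "septum", "whole_heart"))
            total = mf.f_zero + mf.f_pos + mf.f_neg
            np.testing.assert_allclose(total, 1.0, rtol=0.0, atol=5e-16)

    def test_all_nonworking_before_activation(self, patient, sinus_result):
        mode = wa.classify_modes(sinus_result.trace)
        mf = wa.mode_fractions(mode, patient, ("LV", "RV", "septum"))
        assert np.all(mf.f_zero[0] == 1.0)

    def test_two_segment_hand_calculation(self):
        """One active shortening segment (2 mL), one passive (1 mL):
        f_pos = 2/3, f_zero = 1/3, f_neg = 0 — and with the passive segment
        stretched under tension instead, f_neg = 1/3."""
        p = _toy_patient(volumes=(2.0, 1.0))
        tr = _toy_trace([0.0, 1.0], [[0.0, 0.0], [-0.001, 0.0005]],
                        [[0.0, 0.0], [50.0, 0.0]])
        mf = wa.mode_fractions(wa.classify_modes(tr), p, ("whole_heart",))
        assert mf.f_pos[1, 0] == pytest.approx(2.0 / 3.0)
        assert mf.f_zero[1, 0] == pytest.approx(1.0 / 3.0)
        tr2 = _toy_trace([0.0, 1.0], [[0.0, 0.0], [-0.001, 0.0005]],
                         [[0.0, 0.0], [50.0, 50.0]])
        mf2 = wa.mode_fractions(wa.classify_modes(tr2), p, ("whole_heart",))
        assert mf2.f_neg[1, 0] == pytest.approx(1.0 / 3.0)

    def test_scar_always_non_working(self):
        p = _toy_patient(volumes=(2.0, 1.0), scars=(0.5, 0.0))
        tr = _toy_trace([0.0, 1.0], [[0.0, 0.0], [-0.001, -0.001]],
                        [[0.0, 0.0], [50.0, 50.0]])
        mf = wa.mode_fractions(wa.classify_modes(tr), p, ("whole_heart",))
        assert mf.f_zero[1, 0] == pytest.approx(1.0 / 3.0)   # 0.5·2 mL of 3 mL
        assert mf.f_pos[1, 0] == pytest.approx(2.0 / 3.0)


class TestIntegrals:
    def test_constant_and_ramp(self):
        t = np.linspace(0.0, 400.0, 401)
        assert wa.total_work(np.full(401, -0.01), t) == pytest.approx(-4.0)
        assert wa.total_work(-0.02 * t / 400.0, t) == pytest.approx(-4.0)

    def test_refinement_agreement(self):
        coarse = np.linspace(0.0, 400.0, 401)
        fine = np.linspace(0.0, 400.0, 4001)
        f = lambda t: -0.01 * np.sin(np.pi * t / 400.0) ** 2
        a = wa.total_work(f(coarse), coarse)
        b = wa.total_work(f(fine), fine)
        assert abs(a - b) / abs(b) < 0.005

    def test_ejection_work_rectangle(self):
        p = np.array([5.0, 15.0, 15.0, 5.0])
        v = np.array([250.0, 250.0, 220.0, 220.0])
        assert wa.ejection_work(p, v) == pytest.approx(0.3)     # 10 kPa × 30 mL
        assert wa.ejection_work(p[::-1], v[::-1]) == pytest.approx(-0.3)
        assert wa.ejection_work(np.array([5.0, 15.0, 5.0]),
                                np.full(3, 250.0)) == 0.0


class TestEnergyBalance:
    def test_default_run_conserves_energy(self, patient, model_params,
                                          sinus_result, crt_result):
        for res in (sinus_result, crt_result):
            eb = wa.energy_balance(res.trace, patient, model_params)
            assert not eb.absolute_residual
            assert eb.residual_fraction < 0.05
            assert eb.viscous_dissipated > 0.0

    def test_quiescent_run_all_terms_zero(self, patient, model_params):
        tr = run_simulation(patient, None, model_params, disable_active=True)
        eb = wa.energy_balance(tr, patient, model_params)
        assert abs(eb.active_work) < 1e-6
        assert abs(eb.boundary_work) < 1.0          # mJ; numerically quiescent
        assert abs(eb.passive_stored) < 1.0

    def test_residual_shrinks_with_time_step(self, patient, model_params,
                                             sinus_result):
        fine = run_simulation(patient, sinus_result.activation, model_params,
                              dt=0.5)
        r_fine = wa.energy_balance(fine, patient, model_params).residual_fraction
        r_coarse = wa.energy_balance(sinus_result.trace, patient,
                                     model_params).residual_fraction
        assert r_fine < r_coarse


class TestSwap:
    def test_identity(self, patient, sinus_result):
        tr = sinus_result.trace
        swapped = wa.swap_work(tr, tr, patient)
        w = wa.work_rate(tr).w
        for region in ("LV", "RV", "septum", "whole_heart"):
            direct = wa.regional_average(w, region, patient, tr.segment_ids)
            np.testing.assert_allclose(swapped[region], direct, atol=1e-15)

    def test_two_by_two_grid(self, patient, sinus_result, crt_result):
        traces = {"sinus": sinus_result.trace, "paced": crt_result.trace}
        grid = {(a, b): wa.swap_work(traces[a], traces[b], patient)
                for a in traces for b in traces}
        assert len(grid) == 4
        for series in grid.values():
            assert set(series) == {"time", "LV", "RV", "septum", "whole_heart"}

    def test_hand_computed_shifted_product(self):
        p = _toy_patient(volumes=(1.0, 1.0))
        a = _toy_trace([0.0, 1.0, 2.0], [[0.0, 0.0], [-0.001, 0.0], [-0.002, 0.0]],
                       [[10.0, 0.0], [20.0, 0.0], [30.0, 0.0]])
        b = _toy_trace([0.0, 1.0, 2.0], [[0.0, 0.0], [-0.002, 0.0], [-0.006, 0.0]],
                       [[0.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        out = wa.swap_work(a, b, p, regions=("whole_heart",))
        # tension from a at t=2 is 30 kPa on segment 0; SR from b is −0.004
        assert out["whole_heart"][2] == pytest.approx(0.5 * 30.0 * -0.004)

    def test_mismatched_segments_rejected(self, patient, sinus_result):
        tr = sinus_result.trace
        other = _toy_trace([0.0, 1.0], [[0.0, 0.0], [0.0, 0.0]],
                           [[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            wa.swap_work(tr, other, patient)


class TestSummaryTable:
    def test_printed_percent_changes_reproduced(self):
        """Signed percent change on the published septum entries reproduces
        the printed changes within rounding."""
        assert wa.percent_change(-3.42, -4.87) == pytest.approx(42.36, rel=0.01)
        assert wa.percent_change(0.117, 0.201) == pytest.approx(72.51, rel=0.01)

    def test_no_change_is_zero(self, patient, sinus_result):
        s = wa.summary_table(sinus_result.trace, sinus_result.trace, patient)
        for region in wa.TABLE_REGIONS:
            for metric in s.data[region].values():
                assert metric["percent_change"] == pytest.approx(0.0, abs=1e-12)

    def test_structure_and_additivity(self, patient, sinus_result, crt_result):
        s = wa.summary_table(sinus_result.trace, crt_result.trace, patient,
                             regions=("LV", "RV", "septum", "whole_heart"))
        metrics = {"total_work", "peak_avg_work_rate", "peak_avg_strain_rate",
                   "peak_avg_active_tension", "peak_neg_fraction_ivc"}
        for region in ("LV", "RV", "septum", "whole_heart"):
            assert set(s.data[region]) == metrics
        # whole-heart total work = volume-weighted sum of the region works
        vols = {r: sum(seg.wall_volume for seg in patient.segments
                       if seg.id in set(wa.region_member_ids(patient, r)))
                for r in ("LV", "RV", "septum")}
        total = sum(vols.values())
        for run in ("sinus", "paced"):
            combo = sum(vols[r] * s.data[r]["total_work"][run] for r in vols) / total
            assert s.data["whole_heart"]["total_work"][run] == pytest.approx(
                combo, abs=1e-12)

    def test_signed_peak_convention(self):
        assert wa.signed_peak(np.array([0.5, -2.0, 1.0])) == -2.0
        assert wa.signed_peak(np.array([0.5, 2.0, -1.0])) == 2.0
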