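"""Activation mapping: graph layout, shortest-path oracle, calibration."""

import numpy as np
import pytest

from crtwork.activation import (ActivationMap, ConductionParams, PacingProtocol,
                                SegmentGraph, build_segment_graph,
                                calibrate_conduction, compute_activation,
                                fuse_maps, lv_paced_protocol,
                                sinus_lbbb_protocol)
from crtwork.virtual_patient import PatientConfig, ScarDescriptor, generate_patient

from .oracles import brute_force_activation


@pytest.fixture(scope="module")
def graph(patient):
    return build_segment_graph(patient)


@pytest.fixture(scope="module")
def mini_patient():
    """Six segments (one per region): small enough for pure enumeration."""
    return generate_patient(PatientConfig(
        n_per_region=1, scar=ScarDescriptor(fraction=0.0)), seed=5)


class TestGraph:
    def test_connected_and_symmetric(self, graph):
        seen = {}
        for i, j, d in graph.edges:
            assert d > 0
            assert (j, i) not in seen   # undirected edges stored once
            seen[(i, j)] = d

    def test_apex_adjacent_to_all_columns(self, patient, graph):
        """Each apical segment touches its column's deepest level, covering
        lateral, anterior, posterior and septal columns together."""
        apex = {s.id: s for s in patient.segments_in_region("LV_apex")}
        deepest = {s.column: s.id for s in patient.segments
                   if s.region in ("LV_lateral", "LV_anterior", "LV_posterior",
                                   "septum") and s.level == 3}
        touched = set()
        for i, j, _ in graph.edges:
            for a, b in ((i, j), (j, i)):
                if a in apex and b in deepest.values():
                    touched.add(next(c for c, sid in deepest.items() if sid == b))
        assert touched == {"LV_lateral", "LV_anterior", "LV_posterior", "septum"}

    def test_disconnected_layout_rejected(self, patient, graph):
        isolated = int(graph.segment_ids[0])
        edges = tuple(e for e in graph.edges if isolated not in e[:2])
        broken = SegmentGraph(segment_ids=graph.segment_ids, edges=edges,
                              index=graph.index)
        proto = sinus_lbbb_protocol(patient)
        with pytest.raises(ValueError, match="unreachable"):
            compute_activation(broken, proto, ConductionParams(), patient)


class TestComputeActivation:
    def test_matches_exhaustive_enumeration_small(self, mini_patient):
        graph = build_segment_graph(mini_patient)
        conduction = ConductionParams(velocity=0.05)
        seeds = ((int(graph.segment_ids[0]), 0.0), (int(graph.segment_ids[3]), 12.0))
        proto = PacingProtocol(mode="sinus_LBBB", seeds=seeds)
        amap = compute_activation(graph, proto, conduction, mini_patient)
        scar = np.array([s.scar_fraction for s in
                         sorted(mini_patient.segments, key=lambda s: s.id)])
        vel = conduction.segment_velocity(scar)
        expected = brute_force_activation(graph, seeds, vel, prune=False)
        np.testing.assert_allclose(amap.t_act, expected, rtol=1e-12)

    def test_matches_enumeration_default_graph(self, patient, graph):
        """Single seed, uniform velocity: exact agreement with (bounded)
        all-paths enumeration on the 24-node graph."""
        conduction = ConductionParams(velocity=0.06)
        seeds = ((int(graph.segment_ids[0]), 0.0),)
        proto = PacingProtocol(mode="sinus_LBBB", seeds=seeds)
        amap = compute_activation(graph, proto, conduction, patient)
        scar = np.array([s.scar_fraction for s in
                         sorted(patient.segments, key=lambda s: s.id)])
        expected = brute_force_activation(graph, seeds,
                                          conduction.segment_velocity(scar))
        np.testing.assert_allclose(amap.t_act, expected, rtol=1e-12)

    def test_seed_segment_gets_its_onset(self, patient, graph):
        proto = sinus_lbbb_protocol(patient, onset=7.5)
        amap = compute_activation(graph, proto, ConductionParams(), patient)
        d = amap.as_dict()
        for sid, onset in proto.seeds:
            assert d[sid] == onset
        assert amap.t_act.min() == 7.5

    def test_scar_slowing_monotone(self, graph):
        """Slowing conduction in scar never decreases any activation time."""
        cfg = PatientConfig(scar=ScarDescriptor(region="septum",
                                                levels=(0, 1, 2, 3), fraction=0.8))
        scarred = generate_patient(cfg, seed=1)
        clean = generate_patient(cfg.replace(
            scar=ScarDescriptor(fraction=0.0)), seed=1)
        proto = sinus_lbbb_protocol(scarred)
        slow = compute_activation(graph, proto,
                                  ConductionParams(0.06, 0.25), scarred)
        fast = compute_activation(graph, proto,
                                  ConductionParams(0.06, 0.25), clean)
        assert np.all(slow.t_act >= fast.t_act - 1e-12)
        assert slow.span() > fast.span()


class TestFuseMaps:
    def test_idempotent_and_commutative(self, sinus_result):
        a = sinus_result.activation
        assert np.array_equal(fuse_maps(a, a, 0.0).t_act, a.t_act)
        b = ActivationMap(a.segment_ids, a.t_act[::-1].copy())
        ab = fuse_maps(a, b, 0.0).t_act
        ba = fuse_maps(b, a, 0.0).t_act
        np.testing.assert_array_equal(ab, ba)

    def test_large_offset_returns_paced(self, sinus_result):
        a = sinus_result.activation
        b = ActivationMap(a.segment_ids, a.t_act + 3.0)
        fused = fuse_maps(a, b, offset=1e6)
        np.testing.assert_array_equal(fused.t_act, b.t_act)

    def test_mismatched_segments_rejected(self, sinus_result):
        a = sinus_result.activation
        b = ActivationMap(a.segment_ids[:-1], a.t_act[:-1])
        with pytest.raises(ValueError, match="different segment sets"):
            fuse_maps(a, b)


class TestCalibrateConduction:
    def test_hits_qrs_target(self, patient, graph):
        proto = sinus_lbbb_protocol(patient)
        fitted = calibrate_conduction(graph, proto, patient, qrs_target=154.0)
        amap = compute_activation(graph, proto, fitted, patient)
        assert amap.span() == pytest.approx(154.0, abs=0.1)

    def test_velocity_span_reciprocal(self, patient, graph):
        proto = PacingProtocol(mode="sinus_LBBB",
                               seeds=((int(graph.segment_ids[2]), 0.0),))
        clean = generate_patient(PatientConfig(
            scar=ScarDescriptor(fraction=0.0)), seed=1)
        s1 = compute_activation(graph, proto, ConductionParams(0.05), clean).span()
        s2 = compute_activation(graph, proto, ConductionParams(0.10), clean).span()
        assert s2 == pytest.approx(s1 / 2.0, rel=1e-12)

    def test_fixed_point(self, patient, graph):
        proto = sinus_lbbb_protocol(patient)
        base = ConductionParams(velocity=0.08)
        span = compute_activation(graph, proto, base, patient).span()
        refit = calibrate_conduction(graph, proto, patient, qrs_target=span,
                                     conduction=base)
        assert refit.velocity == pytest.approx(base.velocity, rel=2e-3)

    def test_nonpositive_target_rejected(self, patient, graph):
        """Any positive span is reachable by scaling the velocity (travel
        times are 1/v-linear and fusion discards late seeds), so the only
        a-priori invalid target is a non-positive one."""
        proto = sinus_lbbb_protocol(patient)
        with pytest.raises(ValueError, match="qrs_target"):
            calibrate_conduction(graph, proto, patient, qrs_target=0.0)


class TestProtocols:
    def test_lbbb_seeds_rv_only(self, patient):
        proto = sinus_lbbb_protocol(patient)
        rv_ids = {s.id for s in patient.segments_in_region("RV")}
        sept_ids = {s.id for s in patient.segments_in_region("septum")}
        assert all(sid in rv_ids | sept_ids for sid, _ in proto.seeds)

    def test_crt_narrows_qrs(self, sinus_result, crt_result):
        assert crt_result.activation.span() < sinus_result.activation.span()

    def test_lv_paced_seed_is_lateral(self, patient):
        proto = lv_paced_protocol(patient)
        seg = {s.id: s for s in patient.segments}[proto.seeds[0][0]]
        assert seg.region == "LV_lateral"
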