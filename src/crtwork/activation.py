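"""Eikonal-style activation mapping on the segment adjacency graph.

Only activation TIMES feed the mechanics (active tension is gated by the
local activation time), so full reaction–diffusion electrophysiology is
replaced by multi-source shortest-path travel times: edge weights are
centroid distances divided by a local conduction velocity, with scar
segments conducting more slowly.  The conduction velocity is calibrated by
bisection so the baseline sinus-LBBB map spans the target QRS duration.

LBBB is represented by Purkinje-like seeds on the RV side only; the LV free
wall is reached transseptally, reproducing the late-lateral-wall pattern.
CRT (coronary-sinus LV pacing fused with intrinsic conduction) is the
element-wise minimum of the intrinsic map and a map seeded in the LV
lateral wall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .virtual_patient import COLUMNS, LV_COLUMNS, VirtualPatient

__all__ = [
    "PacingProtocol",
    "ConductionParams",
    "ActivationMap",
    "SegmentGraph",
    "build_segment_graph",
    "compute_activation",
    "fuse_maps",
    "calibrate_conduction",
    "sinus_lbbb_protocol",
    "lv_paced_protocol",
]

PACING_MODES = ("sinus_LBBB", "LV_CS_paced_fused", "RV_paced", "BiV")


@dataclass(frozen=True)
class PacingProtocol:
    mode: str
    seeds: tuple                 # ((segment id, onset ms), ...)
    av_delay: float = 100.0      # ms, used by fused modes
    rate: float = 69.0           # bpm (metadata; no frequency dependence)

    def __post_init__(self):
        if self.mode not in PACING_MODES:
            raise ValueError(f"mode must be one of {PACING_MODES}")
        if not self.seeds:
            raise ValueError("at least one pacing seed is required")
        if any(onset < 0 for _, onset in self.seeds):
            raise ValueError("seed onsets must be >= 0")


@dataclass(frozen=True)
class ConductionParams:
    velocity: float = 0.06              # cm/ms, healthy myocardium
    scar_velocity_factor: float = 0.25  # in (0, 1]

    def __post_init__(self):
        if self.velocity <= 0:
            raise ValueError("conduction velocity must be > 0")
        if not (0.0 < self.scar_velocity_factor <= 1.0):
            raise ValueError("scar_velocity_factor must be in (0, 1]")

    def segment_velocity(self, scar_fraction):
        """Local velocity: scar mixes in a slow phase linearly in its fraction."""
        f = np.asarray(scar_fraction)
        return self.velocity * (self.scar_velocity_factor * f + (1.0 - f))


@dataclass(frozen=True)
class ActivationMap:
    segment_ids: np.ndarray
    t_act: np.ndarray            # ms, per segment

    def __post_init__(self):
        if not np.all(np.isfinite(self.t_act)):
            raise ValueError("activation times must be finite")

    def span(self) -> float:
        return float(self.t_act.max() - self.t_act.min())

    def as_dict(self) -> dict:
        return {int(i): float(t) for i, t in zip(self.segment_ids, self.t_act)}

    def shifted(self, offset: float) -> "ActivationMap":
        return replace(self, t_act=self.t_act + offset)


@dataclass(frozen=True)
class SegmentGraph:
    segment_ids: np.ndarray
    edges: tuple                 # ((i, j, distance cm), ...) on segment ids
    index: dict                  # segment id -> array position


def build_segment_graph(patient: VirtualPatient) -> SegmentGraph:
    """Undirected adjacency over segments with Euclidean centroid distances.

    Adjacency, per the documented layout: circumferential ring neighbours
    within a level (anterior–lateral–posterior–septum, with wrap),
    longitudinal neighbours along each column (including the RV column),
    RV–septum bridges at every level, and each apical segment attached to
    its column's deepest level plus the apical ring.
    """
    by_key = {}
    apex, rv = [], []
    for s in patient.segments:
        if s.region == "RV":
            rv.append(s)
        elif s.region == "LV_apex":
            apex.append(s)
        else:
            by_key[(s.column, s.level)] = s
    rv.sort(key=lambda s: s.level)
    apex.sort(key=lambda s: s.id)
    n_levels = max(lv for (_, lv) in by_key) + 1

    pairs = set()

    def connect(a, b):
        pairs.add((min(a.id, b.id), max(a.id, b.id)))

    for level in range(n_levels):
        ring = [by_key[(c, level)] for c in COLUMNS]
        for a, b in zip(ring, ring[1:] + ring[:1]):
            connect(a, b)
    for column in COLUMNS:
        for level in range(n_levels - 1):
            connect(by_key[(column, level)], by_key[(column, level + 1)])
    for level in range(len(rv) - 1):
        connect(rv[level], rv[level + 1])
    for level, seg in enumerate(rv):
        connect(seg, by_key[("septum", min(level, n_levels - 1))])
    for seg in apex:
        connect(seg, by_key[(seg.column, n_levels - 1)])
    for a, b in zip(apex, apex[1:] + apex[:1]):
        if a.id != b.id:
            connect(a, b)

    centroid = {s.id: np.asarray(s.centroid) for s in patient.segments}
    edges = tuple(
        (i, j, float(np.linalg.norm(centroid[i] - centroid[j])))
        for i, j in sorted(pairs))

    ids = np.array(sorted(centroid))
    index = {int(i): k for k, i in enumerate(ids)}
    graph = SegmentGraph(segment_ids=ids, edges=edges, index=index)
    if _n_components(graph) != 1:
        raise ValueError("segment layout produced a disconnected graph")
    return graph


def _n_components(graph: SegmentGraph) -> int:
    m = _travel_time_matrix(graph, np.ones(len(graph.segment_ids)))
    return connected_components(m, directed=False, return_labels=False)


def _travel_time_matrix(graph: SegmentGraph, velocity_per_segment) -> csr_matrix:
    """Symmetric travel-time matrix: half of each edge is traversed at each
    endpoint's local velocity."""
    n = len(graph.segment_ids)
    rows, cols, vals = [], [], []
    for i, j, d in graph.edges:
        a, b = graph.index[i], graph.index[j]
        tt = 0.5 * d / velocity_per_segment[a] + 0.5 * d / velocity_per_segment[b]
        rows += [a, b]
        cols += [b, a]
        vals += [tt, tt]
    return csr_matrix((vals, (rows, cols)), shape=(n, n))


def compute_activation(graph: SegmentGraph, protocol: PacingProtocol,
                       conduction: ConductionParams,
                       patient: VirtualPatient) -> ActivationMap:
    """t_act(i) = min over seeds s of [onset(s) + travel time s→i].

    Exact shortest-path semantics (Dijkstra); an unreachable segment raises
    instead of silently returning infinity.
    """
    scar = np.array([s.scar_fraction for s in
                     sorted(patient.segments, key=lambda s: s.id)])
    ids = graph.segment_ids
    if not np.array_equal(ids, np.sort(patient.segment_ids())):
        raise ValueError("graph and patient segment sets differ")
    for sid, _ in protocol.seeds:
        if sid not in graph.index:
            raise ValueError(f"pacing seed references unknown segment {sid}")

    vel = conduction.segment_velocity(scar)
    m = _travel_time_matrix(graph, vel)
    seed_idx = [graph.index[sid] for sid, _ in protocol.seeds]
    dist = dijkstra(m, directed=False, indices=seed_idx)
    onsets = np.array([onset for _, onset in protocol.seeds])
    t_act = np.min(dist + onsets[:, None], axis=0)
    if not np.all(np.isfinite(t_act)):
        bad = ids[~np.isfinite(t_act)]
        raise ValueError(f"segments unreachable from pacing seeds: {bad.tolist()}")
    return ActivationMap(segment_ids=ids, t_act=t_act)


def fuse_maps(intrinsic: ActivationMap, paced: ActivationMap,
              offset: float = 0.0) -> ActivationMap:
    """Fusion of an intrinsic and a paced wavefront: element-wise minimum of
    (intrinsic shifted by ``offset``) and the paced map."""
    if not np.array_equal(intrinsic.segment_ids, paced.segment_ids):
        raise ValueError("activation maps cover different segment sets")
    return ActivationMap(segment_ids=intrinsic.segment_ids,
                         t_act=np.minimum(intrinsic.t_act + offset, paced.t_act))


def calibrate_conduction(graph: SegmentGraph, protocol: PacingProtocol,
                         patient: VirtualPatient, qrs_target: float,
                         conduction: ConductionParams | None = None,
                         tol: float = 0.1, max_iter: int = 100) -> ConductionParams:
    """Bisect the healthy conduction velocity until the activation span
    (max − min of t_act) matches ``qrs_target`` within ``tol`` ms.

    The scar velocity factor is held at its configured value.
    """
    if qrs_target <= 0:
        raise ValueError("qrs_target must be > 0")
    base = conduction or ConductionParams()

    def span(v):
        return compute_activation(
            graph, protocol, ConductionParams(v, base.scar_velocity_factor),
            patient).span()

    # bracket: span is monotone non-increasing in velocity
    v_lo, v_hi = base.velocity, base.velocity
    for _ in range(60):
        if span(v_lo) >= qrs_target:
            break
        v_lo /= 2.0
    for _ in range(60):
        if span(v_hi) <= qrs_target:
            break
        v_hi *= 2.0
    s_lo, s_hi = span(v_lo), span(v_hi)
    if not (s_hi <= qrs_target <= s_lo):
        raise ValueError(
            f"QRS target {qrs_target} ms not bracketable: achievable span range "
            f"[{s_hi:.2f}, {s_lo:.2f}] ms over velocities [{v_lo:.4g}, {v_hi:.4g}] cm/ms")
    for _ in range(max_iter):
        v_mid = math.sqrt(v_lo * v_hi)
        s_mid = span(v_mid)
        if abs(s_mid - qrs_target) <= tol:
            return ConductionParams(v_mid, base.scar_velocity_factor)
        if s_mid > qrs_target:
            v_lo = v_mid
        else:
            v_hi = v_mid
    raise ValueError("conduction calibration did not converge "
                     f"(last span {s_mid:.3f} ms for target {qrs_target} ms)")


# --------------------------------------------------------------------------
# protocol builders

def sinus_lbbb_protocol(patient: VirtualPatient, onset: float = 0.0,
                        rv_levels=(1, 2)) -> PacingProtocol:
    """Sinus rhythm with LBBB: Purkinje-like seeds on the RV side only, so the
    LV free wall activates transseptally and the lateral wall last."""
    seeds = tuple((s.id, onset) for s in patient.segments_in_region("RV")
                  if s.level in rv_levels)
    return PacingProtocol(mode="sinus_LBBB", seeds=seeds, rate=patient.sinus_rate)


def lv_paced_protocol(patient: VirtualPatient, column: str = "LV_lateral",
                      level: int = 1, onset: float = 0.0) -> PacingProtocol:
    """Epicardial LV pacing from a postero-lateral coronary-sinus branch:
    a single seed on the LV lateral (configurable) wall."""
    if column not in LV_COLUMNS:
        raise ValueError(f"pacing column must be one of {LV_COLUMNS}")
    seg = next(s for s in patient.segments
               if s.region == column and s.level == level)
    return PacingProtocol(mode="LV_CS_paced_fused", seeds=((seg.id, onset),),
                          av_delay=patient.av_delay, rate=patient.paced_rate)
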