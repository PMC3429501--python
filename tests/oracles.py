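"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's own algorithms: activation times are
recomputed by exhaustive simple-path enumeration (depth-first, with an
optional admissible bound so the 24-node default graph stays tractable).
"""

import numpy as np


def edge_travel_time(d, v_i, v_j):
    """Half of each edge is traversed at each endpoint's local velocity."""
    return 0.5 * d / v_i + 0.5 * d / v_j


def brute_force_activation(graph, seeds, velocities, prune=True):
    """Activation times by enumerating simple paths from every seed.

    graph: SegmentGraph; seeds: ((segment id, onset), ...);
    velocities: per-node local conduction velocity (graph order).
    """
    index = graph.index
    n = len(graph.segment_ids)
    adj = {k: [] for k in range(n)}
    for i, j, d in graph.edges:
        a, b = index[i], index[j]
        tt = edge_travel_time(d, velocities[a], velocities[b])
        adj[a].append((b, tt))
        adj[b].append((a, tt))

    best = np.full(n, np.inf)

    def dfs(node, t, visited):
        if prune and t >= best[node]:
            return
        if t < best[node]:
            best[node] = t
        for nxt, tt in adj[node]:
            if nxt not in visited:
                dfs(nxt, t + tt, visited | {nxt})

    for sid, onset in seeds:
        s = index[sid]
        dfs(s, onset, {s})
    return best
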