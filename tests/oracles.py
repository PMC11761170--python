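"""Independent brute-force oracles, written against the definitions only.

Everything here is a plain double loop or textbook iteration, deliberately
sharing no code with the package implementation, for use on small
fixtures.
"""

import numpy as np


def count_matrix(events, nodes):
    """Bidirectional event tally by exhaustive pairwise loop."""
    from apesoc.obs_data import node_for

    ids = [n.node_id for n in nodes]
    m = np.zeros((len(ids), len(ids)))
    for a_i, a in enumerate(ids):
        for b_i, b in enumerate(ids):
            if a_i == b_i:
                continue
            for ev in events:
                na = node_for(nodes, ev.actor_id, ev.event_date).node_id
                nb = node_for(nodes, ev.receiver_id, ev.event_date).node_id
                if {na, nb} == {a, b}:
                    m[a_i, b_i] += 1
    return m


def sri_matrix(scans, nodes):
    """Per-dyad SRI by scanning every record for every dyad; no flooring."""
    from apesoc.obs_data import node_for

    n = len(nodes)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = nodes[i], nodes[j]
            if a.age_class != "silverback" and b.age_class != "silverback":
                continue
            together = apart = 0
            for scan in scans:
                date = scan.scan_datetime.date()
                obs = {node_for(nodes, p, date).node_id for p in scan.observed_ids}
                pair = set()
                if scan.nearest_neighbor_id is not None:
                    pair = {
                        node_for(nodes, scan.silverback_id, date).node_id,
                        node_for(nodes, scan.nearest_neighbor_id, date).node_id,
                    }
                if pair == {a.node_id, b.node_id}:
                    together += 1
                elif a.node_id in obs or b.node_id in obs:
                    apart += 1
            if together + apart > 0:
                m[i, j] = m[j, i] = together / (together + apart)
    return m


def valued_density(values):
    """Mean over every off-diagonal cell, by explicit loop."""
    n = values.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                total += values[i, j]
    return total / (n * (n - 1))


def binary_density(values):
    n = values.shape[0]
    edges = 0
    for i in range(n):
        for j in range(i + 1, n):
            if values[i, j] != 0:
                edges += 1
    return edges / (n * (n - 1) / 2)


def zero_class(values, nodes, removed_class):
    out = values.copy()
    for i, node in enumerate(nodes):
        if node.age_class == removed_class:
            for j in range(len(nodes)):
                out[i, j] = 0.0
                out[j, i] = 0.0
    return out


def power_iteration_centrality(values, tol=1e-13, max_iter=100000):
    """Top-eigenvalue eigenvector by power iteration, scaled to max 1.

    Iterates on the Gershgorin-shifted matrix A + sI so the target
    eigenvalue is the largest in magnitude even on bipartite components
    (whose spectra come in ±λ pairs).
    """
    n = values.shape[0]
    if not values.any():
        return np.zeros(n)
    shifted = values + np.abs(values).sum(axis=1).max() * np.eye(n)
    v = np.ones(n)
    for _ in range(max_iter):
        w = shifted @ v
        w = w / np.linalg.norm(w)
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    v = np.abs(v)
    return v / v.max()
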