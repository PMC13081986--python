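"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive quantities by the most naive route
possible (explicit path enumeration, dense sampling) so they share no code
with the implementation under test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from morphoscreen.swc import NODE_COLUMNS, NeuronReconstruction


def make_recon(rows, soma_id=1, metadata=None) -> NeuronReconstruction:
    """Build a reconstruction from (id, type, x, y, z, radius, parent) rows."""
    nodes = pd.DataFrame(rows, columns=NODE_COLUMNS)
    return NeuronReconstruction(nodes=nodes, soma_id=soma_id,
                                metadata=metadata or {})


@pytest.fixture
def straight_apical():
    """Soma with a straight 100 um apical path (4 nodes, no side branches)."""
    return make_recon([
        (1, 1, 0, 0, 0, 5, -1),
        (2, 4, 0, 30, 0, 1, 1),
        (3, 4, 0, 70, 0, 1, 2),
        (4, 4, 0, 100, 0, 1, 3),
    ])


@pytest.fixture
def three_basal_rays():
    """Three straight 35 um basal rays from the soma along x, y, z."""
    rows = [(1, 1, 0, 0, 0, 5, -1)]
    nid = 2
    for axis in range(3):
        v = np.zeros(3)
        v[axis] = 35.0
        rows.append((nid, 3, *v, 1.0, 1))
        nid += 1
    return make_recon(rows)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_total_length(recon) -> float:
    """Sum of Euclidean edge lengths over dendritic edges, from scratch."""
    pos = {int(r.id): np.array([r.x, r.y, r.z]) for r in recon.nodes.itertuples()}
    typ = {int(r.id): int(r.type) for r in recon.nodes.itertuples()}
    total = 0.0
    for r in recon.nodes.itertuples():
        if r.parent != -1 and typ[int(r.id)] in (3, 4):
            total += float(np.linalg.norm(pos[int(r.id)] - pos[int(r.parent)]))
    return total


def oracle_branch_paths(recon, node_subset=None):
    """Enumerate maximal unbranched paths of the (optionally restricted)
    dendritic subgraph by explicit traversal from every entry point."""
    typ = {int(r.id): int(r.type) for r in recon.nodes.itertuples()}
    edges = []
    for r in recon.nodes.itertuples():
        nid, pid = int(r.id), int(r.parent)
        if pid == -1 or typ[nid] not in (3, 4):
            continue
        if node_subset is not None and nid not in node_subset:
            continue
        edges.append((pid, nid))
    children = {}
    child_nodes = set()
    for p, c in edges:
        children.setdefault(p, []).append(c)
        child_nodes.add(c)
    entries = [p for p in children if p not in child_nodes]
    paths = []
    frontier = [(e, c) for e in entries for c in children[e]]
    while frontier:
        p, c = frontier.pop()
        path = [p, c]
        while len(children.get(c, [])) == 1:
            c = children[c][0]
            path.append(c)
        paths.append(path)
        frontier.extend((c, k) for k in children.get(c, []))
    return paths


def oracle_sholl(recon, step_um, node_subset=None, resolution=0.01):
    """Shell-crossing counts by dense sampling along every edge.

    Samples each edge at ``resolution`` um and counts half-open threshold
    crossings of the sampled soma distance, matching the convention that a
    crossing at radius r belongs to the edge whose far end reaches r.
    """
    pos = {int(r.id): np.array([r.x, r.y, r.z], float)
           for r in recon.nodes.itertuples()}
    typ = {int(r.id): int(r.type) for r in recon.nodes.itertuples()}
    centre = pos[recon.soma_id]
    segs = []
    max_r = 0.0
    for r in recon.nodes.itertuples():
        nid, pid = int(r.id), int(r.parent)
        if pid == -1 or typ[nid] not in (3, 4):
            continue
        if node_subset is not None and nid not in node_subset:
            continue
        a, b = pos[pid] - centre, pos[nid] - centre
        segs.append((a, b))
        max_r = max(max_r, np.linalg.norm(a), np.linalg.norm(b))
    n_shells = int(np.floor(max_r / step_um + 1e-9))
    counts = np.zeros(n_shells, dtype=int)
    for a, b in segs:
        L = np.linalg.norm(b - a)
        n_samp = max(int(np.ceil(L / resolution)), 1)
        t = np.linspace(0.0, 1.0, n_samp + 1)
        radii = np.linalg.norm(a[None, :] + t[:, None] * (b - a)[None, :], axis=1)
        for k in range(1, n_shells + 1):
            r = k * step_um
            lo, hi = radii[:-1], radii[1:]
            up = (lo < r) & (hi >= r)
            down = (lo >= r) & (hi < r)
            counts[k - 1] += int(up.sum() + down.sum())
    return counts


def random_tree_params(rng):
    """Random but valid neuron-template parameters for property tests."""
    from morphoscreen.synth import NeuronSimParams

    trunk = float(rng.uniform(100, 220))
    n_obl = int(rng.integers(0, 4))
    # realistic pyramidal proportions: obliques are short relative to the
    # apical tree remaining beyond their junction (the trunk-terminus rule's
    # premise), so segment length is capped by the inter-junction spacing
    seg_hi = min(35.0, 0.7 * trunk / (n_obl + 1))
    return NeuronSimParams(
        n_basal_roots=int(rng.integers(1, 4)),
        basal_depth=int(rng.integers(0, 3)),
        segment_length_um=float(rng.uniform(min(12.0, seg_hi * 0.8), seg_hi)),
        trunk_length_um=trunk,
        n_obliques=n_obl,
        tuft_depth=int(rng.integers(1, 3)),
        branch_angle_deg=float(rng.uniform(25, 70)),
        jitter_sd_um=float(rng.uniform(0, 2.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
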