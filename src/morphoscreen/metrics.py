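"""Compartment-resolved morphometrics: Sholl profiles, the metric panel, and
spine densities.

Conventions
-----------
* A *branch* is a maximal unbranched path of the compartment-restricted
  subgraph, delimited by entry points, bifurcations, and terminals.  The
  global branch number is the sum over compartments (the trunk, being a
  single path, counts once), so junctions with another compartment do not
  subdivide a branch.
* Metrics that do not apply to a neuron (e.g. tuft metrics when the tuft is
  empty) are missing (NaN), never zero.
* ``height`` is the axis-aligned extent along the configured cortical-depth
  axis (default y); ``width``/``depth_extent`` are the remaining axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .swc import CompartmentLabeling, NeuronReconstruction, DENDRITE_TYPES

COMPARTMENTS = ("basal", "oblique", "tuft", "global")
AXIS_NAMES = ("x", "y", "z")


@dataclass
class ShollProfile:
    radii: np.ndarray
    intersections: np.ndarray
    compartment: str = "global"

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.intersections = np.asarray(self.intersections, dtype=int)
        if len(self.radii) > 1 and not np.all(np.diff(self.radii) > 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(self.intersections < 0):
            raise ValueError("intersections must be non-negative")


@dataclass
class MetricConfig:
    """Knobs for the morphometric engine."""

    step_um: float = 10.0            # Sholl shell spacing
    depth_axis: int = 1              # cortical depth axis (0=x, 1=y, 2=z)
    angle_method: str = "immediate"  # bifurcation angle: immediate children
                                     # or "endpoint" (vectors to branch ends)


@dataclass
class SpineRecord:
    neuron_id: str
    crops: list = field(default_factory=list)  # (length_um, spine_count)


def spine_density(record: SpineRecord) -> float:
    """Length-weighted spine density: total spines / total crop length."""
    total_len = sum(c[0] for c in record.crops)
    total_count = sum(c[1] for c in record.crops)
    if total_len <= 0:
        raise ValueError("total crop length must be positive")
    return total_count / total_len


# ---------------------------------------------------------------------------
# Sholl analysis
# ---------------------------------------------------------------------------

def _compartment_edges(recon: NeuronReconstruction,
                       labeling: CompartmentLabeling | None,
                       compartment: str) -> pd.DataFrame:
    edges = recon.edges(dendrite_only=True)
    if compartment == "global" or labeling is None:
        return edges
    labs = labeling.labels
    keep = [labs.get(int(c)) == compartment for c in edges["child"]]
    return edges[np.asarray(keep, dtype=bool)]


def _edge_shell_crossings(a: np.ndarray, b: np.ndarray, step: float,
                          counts: np.ndarray) -> None:
    """Accumulate crossings of spheres radius k*step by segment a->b.

    The segment is split at the point of minimal distance to the centre so
    each piece has monotone radial distance; on a monotone piece running from
    radius r0 to r1, shell k is crossed once iff min < k*step <= max
    (half-open, so a node exactly on a sphere credits the inbound edge).
    """
    d = b - a
    dd = float(d @ d)
    if dd == 0.0:
        return
    tmin = float(np.clip(-(a @ d) / dd, 0.0, 1.0))
    ts = [0.0, tmin, 1.0] if 0.0 < tmin < 1.0 else [0.0, 1.0]
    for t0, t1 in zip(ts[:-1], ts[1:]):
        r0 = float(np.linalg.norm(a + t0 * d))
        r1 = float(np.linalg.norm(a + t1 * d))
        lo, hi = (r0, r1) if r0 <= r1 else (r1, r0)
        k0 = int(math.floor(lo / step)) + 1     # first shell with k*step > lo
        k1 = int(math.floor(hi / step))         # last shell with k*step <= hi
        for k in range(k0, k1 + 1):
            if k - 1 < len(counts):
                counts[k - 1] += 1


def sholl_profile(recon: NeuronReconstruction,
                  labeling: CompartmentLabeling | None = None,
                  compartment: str = "global",
                  step_um: float = 10.0) -> ShollProfile:
    """Count dendrite crossings of concentric spheres centred on the soma.

    The profile runs from ``step_um`` to the largest multiple of ``step_um``
    not exceeding the compartment's maximal radial distance; an empty
    compartment yields a zero-length profile.
    """
    edges = _compartment_edges(recon, labeling, compartment)
    coords = recon.coords()
    centre = coords[recon.soma_id]
    if len(edges) == 0:
        return ShollProfile(np.array([]), np.array([], dtype=int), compartment)
    max_r = 0.0
    segs = []
    for p, c in zip(edges["parent"], edges["child"]):
        a = coords[int(p)] - centre
        b = coords[int(c)] - centre
        segs.append((a, b))
        max_r = max(max_r, float(np.linalg.norm(a)), float(np.linalg.norm(b)))
    n_shells = int(math.floor(max_r / step_um + 1e-9))
    counts = np.zeros(n_shells, dtype=int)
    for a, b in segs:
        _edge_shell_crossings(a, b, step_um, counts)
    radii = step_um * np.arange(1, n_shells + 1)
    return ShollProfile(radii, counts, compartment)


def sholl_summary(profile: ShollProfile) -> dict[str, float]:
    """Peak radius (smallest maximiser), intersection-weighted centroid
    radius, dispersion (weighted SD of radius), and peak count.

    All-zero or empty profiles give NaN summaries.
    """
    n = profile.intersections.astype(float)
    r = profile.radii
    total = n.sum()
    if len(n) == 0 or total == 0:
        nan = float("nan")
        return {"peak_radius": nan, "centroid_radius": nan,
                "dispersion": nan, "peak_intersections": nan}
    peak_idx = int(np.argmax(n))          # argmax returns the first (smallest r)
    centroid = float((r * n).sum() / total)
    dispersion = float(math.sqrt(((r - centroid) ** 2 * n).sum() / total))
    return {"peak_radius": float(r[peak_idx]),
            "centroid_radius": centroid,
            "dispersion": dispersion,
            "peak_intersections": float(n[peak_idx])}


# ---------------------------------------------------------------------------
# metric registry
# ---------------------------------------------------------------------------

_BASE_METRICS = [
    # (suffix, category, derived_variant)
    ("total_length", "size", False),
    ("height", "size", False),
    ("width", "size", False),
    ("depth_extent", "size", False),
    ("max_euclidean_distance", "size", False),
    ("branch_number", "complexity", False),
    ("tip_number", "complexity", False),
    ("max_branch_order", "complexity", False),
    ("mean_bifurcation_angle", "angle", False),
    ("sholl_peak_radius", "complexity", False),
    ("sholl_centroid_radius", "complexity", False),
    ("sholl_dispersion", "complexity", False),
    ("sholl_peak_intersections", "complexity", False),
    ("mean_branch_length", "size", False),
    ("branch_length_max", "size", True),
    ("branch_length_min", "size", True),
    ("branch_length_median", "size", True),
    ("branch_length_sd", "size", True),
]


def metric_definitions() -> pd.DataFrame:
    """Registry of every metric the engine computes: name, compartment,
    category (size/complexity/angle), and whether it is a derived
    summary-statistic variant (min/median/max/sd) slated for exclusion."""
    rows = [("trunk_length", "trunk", "size", False)]
    for comp in COMPARTMENTS:
        for suffix, cat, derived in _BASE_METRICS:
            rows.append((f"{comp}_{suffix}", comp, cat, derived))
    return pd.DataFrame(rows, columns=["metric", "compartment", "category", "derived_variant"])


# ---------------------------------------------------------------------------
# metric computation
# ---------------------------------------------------------------------------

def _branch_decomposition(edges: pd.DataFrame) -> list[list[tuple[int, int]]]:
    """Maximal unbranched paths (lists of edges) of an edge-restricted
    subgraph.  A path ends at nodes whose out-degree differs from 1."""
    children: dict[int, list[int]] = {}
    has_parent: set[int] = set()
    length = {}
    for p, c, ln in zip(edges["parent"], edges["child"], edges["length"]):
        children.setdefault(int(p), []).append(int(c))
        has_parent.add(int(c))
        length[(int(p), int(c))] = float(ln)
    starts = [n for n in children if n not in has_parent]
    # also restart at bifurcation nodes
    paths = []
    stack = [(s, c) for s in starts for c in children[s]]
    while stack:
        p, c = stack.pop()
        path = [(p, c)]
        while len(children.get(c, [])) == 1:
            nxt = children[c][0]
            path.append((c, nxt))
            c = nxt
        paths.append(path)
        for k in children.get(c, []):
            stack.append((c, k))
    return paths


def _branch_lengths(edges: pd.DataFrame) -> list[float]:
    lengths = {(int(p), int(c)): float(ln)
               for p, c, ln in zip(edges["parent"], edges["child"], edges["length"])}
    return [sum(lengths[e] for e in path) for path in _branch_decomposition(edges)]


def _branch_orders(recon: NeuronReconstruction) -> dict[int, int]:
    """Branch order per node: number of bifurcations (dendritic nodes with
    >=2 dendritic children) strictly between the soma and the node."""
    ch = recon.children_map()
    types = dict(zip((int(i) for i in recon.nodes["id"]),
                     (int(t) for t in recon.nodes["type"])))
    dend_children = {n: [c for c in kids if types[c] in DENDRITE_TYPES]
                     for n, kids in ch.items()}
    orders: dict[int, int] = {}
    root = recon.soma_id
    stack = [(root, 0)]
    while stack:
        n, order = stack.pop()
        orders[n] = order
        kids = dend_children.get(n, [])
        bump = 1 if (len(kids) >= 2 and types.get(n) in DENDRITE_TYPES) else 0
        for c in ch.get(n, []):
            stack.append((c, order + bump))
    return orders


def _bifurcation_angles(recon: NeuronReconstruction, node_set: set[int],
                        method: str = "immediate") -> list[float]:
    ch = recon.children_map()
    coords = recon.coords()
    types = dict(zip((int(i) for i in recon.nodes["id"]),
                     (int(t) for t in recon.nodes["type"])))
    def branch_end(start: int) -> int:
        # endpoint of the unbranched path starting at ``start``
        n = start
        while True:
            kids = [c for c in ch.get(n, []) if types[c] in DENDRITE_TYPES]
            if len(kids) != 1:
                return n
            n = kids[0]

    angles = []
    for n in node_set:
        kids = [c for c in ch.get(n, []) if types[c] in DENDRITE_TYPES]
        if len(kids) < 2:
            continue
        vecs = []
        for c in kids:
            target = c if method == "immediate" else branch_end(c)
            v = coords[target] - coords[n]
            nv = np.linalg.norm(v)
            if nv > 0:
                vecs.append(v / nv)
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                cosang = float(np.clip(vecs[i] @ vecs[j], -1.0, 1.0))
                angles.append(math.degrees(math.acos(cosang)))
    return angles


def compute_metrics(recon: NeuronReconstruction,
                    labeling: CompartmentLabeling,
                    config: MetricConfig | None = None) -> pd.Series:
    """One morphometric-table row for a QC-passed, labeled reconstruction."""
    if labeling is None:
        raise ValueError("compute_metrics requires a compartment labeling")
    config = config or MetricConfig()
    coords = recon.coords()
    soma = coords[recon.soma_id]
    ch = recon.children_map()
    types = dict(zip((int(i) for i in recon.nodes["id"]),
                     (int(t) for t in recon.nodes["type"])))
    labs = labeling.labels
    orders = _branch_orders(recon)

    out: dict[str, float] = {}

    # trunk length: path length soma -> trunk terminus (= trunk path length)
    trunk_edges = _compartment_edges(recon, labeling, "trunk")
    out["trunk_length"] = float(trunk_edges["length"].sum()) if len(trunk_edges) else np.nan

    axes = [config.depth_axis] + [a for a in range(3) if a != config.depth_axis]
    extent_names = ["height", "width", "depth_extent"]

    for comp in COMPARTMENTS:
        edges = _compartment_edges(recon, labeling, comp)
        prefix = f"{comp}_"
        if len(edges) == 0:
            for suffix, _, _ in _BASE_METRICS:
                out[prefix + suffix] = np.nan
            continue
        if comp == "global":
            node_set = {n for n, t in types.items() if t in DENDRITE_TYPES}
        else:
            node_set = {n for n, lab in labs.items() if lab == comp}

        out[prefix + "total_length"] = float(edges["length"].sum())
        pts = np.array([coords[n] for n in node_set])
        for name, axis in zip(extent_names, axes):
            out[prefix + name] = float(pts[:, axis].max() - pts[:, axis].min())
        out[prefix + "max_euclidean_distance"] = float(
            max(np.linalg.norm(coords[n] - soma) for n in node_set))

        if comp == "global":
            # compartment-restricted decomposition: junctions with another
            # compartment do not subdivide a branch, so the global count is
            # the sum over compartments (trunk counted once)
            blens = []
            for sub in ("basal", "trunk", "oblique", "tuft"):
                sub_edges = _compartment_edges(recon, labeling, sub)
                if len(sub_edges):
                    blens.extend(_branch_lengths(sub_edges))
        else:
            blens = _branch_lengths(edges)
        out[prefix + "branch_number"] = float(len(blens))
        out[prefix + "mean_branch_length"] = float(np.mean(blens))
        out[prefix + "branch_length_max"] = float(np.max(blens))
        out[prefix + "branch_length_min"] = float(np.min(blens))
        out[prefix + "branch_length_median"] = float(np.median(blens))
        out[prefix + "branch_length_sd"] = float(np.std(blens, ddof=1)) if len(blens) > 1 else np.nan

        tips = [n for n in node_set
                if not any(types[c] in DENDRITE_TYPES for c in ch.get(n, []))]
        out[prefix + "tip_number"] = float(len(tips))
        out[prefix + "max_branch_order"] = float(max(orders[n] for n in node_set))

        bif_nodes = node_set if comp != "global" else node_set
        angs = _bifurcation_angles(recon, bif_nodes, config.angle_method)
        out[prefix + "mean_bifurcation_angle"] = float(np.mean(angs)) if angs else np.nan

        prof = sholl_profile(recon, labeling, comp, config.step_um)
        summ = sholl_summary(prof)
        out[prefix + "sholl_peak_radius"] = summ["peak_radius"]
        out[prefix + "sholl_centroid_radius"] = summ["centroid_radius"]
        out[prefix + "sholl_dispersion"] = summ["dispersion"]
        out[prefix + "sholl_peak_intersections"] = summ["peak_intersections"]

    return pd.Series(out, name=recon.metadata.get("neuron_id"))


def morphometric_table(neurons: list[tuple[NeuronReconstruction, CompartmentLabeling]],
                       config: MetricConfig | None = None) -> pd.DataFrame:
    """Stack per-neuron metric rows into a neurons x metrics table."""
    rows = [compute_metrics(r, lab, config) for r, lab in neurons]
    table = pd.DataFrame(rows)
    table.index = [r.metadata.get("neuron_id", i) for i, (r, _) in enumerate(neurons)]
    return table
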