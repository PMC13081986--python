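"""SWC reconstruction I/O, quality control, and dendritic compartment labeling.

The SWC dialect used throughout is the de-facto standard: whitespace-delimited
7-column records ``id type x y z radius parent``, ``#`` comments, parent ``-1``
for a root, structure codes 1=soma, 2=axon, 3=basal dendrite, 4=apical
dendrite.  Coordinates and radii are micrometres.  Node ids need not be
ordered: the parser tolerates children appearing before their parents.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SOMA, AXON, BASAL, APICAL = 1, 2, 3, 4
DENDRITE_TYPES = (BASAL, APICAL)

NODE_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]


class SWCError(ValueError):
    """Malformed SWC content (duplicate ids, cycles, unresolved parents)."""


@dataclass
class NeuronReconstruction:
    """A rooted (possibly multi-component) tree of 3D points plus metadata.

    ``nodes`` is a DataFrame with columns ``id type x y z radius parent``;
    ``parent`` is ``-1`` for roots.  ``soma_id`` is the id of the primary
    root.  Extra roots (disconnected components) are permitted after parsing
    and are resolved or reported by :func:`qc_repair`.
    """

    nodes: pd.DataFrame
    soma_id: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = self.nodes["id"].to_numpy()
        if len(ids) != len(set(ids)):
            raise SWCError("duplicate node ids")

    # -- structural helpers -------------------------------------------------

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {int(i): [] for i in self.nodes["id"]}
        for nid, pid in zip(self.nodes["id"], self.nodes["parent"]):
            if pid != -1:
                out[int(pid)].append(int(nid))
        return out

    def roots(self) -> list[int]:
        return [int(i) for i in self.nodes.loc[self.nodes["parent"] == -1, "id"]]

    def coords(self) -> dict[int, np.ndarray]:
        xyz = self.nodes[["x", "y", "z"]].to_numpy(float)
        return {int(i): xyz[k] for k, i in enumerate(self.nodes["id"])}

    def edge_length(self, child_id: int) -> float:
        row = self.nodes.set_index("id")
        c = row.loc[child_id]
        p = row.loc[int(c["parent"])]
        return float(math.dist((c["x"], c["y"], c["z"]), (p["x"], p["y"], p["z"])))

    def edges(self, dendrite_only: bool = True) -> pd.DataFrame:
        """Edges as a frame (parent, child, length, child_type)."""
        ids = self.nodes["id"].to_numpy()
        parents = self.nodes["parent"].to_numpy()
        types = self.nodes["type"].to_numpy()
        xyz = self.nodes[["x", "y", "z"]].to_numpy(float)
        mask = parents != -1
        if dendrite_only:
            mask &= np.isin(types, DENDRITE_TYPES)
        child_pos = xyz[mask]
        pidx = pd.Index(ids).get_indexer(parents[mask])
        lengths = np.linalg.norm(child_pos - xyz[pidx], axis=1)
        return pd.DataFrame({"parent": parents[mask], "child": ids[mask],
                             "length": lengths, "child_type": types[mask]})

    def total_dendritic_length(self) -> float:
        e = self.edges(dendrite_only=True)
        return float(e["length"].sum()) if len(e) else 0.0


@dataclass
class QCReport:
    n_overbranched: int = 0
    n_short_branches_removed: int = 0
    n_disconnected_components: int = 0
    repaired: dict = field(default_factory=dict)
    actions: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(self.repaired.get(k, True) for k in
                   ("overbranched", "short_branches", "disconnected"))

    def to_dict(self) -> dict:
        return {
            "n_overbranched": self.n_overbranched,
            "n_short_branches_removed": self.n_short_branches_removed,
            "n_disconnected_components": self.n_disconnected_components,
            "repaired": dict(self.repaired),
            "pass": self.passed,
            "actions": list(self.actions),
        }


@dataclass
class CompartmentLabeling:
    """Per-node compartment labels: soma / basal / trunk / oblique / tuft."""

    labels: dict[int, str]
    trunk_terminus: int | None = None

    def nodes_in(self, compartment: str) -> list[int]:
        return [n for n, lab in self.labels.items() if lab == compartment]


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

def read_swc(path, metadata: dict | None = None) -> NeuronReconstruction:
    """Parse an SWC file into a :class:`NeuronReconstruction`.

    Raises :class:`SWCError` naming the offending line for duplicate ids,
    unresolved parent references, or cyclic parent chains.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0]); typ = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise SWCError(f"line {lineno}: unparsable field ({exc})") from None
            records.append((nid, typ, x, y, z, r, pid, lineno))

    if not records:
        raise SWCError("empty SWC file")

    seen: dict[int, int] = {}
    for nid, *_, lineno in records:
        if nid in seen:
            raise SWCError(f"line {lineno}: duplicate id {nid} (first at line {seen[nid]})")
        seen[nid] = lineno
    for nid, typ, x, y, z, r, pid, lineno in records:
        if pid != -1 and pid not in seen:
            raise SWCError(f"line {lineno}: unresolved parent {pid}")

    # cycle check by walking parent chains
    parent = {nid: pid for nid, typ, x, y, z, r, pid, _ in records}
    state: dict[int, int] = {}
    for start in parent:
        chain = []
        n = start
        while n != -1 and state.get(n, 0) == 0:
            state[n] = 1
            chain.append(n)
            n = parent[n]
        if n != -1 and state.get(n) == 1:
            raise SWCError(f"line {seen[n]}: cyclic parent reference at id {n}")
        for c in chain:
            state[c] = 2

    nodes = pd.DataFrame(
        [(nid, typ, x, y, z, r, pid) for nid, typ, x, y, z, r, pid, _ in records],
        columns=NODE_COLUMNS,
    )
    root_ids = nodes.loc[nodes["parent"] == -1, "id"]
    if root_ids.empty:
        raise SWCError("no root node (parent -1) found")
    soma_rows = nodes[(nodes["parent"] == -1) & (nodes["type"] == SOMA)]
    soma_id = int(soma_rows["id"].iloc[0]) if len(soma_rows) else int(root_ids.iloc[0])
    return NeuronReconstruction(nodes=nodes, soma_id=soma_id, metadata=metadata or {})


def write_swc(recon: NeuronReconstruction, path) -> None:
    """Write SWC; round-trips topology and coordinates exactly (repr floats)."""
    if len(recon.nodes) == 0:
        raise SWCError("refusing to write an empty reconstruction")
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for row in recon.nodes.itertuples(index=False):
            fh.write(f"{int(row.id)} {int(row.type)} {row.x!r} {row.y!r} "
                     f"{row.z!r} {row.radius!r} {int(row.parent)}\n")


def reindex_preorder(recon: NeuronReconstruction) -> NeuronReconstruction:
    """Re-number nodes 1..N in pre-order (root first), remapping parents."""
    ch = recon.children_map()
    order: list[int] = []
    for root in recon.roots():
        stack = [root]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(sorted(ch[n], reverse=True))
    mapping = {old: new for new, old in enumerate(order, start=1)}
    nodes = recon.nodes.set_index("id").loc[order].reset_index()
    nodes["id"] = [mapping[i] for i in nodes["id"]]
    nodes["parent"] = [mapping[p] if p != -1 else -1 for p in nodes["parent"]]
    return NeuronReconstruction(nodes=nodes, soma_id=mapping[recon.soma_id],
                                metadata=dict(recon.metadata))


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def _terminal_branch(recon: NeuronReconstruction, tip: int, ch: dict, idx) -> tuple[list[int], float]:
    """Nodes (tip upward, excluding the branch point) and path length of the
    terminal branch ending at ``tip``."""
    nodes = [tip]
    length = 0.0
    n = tip
    while True:
        pid = int(idx.loc[n, "parent"])
        if pid == -1:
            break
        dx = idx.loc[n, ["x", "y", "z"]].to_numpy(float) - idx.loc[pid, ["x", "y", "z"]].to_numpy(float)
        length += float(np.linalg.norm(dx))
        if len(ch[pid]) > 1 or int(idx.loc[pid, "parent"]) == -1:
            break
        n = pid
        nodes.append(n)
    return nodes, length


def _prune_short_branches(recon: NeuronReconstruction,
                          min_branch_um: float) -> tuple[NeuronReconstruction, int]:
    """Iteratively remove terminal dendritic branches shorter than the
    threshold until none remain (a pruned spur may expose a new one)."""
    work = recon
    removed = 0
    while True:
        ch = work.children_map()
        idx = work.nodes.set_index("id")
        tips = [n for n, c in ch.items() if not c
                and int(idx.loc[n, "type"]) in DENDRITE_TYPES]
        pruned_any = False
        for tip in tips:
            branch, length = _terminal_branch(work, tip, ch, idx)
            if length < min_branch_um:
                work = NeuronReconstruction(
                    work.nodes[~work.nodes["id"].isin(branch)].reset_index(drop=True),
                    work.soma_id, dict(work.metadata))
                removed += 1
                pruned_any = True
                break  # recompute maps after each pruning
        if not pruned_any:
            break
    return work, removed


def qc_repair(
    recon: NeuronReconstruction,
    min_branch_um: float = 1.0,
    resolve_overbranched: bool = False,
    reattach_tolerance_um: float | None = 10.0,
) -> tuple[NeuronReconstruction, QCReport]:
    """Apply reconstruction QC: prune spurious short terminal branches
    (< ``min_branch_um`` path length, iteratively to a fixed point), report
    over-branched nodes (> 2 daughters; optionally resolved by splitting the
    closest daughter onto an inserted zero-length node), and reattach or drop
    disconnected components.

    Always returns a report; never raises on defects.
    """
    report = QCReport()

    # --- short terminal branches, pass 1 (all components) ------------------
    work, n_removed = _prune_short_branches(recon, min_branch_um)

    # --- disconnected components ------------------------------------------
    nodes = work.nodes.copy()
    roots = work.roots()
    extra_roots = [r for r in roots if r != _primary_root(work)]
    report.n_disconnected_components = len(extra_roots)
    if extra_roots:
        coords = work.coords()
        main = _component_nodes(work, _primary_root(work))
        for r in extra_roots:
            comp = _component_nodes(work, r)
            # nearest main-component node to the stray root
            best, bestd = None, np.inf
            for m in main:
                d = float(np.linalg.norm(coords[m] - coords[r]))
                if d < bestd:
                    best, bestd = m, d
            if reattach_tolerance_um is not None and bestd <= reattach_tolerance_um:
                nodes.loc[nodes["id"] == r, "parent"] = best
                main |= comp
                report.actions.append(f"reattached component rooted at {r} to {best} (gap {bestd:.3g} um)")
            else:
                nodes = nodes[~nodes["id"].isin(comp)]
                report.actions.append(f"dropped component rooted at {r} ({len(comp)} nodes)")
        work = NeuronReconstruction(nodes.reset_index(drop=True), recon.soma_id, dict(recon.metadata))
    report.repaired["disconnected"] = True

    # --- short terminal branches, pass 2 (reattachment can expose new
    # sub-threshold terminals) ----------------------------------------------
    work, n_removed_2 = _prune_short_branches(work, min_branch_um)
    report.n_short_branches_removed = n_removed + n_removed_2
    report.repaired["short_branches"] = True

    # --- over-branched nodes ----------------------------------------------
    ch = work.children_map()
    idx = work.nodes.set_index("id")
    over = [n for n, c in ch.items() if len(c) > 2 and int(idx.loc[n, "type"]) != SOMA]
    report.n_overbranched = len(over)
    if over and resolve_overbranched:
        nodes = work.nodes.copy()
        next_id = int(nodes["id"].max()) + 1
        pos = {int(r.id): np.array([r.x, r.y, r.z], float)
               for r in nodes.itertuples()}
        for n in over:
            daughters = list(ch[n])
            pn = pos[n]
            row = idx.loc[n]
            while len(daughters) > 2:
                # move the two daughters closest to the node onto an inserted
                # zero-length intermediate, reducing the daughter count by one
                order = sorted(daughters,
                               key=lambda d: float(np.linalg.norm(pos[d] - pn)))
                d1, d2 = order[0], order[1]
                new = pd.DataFrame([[next_id, int(row["type"]), row["x"],
                                     row["y"], row["z"], row["radius"], n]],
                                   columns=NODE_COLUMNS)
                nodes.loc[nodes["id"].isin([d1, d2]), "parent"] = next_id
                nodes = pd.concat([nodes, new], ignore_index=True)
                pos[next_id] = pn.copy()
                daughters = [d for d in daughters if d not in (d1, d2)] + [next_id]
                next_id += 1
            report.actions.append(f"split daughters of over-branched node {n}")
        work = NeuronReconstruction(nodes, work.soma_id, dict(work.metadata))
        report.repaired["overbranched"] = True
    else:
        report.repaired["overbranched"] = not over

    return work, report


def _primary_root(recon: NeuronReconstruction) -> int:
    roots = recon.roots()
    return recon.soma_id if recon.soma_id in roots else roots[0]


def _component_nodes(recon: NeuronReconstruction, root: int) -> set[int]:
    ch = recon.children_map()
    out, stack = set(), [root]
    while stack:
        n = stack.pop()
        out.add(n)
        stack.extend(ch[n])
    return out


# ---------------------------------------------------------------------------
# compartment labeling
# ---------------------------------------------------------------------------

def _subtree_lengths(recon: NeuronReconstruction) -> dict[int, float]:
    """Total path length of the subtree rooted at each node (edges below it,
    including the edge from its parent? no: edges strictly below the node)."""
    ch = recon.children_map()
    coords = recon.coords()
    out: dict[int, float] = {}
    order: list[int] = []
    for root in recon.roots():
        stack = [root]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(ch[n])
    for n in reversed(order):
        total = 0.0
        for c in ch[n]:
            total += out[c] + float(np.linalg.norm(coords[c] - coords[n]))
        out[n] = total
    return out


def label_compartments(
    recon: NeuronReconstruction, trunk_split_ratio: float = 0.33
) -> CompartmentLabeling:
    """Assign each dendritic node to basal / trunk / oblique / tuft.

    Basal nodes are all type-3 subtrees.  Within the apical (type-4) subtree
    the trunk is traced from the apical root by always descending into the
    daughter with the largest total subtree path length; the trunk terminus is
    the first bifurcation where the second-largest daughter subtree is at
    least ``trunk_split_ratio`` of the largest, else the end of that
    maximal-length path.  Tuft nodes are the strict descendants of the
    terminus; obliques are the off-trunk side subtrees proximal to it.
    """
    ch = recon.children_map()
    types = dict(zip((int(i) for i in recon.nodes["id"]), (int(t) for t in recon.nodes["type"])))
    labels: dict[int, str] = {}
    for n, t in types.items():
        if t == SOMA:
            labels[n] = "soma"
        elif t == BASAL:
            labels[n] = "basal"

    apical_nodes = [n for n, t in types.items() if t == APICAL]
    if not apical_nodes:
        warnings.warn("no apical subtree: trunk/oblique/tuft empty", stacklevel=2)
        return CompartmentLabeling(labels, trunk_terminus=None)

    sub = _subtree_lengths(recon)
    coords = recon.coords()

    # apical roots: apical nodes whose parent is not apical
    apical_roots = [n for n in apical_nodes
                    if recon.nodes.set_index("id").loc[n, "parent"] == -1
                    or types.get(int(recon.nodes.set_index("id").loc[n, "parent"]), 0) != APICAL]

    def subtree_len_with_edge(parent: int, child: int) -> float:
        return sub[child] + float(np.linalg.norm(coords[child] - coords[parent]))

    trunk: list[int] = []
    terminus: int | None = None
    n = apical_roots[0]
    while True:
        trunk.append(n)
        kids = [k for k in ch[n] if types[k] == APICAL]
        if not kids:
            terminus = None  # trunk runs to the end of the maximal path
            break
        if len(kids) == 1:
            n = kids[0]
            continue
        lens = sorted(((subtree_len_with_edge(n, k), k) for k in kids), reverse=True)
        largest, second = lens[0][0], lens[1][0]
        if largest > 0 and second / largest >= trunk_split_ratio:
            terminus = n
            break
        n = lens[0][1]

    for t in trunk:
        labels[t] = "trunk"

    def fill(start: int, lab: str) -> None:
        stack = [start]
        while stack:
            m = stack.pop()
            labels[m] = lab
            stack.extend(k for k in ch[m] if types[k] == APICAL)

    trunk_set = set(trunk)
    if terminus is not None:
        for k in ch[terminus]:
            if types[k] == APICAL:
                fill(k, "tuft")
    # obliques: apical side subtrees off trunk-interior nodes
    for t in trunk:
        if t == terminus:
            continue
        for k in ch[t]:
            if types[k] == APICAL and k not in trunk_set and labels.get(k) != "tuft":
                fill(k, "oblique")

    return CompartmentLabeling(labels, trunk_terminus=terminus)


def filter_by_layer(metadata: pd.DataFrame, boundary_depth: float,
                    depth_column: str = "soma_depth") -> pd.DataFrame:
    """Drop neurons whose soma lies beyond (deeper than) ``boundary_depth``.

    Mirrors the exclusion of neurons with somata below the layer-4/5
    boundary.  Returns retained records; warns when nothing survives.
    """
    keep = metadata[metadata[depth_column] <= boundary_depth].copy()
    n_removed = len(metadata) - len(keep)
    keep.attrs["n_removed"] = n_removed
    if len(keep) == 0 and len(metadata) > 0:
        warnings.warn("all neurons fall below the layer boundary", stacklevel=2)
    return keep
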