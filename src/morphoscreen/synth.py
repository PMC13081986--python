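"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be simulated here: branched pyramidal
neuron arbors (basal / trunk / oblique / tuft structure, optional QC
defects), perturbation-screen cohorts with brain-of-origin random effects and
geometrically injected metric shifts, negative-binomial count matrices with
batch structure and known log fold-changes, dual-guide assignment tables with
known vector pairing, and three-age developmental pseudobulk series.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .swc import (APICAL, BASAL, SOMA, NODE_COLUMNS, CompartmentLabeling,
                  NeuronReconstruction)

# ---------------------------------------------------------------------------
# neuron arbors
# ---------------------------------------------------------------------------

#: metric knobs the cohort generator can shift geometrically; each
#: compartment is driven by exactly one knob so an injected standardized
#: effect maps one-to-one onto that compartment's metric variation
EFFECT_KNOBS = {
    "basal_height": "basal",
    "tuft_height": "tuft",
    "trunk_length": "trunk",
    "oblique_length": "oblique",
}


@dataclass
class NeuronSimParams:
    """Template for one synthetic pyramidal arbor (lengths in micrometres)."""

    n_basal_roots: int = 3
    basal_depth: int = 2          # binary branch orders below each basal root
    segment_length_um: float = 25.0
    trunk_length_um: float = 180.0
    n_obliques: int = 3
    tuft_depth: int = 2
    branch_angle_deg: float = 40.0
    jitter_sd_um: float = 1.0
    depth_axis: int = 1
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_basal_roots, self.basal_depth, self.n_obliques,
               self.tuft_depth) < 0:
            raise ValueError("counts must be non-negative")
        if self.segment_length_um <= 0:
            raise ValueError("segment_length_um must be positive")
        if self.trunk_length_um < 0:
            raise ValueError("trunk_length_um must be non-negative")
        if self.trunk_length_um == 0 and (self.n_obliques > 0 or self.tuft_depth > 0):
            raise ValueError("obliques/tuft require a trunk (trunk_length_um > 0)")
        if self.jitter_sd_um < 0:
            raise ValueError("jitter_sd_um must be non-negative")
        if self.depth_axis not in (0, 1, 2):
            raise ValueError("depth_axis must be 0, 1, or 2")


def _frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to u (deterministic)."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 0.0, 1.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _tilt(u: np.ndarray, angle_deg: float, azimuth_deg: float) -> np.ndarray:
    e1, e2 = _frame(u)
    a = math.radians(angle_deg)
    b = math.radians(azimuth_deg)
    return math.cos(a) * u + math.sin(a) * (math.cos(b) * e1 + math.sin(b) * e2)


class _Builder:
    def __init__(self, rng: np.random.Generator, jitter: float):
        self.rng = rng
        self.jitter = jitter
        self.rows: list[list] = []
        self.labels: dict[int, str] = {}
        self.next_id = 1

    def add(self, typ: int, pos: np.ndarray, parent: int, label: str,
            radius: float = 1.0) -> int:
        nid = self.next_id
        self.next_id += 1
        self.rows.append([nid, typ, float(pos[0]), float(pos[1]), float(pos[2]),
                          radius, parent])
        self.labels[nid] = label
        return nid

    def pos(self, nid: int) -> np.ndarray:
        for row in self.rows:
            if row[0] == nid:
                return np.array(row[2:5])
        raise KeyError(nid)

    def jittered(self, p: np.ndarray) -> np.ndarray:
        if self.jitter > 0:
            return p + self.rng.normal(0.0, self.jitter, size=3)
        return p


def _grow_binary(b: _Builder, parent: int, parent_pos: np.ndarray,
                 direction: np.ndarray, depth: int, seg_len: float,
                 angle: float, typ: int, label: str, azimuth: float) -> None:
    tip = b.jittered(parent_pos + seg_len * direction)
    nid = b.add(typ, tip, parent, label)
    if depth <= 0:
        return
    for sign in (+1, -1):
        child_dir = _tilt(direction, sign * angle / 2.0, azimuth)
        _grow_binary(b, nid, tip, child_dir, depth - 1, seg_len, angle, typ,
                     label, azimuth + 137.5)


def gen_neuron(params: NeuronSimParams,
               scale: dict[str, float] | None = None,
               metadata: dict | None = None
               ) -> tuple[NeuronReconstruction, CompartmentLabeling, dict]:
    """Generate one SWC-conformant arbor plus ground-truth compartment labels
    and a record of exact construction-implied quantities.

    ``scale`` optionally multiplies segment lengths per compartment
    (keys: basal, trunk, oblique, tuft, all) — the hook used by
    :func:`gen_screen_cohort` to inject geometric effects.
    """
    params.validate()
    sc = {"basal": 1.0, "trunk": 1.0, "oblique": 1.0, "tuft": 1.0, "all": 1.0}
    sc.update(scale or {})
    rng = np.random.default_rng(params.seed)
    b = _Builder(rng, params.jitter_sd_um)

    axis = params.depth_axis
    up = np.zeros(3)
    up[axis] = 1.0

    soma = b.add(SOMA, np.zeros(3), -1, "soma", radius=5.0)

    # basal arbors: roots pointing below the horizontal plane
    seg_b = params.segment_length_um * sc["basal"] * sc["all"]
    for i in range(params.n_basal_roots):
        az = 360.0 * i / max(params.n_basal_roots, 1)
        root_dir = _tilt(-up, 50.0, az)
        _grow_binary(b, soma, np.zeros(3), root_dir, params.basal_depth,
                     seg_b, params.branch_angle_deg, BASAL, "basal", az + 60.0)

    # apical trunk with oblique side branches and a distal tuft
    trunk_top = soma
    trunk_top_pos = np.zeros(3)
    if params.trunk_length_um > 0:
        L = params.trunk_length_um * sc["trunk"] * sc["all"]
        n_junc = params.n_obliques
        fracs = [(i + 1) / (n_junc + 1) for i in range(n_junc)] + [1.0]
        prev, prev_pos, prev_frac = soma, np.zeros(3), 0.0
        junctions = []
        for frac in fracs:
            ideal = prev_pos + (frac - prev_frac) * L * up
            pos = b.jittered(ideal) if frac < 1.0 else b.jittered(prev_pos + (frac - prev_frac) * L * up)
            nid = b.add(APICAL, pos, prev, "trunk")
            junctions.append((nid, pos))
            prev, prev_pos, prev_frac = nid, pos, frac
        trunk_top, trunk_top_pos = junctions[-1]
        seg_o = params.segment_length_um * sc["oblique"] * sc["all"]
        for i, (jid, jpos) in enumerate(junctions[:-1]):
            d = _tilt(up, 90.0 - params.branch_angle_deg / 2.0, 137.5 * i)
            b.add(APICAL, b.jittered(jpos + seg_o * d), jid, "oblique")

    if params.tuft_depth > 0:
        seg_t = params.segment_length_um * sc["tuft"] * sc["all"]
        for sign in (+1, -1):
            d = _tilt(up, sign * params.branch_angle_deg / 2.0, 30.0)
            _grow_binary(b, trunk_top, trunk_top_pos, d, params.tuft_depth - 1,
                         seg_t, params.branch_angle_deg, APICAL, "tuft", 210.0)

    nodes = pd.DataFrame(b.rows, columns=NODE_COLUMNS)
    recon = NeuronReconstruction(nodes=nodes, soma_id=soma,
                                 metadata=metadata or {})
    terminus = trunk_top if params.tuft_depth > 0 else None
    labeling = CompartmentLabeling(dict(b.labels), trunk_terminus=terminus)
    record = _construction_record(recon, labeling, params)
    return recon, labeling, record


def _construction_record(recon: NeuronReconstruction,
                         labeling: CompartmentLabeling,
                         params: NeuronSimParams) -> dict:
    """Exact per-compartment counts/lengths implied by the construction,
    computed by direct summation over the generated node table (independent
    of the morphometric engine)."""
    coords = recon.coords()
    labs = labeling.labels
    idx = recon.nodes.set_index("id")
    comp_len = {c: 0.0 for c in ("basal", "trunk", "oblique", "tuft")}
    for nid, pid in zip(recon.nodes["id"], recon.nodes["parent"]):
        if pid == -1:
            continue
        lab = labs[int(nid)]
        if lab in comp_len:
            comp_len[lab] += float(np.linalg.norm(coords[int(nid)] - coords[int(pid)]))
    axis = params.depth_axis

    def extent(lab: str) -> float:
        pts = [coords[n][axis] for n, l in labs.items() if l == lab]
        return max(pts) - min(pts) if pts else float("nan")

    basal_branches = params.n_basal_roots * (2 ** (params.basal_depth + 1) - 1)
    tuft_branches = (2 ** (params.tuft_depth + 1) - 2) if params.tuft_depth > 0 else 0
    return {
        "basal_branch_number": basal_branches,
        "oblique_branch_number": params.n_obliques,
        "tuft_branch_number": tuft_branches,
        "trunk_length": comp_len["trunk"],
        "basal_length": comp_len["basal"],
        "oblique_length": comp_len["oblique"],
        "tuft_length": comp_len["tuft"],
        "total_length": sum(comp_len.values()),
        "basal_height": extent("basal"),
        "tuft_height": extent("tuft"),
    }


# ---------------------------------------------------------------------------
# screen cohorts
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimParams:
    """Design of a simulated morphology screen.

    ``true_effects`` maps (perturbation, metric knob) to a standardized
    effect; supported knobs are the keys of :data:`EFFECT_KNOBS`.  Brain and
    residual SDs are on the standardized latent-trait scale (defaults sum to
    ~unit total variance so injected effects are in SD units).
    """

    perturbations: tuple = ("control", "pertA", "pertB")
    true_effects: dict = field(default_factory=dict)
    n_brains_per_arm: int = 6
    neurons_per_brain: int = 10
    brain_sd: float = 0.3
    residual_sd: float = 0.95
    rel_scale: float = 0.15      # multiplier change per latent SD
    control_label: str = "control"
    seed: int = 0

    def validate(self) -> None:
        if self.n_brains_per_arm < 2:
            raise ValueError("need at least 2 brains per arm")
        if self.brain_sd < 0 or self.residual_sd < 0:
            raise ValueError("variance components must be non-negative")
        for (pert, metric), eff in self.true_effects.items():
            if metric not in EFFECT_KNOBS:
                raise ValueError(f"unknown metric knob {metric!r}; "
                                 f"supported: {sorted(EFFECT_KNOBS)}")
            if pert not in self.perturbations:
                raise ValueError(f"unknown perturbation {pert!r}")
            if pert == self.control_label and eff != 0:
                raise ValueError("control arm must have all-zero effects")


def gen_screen_cohort(params: ScreenSimParams,
                      neuron_template: NeuronSimParams | None = None
                      ) -> tuple[list, pd.DataFrame, dict]:
    """Simulate a cohort of reconstructions across perturbation arms.

    Effects are injected geometrically (per-neuron segment-length
    multipliers), so the morphometric engine must recover them from the
    raw trees.  Returns (list of (recon, ground-truth labeling), metadata
    frame, truth ledger).
    """
    params.validate()
    template = neuron_template or NeuronSimParams()
    rng = np.random.default_rng(params.seed)
    neurons = []
    meta_rows = []
    brain_effects: dict = {}
    knobs = list(EFFECT_KNOBS)
    brain_counter = 0
    for pert in params.perturbations:
        for _ in range(params.n_brains_per_arm):
            brain_counter += 1
            brain_id = f"brain{brain_counter:03d}"
            beff = {k: rng.normal(0.0, params.brain_sd) for k in knobs}
            brain_effects[brain_id] = beff
            for j in range(params.neurons_per_brain):
                traits = {}
                scale = {"basal": 1.0, "trunk": 1.0, "oblique": 1.0,
                         "tuft": 1.0, "all": 1.0}
                for k in knobs:
                    t = (params.true_effects.get((pert, k), 0.0)
                         + beff[k] + rng.normal(0.0, params.residual_sd))
                    traits[k] = t
                    mult = max(0.1, 1.0 + params.rel_scale * t)
                    scale[EFFECT_KNOBS[k]] *= mult
                nid = f"{brain_id}_n{j:02d}"
                seed_i = int(rng.integers(0, 2**31 - 1))
                meta = {"neuron_id": nid, "brain_id": brain_id,
                        "batch": f"batch{(brain_counter - 1) // 4 + 1}",
                        "age": 28, "perturbation": pert,
                        "tag": ("HA", "Myc", "V5")[j % 3]}
                recon, labeling, _ = gen_neuron(
                    replace(template, seed=seed_i), scale=scale, metadata=meta)
                neurons.append((recon, labeling))
                meta_rows.append(meta)
    metadata = pd.DataFrame(meta_rows)
    ledger = {
        "true_effects": {f"{p}:{m}": e for (p, m), e in params.true_effects.items()},
        "rel_scale": params.rel_scale,
        "brain_sd": params.brain_sd,
        "residual_sd": params.residual_sd,
        "brain_effects": brain_effects,
    }
    return neurons, metadata, ledger


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

@dataclass
class CountSimParams:
    """Negative-binomial count simulation with known log2 fold-changes.

    ``groups`` maps group label -> number of units (cells or pseudobulk
    samples); ``true_log2fc`` is genes x groups (reference group columns are
    zero); ``batch_shift`` maps batch label -> natural-log scale offset,
    batches assigned round-robin within each group.
    """

    n_genes: int = 2000
    groups: dict = field(default_factory=lambda: {"control": 6, "pert": 6})
    true_log2fc: np.ndarray | None = None
    dispersion: float | np.ndarray = 0.1
    baseline_mean: float | np.ndarray = 20.0
    batch_shift: dict = field(default_factory=dict)
    level: str = "pseudobulk"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or not self.groups:
            raise ValueError("need genes and groups")
        if np.any(np.asarray(self.baseline_mean) <= 0):
            raise ValueError("baseline means must be positive")
        if np.any(np.asarray(self.dispersion) < 0):
            raise ValueError("dispersion must be non-negative")
        if self.level not in ("cell", "pseudobulk"):
            raise ValueError("level must be 'cell' or 'pseudobulk'")


def gen_counts(params: CountSimParams):
    """Simulate a genes x units count matrix; counts ~ NB with
    mean = baseline * 2^log2fc * exp(batch shift) and var = mu + disp*mu^2.
    Returns (CountMatrix, truth ledger)."""
    from .expression import CountMatrix

    params.validate()
    rng = np.random.default_rng(params.seed)
    glabels = list(params.groups)
    n_units = sum(params.groups.values())
    mean = np.broadcast_to(np.asarray(params.baseline_mean, float),
                           (params.n_genes,)).copy()
    disp = np.broadcast_to(np.asarray(params.dispersion, float),
                           (params.n_genes,)).copy()
    lfc = (np.zeros((params.n_genes, len(glabels)))
           if params.true_log2fc is None else np.asarray(params.true_log2fc, float))
    if lfc.shape != (params.n_genes, len(glabels)):
        raise ValueError("true_log2fc must be genes x groups")

    batches = list(params.batch_shift) or ["batch1"]
    shifts = {b: params.batch_shift.get(b, 0.0) for b in batches}

    unit_meta = []
    cols = []
    for gi, g in enumerate(glabels):
        for j in range(params.groups[g]):
            b = batches[j % len(batches)]
            unit_meta.append({"unit_id": f"{g}_{j:03d}", "group": g,
                              "perturbation": g, "batch": b, "sample_id": f"{g}_{j:03d}"})
            mu = mean * (2.0 ** lfc[:, gi]) * math.exp(shifts[b])
            lam = mu.copy()
            od = disp > 0
            if np.any(od):
                r = 1.0 / disp[od]
                lam[od] = mu[od] * rng.gamma(r, 1.0) / r
            cols.append(rng.poisson(lam))
    genes = [f"gene{i:05d}" for i in range(params.n_genes)]
    counts = pd.DataFrame(np.column_stack(cols), index=genes,
                          columns=[m["unit_id"] for m in unit_meta])
    meta = pd.DataFrame(unit_meta).set_index("unit_id")
    ledger = {"log2fc": pd.DataFrame(lfc, index=genes, columns=glabels),
              "dispersion": disp, "baseline_mean": mean,
              "batch_shift": shifts}
    return CountMatrix(counts=counts, unit_meta=meta), ledger


# ---------------------------------------------------------------------------
# guide assignment tables
# ---------------------------------------------------------------------------

@dataclass
class GuideSimParams:
    """Dual-guide vector detection model.

    Each cell carries one true vector (a matched guide pair); with
    probability ``co_detection_rate`` both guides are called, else one; with
    probability ``cross_contamination_rate`` a spurious extra guide drawn
    from ``guide_freqs`` is added.
    """

    n_pairs: int = 8
    guide_freqs: np.ndarray | None = None
    n_cells: int = 1000
    co_detection_rate: float = 0.4
    cross_contamination_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1 or self.n_cells < 1:
            raise ValueError("need pairs and cells")
        for r in (self.co_detection_rate, self.cross_contamination_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.guide_freqs is not None:
            f = np.asarray(self.guide_freqs, float)
            if f.shape != (2 * self.n_pairs,) or not math.isclose(f.sum(), 1.0,
                                                                  rel_tol=1e-9):
                raise ValueError("guide_freqs must sum to 1 over 2*n_pairs guides")


def guide_library(n_pairs: int, n_control_pairs: int = 1) -> pd.DataFrame:
    """Two guides per vector; the last ``n_control_pairs`` vectors are
    controls.  Columns: guide, vector, perturbation, is_control."""
    rows = []
    for i in range(n_pairs):
        is_ctrl = i >= n_pairs - n_control_pairs
        pert = f"control{i - (n_pairs - n_control_pairs) + 1}" if is_ctrl else f"gene{i + 1}"
        vec = f"vec{i + 1}"
        for half in "ab":
            rows.append({"guide": f"{vec}_{half}", "vector": vec,
                         "perturbation": pert, "is_control": is_ctrl})
    return pd.DataFrame(rows)


def gen_guide_assignments(params: GuideSimParams
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-cell raw guide-call sets.

    Returns (raw_calls with columns cell_id/guides, library frame, truth
    frame with the true vector per cell)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    lib = guide_library(params.n_pairs)
    guides = lib["guide"].tolist()
    f = (np.full(2 * params.n_pairs, 1.0 / (2 * params.n_pairs))
         if params.guide_freqs is None else np.asarray(params.guide_freqs, float))
    pair_of = dict(zip(lib["guide"], lib["vector"]))

    rows, truth = [], []
    for i in range(params.n_cells):
        gidx = rng.choice(len(guides), p=f)
        g = guides[gidx]
        vec = pair_of[g]
        mate = [x for x in guides if pair_of[x] == vec and x != g][0]
        calls = {g, mate} if rng.random() < params.co_detection_rate else {g}
        if rng.random() < params.cross_contamination_rate:
            extra = guides[rng.choice(len(guides), p=f)]
            calls.add(extra)
        rows.append({"cell_id": f"cell{i:05d}", "guides": sorted(calls)})
        truth.append({"cell_id": f"cell{i:05d}", "true_vector": vec})
    return pd.DataFrame(rows), lib, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# developmental series
# ---------------------------------------------------------------------------

DEV_AGES = ("P10", "P14", "P28")
_CLASS_LATE_LFC = {"Progressing": 0.6, "Stabilizing": 0.0, "Transient": -0.6,
                   "Flat": 0.0}


def gen_dev_series(classes: dict[str, str], n_samples: int = 4,
                   noise_sd: float = 0.1, seed: int = 0):
    """Three-age pseudobulk log2 expression with planted temporal classes.

    Non-Flat genes rise P10 -> P14 (log2FC +0.6, comfortably above the 0.3
    eligibility threshold); the P14 -> P28 change is +0.6 / 0 / -0.6 for
    Progressing / Stabilizing / Transient.  Returns (expression frame with a
    sample metadata frame, truth Series, and the two effect tables the
    signature classifier consumes).
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples per age")
    rng = np.random.default_rng(seed)
    genes = list(classes)
    for g, c in classes.items():
        if c not in _CLASS_LATE_LFC:
            raise ValueError(f"unknown class {c!r} for gene {g}")
    base = rng.uniform(3.0, 8.0, size=len(genes))
    early = np.array([0.0 if classes[g] == "Flat" else 0.6 for g in genes])
    late = np.array([_CLASS_LATE_LFC[classes[g]] for g in genes])
    age_means = {"P10": base, "P14": base + early, "P28": base + early + late}

    cols, meta = [], []
    for age in DEV_AGES:
        for s in range(n_samples):
            cols.append(age_means[age] + rng.normal(0.0, noise_sd, len(genes)))
            meta.append({"sample_id": f"{age}_s{s}", "age": age})
    expr = pd.DataFrame(np.column_stack(cols), index=genes,
                        columns=[m["sample_id"] for m in meta])
    meta = pd.DataFrame(meta).set_index("sample_id")

    de_early = _mean_diff_table(expr, meta, "P14", "P10")
    de_late = _mean_diff_table(expr, meta, "P28", "P14")
    truth = pd.Series({g: classes[g] for g in genes}, name="class")
    return (expr, meta), truth, de_early, de_late


def _mean_diff_table(expr: pd.DataFrame, meta: pd.DataFrame,
                     age_num: str, age_den: str) -> pd.DataFrame:
    from scipy import stats as sps
    from .stats import bh_adjust

    a = expr.loc[:, meta.index[meta["age"] == age_num]]
    b = expr.loc[:, meta.index[meta["age"] == age_den]]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    pvals = np.ones(len(expr))
    for i in range(len(expr)):
        if va.iloc[i] + vb.iloc[i] == 0:
            pvals[i] = 0.0 if lfc.iloc[i] != 0 else 1.0  # noiseless construction
        else:
            pvals[i] = sps.ttest_ind(a.iloc[i], b.iloc[i], equal_var=False).pvalue
    return pd.DataFrame({"effect": lfc, "se": np.sqrt(va / a.shape[1] + vb / b.shape[1]),
                         "p": pvals, "p_adj": bh_adjust(pvals)}, index=expr.index)
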