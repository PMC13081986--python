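"""End-to-end orchestration: simulate -> morphometrics -> screen ->
expression -> concordance, with a YAML-serializable config and a run
manifest of checksums for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concord, expression, metrics as mm, panel, stats, swc, synth


@dataclass
class RunConfig:
    out_dir: str = "morphoscreen_run"
    seed: int = 1
    # simulation sizing
    perturbations: tuple = ("control", "pertA", "pertB", "pertC")
    true_effects: dict = field(default_factory=lambda: {
        ("pertA", "basal_height"): 1.2, ("pertB", "tuft_height"): 1.0})
    n_brains_per_arm: int = 6
    neurons_per_brain: int = 10
    n_genes: int = 300
    n_samples_per_arm: int = 6
    rna_effect_sd: dict = field(default_factory=lambda: {
        "pertA": 0.5, "pertB": 0.3, "pertC": 0.0})
    # analysis parameters
    step_um: float = 10.0
    trunk_split_ratio: float = 0.33
    min_branch_um: float = 1.0
    fdr_alpha: float = 0.05
    ref_group: str = "control"
    n_dims: int = 10
    min_group_size: int = 5

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["true_effects"] = {f"{p}:{m}": v for (p, m), v in self.true_effects.items()}
        d["perturbations"] = list(self.perturbations)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["true_effects"] = {tuple(k.split(":")): v
                             for k, v in d.get("true_effects", {}).items()}
        d["perturbations"] = tuple(d.get("perturbations", ()))
        return cls(**d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["true_effects"] = sorted((f"{p}:{m}", v)
                                   for (p, m), v in self.true_effects.items())
        return hashlib.sha256(json.dumps(d, sort_keys=True,
                                         default=str).encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_demo(seed: int, out_dir, config: RunConfig | None = None) -> dict:
    """Write a self-contained demo dataset: an SWC cohort across perturbation
    arms with geometric effects, pseudobulk counts with known log2FCs, a
    dual-guide assignment table, and JSON truth ledgers."""
    cfg = config or RunConfig(seed=seed)
    if cfg.n_brains_per_arm < 2 or cfg.neurons_per_brain < 1 or cfg.n_genes < 1:
        raise ValueError("demo sizes must be positive (>=2 brains per arm)")
    out = Path(out_dir)
    (out / "swc").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    sp = synth.ScreenSimParams(perturbations=cfg.perturbations,
                               true_effects=cfg.true_effects,
                               n_brains_per_arm=cfg.n_brains_per_arm,
                               neurons_per_brain=cfg.neurons_per_brain,
                               seed=int(rng.integers(2**31 - 1)))
    neurons, metadata, ledger = synth.gen_screen_cohort(sp)
    for recon, _ in neurons:
        swc.write_swc(recon, out / "swc" / f"{recon.metadata['neuron_id']}.swc")
    metadata.to_csv(out / "metadata.csv", index=False)

    # expression arm: per-gene random true effects scaled per perturbation
    glabels = list(cfg.perturbations)
    lfc = np.zeros((cfg.n_genes, len(glabels)))
    crng = np.random.default_rng(seed + 1)
    for gi, g in enumerate(glabels):
        sd = cfg.rna_effect_sd.get(g, 0.0)
        if sd > 0:
            lfc[:, gi] = crng.normal(0.0, sd, cfg.n_genes)
    cp = synth.CountSimParams(n_genes=cfg.n_genes,
                              groups={g: cfg.n_samples_per_arm for g in glabels},
                              true_log2fc=lfc, dispersion=0.1,
                              baseline_mean=50.0,
                              seed=int(rng.integers(2**31 - 1)))
    counts, count_ledger = synth.gen_counts(cp)
    counts.write_mtx(str(out / "counts"))

    gp = synth.GuideSimParams(seed=int(rng.integers(2**31 - 1)))
    raw_calls, library, guide_truth = synth.gen_guide_assignments(gp)
    library.to_csv(out / "guide_library.tsv", sep="\t", index=False)
    raw_calls.assign(guides=raw_calls["guides"].map("|".join)).to_csv(
        out / "guide_calls.tsv", sep="\t", index=False)

    truth = {
        "seed": seed,
        "morphology": ledger["true_effects"],
        "rna_effect_sd": cfg.rna_effect_sd,
        "rna_log2fc_file": "counts_truth.csv",
        "guide_truth_file": "guide_truth.tsv",
    }
    count_ledger["log2fc"].to_csv(out / "counts_truth.csv")
    guide_truth.to_csv(out / "guide_truth.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return {"n_neurons": len(neurons), "n_genes": cfg.n_genes,
            "out_dir": str(out)}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a (simulated) dataset and return the manifest.

    Stages: simulate, morphometrics, differential morphometry, differential
    expression, and cross-modality concordance.  Each stage writes its
    outputs under ``config.out_dir`` before the next begins, so a failure
    leaves prior outputs intact.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                      "stages": {}, "started": time.time()}
    config.to_yaml(out / "config.yaml")

    # stage 1: simulate
    info = simulate_demo(config.seed, out, config)
    manifest["stages"]["simulate"] = info

    # stage 2: morphometrics
    swc_dir = out / "swc"
    meta = pd.read_csv(out / "metadata.csv").set_index("neuron_id", drop=False)
    cfgm = mm.MetricConfig(step_um=config.step_um)
    pairs = []
    for f in sorted(swc_dir.glob("*.swc")):
        recon = swc.read_swc(f, metadata=meta.loc[f.stem].to_dict())
        recon, _report = swc.qc_repair(recon, min_branch_um=config.min_branch_um)
        labeling = swc.label_compartments(recon, config.trunk_split_ratio)
        pairs.append((recon, labeling))
    table = mm.morphometric_table(pairs, cfgm)
    table.to_csv(out / "morphometrics.csv")
    mm.metric_definitions().to_csv(out / "metric_definitions.csv", index=False)
    manifest["stages"]["morphometrics"] = {"n_neurons": len(table),
                                           "n_metrics": table.shape[1]}

    # stage 3: differential morphometry
    effects = stats.differential_morphometry(table, meta.loc[table.index],
                                             ref_group=config.ref_group)
    effects.to_csv(out / "morphology_effects.csv", index=False)
    n_hits = int((effects["p_adj"] < config.fdr_alpha).sum())
    manifest["stages"]["screen"] = {"n_tests": len(effects), "n_hits": n_hits}

    # stage 4: differential expression
    counts = expression.CountMatrix.read_mtx(str(out / "counts"))
    counts = expression.filter_genes(counts, min_count=10, min_units=2)
    de = expression.nb_glm_de(counts, ref_level=config.ref_group)
    de.to_csv(out / "expression_effects.csv", index=False)
    manifest["stages"]["expression"] = {
        "n_genes": counts.n_genes,
        "n_hits": int((de["p_adj"] < config.fdr_alpha).sum())}

    # stage 5: concordance
    twi_m, twi_r = {}, {}
    for g in config.perturbations:
        if g == config.ref_group:
            continue
        em = effects[effects["group"] == g].rename(columns={"effect": "effect"})
        twi_m[g] = concord.twi(em[["effect", "se"]], g, "morphology").twi
        er = de[de["contrast"] == f"{g} vs {config.ref_group}"].rename(
            columns={"log2fc": "effect"})
        twi_r[g] = concord.twi(er[["effect", "se"]], g, "RNA").twi
    imputed = panel.impute_mean(table.dropna(axis=1, how="all"))
    ed = concord.edist_matrix(imputed, meta.loc[table.index, "perturbation"],
                              batch_labels=meta.loc[table.index, "brain_id"],
                              n_dims=config.n_dims,
                              min_group_size=config.min_group_size)
    ed.matrix.to_csv(out / "edist_morphology.csv")
    pd.DataFrame({"twi_morphology": pd.Series(twi_m),
                  "twi_rna": pd.Series(twi_r)}).to_csv(out / "twi.csv")
    if len(twi_m) >= 2:
        r, scatter = concord.cross_modality(pd.Series(twi_m), pd.Series(twi_r))
        scatter.to_csv(out / "cross_modality.csv")
        manifest["stages"]["concordance"] = {"pearson_r": r}

    manifest["checksums"] = {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))}
    manifest["finished"] = time.time()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
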