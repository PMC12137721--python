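"""End-to-end orchestration: simulate -> QC -> metrics -> fits -> networks.

`run_pipeline` executes the stages on either a synthetic dataset (built
from the config's generator settings) or user-supplied count/ASE tables,
writes every stage's output as TSV/JSON into the output directory, and
records a manifest with seeds and content digests so a rerun with the same
config is bit-reproducible. `report` condenses a finished run into the
headline tables (gene class counts, overall change ratios, monoallelic
calls, dosage summary, MI change gene lists, simulation noise changes).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import inference, minet, popqc, synthetic, telegraph
from .metrics import compute_all_metrics, MetricsConfig

log = logging.getLogger("allelenoise")

_KNOWN_KEYS = {
    "outdir", "seed", "counts_path", "metadata_path", "ase_path",
    "annotations_path", "synthetic", "cpm_threshold", "min_bias_cells",
    "min_bias_reads", "min_populations", "alpha", "b_threshold",
    "mi_factor", "degree_min", "sim_n_rate_sets", "sim_n_cells",
    "run_simulation", "run_minet", "log_level",
}


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run. Unknown keys are rejected."""
    outdir: str = "allelenoise_run"
    seed: int = 0
    counts_path: str | None = None
    metadata_path: str | None = None
    ase_path: str | None = None
    annotations_path: str | None = None
    synthetic: dict = field(default_factory=dict)   # SyntheticConfig overrides
    cpm_threshold: float = 0.2
    min_bias_cells: int = 5
    min_bias_reads: int = 25
    min_populations: int = 10
    alpha: float = 0.05
    b_threshold: float = 0.5
    mi_factor: float = 2.0
    degree_min: int = 0
    sim_n_rate_sets: int = 10
    sim_n_cells: int = 200
    run_simulation: bool = True
    run_minet: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_counts(path: str) -> pd.DataFrame:
    if path.endswith(".mtx"):
        from scipy import io as sio
        base = os.path.dirname(path)
        mat = sio.mmread(path).toarray()
        genes = pd.read_csv(os.path.join(base, "genes.tsv"), sep="\t",
                            header=None)[0]
        cells = pd.read_csv(os.path.join(base, "cells.tsv"), sep="\t",
                            header=None)[0]
        return pd.DataFrame(mat, index=genes, columns=cells)
    return pd.read_csv(path, sep="\t", index_col=0)


def _read_ase(path: str) -> pd.DataFrame:
    ase = pd.read_csv(path, sep="\t")
    for col in ("ref_count", "alt_count"):
        bad = pd.to_numeric(ase[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header line + 1-based
            raise ValueError(
                f"{path}: non-integer value in column {col!r} at line {line}")
        ase[col] = ase[col].astype(int)
    return ase


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Run all stages; returns the result bundle (also written to disk)."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    logging.basicConfig(level=config.log_level,
                        format="%(asctime)s %(name)s %(message)s")
    os.makedirs(config.outdir, exist_ok=True)
    manifest = {"seed": config.seed, "stages": {}, "outputs": {}}
    with open(os.path.join(config.outdir, "config.json"), "w") as fh:
        json.dump(asdict(config), fh, indent=1)

    def _stage(name):
        log.info("stage %s", name)
        return time.perf_counter()

    def _done(name, t0, **outputs):
        manifest["stages"][name] = round(time.perf_counter() - t0, 3)
        for key, path in outputs.items():
            manifest["outputs"][key] = {"path": os.path.basename(path),
                                        "sha256": _digest(path)}

    bundle: dict = {}

    # --- data -----------------------------------------------------------
    t0 = _stage("data")
    if config.counts_path:
        counts = _read_counts(config.counts_path)
        metadata = pd.read_csv(config.metadata_path, sep="\t")
        ase = _read_ase(config.ase_path) if config.ase_path else None
        truth = None
    else:
        syn = synthetic.SyntheticConfig(seed=config.seed, **config.synthetic)
        counts, metadata, truth = synthetic.generate_counts(syn)
        ase = synthetic.generate_ase(counts, metadata, syn, truth)
    if config.annotations_path:
        annotations = pd.read_csv(config.annotations_path, sep="\t")
    else:
        annotations = None
    data_dir = os.path.join(config.outdir, "data")
    synthetic.write_dataset(data_dir, counts, metadata,
                            truth or {}, ase=ase)
    _done("data", t0, counts=os.path.join(data_dir, "counts.mtx"),
          metadata=os.path.join(data_dir, "metadata.tsv"))
    bundle.update(counts=counts, metadata=metadata, ase=ase, truth=truth)

    # --- qc ------------------------------------------------------------
    t0 = _stage("qc")
    cpm = popqc.cpm_normalize(counts)
    expr_pass = popqc.expression_qc(cpm, metadata, config.cpm_threshold)
    pops = metadata["population_id"].unique()
    bias_pass = popqc.bias_qc(ase, metadata, counts.index, pops,
                              config.min_bias_cells, config.min_bias_reads) \
        if ase is not None else None
    qc_path = os.path.join(config.outdir, "qc_expression.tsv")
    expr_pass.to_csv(qc_path, sep="\t")
    _done("qc", t0, qc_expression=qc_path)
    bundle.update(cpm=cpm, expression_pass=expr_pass, bias_pass=bias_pass)

    # --- metrics --------------------------------------------------------
    t0 = _stage("metrics")
    metrics = compute_all_metrics(cpm, metadata, ase=ase,
                                  expression_pass=expr_pass,
                                  bias_pass=bias_pass)
    day_of = metadata.drop_duplicates("population_id") \
        .set_index("population_id")["day"]
    metrics["day"] = metrics["population_id"].map(day_of)
    metrics_path = os.path.join(config.outdir, "gene_metrics.tsv")
    metrics.to_csv(metrics_path, sep="\t", index=False)
    _done("metrics", t0, gene_metrics=metrics_path)
    bundle["metrics"] = metrics

    # --- fits -----------------------------------------------------------
    t0 = _stage("fits")
    eta_fits = inference.classify_changes(
        inference.fit_all_genes(metrics, "eta",
                                min_populations=config.min_populations),
        alpha=config.alpha)
    h_fits = inference.classify_changes(
        inference.fit_all_genes(metrics, "h",
                                min_populations=config.min_populations),
        alpha=config.alpha)
    mu_fits = inference.fit_all_genes(metrics, "mu",
                                      min_populations=config.min_populations)
    fits = pd.concat([eta_fits, h_fits, mu_fits], ignore_index=True)
    fits_path = os.path.join(config.outdir, "fits.tsv")
    fits.to_csv(fits_path, sep="\t", index=False)
    overall = inference.overall_fit(metrics, "eta")
    dosage = inference.dosage_assessment(mu_fits)
    dosage["per_gene"].to_csv(os.path.join(config.outdir, "dosage.tsv"),
                              sep="\t", index=False)
    calls, contingency = None, None
    if annotations is not None:
        try:
            calls, contingency = inference.call_monoallelic(
                metrics, annotations, b_threshold=config.b_threshold)
            calls.to_csv(os.path.join(config.outdir, "monoallelic_calls.tsv"),
                         sep="\t", index=False)
        except ValueError as err:
            log.warning("monoallelic calling skipped: %s", err)
    _done("fits", t0, fits=fits_path)
    bundle.update(eta_fits=eta_fits, h_fits=h_fits, mu_fits=mu_fits,
                  overall=overall, dosage=dosage, calls=calls,
                  contingency=contingency)

    # --- minet ----------------------------------------------------------
    if config.run_minet:
        t0 = _stage("minet")
        bcfg = synthetic.BrainConfig(seed=config.seed)
        bcounts, bmeta, btruth = synthetic.generate_brain_like(bcfg)
        bcpm = popqc.cpm_normalize(bcounts)
        net = minet.MINetwork.from_expression(
            bcpm, bmeta, "NI|P0", "NII|P42",
            factor=config.mi_factor, degree_min=config.degree_min)
        delta_path = os.path.join(config.outdir, "mi_change.tsv")
        net.delta.to_csv(delta_path, sep="\t")
        edges = [(u, v, d["mi"]) for u, v, d in net.graph.edges(data=True)]
        pd.DataFrame(edges, columns=["node1", "node2", "mi"]).to_csv(
            os.path.join(config.outdir, "mi_edges.tsv"), sep="\t", index=False)
        _done("minet", t0, mi_change=delta_path)
        bundle["minetwork"] = net

    # --- simulation -----------------------------------------------------
    if config.run_simulation:
        t0 = _stage("simulation")
        ensemble = telegraph.rate_ensemble(n_sets=config.sim_n_rate_sets,
                                           seed=config.seed)
        rows = []
        for ri, rates in enumerate(ensemble):
            res = telegraph.network_experiment(rates,
                                               n_cells=config.sim_n_cells,
                                               seed=config.seed + ri)
            rows.append({"rate_set": ri, "role": "imprinted",
                         "xi_sim": float(res.xi_sim[0]),
                         "se": float(res.xi_sim_se[0])})
        sim = pd.DataFrame(rows)
        sim_path = os.path.join(config.outdir, "simulation.tsv")
        sim.to_csv(sim_path, sep="\t", index=False)
        _done("simulation", t0, simulation=sim_path)
        bundle["simulation"] = sim

    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    bundle["manifest"] = manifest
    bundle["config"] = config
    return bundle


def report(bundle: dict) -> dict:
    """Headline summary tables of a finished (possibly partial) run."""
    out: dict = {"missing": []}
    if "eta_fits" in bundle:
        eta = bundle["eta_fits"]
        ok = eta[eta["status"] == "ok"]
        out["noise_changes"] = {
            "n_genes": int(len(ok)),
            "n_increase": int((ok["class_b"] == "increase").sum()),
            "n_decrease": int((ok["class_b"] == "decrease").sum()),
        }
    else:
        out["missing"].append("eta_fits")
    if bundle.get("overall") is not None and bundle["overall"].status == "ok":
        ov = bundle["overall"]
        out["overall"] = {"xi_b": float(ov.xi_b), "xi_d": float(ov.xi_d)}
    if "dosage" in bundle:
        d = bundle["dosage"]
        out["dosage"] = {"median_xi_mu_b": d["median_xi_mu_b"],
                         "n_beyond_halving": d["n_beyond_halving"],
                         "n_genes": d["n_genes"]}
    if bundle.get("contingency") is not None:
        out["monoallelic_contingency"] = bundle["contingency"]
    if "minetwork" in bundle:
        net = bundle["minetwork"]
        out["mi_change"] = {
            "n_high_increase": len(net.high_change["increase"]),
            "n_high_decrease": len(net.high_change["decrease"]),
            "n_network_nodes": net.graph.number_of_nodes(),
        }
    else:
        out["missing"].append("minetwork")
    if "simulation" in bundle:
        sim = bundle["simulation"]
        out["simulation"] = {
            "mean_xi_sim": float(sim["xi_sim"].mean()),
            "n_rate_sets": int(sim["rate_set"].nunique()),
        }
    else:
        out["missing"].append("simulation")
    return out
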