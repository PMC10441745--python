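"""End-to-end orchestration: simulate -> DE -> ceRNA -> clinical correlation
-> enrichment -> PPI hubs -> ROC, with a machine-readable run manifest.

Every stage writes tab-delimited outputs into the run directory; a failure
in any stage aborts the run with the stage name and cause while keeping
the partial outputs next to a FAILED marker file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cerna, clinstats, diffexpr, enrich, ppihub, rocdx
from . import synthetic_data as simdata

logger = logging.getLogger(__name__)

STAGES = ("simulate", "de", "network", "correlate", "enrich", "ppi", "roc")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_config() -> dict:
    return {
        "simulation": dataclasses.asdict(simdata.SimulationConfig()),
        "de": {"fc_threshold": 2.0, "p_threshold": 0.05, "pseudocount": 1.0,
               "pooled": True, "log_transform": True},
        "enrich": {"p_threshold": 0.05},
        "ppi": {"score_threshold": 0.4, "top_k": 10},
        "roc": {"loo": False, "max_triplets": 10},
    }


def load_config(path: str | Path | None) -> dict:
    cfg = default_config()
    if path is not None:
        import yaml

        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if section not in cfg:
                raise ValueError(f"unknown config section: {section}")
            cfg[section].update(values or {})
    return cfg


def run_pipeline(
    config: dict | None = None,
    outdir: str | Path = "exocerna_run",
    seed: int | None = None,
) -> dict:
    """Run every stage in order; returns the manifest dictionary."""
    cfg = config or default_config()
    if seed is not None:
        cfg["simulation"]["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg["simulation"]["seed"],
        "versions": {"exocerna": __version__, "python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
    }
    state: dict = {}
    try:
        for stage in STAGES:
            logger.info("stage %s", stage)
            outputs = _STAGE_FUNCS[stage](cfg, state, outdir)
            manifest["stages"][stage] = sorted(str(p.name) for p in outputs)
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n", encoding="utf-8")
        raise StageError(stage, exc) from exc
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_simulate(cfg: dict, state: dict, outdir: Path) -> list[Path]:
    sim_cfg = simdata.config_from_mapping(cfg["simulation"])
    data = simdata.generate_bundle(sim_cfg)
    data.bundle.validate()
    state["data"] = data
    paths = simdata.write_outputs(data, outdir)
    demo = clinstats.demographics_table(data.clinical)
    p = outdir / "demographics.tsv"
    demo.to_csv(p, sep="\t", index=False, float_format="%.4f")
    return [*paths.values(), p]


def _stage_de(cfg: dict, state: dict, outdir: Path) -> list[Path]:
    params = diffexpr.DEParams(**cfg["de"])
    de_tables = diffexpr.compute_de(state["data"].bundle, params)
    state["de_tables"] = de_tables
    state["de_sets"] = diffexpr.de_sets(de_tables)
    paths = []
    for rna_class, de in de_tables.items():
        p = outdir / f"de_{rna_class.lower()}.tsv"
        de.to_csv(p, sep="\t", float_format="%.6g")
        paths.append(p)
    # volcano-plot export: log2fc vs -log10 p with the gate flag
    volcano = pd.concat(de_tables.values())[
        ["rna_class", "log2fc", "p_value", "direction", "passes_filter"]
    ].assign(neg_log10_p=lambda d: -np.log10(d["p_value"]))
    p = outdir / "volcano.tsv"
    volcano.to_csv(p, sep="\t", float_format="%.6g")
    paths.append(p)
    return paths


def _stage_network(cfg: dict, state: dict, outdir: Path) -> list[Path]:
    targets = state["data"].targets
    paths = []
    summaries = []
    state["networks"] = {}
    for polarity in (cerna.UP_MIR, cerna.DOWN_MIR):
        net = cerna.build_network(state["de_sets"], targets, polarity)
        state["networks"][polarity] = net
        prefix = outdir / f"cerna_{polarity}"
        cerna.export_network(net, prefix)
        s = cerna.network_summary(net)
        summaries.append({k: v for k, v in s.items() if k != "degree_table"})
        paths += [Path(f"{prefix}_nodes.tsv"), Path(f"{prefix}_edges.tsv"),
                  Path(f"{prefix}.graphml"), Path(f"{prefix}.sif")]
    p = outdir / "cerna_summary.tsv"
    pd.DataFrame(summaries).to_csv(p, sep="\t", index=False)
    paths.append(p)
    return paths


def _main_network(state: dict) -> cerna.CeRNANetwork:
    """The larger of the two directional networks (by node count)."""
    nets = state["networks"]
    return max(nets.values(), key=lambda n: n.graph.number_of_nodes())


def _stage_correlate(cfg: dict, state: dict, outdir: Path) -> list[Path]:
    net = _main_network(state)
    table = clinstats.correlate_network_features(
        net, state["data"].bundle, state["data"].clinical
    )
    state["correlations"] = table
    p = outdir / "panss_correlations.tsv"
    table.to_csv(p, sep="\t", index=False, float_format="%.4g")
    return [p]


def _stage_enrich(cfg: dict, state: dict, outdir: Path) -> list[Path]:
    data = state["data"]
    net = _main_network(state)
    universe = set(data.bundle.mrna.index)
    query = net.mrnas
    if query:
        table = enrich.ora(query, data.annotations, universe,
                           alpha=cfg["enrich"]["p_threshold"])
    else:
        table = enrich.ora(universe, data.annotations, universe).iloc[0:0]
    state["enrichment"] = table
    p = outdir / "enrichment.tsv"
    table.to_csv(p, sep="\t", index=False, float_format="%.4g")
    return [p]


def _stage_ppi(cfg: dict, state: dict, outdir: Path) -> list[Path]:
    data = state["data"]
    net = _main_network(state)
    graph = ppihub.induce_subgraph(
        net.mrnas, data.ppi, threshold=cfg["ppi"]["score_threshold"]
    )
    hubs = ppihub.hub_genes(graph, top_k=cfg["ppi"]["top_k"]) if len(graph) else []
    state["ppi_graph"], state["hubs"] = graph, hubs
    p = outdir / "ppi_hubs.tsv"
    pd.DataFrame(hubs, columns=["gene", "degree"]).to_csv(p, sep="\t", index=False)
    return [p]


def _stage_roc(cfg: dict, state: dict, outdir: Path) -> list[Path]:
    net = _main_network(state)
    triplets = cerna.extract_triplets(net)[: cfg["roc"]["max_triplets"]]
    report, curves = rocdx.compare_markers(
        state["data"].bundle, triplets, loo=cfg["roc"]["loo"]
    )
    state["roc_report"] = report
    paths = []
    p = outdir / "roc_auc.tsv"
    report.to_csv(p, sep="\t", index=False, float_format="%.4f")
    paths.append(p)
    points = pd.concat(
        [
            pd.DataFrame({"marker": name, "fpr": c.fpr, "tpr": c.tpr})
            for name, c in curves.items()
        ],
        ignore_index=True,
    ) if curves else pd.DataFrame(columns=["marker", "fpr", "tpr"])
    p = outdir / "roc_points.tsv"
    points.to_csv(p, sep="\t", index=False, float_format="%.4f")
    paths.append(p)
    return paths


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "de": _stage_de,
    "network": _stage_network,
    "correlate": _stage_correlate,
    "enrich": _stage_enrich,
    "ppi": _stage_ppi,
    "roc": _stage_roc,
}
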