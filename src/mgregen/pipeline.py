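"""End-to-end orchestration: simulate -> QC -> trajectory -> GRN -> specificity
-> screen, behind a single configuration with one global seed.

Stages run in a fixed order and each stage's outputs are written before the
next begins; a failure aborts with the stage named. The run report records
record counts before/after every filter so outputs can be reconciled.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mgregen import fate_bias, grn, io, preprocess, screen_stats, synthetic_data
from mgregen import trajectory as traj

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "trajectory", "grn", "specificity", "screen")

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]


def _sub(cls, overrides: dict, **extra):
    names = {f.name for f in fields(cls)}
    bad = set(overrides) - names
    if bad:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(bad)}")
    return cls(**{**extra, **overrides})


@dataclass
class PipelineConfig:
    outdir: str = "mgregen_run"
    seed: int = 0
    through: str = "screen"  # last stage to run
    marker_file: str | None = None  # optional external marker TSV
    pattern_k: int = 11
    simulation: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    deg: dict = field(default_factory=dict)
    trajectory: dict = field(default_factory=dict)
    grn: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    screen_sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        names = {f.name for f in fields(cls)}
        bad = set(data) - names
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def validate(self) -> None:
        if self.through not in STAGES:
            raise ValueError(f"unknown stage {self.through!r}")
        if self.marker_file is not None and not Path(self.marker_file).exists():
            raise FileNotFoundError(
                f"marker file not found: {self.marker_file}"
            )
        # construct every sub-config up front so bad keys fail before any stage
        self.sim_config()
        self.qc_params()
        self.deg_params()
        self.traj_params()
        self.grn_params()
        self.screen_params()

    def sim_config(self) -> synthetic_data.SimulationConfig:
        return _sub(synthetic_data.SimulationConfig, self.simulation,
                    seed=self.seed)

    def qc_params(self) -> preprocess.QCParams:
        return _sub(preprocess.QCParams, self.qc)

    def deg_params(self) -> preprocess.DEGParams:
        base = preprocess.DEGParams.condition_degs()
        return replace(base, **self.deg) if self.deg else base

    def traj_params(self) -> traj.TrajectoryParams:
        return _sub(traj.TrajectoryParams, self.trajectory, seed=self.seed)

    def grn_params(self) -> grn.GRNParams:
        return _sub(grn.GRNParams, self.grn, seed=self.seed)

    def screen_params(self) -> screen_stats.ScreenParams:
        return _sub(screen_stats.ScreenParams, self.screen)


def _meta_frame(ds: synthetic_data.SyntheticDataset) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": ds.counts.cell_ids,
            "t": ds.true_pseudotime,
            "state": ds.state_label,
            "condition": ds.condition_label,
        }
    ).set_index("cell_id")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the pipeline through ``config.through``; returns the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    state: dict = {}
    last = STAGES.index(config.through)
    for stage in STAGES[: last + 1]:
        t0 = time.time()
        logger.info("stage %s: start", stage)
        try:
            _STAGE_FUNCS[stage](config, outdir, state, report)
        except Exception:
            logger.exception("stage %s failed", stage)
            raise
        report["stages"][stage]["elapsed_s"] = round(time.time() - t0, 3)
    report["params"] = {
        "simulation": asdict(config.sim_config()),
        "qc": asdict(config.qc_params()),
        "deg": asdict(config.deg_params()),
        "trajectory": asdict(config.traj_params()),
        "grn": asdict(config.grn_params()),
        "screen": asdict(config.screen_params()),
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2,
                                                       default=str))
    return report


def _stage_simulate(config, outdir, state, report):
    sim = config.sim_config()
    abl = synthetic_data.simulate_ablation_pair(sim)
    ko, ko_tf = synthetic_data.simulate_ko_pair(sim)
    plate, truth = synthetic_data.simulate_screen_plate(
        seed=config.seed, **config.screen_sim
    )
    io.write_counts_mtx(abl.counts, outdir / "ablation_counts")
    io.write_counts_mtx(ko.counts, outdir / "ko_counts")
    _meta_frame(abl).to_csv(outdir / "ablation_truth.tsv", sep="\t")
    _meta_frame(ko).to_csv(outdir / "ko_truth.tsv", sep="\t")
    io.write_network_tsv(abl.network.edges, outdir / "planted_network.tsv")
    plate.to_csv(outdir / "plates.csv", index=False)
    state.update(abl=abl, ko=ko, ko_tf=ko_tf, plate=plate, screen_truth=truth)
    report["stages"]["simulate"] = {
        "ablation_cells": abl.counts.n_cells,
        "ko_cells": ko.counts.n_cells,
        "genes": abl.counts.n_genes,
        "planted_edges": len(abl.network.edges),
        "ko_tf": ko_tf,
        "plate_wells": len(plate),
    }


def _qc_and_norm(ds, qc_params):
    filtered = preprocess.qc_filter(ds.counts, qc_params)
    norm = preprocess.normalize_log(filtered)
    meta = _meta_frame(ds).loc[filtered.cell_ids]
    return filtered, norm, meta


def _stage_preprocess(config, outdir, state, report):
    qc = config.qc_params()
    rec = {}
    for name in ("abl", "ko"):
        ds = state[name]
        filtered, norm, meta = _qc_and_norm(ds, qc)
        state[f"{name}_counts"] = filtered
        state[f"{name}_norm"] = norm
        state[f"{name}_meta"] = meta
        rec[name] = {
            "cells_in": ds.counts.n_cells, "cells_out": filtered.n_cells,
            "genes_in": ds.counts.n_genes, "genes_out": filtered.n_genes,
        }
    # cell-type marker sets: external file or findAllMarkers-style calling
    universe = set(state["abl_counts"].gene_ids)
    if config.marker_file:
        sets = io.read_marker_sets_tsv(config.marker_file)
        sets = {k: s & universe for k, s in sets.items() if s & universe}
        markers = fate_bias.LineageMarkerSets(sets, universe)
    else:
        table = preprocess.rank_sum_markers(
            state["abl_norm"], state["abl_meta"]["state"].to_numpy(),
            preprocess.DEGParams.cell_type_markers(),
        )
        table.to_csv(outdir / "cell_type_markers.tsv", sep="\t", index=False)
        markers = fate_bias.LineageMarkerSets.from_marker_table(table, universe)
    io.write_marker_sets_tsv(markers.sets, outdir / "marker_sets.tsv")
    state["markers"] = markers
    rec["marker_sets"] = {k: len(s) for k, s in markers.sets.items()}
    report["stages"]["preprocess"] = rec


def _stage_trajectory(config, outdir, state, report):
    params = config.traj_params()
    rec = {}
    # common trajectory over control + ablated cells, MG as root
    pt = traj.fit_pseudotime(state["abl_norm"],
                             state["abl_meta"]["state"].to_numpy(), params)
    pt.to_frame().to_csv(outdir / "pseudotime.tsv", sep="\t", index=False)
    dens = traj.condition_density(
        pt, state["abl_meta"]["condition"].to_numpy(),
        "control_wildtype", "ablated_wildtype",
    )
    pd.DataFrame({"t": dens.grid, **dens.density,
                  "log_ratio": dens.log_ratio}).to_csv(
        outdir / "condition_density.tsv", sep="\t", index=False)
    # knockout-vs-wildtype delta profiles on the KO trajectory
    pt_ko = traj.fit_pseudotime(state["ko_norm"],
                                state["ko_meta"]["state"].to_numpy(), params)
    binned, delta = traj.bin_and_delta(
        state["ko_norm"], pt_ko, state["ko_meta"]["condition"].to_numpy(),
        params, cond_a="ablated_wildtype", cond_b="ablated_knockout",
    )
    delta.to_frame().to_csv(outdir / "delta_profiles.tsv", sep="\t")
    sig = delta.p < 0.05
    profiles = delta.delta[sig] if sig.sum() >= config.pattern_k else delta.delta
    patterns = traj.cluster_profiles(profiles, config.pattern_k, config.seed)
    genes = (np.asarray(delta.gene_ids)[sig]
             if sig.sum() >= config.pattern_k else delta.gene_ids)
    pd.DataFrame({"gene": genes, "pattern": patterns}).to_csv(
        outdir / "pattern_labels.tsv", sep="\t", index=False)
    state.update(pt=pt, pt_ko=pt_ko, delta=delta)
    rec.update(path=pt.path, n_delta_significant=int(sig.sum()),
               n_bins=params.n_bins)
    report["stages"]["trajectory"] = rec


def _stage_grn(config, outdir, state, report):
    params = config.grn_params()
    tf_list = state["abl"].network.tf_ids
    present = [t for t in tf_list if t in set(state["abl_norm"].gene_ids)]
    imp = grn.infer_importance(state["abl_norm"], present, params)
    edges = grn.filter_importance_quantile(imp, params.importance_quantile)
    n_after_q = len(edges)
    edges = grn.annotate_edge_sign(edges, state["abl_norm"],
                                   params.cor_threshold)
    n_after_sign = len(edges)
    edges = grn.filter_tf_expressed(
        edges, state["abl_counts"],
        state["abl_meta"]["state"].to_numpy(), params,
    )
    io.write_network_tsv(edges, outdir / "grn_edges.tsv")
    state["edges"] = edges
    state["importance"] = imp
    report["stages"]["grn"] = {
        "tfs": len(present),
        "pairs_scored": int(imp.pooled().notna().sum()),
        "edges_after_quantile": n_after_q,
        "edges_after_sign": n_after_sign,
        "edges_after_rpc_filter": len(edges),
    }


def _stage_specificity(config, outdir, state, report):
    markers = state["markers"]
    spec = fate_bias.tf_specificity(state["edges"], markers)
    spec.to_csv(outdir / "tf_specificity.tsv", sep="\t", index=False)
    # fate bias of knockout DEGs in progenitors
    meta = state["ko_meta"]
    prog = meta["state"].to_numpy() == "progenitor"
    norm = state["ko_norm"]
    sub = preprocess.ExpressionMatrix(
        norm.values[:, prog], norm.gene_ids,
        [c for c, keep in zip(norm.cell_ids, prog) if keep],
    )
    degs = preprocess.rank_sum_markers(
        sub, meta["condition"].to_numpy()[prog], config.deg_params(),
        groups=["ablated_knockout"], reference="ablated_wildtype",
    )
    degs.to_csv(outdir / "progenitor_ko_degs.tsv", sep="\t", index=False)
    tally = fate_bias.lineage_bias_tally(degs, markers)
    tally.to_csv(outdir / "lineage_bias.tsv", sep="\t", index=False)
    state["specificity"] = spec
    report["stages"]["specificity"] = {
        "tf_celltype_rows": len(spec),
        "n_progenitor_degs": int(degs["passed"].sum()),
    }


def _stage_screen(config, outdir, state, report):
    params = config.screen_params()
    rel = screen_stats.normalize_relative_yfp(state["plate"])
    result = screen_stats.screen_test(rel, params)
    result.to_csv(outdir / "screen_results.tsv", sep="\t", index=False)
    state["screen_result"] = result
    counts = result["class"].value_counts().to_dict()
    report["stages"]["screen"] = {
        "genes_tested": len(result),
        "classes": {k: int(v) for k, v in counts.items()},
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "trajectory": _stage_trajectory,
    "grn": _stage_grn,
    "specificity": _stage_specificity,
    "screen": _stage_screen,
}
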