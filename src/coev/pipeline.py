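"""End-to-end orchestration of the two analysis paths.

``run_sca_pipeline``: alignment -> redundancy filter -> gap-column filter ->
SCA coupling matrix -> hierarchical clustering -> (optional) structure
mapping, with a machine-readable JSON report carrying every intermediate
count so headline statistics (fraction of pairs above a score threshold,
top-cluster membership and size) can be recomputed from the report.

``run_traj_pipeline``: replicate trajectories -> per-metric time series ->
pooled mean ± SD summaries -> (optional) distance-landscape KDE modes.

Both are deterministic given inputs + config; every report carries a hash
of the resolved config.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import curves, metrics, msa, sca, structure, traj as traj_mod


class StageError(RuntimeError):
    """An error labelled with the pipeline stage that raised it."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[stage: {stage}] {original}")
        self.stage = stage
        self.original = original


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return deco


SCA_DEFAULTS = {
    "format": "fasta",
    "redundancy": 0.95,
    "max_gap": 0.20,
    "lambda": 0.03,
    "weights_cutoff": 0.8,
    "n_clusters": None,
    "min_size": 2,
    "score_threshold": 0.25,
    "ref_id": None,
    "ref_start": 1,
}


def run_sca_pipeline(config: dict, out_prefix: str | None = None) -> dict:
    """Sequence -> coupling matrix -> coevolving cluster.

    ``config`` must contain ``alignment`` (path) and may override any key in
    :data:`SCA_DEFAULTS`. When ``out_prefix`` is given the filtered FASTA,
    column map, coupling TSV/edge list, cluster JSON and report JSON are
    written with that prefix.
    """
    cfg = {**SCA_DEFAULTS, **config}
    report = {"config": {k: v for k, v in cfg.items()},
              "config_hash": config_hash(cfg)}

    aln = _stage("read_alignment")(msa.read_alignment)(
        cfg["alignment"], cfg["format"])
    report["n_sequences_input"] = aln.n_seqs
    report["n_columns_input"] = aln.length

    aln = _stage("filter_redundant")(msa.filter_redundant)(
        aln, cfg["redundancy"])
    report["n_sequences_after_redundancy"] = aln.n_seqs

    aln, dropped = _stage("filter_gap_columns")(msa.filter_gap_columns)(
        aln, cfg["max_gap"])
    report["n_columns_dropped_gap"] = len(dropped)
    report["n_columns_retained"] = aln.length

    posmap = None
    if cfg["ref_id"]:
        posmap = _stage("map_to_reference")(msa.map_to_reference)(
            aln, cfg["ref_id"], cfg["ref_start"])

    weights, meff = _stage("sequence_weights")(sca.sequence_weights)(
        aln, cfg["weights_cutoff"])
    report["meff"] = meff

    freqs = _stage("weighted_frequencies")(sca.weighted_frequencies)(
        aln, weights, cfg["lambda"])
    cm = _stage("coupling_matrix")(sca.coupling_matrix)(freqs)
    report["fraction_above_threshold"] = _stage("fraction_above")(
        sca.fraction_above)(cm, cfg["score_threshold"])
    report["score_threshold"] = cfg["score_threshold"]
    report["max_coupling"] = float(cm.scores.max())

    cl = _stage("cluster_coupling_matrix")(sca.cluster_coupling_matrix)(
        cm, n_clusters=cfg["n_clusters"], min_size=cfg["min_size"],
        posmap=posmap)
    report["n_clusters"] = cl.n_clusters
    report["top_cluster"] = cl.top_cluster
    report["top_cluster_size"] = len(cl.top_cluster)
    report["top_cluster_score"] = cl.top_cluster_score

    if out_prefix:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        msa.write_alignment(aln, f"{prefix}_filtered.fasta")
        if posmap is not None:
            msa.write_column_map(posmap, aln, f"{prefix}_column_map.tsv")
        cm.to_tsv(f"{prefix}_coupling.tsv", posmap=posmap)
        cm.to_edge_list(f"{prefix}_edges.tsv", threshold=0.0)
        cl.to_json(f"{prefix}_clusters.json")
        with open(f"{prefix}_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


TRAJ_DEFAULTS = {
    "metrics": ["rmsd", "rmsf", "rg", "dcc"],
    "ligand": None,
    "distance_pair": None,      # [[resnum_a], [resnum_b]] in structure numbering
    "distance_mode": "com",
    "elements": None,           # {"beta3": [a, b], ...} required for landscape
    "sasa_probe": 1.4,
    "sasa_points": 960,
    "hbond_dcut": 3.5,
    "hbond_angle": 150.0,
    "kde_grid_step": 0.1,
    "stride": 1,
    "discard": 0,
}


def run_traj_pipeline(
    config: dict,
    trajectories: list | None = None,
    out_prefix: str | None = None,
) -> dict:
    """Trajectories -> per-replicate metrics -> pooled summaries.

    ``config['trajectories']`` lists multi-model PDB paths (or pass loaded
    :class:`coev.traj.Trajectory` objects via ``trajectories``). Summary
    statistics are reported per replicate and pooled over all frames, in
    the ``mean ± SD`` convention.
    """
    cfg = {**TRAJ_DEFAULTS, **config}
    report = {"config": {k: v for k, v in cfg.items()
                         if k != "trajectories" or trajectories is None},
              "config_hash": config_hash(
                  {k: v for k, v in cfg.items()})}

    if trajectories is None:
        trajectories = [
            _stage("read_trajectory")(traj_mod.read_trajectory_pdb)(p)
            for p in cfg["trajectories"]
        ]
    trajectories = [
        t.with_stride(cfg["stride"], cfg["discard"]) for t in trajectories
    ]
    report["n_replicates"] = len(trajectories)
    report["n_frames"] = [t.n_frames for t in trajectories]

    want = set(cfg["metrics"])
    summaries: dict = {}

    def summarize(name, series_list):
        per_rep = {s.replicate_id: dict(zip(("mean", "sd"), s.summary()))
                   for s in series_list}
        mean, sd = metrics.pooled_summary(series_list)
        summaries[name] = {"per_replicate": per_rep,
                           "pooled": {"mean": mean, "sd": sd}}
        if out_prefix:
            for i, s in enumerate(series_list):
                s.to_tsv(f"{out_prefix}_{name}_rep{i + 1}.tsv")

    if "rmsd" in want:
        series = [_stage("rmsd")(metrics.rmsd_series)(t) for t in trajectories]
        summarize("rmsd", series)
    if "rmsf" in want:
        prof = []
        for t in trajectories:
            resnums, vals = _stage("rmsf")(metrics.rmsf_profile)(t)
            prof.append(vals)
        summaries["rmsf"] = {
            "residues": resnums.tolist(),
            "mean_profile": np.mean(prof, axis=0).tolist(),
        }
    if "rg" in want:
        series = [_stage("rg")(metrics.rg_series)(t) for t in trajectories]
        summarize("rg", series)
    if "dist" in want:
        if not cfg["distance_pair"]:
            raise StageError("group_distance",
                             ValueError("config missing 'distance_pair'"))
        ra, rb = cfg["distance_pair"]
        chain = str(trajectories[0].topology.chains[0])
        sel_a = structure.ResidueSelection({(chain, r) for r in ra})
        sel_b = structure.ResidueSelection({(chain, r) for r in rb})
        series = [
            _stage("group_distance")(metrics.group_distance_series)(
                t, sel_a, sel_b, mode=cfg["distance_mode"])
            for t in trajectories
        ]
        summarize("dist", series)
    if "sasa" in want:
        if not cfg["ligand"]:
            raise StageError("sasa", ValueError("config missing 'ligand'"))
        series = [
            _stage("sasa")(metrics.ligand_sasa_series)(
                t, cfg["ligand"], probe=cfg["sasa_probe"],
                n_points=cfg["sasa_points"])
            for t in trajectories
        ]
        summarize("sasa", series)
        counts, edges = metrics.sasa_histogram(series)
        summaries["sasa"]["histogram"] = {
            "counts": counts.tolist(), "bin_edges": edges.tolist()}
    if "hbonds" in want:
        if not cfg["ligand"]:
            raise StageError("hbonds", ValueError("config missing 'ligand'"))
        series = [
            _stage("hbonds")(metrics.hbond_count_series)(
                t, cfg["ligand"], d_cut=cfg["hbond_dcut"],
                angle_cut=cfg["hbond_angle"])
            for t in trajectories
        ]
        summarize("hbonds", series)
    if "dcc" in want:
        dcc = _stage("dcc")(metrics.pooled_dcc)(trajectories)
        summaries["dcc"] = {
            "min": float(dcc.min()), "max": float(dcc.max()),
            "n": int(dcc.shape[0]),
        }
        if out_prefix:
            np.savetxt(f"{out_prefix}_dcc.tsv", dcc, delimiter="\t",
                       fmt="%.6f")
    if "landscape" in want:
        if not cfg["elements"]:
            raise StageError(
                "landscape",
                ValueError("config missing 'elements' (residue ranges for "
                           "beta3/alpha4/alpha2/alpha5)"))
        eldef = metrics.ElementDef(
            ranges={k: tuple(v) for k, v in cfg["elements"].items()})
        land = _stage("landscape")(metrics.distance_landscape)(
            trajectories, eldef, grid_step=cfg["kde_grid_step"])
        summaries["landscape"] = {
            "modes": [list(m) for m in land.modes],
            "bandwidths": list(land.bandwidths),
            "degenerate": land.degenerate,
        }
        if out_prefix:
            land.to_tsv(f"{out_prefix}_landscape.tsv")
            with open(f"{out_prefix}_landscape_modes.json", "w") as fh:
                json.dump(summaries["landscape"], fh, indent=2)

    report["metrics"] = summaries
    if out_prefix:
        Path(out_prefix).parent.mkdir(parents=True, exist_ok=True)
        with open(f"{out_prefix}_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
    return report


def fit_curve_table(kind: str, x, y) -> dict:
    """Dispatch a tabular (x, y) dataset to the matching curve fit."""
    if kind == "dose":
        fit = curves.fit_dose_response(x, y)
        return {"kind": "dose", "bottom": fit.bottom, "top": fit.top,
                "log_ec50": fit.log_ec50, "ec50_M": fit.ec50,
                "hill": fit.hill, "se": fit.se,
                "residual_rms": fit.residual_rms,
                "underdetermined": fit.underdetermined}
    if kind == "melt":
        fit = curves.fit_melt(x, y)
        return {"kind": "melt", "bottom": fit.bottom, "top": fit.top,
                "tm_C": fit.tm, "slope": fit.slope, "se": fit.se,
                "residual_rms": fit.residual_rms}
    if kind == "spectrum":
        fit = curves.fit_spectrum(x, y, n_components=2)
        return {"kind": "spectrum", "amplitudes": fit.amplitudes,
                "centers_nm": fit.centers, "widths_nm": fit.widths,
                "residual_rms": fit.residual_rms}
    raise ValueError(f"unknown curve kind {kind!r}")


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    return str(o)
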