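"""Configuration-driven orchestration of the analysis stages.

A :class:`RunConfig` names the input (coordinate files or a synthetic
configuration), the stages to run, parameter overrides, an output
directory and a seed.  ``run_pipeline`` executes the stages in
dependency order (alignment first), writes TSV/JSON/cube outputs whose
headers embed the parameter set and seed, and returns a machine-readable
summary.  Config files are flat ``key = value`` text; any
SyntheticConfig or AnalysisParameters field name is accepted as a key.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import yaml

from . import binding, dimers, peptides, pose, sasa
from .align import align_disc
from .io import load_trajectory, write_fixture_tsv, write_ground_truth
from .model import Trajectory
from .params import DEFAULT_PARAMS, AnalysisParameters
from .synthetic import (
    GroundTruth,
    SyntheticConfig,
    generate_disc_system,
    generate_lcat_system,
)

logger = logging.getLogger(__name__)

STAGES = (
    "rdf",
    "angles",
    "rotacf",
    "clusters",
    "dimers",
    "fel",
    "pose",
    "occupancy",
    "heatmap",
    "density",
    "sasa",
)

_LCAT_STAGES = {"pose", "occupancy", "heatmap", "density", "sasa"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    input_path: str | None = None
    topology_path: str | None = None
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    synthetic: SyntheticConfig | None = None
    params: AnalysisParameters = DEFAULT_PARAMS
    output_dir: str = "pepdisc_out"
    seed: int = 0
    log_level: str = "INFO"
    start_frame: int = 0

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}; known: {STAGES}")


_SYNTH_FIELDS = {f.name for f in dataclasses.fields(SyntheticConfig)}
_PARAM_FIELDS = {f.name for f in dataclasses.fields(AnalysisParameters)}
_TOP_KEYS = {"input", "topology", "stages", "output_dir", "seed",
             "log_level", "start_frame"}


def parse_config_file(path: str | Path) -> RunConfig:
    """Flat ``key = value`` config; '#' starts a comment."""
    synth_kwargs: dict[str, Any] = {}
    param_kwargs: dict[str, Any] = {}
    top: dict[str, Any] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), yaml.safe_load(value.strip())
        # top-level keys win over identically named generator fields
        # (the run seed is pushed into the generator at run time)
        if key in _TOP_KEYS:
            top[key] = value
        elif key in _SYNTH_FIELDS:
            synth_kwargs[key] = tuple(value) if isinstance(value, list) else value
        elif key in _PARAM_FIELDS:
            param_kwargs[key] = tuple(value) if isinstance(value, list) else value
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    stages = top.get("stages")
    if isinstance(stages, str):
        stages = [s.strip() for s in stages.split(",") if s.strip()]
    cfg = RunConfig(
        input_path=top.get("input"),
        topology_path=top.get("topology"),
        stages=stages or list(STAGES),
        synthetic=SyntheticConfig(**synth_kwargs) if synth_kwargs or not top.get("input") else None,
        params=DEFAULT_PARAMS.with_overrides(**param_kwargs),
        output_dir=str(top.get("output_dir", "pepdisc_out")),
        seed=int(top.get("seed", 0)),
        log_level=str(top.get("log_level", "INFO")),
        start_frame=int(top.get("start_frame", 0)),
    )
    return cfg


# ---------------------------------------------------------------------------
# output helpers
# ---------------------------------------------------------------------------

def _header(config: RunConfig) -> str:
    lines = [f"# seed = {config.seed}", f"# start_frame = {config.start_frame}"]
    for f in dataclasses.fields(config.params):
        lines.append(f"# {f.name} = {getattr(config.params, f.name)}")
    if config.synthetic is not None:
        for f in dataclasses.fields(config.synthetic):
            lines.append(f"# synthetic.{f.name} = {getattr(config.synthetic, f.name)}")
    return "\n".join(lines) + "\n"


def _write_tsv(path: Path, config: RunConfig, columns: list[str],
               rows: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("\t".join(columns) + "\n")
        for row in np.atleast_2d(rows):
            fh.write("\t".join(f"{v:.6g}" if isinstance(v, (float, np.floating))
                               else str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_rdf(traj, config, out) -> dict:
    prof_pep = peptides.radial_profile(traj, "peptide", params=config.params)
    prof_lip = peptides.radial_profile(traj, "lipid", params=config.params)
    _write_tsv(out / "rdf_peptide.tsv", config, ["r_nm", "density"],
               np.stack([prof_pep.bin_centers, prof_pep.density], axis=1))
    _write_tsv(out / "rdf_lipid.tsv", config, ["r_nm", "density"],
               np.stack([prof_lip.bin_centers, prof_lip.density], axis=1))
    return {"peptide_mode_radius_nm": prof_pep.mode_radius,
            "lipid_mode_radius_nm": prof_lip.mode_radius}


def _stage_angles(traj, config, out) -> dict:
    dist = peptides.normal_angle_distribution(traj, params=config.params)
    _write_tsv(out / "angle_distribution.tsv", config,
               ["angle_deg", "probability"],
               np.stack([dist.bin_centers, dist.probability], axis=1))
    mean_angle = float((dist.bin_centers * dist.probability).sum())
    return {"mean_angle_deg": mean_angle}


def _stage_rotacf(traj, config, out) -> dict:
    acf = peptides.rotacf(traj, order=1,
                          max_lag=min(traj.n_frames - 1, 200))
    _write_tsv(out / "rotacf.tsv", config, ["lag", "C"],
               np.stack([acf.lags, acf.values], axis=1))
    return {"half_life": None if np.isnan(acf.half_life) else acf.half_life}


def _stage_clusters(traj, config, out) -> dict:
    result = {}
    # clustering is per-frame O(beads^2); sample at most ~200 frames
    stride = max(1, traj.n_frames // 200)
    sub = Trajectory(traj.beads, traj.coords[::stride], traj.times[::stride],
                     traj.topology, None, traj.replicate_id)
    for cutoff in config.params.cluster_cutoffs:
        summary = peptides.cluster_summary(sub, cutoff)
        _write_tsv(out / f"clusters_{cutoff:g}nm.tsv", config,
                   ["frame", "n_clusters"],
                   np.stack([np.arange(len(summary.per_frame_counts)),
                             summary.per_frame_counts], axis=1))
        result[f"{cutoff:g}"] = {
            "mean_clusters": float(summary.per_frame_counts.mean()),
            "oligomer_fraction": summary.oligomer_fraction,
        }
    return result


def _stage_dimers(traj, config, out, cache) -> dict:
    counts, records = dimers.dimer_counts_per_frame(traj, config.params)
    cache["records"] = records
    _write_tsv(out / "dimer_counts.tsv", config,
               ["frame", "parallel", "antiparallel", "unclassified"],
               np.stack([counts.frames, counts.parallel, counts.antiparallel,
                         counts.unclassified], axis=1))
    cmap = dimers.charged_contact_map(traj, config.params, records)
    for cls in ("parallel", "antiparallel"):
        _write_tsv(out / f"charged_contacts_{cls}.tsv", config,
                   ["residue"] + cmap.labels,
                   np.asarray([[lab] + [f"{v:.4f}" for v in row]
                               for lab, row in zip(cmap.labels,
                                                   cmap.normalized[cls])],
                              dtype=object))
    return {"mean_counts": counts.means,
            "contact_map_max": {c: float(cmap.normalized[c].max())
                                for c in ("parallel", "antiparallel")}}


def _stage_fel(traj, config, out) -> dict:
    landscape = dimers.pair_landscape(traj, params=config.params)
    try:
        fel = dimers.free_energy(landscape, config.params)
    except ValueError as exc:
        raise PipelineError("fel", str(exc)) from exc
    dg = fel.delta_g
    with open(out / "free_energy_landscape.tsv", "w") as fh:
        fh.write(_header(config))
        fh.write("# rows: r bins, columns: theta bins; masked bins as nan\n")
        fh.write("r_nm\\theta_deg\t" + "\t".join(
            f"{t:.1f}" for t in 0.5 * (fel.theta_edges[:-1] + fel.theta_edges[1:])
        ) + "\n")
        centers = 0.5 * (fel.r_edges[:-1] + fel.r_edges[1:])
        filled = dg.filled(np.nan)
        for rc, row in zip(centers, filled):
            fh.write(f"{rc:.3f}\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")
    return {"dg_min_kj_mol": float(dg.min()), "dg_max_kj_mol": float(dg.max()),
            "mode_bin": list(landscape.mode_bin())}


def _stage_pose(traj, config, out) -> dict:
    series = pose.pose_series(traj, config.params)
    contacts = pose.lcat_contact_series(traj, config.params)
    _write_tsv(out / "lcat_contacts.tsv", config, ["time", "count"],
               np.stack([contacts.times, contacts.counts], axis=1))
    _write_tsv(out / "pose_series.tsv", config,
               ["frame", "r_xy", "z", "pitch", "yaw", "roll", "flip"],
               np.stack([series.frames, series.r_xy, series.z, series.pitch,
                         series.yaw, series.roll,
                         series.flip_applied.astype(int)], axis=1))
    corr = pose.pose_correlation(series, start=config.start_frame)
    return {
        "slope_deg_per_nm": corr.slope,
        "intercept_deg": corr.intercept,
        "r_squared": corr.r_squared,
        "z_mean_nm": corr.z_mean,
        "z_sd_nm": corr.z_sd,
        "n_flipped": int(series.flip_applied.sum()),
    }


def _stage_occupancy(traj, config, out) -> dict:
    series = binding.siteA_series(traj, config.params)
    stats = binding.occupancy_stats(series)
    _write_tsv(out / "siteA_states.tsv", config,
               ["frame", "bound", "peptide_id", "d1_nm", "d2_nm"],
               np.stack([series.frames, series.bound.astype(int),
                         series.peptide_id, series.d1, series.d2], axis=1))
    block = {
        "occupancy_percent": stats.occupancy_percent,
        "n_entries": stats.n_entries,
        "mean_event_length": stats.mean_event_length,
        "max_event_length": stats.max_event_length,
        "n_peptide_changes": stats.n_peptide_changes,
    }
    _write_tsv(out / "occupancy_summary.tsv", config,
               list(block.keys()),
               np.asarray([[v for v in block.values()]], dtype=object))
    return block


def _stage_heatmap(traj, config, out) -> dict:
    hm = binding.residue_contact_heatmap(traj, params=config.params)
    _write_tsv(out / "residue_contact_heatmap.tsv", config,
               ["peptide_residue"] + hm.lcat_residues,
               np.asarray([[lab] + [f"{v:.4f}" for v in row]
                           for lab, row in zip(hm.peptide_rows, hm.normalized)],
                          dtype=object))
    return {"rows": hm.peptide_rows, "max_raw": float(hm.raw.max())}


def _stage_density(traj, config, out) -> dict:
    stride = max(1, traj.n_frames // 200)
    sub = Trajectory(traj.beads, traj.coords[::stride], traj.times[::stride],
                     traj.topology, None, traj.replicate_id)
    grid = binding.spatial_density(sub, params=config.params)
    grid.write_cube(out / "peptide_density.cube")
    return {"total_counts": grid.total,
            "argmax_nm": [float(v) for v in grid.argmax_position()]}


def _stage_sasa(traj, config, out) -> dict:
    stride = max(1, (traj.n_frames - config.start_frame) // 20)
    prof = sasa.per_residue_profile(
        traj, "lcat", start=config.start_frame, stride=stride,
        label="disc-bound", params=config.params,
    )
    _write_tsv(out / "sasa_per_residue.tsv", config,
               ["residue_index", "residue_name", "mean_nm2", "sd_nm2"],
               np.asarray([[int(i), n, f"{m:.4f}", f"{s:.4f}"]
                           for i, n, m, s in zip(prof.residue_index,
                                                 prof.residue_name,
                                                 prof.mean, prof.sd)],
                          dtype=object))
    return {"total_mean_nm2": float(prof.mean.sum()),
            "n_frames": prof.n_frames}


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns (and writes) the summary."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    ground_truth: GroundTruth | None = None
    if config.input_path:
        traj = load_trajectory(config.input_path, config.topology_path)
    else:
        synth = config.synthetic or SyntheticConfig(seed=config.seed)
        synth = dataclasses.replace(synth, seed=config.seed)
        lcat_needed = bool(_LCAT_STAGES & set(config.stages))
        if lcat_needed and not synth.lcat_enabled:
            synth = dataclasses.replace(synth, lcat_enabled=True)
        if synth.lcat_enabled:
            traj, ground_truth = generate_lcat_system(synth)
        else:
            traj, ground_truth = generate_disc_system(synth)
        config = dataclasses.replace(config, synthetic=synth)
    traj = align_disc(traj)

    has_lcat = bool((traj.beads.molecule_type == "lcat").any())
    summary: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "n_frames": traj.n_frames,
        "replicate_id": traj.replicate_id,
    }
    cache: dict = {}
    runners: dict[str, Callable] = {
        "rdf": lambda: _stage_rdf(traj, config, out),
        "angles": lambda: _stage_angles(traj, config, out),
        "rotacf": lambda: _stage_rotacf(traj, config, out),
        "clusters": lambda: _stage_clusters(traj, config, out),
        "dimers": lambda: _stage_dimers(traj, config, out, cache),
        "fel": lambda: _stage_fel(traj, config, out),
        "pose": lambda: _stage_pose(traj, config, out),
        "occupancy": lambda: _stage_occupancy(traj, config, out),
        "heatmap": lambda: _stage_heatmap(traj, config, out),
        "density": lambda: _stage_density(traj, config, out),
        "sasa": lambda: _stage_sasa(traj, config, out),
    }
    for stage in config.stages:
        if stage in _LCAT_STAGES and not has_lcat:
            raise PipelineError(stage, "no LCAT molecule in the system")
        logger.info("running stage %s", stage)
        try:
            summary[stage] = runners[stage]()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    if ground_truth is not None:
        write_ground_truth(ground_truth, out / "ground_truth.json")
        write_fixture_tsv(
            Trajectory(traj.beads, traj.coords[: min(3, traj.n_frames)],
                       traj.times[: min(3, traj.n_frames)], traj.topology),
            out / "first_frames.tsv",
        )
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
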