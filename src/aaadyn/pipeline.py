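"""End-to-end orchestration of the two analyses from a YAML config.

`run_o2_accessibility` chains ILS map -> bulk reference -> channels +
minimax barriers -> group summary; `run_loop_dynamics` chains alignment ->
per-monomer loop metrics -> correlation times -> pooled PCA -> free-energy
surface -> GROMOS clusters.  Every run writes a JSON provenance manifest
(config hash, package/library versions, seed) next to its artifacts.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .conformational_landscape import fes_2d, gromos_cluster, pca_loop
from .ils_engine import (IlsConfig, bulk_reference, compute_ils_map,
                         compute_occupancy_map)
from .loop_geometry import (ThetaDefinition, align_principal_axis_z,
                            correlation_time, loop_metrics)
from .pathway_analysis import enumerate_pathways, minimax_barrier, pathway_report
from .probe_model import ProbeModel, generate_orientations
from .stats_compare import BarrierSample, summarize_barriers
from .trajectory_io import (FrameEnsemble, load_parameter_table,
                            load_structure, load_trajectory, select_atoms,
                            write_volumetric_map)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated run settings (see aaadyn docs for the YAML layout)."""

    raw: dict
    output_dir: Path
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        out = Path(raw.get("output_dir", "aaadyn_out"))
        for key in ("topology", "trajectory", "parameters"):
            p = raw.get("input", {}).get(key)
            if p and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        return cls(raw=raw, output_dir=out, seed=int(raw.get("seed", 0)))

    def ils_config(self) -> IlsConfig:
        ils = dict(self.raw.get("ils", {}))
        region = ils.pop("region", None)
        if region is not None:
            region = (tuple(region[0]), tuple(region[1]))
        try:
            return IlsConfig(region=region, seed=self.seed, **ils)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"bad ils settings: {exc}") from exc

    def probe(self) -> ProbeModel:
        p = self.raw.get("probe")
        return ProbeModel.o2() if p is None else ProbeModel.from_dict(p)


def _load_input(config: RunConfig) -> FrameEnsemble:
    inp = config.raw.get("input", {})
    if "topology" not in inp:
        raise ConfigError("config needs input.topology")
    table = (load_parameter_table(inp["parameters"])
             if inp.get("parameters") else None)
    box = tuple(inp["box"]) if inp.get("box") else None
    kwargs = dict(parameter_table=table, box=box,
                  allow_missing_parameters=bool(
                      inp.get("allow_missing_parameters", table is None)))
    if inp.get("trajectory"):
        return load_trajectory(inp["topology"], inp["trajectory"],
                               stride=int(inp.get("stride", 1)), **kwargs)
    return load_structure(inp["topology"], **kwargs)


def _manifest(config: RunConfig, stage: str, extra: dict) -> dict:
    cfg_hash = hashlib.sha256(
        json.dumps(config.raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return {"stage": stage, "config_sha256": cfg_hash, "seed": config.seed,
            "aaadyn_version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__, **extra}


def _write_manifest(config: RunConfig, name: str, manifest: dict) -> None:
    config.output_dir.mkdir(parents=True, exist_ok=True)
    with open(config.output_dir / name, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (ConfigError, StageError):
                raise
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc
        return wrapped
    return deco


def run_o2_accessibility(config: RunConfig,
                         ensemble: Optional[FrameEnsemble] = None) -> dict:
    """ILS map, bulk reference, channels and barriers per active site."""
    if ensemble is None:
        ensemble = _stage("load")(_load_input)(config)
    ils_cfg = config.ils_config()
    probe = config.probe()
    orientations = generate_orientations(ils_cfg.orientation_count)
    pmf = _stage("ils")(compute_ils_map)(ensemble, probe, orientations,
                                         ils_cfg)
    bulk_cfg = config.raw.get("bulk", {})
    bulk = _stage("bulk")(bulk_reference)(
        pmf, ensemble,
        min_distance_from_solute=float(
            bulk_cfg.get("min_distance_from_solute", 12.0)))
    reports = {}
    samples = []
    for site in config.raw.get("sites", []):
        name = site.get("name", "site")
        pos = np.asarray(site["position"], dtype=np.float64)
        voxel = tuple(np.round(
            (pos - pmf.grid.origin) / pmf.grid.spacing).astype(int))
        goal = _boundary_mask(pmf.values.shape)
        rep = _stage("barrier")(pathway_report)(
            pmf, bulk, voxel, goal, ensemble,
            lining_radius=float(site.get("lining_radius", 4.5)))
        iso = site.get("isovalue")
        channels = (_stage("channels")(enumerate_pathways)(
            pmf, float(iso), voxel) if iso is not None else [])
        reports[name] = {"report": rep, "channels": channels}
        samples.append(BarrierSample(value=rep.barrier_abs,
                                     group=site.get("group", "WT"),
                                     form=site.get("form", "apo"),
                                     replica=int(site.get("replica", 0)),
                                     monomer=name))
    summary = summarize_barriers(samples, bulk) if samples else None

    config.output_dir.mkdir(parents=True, exist_ok=True)
    write_volumetric_map(pmf.grid, config.output_dir / "pmf.dx")
    if summary is not None:
        summary.to_csv(config.output_dir / "barrier_summary.csv", index=False)
    _write_manifest(config, "o2_accessibility_manifest.json", _manifest(
        config, "o2_accessibility",
        {"n_frames": ensemble.n_frames,
         "bulk_mean_G": bulk.mean_G, "bulk_sd": bulk.sd,
         "sites": list(reports)}))
    return {"pmf": pmf, "bulk": bulk, "reports": reports, "summary": summary}


def _boundary_mask(shape) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[0, :, :] = m[-1, :, :] = True
    m[:, 0, :] = m[:, -1, :] = True
    m[:, :, 0] = m[:, :, -1] = True
    return m


def run_loop_dynamics(config: RunConfig,
                      ensemble: Optional[FrameEnsemble] = None) -> dict:
    """Loop metrics, τ, pooled PCA, FES and GROMOS clusters."""
    if ensemble is None:
        ensemble = _stage("load")(_load_input)(config)
    loop_cfg = config.raw.get("loop", {})
    theta_cfg = loop_cfg.get("theta", {})
    align_sel = loop_cfg.get("align_selection", "name CA")
    aligned = _stage("align")(align_principal_axis_z)(ensemble, align_sel)

    theta_def = ThetaDefinition(
        anchor_selection=theta_cfg.get("anchor", "name CA and resid 342"),
        tip_selection=theta_cfg.get("tip", "name CA and resid 348"),
        loop_selection=theta_cfg.get("loop", "name CA and resid 342-361"))
    ref_path = theta_cfg.get("closed_reference")
    if ref_path:
        ref = load_structure(ref_path, allow_missing_parameters=True)
        ref_aligned = align_principal_axis_z(ref, align_sel)
        theta_def = theta_def.with_reference_from(ref_aligned)
    else:
        theta_def = theta_def.with_reference_from(aligned)

    helix_range = loop_cfg.get("helix_range", (342, 361))
    if helix_range is not None:
        helix_range = tuple(helix_range)
    metrics = _stage("metrics")(loop_metrics)(
        aligned, theta_def,
        loop_cfg.get("contact_a", "resid 348"),
        loop_cfg.get("contact_b", "resid 203"),
        helix_range)
    notices = []
    dt_ns = aligned.frame_interval / 1000.0
    if aligned.n_frames >= 50 and np.var(metrics.theta_deg) > 0:
        tau = correlation_time(metrics.theta_deg, dt=dt_ns)
    else:
        tau = None
        notices.append("tau skipped: too few frames or zero variance")

    loop_sel = theta_cfg.get("loop", "name CA and resid 342-361")
    fit_sel = loop_cfg.get("fit_selection")
    if aligned.n_frames >= 2:
        pca = _stage("pca")(pca_loop)(aligned, loop_sel, fit_sel)
        fes = _stage("fes")(fes_2d)(
            pca.projections[:, :2], bins=int(loop_cfg.get("pca_bins", 50)),
            temperature=float(loop_cfg.get("temperature", 300.0)))
        clusters = _stage("cluster")(gromos_cluster)(
            aligned, loop_sel, cutoff=float(
                loop_cfg.get("cluster_cutoff", 6.2)),
            fit_selection=fit_sel)
    else:
        pca = fes = clusters = None
        notices.append("pca/fes/clustering skipped: single frame")

    config.output_dir.mkdir(parents=True, exist_ok=True)
    metrics.to_dataframe().to_csv(config.output_dir / "loop_metrics.csv",
                                  index=False)
    if pca is not None:
        import pandas as pd
        pd.DataFrame({"frame": np.arange(aligned.n_frames),
                      "PC1": pca.projections[:, 0],
                      "PC2": pca.projections[:, 1]}).to_csv(
            config.output_dir / "pca_projections.csv", index=False)
        pd.DataFrame({"frame": np.arange(aligned.n_frames),
                      "cluster": clusters.labels}).to_csv(
            config.output_dir / "clusters.csv", index=False)
        from .trajectory_io import write_structure
        for ci, center in enumerate(clusters.centers):
            write_structure(aligned, config.output_dir
                            / f"cluster_{ci + 1}_centroid.pdb", frame=center)
    _write_manifest(config, "loop_dynamics_manifest.json", _manifest(
        config, "loop_dynamics",
        {"n_frames": aligned.n_frames,
         "tau_ns": None if tau is None else tau.tau,
         "notices": notices}))
    return {"metrics": metrics, "tau": tau, "pca": pca, "fes": fes,
            "clusters": clusters, "notices": notices,
            "theta_def": theta_def, "aligned": aligned}
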