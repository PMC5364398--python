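"""Configuration-driven orchestration of the full analysis.

A pipeline run takes one YAML-style config (validated against a known-key
schema), loads or synthesizes a trajectory, executes the requested stages in
dependency order and writes CSV/JSON outputs plus a run manifest holding the
config hash, package version, seed and per-stage wall times.  Identical
config + seed reproduces every numeric output bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .builder import build_hexagonal_scaffold, place_hydrophobic_bands
from .membrane import (ion_selectivity, order_parameter_grid, radial_density,
                       rdf, thickness_profile)
from .model import analysis_window, read_structure, read_trajectory, select
from .pore import (RESISTIVITY_OHM_CM, conductance_estimate,
                   pore_profile_over_time)
from .dynamics import (com_displacement, membrane_deformation_track,
                       residence_times, rmsd_partitioned, smd_barriers,
                       tilt_series)
from .roles import DNT_ROLES, LIPID_ROLES, Role, builtin_dialect
from .synth import (MembraneSystemParams, SMDTraceParams,
                    generate_membrane_system, generate_smd_trace)

STAGES = ("profile", "thickness", "order", "rdf", "ions", "pore", "residence",
          "tilt", "com", "smd", "rmsd", "deform")

_TOP_KEYS = {"input", "synth", "dialect", "window_ns", "stages", "seed",
             "output_dir", "params"}
_INPUT_KEYS = {"structure", "trajectory", "frame_interval_ps"}


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    unknown = set(config) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "input" in config and "synth" in config:
        raise ConfigError("config must give either 'input' or 'synth', not both")
    if "input" in config:
        bad = set(config["input"]) - _INPUT_KEYS
        if bad:
            raise ConfigError(f"unknown input keys: {sorted(bad)}")
    stages = config.get("stages", [])
    bad = set(stages) - set(STAGES)
    if bad:
        raise ConfigError(f"unknown stages: {sorted(bad)}; known: {STAGES}")
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_csv(path: Path, df: pd.DataFrame, units: str, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# units: {units}; config={chash}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def _load_trajectory(config: dict):
    seed = int(config.get("seed", 0))
    if "synth" in config:
        sp = dict(config["synth"])
        n_frames = int(sp.pop("n_frames", 20))
        frame_interval = float(sp.pop("frame_interval_ps", 50.0))
        band_layout = sp.pop("band_layout", None)
        tube_kwargs = sp.pop("tube", None)
        params = MembraneSystemParams(**sp, seed=seed)
        if tube_kwargs or band_layout:
            model = build_hexagonal_scaffold(**(tube_kwargs or {}))
            if band_layout:
                model = place_hydrophobic_bands(model, band_layout)
            params.tube = model
        traj, truth = generate_membrane_system(params, n_frames, frame_interval)
        return traj, truth
    inp = config["input"]
    dialect = builtin_dialect(config.get("dialect", "cg-martini"))
    top, frame = read_structure(inp["structure"], dialect)
    if "trajectory" in inp:
        traj = read_trajectory(inp["trajectory"], top,
                               frame_interval=inp.get("frame_interval_ps"))
    else:
        from .model import Trajectory
        traj = Trajectory(top, [frame])
    return traj, None


def run_pipeline(config: dict, output_dir) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    validate_config(config)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seed = int(config.get("seed", 0))
    params = config.get("params", {})
    manifest = {
        "config_hash": chash,
        "package_version": __version__,
        "seed": seed,
        "stages": {},
        "warnings": [],
    }

    traj, truth = _load_trajectory(config)
    if truth is not None:
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    if "window_ns" in config:
        traj = analysis_window(traj, float(config["window_ns"]))
    manifest["n_frames"] = len(traj)

    stage_fns = {
        "profile": _stage_profile,
        "thickness": _stage_thickness,
        "order": _stage_order,
        "rdf": _stage_rdf,
        "ions": _stage_ions,
        "pore": _stage_pore,
        "residence": _stage_residence,
        "tilt": _stage_tilt,
        "com": _stage_com,
        "smd": _stage_smd,
        "rmsd": _stage_rmsd,
        "deform": _stage_deform,
    }
    for stage in config.get("stages", []):
        t0 = _time.perf_counter()
        try:
            stage_fns[stage](traj, params.get(stage, {}), outdir, chash,
                             manifest, seed)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "wall_time_s": round(_time.perf_counter() - t0, 3)
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# --- stage implementations (thin wrappers over the library) ----------------

def _stage_profile(traj, p, outdir, chash, manifest, seed):
    roles = [Role(r) for r in p.get("roles", ["DNA_BB", "ETHYL", "LIPID_PO4",
                                              "WATER", "ION_NA", "ION_CL"])]
    prof = radial_density(traj, roles,
                          shell_width=p.get("shell_width", 0.1),
                          cylinder_half_length=p.get("cylinder_half_length", 2.0))
    df = pd.DataFrame({"r_nm": prof.shell_centres})
    for role, dens in prof.density_per_role.items():
        df[f"density_{role.value}"] = dens
    _write_csv(outdir / "radial_density.csv", df, "r in nm, density in nm^-3", chash)


def _stage_thickness(traj, p, outdir, chash, manifest, seed):
    r, th = thickness_profile(traj, shell_width=p.get("shell_width", 0.1))
    _write_csv(outdir / "thickness.csv",
               pd.DataFrame({"r_nm": r, "thickness_nm": th}),
               "r and thickness in nm", chash)
    if np.isnan(th).any():
        manifest["warnings"].append("thickness: some shells unpopulated")


def _stage_order(traj, p, outdir, chash, manifest, seed):
    grid = order_parameter_grid(traj, grid_cell=p.get("grid_cell", 1.0))
    nx, ny = grid.S.shape
    xs, ys = np.meshgrid(range(nx), range(ny), indexing="ij")
    df = pd.DataFrame({"ix": xs.ravel(), "iy": ys.ravel(),
                       "S": grid.S.ravel(), "n_bonds": grid.counts.ravel()})
    _write_csv(outdir / "order_parameter.csv", df,
               "1x1 nm^2 cells, S dimensionless", chash)


def _stage_rdf(traj, p, outdir, chash, manifest, seed):
    a = select(traj.topology, roles=Role(p.get("role_a", "DNA_BB")))
    b = select(traj.topology, roles=Role(p.get("role_b", "LIPID_PO4")))
    res = rdf(traj, a, b, bin_width=p.get("bin_width", 0.02),
              r_max=p.get("r_max", 3.0))
    _write_csv(outdir / "rdf.csv", pd.DataFrame({"r_nm": res.r, "g": res.g}),
               "r in nm, g dimensionless", chash)


def _stage_ions(traj, p, outdir, chash, manifest, seed):
    sel = ion_selectivity(traj, lumen_radius=p.get("lumen_radius", 1.0),
                          lumen_half_length=p.get("lumen_half_length", 5.0))
    (outdir / "ion_selectivity.json").write_text(json.dumps({
        "ratio": sel.ratio, "mean_na": sel.mean_na, "mean_cl": sel.mean_cl,
        "ci_95": [sel.ci_low, sel.ci_high], "config": chash}, indent=1))


def _stage_pore(traj, p, outdir, chash, manifest, seed):
    prof = pore_profile_over_time(
        traj, z_range=tuple(p.get("z_range", (-5.0, 5.0))),
        dz=p.get("dz", 0.2), seed=seed,
        n_moves=p.get("n_moves", 1000),
    )
    df = pd.DataFrame({"z_nm": prof.z_grid, "mean_radius_nm": prof.mean_radius,
                       "sd_radius_nm": prof.sd_radius})
    _write_csv(outdir / "pore_profile.csv", df, "z and radius in nm", chash)
    long = pd.DataFrame({
        "frame": np.repeat(np.arange(prof.radius_per_frame.shape[0]),
                           len(prof.z_grid)),
        "z_nm": np.tile(prof.z_grid, prof.radius_per_frame.shape[0]),
        "radius_nm": prof.radius_per_frame.ravel(),
    })
    _write_csv(outdir / "pore_profile_frames.csv", long, "z and radius in nm", chash)
    if "resistivity" in p:
        est = conductance_estimate(
            prof, p["resistivity"] if isinstance(p["resistivity"], (int, float))
            else RESISTIVITY_OHM_CM[p["resistivity"]],
            mode=p.get("mode", "series_integral"))
        (outdir / "conductance.json").write_text(json.dumps({
            "g_nS": est.g_nS, "mode": est.mode, "length_nm": est.length,
            "resistivity_ohm_cm": est.resistivity_ohm_cm, "config": chash},
            indent=1))


def _stage_residence(traj, p, outdir, chash, manifest, seed):
    lip = select(traj.topology, roles=LIPID_ROLES)
    dna = select(traj.topology, roles=DNT_ROLES)
    rmap = residence_times(traj, lip, dna, cutoff=p.get("cutoff", 0.5),
                           gap_tolerance=p.get("gap_tolerance", 0))
    rows = [{"bead": k[0], "groove": k[1], "mean_residence_ps": v[0],
             "n_events": v[1]} for k, v in sorted(rmap.mean_residence().items())]
    _write_csv(outdir / "residence.csv", pd.DataFrame(rows),
               "residence in ps", chash)


def _stage_tilt(traj, p, outdir, chash, manifest, seed):
    angles, hist, edges = tilt_series(traj, bins_deg=p.get("bins_deg", 1.0))
    _write_csv(outdir / "tilt.csv",
               pd.DataFrame({"time_ps": traj.times, "tilt_deg": angles}),
               "tilt in degrees", chash)


def _stage_com(traj, p, outdir, chash, manifest, seed):
    group = select(traj.topology, roles=Role.ETHYL)
    if len(group) == 0:
        group = select(traj.topology, roles=DNT_ROLES)
    trace = com_displacement(traj, group, tol_rel=p.get("tol_rel", 0.3))
    _write_csv(outdir / "com_displacement.csv",
               pd.DataFrame({"time_ps": trace.time, "dz_nm": trace.dz}),
               "dz in nm", chash)
    (outdir / "com_classification.json").write_text(json.dumps({
        "classification": trace.classification,
        "relaxation_time_ns": trace.relaxation_time_ns, "config": chash},
        indent=1))


def _stage_smd(traj, p, outdir, chash, manifest, seed):
    sp = SMDTraceParams(**{k: v for k, v in p.items()
                           if k not in ("duration_us", "dt_ps")}, seed=seed)
    trace, truth = generate_smd_trace(sp, duration_us=p.get("duration_us", 2.5),
                                      dt_ps=p.get("dt_ps", 100.0))
    res = smd_barriers(trace)
    (outdir / "smd_barriers.json").write_text(json.dumps({
        "entry_barrier": res.entry_barrier, "exit_barrier": res.exit_barrier,
        "entry_location_z": res.entry_location_z,
        "exit_location_z": res.exit_location_z, "config": chash}, indent=1))


def _stage_rmsd(traj, p, outdir, chash, manifest, seed):
    tm, out = rmsd_partitioned(traj, traj.frames[0])
    _write_csv(outdir / "rmsd.csv",
               pd.DataFrame({"time_ps": traj.times, "rmsd_tm_nm": tm,
                             "rmsd_outside_nm": out}),
               "rmsd in nm", chash)


def _stage_deform(traj, p, outdir, chash, manifest, seed):
    times, x, curves = membrane_deformation_track(
        traj, lateral_bin=p.get("lateral_bin", 1.0),
        sample_every_ps=p.get("sample_every_ps"))
    rows = []
    for k, t in enumerate(times):
        for leaflet in (0, 1):
            for b, xc in enumerate(x):
                rows.append({"time_ps": t, "leaflet": leaflet, "x_nm": xc,
                             "z_nm": curves[k, leaflet, b]})
    _write_csv(outdir / "membrane_deformation.csv", pd.DataFrame(rows),
               "x and z in nm", chash)
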