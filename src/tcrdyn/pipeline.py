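"""Study orchestration: run every analysis stage over every system from
one structured config, reproducibly.

The driver loads each system (topology + trajectory + region config),
discards the equilibration head (trim_ns, 50 ns in the original
workflow), runs the enabled stages, and writes flat CSV/JSON tables plus
a run manifest. Identical config + seed produces byte-identical stage
outputs. A failing stage is recorded in the manifest and later
independent stages still run.
"""

from __future__ import annotations

import json
import logging
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import correlation as corr_mod
from . import energies as en_mod
from . import essential as ed_mod
from . import fluctuations as fl_mod
from . import hbonds as hb_mod
from . import membrane as mb_mod
from . import network as net_mod
from . import zernike as zk_mod
from .io import read_structure, read_trajectory
from .model import TrajectoryError, apply_region_config, load_region_config, trim_equilibration

__all__ = ["load_study_config", "validate_config", "run_study"]

log = logging.getLogger("tcrdyn.pipeline")

_FLOAT_FMT = "%.10g"

STAGES = (
    "rmsd",
    "rmsf",
    "ed",
    "ccmap",
    "network",
    "hbonds",
    "zernike",
    "membrane",
    "energy",
)


def load_study_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cfg.setdefault("_base_dir", os.path.dirname(os.path.abspath(path)))
    return cfg


def _resolve(cfg: dict, p: str) -> str:
    base = cfg.get("_base_dir", ".")
    return p if os.path.isabs(p) else os.path.join(base, p)


def validate_config(cfg: dict) -> list:
    """Check a study config; returns a list of diagnostics (empty = runnable)."""
    diags = []
    systems = cfg.get("systems", [])
    if not systems:
        diags.append("config lists no systems")
    names = [s.get("name") for s in systems]
    for n in set(names):
        if names.count(n) > 1:
            diags.append(f"duplicate system name {n!r}")
    for s in systems:
        if "topology" not in s:
            diags.append(f"system {s.get('name')!r} lacks a topology path")
        elif not os.path.exists(_resolve(cfg, s["topology"])):
            diags.append(f"system {s.get('name')!r}: missing topology file {s['topology']}")
        if "trajectory" in s and not os.path.exists(_resolve(cfg, s["trajectory"])):
            diags.append(f"system {s.get('name')!r}: missing trajectory file {s['trajectory']}")
        if "regions" in s and not os.path.exists(_resolve(cfg, s["regions"])):
            diags.append(f"system {s.get('name')!r}: missing region config {s['regions']}")
    for group in cfg.get("combined_ed", []):
        for n in group.get("systems", []):
            if n not in names:
                diags.append(f"combined_ed group references unknown system {n!r}")
    trim = cfg.get("trim_ns", 0.0)
    if trim is not None and trim < 0:
        diags.append("trim_ns must be >= 0")
    return diags


def _load_system(cfg: dict, syscfg: dict):
    top, ens = read_structure(_resolve(cfg, syscfg["topology"]))
    if "trajectory" in syscfg:
        ens = read_trajectory(
            top,
            _resolve(cfg, syscfg["trajectory"]),
            fmt=syscfg.get("trajectory_format"),
            dt_ns=syscfg.get("dt_ns"),
        )
    if "regions" in syscfg:
        apply_region_config(top, load_region_config(_resolve(cfg, syscfg["regions"])))
    trim = cfg.get("trim_ns", 0.0) or 0.0
    if trim > 0 and ens.times is not None:
        ens = trim_equilibration(ens, trim)
    return top, ens


def _write_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _stage_rmsd(ens, outdir, params, seed):
    sel = params.get("selection")
    series = fl_mod.rmsd_series(ens, selection=sel, fit=params.get("fit", True))
    t = series.times if series.times is not None else np.arange(len(series.values))
    _write_csv(
        pd.DataFrame({"time_ns": t, "rmsd_nm": series.values}),
        os.path.join(outdir, "rmsd.csv"),
    )
    return ["rmsd.csv"]


def _stage_rmsf(ens, outdir, params, seed):
    prof = fl_mod.rmsf_profile(
        ens,
        selection=params.get("selection"),
        reference_mode=params.get("reference_mode", "initial"),
    )
    _write_csv(
        pd.DataFrame({"atom_id": prof.atom_ids, "rmsf_nm": prof.values}),
        os.path.join(outdir, "rmsf.csv"),
    )
    res, vals = fl_mod.rmsf_by_residue(ens, prof)
    _write_csv(
        pd.DataFrame({"residue": res, "rmsf_nm": vals}),
        os.path.join(outdir, "rmsf_residue.csv"),
    )
    return ["rmsf.csv", "rmsf_residue.csv"]


def _stage_ed(ens, outdir, params, seed):
    sel = params.get("selection")
    space = ed_mod.essential_subspace(ens, selection=sel)
    k = params.get("k", 2)
    proj = ed_mod.project(ens, space, selection=sel, k=k)
    _write_csv(
        pd.DataFrame(
            {"mode": np.arange(1, len(space.eigenvalues) + 1), "eigenvalue_nm2": space.eigenvalues}
        ),
        os.path.join(outdir, "ed_eigenvalues.csv"),
    )
    _write_csv(
        pd.DataFrame(proj.coords, columns=[f"pc{i+1}" for i in range(k)]),
        os.path.join(outdir, "ed_projection.csv"),
    )
    return ["ed_eigenvalues.csv", "ed_projection.csv"]


def _stage_ccmap(ens, outdir, params, seed):
    sel = params.get("selection")
    cm = corr_mod.cross_correlation_matrix(ens, selection=sel)
    _write_csv(pd.DataFrame(cm.values), os.path.join(outdir, "ccmap.csv"))
    labels = corr_mod.classify_correlations(cm)
    _write_csv(pd.DataFrame(labels), os.path.join(outdir, "ccmap_classes.csv"))
    files = ["ccmap.csv", "ccmap_classes.csv"]
    top = ens.topology
    if top.region_map:
        idx = {int(a): k for k, a in enumerate(cm.atom_ids)}
        region_pos = {
            name: np.array([idx[int(a)] for a in ids if int(a) in idx], dtype=int)
            for name, ids in top.region_map.items()
        }
        region_pos = {k: v for k, v in region_pos.items() if v.size}
        # drop aggregate regions that overlap the fine-grained ones
        seen: set = set()
        disjoint = {}
        for name in sorted(region_pos):
            s = set(region_pos[name].tolist())
            if not (seen & s):
                disjoint[name] = region_pos[name]
                seen |= s
        summary = corr_mod.region_block_summary(cm, disjoint)
        _write_json(
            summary.to_dict(orient="records"), os.path.join(outdir, "ccmap_blocks.json")
        )
        files.append("ccmap_blocks.json")
    return files


def _stage_network(ens, outdir, params, seed):
    sample_n = min(params.get("sample_n", 100), ens.n_frames)
    dist = net_mod.metric_distributions(
        ens,
        selection=params.get("selection"),
        sample_n=sample_n,
        cutoff=params.get("cutoff", net_mod.DEFAULT_CUTOFF_NM),
        sampling=params.get("sampling", "even"),
        seed=seed,
    )
    _write_csv(dist, os.path.join(outdir, "network_metrics.csv"))
    summary = (
        dist.groupby(["residue", "metric"])["value"]
        .agg(median="median", q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
    _write_csv(summary, os.path.join(outdir, "network_summary.csv"))
    return ["network_metrics.csv", "network_summary.csv"]


def _stage_hbonds(ens, outdir, params, seed):
    top = ens.topology
    if not top.position_labels:
        raise TrajectoryError("hbonds stage needs peptide position labels")
    crit = hb_mod.HBondCriteria(
        d_cut=params.get("d_cut", 0.35), angle_cut=params.get("angle_cut", 30.0)
    )
    partner = {
        name: top.region_map[name]
        for name in ("groove", "TCRa", "TCRb", "donors")
        if name in top.region_map
    }
    table = hb_mod.occupancy_table(ens, partner_selections=partner, criteria=crit)
    _write_csv(table, os.path.join(outdir, "hbond_occupancy.csv"))
    pres = hb_mod.presence_table(table, min_occupancy=params.get("min_occupancy", 0.1))
    pres.to_csv(os.path.join(outdir, "hbond_presence.csv"), float_format=_FLOAT_FMT)
    return ["hbond_occupancy.csv", "hbond_presence.csv"]


def _stage_zernike(ens, outdir, params, seed):
    top = ens.topology
    sel = params.get("selection", "groove")
    from .model import as_indices

    idx = as_indices(top, sel)
    frame = params.get("frame", 0)
    grid = zk_mod.voxelize_shape(
        ens.coords[frame, idx, :],
        elements=top.elements[idx],
        grid_side=params.get("grid_side", 64),
    )
    desc = zk_mod.zernike_invariants(
        zk_mod.zernike_moments(grid, order=params.get("order", 20))
    )
    df = pd.DataFrame(
        {
            "n": [nl[0] for nl in desc.index],
            "l": [nl[1] for nl in desc.index],
            "invariant": desc.values,
        }
    )
    _write_csv(df, os.path.join(outdir, "zernike_shape.csv"))
    files = ["zernike_shape.csv"]
    charges = params.get("charges")  # optional per-atom charge list
    if charges is not None:
        pos, neg = zk_mod.voxelize_electrostatics(
            ens.coords[frame, idx, :],
            charges=np.asarray(charges, dtype=float),
            elements=top.elements[idx],
            grid_side=params.get("grid_side", 64),
        )
        for g, tag in ((pos, "positive"), (neg, "negative")):
            d = zk_mod.zernike_invariants(zk_mod.zernike_moments(g, order=params.get("order", 20)))
            _write_csv(
                pd.DataFrame(
                    {
                        "n": [nl[0] for nl in d.index],
                        "l": [nl[1] for nl in d.index],
                        "invariant": d.values,
                    }
                ),
                os.path.join(outdir, f"zernike_{tag}.csv"),
            )
            files.append(f"zernike_{tag}.csv")
    return files


def _stage_membrane(ens, outdir, params, seed):
    top = ens.topology
    if "headgroups" not in top.region_map:
        raise TrajectoryError("membrane stage needs a 'headgroups' region")
    n_x = params.get("n_x", 100)
    n_y = params.get("n_y", 100)
    tm = mb_mod.thickness_map(ens, frame=params.get("frame", 0), n_x=n_x, n_y=n_y)
    nx_i, ny_i = np.meshgrid(np.arange(n_x), np.arange(n_y), indexing="ij")
    _write_csv(
        pd.DataFrame(
            {
                "ix": nx_i.ravel(),
                "iy": ny_i.ravel(),
                "thickness_nm": tm.values.ravel(),
                "occupied": tm.occupied.ravel().astype(int),
            }
        ),
        os.path.join(outdir, "thickness_map.csv"),
    )
    halves = mb_mod.thickness_comparison(ens, n_x=n_x, n_y=n_y)
    _write_json(halves, os.path.join(outdir, "thickness_halves.json"))
    files = ["thickness_map.csv", "thickness_halves.json"]
    sels = params.get("distance_selections")
    if sels:
        df = mb_mod.bilayer_distance_series(ens, sels[0], sels[1])
        _write_csv(df, os.path.join(outdir, "bilayer_distance.csv"))
        files.append("bilayer_distance.csv")
    return files


def _stage_energy(ens, outdir, params, seed):
    pairs = [tuple(p) for p in params.get("pairs", [["peptide", "groove"]])]
    if "params" in params:
        nb = en_mod.NonbondedParams.from_table(params["params"])
    else:
        nb = en_mod.toy_params()
    result = en_mod.energy_distribution(
        ens, pairs, nb, cutoff=params.get("cutoff", en_mod.DEFAULT_CUTOFF_NM)
    )
    files = []
    for (a, b), res in result.items():
        stem = f"energy_{a}_{b}"
        _write_csv(res["series"], os.path.join(outdir, f"{stem}.csv"))
        _write_csv(
            pd.DataFrame(
                {
                    "bin_left": res["hist_edges"][:-1],
                    "bin_right": res["hist_edges"][1:],
                    "count": res["hist_counts"],
                }
            ),
            os.path.join(outdir, f"{stem}_hist.csv"),
        )
        files += [f"{stem}.csv", f"{stem}_hist.csv"]
    return files


_STAGE_FUNCS = {
    "rmsd": _stage_rmsd,
    "rmsf": _stage_rmsf,
    "ed": _stage_ed,
    "ccmap": _stage_ccmap,
    "network": _stage_network,
    "hbonds": _stage_hbonds,
    "zernike": _stage_zernike,
    "membrane": _stage_membrane,
    "energy": _stage_energy,
}


def run_study(cfg, outdir=None) -> dict:
    """Execute the configured stages on every system; returns the manifest.

    ``cfg`` is a config dict or a path to a YAML study config. The
    manifest records per-stage status, parameters and output files, and is
    written atomically to ``<outdir>/manifest.json``.
    """
    if not isinstance(cfg, dict):
        cfg = load_study_config(cfg)
    diags = validate_config(cfg)
    if diags:
        raise TrajectoryError("invalid study config: " + "; ".join(diags))
    outdir = outdir or cfg.get("outdir", "tcrdyn_out")
    os.makedirs(outdir, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stage_cfg = cfg.get("stages", {})
    manifest: dict = {"systems": {}, "combined_ed": {}, "parameters": stage_cfg, "seed": seed}

    loaded = {}
    for syscfg in cfg["systems"]:
        name = syscfg["name"]
        sysdir = os.path.join(outdir, name)
        os.makedirs(sysdir, exist_ok=True)
        manifest["systems"][name] = {}
        try:
            top, ens = _load_system(cfg, syscfg)
            loaded[name] = (top, ens, syscfg)
        except Exception as exc:  # noqa: BLE001 - recorded, later systems still run
            manifest["systems"][name]["load"] = {"status": "failed", "error": str(exc)}
            log.error("system %s failed to load: %s", name, exc)
            continue
        enabled = syscfg.get("stages", list(stage_cfg) or ["rmsd", "rmsf", "ed", "ccmap", "network"])
        for stage in enabled:
            if stage not in _STAGE_FUNCS:
                manifest["systems"][name][stage] = {
                    "status": "failed",
                    "error": f"unknown stage {stage!r}",
                }
                continue
            params = dict(stage_cfg.get(stage) or {})
            t0 = time.time()
            try:
                files = _STAGE_FUNCS[stage](ens, sysdir, params, seed)
                manifest["systems"][name][stage] = {
                    "status": "ok",
                    "outputs": files,
                    "wall_s": round(time.time() - t0, 3),
                }
                log.info("system %s stage %s ok (%s)", name, stage, files)
            except Exception as exc:  # noqa: BLE001
                manifest["systems"][name][stage] = {"status": "failed", "error": str(exc)}
                log.error("system %s stage %s failed: %s", name, stage, exc)

    for group in cfg.get("combined_ed", []):
        gname = group.get("name", "+".join(group["systems"]))
        gdir = os.path.join(outdir, "combined", gname)
        os.makedirs(gdir, exist_ok=True)
        try:
            members = [loaded[n] for n in group["systems"]]
            ensembles = [m[1] for m in members]
            sel = group.get("selection")
            space, projs = ed_mod.combined_subspace(
                ensembles, selections=[sel] * len(ensembles), systems=group["systems"]
            )
            _write_csv(
                pd.DataFrame(
                    {
                        "mode": np.arange(1, len(space.eigenvalues) + 1),
                        "eigenvalue_nm2": space.eigenvalues,
                    }
                ),
                os.path.join(gdir, "eigenvalues.csv"),
            )
            overlaps = {}
            for i, pa in enumerate(projs):
                _write_csv(
                    pd.DataFrame(pa.coords, columns=["pc1", "pc2"]),
                    os.path.join(gdir, f"projection_{pa.system}.csv"),
                )
                for pb in projs[i + 1:]:
                    overlaps[f"{pa.system}|{pb.system}"] = ed_mod.subspace_overlap(pa, pb)
            _write_json(overlaps, os.path.join(gdir, "overlap.json"))
            manifest["combined_ed"][gname] = {"status": "ok", "overlaps": overlaps}
        except Exception as exc:  # noqa: BLE001
            manifest["combined_ed"][gname] = {"status": "failed", "error": str(exc)}
            log.error("combined ED group %s failed: %s", gname, exc)

    tmp = os.path.join(outdir, "manifest.json.tmp")
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, os.path.join(outdir, "manifest.json"))
    return manifest
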