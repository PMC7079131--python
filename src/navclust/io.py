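"""Readers/writers for the interchange formats and the pipeline runner.

Formats: localization tables are CSV with header frame,x_nm,y_nm,intensity,
precision_nm (vendor extras preserved); clamp traces are long-format CSV
(sweep,time_ms,v_mV,i_pA) with a sidecar JSON carrying capacitance and
protocol metadata; movies and stacks are multi-page TIFF; ground truth and
summaries are JSON.  Every pipeline run writes a manifest (seed, parameters,
versions) sufficient to reproduce its outputs bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .traces import Sweep, TraceSet

__all__ = [
    "SchemaError",
    "FormatError",
    "read_localizations",
    "write_localizations",
    "read_traces",
    "write_traces",
    "read_stack",
    "write_stack",
    "run_pipeline",
]

LOC_REQUIRED = ["frame", "x_nm", "y_nm", "intensity", "precision_nm"]
TRACE_COLUMNS = ["sweep", "time_ms", "v_mV", "i_pA"]


class SchemaError(ValueError):
    """A file is missing a required column; the message names it."""


class FormatError(ValueError):
    """A file violates a structural constraint (sampling, row shape)."""


# --------------------------------------------------------------------------
# localization tables
# --------------------------------------------------------------------------

def write_localizations(table: pd.DataFrame, path) -> None:
    missing = [c for c in LOC_REQUIRED if c not in table.columns]
    if missing:
        raise SchemaError(f"localization table missing required column(s): {missing}")
    table.to_csv(path, index=False, lineterminator="\n")


def read_localizations(path) -> pd.DataFrame:
    """Read a localization CSV; vendor extra columns are passed through."""
    df = pd.read_csv(path)
    missing = [c for c in LOC_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; header must "
            f"include {LOC_REQUIRED}")
    bad = df.index[df[LOC_REQUIRED].isna().any(axis=1)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise FormatError(f"{path}: malformed rows at line(s) {lines}")
    return df


# --------------------------------------------------------------------------
# clamp traces
# --------------------------------------------------------------------------

def write_traces(ts: TraceSet, csv_path, sidecar_path=None) -> None:
    """Long-format trace CSV plus a sidecar JSON with cell/protocol metadata."""
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json") if sidecar_path is None else Path(sidecar_path)
    frames = []
    for k, sw in enumerate(ts.sweeps):
        frames.append(pd.DataFrame({
            "sweep": k, "time_ms": sw.time_ms, "v_mV": sw.voltage,
            "i_pA": sw.current_pa}))
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False, lineterminator="\n")
    meta = {
        "capacitance_pf": ts.c_m,
        "protocol": ts.protocol,
        "intervals_ms": [sw.interval_ms for sw in ts.sweeps],
        "meta": {k: v for k, v in ts.meta.items() if not isinstance(v, np.ndarray)},
    }
    if "p1_time_ms" in ts.meta:
        meta["p1_time_ms"] = np.asarray(ts.meta["p1_time_ms"]).tolist()
        meta["p1_current_pa"] = np.asarray(ts.meta["p1_current_pa"]).tolist()
    sidecar_path.write_text(json.dumps(meta))


def read_traces(csv_path, sidecar_path=None) -> TraceSet:
    """Reconstruct a TraceSet; row order independent, sampling validated."""
    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json") if sidecar_path is None else Path(sidecar_path)
    df = pd.read_csv(csv_path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{csv_path}: missing required column(s) {missing}")
    meta = json.loads(sidecar_path.read_text())
    intervals = meta.get("intervals_ms") or []
    sweeps = []
    for k, grp in df.groupby("sweep", sort=True):
        grp = grp.sort_values("time_ms")
        t = grp["time_ms"].to_numpy(dtype=float)
        if t.size >= 3:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise FormatError(
                    f"{csv_path}: non-uniform sampling within sweep {k} "
                    f"(missing or duplicated time points)")
        iv = intervals[int(k)] if int(k) < len(intervals) else None
        sweeps.append(Sweep(voltage=float(grp["v_mV"].iloc[0]), time_ms=t,
                            current_pa=grp["i_pA"].to_numpy(dtype=float),
                            interval_ms=iv))
    ts = TraceSet(sweeps, c_m=float(meta["capacitance_pf"]),
                  protocol=meta.get("protocol", "activation"),
                  meta=dict(meta.get("meta", {})))
    if "p1_time_ms" in meta:
        ts.meta["p1_time_ms"] = np.asarray(meta["p1_time_ms"], dtype=float)
        ts.meta["p1_current_pa"] = np.asarray(meta["p1_current_pa"], dtype=float)
    return ts


# --------------------------------------------------------------------------
# image stacks
# --------------------------------------------------------------------------

def write_stack(stack: np.ndarray, path, voxel_size=None) -> None:
    tifffile.imwrite(path, np.asarray(stack))
    if voxel_size is not None:
        Path(path).with_suffix(".json").write_text(
            json.dumps({"voxel_size_um": list(voxel_size)}))


def read_stack(path) -> tuple[np.ndarray, tuple | None]:
    arr = tifffile.imread(path)
    sidecar = Path(path).with_suffix(".json")
    voxel = None
    if sidecar.exists():
        voxel = tuple(json.loads(sidecar.read_text())["voxel_size_um"])
    return arr, voxel


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

_KNOWN_KEYS = {
    "command", "seed", "out_dir", "ephys", "loc", "pla", "fit", "cluster",
    "tau_rec", "input", "log_level",
}


def _validate_config(config: dict) -> None:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")


def run_pipeline(config: dict) -> dict:
    """Execute one pipeline stage and write its artifacts plus a manifest.

    ``config`` holds the command name, seed, output directory and the
    command-specific parameter block.  Commands: simulate-ephys, fit-ephys,
    simulate-storm, analyze-storm, simulate-pla, quantify-pla.  Returns the
    manifest dict.  A stage failure raises with a stage-tagged message.
    """
    from . import __version__, fitting, pla, simulate, storm

    _validate_config(config)
    command = config.get("command")
    seed = int(config.get("seed", 0))
    out = Path(config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    # one global seed expanded into per-stage substreams
    stage_names = ["simulate-ephys", "fit-ephys", "simulate-storm",
                   "analyze-storm", "simulate-pla", "quantify-pla"]
    if command not in stage_names:
        raise ValueError(f"unknown command {command!r}; choose from {stage_names}")
    sub = {name: int(s.generate_state(1)[0] % (2**31))
           for name, s in zip(stage_names, np.random.SeedSequence(seed).spawn(len(stage_names)))}
    manifest = {"command": command, "seed": seed, "stage_seed": sub[command],
                "version": __version__, "parameters": {}, "outputs": [],
                "inputs": {}}

    def save_json(name, obj):
        p = out / name
        p.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable))
        manifest["outputs"].append(name)

    try:
        if command == "simulate-ephys":
            cfg = simulate.EphysSimConfig(**{**config.get("ephys", {}), "seed": sub[command]})
            manifest["parameters"] = _cfg_dict(cfg)
            act, truth_a = simulate.simulate_activation_family(cfg)
            inact, _ = simulate.simulate_inactivation_family(cfg)
            rec, truth_r = simulate.simulate_recovery_family(cfg, config.get("tau_rec", 7.64))
            for name, ts in [("activation", act), ("inactivation", inact), ("recovery", rec)]:
                write_traces(ts, out / f"{name}.csv")
                manifest["outputs"] += [f"{name}.csv", f"{name}.json"]
            save_json("truth.json", {
                "peak_g_over_gmax": truth_a["peak_g_over_gmax"],
                "tau_rec": truth_r["tau_rec"], "t_half": truth_r["t_half"]})
        elif command == "fit-ephys":
            src = Path(config["input"])
            manifest["inputs"]["traces"] = str(src)
            upstream = src / "manifest.json"
            if upstream.exists():
                manifest["inputs"]["upstream_seed"] = json.loads(
                    upstream.read_text()).get("seed")
            act = read_traces(src / "activation.csv")
            inact = read_traces(src / "inactivation.csv")
            rec = read_traces(src / "recovery.csv")
            res = fitting.analyze_condition(act, inact, rec)
            save_json("gating_fit.json", {
                "act_vhalf_mv": res.act.vhalf, "act_k_mv": res.act.k,
                "inact_vhalf_mv": res.inact.vhalf, "inact_k_mv": res.inact.k,
                "e_na_mv": res.e_na_fit, "gmax_ns": res.gmax,
                "peak_density_pa_pf": res.peak_density,
                "recovery_tau_ms": res.recovery_tau,
                "recovery_t_half_ms": res.recovery_t_half,
                "z_act": res.z_act, "z_inact": res.z_inact})
            res.tau_table.to_csv(out / "tau_table.tsv", sep="\t", index=False,
                                 lineterminator="\n")
            manifest["outputs"].append("tau_table.tsv")
        elif command == "simulate-storm":
            cfg = simulate.LocSimConfig(**{**config.get("loc", {}), "seed": sub[command]})
            manifest["parameters"] = _cfg_dict(cfg)
            table, truth = simulate.simulate_localization_pattern(cfg)
            write_localizations(table, out / "localizations.csv")
            manifest["outputs"].append("localizations.csv")
            save_json("truth.json", {
                "n_blinks": int(len(table)),
                "clustered_fraction": float((truth["blink_cluster"] >= 0).mean())})
        elif command == "analyze-storm":
            src = Path(config["input"])
            manifest["inputs"]["localizations"] = str(src)
            table = read_localizations(src)
            opts = config.get("cluster", {})
            cs = storm.detect_clusters(table, eps=opts.get("eps", 20.0),
                                       min_pts=opts.get("min_pts", 3))
            nn = storm.nearest_neighbor_distances(table,
                                                  bin_width=opts.get("bin_width", 2.0))
            cs.clusters.to_csv(out / "clusters.tsv", sep="\t", index=False,
                               lineterminator="\n")
            pd.DataFrame({"nn_nm": nn.distances}).to_csv(
                out / "nn.tsv", sep="\t", index=False, lineterminator="\n")
            manifest["outputs"] += ["clusters.tsv", "nn.tsv"]
            save_json("summary.json", {
                "percent_clustered": cs.percent_clustered,
                "n_clusters": int(len(cs.clusters)),
                "cluster_density_per_um2": cs.cluster_density_per_um2,
                "median_radius_nm": float(cs.clusters["radius_nm"].median())
                if len(cs.clusters) else float("nan")})
        elif command == "simulate-pla":
            cfg = simulate.PlaSimConfig(**{**config.get("pla", {}), "seed": sub[command]})
            manifest["parameters"] = _cfg_dict(cfg)
            stack, truth = simulate.simulate_pla_stack(cfg)
            write_stack(stack, out / "stack.tif", cfg.voxel_size)
            manifest["outputs"] += ["stack.tif", "stack.json"]
            truth["dots"].to_csv(out / "true_dots.tsv", sep="\t", index=False,
                                 lineterminator="\n")
            manifest["outputs"].append("true_dots.tsv")
        elif command == "quantify-pla":
            src = Path(config["input"])
            manifest["inputs"]["stack"] = str(src)
            stack, voxel = read_stack(src)
            res = pla.quantify_stack(stack, voxel or (0.3, 0.1, 0.1),
                                     **config.get("fit", {}))
            res.dots.to_csv(out / "dots.tsv", sep="\t", index=False,
                            lineterminator="\n")
            res.per_cell.to_csv(out / "per_cell.tsv", sep="\t", index=False,
                                lineterminator="\n")
            manifest["outputs"] += ["dots.tsv", "per_cell.tsv"]
            save_json("summary.json", {
                "mean_count": res.mean_count, "sem_count": res.sem_count,
                "mean_intensity": res.mean_intensity,
                "sem_intensity": res.sem_intensity})
    except Exception as exc:
        raise RuntimeError(f"[{command}] stage failed: {exc}") from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=_jsonable))
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _cfg_dict(cfg) -> dict:
    from dataclasses import asdict, is_dataclass

    def conv(v):
        if is_dataclass(v) and not isinstance(v, type):
            return {k: conv(x) for k, x in asdict(v).items()}
        if callable(v):
            return repr(v)
        if isinstance(v, (tuple, list)):
            return [conv(x) for x in v]
        return v

    return {k: conv(v) for k, v in cfg.__dict__.items()}
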