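"""Stage orchestration with config validation and a provenance manifest.

A run is described by a single YAML/JSON config listing stages to
execute in dependency order (synth -> build_ff -> simulate -> measure ->
landscape/transits; enrich is independent).  Every input and output file
is hashed (SHA-256) into the manifest, so identical configs and seeds
reproduce identical manifests for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .dynamics import SimulationConfig, Trajectory, run_langevin
from .forcefield import ForceField, build_forcefield, merge_basins
from .enrichment import ExtractionSpec, enrichment_from_fastq
from .geometry import measure_angles_series
from .landscapes import StateThresholds, make_landscape, transit_times
from .structure import read_pdb, write_pdb
from .synthetic import (
    DumbbellSpec, SyntheticPoolSpec, dumbbell_scaling_scheme,
    make_hinge_dumbbell, make_fastq_pools, make_swivel_trajectory, refdef_from_truth,
)

log = logging.getLogger("riboswivel")

KNOWN_STAGES = ("synth", "build_ff", "simulate", "measure", "landscape", "transits", "enrich")


class ConfigError(ValueError):
    """Config failed schema validation (exit code 2 at the CLI)."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    text = Path(path).read_text()
    try:
        cfg = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """Pre-flight validation; raises ConfigError before any stage runs."""
    stages = cfg.get("stages")
    if not stages or not isinstance(stages, list):
        raise ConfigError("config needs a non-empty 'stages' list")
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ConfigError(f"unknown stages {unknown}; known: {list(KNOWN_STAGES)}")
    if "out_dir" not in cfg:
        raise ConfigError("config needs 'out_dir'")
    # every declared existing-file input must exist before compute starts
    for key in ("start_pdb", "endpoint_pdb", "input_fastq", "output_fastq"):
        val = cfg.get(key)
        if val is not None and not Path(val).exists():
            produced = ("synth" in stages)
            if not produced:
                raise ConfigError(f"input file for '{key}' does not exist: {val}")
    return stages


def run_pipeline(config_path) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    t_start = time.time()
    cfg = load_config(config_path)
    stages = validate_config(cfg)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = {
        "tool_version": __version__,
        "config": cfg,
        "seeds": {"seed": seed},
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    state: dict = {}

    for stage in stages:
        t0 = time.time()
        log.info("stage %s: starting (seed=%d)", stage, seed)
        outputs = _STAGE_FUNCS[stage](cfg, seed, out_dir, state)
        for name, path in outputs.items():
            manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(Path(path))}
        manifest["stages"][stage] = {
            "wall_seconds": round(time.time() - t0, 3),
            "outputs": sorted(outputs),
        }
        log.info("stage %s: done in %.2fs", stage, time.time() - t0)

    manifest["wall_seconds"] = round(time.time() - t_start, 3)
    man_path = out_dir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# --- stages ---------------------------------------------------------------

def _stage_synth(cfg, seed, out_dir, state):
    sub = cfg.get("synth", {})
    kind = sub.get("kind", "dumbbell")
    outputs = {}
    if kind == "dumbbell":
        spec = DumbbellSpec(seed=seed, **{k: v for k, v in sub.items()
                                          if k in ("swivel_deg", "tilt_deg", "jitter")})
        start, endpoint, truth = make_hinge_dumbbell(spec)
        write_pdb(start, out_dir / "start.pdb")
        write_pdb(endpoint, out_dir / "endpoint.pdb")
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
        state.update(start=start, endpoint=endpoint, truth=truth)
        outputs = {"start_pdb": out_dir / "start.pdb",
                   "endpoint_pdb": out_dir / "endpoint.pdb",
                   "truth_json": out_dir / "truth.json"}
        if sub.get("trajectory"):
            tr = sub["trajectory"]
            n = int(tr.get("n_frames", 100))
            ramp = np.linspace(0.0, spec.swivel_deg, n)
            schedule = np.stack([ramp, np.zeros(n)], axis=1)
            traj = make_swivel_trajectory(start, truth, schedule,
                                          noise_sigma=float(tr.get("noise_sigma", 0.0)),
                                          seed=seed)
            p, c = traj.write(start, str(out_dir / "planted_traj"))
            state["trajectory"] = traj
            outputs["trajectory_pdb"] = p
            outputs["trajectory_csv"] = c
    elif kind == "fastq":
        spec = SyntheticPoolSpec(seed=seed, **{k: v for k, v in sub.items()
                                               if k in ("variants", "input_freqs", "output_freqs",
                                                        "depth", "contamination_rate")})
        truth = make_fastq_pools(spec, out_dir / "input.fastq", out_dir / "output.fastq")
        (out_dir / "pool_truth.json").write_text(json.dumps(truth, indent=2))
        state["pool_spec"] = spec
        outputs = {"input_fastq": out_dir / "input.fastq",
                   "output_fastq": out_dir / "output.fastq",
                   "pool_truth_json": out_dir / "pool_truth.json"}
    else:
        raise ConfigError(f"unknown synth kind {kind!r}")
    return outputs


def _get_structures(cfg, state):
    if "start" not in state:
        state["start"] = read_pdb(cfg["start_pdb"])
        if cfg.get("endpoint_pdb"):
            state["endpoint"] = read_pdb(cfg["endpoint_pdb"])
        if cfg.get("truth_json"):
            state["truth"] = json.loads(Path(cfg["truth_json"]).read_text())
    return state


def _stage_build_ff(cfg, seed, out_dir, state):
    _get_structures(cfg, state)
    sub = cfg.get("build_ff", {})
    ff = build_forcefield(state["start"], dumbbell_scaling_scheme())
    if "endpoint" in state:
        ff = merge_basins(ff, state["endpoint"], weight=float(sub.get("endpoint_weight", 1.0)),
                          scheme=dumbbell_scaling_scheme())
    ff_path = out_dir / "forcefield.top"
    ff.to_file(ff_path)
    state["forcefield"] = ff
    return {"forcefield": ff_path}


def _stage_simulate(cfg, seed, out_dir, state):
    sub = cfg.get("simulate", {})
    ff = state.get("forcefield") or ForceField.from_file(cfg["forcefield"])
    sim = SimulationConfig(
        temperature=float(sub.get("temperature", 0.5)),
        dt=float(sub.get("dt", 0.002)),
        n_steps=int(sub.get("n_steps", 100_000)),
        friction=float(sub.get("friction", 1.0)),
        seed=seed,
        report_interval=int(sub.get("report_interval", 500)),
    )
    traj = run_langevin(ff, state["start"].coords, sim)
    p, c = traj.write(state["start"], str(out_dir / "traj"))
    state["trajectory"] = traj
    return {"trajectory_pdb": p, "trajectory_csv": c}


def _stage_measure(cfg, seed, out_dir, state):
    _get_structures(cfg, state)
    traj = state.get("trajectory")
    if traj is None:
        traj, _ = Trajectory.read(cfg["trajectory_pdb"], cfg.get("trajectory_csv"))
    refdef = refdef_from_truth(state["start"], state["truth"])
    series = measure_angles_series(traj.frames, traj.times, refdef)
    path = out_dir / "angles.csv"
    with open(path, "w") as fh:
        fh.write("# head angles per frame; angles in degrees, time in reduced time units\n")
        fh.write("frame,time_tru,swivel_deg,tilt_deg\n")
        for i, (t, s, ti) in enumerate(zip(series.time, series.swivel, series.tilt)):
            fh.write(f"{i},{t:.9g},{s:.6f},{ti:.6f}\n")
    state["angles"] = series
    return {"angles_csv": path}


def _read_angles(path):
    rows = [l.split(",") for l in open(path)
            if l.strip() and not l.startswith(("#", "frame"))]
    return (np.array([float(r[2]) for r in rows]), np.array([float(r[3]) for r in rows]))


def _stage_landscape(cfg, seed, out_dir, state):
    sub = cfg.get("landscape", {})
    if "angles" in state:
        sw, ti = state["angles"].swivel, state["angles"].tilt
    else:
        sw, ti = _read_angles(cfg["angles_csv"])
    bin_w = float(sub.get("bin_width_deg", 0.5))
    xe = np.arange(np.floor(sw.min()), np.ceil(sw.max()) + bin_w, bin_w)
    ye = np.arange(np.floor(ti.min()), np.ceil(ti.max()) + bin_w, bin_w)
    ls = make_landscape(sw, ti, xe, ye)
    path = out_dir / "landscape.csv"
    ls.to_csv(path)
    return {"landscape_csv": path}


def _stage_transits(cfg, seed, out_dir, state):
    sub = cfg.get("transits", {})
    if "angles" in state:
        series = [state["angles"].swivel]
    else:
        series = [_read_angles(cfg["angles_csv"])[0]]
    thr = StateThresholds(**sub.get("thresholds", {}))
    summ = transit_times(series, thr, direction=sub.get("direction", "forward"))
    path = out_dir / "transits.csv"
    with open(path, "w") as fh:
        fh.write("# first-passage summary; times in frames\n")
        fh.write("transition,mean_frames,sd_frames,n_reaching,n_not_reaching\n")
        for row in summ.as_rows():
            fh.write(f"{row['transition']},{row['mean_frames']:.6g},{row['sd_frames']:.6g},"
                     f"{row['n_reaching']},{row['n_not_reaching']}\n")
    return {"transits_csv": path}


def _stage_enrich(cfg, seed, out_dir, state):
    sub = cfg.get("enrich", {})
    spec = ExtractionSpec(
        upstream=sub.get("upstream", SyntheticPoolSpec().upstream),
        downstream=sub.get("downstream", SyntheticPoolSpec().downstream),
        n=int(sub.get("n", 8)),
    )
    in_fq = cfg.get("input_fastq", out_dir / "input.fastq")
    out_fq = cfg.get("output_fastq", out_dir / "output.fastq")
    table, tallies = enrichment_from_fastq(in_fq, out_fq, spec,
                                           min_phred=int(sub.get("min_phred", 30)))
    path = out_dir / "enrichment.csv"
    with open(path, "w") as fh:
        fh.write("# variant enrichment: output abundance / input abundance, ranked\n")
        table.to_csv(fh, index=False)
    tpath = out_dir / "read_tallies.json"
    tpath.write_text(json.dumps({k: dict(v) for k, v in tallies.items()}, indent=2))
    return {"enrichment_csv": path, "tallies_json": tpath}


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "build_ff": _stage_build_ff,
    "simulate": _stage_simulate,
    "measure": _stage_measure,
    "landscape": _stage_landscape,
    "transits": _stage_transits,
    "enrich": _stage_enrich,
}
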