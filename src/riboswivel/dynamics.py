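"""Energy minimization and reduced-unit Langevin dynamics.

The integrator is BAOAB with uniform unit masses by default (standard
for reduced-unit structure-based models), friction 1.0 inverse reduced
time, and Maxwell-Boltzmann velocity initialisation from the seed.
Temperature is in units of the contact energy (Boltzmann constant 1);
the production-scale protocol is T = 0.5, dt = 0.002 and 1.5e7 steps, i.e.
3e4 reduced time units (~30 microseconds at the ~1 ns per reduced time
unit calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energies import forces, potential_energy
from .forcefield import ForceField
from .structure import MolecularStructure, write_pdb, read_pdb_models

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "minimize",
    "run_langevin",
    "total_simulated_time",
]


@dataclass
class SimulationConfig:
    temperature: float = 0.5
    dt: float = 0.002
    n_steps: int = 15_000_000
    friction: float = 1.0
    seed: int = 0
    report_interval: int = 1000
    tru_to_ns: float = 1.0
    mass_scheme: str = "uniform"

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.report_interval < 1:
            raise ValueError("report_interval must be >= 1")


@dataclass
class Trajectory:
    """Frames of coordinates with step indices and reduced-time stamps."""

    frames: np.ndarray          # (F, N, 3) A
    steps: np.ndarray           # (F,) integer step index
    times: np.ndarray           # (F,) reduced time units
    provenance: dict = field(default_factory=dict)
    kinetic_energy: np.ndarray | None = None   # (F,) per-frame KE (reduced)
    velocities_last: np.ndarray | None = None  # (N, 3) final velocities

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.steps = np.asarray(self.steps, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("trajectory frames contain non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def write(self, structure: MolecularStructure, prefix: str) -> tuple[str, str]:
        """Write multi-model PDB plus a CSV sidecar (step, time_tru)."""
        pdb_path = f"{prefix}.pdb"
        csv_path = f"{prefix}_frames.csv"
        write_pdb(structure, pdb_path, frames=self.frames)
        with open(csv_path, "w") as fh:
            fh.write("# frame metadata; time in reduced time units\nframe,step,time_tru\n")
            for i, (s, t) in enumerate(zip(self.steps, self.times)):
                fh.write(f"{i},{int(s)},{t:.9g}\n")
        return pdb_path, csv_path

    @classmethod
    def read(cls, pdb_path, csv_path=None) -> tuple["Trajectory", MolecularStructure]:
        models = read_pdb_models(pdb_path)
        frames = np.stack([m.coords for m in models])
        if csv_path is not None:
            rows = [l.split(",") for l in open(csv_path)
                    if l.strip() and not l.startswith(("#", "frame"))]
            steps = np.array([int(r[1]) for r in rows])
            times = np.array([float(r[2]) for r in rows])
        else:
            steps = np.arange(len(models))
            times = np.arange(len(models), dtype=float) + 1.0
        return cls(frames, steps, times), models[0]


def _masses(ff: ForceField, structure: MolecularStructure | None, scheme: str) -> np.ndarray:
    if scheme == "uniform" or structure is None:
        return np.ones(ff.n_atoms)
    from .structure import ELEMENT_MASSES

    return np.array([ELEMENT_MASSES.get(a.element.upper(), 12.011) for a in structure.atoms])


def minimize(
    ff: ForceField,
    coords: np.ndarray,
    max_iter: int = 2000,
    tolerance: float = 1e-4,
):
    """Iterative steepest descent with Barzilai-Borwein step sizes.

    Steps follow the force (negative gradient) direction; the step
    length is the Barzilai-Borwein secant estimate, safeguarded by an
    energy check that falls back to halving.  Terminates when the
    largest force component drops below ``tolerance`` or after
    ``max_iter`` steps; the returned energy never exceeds the starting
    energy.
    """
    x = np.array(coords, dtype=float)
    e, _ = potential_energy(ff, x)
    if not np.isfinite(e):
        raise ValueError("non-finite energy at the starting coordinates")
    F = forces(ff, x)
    gamma = 1e-3
    x_prev = None
    F_prev = None
    for _ in range(max_iter):
        fmax = np.abs(F).max()
        if fmax < tolerance:
            break
        if x_prev is not None:
            dx = (x - x_prev).ravel()
            dg = (F_prev - F).ravel()  # gradient difference = -(F - F_prev)
            denom = float(dg @ dg)
            if denom > 1e-300:
                gamma = abs(float(dx @ dg)) / denom
                gamma = min(max(gamma, 1e-12), 1.0)
        accepted = False
        g = gamma
        for _try in range(40):
            trial = x + g * F
            e_trial, _ = potential_energy(ff, trial)
            if np.isfinite(e_trial) and e_trial <= e + 1e-12:
                x_prev, F_prev = x, F
                x, e = trial, e_trial
                F = forces(ff, x)
                gamma = g
                accepted = True
                break
            g *= 0.5
        if not accepted:
            break
    return x, e


def _pack_torsions(ff: ForceField):
    b = ff.bonded
    p = ff.parameters
    parts_idx, parts_x0, parts_eps, parts_fd = [], [], [], []
    if len(b.impropers):
        parts_idx.append(b.impropers)
        parts_x0.append(b.impropers_x0)
        parts_eps.append(np.full(len(b.impropers), p.eps_chi_improper))
        parts_fd.append(np.zeros(len(b.impropers), dtype=np.int64))
    if len(b.planars):
        parts_idx.append(b.planars)
        parts_x0.append(b.planars_x0)
        parts_eps.append(np.full(len(b.planars), p.eps_chi_planar))
        parts_fd.append(np.zeros(len(b.planars), dtype=np.int64))
    if len(b.dihedrals):
        parts_idx.append(b.dihedrals)
        parts_x0.append(b.dihedrals_p0)
        parts_eps.append(np.where(b.dihedrals_backbone, p.eps_BB, p.eps_SC))
        parts_fd.append(np.ones(len(b.dihedrals), dtype=np.int64))
    if parts_idx:
        return (np.vstack(parts_idx).astype(np.int64), np.concatenate(parts_x0),
                np.concatenate(parts_eps), np.concatenate(parts_fd))
    return (np.zeros((0, 4), dtype=np.int64), np.zeros(0), np.zeros(0),
            np.zeros(0, dtype=np.int64))


def _kernel_args(ff: ForceField):
    b = ff.bonded
    p = ff.parameters
    tors, tors_x0, tors_eps, tors_fd = _pack_torsions(ff)
    return (
        b.bonds.astype(np.int64), np.asarray(b.bonds_r0, dtype=float), float(p.eps_r),
        b.angles.astype(np.int64), np.asarray(b.angles_t0, dtype=float), float(p.eps_theta),
        tors, np.asarray(tors_x0, dtype=float), np.asarray(tors_eps, dtype=float), tors_fd,
        ff.contacts.pairs.astype(np.int64), np.asarray(ff.contacts.sigma, dtype=float),
        np.asarray(ff.contacts.eps, dtype=float),
        ff.noncontact_pairs.astype(np.int64), float(p.eps_NC), float(p.sigma_NC),
    )


def kernel_forces(ff: ForceField, coords: np.ndarray) -> np.ndarray:
    """Forces from the compiled kernel (consistency hook for tests)."""
    from ._kernels import compute_forces_kernel

    x = np.array(coords, dtype=float)
    F = np.zeros_like(x)
    compute_forces_kernel(x, F, *_kernel_args(ff))
    return F


def run_langevin(
    ff: ForceField,
    start_coords: np.ndarray,
    config: SimulationConfig,
    structure: MolecularStructure | None = None,
) -> Trajectory:
    """Propagate BAOAB Langevin dynamics; bit-identical replay under one seed.

    Frames (and per-frame kinetic energy) are recorded every
    ``config.report_interval`` steps.  A non-finite configuration aborts
    with the step index in the error message.
    """
    from ._kernels import baoab_segment

    x = np.array(start_coords, dtype=float)
    if x.shape != (ff.n_atoms, 3):
        raise ValueError(f"start coords shape {x.shape} != ({ff.n_atoms}, 3)")
    if not np.all(np.isfinite(x)):
        raise ValueError("start coordinates are not finite")
    rng = np.random.default_rng(config.seed)
    masses = _masses(ff, structure, config.mass_scheme)
    T = config.temperature
    # Maxwell-Boltzmann initial velocities
    v = rng.standard_normal(x.shape) * np.sqrt(T / masses)[:, None] if T > 0 else np.zeros_like(x)
    F = forces(ff, x)
    c1 = float(np.exp(-config.friction * config.dt))
    noise_scale = float(np.sqrt(T * (1.0 - c1 * c1)))
    args = _kernel_args(ff)

    n_report = config.n_steps // config.report_interval
    frames = np.empty((n_report, ff.n_atoms, 3))
    kes = np.empty(n_report)
    steps = np.empty(n_report, dtype=np.int64)
    for r in range(n_report):
        noise = (rng.standard_normal((config.report_interval, ff.n_atoms, 3))
                 if T > 0 else np.zeros((config.report_interval, ff.n_atoms, 3)))
        baoab_segment(x, v, F, masses, config.report_interval, config.dt,
                      c1, noise_scale, noise, *args)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"energy divergence: non-finite coordinates at step {(r + 1) * config.report_interval}"
            )
        frames[r] = x
        kes[r] = 0.5 * float(np.sum(masses[:, None] * v * v))
        steps[r] = (r + 1) * config.report_interval
    times = steps * config.dt
    return Trajectory(
        frames, steps, times,
        provenance={
            "temperature": T, "dt": config.dt, "n_steps": config.n_steps,
            "friction": config.friction, "seed": config.seed,
            "report_interval": config.report_interval,
            "n_contacts": int(len(ff.contacts)),
        },
        kinetic_energy=kes,
        velocities_last=v,
    )


def total_simulated_time(config: SimulationConfig) -> tuple[float, float]:
    """(reduced time units, physical ns) covered by a run."""
    tru = config.n_steps * config.dt
    return tru, tru * config.tru_to_ns
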