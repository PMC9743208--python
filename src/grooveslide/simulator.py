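"""Langevin propagation of a coarse-grained topology in the study box.

The propagator is the BAOAB splitting of underdamped Langevin dynamics (it
reduces to velocity Verlet in the gamma -> 0, T = 0 limit).  All beads carry
unit reduced mass; DNA beads are held rigid by default so the duplex axis
stays on the lab z-axis for the downstream groove analysis.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import constants as C
from .forcefield import ForceFieldParams, build_pair_tables, total_energy_and_forces
from .kernels import HAVE_NUMBA, forces_kernel, integrate_chunk
from .topology import CGTopology

DEFAULT_BOX = ((-240.0, 240.0), (-240.0, 240.0), (-225.0, 225.0))


class IntegrationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    n_steps: int = 1_000_000
    dt: float = 0.005            # reduced time units
    gamma: float = 0.01          # reduced friction
    kBT: float = C.KBT_ROOM      # kcal/mol
    seed: int = 0
    save_interval: int = 1000    # steps between saved frames
    step_ps: float = C.STEP_PS   # physical time assigned to one step
    box: tuple | None = DEFAULT_BOX
    rigid_dna: bool = True
    record_beads: list | None = None  # bead indices to record (None = all)

    @property
    def frame_interval_ns(self) -> float:
        return self.save_interval * self.step_ps * 1e-3


@dataclass
class Trajectory:
    frames: np.ndarray           # (n_frames, n_recorded, 3)
    times_ns: np.ndarray
    frame_interval_ns: float
    bead_indices: np.ndarray
    box: tuple | None
    seed: int
    config: dict
    topology_hash: str
    energies: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_frames(self) -> int:
        return int(len(self.frames))


def steps_to_time(n_steps: int, step_ps: float = C.STEP_PS) -> float:
    """Physical time in milliseconds for a number of MD steps (50 ps/step)."""
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    return n_steps * step_ps * 1e-9


def topology_hash(top: CGTopology) -> str:
    h = hashlib.sha256()
    for name in sorted(top.__dataclass_fields__):
        h.update(np.ascontiguousarray(getattr(top, name)).tobytes())
    return h.hexdigest()[:16]


class ForceEngine:
    """Binds a topology + parameters to a fast force evaluator."""

    def __init__(self, top: CGTopology, params: ForceFieldParams,
                 mobile: np.ndarray | None = None, use_numba: bool = True):
        self.top = top
        self.params = params
        self.tables = build_pair_tables(top, mobile=mobile)
        self.use_numba = (
            use_numba and HAVE_NUMBA and params.dihedral_form == "cosine"
            and params.elec_cutoff_debye is None
        )
        t = self.tables
        self._args = (
            np.ascontiguousarray(top.bonds, dtype=np.int64),
            np.ascontiguousarray(top.bond_x0), np.ascontiguousarray(top.bond_k),
            np.ascontiguousarray(top.angles, dtype=np.int64),
            np.ascontiguousarray(top.angle_x0), np.ascontiguousarray(top.angle_k),
            np.ascontiguousarray(top.dihedrals, dtype=np.int64),
            np.ascontiguousarray(top.dihedral_x0),
            np.ascontiguousarray(top.dihedral_k * top.dihedral_f),
            np.ascontiguousarray(t.contact_pairs, dtype=np.int64),
            np.ascontiguousarray(t.contact_a), np.ascontiguousarray(t.contact_kf),
            np.ascontiguousarray(t.ev_pairs, dtype=np.int64),
            np.ascontiguousarray(t.ev_sigma), params.k_excluded_volume,
            np.ascontiguousarray(t.elec_pairs, dtype=np.int64),
            np.ascontiguousarray(t.elec_qq), params.kappa,
            params.k_coulomb * params.b_kappa / params.eps,
        )

    def __call__(self, positions: np.ndarray):
        if self.use_numba:
            forces = np.empty_like(positions)
            energy = forces_kernel(positions, *self._args, forces)
            return float(energy), forces
        return total_energy_and_forces(self.top, positions, self.params, self.tables)


def _reflect(pos, vel, box, mobile):
    for dim, (lo, hi) in enumerate(box):
        m = mobile & (pos[:, dim] < lo)
        pos[m, dim] = 2 * lo - pos[m, dim]
        vel[m, dim] *= -1.0
        m = mobile & (pos[:, dim] > hi)
        pos[m, dim] = 2 * hi - pos[m, dim]
        vel[m, dim] *= -1.0


def langevin_step(positions, velocities, force_fn, config: SimulationConfig,
                  rng: np.random.Generator, forces=None,
                  mobile: np.ndarray | None = None):
    """One BAOAB step.  Returns (positions, velocities, forces, energy).

    ``forces`` are the forces at the incoming positions (computed if absent);
    the returned forces belong to the returned positions, so successive calls
    cost one force evaluation per step.
    """
    n = len(positions)
    if mobile is None:
        mobile = np.ones(n, dtype=bool)
    if forces is None:
        _, forces = force_fn(positions)
    dt, gamma, kBT = config.dt, config.gamma, config.kBT
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(0.0, (1.0 - c1 * c1)) * kBT)

    cap = 0.5  # A per half-drift; guards against rare force spikes
    vel = velocities.copy()
    pos = positions.copy()
    vel[mobile] += 0.5 * dt * forces[mobile]
    pos[mobile] += np.clip(0.5 * dt * vel[mobile], -cap, cap)
    noise = rng.standard_normal((int(mobile.sum()), 3))
    vel[mobile] = c1 * vel[mobile] + c2 * noise
    pos[mobile] += np.clip(0.5 * dt * vel[mobile], -cap, cap)
    if config.box is not None:
        _reflect(pos, vel, config.box, mobile)
    energy, new_forces = force_fn(pos)
    if not np.all(np.isfinite(new_forces[mobile])):
        raise IntegrationError("non-finite force encountered")
    vel[mobile] += 0.5 * dt * new_forces[mobile]
    return pos, vel, new_forces, energy


def run_simulation(top: CGTopology, config: SimulationConfig,
                   params: ForceFieldParams | None = None,
                   engine: ForceEngine | None = None) -> Trajectory:
    """Propagate and record frames every ``save_interval`` steps.

    The initial state is always recorded, so ``n_steps = 0`` yields a
    single-frame trajectory.
    """
    params = params or ForceFieldParams()
    mobile = np.ones(top.n_beads, dtype=bool)
    if config.rigid_dna:
        mobile &= top.is_protein
    if engine is None:
        engine = ForceEngine(top, params, mobile=mobile)

    rng = np.random.default_rng(config.seed)
    pos = top.positions.copy()
    vel = np.zeros_like(pos)
    if config.kBT > 0:
        vel[mobile] = rng.standard_normal((int(mobile.sum()), 3)) * np.sqrt(config.kBT)

    record = (np.arange(top.n_beads) if config.record_beads is None
              else np.asarray(config.record_beads, dtype=int))
    n_frames = config.n_steps // config.save_interval + 1
    frames = np.empty((n_frames, len(record), 3))
    energies = np.empty(n_frames)
    times = np.empty(n_frames)

    energy, forces = engine(pos)
    frames[0] = pos[record]
    energies[0] = energy
    times[0] = 0.0
    fidx = 1
    mobile_idx = np.where(mobile)[0].astype(np.int64)
    use_box = config.box is not None
    box_lo = np.array([b[0] for b in config.box]) if use_box else np.zeros(3)
    box_hi = np.array([b[1] for b in config.box]) if use_box else np.zeros(3)
    step = 0
    while step < config.n_steps:
        n_chunk = min(config.save_interval, config.n_steps - step)
        if engine.use_numba:
            noise = rng.standard_normal((n_chunk, len(mobile_idx), 3))
            energy = integrate_chunk(
                pos, vel, forces, mobile_idx, noise,
                config.dt, config.gamma, config.kBT, box_lo, box_hi, use_box,
                *engine._args,
            )
            if not np.all(np.isfinite(forces[mobile])):
                raise IntegrationError("non-finite force encountered")
        else:
            for _ in range(n_chunk):
                pos, vel, forces, energy = langevin_step(
                    pos, vel, engine, config, rng, forces=forces, mobile=mobile
                )
        step += n_chunk
        if step % config.save_interval == 0:
            if use_box:
                for dim in range(3):
                    if (np.any(pos[mobile, dim] < box_lo[dim] - 10.0)
                            or np.any(pos[mobile, dim] > box_hi[dim] + 10.0)):
                        raise IntegrationError(
                            f"bead escaped the box by more than 10 A at step {step}"
                        )
            frames[fidx] = pos[record]
            energies[fidx] = energy
            times[fidx] = step * config.step_ps * 1e-3
            fidx += 1

    cfg = asdict(config)
    cfg["box"] = list(map(list, config.box)) if config.box else None
    cfg["record_beads"] = record.tolist()
    return Trajectory(
        frames=frames[:fidx],
        times_ns=times[:fidx],
        frame_interval_ns=config.frame_interval_ns,
        bead_indices=record,
        box=config.box,
        seed=config.seed,
        config=json.loads(json.dumps(cfg)),
        topology_hash=topology_hash(top),
        energies=energies[:fidx],
    )
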