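"""Encounter-complex scoring: protein-DNA electrostatic interaction energy and
specific-contact occupancy over frames aligned with the target site."""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import constants as C
from .forcefield import ForceFieldParams
from .topology import CGTopology


@dataclass
class EncounterStats:
    mean_energy_kcal: float | None
    sd_energy_kcal: float | None
    occupancy: np.ndarray | None      # per target-site contact, in [0, 1]
    aggregate_occupancy: float | None
    n_frames: int
    formed_threshold: float
    half_width_bp: float | None = None

    def to_dict(self) -> dict:
        return {
            "mean_energy_kcal": self.mean_energy_kcal,
            "sd_energy_kcal": self.sd_energy_kcal,
            "occupancy": None if self.occupancy is None else list(map(float, self.occupancy)),
            "aggregate_occupancy": self.aggregate_occupancy,
            "n_frames": self.n_frames,
            "formed_threshold": self.formed_threshold,
            "half_width_bp": self.half_width_bp,
        }


def _frame_array(trajectory):
    """Accept a Trajectory or a raw (n_frames, n_beads, 3) array."""
    if hasattr(trajectory, "frames"):
        return np.asarray(trajectory.frames, float), np.asarray(trajectory.bead_indices)
    arr = np.asarray(trajectory, dtype=float)
    return arr, np.arange(arr.shape[1])


def interaction_electrostatic_energy(trajectory, top: CGTopology,
                                     params: ForceFieldParams) -> np.ndarray:
    """Per-frame Debye-Hueckel energy restricted to protein-DNA charged pairs."""
    frames, recorded = _frame_array(trajectory)
    lookup = {int(b): r for r, b in enumerate(recorded)}
    prot = np.where(top.is_protein & (top.charges != 0))[0]
    dna = np.where(top.is_dna & (top.charges != 0))[0]
    prot = np.asarray([p for p in prot if int(p) in lookup], int)
    dna = np.asarray([d for d in dna if int(d) in lookup], int)
    if len(prot) == 0 or len(dna) == 0:
        warnings.warn("no inter-molecular charged pairs; energies are zero")
        return np.zeros(len(frames))
    rows_p = np.asarray([lookup[int(b)] for b in prot])
    rows_d = np.asarray([lookup[int(b)] for b in dna])
    qq = np.outer(top.charges[prot], top.charges[dna])
    kappa = params.kappa
    pref = params.k_coulomb * params.b_kappa / params.eps
    energies = np.empty(len(frames))
    for f, frame in enumerate(frames):
        diff = frame[rows_p][:, None, :] - frame[rows_d][None, :, :]
        r = np.sqrt(np.sum(diff * diff, axis=2))
        energies[f] = np.sum(pref * qq * np.exp(-kappa * r) / r)
    return energies


def contact_occupancy(trajectory, top: CGTopology,
                      formed_threshold: float = 1.2) -> np.ndarray:
    """Fraction of frames in which each target-site contact is formed
    (r <= formed_threshold * A_ij)."""
    frames, recorded = _frame_array(trajectory)
    if len(frames) == 0:
        warnings.warn("no frames to analyze; occupancy undefined")
        return np.full(len(top.target_pairs), np.nan)
    if len(top.target_pairs) == 0:
        return np.zeros(0)
    lookup = {int(b): r for r, b in enumerate(recorded)}
    ri = np.asarray([lookup[int(i)] for i in top.target_pairs[:, 0]])
    rj = np.asarray([lookup[int(j)] for j in top.target_pairs[:, 1]])
    formed = np.zeros(len(top.target_pairs))
    for frame in frames:
        r = np.linalg.norm(frame[rj] - frame[ri], axis=1)
        formed += (r <= formed_threshold * top.target_a)
    return formed / len(frames)


def select_aligned_frames(trace, target_center_bp: float,
                          half_width_bp: float = 2.0,
                          rise: float = C.BP_RISE,
                          z_of_bp=None) -> np.ndarray:
    """Boolean frame mask: every recognition region's Z within half_width bp
    of its target position.

    Region k's target Z defaults to the target center shifted by the same
    offset the regions had at frame 0 (a parked dimer straddles its site);
    pass ``z_of_bp`` to convert bp to Z (defaults to centered numbering with
    3.32 A rise against the trace's own frame-0 layout).
    """
    mask = np.ones(trace.n_frames, dtype=bool)
    names = list(trace.regions)
    z0 = {n: trace.regions[n]["Z"][0] for n in names}
    center_off = np.mean([z0[n] for n in names])
    target_z = {}
    for n in names:
        target_z[n] = (z_of_bp(target_center_bp) if z_of_bp is not None else 0.0) \
            + (z0[n] - center_off)
    for n in names:
        dz = np.abs(trace.regions[n]["Z"] - target_z[n])
        ok = dz <= half_width_bp * rise
        # also restricted to 1D frames
        ok &= trace.regions[n]["d"] <= trace.r_c
        mask &= ok
    if not mask.any():
        warnings.warn("alignment filter selected no frames")
    return mask


def encounter_statistics(trajectory, top: CGTopology, params: ForceFieldParams,
                         trace=None, target_center_bp: float | None = None,
                         half_width_bp: float = 2.0,
                         formed_threshold: float = 1.2) -> EncounterStats:
    """Energy and occupancy over (optionally target-aligned) frames."""
    frames, recorded = _frame_array(trajectory)
    mask = np.ones(len(frames), dtype=bool)
    if trace is not None and target_center_bp is not None:
        mask = select_aligned_frames(trace, target_center_bp, half_width_bp)
    if not mask.any():
        return EncounterStats(None, None, None, None, 0, formed_threshold,
                              half_width_bp)
    sub = frames[mask]

    class _Sub:
        pass

    subtraj = _Sub()
    subtraj.frames = sub
    subtraj.bead_indices = recorded
    energies = interaction_electrostatic_energy(subtraj, top, params)
    occ = contact_occupancy(subtraj, top, formed_threshold)
    return EncounterStats(
        mean_energy_kcal=float(np.mean(energies)),
        sd_energy_kcal=float(np.std(energies)),
        occupancy=occ,
        aggregate_occupancy=float(np.mean(occ)) if len(occ) else None,
        n_frames=int(mask.sum()),
        formed_threshold=formed_threshold,
        half_width_bp=half_width_bp,
    )
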