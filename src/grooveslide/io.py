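"""File I/O: PDB structures (via biotite), plain-text XYZ trajectories with a
JSON metadata sidecar, and CSV traces."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile


def read_structure(path, model: int | None = None):
    """Read a PDB file into an AtomArray.

    Multi-model (NMR) files require an explicit 1-based ``model`` index.
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models > 1 and model is None:
        raise ValueError(
            f"{path} contains {n_models} models; pass an explicit model index"
        )
    atoms = pdb.get_structure(model=model if model is not None else 1)
    return atoms


def write_structure(atoms, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def make_atom_array(coords, atom_names, res_names, res_ids, chain_ids, elements=None):
    """Assemble a biotite AtomArray from parallel per-atom annotation lists."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    atoms = struc.AtomArray(n)
    atoms.coord = coords
    atoms.atom_name = np.asarray(atom_names, dtype="<U6")
    atoms.res_name = np.asarray(res_names, dtype="<U5")
    atoms.res_id = np.asarray(res_ids, dtype=int)
    atoms.chain_id = np.asarray(chain_ids, dtype="<U4")
    if elements is None:
        elements = [str(a)[0] for a in atom_names]
    atoms.element = np.asarray(elements, dtype="<U2")
    atoms.hetero = np.zeros(n, dtype=bool)
    return atoms


def write_trajectory_xyz(traj, prefix) -> tuple[Path, Path]:
    """Write a Trajectory as plain-text XYZ plus a JSON metadata sidecar."""
    prefix = Path(prefix)
    xyz_path = prefix.with_suffix(".xyz")
    meta_path = prefix.with_suffix(".meta.json")
    with open(xyz_path, "w") as fh:
        for f, frame in enumerate(traj.frames):
            fh.write(f"{len(frame)}\n")
            fh.write(f"frame {f} t_ns {traj.times_ns[f]:.6f}\n")
            for x, y, z in frame:
                fh.write(f"X {x:.4f} {y:.4f} {z:.4f}\n")
    meta = {
        "frame_interval_ns": traj.frame_interval_ns,
        "n_frames": int(len(traj.frames)),
        "bead_indices": np.asarray(traj.bead_indices).tolist(),
        "seed": traj.seed,
        "box": traj.box,
        "config": traj.config,
        "topology_hash": traj.topology_hash,
    }
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)
    return xyz_path, meta_path


def read_trajectory_xyz(prefix):
    """Read back a trajectory written by :func:`write_trajectory_xyz`."""
    from .simulator import Trajectory

    prefix = Path(prefix)
    with open(prefix.with_suffix(".meta.json")) as fh:
        meta = json.load(fh)
    frames, times = [], []
    with open(prefix.with_suffix(".xyz")) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        times.append(float(lines[i + 1].split()[-1]))
        block = [list(map(float, ln.split()[1:4])) for ln in lines[i + 2:i + 2 + n]]
        frames.append(block)
        i += 2 + n
    return Trajectory(
        frames=np.asarray(frames, dtype=float),
        times_ns=np.asarray(times, dtype=float),
        frame_interval_ns=float(meta["frame_interval_ns"]),
        bead_indices=np.asarray(meta["bead_indices"], dtype=int),
        box=tuple(tuple(b) for b in meta["box"]) if meta["box"] else None,
        seed=meta["seed"],
        config=meta["config"],
        topology_hash=meta["topology_hash"],
    )


def trace_to_csv(trace, path) -> None:
    """Write a HelixTrace as a flat CSV of (region, t_ns, Z, d, phi)."""
    rows = []
    for region, data in trace.regions.items():
        for t, z, d, p in zip(trace.times_ns, data["Z"], data["d"], data["phi"]):
            rows.append({"region": region, "t_ns": t, "Z": z, "d": d, "phi": p})
    pd.DataFrame(rows).to_csv(path, index=False)


def trace_from_csv(path, groove_map=None):
    from .analysis import HelixTrace

    df = pd.read_csv(path)
    regions = {}
    times = None
    for region, sub in df.groupby("region", sort=False):
        sub = sub.sort_values("t_ns")
        if times is None:
            times = sub["t_ns"].to_numpy()
        regions[str(region)] = {
            "Z": sub["Z"].to_numpy(),
            "d": sub["d"].to_numpy(),
            "phi": sub["phi"].to_numpy(),
        }
    return HelixTrace(times_ns=times, regions=regions, groove_map=groove_map)
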