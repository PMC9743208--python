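"""Orchestration: build a binder + DNA system, run replicas over a
(variant x salt) grid, analyze events and diffusion, and report.

The desk preset (toy dimeric binder on 30-bp ideal B-DNA, ~1e6 steps) runs in
minutes on one core; the cluster preset mirrors the full study conditions
(100-bp DNA, 1e8 steps, up to eight replicas per salt) and is provided for
batch execution only.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants as C
from .analysis import compute_helix_trace, detect_flips, event_statistics, fit_groove_map, segment_events
from .diffusion import combine_hopping, estimate_from_trace, hopping_speedup
from .forcefield import ForceFieldParams
from .simulator import SimulationConfig, run_simulation, topology_hash
from .synthetic import DNAGeometry, generate_ideal_bdna, generate_toy_binder

DESK_PRESET = dict(
    n_bp=30,
    n_steps=600_000,
    save_interval=20,   # 1 ns frames resolve the toy binder's fast azimuth
    replicas=2,
    salts=(0.01, 0.02, 0.04),
    box=((-60.0, 60.0), (-60.0, 60.0), (-45.0, 45.0)),
)

# Full study scale: not run by the desk tests; submit per-replica jobs.
CLUSTER_PRESET = dict(
    n_bp=100,
    n_steps=100_000_000,
    save_interval=1000,
    replicas=8,
    salts=(0.01, 0.02, 0.03, 0.04, 0.05, 0.06),
    box=((-240.0, 240.0), (-240.0, 240.0), (-225.0, 225.0)),
)

VARIANTS = ("search", "recognition")


@dataclass
class RunManifest:
    config: dict
    entries: list = field(default_factory=list)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump({"config": self.config, "entries": self.entries}, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(config=d["config"], entries=d["entries"])


def build_system(variant: str = "search", n_bp: int = 30, seed: int = 0):
    """Toy binder + ideal B-DNA merged topology.

    ``search`` uses a fully flexible hinge (f = 0); ``recognition`` keeps the
    hinge rigid.  Returns ``(topology, recognition_bead_sets, groove_map)``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    geom = DNAGeometry(n_bp=n_bp)
    _, dna = generate_ideal_bdna(geom)
    binder = generate_toy_binder(
        dimeric=True, hinge_flexible=(variant == "search"), seed=seed, geom=geom
    )
    top = dna.merge(binder.topology)
    n_dna = dna.n_beads
    regions = {k: v + n_dna for k, v in binder.recognition_beads().items()}
    return top, regions, fit_groove_map(dna)


def run_replica(top, regions, groove_map, salt: float, seed: int,
                n_steps: int, save_interval: int, box) -> dict:
    """One replica: simulate, trace, classify, estimate diffusion."""
    params = ForceFieldParams(ionic_strength=salt)
    record = sorted(set(int(b) for r in regions.values() for b in r))
    config = SimulationConfig(
        n_steps=n_steps, save_interval=save_interval, seed=seed, box=box,
        record_beads=record,
    )
    traj = run_simulation(top, config, params)
    trace = compute_helix_trace(traj, regions, groove_map)
    events, labels = segment_events(trace)
    stats = event_statistics(events)
    n_frames = trace.n_frames
    hi = max(10, min(1000, n_frames // 5))
    window = (max(2, min(250, hi // 2)), hi)
    est = estimate_from_trace(trace, window=window, bound_only=True)
    flips = detect_flips(trace) if len(regions) > 1 else []
    return {
        "trace": trace,
        "events": events,
        "stats": stats,
        "estimate": est,
        "n_flips": len(flips),
        "seed": seed,
        "salt": salt,
    }


def run_condition_grid(variants=VARIANTS, salts=None, replicas=None,
                       n_steps=None, preset=None, seed: int = 0,
                       outdir=None) -> tuple[pd.DataFrame, RunManifest]:
    """Per-(variant, salt) summary over replicas; failures are recorded in the
    manifest and the grid continues."""
    preset = dict(DESK_PRESET if preset is None else preset)
    salts = preset["salts"] if salts is None else tuple(salts)
    replicas = preset["replicas"] if replicas is None else int(replicas)
    n_steps = preset["n_steps"] if n_steps is None else int(n_steps)
    for s in salts:
        if not 0.01 - 1e-9 <= s <= 0.06 + 1e-9:
            raise ValueError("supported ionic strengths are 0.01-0.06 M")

    manifest = RunManifest(config={
        "variants": list(variants), "salts": list(salts),
        "replicas": replicas, "n_steps": n_steps, "seed": seed,
        "n_bp": preset["n_bp"], "save_interval": preset["save_interval"],
    })
    rows = []
    for variant in variants:
        top, regions, gm = build_system(variant, n_bp=preset["n_bp"], seed=seed)
        thash = topology_hash(top)
        for salt in salts:
            per_rep = []
            for rep in range(replicas):
                rep_seed = (seed * 7919 + VARIANTS.index(variant) * 104729
                            + int(round(salt * 1000)) * 1009 + rep) % (2 ** 31)
                entry = {
                    "variant": variant, "salt": salt, "replica": rep,
                    "seed": rep_seed, "topology_hash": thash, "status": "ok",
                }
                try:
                    res = run_replica(top, regions, gm, salt, rep_seed,
                                      n_steps, preset["save_interval"],
                                      preset["box"])
                    per_rep.append(res)
                except Exception as exc:  # keep the grid going
                    entry["status"] = f"failed: {exc}"
                manifest.entries.append(entry)
            if not per_rep:
                continue
            rows.append(_summarize(variant, salt, per_rep))
    df = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "summary.csv", index=False)
        manifest.to_json(outdir / "manifest.json")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
    return df, manifest


def _summarize(variant, salt, results) -> dict:
    def collect(fn):
        vals = [fn(r) for r in results]
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        if not vals:
            return (np.nan, np.nan)
        return (float(np.mean(vals)), float(np.std(vals)))

    d = collect(lambda r: r["estimate"].D_um2_s)
    dr = collect(lambda r: r["estimate"].D_r_rad2_s)
    pitch = collect(lambda r: r["estimate"].pitch_bp)
    khop = collect(lambda r: r["stats"].hop_frequency_per_ms)
    xhop = collect(lambda r: (r["stats"].hop_span_bp or (None,))[0])
    groove_dur = collect(lambda r: (r["stats"].groove_duration_us or (None,))[0])
    row = {
        "variant": variant, "salt": salt, "n_replicas": len(results),
        "D_um2_s": d[0], "D_um2_s_sd": d[1],
        "D_r_rad2_s": dr[0], "D_r_rad2_s_sd": dr[1],
        "pitch_bp": pitch[0], "pitch_bp_sd": pitch[1],
        "pitch_bp_median": float(np.median([r["estimate"].pitch_bp for r in results
                                            if r["estimate"].pitch_bp is not None])
                                 ) if any(r["estimate"].pitch_bp is not None for r in results) else np.nan,
        "x_hop_bp": xhop[0], "k_hop_per_ms": khop[0],
        "groove_duration_us": groove_dur[0],
        "n_flips": int(sum(r["n_flips"] for r in results)),
    }
    if np.isfinite(row["D_um2_s"]) and np.isfinite(row["x_hop_bp"]) and np.isfinite(row["k_hop_per_ms"]):
        d1d = combine_hopping(row["D_um2_s"], row["x_hop_bp"], row["k_hop_per_ms"])
        row["D_1D_um2_s"] = d1d
        sp = hopping_speedup(d1d, row["D_um2_s"])
        row["speedup"] = sp if sp is not None else np.nan
    return row


def report(summary: pd.DataFrame) -> str:
    """Human-readable per-condition tables (diffusion, events, energetics)."""
    if summary is None or len(summary) == 0:
        return "no conditions to report\n"
    lines = ["Facilitated-diffusion condition report", "=" * 40]
    cols_diff = ["variant", "salt", "D_um2_s", "D_r_rad2_s", "pitch_bp"]
    lines.append("\n[diffusion vs salt]")
    lines.append(summary[ [c for c in cols_diff if c in summary] ].to_string(index=False))
    cols_ev = ["variant", "salt", "x_hop_bp", "k_hop_per_ms",
               "groove_duration_us", "n_flips"]
    have = [c for c in cols_ev if c in summary]
    if len(have) > 2:
        lines.append("\n[event statistics]")
        lines.append(summary[have].to_string(index=False))
    extra = [c for c in ("D_1D_um2_s", "speedup") if c in summary]
    if extra:
        lines.append("\n[hopping contribution]")
        lines.append(summary[["variant", "salt"] + extra].to_string(index=False))
    return "\n".join(lines) + "\n"
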