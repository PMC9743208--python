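"""Trajectory analysis: per-frame (Z, d, phi) helix traces, 1D/3D separation,
groove-tracking vs hopping segmentation with the short-event smoothing rules,
flip detection, and aggregate event statistics.

Frames with axis distance d above R_c = 32 A are 3D; within 1D intervals of at
least ~5 ns, frames whose recognition-region azimuth lies within 1.5 bp of the
major-groove center line phi(Z) are groove tracking and the rest are hopping.
Hops spanning less than 1 bp are folded into the flanking groove tracking, and
groove tracking shorter than 0.5 ns is relabeled as hopping.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import constants as C
from .geometry import wrap_angle
from .topology import CGTopology, ROLE_PHOSPHATE

LABEL_3D = "3D"
LABEL_GROOVE = "groove"
LABEL_HOP = "hop"


@dataclass
class GrooveMap:
    """Linear calibration phi(Z) = slope * Z + phi0 of the major-groove center.

    slope = 2 pi / (helical repeat * rise); offsets from the groove center are
    reported in base pairs: offset_bp = wrap(phi - phi(Z)) / (2 pi / repeat).
    """

    slope: float
    phi0: float
    repeat_bp: float = C.HELICAL_REPEAT_BP
    rise: float = C.BP_RISE
    tolerance_bp: float = C.GROOVE_TOL_BP

    def groove_phi(self, z):
        return self.slope * np.asarray(z, dtype=float) + self.phi0

    def offset_bp(self, z, phi):
        """Signed distance (bp) of an azimuth from the groove center at Z."""
        dphi = wrap_angle(np.asarray(phi, float) - self.groove_phi(z))
        return dphi / (2.0 * np.pi / self.repeat_bp)


def fit_groove_map(dna: CGTopology, repeat_bp: float = C.HELICAL_REPEAT_BP,
                   rise: float = C.BP_RISE) -> GrooveMap:
    """Calibrate the groove center line from phosphate bead geometry.

    For each base pair the major-groove center azimuth is the bisector of the
    wider angular gap between the two strands' phosphates; a linear fit of the
    unwrapped bisector against z yields slope and phase.
    """
    phos = np.where(dna.roles == ROLE_PHOSPHATE)[0]
    chains = np.unique(dna.chain_ids[phos])
    if len(chains) != 2:
        raise ValueError("groove calibration expects a two-strand duplex")
    a = phos[dna.chain_ids[phos] == chains[0]]
    b = phos[dna.chain_ids[phos] == chains[1]]
    # pair strand-B phosphates to strand-A ones by z
    za = dna.positions[a, 2]
    zb = dna.positions[b, 2]
    order_a = a[np.argsort(za)]
    centers_z, centers_phi = [], []
    for i in order_a:
        j = b[np.argmin(np.abs(zb - dna.positions[i, 2]))]
        p1 = np.arctan2(dna.positions[i, 0], dna.positions[i, 1])
        p2 = np.arctan2(dna.positions[j, 0], dna.positions[j, 1])
        half = wrap_angle(p2 - p1) / 2.0
        bis1 = wrap_angle(p1 + half)       # bisector of the smaller gap
        bis2 = wrap_angle(bis1 + np.pi)    # bisector of the wider gap
        # the major groove is the wider gap between the backbones
        centers_z.append(0.5 * (dna.positions[i, 2] + dna.positions[j, 2]))
        centers_phi.append(bis2)
    centers_z = np.asarray(centers_z)
    centers_phi = np.unwrap(np.asarray(centers_phi))
    slope, phi0 = np.polyfit(centers_z, centers_phi, 1)
    expected = 2.0 * np.pi / (repeat_bp * rise)
    if not np.isclose(slope, expected, rtol=0.2):
        warnings.warn(
            f"fitted groove slope {slope:.4f} rad/A deviates from the ideal "
            f"{expected:.4f}; check DNA alignment"
        )
    return GrooveMap(slope=float(slope), phi0=float(wrap_angle(phi0)),
                     repeat_bp=repeat_bp, rise=rise)


@dataclass
class HelixTrace:
    """Per-frame (Z, d, phi) of recognition-region centers of mass."""

    times_ns: np.ndarray
    regions: dict
    groove_map: GrooveMap | None = None
    r_c: float = C.R_C

    @property
    def frame_dt_ns(self) -> float:
        return float(self.times_ns[1] - self.times_ns[0])

    @property
    def n_frames(self) -> int:
        return int(len(self.times_ns))

    def phi_unwrapped(self, region) -> np.ndarray:
        return np.unwrap(self.regions[region]["phi"])


@dataclass
class EventRecord:
    type: str            # groove | hop | threeD | flip
    start_us: float
    end_us: float
    span_bp: float       # signed; 0 for threeD and flip markers
    region: str = "1"

    @property
    def duration_us(self) -> float:
        return self.end_us - self.start_us


@dataclass
class EventStats:
    """Aggregate event statistics; absent quantities are None."""

    n_groove: int = 0
    n_hop: int = 0
    groove_duration_us: tuple | None = None    # (mean, sd)
    groove_span_bp: tuple | None = None
    hop_duration_us: tuple | None = None
    hop_span_bp: tuple | None = None
    hop_frequency_per_ms: float | None = None        # hops per ms of 1D time
    hop_frequency_total_per_ms: float | None = None  # hops per ms of total time
    long_hop_frequency_per_ms: float | None = None   # hops > 5 bp
    time_1d_us: float = 0.0
    total_time_us: float = 0.0

    def to_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = list(v) if isinstance(v, tuple) else v
        return out


def compute_helix_trace(trajectory, recognition_bead_sets: dict,
                        groove_map: GrooveMap | None = None,
                        r_c: float = C.R_C) -> HelixTrace:
    """Project recognition-region COMs onto (Z, d, phi) per frame.

    phi is the signed angle between the COM's (x, y) vector and the reference
    direction (0, 1): phi = atan2(x, y), positive for x > 0.  Frames with the
    COM on the axis (d = 0) get phi = nan and are excluded from groove tests.
    The DNA is assumed aligned on the lab z-axis.
    """
    regions = {}
    # map bead indices to rows of the recorded subset
    recorded = np.asarray(trajectory.bead_indices)
    lookup = {int(b): r for r, b in enumerate(recorded)}
    for name, beads in recognition_bead_sets.items():
        beads = np.asarray(beads, dtype=int)
        if beads.size == 0:
            raise ValueError(f"recognition region {name!r} has no beads")
        rows = np.asarray([lookup[int(b)] for b in beads])
        com = trajectory.frames[:, rows, :].mean(axis=1)
        z = com[:, 2]
        d = np.hypot(com[:, 0], com[:, 1])
        phi = np.where(d > 0, np.arctan2(com[:, 0], com[:, 1]), np.nan)
        regions[str(name)] = {"Z": z, "d": d, "phi": phi}
    return HelixTrace(times_ns=np.asarray(trajectory.times_ns, float),
                      regions=regions, groove_map=groove_map, r_c=r_c)


def classify_1d_3d(trace: HelixTrace, region: str = "1") -> np.ndarray:
    """Per-frame {1D, 3D}: a frame is 3D iff d > R_c (closed threshold)."""
    d = trace.regions[region]["d"]
    return np.where(d > trace.r_c, "3D", "1D")


def _runs(labels: np.ndarray):
    """Yield (start, end_exclusive, label) for maximal constant runs."""
    edges = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.concatenate([[0], edges, [len(labels)]])
    for s, e in zip(bounds[:-1], bounds[1:]):
        yield int(s), int(e), labels[s]


def segment_events(trace: HelixTrace, region: str = "1",
                   min_1d_ns: float = C.MIN_1D_NS,
                   groove_tol_bp: float = C.GROOVE_TOL_BP,
                   min_hop_bp: float = C.MIN_HOP_BP,
                   min_groove_ns: float = C.MIN_GROOVE_NS):
    """Classify frames and build the event list.

    Returns ``(events, labels)`` where labels is a per-frame array over
    {3D, groove, hop}.  1D intervals shorter than ``min_1d_ns`` are excluded
    from event statistics (folded into 3D).
    """
    if trace.groove_map is None:
        raise ValueError("trace has no groove_map; calibrate with fit_groove_map")
    gm = trace.groove_map
    z = trace.regions[region]["Z"]
    d = trace.regions[region]["d"]
    phi = trace.regions[region]["phi"]
    dt_ns = trace.frame_dt_ns
    n = len(z)

    labels = np.empty(n, dtype="<U6")
    labels[:] = LABEL_3D
    is_1d = d <= trace.r_c
    offset = gm.offset_bp(z, phi)
    in_groove = np.abs(offset) <= groove_tol_bp
    in_groove &= ~np.isnan(phi)

    min_1d_frames = max(1, int(np.ceil(min_1d_ns / dt_ns)))
    for s, e, val in _runs(np.where(is_1d, "1", "0")):
        if val == "1" and (e - s) >= min_1d_frames:
            labels[s:e] = np.where(in_groove[s:e], LABEL_GROOVE, LABEL_HOP)

    labels = _smooth_labels(labels, z, dt_ns, min_hop_bp, min_groove_ns)
    events = _events_from_labels(labels, z, trace.times_ns, region)
    return events, labels


def _smooth_labels(labels, z, dt_ns, min_hop_bp, min_groove_ns):
    """Apply the short-event rules to a fixpoint.

    1. hops spanning < 1 bp flanked by groove tracking join the groove event;
    2. groove tracking shorter than 0.5 ns becomes hopping;
    then adjacent same-type events merge implicitly (label arrays).
    """
    labels = labels.copy()
    for _ in range(len(labels)):
        changed = False
        runs = list(_runs(labels))
        for idx, (s, e, val) in enumerate(runs):
            if val == LABEL_HOP:
                span_bp = abs(z[e - 1] - z[s]) / C.BP_RISE
                left = runs[idx - 1][2] if idx > 0 else None
                right = runs[idx + 1][2] if idx < len(runs) - 1 else None
                if span_bp < min_hop_bp and (left == LABEL_GROOVE or right == LABEL_GROOVE):
                    labels[s:e] = LABEL_GROOVE
                    changed = True
        runs = list(_runs(labels))
        for s, e, val in runs:
            if val == LABEL_GROOVE and (e - s) * dt_ns < min_groove_ns:
                labels[s:e] = LABEL_HOP
                changed = True
        if not changed:
            break
    return labels


def _events_from_labels(labels, z, times_ns, region):
    events = []
    for s, e, val in _runs(labels):
        t0 = times_ns[s] * 1e-3
        t1 = (times_ns[e - 1] + (times_ns[1] - times_ns[0])) * 1e-3
        if val == LABEL_3D:
            events.append(EventRecord("threeD", t0, t1, 0.0, region))
        else:
            span = (z[e - 1] - z[s]) / C.BP_RISE
            kind = "groove" if val == LABEL_GROOVE else "hop"
            events.append(EventRecord(kind, t0, t1, float(span), region))
    return events


def detect_flips(trace: HelixTrace, debounce_frames: int = 10) -> list[float]:
    """Times (us) at which the Z-order of the two recognition regions inverts
    and the inversion persists for at least ``debounce_frames`` frames."""
    names = list(trace.regions.keys())
    if len(names) < 2:
        warnings.warn("flip detection needs a dimeric trace (two regions)")
        return []
    z1 = trace.regions[names[0]]["Z"]
    z2 = trace.regions[names[1]]["Z"]
    sign = np.sign(z1 - z2)
    sign[sign == 0] = 1
    flips = []
    current = sign[0]
    i = 1
    n = len(sign)
    while i < n:
        if sign[i] != current:
            j = i
            while j < n and sign[j] == sign[i]:
                j += 1
            if (j - i) >= debounce_frames:
                flips.append(float(trace.times_ns[i] * 1e-3))
                current = sign[i]
            i = j
        else:
            i += 1
    return flips


def event_statistics(events: list[EventRecord],
                     total_time_us: float | None = None,
                     long_hop_bp: float = 5.0) -> EventStats:
    """Means/sds of event durations and spans plus hopping frequencies.

    The hopping frequency is normalized by the time assigned to 1D diffusion
    (groove + hop); the per-total-time variant is reported alongside.
    """
    groove = [ev for ev in events if ev.type == "groove"]
    hops = [ev for ev in events if ev.type == "hop"]
    time_1d = sum(ev.duration_us for ev in groove + hops)
    if total_time_us is None:
        total_time_us = sum(ev.duration_us for ev in events)

    def agg(vals):
        if not vals:
            return None
        arr = np.asarray(vals, float)
        return (float(arr.mean()), float(arr.std()))

    stats = EventStats(
        n_groove=len(groove),
        n_hop=len(hops),
        groove_duration_us=agg([ev.duration_us for ev in groove]),
        groove_span_bp=agg([abs(ev.span_bp) for ev in groove]),
        hop_duration_us=agg([ev.duration_us for ev in hops]),
        hop_span_bp=agg([abs(ev.span_bp) for ev in hops]),
        time_1d_us=float(time_1d),
        total_time_us=float(total_time_us),
    )
    if time_1d > 0:
        stats.hop_frequency_per_ms = len(hops) / (time_1d * 1e-3)
        stats.long_hop_frequency_per_ms = (
            sum(1 for ev in hops if abs(ev.span_bp) > long_hop_bp) / (time_1d * 1e-3)
        )
    else:
        warnings.warn("no 1D diffusion time; hopping frequency undefined")
    if total_time_us > 0:
        stats.hop_frequency_total_per_ms = len(hops) / (total_time_us * 1e-3)
    return stats
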