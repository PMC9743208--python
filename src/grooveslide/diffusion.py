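"""MSD-based diffusion estimation: translational D along the DNA axis,
rotational D_r around it, the helical pitch p = 2 pi sqrt(D / D_r), and the
hopping-augmented 1D coefficient D_1D = D_helix + x_hop^2 k_hop / 2.

Unit conventions follow the field: Z in A, phi in rad, D in um^2/s, D_r in
rad^2/s, x_hop in bp (converted at 3.32 A/bp) and k_hop in 1/ms.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import constants as C

A2_PER_NS_TO_UM2_PER_S = 10.0  # 1 A^2/ns = 1e-8 um^2 / 1e-9 s


@dataclass
class DiffusionEstimate:
    D_um2_s: float | None = None
    D_r_rad2_s: float | None = None
    pitch_bp: float | None = None
    pitch_A: float | None = None
    D_helix_um2_s: float | None = None
    x_hop_bp: float | None = None
    k_hop_per_ms: float | None = None
    D_1D_um2_s: float | None = None
    speedup: float | None = None
    fit_window_frames: tuple = (50, 200)
    frame_dt_ns: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compute_msd(series: np.ndarray, tau_max: int,
                mask: np.ndarray | None = None) -> np.ndarray:
    """Time-averaged MSD(tau) over all start frames for tau = 1..tau_max.

    The input must be uniformly sampled (and unwrapped, for angles).  With a
    boolean ``mask``, displacements are averaged only within contiguous
    masked segments (e.g. frames where the protein is associated with the
    DNA), so excursions outside the mask do not contaminate the curve; lags
    with no valid pair are returned as nan.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < tau_max + 1:
        raise ValueError(f"series of length {n} too short for tau_max={tau_max}")
    if mask is None:
        msd = np.empty(tau_max)
        for tau in range(1, tau_max + 1):
            diff = series[tau:] - series[:-tau]
            msd[tau - 1] = np.mean(diff * diff)
        return msd
    mask = np.asarray(mask, dtype=bool)
    sums = np.zeros(tau_max)
    counts = np.zeros(tau_max, dtype=int)
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    bounds = np.concatenate([[0], edges + 1, [n]])
    for s, e in zip(bounds[:-1], bounds[1:]):
        if not mask[s]:
            continue
        seg = series[s:e]
        for tau in range(1, min(tau_max, len(seg) - 1) + 1):
            diff = seg[tau:] - seg[:-tau]
            sums[tau - 1] += np.sum(diff * diff)
            counts[tau - 1] += len(diff)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def fit_diffusion_coefficient(msd: np.ndarray, window: tuple = (50, 200),
                              frame_dt_ns: float = 50.0,
                              kind: str = "translational"):
    """Least-squares slope of MSD over the tau window, divided by 2 (1D).

    Translational MSDs (A^2) are converted to um^2/s; rotational MSDs (rad^2)
    to rad^2/s.  A negative slope is clamped to 0 with a warning; strongly
    super-diffusive curvature (log-log slope well above 1) sets a diagnostic
    flag.  Returns ``(D, diagnostics)``.
    """
    lo, hi = int(window[0]), int(window[1])
    if lo < 1 or hi > len(msd):
        raise ValueError("fit window outside the computed tau range")
    taus = np.arange(lo, hi + 1)
    y = msd[lo - 1:hi]
    finite = np.isfinite(y)
    if finite.sum() < 2:
        raise ValueError("fewer than two valid MSD points in the fit window")
    taus, y = taus[finite], y[finite]
    slope, intercept = np.polyfit(taus.astype(float), y, 1)
    diagnostics = {"slope_per_frame": float(slope), "intercept": float(intercept)}
    if slope < 0:
        warnings.warn("negative MSD slope; D clamped to 0")
        slope = 0.0
    with np.errstate(divide="ignore"):
        pos = y > 0
        if pos.sum() >= 3:
            alpha = np.polyfit(np.log(taus[pos].astype(float)), np.log(y[pos]), 1)[0]
            diagnostics["loglog_slope"] = float(alpha)
            diagnostics["superdiffusive"] = bool(alpha > 1.5)
            if diagnostics["superdiffusive"]:
                warnings.warn("super-diffusive MSD curvature in the fit window")
    d_per_frame = slope / 2.0
    d_per_ns = d_per_frame / frame_dt_ns
    if kind == "translational":
        d = d_per_ns * A2_PER_NS_TO_UM2_PER_S  # A^2/ns -> um^2/s
    elif kind == "rotational":
        d = d_per_ns * 1e9                     # rad^2/ns -> rad^2/s
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return float(d), diagnostics


def compute_pitch(D_um2_s: float, D_r_rad2_s: float,
                  rise: float = C.BP_RISE):
    """Helical pitch p = 2 pi sqrt(D / D_r), in A and in bp.

    Returns ``(pitch_bp, pitch_A)``; undefined (None) when D_r = 0.
    """
    if D_r_rad2_s < 0 or D_um2_s < 0:
        raise ValueError("diffusion coefficients must be non-negative")
    if D_r_rad2_s == 0:
        warnings.warn("D_r = 0; pitch undefined")
        return None, None
    d_a2_s = D_um2_s * 1e8  # um^2/s -> A^2/s
    pitch_a = 2.0 * np.pi * np.sqrt(d_a2_s / D_r_rad2_s)
    return float(pitch_a / rise), float(pitch_a)


def combine_hopping(D_helix_um2_s: float, x_hop_bp: float, k_hop_per_ms: float,
                    bp_step: float = C.BP_RISE) -> float:
    """Hopping-augmented 1D diffusion: D_1D = D_helix + x_hop^2 k_hop / 2.

    x_hop enters in A (bp * 3.32 A) and k_hop in 1/ms; the result is um^2/s.
    """
    if min(D_helix_um2_s, x_hop_bp, k_hop_per_ms) < 0:
        raise ValueError("inputs must be non-negative")
    x_um = x_hop_bp * bp_step * 1e-4      # A -> um
    k_s = k_hop_per_ms * 1e3              # 1/ms -> 1/s
    return float(D_helix_um2_s + x_um ** 2 * k_s / 2.0)


def hopping_speedup(D_1D: float, D_helix: float):
    """How much hopping accelerates 1D diffusion: D_1D / D_helix."""
    if D_helix <= 0:
        warnings.warn("D_helix <= 0; speed-up undefined")
        return None
    return float(D_1D / D_helix)


def estimate_from_trace(trace, region: str = "1", window: tuple = (50, 200),
                        rise: float = C.BP_RISE,
                        bound_only: bool = False) -> DiffusionEstimate:
    """Fit D (from Z) and D_r (from unwrapped phi) on one trace region and
    derive the pitch.

    With ``bound_only`` the MSDs are restricted to contiguous stretches with
    d <= R_c, so 3D excursions do not enter the 1D-diffusion estimate.
    """
    z = trace.regions[region]["Z"]
    phi = trace.phi_unwrapped(region)
    dt = trace.frame_dt_ns
    tau_max = int(window[1])
    mask = (trace.regions[region]["d"] <= trace.r_c) if bound_only else None
    msd_t = compute_msd(z, tau_max, mask)
    msd_r = compute_msd(phi, tau_max, mask)
    d, _ = fit_diffusion_coefficient(msd_t, window, dt, "translational")
    dr, _ = fit_diffusion_coefficient(msd_r, window, dt, "rotational")
    pitch_bp, pitch_a = (None, None)
    if dr > 0:
        pitch_bp, pitch_a = compute_pitch(d, dr, rise)
    return DiffusionEstimate(
        D_um2_s=d, D_r_rad2_s=dr, pitch_bp=pitch_bp, pitch_A=pitch_a,
        fit_window_frames=(int(window[0]), int(window[1])), frame_dt_ns=dt,
    )
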