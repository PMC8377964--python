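"""Synthetic-data generators with known ground truth.

Every input modality of the pipeline can be generated here so each stage is
testable without clinical samples: log-normal HA molecular-weight
distributions, stained-gel lane profiles and images, nanopore current
traces with Poisson-arriving rectangular blockades, 2-D Brownian bead
trajectories, immunoblot band-density tables, and a two-group
(healthy / OA) cohort whose per-variable medians and IQRs follow the study
conditions (gel Mw 3660 vs 3070 kDa, TNF-alpha 4.97 vs 15.6 ng/mL, HC-HA
0.10 vs 0.38 a.u., viscosity tied to HA concentration through
y = 1 + B2 x^2 with B2 = 434 in OA, ...).

All randomness flows from a single ``numpy.random.default_rng(seed)`` per
call; identical arguments give bit-identical outputs.  Each generator
returns its outputs together with a machine-readable truth record.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .gel import GelCalibration, LaneProfile
from .mwdist import MWDistribution
from .nanopore import CurrentTrace, ECDCalibration
from .rheology import K_BOLTZMANN, Trajectory

__all__ = [
    "gen_mw_lognormal",
    "gen_gel_lane",
    "gen_gel_image",
    "gen_nanopore_trace",
    "gen_brownian_tracks",
    "gen_cohort",
    "gen_blot_pairs",
    "DEFAULT_COHORT_EFFECTS",
    "lognormal_params_from_median_iqr",
]


# ---------------------------------------------------------------------------
# molecular-weight distributions


def gen_mw_lognormal(
    mw_target_kda: float = 3660.0,
    pdi_target: float = 2.26,
    grid: Optional[np.ndarray] = None,
    n_grid: int = 2000,
) -> Tuple[MWDistribution, dict]:
    """Mass-weighted log-normal distribution with exact analytic Mw and PDI.

    If the mass-weighted density of log M is Normal(mu_w, sigma^2), then
    Mw = exp(mu_w + sigma^2/2), Mn = exp(mu_w - sigma^2/2) and
    PDI = exp(sigma^2); these relations are inverted in closed form so the
    targets are met exactly in the continuum limit (grid discretization
    error shrinks with n_grid).
    """
    if pdi_target < 1:
        raise ValueError("pdi_target must be >= 1")
    if mw_target_kda <= 0:
        raise ValueError("mw_target_kda must be positive")
    sigma2 = math.log(pdi_target)
    sigma = math.sqrt(sigma2)
    mu_w = math.log(mw_target_kda) - sigma2 / 2.0
    if grid is None:
        span = max(5.0 * sigma, 1e-3)
        grid = np.geomspace(math.exp(mu_w - span), math.exp(mu_w + span), n_grid)
    grid = np.asarray(grid, dtype=float)
    if sigma == 0:
        weights = np.zeros_like(grid)
        weights[np.argmin(np.abs(np.log(grid) - mu_w))] = 1.0
    else:
        pdf = np.exp(-((np.log(grid) - mu_w) ** 2) / (2 * sigma2)) / (grid * sigma * math.sqrt(2 * math.pi))
        weights = pdf * np.gradient(grid)
    dist = MWDistribution(grid, weights, "mass")
    truth = {
        "mw_kda": mw_target_kda,
        "mn_kda": mw_target_kda / pdi_target,
        "pdi": pdi_target,
        "mu_w": mu_w,
        "sigma": sigma,
    }
    return dist, truth


def _mass_cdf(dist: MWDistribution):
    """Cumulative mass fraction as a function of MW (linear interpolation)."""
    if len(dist.masses) == 1:  # delta distribution: step CDF
        m0 = float(dist.masses[0])
        return lambda m: (np.asarray(m, dtype=float) >= m0).astype(float)
    cum = np.concatenate(([0.0], np.cumsum(dist.weights)))
    cum /= cum[-1]
    edges = np.concatenate(([dist.masses[0]], 0.5 * (dist.masses[1:] + dist.masses[:-1]), [dist.masses[-1]]))
    # edges has len n+1 but first/last duplicate grid endpoints; make ascending-safe
    edges = np.maximum.accumulate(edges)
    return lambda m: np.interp(np.asarray(m, dtype=float), edges, cum, left=0.0, right=1.0)


# ---------------------------------------------------------------------------
# gel lanes


def gen_gel_lane(
    dist: MWDistribution,
    calib: GelCalibration,
    noise_sd: float = 0.0,
    baseline: float = 0.0,
    seed: int = 0,
    total_intensity: float = 1000.0,
) -> Tuple[LaneProfile, dict]:
    """Synthesize a densitometric lane profile from a known distribution.

    Each integer pixel inside the calibration range receives the mass
    fraction migrating into it (via the distribution's cumulative mass
    between the pixel-edge MWs), scaled to ``total_intensity``, plus a
    smooth additive baseline and i.i.d. Gaussian noise.  Mass outside the
    ladder range is truncated and recorded in the truth record.
    """
    rng = np.random.default_rng(seed)
    lo, hi = calib.valid_range
    px = np.arange(math.ceil(lo), math.floor(hi) + 1, dtype=float)
    if px.size < 2:
        raise ValueError("calibration range spans fewer than 2 pixels")
    cdf = _mass_cdf(dist)
    edges_lo = np.clip(px - 0.5, lo, hi)
    edges_hi = np.clip(px + 0.5, lo, hi)
    # MW decreases with distance: the pixel's mass is cdf(MW at near edge)
    # minus cdf(MW at far edge)
    mw_near = calib.mw_at(edges_lo)
    mw_far = calib.mw_at(edges_hi)
    frac = cdf(mw_near) - cdf(mw_far)
    truncated = float(1.0 - frac.sum())
    signal = total_intensity * frac
    profile = signal + baseline
    if noise_sd > 0:
        profile = profile + rng.normal(0.0, noise_sd * signal.max(), size=px.size)
    profile = np.maximum(profile, 0.0)
    truth = {
        "mass_per_px": signal,
        "truncated_mass_fraction": truncated,
        "total_intensity": total_intensity,
    }
    return LaneProfile(px, profile), truth


def gen_gel_image(
    dist: MWDistribution,
    calib: GelCalibration,
    lane_width_px: int = 10,
    noise_sd: float = 0.0,
    baseline: float = 0.0,
    seed: int = 0,
) -> Tuple[np.ndarray, dict]:
    """A two-lane grayscale gel image: ladder bands and one sample lane.

    Returns (image, truth); truth records the sample lane's column bounds
    and the ladder's per-anchor band rows.  Dark-background convention.
    """
    lane, truth = gen_gel_lane(dist, calib, noise_sd=noise_sd, baseline=baseline, seed=seed)
    n_rows = int(lane.distance_px[-1]) + 1
    img = np.zeros((n_rows, 2 * lane_width_px))
    for px_anchor in calib.anchors_px:
        r = int(round(px_anchor))
        if 0 <= r < n_rows:
            img[r, :lane_width_px] = 1.0
    rows = lane.distance_px.astype(int)
    img[rows, lane_width_px:] = lane.intensity[:, None]
    truth = dict(truth)
    truth["sample_lane_bounds"] = (lane_width_px, 2 * lane_width_px)
    truth["ladder_lane_bounds"] = (0, lane_width_px)
    return img, truth


# ---------------------------------------------------------------------------
# nanopore traces


def gen_nanopore_trace(
    dist: MWDistribution,
    ecd_calib: ECDCalibration,
    event_rate_hz: float = 20.0,
    sigma_pa: float = 8.0,
    duration_s: float = 5.0,
    sample_rate: float = 200_000.0,
    baseline_pa: float = 4000.0,
    seed: int = 0,
    snr: Optional[float] = None,
    min_snr: float = 6.0,
    dmin_gen_s: float = 50e-6,
    dmax_gen_s: float = 2e-3,
    edge_smooth_samples: int = 0,
) -> Tuple[CurrentTrace, pd.DataFrame]:
    """Baseline + Gaussian noise + Poisson-arriving rectangular blockades.

    Each event's MW is drawn number-weighted from ``dist`` (n_i ~ w_i/M_i
    for a mass-weighted input); its ECD follows the calibration's forward
    map, and it is realized as a rectangular dip of depth ECD/duration.
    With ``snr`` set, the depth is pinned at ``snr * sigma_pa`` and the
    duration follows from the ECD (clipped into the generated-duration
    window, preserving ECD by adjusting depth).  Otherwise durations are
    uniform in [dmin_gen_s, dmax_gen_s], capped so the depth stays at least
    ``min_snr`` noise SDs.  Overlapping placements are redrawn.  The truth
    table lists start/end sample, MW, ECD and depth per event.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    trace = np.full(n, baseline_pa)
    if sigma_pa > 0:
        trace = trace + rng.normal(0.0, sigma_pa, size=n)
    n_events = rng.poisson(event_rate_hz * duration_s)

    if dist.weighting == "mass":
        number_w = dist.weights / dist.masses
    else:
        number_w = dist.weights
    p = number_w / number_w.sum()
    mws = rng.choice(dist.masses, size=n_events, p=p)
    ecds = ecd_calib.mw_to_ecd(mws)  # pA*s

    rows = []
    occupied: List[Tuple[int, int]] = []
    # separation guard: events closer than the analysis filter's smear
    # (~0.2 ms at 5 kHz) are unresolvable, so placements are redrawn
    guard = max(1, int(round(5e-4 * sample_rate)))
    for mw, ecd in zip(mws, ecds):
        if snr is not None and sigma_pa > 0:
            depth = snr * sigma_pa
            dur = float(np.clip(ecd / depth, dmin_gen_s, dmax_gen_s))
            depth = ecd / dur
        else:
            dmax_eff = dmax_gen_s
            if sigma_pa > 0:
                dmax_eff = min(dmax_gen_s, ecd / (min_snr * sigma_pa))
            if dmax_eff <= dmin_gen_s:
                dur = dmin_gen_s
            else:
                dur = rng.uniform(dmin_gen_s, dmax_eff)
            depth = ecd / dur
        length = max(1, int(round(dur * sample_rate)))
        placed = False
        for _ in range(1000):
            start = int(rng.integers(guard, n - length - guard))
            if all(start + length + guard <= s or start >= e + guard for s, e in occupied):
                placed = True
                break
        if not placed:
            continue
        end = start + length
        occupied.append((start, end))
        if edge_smooth_samples > 0:
            ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, edge_smooth_samples)))
            pulse = np.full(length, depth)
            k = min(edge_smooth_samples, length // 2)
            pulse[:k] = depth * ramp[:k]
            pulse[-k:] = depth * ramp[:k][::-1]
            trace[start:end] -= pulse
        else:
            trace[start:end] -= depth
        rows.append(
            {
                "start_idx": start,
                "end_idx": end,
                "mw_kda": float(mw),
                "ecd_pas": float(depth * length / sample_rate),
                "depth_pa": float(depth),
            }
        )
    truth = pd.DataFrame(rows, columns=["start_idx", "end_idx", "mw_kda", "ecd_pas", "depth_pa"])
    truth = truth.sort_values("start_idx").reset_index(drop=True)
    return CurrentTrace(trace, sample_rate), truth


# ---------------------------------------------------------------------------
# Brownian trajectories


def gen_brownian_tracks(
    eta_cp: float = 1.0,
    temp_K: float = 295.15,
    bead_radius_um: float = 0.25,
    fps: float = 16.0,
    duration_s: float = 30.0,
    n_tracks: int = 45,
    loc_noise_um: float = 0.0,
    seed: int = 0,
) -> Tuple[List[Trajectory], dict]:
    """2-D Brownian bead tracks at a known viscosity.

    The truth diffusion coefficient follows Stokes-Einstein,
    D = k_B T / (6 pi r eta); per-axis steps are Gaussian with
    sd = sqrt(2 D dt).  Optional i.i.d. localization noise is added to the
    recorded positions (inflating the MSD intercept, not the slope).
    Defaults emulate three 30-s videos of ~15 beads at 16 Hz.
    """
    if eta_cp <= 0 or temp_K <= 0 or bead_radius_um <= 0 or fps <= 0:
        raise ValueError("eta, temperature, radius and fps must be positive")
    rng = np.random.default_rng(seed)
    eta_pas = eta_cp * 1e-3
    D_m2 = K_BOLTZMANN * temp_K / (6.0 * np.pi * bead_radius_um * 1e-6 * eta_pas)
    D = D_m2 * 1e12  # um^2/s
    dt = 1.0 / fps
    n_frames = int(round(duration_s * fps))
    step_sd = math.sqrt(2.0 * D * dt)
    tracks = []
    times = np.arange(n_frames) * dt
    for tid in range(n_tracks):
        steps = rng.normal(0.0, step_sd, size=(n_frames - 1, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        if loc_noise_um > 0:
            pos = pos + rng.normal(0.0, loc_noise_um, size=pos.shape)
        tracks.append(Trajectory(tid, times, pos[:, 0], pos[:, 1]))
    truth = {"eta_cp": eta_cp, "D_um2_per_s": D, "step_sd_um": step_sd, "dt_s": dt}
    return tracks, truth


# ---------------------------------------------------------------------------
# cohort table


def lognormal_params_from_median_iqr(median: float, iqr: float) -> Tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and IQR.

    median = exp(mu); IQR = exp(mu) * 2 sinh(z * sigma) with z = 0.6745
    (the standard-normal upper quartile), so sigma = asinh(IQR/2m)/z.
    """
    if median <= 0:
        raise ValueError("median must be positive")
    if iqr < 0:
        raise ValueError("IQR must be non-negative")
    z = 0.6744897501960817
    sigma = math.asinh(iqr / (2.0 * median)) / z
    return math.log(median), sigma


# Per-variable (healthy, OA) medians and IQRs as reported for the study
# cohort, used as generator defaults.  lod: detection limit below which a
# generated value is recorded as 0 (undetectable).
DEFAULT_COHORT_EFFECTS: Dict[str, dict] = {
    "ha_sandwich_mgml": {"median": (0.35, 0.29), "iqr": (0.3, 0.3)},
    "ha_competitive_mgml": {"median": (0.70, 0.69), "iqr": (0.4, 0.5)},
    "mw_gel_kda": {"median": (3660.0, 3070.0), "iqr": (1000.0, 740.0)},
    "mn_gel_kda": {"median": (1520.0, 1260.0), "iqr": (680.0, 410.0)},
    "pdi_gel": {"median": (2.26, 2.38), "iqr": (0.4, 0.4)},
    "tnfa_ngml": {"median": (4.97, 15.6), "iqr": (11.7, 22.7), "lod": 1.0},
    "ccl2_ngml": {"median": (1.61, 1.78), "iqr": (7.0, 6.6)},
    "ccl5_ngml": {"median": (0.025, 0.06), "iqr": (0.1, 0.3), "lod": 0.05},
    "ccl11_ngml": {"median": (0.86, 0.53), "iqr": (0.6, 0.4)},
    "hcha_au": {"median": (0.10, 0.38), "iqr": (0.1, 0.6)},
}

# viscosity = 1 + B2 * concentration^2 (cP, concentration in mg/mL)
DEFAULT_B2 = {"healthy": 256.0, "OA": 434.0}


def gen_cohort(
    n_healthy: int = 25,
    n_oa: int = 61,
    effects: Optional[Dict[str, dict]] = None,
    b2: Optional[Dict[str, float]] = None,
    visc_noise_sigma: float = 0.15,
    seed: int = 0,
) -> Tuple[pd.DataFrame, dict]:
    """Two-group cohort table with the study's effect structure.

    Each variable is drawn from a log-normal matched to its configured
    group median and IQR; variables with a detection limit are censored to
    0 below it.  Viscosity is generated from the sandwich-ELISA HA
    concentration through y = 1 + B2 x^2 (per-group B2) times log-normal
    noise.  TSG6 qPCR cycle thresholds are included with the OA group
    up-shifted in expression (lower dCT).
    """
    effects = effects if effects is not None else DEFAULT_COHORT_EFFECTS
    b2 = b2 if b2 is not None else dict(DEFAULT_B2)
    rng = np.random.default_rng(seed)
    n = n_healthy + n_oa
    groups = np.array(["healthy"] * n_healthy + ["OA"] * n_oa)
    df = pd.DataFrame(
        {"sample_id": [f"S{i:03d}" for i in range(n)], "group": groups}
    )
    for var, cfg in effects.items():
        med_h, med_o = cfg["median"]
        iqr_h, iqr_o = cfg["iqr"]
        vals = np.empty(n)
        for sel, med, iqr in (
            (groups == "healthy", med_h, iqr_h),
            (groups == "OA", med_o, iqr_o),
        ):
            mu, sigma = lognormal_params_from_median_iqr(med, iqr)
            vals[sel] = rng.lognormal(mu, sigma, size=sel.sum())
        lod = cfg.get("lod")
        if lod is not None:
            vals = np.where(vals < lod, 0.0, vals)
        df[var] = vals
    # viscosity tied to HA concentration (only when that variable exists)
    if "ha_sandwich_mgml" in df.columns:
        conc = df["ha_sandwich_mgml"].to_numpy()
        b2_per_sample = np.where(groups == "OA", b2["OA"], b2["healthy"])
        noise = rng.lognormal(0.0, visc_noise_sigma, size=n)
        df["viscosity_cp"] = (1.0 + b2_per_sample * conc**2) * noise
    # TSG6 qPCR: OA expresses more TSG6 (smaller dCT)
    fold_oa = 2.5
    dct = rng.normal(8.0, 0.8, size=n)
    dct[groups == "OA"] -= math.log2(fold_oa)
    ct_ref = rng.normal(15.0, 0.5, size=n)
    df["ct_18s"] = ct_ref
    df["ct_tsg6"] = ct_ref + dct
    truth = {
        "effects": effects,
        "b2": b2,
        "tsg6_fold_oa": fold_oa,
        "n_healthy": n_healthy,
        "n_oa": n_oa,
    }
    return df, truth


# ---------------------------------------------------------------------------
# immunoblot lane pairs


def gen_blot_pairs(
    n_per_group: Dict[str, int] = {"healthy": 25, "OA": 61},
    group_medians: Dict[str, float] = {"healthy": 0.10, "OA": 0.38},
    group_iqrs: Dict[str, float] = {"healthy": 0.1, "OA": 0.6},
    noise: float = 0.0,
    base_hc_ratio: float = 0.3,
    seed: int = 0,
) -> Tuple[pd.DataFrame, dict]:
    """Band-density table whose HC-HA a.u. truth follows configured medians.

    Pre-IaI densities vary between lanes; the undigested lane's HC band is
    ``base_hc_ratio`` times its Pre-IaI, and the digested lane's HC carries
    the sample's true a.u. on top.  ``noise`` adds multiplicative Gaussian
    density noise (0 gives exact truth recovery).
    """
    for g, m in group_medians.items():
        if m < 0:
            raise ValueError(f"negative median for group {g}")
    rng = np.random.default_rng(seed)
    rows = []
    truths = []
    i = 0
    for grp, n in n_per_group.items():
        med, iqr = group_medians[grp], group_iqrs[grp]
        if med == 0:
            au = np.zeros(n)
        else:
            mu, sigma = lognormal_params_from_median_iqr(med, iqr)
            au = rng.lognormal(mu, sigma, size=n)
        pre_minus = rng.lognormal(0.0, 0.2, size=n)
        pre_plus = rng.lognormal(0.0, 0.2, size=n)
        hc_minus = base_hc_ratio * pre_minus
        hc_plus = (base_hc_ratio + au) * pre_plus
        if noise > 0:
            for arr in (hc_minus, hc_plus, pre_minus, pre_plus):
                arr *= np.abs(1.0 + rng.normal(0.0, noise, size=n))
        for j in range(n):
            rows.append(
                {
                    "sample_id": f"B{i:03d}",
                    "group": grp,
                    "hc_minus": hc_minus[j],
                    "preiai_minus": pre_minus[j],
                    "hc_plus": hc_plus[j],
                    "preiai_plus": pre_plus[j],
                }
            )
            truths.append(au[j])
            i += 1
    df = pd.DataFrame(rows)
    truth = {"hcha_au": np.array(truths), "group_medians": dict(group_medians)}
    return df, truth
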