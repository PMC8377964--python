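"""Passive particle-tracking microrheology.

Fluorescent tracer beads embedded in synovial fluid undergo 2-D Brownian
motion whose mean-squared displacement (MSD) grows linearly with lag time
in a Newtonian fluid:

    MSD(tau) = 4 D tau + b,

where the intercept b absorbs static localization noise.  The diffusion
coefficient D gives the viscosity through the Stokes-Einstein relation

    eta = k_B T / (6 pi r D),

with bead radius r and absolute temperature T.  Videos are acquired at
16 Hz for 30 s with ~15 beads per frame, three videos per sample; the MSD
is both time- and ensemble-averaged over all tracks.

Only a Newtonian viscosity is reported (no frequency-dependent moduli).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "MSDCurve",
    "RheologyConfig",
    "compute_msd",
    "fit_diffusion",
    "viscosity_from_diffusion",
    "subtract_drift",
    "sf_viscosity_pipeline",
    "PipelineResult",
    "K_BOLTZMANN",
]

K_BOLTZMANN = 1.380649e-23  # J/K


@dataclass(frozen=True)
class Trajectory:
    """One bead track: uniformly sampled 2-D positions in micrometres."""

    track_id: int
    frame_times_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_times_s, dtype=float)
        x = np.asarray(self.x_um, dtype=float)
        y = np.asarray(self.y_um, dtype=float)
        for name, arr in (("frame_times_s", t), ("x_um", x), ("y_um", y)):
            object.__setattr__(self, name, arr)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1:
            raise ValueError("times and positions must be equal-length 1-D vectors")
        if len(t) < 2:
            raise ValueError("trajectory needs >= 2 points")
        steps = np.diff(t)
        if np.any(np.abs(steps - steps[0]) > 1e-9):
            raise ValueError("frame times must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.frame_times_s[1] - self.frame_times_s[0])


@dataclass(frozen=True)
class MSDCurve:
    """Lag-indexed mean-squared displacement with pair counts."""

    lag_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        lag = np.asarray(self.lag_s, dtype=float)
        msd = np.asarray(self.msd_um2, dtype=float)
        n = np.asarray(self.n_pairs, dtype=int)
        object.__setattr__(self, "lag_s", lag)
        object.__setattr__(self, "msd_um2", msd)
        object.__setattr__(self, "n_pairs", n)
        if np.any(np.diff(lag) <= 0):
            raise ValueError("lags must be ascending")
        if np.any(msd < 0) or np.any(n <= 0):
            raise ValueError("msd must be >= 0 and pair counts > 0")


@dataclass(frozen=True)
class RheologyConfig:
    temperature_K: float = 295.15
    bead_radius_um: float = 0.25
    fit_lag_min: int = 1  # in frame lags
    fit_lag_max: int = 8

    def __post_init__(self) -> None:
        if self.temperature_K <= 0 or self.bead_radius_um <= 0:
            raise ValueError("temperature and bead radius must be positive")
        if not (1 <= self.fit_lag_min < self.fit_lag_max):
            raise ValueError("fit lag range must satisfy 1 <= min < max")


def compute_msd(trajectories: Sequence[Trajectory], max_lag_frames: int) -> MSDCurve:
    """Time- and ensemble-averaged 2-D MSD over all tracks and start frames."""
    if len(trajectories) == 0:
        raise ValueError("no trajectories")
    dt = trajectories[0].dt
    sums = np.zeros(max_lag_frames)
    counts = np.zeros(max_lag_frames, dtype=int)
    for tr in trajectories:
        if abs(tr.dt - dt) > 1e-9:
            raise ValueError("all trajectories must share one frame interval")
        n = len(tr.frame_times_s)
        for lag in range(1, min(max_lag_frames, n - 1) + 1):
            dx = tr.x_um[lag:] - tr.x_um[:-lag]
            dy = tr.y_um[lag:] - tr.y_um[:-lag]
            sums[lag - 1] += np.sum(dx * dx + dy * dy)
            counts[lag - 1] += n - lag
    valid = counts > 0
    if not np.any(valid):
        raise ValueError("no displacement pairs at any lag")
    lags = (np.arange(1, max_lag_frames + 1) * dt)[valid]
    return MSDCurve(lags, sums[valid] / counts[valid], counts[valid])


class DiffusionFit(NamedTuple):
    D_um2_per_s: float
    intercept_um2: float
    ok: bool  # False when the fitted D is non-positive


def fit_diffusion(msd: MSDCurve, cfg: RheologyConfig = RheologyConfig()) -> DiffusionFit:
    """Weighted least-squares line msd = 4*D*tau + b over the configured lags.

    Weights are the pair counts at each lag (early lags, with the most
    pairs, dominate).  A non-positive D is flagged rather than raised so a
    pipeline can report it as a QC failure.
    """
    sel = slice(cfg.fit_lag_min - 1, cfg.fit_lag_max)
    tau = msd.lag_s[sel]
    y = msd.msd_um2[sel]
    w = msd.n_pairs[sel].astype(float)
    if len(tau) < 2:
        raise ValueError("need >= 2 lags inside the fit range")
    A = np.column_stack([tau, np.ones_like(tau)])
    sw = np.sqrt(w)
    slope, intercept = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)[0]
    D = slope / 4.0
    return DiffusionFit(float(D), float(intercept), bool(D > 0))


def viscosity_from_diffusion(D_um2_per_s: float, cfg: RheologyConfig = RheologyConfig()) -> float:
    """Stokes-Einstein viscosity in cP from a diffusion coefficient in um^2/s."""
    if D_um2_per_s <= 0:
        raise ValueError("D must be positive")
    D_m2 = D_um2_per_s * 1e-12
    r_m = cfg.bead_radius_um * 1e-6
    eta_pas = K_BOLTZMANN * cfg.temperature_K / (6.0 * np.pi * r_m * D_m2)
    return float(eta_pas * 1000.0)  # Pa*s -> cP


def subtract_drift(trajectories: Sequence[Trajectory]) -> List[Trajectory]:
    """Remove collective drift: subtract the mean per-frame displacement.

    The ensemble-mean step at each frame (over tracks covering that frame)
    is treated as stage/flow drift and removed from every track.  Off by
    default in the pipeline; apply explicitly before `sf_viscosity_pipeline`
    when drift is suspected.
    """
    if not trajectories:
        raise ValueError("no trajectories")
    n_frames = max(len(t.frame_times_s) for t in trajectories)
    sum_dx = np.zeros(n_frames - 1)
    sum_dy = np.zeros(n_frames - 1)
    counts = np.zeros(n_frames - 1)
    for tr in trajectories:
        n = len(tr.frame_times_s)
        sum_dx[: n - 1] += np.diff(tr.x_um)
        sum_dy[: n - 1] += np.diff(tr.y_um)
        counts[: n - 1] += 1
    with np.errstate(invalid="ignore"):
        drift_x = np.where(counts > 0, sum_dx / np.maximum(counts, 1), 0.0)
        drift_y = np.where(counts > 0, sum_dy / np.maximum(counts, 1), 0.0)
    cum_x = np.concatenate(([0.0], np.cumsum(drift_x)))
    cum_y = np.concatenate(([0.0], np.cumsum(drift_y)))
    out = []
    for tr in trajectories:
        n = len(tr.frame_times_s)
        out.append(
            Trajectory(tr.track_id, tr.frame_times_s, tr.x_um - cum_x[:n], tr.y_um - cum_y[:n])
        )
    return out


class PipelineResult(NamedTuple):
    viscosity_cp: Optional[float]
    D_um2_per_s: Optional[float]
    qc: dict


def sf_viscosity_pipeline(
    trajectories: Sequence[Trajectory],
    cfg: RheologyConfig = RheologyConfig(),
    video_ids: Optional[Sequence[int]] = None,
) -> PipelineResult:
    """Full chain: trajectories -> MSD -> D -> viscosity, with a QC report.

    When ``video_ids`` assigns each trajectory to a video, per-video
    estimates are reported alongside the pooled one.  Degenerate inputs
    (too few tracks / very short tracks) produce a wide-uncertainty flag
    rather than an error.
    """
    max_lag = cfg.fit_lag_max
    qc: dict = {
        "n_tracks": len(trajectories),
        "track_lengths": [len(t.frame_times_s) for t in trajectories],
        "per_video_cp": {},
        "flags": [],
    }
    usable_lags = max(len(t.frame_times_s) for t in trajectories) - 1
    if usable_lags < cfg.fit_lag_max:
        qc["flags"].append("wide-uncertainty: tracks shorter than the fit lag range")
    msd = compute_msd(trajectories, min(max_lag, usable_lags))
    if len(msd.lag_s) < 2:
        qc["flags"].append("wide-uncertainty: fewer than 2 MSD lags")
        # fall back to a naive single-lag estimate
        D = msd.msd_um2[0] / (4.0 * msd.lag_s[0])
        eta = viscosity_from_diffusion(D, cfg) if D > 0 else None
        return PipelineResult(eta, float(D) if D > 0 else None, qc)
    fit = fit_diffusion(msd, _clamped_cfg(cfg, len(msd.lag_s)))
    if not fit.ok:
        qc["flags"].append("non-positive fitted D; no viscosity emitted")
        return PipelineResult(None, None, qc)
    eta = viscosity_from_diffusion(fit.D_um2_per_s, cfg)
    qc["pooled_D_um2_per_s"] = fit.D_um2_per_s
    qc["intercept_um2"] = fit.intercept_um2
    if video_ids is not None:
        for vid in sorted(set(video_ids)):
            sub = [t for t, v in zip(trajectories, video_ids) if v == vid]
            try:
                res = sf_viscosity_pipeline(sub, cfg)
                qc["per_video_cp"][int(vid)] = res.viscosity_cp
            except ValueError:
                qc["per_video_cp"][int(vid)] = None
    return PipelineResult(eta, fit.D_um2_per_s, qc)


def _clamped_cfg(cfg: RheologyConfig, n_lags: int) -> RheologyConfig:
    if cfg.fit_lag_max <= n_lags:
        return cfg
    return RheologyConfig(
        cfg.temperature_K, cfg.bead_radius_um, cfg.fit_lag_min, max(2, n_lags)
    )
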