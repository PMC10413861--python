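"""Trajectory observables: R_gyr, translational and rotational diffusion,
block error estimates and diffusion-tensor condition-number summaries.

Translational diffusion uses the Einstein relation ⟨r²⟩ = 6 D δt on
center-of-geometry displacements at a fixed observation interval (10 ns by
default).  Rotational diffusion monitors, for each principal axis, the
autocorrelation θ(δt) = ⟨e(t+δt)·e(t)⟩ of the normalized interbead vector of
a representative bead pair, fits exp(−δt/τ) and reports D_rot = 1/(2τ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hydro import BeadModel, assemble_tensor, condition_number
from .trajectory import Trajectory
from .units import HydroEnvironment

logger = logging.getLogger(__name__)

__all__ = [
    "radius_of_gyration",
    "translational_diffusion",
    "select_axis_bead_pairs",
    "axis_autocorrelation",
    "rotational_diffusion",
    "block_errors",
    "condition_number_series",
    "DiffusionReport",
    "diffusion_report",
]


def radius_of_gyration(frame: np.ndarray) -> float:
    """R_gyr² = (1/N) Σ |r_i − r_mean|², unweighted."""
    frame = np.asarray(frame, dtype=np.float64).reshape(-1, 3)
    centered = frame - frame.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def _lag_frames(traj: Trajectory, interval_ns: float) -> int:
    if traj.n_frames < 2:
        raise ValueError("trajectory too short")
    frame_dt = float(traj.times_ps[1] - traj.times_ps[0])
    lag = int(round(interval_ns * 1000.0 / frame_dt))
    if lag < 1 or lag >= traj.n_frames:
        raise ValueError(
            f"observation interval {interval_ns} ns needs more than "
            f"{lag + 1} frames at {frame_dt} ps spacing; have {traj.n_frames}"
        )
    return lag


def translational_diffusion(
    traj: Trajectory,
    observation_interval_ns: float = 10.0,
    overlapping: bool = True,
) -> float:
    """Einstein-relation D_trans (Å²/ps) from center-of-geometry motion.

    Displacements are taken at the fixed lag ``observation_interval_ns``;
    origins are every frame (overlapping, default) or spaced one lag apart.
    """
    lag = _lag_frames(traj, observation_interval_ns)
    cog = traj.frames.mean(axis=1)
    disp = cog[lag:] - cog[:-lag]
    if not overlapping:
        disp = disp[::lag]
    msd = float(np.mean(np.sum(disp**2, axis=1)))
    dt_ps = lag * float(traj.times_ps[1] - traj.times_ps[0])
    return msd / (6.0 * dt_ps)


def principal_axes(frame: np.ndarray) -> np.ndarray:
    """Principal axes of inertia (uniform bead masses), columns sorted so
    axis 0 has the smallest moment (the longest extent)."""
    frame = np.asarray(frame, dtype=np.float64).reshape(-1, 3)
    centered = frame - frame.mean(axis=0)
    r2 = np.sum(centered**2, axis=1)
    inertia = np.diag([r2.sum()] * 3) - centered.T @ centered
    vals, vecs = np.linalg.eigh(inertia)
    if vals[1] - vals[0] < 1e-9 * max(vals[-1], 1.0):
        logger.info("near-degenerate inertia tensor; axis order by eigh convention")
    return vecs  # eigh returns ascending eigenvalues


def select_axis_bead_pairs(native_frame: np.ndarray) -> list[tuple[int, int]]:
    """One representative bead pair per principal axis.

    The structure is aligned to its principal axes of inertia (uniform
    masses).  For each axis, among pairs whose separation along that axis is
    at least 75% of the maximum such separation, the pair with the smallest
    combined perpendicular distance from the axis is chosen.
    """
    frame = np.asarray(native_frame, dtype=np.float64).reshape(-1, 3)
    if len(frame) < 2:
        raise ValueError("need at least 2 beads")
    centered = frame - frame.mean(axis=0)
    proj = centered @ principal_axes(frame)  # coordinates in the axis frame
    n = len(frame)
    ii, jj = np.triu_indices(n, k=1)
    pairs: list[tuple[int, int]] = []
    for axis in range(3):
        sep = np.abs(proj[ii, axis] - proj[jj, axis])
        candidates = sep >= 0.75 * sep.max()
        perp = np.sqrt(np.sum(np.delete(proj, axis, axis=1) ** 2, axis=1))
        combined = perp[ii] + perp[jj]
        masked = np.where(candidates, combined, np.inf)
        best = int(np.argmin(masked))
        pairs.append((int(ii[best]), int(jj[best])))
    return pairs


def axis_autocorrelation(
    traj: Trajectory, pair: tuple[int, int], max_lag: int
) -> np.ndarray:
    """θ(δt) = ⟨e(t+δt)·e(t)⟩ for lags 1..max_lag (overlapping origins)."""
    i, j = pair
    vec = traj.frames[:, j] - traj.frames[:, i]
    e = vec / np.linalg.norm(vec, axis=1, keepdims=True)
    out = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        out[lag - 1] = float(np.mean(np.sum(e[lag:] * e[:-lag], axis=1)))
    return out


@dataclass
class AxisFit:
    D_rot: float | None  # 1/ps, None on fit failure
    tau_ps: float | None
    failed: bool = False


def rotational_diffusion(
    traj: Trajectory,
    axis_pairs: list[tuple[int, int]],
    fit_horizon_ns: float = 10.0,
    min_theta: float = 0.05,
) -> list[AxisFit]:
    """Per-axis D_rot from exponential fits of axis autocorrelations.

    exp(−δt/τ) is fit in log space (unweighted least squares through the
    origin) using lags up to the horizon with θ above ``min_theta``;
    D_rot = 1/(2τ).  A non-decaying correlation flags fit failure.
    """
    frame_dt = float(traj.times_ps[1] - traj.times_ps[0])
    max_lag = int(round(fit_horizon_ns * 1000.0 / frame_dt))
    max_lag = min(max(max_lag, 1), traj.n_frames - 1)
    fits: list[AxisFit] = []
    for pair in axis_pairs:
        theta = axis_autocorrelation(traj, pair, max_lag)
        lags_ps = np.arange(1, max_lag + 1) * frame_dt
        good = theta > min_theta
        if good.sum() < 2:
            fits.append(AxisFit(None, None, failed=True))
            continue
        x = lags_ps[good]
        y = np.log(theta[good])
        slope = float(np.sum(x * y) / np.sum(x * x))
        if slope >= 0:
            fits.append(AxisFit(None, None, failed=True))
            continue
        tau = -1.0 / slope
        fits.append(AxisFit(D_rot=1.0 / (2.0 * tau), tau_ps=tau))
    return fits


def block_errors(
    traj: Trajectory,
    observable,
    n_blocks: int = 3,
    burn_in_frac: float = 0.01,
) -> tuple[float, float, list[float]]:
    """Observable computed on equal trajectory blocks after a burn-in.

    The first ``burn_in_frac`` of frames is discarded and the remainder cut
    into ``n_blocks`` equal blocks (mirroring the 0.1–3.4 / 3.4–6.7 /
    6.7–10.0 μs convention); returns (mean, sample std over blocks, values).
    """
    start = int(np.floor(burn_in_frac * traj.n_frames))
    usable = traj.n_frames - start
    block = usable // n_blocks
    if block < 1:
        raise ValueError(
            f"too few frames ({traj.n_frames}) for {n_blocks} blocks"
        )
    values = []
    for b in range(n_blocks):
        lo = start + b * block
        values.append(float(observable(traj.slice(lo, lo + block))))
    arr = np.asarray(values)
    return float(arr.mean()), float(arr.std(ddof=1)), values


def mean_rgyr(traj: Trajectory) -> float:
    return float(np.mean([radius_of_gyration(f) for f in traj.frames]))


def condition_number_series(
    traj: Trajectory,
    hydro_radius: float,
    env: HydroEnvironment,
    tensor_kind: str = "full-rpy",
    max_frames: int = 10,
) -> np.ndarray:
    """Condition numbers of the diffusion tensor at evenly sampled frames."""
    idx = np.unique(
        np.linspace(0, traj.n_frames - 1, min(max_frames, traj.n_frames)).astype(int)
    )
    out = []
    for k in idx:
        model = BeadModel(traj.frames[k], hydro_radius)
        out.append(condition_number(assemble_tensor(model, env, tensor_kind)))
    return np.asarray(out)


@dataclass
class DiffusionReport:
    D_trans: float                     # Å²/ps
    D_trans_std: float
    D_rot: list[float | None]          # 1/ps per principal axis
    D_rot_std: list[float | None]
    tau_rot_ps: list[float | None]
    rgyr_mean: float
    rgyr_std: float
    condition_numbers: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def as_dict(self) -> dict:
        return {
            "D_trans": self.D_trans,
            "D_trans_std": self.D_trans_std,
            "D_rot_x": self.D_rot[0], "D_rot_y": self.D_rot[1], "D_rot_z": self.D_rot[2],
            "D_rot_x_std": self.D_rot_std[0], "D_rot_y_std": self.D_rot_std[1],
            "D_rot_z_std": self.D_rot_std[2],
            "tau_rot_x_ps": self.tau_rot_ps[0], "tau_rot_y_ps": self.tau_rot_ps[1],
            "tau_rot_z_ps": self.tau_rot_ps[2],
            "rgyr_mean": self.rgyr_mean, "rgyr_std": self.rgyr_std,
            "condition_numbers": list(self.condition_numbers),
        }


def diffusion_report(
    traj: Trajectory,
    native_frame: np.ndarray | None = None,
    observation_interval_ns: float = 10.0,
    fit_horizon_ns: float = 10.0,
    env: HydroEnvironment | None = None,
    with_condition_numbers: bool = False,
) -> DiffusionReport:
    """Full observable bundle with 3-block error estimates."""
    if native_frame is None:
        native_frame = traj.frames[0]
    pairs = select_axis_bead_pairs(native_frame)

    dt_mean, dt_std, _ = block_errors(
        traj, lambda t: translational_diffusion(t, observation_interval_ns)
    )

    def axis_value(t: Trajectory, axis: int) -> float:
        fit = rotational_diffusion(t, [pairs[axis]], fit_horizon_ns)[0]
        return np.nan if fit.failed else fit.D_rot

    d_rot, d_rot_std, taus = [], [], []
    for axis in range(3):
        mean, std, _ = block_errors(traj, lambda t, a=axis: axis_value(t, a))
        full_fit = rotational_diffusion(traj, [pairs[axis]], fit_horizon_ns)[0]
        d_rot.append(None if full_fit.failed else full_fit.D_rot)
        taus.append(None if full_fit.failed else full_fit.tau_ps)
        d_rot_std.append(None if np.isnan(std) else std)

    rg_mean, rg_std, _ = block_errors(traj, mean_rgyr)
    rgyr_all = np.array([radius_of_gyration(f) for f in traj.frames])

    cond = np.zeros(0)
    if with_condition_numbers:
        cond = condition_number_series(
            traj,
            traj.metadata.get("hydro_radius", 5.3),
            env or HydroEnvironment(),
            traj.metadata.get("tensor_kind", "full-rpy"),
        )
    return DiffusionReport(
        D_trans=dt_mean, D_trans_std=dt_std,
        D_rot=d_rot, D_rot_std=d_rot_std, tau_rot_ps=taus,
        rgyr_mean=float(rgyr_all.mean()), rgyr_std=float(rgyr_all.std()),
        condition_numbers=cond,
    )
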