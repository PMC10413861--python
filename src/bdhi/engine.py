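"""Ermak–McCammon Brownian dynamics propagator with hydrodynamic coupling.

One step displaces all beads by

    ΔR = (Δt / kBT) · D·F  +  (∇·D) Δt  +  √(2Δt) · S·U

where D is the diffusion tensor (full RPY or OA-RPY), S its lower Cholesky
factor, U i.i.d. standard normal, and ∇·D the divergence drift (identically
zero for the full RPY tensor, analytic for the OA tensor).  D, S and the
drift are refreshed every ``tensor_update_interval`` steps and held fixed in
between; the cached drift displacements are added unchanged at every step.

For the OA tensor the expensive products collapse to N×N operations applied
per Cartesian component: D·F becomes C·F with C the scalar coefficient
matrix, and the correlated noise is L·U per component with L = chol(C) —
both are algebraically identical to expanding C ⊗ I₃ to 3N×3N.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .forcefield import ForceFieldParams, Topology, total_energy_forces
from .hydro import (
    BeadModel,
    DiffusionTensor,
    DivergenceField,
    FullDiffusionTensor,
    OADiffusionTensor,
    SqrtFactor,
    assemble_tensor,
    oa_divergence,
    sqrt_factor,
)
from .trajectory import Trajectory
from .units import FS_TO_PS, HydroEnvironment

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "BlowUpError",
    "apply_DF",
    "draw_correlated_noise",
    "propagate_step",
    "run_simulation",
]

BLOWUP_THRESHOLD = 10.0  # Å per-step displacement limit


class BlowUpError(RuntimeError):
    """Raised when a per-step displacement exceeds the blow-up threshold."""


@dataclass
class SimulationConfig:
    n_steps: int
    timestep_fs: float = 25.0
    save_interval: int | None = None  # steps; default makes frames 100 ps apart
    tensor_update_interval: int = 100
    tensor_kind: str = "full-rpy"
    include_divergence: bool = True  # only meaningful for the OA tensor
    rng_seed: int = 0
    env: HydroEnvironment = field(default_factory=HydroEnvironment)
    zero_noise: bool = False  # test hook: suppress the stochastic term

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.tensor_update_interval < 1:
            raise ValueError("tensor_update_interval must be >= 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.tensor_kind not in ("full-rpy", "oa-rpy"):
            raise ValueError(f"unknown tensor kind {self.tensor_kind!r}")
        if self.save_interval is None:
            # frames 100 ps apart, matching the trajectory-saving convention
            self.save_interval = max(1, round(100.0 / (self.timestep_fs * FS_TO_PS)))

    @property
    def timestep_ps(self) -> float:
        return self.timestep_fs * FS_TO_PS


@dataclass
class SimulationState:
    positions: np.ndarray
    step: int = 0
    tensor: DiffusionTensor | None = None
    factor: SqrtFactor | None = None
    divergence: DivergenceField | None = None
    rng: np.random.Generator | None = None


def apply_DF(tensor: DiffusionTensor, forces: np.ndarray) -> np.ndarray:
    """Force-induced displacement pattern D·F (before Δt/kBT scaling).

    ``forces`` is (N, 3); the result is (N, 3).  The OA fast path applies
    the scalar pair coefficient matrix to each Cartesian component, which
    is identical to expanding the OA tensor to 3N×3N and multiplying.
    """
    forces = np.asarray(forces, dtype=np.float64)
    n = forces.shape[0]
    if isinstance(tensor, OADiffusionTensor):
        if tensor.n_beads != n:
            raise ValueError("tensor/forces dimension mismatch")
        return tensor.entries @ forces
    if tensor.entries.shape[0] != 3 * n:
        raise ValueError("tensor/forces dimension mismatch")
    return (tensor.entries @ forces.reshape(3 * n)).reshape(n, 3)


def draw_correlated_noise(
    factor: SqrtFactor,
    rng: np.random.Generator,
    n_draws: int,
    timestep_ps: float,
) -> np.ndarray:
    """√(2Δt)·S·U draws, one per row, shape (n_draws, 3N).

    For an OA factor (N×N) the same lower-triangular matrix is applied to
    each Cartesian component, matching the Cholesky factor of C ⊗ I₃.
    """
    s = factor.factor
    scale = np.sqrt(2.0 * timestep_ps)
    if factor.model_tag == "oa-rpy":
        n = s.shape[0]
        g = rng.standard_normal((n_draws, n, 3))
        return (scale * np.matmul(s, g)).reshape(n_draws, 3 * n)
    g = rng.standard_normal((n_draws, s.shape[0]))
    return scale * (g @ s.T)


def refresh_caches(
    state: SimulationState,
    model_radius: float,
    config: SimulationConfig,
) -> None:
    """Rebuild tensor, Cholesky factor and divergence at current positions."""
    model = BeadModel(positions=state.positions, hydro_radius=model_radius)
    state.tensor = assemble_tensor(model, config.env, config.tensor_kind)
    state.factor = sqrt_factor(state.tensor)
    if config.tensor_kind == "oa-rpy" and config.include_divergence:
        state.divergence = oa_divergence(model, config.env)
    else:
        state.divergence = None


def propagate_step(
    state: SimulationState,
    forces: np.ndarray,
    config: SimulationConfig,
) -> SimulationState:
    """Advance one BD step (reference path; the run loop uses compiled kernels).

    The caller supplies forces evaluated at the current positions; caches in
    ``state`` must have been refreshed at the appropriate interval via
    :func:`refresh_caches`.
    """
    if state.tensor is None or state.factor is None:
        raise ValueError("tensor caches not initialized; call refresh_caches")
    dt = config.timestep_ps
    disp = (dt / config.env.kBT) * apply_DF(state.tensor, forces)
    if state.divergence is not None:
        disp = disp + dt * state.divergence.drift
    if not config.zero_noise:
        if state.rng is None:
            state.rng = np.random.default_rng(config.rng_seed)
        noise = draw_correlated_noise(state.factor, state.rng, 1, dt)
        disp = disp + noise.reshape(-1, 3)
    maxd = float(np.max(np.abs(disp)))
    if maxd > BLOWUP_THRESHOLD:
        fmax = float(np.max(np.abs(forces)))
        raise BlowUpError(
            f"step {state.step + 1}: displacement {maxd:.2f} Å exceeds "
            f"{BLOWUP_THRESHOLD} Å (max |F| = {fmax:.3g} kcal/mol/Å)"
        )
    state.positions = state.positions + disp
    state.step += 1
    return state


def _packed_topology(topology: Topology | None, n: int):
    if topology is None:
        topology = Topology(n_beads=n)
    excl = topology.exclusion_matrix()
    return (
        np.ascontiguousarray(topology.bonds),
        np.ascontiguousarray(topology.bond_req),
        np.ascontiguousarray(topology.angles),
        np.ascontiguousarray(topology.angle_eq),
        np.ascontiguousarray(topology.dihedrals),
        np.ascontiguousarray(topology.dihedral_phi1),
        np.ascontiguousarray(topology.dihedral_phi3),
        np.ascontiguousarray(topology.native_pairs),
        np.ascontiguousarray(topology.native_sigma),
        np.ascontiguousarray(excl),
    )


def run_simulation(
    model: BeadModel,
    topology: Topology | None,
    params: ForceFieldParams | None,
    config: SimulationConfig,
) -> Trajectory:
    """Run a BD-HI simulation and return the saved frames.

    Deterministic for a fixed ``config.rng_seed``.  Frame 0 is the initial
    conformation; subsequent frames are saved every ``save_interval`` steps.
    On blow-up a :class:`BlowUpError` is raised carrying the last positions
    as a checkpoint attribute.
    """
    if params is None:
        params = ForceFieldParams()
    n = model.n_beads
    dt = config.timestep_ps
    rng = np.random.default_rng(config.rng_seed)

    (bonds, bond_req, angles, angle_eq, dihedrals, phi1, phi3,
     nat_pairs, nat_sigma, excl) = _packed_topology(topology, n)

    pos = model.positions.copy()
    n_frames = 1 + config.n_steps // config.save_interval
    frames = np.empty((n_frames, n, 3))
    frames[0] = pos
    frame_count = np.array([1], dtype=np.int64)

    max_pairs = max(1, n * (n - 1) // 2)
    nb_i = np.empty(max_pairs, dtype=np.int64)
    nb_j = np.empty(max_pairs, dtype=np.int64)
    nb_count = np.array([0], dtype=np.int64)

    full_kind = config.tensor_kind == "full-rpy"
    dim = 3 * n if full_kind else n
    tensor_buf = np.empty((dim, dim))
    drift = np.zeros((n, 3))
    drift_dt = np.zeros((n, 3))
    a = model.hydro_radius
    kBT, eta = config.env.kBT, config.env.viscosity
    scale = np.sqrt(2.0 * dt)
    use_div = config.include_divergence and not full_kind

    step = 0
    while step < config.n_steps:
        chunk = min(config.tensor_update_interval, config.n_steps - step)
        if full_kind:
            _kernels.fill_full_rpy(pos, a, kBT, eta, tensor_buf)
        else:
            _kernels.fill_oa_rpy(pos, a, kBT, eta, tensor_buf)
            if use_div:
                _kernels.fill_oa_divergence(pos, a, kBT, eta, drift)
                np.multiply(drift, dt, out=drift_dt)
        factor = np.linalg.cholesky(tensor_buf)
        if config.zero_noise:
            noise = np.zeros((chunk, 3 * n))
        elif full_kind:
            noise = scale * (rng.standard_normal((chunk, 3 * n)) @ factor.T)
        else:
            g = rng.standard_normal((chunk, n, 3))
            noise = (scale * np.matmul(factor, g)).reshape(chunk, 3 * n)
        status = _kernels.run_chunk(
            pos, chunk, step,
            full_kind,
            tensor_buf,
            noise, drift_dt, dt / config.env.kBT,
            bonds, bond_req, params.k_b,
            angles, angle_eq, params.k_a,
            dihedrals, phi1, phi3, params.k_d1, params.k_d3,
            nat_pairs, nat_sigma, params.eps_native,
            excl, nb_i, nb_j, nb_count,
            params.sigma_steric, params.steric_prefactor, params.cutoff,
            params.list_update_interval,
            config.save_interval, frames, frame_count,
            BLOWUP_THRESHOLD,
        )
        if status != _kernels.OK:
            err = BlowUpError(
                f"displacement exceeded {BLOWUP_THRESHOLD} Å at step {-status}"
            )
            err.checkpoint = pos.copy()
            raise err
        step += chunk

    times = np.arange(frame_count[0]) * config.save_interval * dt
    times[0] = 0.0
    meta = {
        "tensor_kind": config.tensor_kind,
        "include_divergence": bool(
            config.include_divergence and config.tensor_kind == "oa-rpy"
        ),
        "timestep_fs": config.timestep_fs,
        "tensor_update_interval": config.tensor_update_interval,
        "save_interval": config.save_interval,
        "rng_seed": config.rng_seed,
        "n_steps": config.n_steps,
        "hydro_radius": model.hydro_radius,
        "temperature_K": config.env.temperature,
        "viscosity_cP": config.env.viscosity_cp,
    }
    return Trajectory(
        frames=frames[: frame_count[0]],
        times_ps=times,
        labels=model.labels,
        metadata=meta,
    )


def single_point(
    model: BeadModel, topology: Topology | None, params: ForceFieldParams | None
):
    """Energy/forces of a conformation with a fresh neighbor list."""
    if params is None:
        params = ForceFieldParams()
    if topology is None:
        topology = Topology(n_beads=model.n_beads)
    return total_energy_forces(model, topology, params)
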