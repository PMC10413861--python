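"""Diffusion tensors for bead hydrodynamics.

Implements the Stokes–Einstein self term, the full Rotne–Prager–Yamakawa
(RPY) pair tensor for equal bead radii (with the regularized overlap form
for r < 2a), its orientational average (OA-RPY), the divergence drift field
required by the Ermak–McCammon propagator when the OA tensor is used, and
Cholesky square-root factors.

Orientational averaging replaces each 3×3 RPY pair block by its average over
all orientations of the separation vector at fixed distance: <x²/r²> = 1/3
and <xy/r²> = 0, so all cross terms vanish and the three diagonal entries
collapse to a single scalar D_rr(r).  Closed forms for equal radii a:

    r >= 2a :  D_rr = kBT / (6 π η r)
    r <  2a :  D_rr = kBT / (6 π η a) · (1 − r / 4a)

Both branches and their first derivatives agree at r = 2a.  The full RPY
tensor is divergence-free; the OA tensor is not, and each pair contributes a
drift  dD_rr/dr · r̂  (pointing outward, since dD_rr/dr < 0) to each bead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cholesky, eigvalsh

from .units import HydroEnvironment

__all__ = [
    "BeadModel",
    "FullDiffusionTensor",
    "OADiffusionTensor",
    "DivergenceField",
    "SqrtFactor",
    "DecompositionError",
    "stokes_einstein_self",
    "rpy_pair_block",
    "oa_pair_coefficient",
    "oa_pair_coefficient_derivative",
    "assemble_tensor",
    "expand_oa_tensor",
    "sqrt_factor",
    "oa_divergence",
    "condition_number",
    "count_apply_DF_multiplications",
    "count_cholesky_multiplications",
]


class DecompositionError(LinAlgError):
    """Raised when a diffusion tensor is not positive definite."""


@dataclass
class BeadModel:
    """A set of beads with one shared hydrodynamic radius.

    positions : (N, 3) float array, Å
    hydro_radius : scalar bead radius a, Å (all beads identical)
    labels : optional per-bead identifiers
    """

    positions: np.ndarray
    hydro_radius: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if self.positions.shape[0] < 1:
            raise ValueError("need at least one bead")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        radius = np.asarray(self.hydro_radius, dtype=np.float64)
        if radius.ndim > 0:
            # one shared radius is a modelling requirement, not a shortcut
            if not np.all(radius == radius.flat[0]):
                raise ValueError(
                    "all beads must share one hydrodynamic radius; "
                    "unequal radii are not supported"
                )
            radius = radius.flat[0]
        if radius <= 0:
            raise ValueError(f"hydrodynamic radius must be > 0, got {radius}")
        self.hydro_radius = float(radius)
        if self.labels is None:
            self.labels = [f"B{i}" for i in range(self.positions.shape[0])]

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]


@dataclass
class FullDiffusionTensor:
    entries: np.ndarray  # (3N, 3N), Å²/ps
    model_tag: str = "full-rpy"

    @property
    def n_beads(self) -> int:
        return self.entries.shape[0] // 3


@dataclass
class OADiffusionTensor:
    entries: np.ndarray  # (N, N) scalar pair coefficients, Å²/ps
    model_tag: str = "oa-rpy"

    @property
    def n_beads(self) -> int:
        return self.entries.shape[0]


DiffusionTensor = Union[FullDiffusionTensor, OADiffusionTensor]


@dataclass
class DivergenceField:
    """Per-bead drift Σ_j ∂/∂r_j · D_ij in Å²/ps/Å (= Å/ps)."""

    drift: np.ndarray  # (N, 3)
    valid_for_positions: np.ndarray  # (N, 3)


@dataclass
class SqrtFactor:
    factor: np.ndarray  # lower triangular, (3N,3N) full / (N,N) OA
    model_tag: str


def stokes_einstein_self(radius: float, env: HydroEnvironment) -> float:
    """Self diffusion coefficient kBT / (6 π η a) in Å²/ps."""
    if radius <= 0:
        raise ValueError(f"bead radius must be > 0, got {radius}")
    return env.kBT / (6.0 * np.pi * env.viscosity * radius)


def rpy_pair_block(
    separation: np.ndarray, radius: float, env: HydroEnvironment
) -> np.ndarray:
    """3×3 RPY diffusion block for two equal beads at a given separation.

    For r >= 2a the far-field RPY form is returned; for r < 2a the
    regularized overlap form, which reduces to the Stokes–Einstein self
    block at r = 0.  The two branches agree at r = 2a.
    """
    if radius <= 0:
        raise ValueError(f"bead radius must be > 0, got {radius}")
    sep = np.asarray(separation, dtype=np.float64)
    if sep.shape != (3,) or not np.all(np.isfinite(sep)):
        raise ValueError("separation must be a finite 3-vector")
    a = radius
    r = float(np.linalg.norm(sep))
    eye = np.eye(3)
    if r >= 2.0 * a:
        pref = env.kBT / (8.0 * np.pi * env.viscosity * r)
        rhat = sep / r
        return pref * (
            (1.0 + 2.0 * a * a / (3.0 * r * r)) * eye
            + (1.0 - 2.0 * a * a / (r * r)) * np.outer(rhat, rhat)
        )
    pref = env.kBT / (6.0 * np.pi * env.viscosity * a)
    if r == 0.0:
        return pref * eye
    rhat = sep / r
    return pref * (
        (1.0 - 9.0 * r / (32.0 * a)) * eye
        + (3.0 * r / (32.0 * a)) * np.outer(rhat, rhat)
    )


def oa_pair_coefficient(
    distance: float | np.ndarray, radius: float, env: HydroEnvironment
) -> float | np.ndarray:
    """Orientationally averaged pair coefficient D_rr(r).

    Average of the diagonal of :func:`rpy_pair_block` over all orientations
    of the separation vector at fixed distance; all cross terms average to
    zero.  Accepts scalars or arrays of distances.
    """
    if radius <= 0:
        raise ValueError(f"bead radius must be > 0, got {radius}")
    r = np.asarray(distance, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("distance must be >= 0")
    a = radius
    self_d = env.kBT / (6.0 * np.pi * env.viscosity * a)
    far = np.divide(
        env.kBT, 6.0 * np.pi * env.viscosity * np.maximum(r, 2.0 * a)
    )
    near = self_d * (1.0 - r / (4.0 * a))
    out = np.where(r >= 2.0 * a, far, near)
    return float(out) if out.ndim == 0 else out


def oa_pair_coefficient_derivative(
    distance: float | np.ndarray, radius: float, env: HydroEnvironment
) -> float | np.ndarray:
    """dD_rr/dr, negative everywhere; continuous across r = 2a."""
    if radius <= 0:
        raise ValueError(f"bead radius must be > 0, got {radius}")
    r = np.asarray(distance, dtype=np.float64)
    a = radius
    far = -env.kBT / (6.0 * np.pi * env.viscosity * np.maximum(r, 2.0 * a) ** 2)
    near = np.full_like(
        far, -env.kBT / (24.0 * np.pi * env.viscosity * a * a)
    )
    out = np.where(r >= 2.0 * a, far, near)
    return float(out) if out.ndim == 0 else out


def _pair_geometry(model: BeadModel):
    pos = model.positions
    diff = pos[None, :, :] - pos[:, None, :]  # diff[i, j] = r_j - r_i
    dist = np.linalg.norm(diff, axis=-1)
    return diff, dist


def assemble_tensor(
    model: BeadModel,
    env: HydroEnvironment,
    tensor_kind: Literal["full-rpy", "oa-rpy"] = "full-rpy",
) -> DiffusionTensor:
    """Assemble the diffusion tensor for a bead model.

    "full-rpy" returns the dense 3N×3N tensor; "oa-rpy" returns the N×N
    matrix of scalar pair coefficients (self coefficients on the diagonal).
    """
    a = model.hydro_radius
    n = model.n_beads
    d_self = stokes_einstein_self(a, env)
    diff, dist = _pair_geometry(model)

    if tensor_kind == "oa-rpy":
        off = ~np.eye(n, dtype=bool)
        entries = np.full((n, n), d_self)
        entries[off] = oa_pair_coefficient(dist[off], a, env)
        return OADiffusionTensor(entries=entries)
    if tensor_kind != "full-rpy":
        raise ValueError(f"unknown tensor kind {tensor_kind!r}")

    eye3 = np.eye(3)
    blocks = np.empty((n, n, 3, 3))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = dist
        rsafe = np.where(r > 0, r, 1.0)
        rhat = diff / rsafe[..., None]
        dyad = rhat[..., :, None] * rhat[..., None, :]
        far_pref = env.kBT / (8.0 * np.pi * env.viscosity * rsafe)
        far_iso = far_pref * (1.0 + 2.0 * a * a / (3.0 * r * r + (r == 0)))
        far_ani = far_pref * (1.0 - 2.0 * a * a / (r * r + (r == 0)))
        near_pref = d_self
        near_iso = near_pref * (1.0 - 9.0 * r / (32.0 * a))
        near_ani = near_pref * (3.0 * r / (32.0 * a))
        use_far = r >= 2.0 * a
        iso = np.where(use_far, far_iso, near_iso)
        ani = np.where(use_far, far_ani, near_ani)
    blocks = iso[..., None, None] * eye3 + ani[..., None, None] * dyad
    idx = np.arange(n)
    blocks[idx, idx] = d_self * eye3
    entries = blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    return FullDiffusionTensor(entries=entries)


def expand_oa_tensor(tensor: OADiffusionTensor) -> FullDiffusionTensor:
    """Expand the N×N OA tensor to its equivalent 3N×3N form (C ⊗ I₃)."""
    n = tensor.n_beads
    out = np.kron(tensor.entries, np.eye(3))
    return FullDiffusionTensor(entries=out.reshape(3 * n, 3 * n), model_tag="oa-rpy-expanded")


def sqrt_factor(tensor: DiffusionTensor) -> SqrtFactor:
    """Lower-triangular Cholesky factor S with S·Sᵀ = D."""
    d = tensor.entries
    dmax = float(np.max(np.abs(np.diag(d))))
    try:
        fac = cholesky(d, lower=True, check_finite=False)
    except LinAlgError as err:
        raise DecompositionError(
            f"diffusion tensor is not positive definite: {err}"
        ) from err
    piv = np.diag(fac) ** 2
    if np.any(piv < 1e-12 * dmax):
        k = int(np.argmax(piv < 1e-12 * dmax))
        raise DecompositionError(
            f"diffusion tensor is numerically singular at leading minor {k + 1}"
        )
    return SqrtFactor(factor=fac, model_tag=tensor.model_tag)


def oa_divergence(model: BeadModel, env: HydroEnvironment) -> DivergenceField:
    """Analytic divergence drift of the OA tensor, per bead.

    Bead i receives Σ_{j≠i} dD_rr/dr(r_ij) · (r_j − r_i)/r_ij, which points
    away from each partner because dD_rr/dr < 0: hydrodynamic drift pushes
    bead pairs apart.  Identically zero for the full RPY tensor, so no
    counterpart function exists for that model.
    """
    n = model.n_beads
    diff, dist = _pair_geometry(model)
    drift = np.zeros((n, 3))
    if n > 1:
        off = ~np.eye(n, dtype=bool)
        deriv = np.zeros_like(dist)
        deriv[off] = oa_pair_coefficient_derivative(
            dist[off], model.hydro_radius, env
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = diff / np.where(dist > 0, dist, 1.0)[..., None]
        drift = np.einsum("ij,ijk->ik", deriv, unit)
    return DivergenceField(drift=drift, valid_for_positions=model.positions.copy())


def condition_number(tensor: DiffusionTensor) -> float:
    """λ_max / λ_min of a symmetric positive-definite diffusion tensor."""
    vals = eigvalsh(tensor.entries)
    if vals[0] <= 0:
        raise DecompositionError(
            f"diffusion tensor has non-positive eigenvalue {vals[0]:.3e}"
        )
    return float(vals[-1] / vals[0])


def count_apply_DF_multiplications(n_beads: int, tensor_kind: str) -> int:
    """Count scalar multiplications in one D·F product by loop enumeration.

    Walks the index ranges of the matrix–vector product actually performed
    by the propagator: the full tensor multiplies a 3N×3N matrix into a 3N
    vector; the OA tensor multiplies an N×N scalar matrix into each of the
    three Cartesian force components.
    """
    count = 0
    if tensor_kind == "full-rpy":
        for _row in range(3 * n_beads):
            for _col in range(3 * n_beads):
                count += 1
    elif tensor_kind == "oa-rpy":
        for _row in range(n_beads):
            for _col in range(n_beads):
                for _comp in range(3):
                    count += 1
    else:
        raise ValueError(f"unknown tensor kind {tensor_kind!r}")
    return count


def count_cholesky_multiplications(n_beads: int, tensor_kind: str) -> int:
    """Count multiplicative flops of a dense Cholesky factorization.

    Enumerates the loop structure of the standard right-looking algorithm
    on the matrix each tensor kind hands to the decomposition (3N×3N full,
    N×N OA): one division per row of each column plus one multiplication
    per trailing update entry.
    """
    if tensor_kind == "full-rpy":
        n = 3 * n_beads
    elif tensor_kind == "oa-rpy":
        n = n_beads
    else:
        raise ValueError(f"unknown tensor kind {tensor_kind!r}")
    count = 0
    for k in range(n):
        count += 1  # sqrt of the pivot
        for _i in range(k + 1, n):
            count += 1  # scale column below the pivot
        for i in range(k + 1, n):
            for _j in range(k + 1, i + 1):
                count += 1  # rank-1 trailing update
    return count


def save_tensor_txt(tensor: DiffusionTensor, path) -> None:
    """Write a tensor to a plain-text array file for debugging."""
    np.savetxt(path, tensor.entries, header=tensor.model_tag)
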