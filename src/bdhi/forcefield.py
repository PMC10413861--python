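"""Gō-type coarse-grained force field.

Energy terms (kcal/mol; lengths in Å, angles in rad):

    bonds      k_b (r − r_eq)²
    angles     k_a (θ − θ_eq)²
    dihedrals  k_d1 [1 + cos(φ − φ₁)] + k_d3 [1 + cos(3φ − φ₃)]
    native     ε [5 (σ_eq/r)¹² − 6 (σ_eq/r)¹⁰]      (12-10, minimum −ε at σ_eq)
    steric     ε_rep (σ/r)¹²                         (all other nonbonded pairs)

k_d1 and k_d3 are half-heights (peak-to-trough 2k).  Attraction is restricted
to native contacts: bead pairs whose residues have at least one interatomic
distance below 5.5 Å in the native structure.  Nonbonded terms use a cutoff
neighbor list; bonded (1-2), angle (1-3) and dihedral (1-4) pairs are
excluded from nonbonded interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hydro import BeadModel

__all__ = [
    "Topology",
    "ForceFieldParams",
    "EnergyForces",
    "bonded_energy_forces",
    "nonbonded_energy_forces",
    "build_neighbor_list",
    "derive_native_contacts",
    "total_energy_forces",
]

_TWO_PI = 2.0 * np.pi


@dataclass
class ForceFieldParams:
    k_b: float = 20.0          # kcal/mol/Å²
    k_a: float = 10.0          # kcal/mol/rad²
    k_d1: float = 0.5          # kcal/mol (half-height, 1-fold)
    k_d3: float = 0.25         # kcal/mol (half-height, 3-fold)
    eps_native: float = 1.0    # kcal/mol; 1.0 folded preset, 0.05 unfolded
    sigma_steric: float = 4.0  # Å
    steric_prefactor: float = 1.0  # kcal/mol
    cutoff: float = 35.0       # Å nonbonded cutoff
    list_update_interval: int = 100  # steps

    def __post_init__(self) -> None:
        for name in (
            "k_b", "k_a", "k_d1", "k_d3", "eps_native",
            "sigma_steric", "steric_prefactor", "cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.list_update_interval < 1:
            raise ValueError("list_update_interval must be >= 1")


@dataclass
class Topology:
    """Bonded terms, native contacts and nonbonded exclusions.

    All index arrays are 0-based.  Equilibrium values are taken from the
    native conformation by the model builders.
    """

    n_beads: int
    bonds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    bond_req: np.ndarray = field(default_factory=lambda: np.zeros(0))
    angles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    angle_eq: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dihedrals: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=np.int64))
    dihedral_phi1: np.ndarray = field(default_factory=lambda: np.zeros(0))
    dihedral_phi3: np.ndarray = field(default_factory=lambda: np.zeros(0))
    native_pairs: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    native_sigma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    # pure elastic networks (e.g. rigidity-bonded clusters) carry no
    # nonbonded terms at all
    exclude_all_nonbonded: bool = False

    def __post_init__(self) -> None:
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.angles = np.asarray(self.angles, dtype=np.int64).reshape(-1, 3)
        self.dihedrals = np.asarray(self.dihedrals, dtype=np.int64).reshape(-1, 4)
        self.native_pairs = np.asarray(self.native_pairs, dtype=np.int64).reshape(-1, 2)
        for arr_name in ("bond_req", "angle_eq", "dihedral_phi1", "dihedral_phi3", "native_sigma"):
            setattr(self, arr_name, np.asarray(getattr(self, arr_name), dtype=np.float64))
        for arr, eq, label in (
            (self.bonds, self.bond_req, "bonds"),
            (self.native_pairs, self.native_sigma, "native_pairs"),
        ):
            if len(arr) != len(eq):
                raise ValueError(f"{label}: index and equilibrium arrays differ in length")
            if np.any(eq <= 0):
                raise ValueError(f"{label}: equilibrium distances must be positive")
        if len(self.angles) != len(self.angle_eq):
            raise ValueError("angles and angle_eq differ in length")
        if len(self.dihedrals) != len(self.dihedral_phi1) or len(self.dihedrals) != len(self.dihedral_phi3):
            raise ValueError("dihedrals and phase arrays differ in length")
        for arr in (self.bonds, self.angles, self.dihedrals, self.native_pairs):
            if arr.size and (arr.min() < 0 or arr.max() >= self.n_beads):
                raise ValueError("topology indices out of range")
        excl = self.nonbonded_exclusions()
        if excl and self.native_pairs.size:
            native = {tuple(sorted(p)) for p in self.native_pairs.tolist()}
            if native & excl:
                raise ValueError("native pairs overlap bonded exclusions")

    def nonbonded_exclusions(self) -> set[tuple[int, int]]:
        """1-2, 1-3 and 1-4 pairs excluded from nonbonded terms."""
        excl: set[tuple[int, int]] = set()
        for i, j in self.bonds.tolist():
            excl.add((min(i, j), max(i, j)))
        for i, _j, k in self.angles.tolist():
            excl.add((min(i, k), max(i, k)))
        for i, _j, _k, l in self.dihedrals.tolist():
            excl.add((min(i, l), max(i, l)))
        return excl

    def exclusion_matrix(self) -> np.ndarray:
        """Boolean (N, N) matrix of pairs excluded from the steric term.

        Marks bonded exclusions, native pairs (they have their own term)
        and the diagonal.
        """
        n = self.n_beads
        if self.exclude_all_nonbonded:
            return np.ones((n, n), dtype=bool)
        mat = np.eye(n, dtype=bool)
        for i, j in self.nonbonded_exclusions():
            mat[i, j] = mat[j, i] = True
        for i, j in self.native_pairs.tolist():
            mat[i, j] = mat[j, i] = True
        return mat


@dataclass
class EnergyForces:
    total_energy: float                    # kcal/mol
    forces: np.ndarray                     # (N, 3) kcal/mol/Å
    breakdown: dict[str, float] = field(default_factory=dict)

    def __add__(self, other: "EnergyForces") -> "EnergyForces":
        merged = dict(self.breakdown)
        for key, val in other.breakdown.items():
            merged[key] = merged.get(key, 0.0) + val
        return EnergyForces(
            total_energy=self.total_energy + other.total_energy,
            forces=self.forces + other.forces,
            breakdown=merged,
        )


def _dihedral_angle_and_grads(p0, p1, p2, p3):
    """Dihedral φ and ∂φ/∂x for the four atoms (standard formulation)."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    n1sq = n1 @ n1
    n2sq = n2 @ n2
    if n1sq < 1e-18 or n2sq < 1e-18 or b2n < 1e-12:
        return None  # collinear, handled by caller
    phi = np.arctan2((np.cross(n1, n2) @ b2) / b2n, n1 @ n2)
    # gradients (e.g. Blondel & Karplus form)
    g0 = -b2n / n1sq * n1
    g3 = b2n / n2sq * n2
    s = (b1 @ b2) / (b2n * b2n)
    t = (b3 @ b2) / (b2n * b2n)
    g1 = -(1.0 + s) * g0 + t * g3
    g2 = s * g0 - (1.0 + t) * g3
    return phi, (g0, g1, g2, g3)


def bonded_energy_forces(
    model: BeadModel, topology: Topology, params: ForceFieldParams
) -> EnergyForces:
    """Harmonic bond/angle terms plus the two cosine dihedral terms."""
    pos = model.positions
    forces = np.zeros_like(pos)
    e_bond = e_angle = e_dih = 0.0

    if topology.bonds.size:
        i, j = topology.bonds[:, 0], topology.bonds[:, 1]
        dvec = pos[j] - pos[i]
        r = np.linalg.norm(dvec, axis=1)
        dr = r - topology.bond_req
        e_bond = float(params.k_b * np.sum(dr * dr))
        # dE/dr = 2 k (r - req); force on j is -dE/dr * r̂
        fmag = (2.0 * params.k_b * dr / r)[:, None] * dvec
        np.add.at(forces, i, fmag)
        np.add.at(forces, j, -fmag)

    for (i, j, k), th_eq in zip(topology.angles.tolist(), topology.angle_eq):
        rij = pos[i] - pos[j]
        rkj = pos[k] - pos[j]
        nij = np.linalg.norm(rij)
        nkj = np.linalg.norm(rkj)
        cos_t = np.clip(rij @ rkj / (nij * nkj), -1.0, 1.0)
        theta = np.arccos(cos_t)
        e_angle += params.k_a * (theta - th_eq) ** 2
        sin_t = np.sqrt(max(1.0 - cos_t * cos_t, 1e-12))  # clamp collinear
        dE_dtheta = 2.0 * params.k_a * (theta - th_eq)
        di = (cos_t * rij / nij - rkj / nkj) / (nij * sin_t)
        dk = (cos_t * rkj / nkj - rij / nij) / (nkj * sin_t)
        forces[i] -= dE_dtheta * di
        forces[k] -= dE_dtheta * dk
        forces[j] += dE_dtheta * (di + dk)

    for (i, j, k, l), p1, p3 in zip(
        topology.dihedrals.tolist(), topology.dihedral_phi1, topology.dihedral_phi3
    ):
        res = _dihedral_angle_and_grads(pos[i], pos[j], pos[k], pos[l])
        if res is None:
            continue  # degenerate geometry contributes no force
        phi, grads = res
        e_dih += params.k_d1 * (1.0 + np.cos(phi - p1))
        e_dih += params.k_d3 * (1.0 + np.cos(3.0 * phi - p3))
        dE_dphi = -params.k_d1 * np.sin(phi - p1) - 3.0 * params.k_d3 * np.sin(3.0 * phi - p3)
        for idx, g in zip((i, j, k, l), grads):
            forces[idx] -= dE_dphi * g

    total = e_bond + e_angle + float(e_dih)
    return EnergyForces(
        total_energy=total,
        forces=forces,
        breakdown={"bond": e_bond, "angle": float(e_angle), "dihedral": float(e_dih)},
    )


def build_neighbor_list(
    model: BeadModel, cutoff: float, exclusions: set[tuple[int, int]] | None = None
) -> np.ndarray:
    """All non-excluded pairs within the cutoff, as an (M, 2) index array."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = model.positions
    n = len(pos)
    diff = pos[None, :, :] - pos[:, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    ii, jj = np.triu_indices(n, k=1)
    keep = dist[ii, jj] <= cutoff
    pairs = np.stack([ii[keep], jj[keep]], axis=1)
    if exclusions:
        mask = np.array(
            [(int(i), int(j)) not in exclusions for i, j in pairs], dtype=bool
        )
        pairs = pairs[mask]
    return pairs.astype(np.int64)


def nonbonded_energy_forces(
    model: BeadModel,
    topology: Topology,
    params: ForceFieldParams,
    neighbor_list: np.ndarray,
) -> EnergyForces:
    """Native 12-10 attraction plus steric 1/r¹² repulsion.

    ``neighbor_list`` holds the candidate steric pairs (already excluding
    bonded exclusions and native pairs); native pairs are evaluated from
    the topology.  Pairs beyond the cutoff contribute zero.
    """
    pos = model.positions
    forces = np.zeros_like(pos)
    e_nat = e_st = 0.0
    cutoff = params.cutoff

    if topology.native_pairs.size:
        i, j = topology.native_pairs[:, 0], topology.native_pairs[:, 1]
        dvec = pos[j] - pos[i]
        r = np.linalg.norm(dvec, axis=1)
        if np.any(r < 1e-9):
            bad = int(np.argmin(r))
            raise FloatingPointError(
                f"native pair ({i[bad]}, {j[bad]}) at zero separation"
            )
        inside = r <= cutoff
        x = np.where(inside, topology.native_sigma / r, 0.0)
        x10 = x**10
        x12 = x10 * x * x
        e_nat = float(params.eps_native * np.sum(5.0 * x12 - 6.0 * x10))
        # dE/dr = eps (−60 x¹² + 60 x¹⁰)/r
        dE_dr = params.eps_native * 60.0 * (x10 - x12) / r
        fvec = (dE_dr / r)[:, None] * dvec  # force on i along +dvec when dE/dr>0
        np.add.at(forces, i, fvec)
        np.add.at(forces, j, -fvec)

    if len(neighbor_list):
        i, j = neighbor_list[:, 0], neighbor_list[:, 1]
        dvec = pos[j] - pos[i]
        r = np.linalg.norm(dvec, axis=1)
        if np.any(r < 1e-9):
            bad = int(np.argmin(r))
            raise FloatingPointError(
                f"nonbonded pair ({i[bad]}, {j[bad]}) at zero separation"
            )
        inside = r <= cutoff
        x = np.where(inside, params.sigma_steric / r, 0.0)
        x12 = x**12
        e_st = float(params.steric_prefactor * np.sum(x12))
        dE_dr = -12.0 * params.steric_prefactor * x12 / r
        fvec = (dE_dr / r)[:, None] * dvec
        np.add.at(forces, i, fvec)
        np.add.at(forces, j, -fvec)

    return EnergyForces(
        total_energy=e_nat + e_st,
        forces=forces,
        breakdown={"native": e_nat, "steric": e_st},
    )


def total_energy_forces(
    model: BeadModel,
    topology: Topology,
    params: ForceFieldParams,
    neighbor_list: np.ndarray | None = None,
) -> EnergyForces:
    """Convenience: bonded + nonbonded with a freshly built neighbor list."""
    if neighbor_list is None:
        excl = topology.nonbonded_exclusions()
        excl |= {tuple(sorted(p)) for p in topology.native_pairs.tolist()}
        neighbor_list = build_neighbor_list(model, params.cutoff, excl)
    return bonded_energy_forces(model, topology, params) + nonbonded_energy_forces(
        model, topology, params, neighbor_list
    )


def derive_native_contacts(
    residue_atoms: list[np.ndarray],
    bead_positions: np.ndarray,
    threshold: float = 5.5,
    min_separation: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Native contact pairs from all-atom residue coordinates.

    Residues i, j (|i − j| >= ``min_separation`` so bonded neighbours are
    not double-counted) form a contact iff any interatomic distance between
    their atoms is below ``threshold``; σ_eq is the bead–bead distance in
    the native structure.  Residues with no atoms are skipped.
    """
    pairs: list[tuple[int, int]] = []
    sigmas: list[float] = []
    n = len(residue_atoms)
    bead_positions = np.asarray(bead_positions, dtype=np.float64)
    for i in range(n):
        ai = residue_atoms[i]
        if ai is None or len(ai) == 0:
            continue
        for j in range(i + min_separation, n):
            aj = residue_atoms[j]
            if aj is None or len(aj) == 0:
                continue
            d2 = np.sum((ai[:, None, :] - aj[None, :, :]) ** 2, axis=-1)
            if np.min(d2) < threshold * threshold:
                pairs.append((i, j))
                sigmas.append(float(np.linalg.norm(bead_positions[i] - bead_positions[j])))
    return (
        np.asarray(pairs, dtype=np.int64).reshape(-1, 2),
        np.asarray(sigmas, dtype=np.float64),
    )
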