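"""Bead-model builders: residue-level models from PDB structures, K-means
very-coarse-grained models with a minimum-connectivity bond rule and radius
calibration, and fully synthetic fixture systems.

Residue-level models place one bead per residue at the Cα (proteins) or P
(RNA) atom, with default hydrodynamic radii of 5.3 Å and 5.5 Å respectively.
Bond/angle/dihedral equilibrium values are taken from the native structure;
attractive 12-10 contacts connect residue pairs with any interatomic
distance below 5.5 Å in the native structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .forcefield import Topology, derive_native_contacts
from .hydro import BeadModel, assemble_tensor, stokes_einstein_self
from .units import HydroEnvironment

logger = logging.getLogger(__name__)

__all__ = [
    "ResolutionSpec",
    "build_residue_model",
    "kmeans_coarsen",
    "add_rigidity_bonds",
    "kirkwood_dtrans",
    "calibrate_bead_radius",
    "build_vcg_model",
    "generate_fixture",
    "chain_topology_from_native",
]

PROTEIN_BEAD_RADIUS = 5.3  # Å, Cα beads
RNA_BEAD_RADIUS = 5.5      # Å, P beads
CONTACT_THRESHOLD = 5.5    # Å, all-atom native contact criterion
RIGIDITY_MIN_BONDS = 4
RIGIDITY_K = 20.0          # kcal/mol/Å²


@dataclass(frozen=True)
class ResolutionSpec:
    """Very-coarse-grained resolution: residues per bead and bead radius."""

    residues_per_bead: int
    bead_radius: float

    def __post_init__(self) -> None:
        if self.residues_per_bead < 1:
            raise ValueError("residues_per_bead must be >= 1")
        if self.bead_radius <= 0:
            raise ValueError("bead_radius must be positive")


def _dihedral_angle(p0, p1, p2, p3) -> float:
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    return float(np.arctan2(np.cross(n1, n2) @ b2 / np.linalg.norm(b2), n1 @ n2))


def _angle(p0, p1, p2) -> float:
    u, v = p0 - p1, p2 - p1
    cos_t = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
    return float(np.arccos(cos_t))


def _wrap_angle(phi: float) -> float:
    return float(np.arctan2(np.sin(phi), np.cos(phi)))


def chain_topology_from_native(
    positions: np.ndarray,
    native_pairs: np.ndarray | None = None,
    native_sigma: np.ndarray | None = None,
) -> Topology:
    """Chain bonds/angles/dihedrals with equilibrium values from ``positions``.

    Dihedral phase angles are set so the native dihedral sits at an energy
    minimum of both cosine terms: the maxima lie at φ_native + 180° (1-fold)
    and 3·φ_native + 180° (3-fold).
    """
    pos = np.asarray(positions, dtype=np.float64)
    n = len(pos)
    bonds = np.array([[i, i + 1] for i in range(n - 1)], dtype=np.int64).reshape(-1, 2)
    bond_req = np.array([np.linalg.norm(pos[i + 1] - pos[i]) for i in range(n - 1)])
    angles = np.array(
        [[i, i + 1, i + 2] for i in range(n - 2)], dtype=np.int64
    ).reshape(-1, 3)
    angle_eq = np.array([_angle(pos[i], pos[i + 1], pos[i + 2]) for i in range(n - 2)])
    dihedrals = np.array(
        [[i, i + 1, i + 2, i + 3] for i in range(n - 3)], dtype=np.int64
    ).reshape(-1, 4)
    phi_native = np.array(
        [_dihedral_angle(pos[i], pos[i + 1], pos[i + 2], pos[i + 3]) for i in range(n - 3)]
    )
    phi1 = np.array([_wrap_angle(p + np.pi) for p in phi_native])
    phi3 = np.array([_wrap_angle(3.0 * p + np.pi) for p in phi_native])
    kwargs = {}
    if native_pairs is not None:
        kwargs = {"native_pairs": native_pairs, "native_sigma": native_sigma}
    return Topology(
        n_beads=n,
        bonds=bonds, bond_req=bond_req,
        angles=angles, angle_eq=angle_eq,
        dihedrals=dihedrals, dihedral_phi1=phi1, dihedral_phi3=phi3,
        **kwargs,
    )


def _filter_contacts(topology_excl: set, pairs: np.ndarray, sigma: np.ndarray):
    keep = [
        k for k, (i, j) in enumerate(pairs.tolist())
        if (min(i, j), max(i, j)) not in topology_excl
    ]
    return pairs[keep].reshape(-1, 2), sigma[keep]


def build_residue_model(
    pdb_structure,
    molecule_kind: str = "protein",
    contact_threshold: float = CONTACT_THRESHOLD,
) -> tuple[BeadModel, Topology]:
    """One-bead-per-residue model from a PDB structure (path or gemmi object).

    Proteins: bead at each Cα, radius 5.3 Å.  RNA: bead at each P, radius
    5.5 Å.  First model, first chain; altloc A.  Residues lacking the anchor
    atom raise an error; residues lacking atoms for contact detection are
    skipped with a warning.
    """
    import gemmi

    if isinstance(pdb_structure, (str, bytes)) or hasattr(pdb_structure, "__fspath__"):
        structure = gemmi.read_structure(str(pdb_structure))
    else:
        structure = pdb_structure
    if molecule_kind not in ("protein", "rna"):
        raise ValueError(f"molecule_kind must be 'protein' or 'rna', got {molecule_kind!r}")
    anchor = "CA" if molecule_kind == "protein" else "P"
    radius = PROTEIN_BEAD_RADIUS if molecule_kind == "protein" else RNA_BEAD_RADIUS

    chain = structure[0][0]  # first model, first chain
    positions: list[np.ndarray] = []
    labels: list[str] = []
    residue_atoms: list[np.ndarray] = []
    missing: list[str] = []
    for residue in chain:
        atoms = []
        anchor_pos = None
        for atom in residue:
            if atom.altloc not in ("", "\x00", "A"):
                continue
            p = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            atoms.append(p)
            if atom.name == anchor:
                anchor_pos = p
        seqid = f"{residue.seqid.num}{residue.seqid.icode}".strip()
        if anchor_pos is None:
            missing.append(f"{residue.name}{seqid}")
            continue
        positions.append(anchor_pos)
        labels.append(f"{residue.name}{seqid}")
        if not atoms:
            warnings.warn(f"residue {residue.name}{seqid} has no atoms for contact detection")
        residue_atoms.append(np.asarray(atoms))
    if missing:
        raise ValueError(
            f"residues missing the {anchor} atom: {', '.join(missing)}"
        )
    pos = np.asarray(positions)
    model = BeadModel(positions=pos, hydro_radius=radius, labels=labels)
    topo = chain_topology_from_native(pos)
    pairs, sigma = derive_native_contacts(
        residue_atoms, pos, threshold=contact_threshold, min_separation=2
    )
    pairs, sigma = _filter_contacts(topo.nonbonded_exclusions(), pairs, sigma)
    topo = chain_topology_from_native(pos, native_pairs=pairs, native_sigma=sigma)
    return model, topo


def kmeans_coarsen(
    coords: np.ndarray, n_beads: int, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """K-means bead placement: centroids and point-to-bead assignment."""
    from sklearn.cluster import KMeans

    coords = np.asarray(coords, dtype=np.float64)
    if n_beads > len(coords):
        raise ValueError("n_beads cannot exceed the number of input points")
    km = KMeans(n_clusters=n_beads, n_init=n_init, random_state=seed)
    assignment = km.fit_predict(coords)
    return km.cluster_centers_.copy(), assignment


def add_rigidity_bonds(
    bead_positions: np.ndarray, min_bonds: int = RIGIDITY_MIN_BONDS
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy rigidity bonds: closest pairs first, until every bead has at
    least ``min_bonds`` bonds (or all pairs are exhausted for tiny systems).

    A pair is added only if at least one of its beads is still below the
    minimum.  Native distances become the harmonic r_eq values.
    """
    pos = np.asarray(bead_positions, dtype=np.float64)
    n = len(pos)
    if n < 2:
        raise ValueError("need at least 2 beads")
    ii, jj = np.triu_indices(n, k=1)
    dist = np.linalg.norm(pos[ii] - pos[jj], axis=1)
    order = np.argsort(dist, kind="stable")
    degree = np.zeros(n, dtype=np.int64)
    bonds: list[tuple[int, int]] = []
    req: list[float] = []
    for idx in order:
        if np.all(degree >= min_bonds):
            break
        i, j = int(ii[idx]), int(jj[idx])
        if degree[i] >= min_bonds and degree[j] >= min_bonds:
            continue
        bonds.append((i, j))
        req.append(float(dist[idx]))
        degree[i] += 1
        degree[j] += 1
    return (
        np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        np.asarray(req, dtype=np.float64),
    )


def kirkwood_dtrans(model: BeadModel, env: HydroEnvironment) -> float:
    """Rigid-body short-time translational diffusion estimate.

    D_trans ≈ (1/N²) Σ_ij tr(D_ij)/3 over all 3×3 blocks of the full RPY
    tensor; reduces to Stokes–Einstein for a single bead.
    """
    n = model.n_beads
    entries = assemble_tensor(model, env, "full-rpy").entries
    blocks = entries.reshape(n, 3, n, 3)
    return float(np.einsum("icjc->", blocks)) / (3.0 * n * n)


def calibrate_bead_radius(
    positions: np.ndarray,
    target_D_trans: float,
    env: HydroEnvironment | None = None,
    tolerance: float = 1e-4,
    bracket: tuple[float, float] = (0.05, 60.0),
) -> float:
    """Bisect the shared bead radius until the rigid-body Kirkwood
    short-time D_trans estimate matches ``target_D_trans``.

    D_trans decreases monotonically with the radius, so bisection on the
    bracket converges; a non-bracketing interval raises with the searched
    range.  ``tolerance`` is relative on D_trans.
    """
    if target_D_trans <= 0:
        raise ValueError("target_D_trans must be positive")
    env = env or HydroEnvironment()
    pos = np.asarray(positions, dtype=np.float64).reshape(-1, 3)

    def f(radius: float) -> float:
        return kirkwood_dtrans(BeadModel(pos, radius), env) - target_D_trans

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo < 0 or fhi > 0:
        raise ValueError(
            f"target D_trans {target_D_trans:.4g} not bracketed by radii "
            f"[{lo}, {hi}] Å (D range [{fhi + target_D_trans:.4g}, "
            f"{flo + target_D_trans:.4g}] Å²/ps)"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fmid = f(mid)
        if abs(fmid) <= tolerance * target_D_trans:
            return mid
        if fmid > 0:  # D too large -> radius too small
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_vcg_model(
    residue_positions: np.ndarray,
    residues_per_bead: int,
    env: HydroEnvironment | None = None,
    target_D_trans: float | None = None,
    bead_radius: float | None = None,
    seed: int = 0,
) -> tuple[BeadModel, Topology, ResolutionSpec]:
    """Very-coarse-grained model: K-means beads, rigidity bonds, calibrated
    radius (matched to ``target_D_trans`` unless an explicit radius is given).
    """
    env = env or HydroEnvironment()
    coords = np.asarray(residue_positions, dtype=np.float64)
    n_beads = max(2, int(np.ceil(len(coords) / residues_per_bead)))
    centers, _ = kmeans_coarsen(coords, n_beads, seed=seed)
    bonds, req = add_rigidity_bonds(centers)
    if bead_radius is None:
        if target_D_trans is None:
            raise ValueError("provide target_D_trans or bead_radius")
        bead_radius = calibrate_bead_radius(centers, target_D_trans, env)
    model = BeadModel(positions=centers, hydro_radius=bead_radius)
    topo = Topology(n_beads=n_beads, bonds=bonds, bond_req=req)
    return model, topo, ResolutionSpec(residues_per_bead, bead_radius)


def _self_avoiding_chain(
    n: int, bond_length: float, rng: np.random.Generator,
    min_separation: float, confine_radius: float | None,
) -> np.ndarray:
    """Fixed-bond-length random walk with pairwise clash rejection and an
    optional spherical confinement (used for compact, folded-like natives).
    """
    pos = np.zeros((n, 3))
    pos[1] = [bond_length, 0.0, 0.0]
    i = 2
    attempts = 0
    while i < n:
        # bond angle in a realistic CG range, dihedral uniform
        theta = np.deg2rad(rng.uniform(85.0, 150.0))
        u = pos[i - 1] - pos[i - 2]
        u /= np.linalg.norm(u)
        # random unit vector perpendicular to u
        v = rng.standard_normal(3)
        v -= (v @ u) * u
        v /= np.linalg.norm(v)
        step = bond_length * (np.cos(np.pi - theta) * u + np.sin(np.pi - theta) * v)
        cand = pos[i - 1] + step
        ok = True
        if i >= 2:
            d = np.linalg.norm(pos[: i - 1] - cand, axis=1)
            ok = bool(np.all(d >= min_separation))
        if ok and confine_radius is not None:
            center = pos[:i].mean(axis=0)
            ok = np.linalg.norm(cand - center) <= confine_radius
        attempts += 1
        if ok:
            pos[i] = cand
            i += 1
            attempts = 0
        elif attempts > 500:
            # back up one bead and retry from there
            i = max(2, i - 1)
            attempts = 0
    return pos


def _contacts_from_beads(
    pos: np.ndarray, threshold: float, excl: set
) -> tuple[np.ndarray, np.ndarray]:
    n = len(pos)
    pairs, sigma = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in excl:
                continue
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if d < threshold:
                pairs.append((i, j))
                sigma.append(d)
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2), np.asarray(sigma)


def generate_fixture(
    kind: str, seed: int = 0, **params
) -> tuple[BeadModel, Topology]:
    """Deterministic synthetic systems exercising every code path.

    kinds
    -----
    grid2d : planar square lattice (Fig-style displacement demos);
        ``nx``, ``ny`` (default 5×5), ``spacing`` (5.3 Å), ``radius`` (5.3 Å);
        no topology terms.
    chain : bead-spring chain with 3.8 Å bonds, native-structure angle and
        dihedral equilibria and weak native contacts — the unfolded-state
        setup; ``n`` (60), ``radius`` (5.3 Å), ``contact_threshold`` (8 Å).
    compact_cluster : folded-like globular chain confined at generation
        time, dense native contacts; same parameters as chain.
    rigid_cluster : ellipsoidal bead cloud held by a >=4-bonds-per-bead
        stiff harmonic network (no angles/dihedrals/contacts); ``n`` (40),
        ``radius`` (5.3 Å), ``extent`` (38 Å long-axis target),
        ``min_separation`` (4.5 Å).
    """
    rng = np.random.default_rng(seed)
    if kind == "grid2d":
        nx = int(params.get("nx", 5))
        ny = int(params.get("ny", 5))
        spacing = float(params.get("spacing", 5.3))
        radius = float(params.get("radius", 5.3))
        if nx < 1 or ny < 1 or spacing <= 0:
            raise ValueError("grid2d needs nx, ny >= 1 and spacing > 0")
        xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        pos = np.stack(
            [xs.ravel() * spacing, ys.ravel() * spacing, np.zeros(nx * ny)], axis=1
        )
        model = BeadModel(positions=pos, hydro_radius=radius)
        return model, Topology(n_beads=nx * ny)

    if kind in ("chain", "compact_cluster"):
        n = int(params.get("n", 60))
        if n < 2:
            raise ValueError("chain needs n >= 2")
        radius = float(params.get("radius", 5.3))
        bond_length = float(params.get("bond_length", 3.8))
        threshold = float(params.get("contact_threshold", 8.0))
        confine = None
        if kind == "compact_cluster":
            # globule radius scaling for a collapsed chain
            confine = float(params.get("confine_radius", 2.4 * bond_length * n ** (1 / 3) / 2))
        pos = _self_avoiding_chain(n, bond_length, rng, 0.9 * bond_length, confine)
        topo0 = chain_topology_from_native(pos)
        excl = topo0.nonbonded_exclusions()
        pairs, sigma = _contacts_from_beads(pos, threshold, excl)
        topo = chain_topology_from_native(pos, native_pairs=pairs, native_sigma=sigma)
        return BeadModel(positions=pos, hydro_radius=radius), topo

    if kind == "rigid_cluster":
        n = int(params.get("n", 40))
        if n < 2:
            raise ValueError("rigid_cluster needs n >= 2")
        radius = float(params.get("radius", 5.3))
        extent = float(params.get("extent", 38.0))
        min_sep = float(params.get("min_separation", 4.5))
        semi = np.array([0.5, 0.40, 0.31]) * extent
        pts: list[np.ndarray] = []
        while len(pts) < n:
            cand = rng.uniform(-1.0, 1.0, 3)
            if cand @ cand > 1.0:
                continue
            cand = cand * semi
            if pts and np.min(np.linalg.norm(np.asarray(pts) - cand, axis=1)) < min_sep:
                continue
            pts.append(cand)
        pos = np.asarray(pts)
        # braced elastic network: local bonds within a cutoff give generic
        # rigidity (a bare minimum-degree bond set leaves floppy hinge
        # modes), and long-range bonds to each bead's farthest partners
        # brace the soft collective bending modes. Drive it with a soft
        # spring constant (k_b ~ 1.5 kcal/mol/Å²) so the 25 fs Euler step
        # stays well below the stability limit of the stiffest OA-coupled
        # mode — see the methods note.
        bond_cutoff = float(params.get("bond_cutoff", 14.0))
        n_far = int(params.get("n_far_braces", 8))
        d = np.linalg.norm(pos[None] - pos[:, None], axis=-1)
        pair_set: set[tuple[int, int]] = set()
        for i in range(n):
            for j in range(i + 1, n):
                if d[i, j] < bond_cutoff:
                    pair_set.add((i, j))
            for j in np.argsort(d[i])[::-1][:n_far]:
                pair_set.add((min(i, int(j)), max(i, int(j))))
        bonds = np.array(sorted(pair_set), dtype=np.int64).reshape(-1, 2)
        req = d[bonds[:, 0], bonds[:, 1]]
        topo = Topology(n_beads=n, bonds=bonds, bond_req=req, exclude_all_nonbonded=True)
        return BeadModel(positions=pos, hydro_radius=radius), topo

    raise ValueError(f"unknown fixture kind {kind!r}")
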