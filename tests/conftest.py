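import numpy as np
import pytest

from bdhi.hydro import BeadModel, assemble_tensor, expand_oa_tensor, rpy_pair_block
from bdhi.units import HydroEnvironment


@pytest.fixture(scope="session")
def env() -> HydroEnvironment:
    return HydroEnvironment()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_nonoverlapping_beads(
    n: int, radius: float, rng: np.random.Generator, box: float | None = None
) -> BeadModel:
    """Random bead cluster with pair distances of at least one diameter."""
    box = box or max(4.0 * radius * n ** (1 / 3), 6 * radius)
    pts: list[np.ndarray] = []
    while len(pts) < n:
        cand = rng.uniform(0, box, 3)
        if pts and np.min(np.linalg.norm(np.asarray(pts) - cand, axis=1)) < 2.0 * radius:
            continue
        pts.append(cand)
    return BeadModel(positions=np.asarray(pts), hydro_radius=radius)


def sphere_average_block(r: float, a: float, env, n_theta: int = 24, n_phi: int = 48):
    """Quadrature average of the full RPY pair block over orientations at
    fixed distance (Gauss–Legendre in cos θ, uniform in φ)."""
    nodes, weights = np.polynomial.legendre.leggauss(n_theta)
    phis = (np.arange(n_phi) + 0.5) * 2.0 * np.pi / n_phi
    acc = np.zeros((3, 3))
    wsum = 0.0
    for ct, w in zip(nodes, weights):
        st = np.sqrt(1.0 - ct * ct)
        for phi in phis:
            u = np.array([st * np.cos(phi), st * np.sin(phi), ct])
            acc += w * rpy_pair_block(r * u, a, env)
            wsum += w
    return acc / wsum


def numeric_divergence(
    positions: np.ndarray, radius: float, env, kind: str, h: float = 1e-4
) -> np.ndarray:
    """Central finite-difference divergence (∇·D)_iα = Σ_jβ ∂D_iα,jβ/∂r_jβ
    of the 3N-expanded diffusion tensor."""
    pos = np.asarray(positions, dtype=np.float64)
    n = len(pos)

    def dense(p):
        t = assemble_tensor(BeadModel(p, radius), env, kind)
        return expand_oa_tensor(t).entries if kind == "oa-rpy" else t.entries

    out = np.zeros(3 * n)
    for j in range(n):
        for beta in range(3):
            pp = pos.copy()
            pp[j, beta] += h
            pm = pos.copy()
            pm[j, beta] -= h
            dD = (dense(pp) - dense(pm)) / (2.0 * h)
            out += dD[:, 3 * j + beta]
    return out.reshape(n, 3)
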