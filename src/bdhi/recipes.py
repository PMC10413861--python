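"""Reproducible experiment recipes tying the modules together.

Each recipe builds a system, runs the required simulations and analyses,
and returns a report dictionary with provenance (config hash, seeds,
package version).  Problem sizes are desk-scale by default and can be
overridden per call.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    block_errors,
    diffusion_report,
    mean_rgyr,
    rotational_diffusion,
    select_axis_bead_pairs,
    translational_diffusion,
)
from .builders import generate_fixture
from .engine import SimulationConfig, apply_DF, run_simulation
from .forcefield import ForceFieldParams
from .hydro import assemble_tensor
from .units import HydroEnvironment

__all__ = ["ExperimentRecipe", "run_recipe", "figure1_demo",
           "divergence_ablation", "rotation_benchmark", "RECIPES"]

FOLDED_EPS = 1.0
UNFOLDED_EPS = 0.05


@dataclass
class ExperimentRecipe:
    name: str
    seed: int = 0
    options: dict = field(default_factory=dict)

    def provenance(self) -> dict:
        payload = json.dumps(asdict(self), sort_keys=True)
        return {
            "recipe": self.name,
            "seed": self.seed,
            "options": self.options,
            "config_hash": hashlib.sha256(payload.encode()).hexdigest()[:16],
            "bdhi_version": __version__,
        }


def figure1_demo(seed: int = 0, nx: int = 5, ny: int = 5) -> dict:
    """Force-displacement pattern on a 2D bead grid, both tensor kinds.

    A unit +x force acts on the central bead only; the returned table lists
    the D·F displacement of every bead under the full and the OA tensor.
    The full tensor moves diagonal neighbours diagonally; the OA tensor
    moves every bead co-directionally with the forced bead, with magnitude
    decreasing with distance.
    """
    env = HydroEnvironment()
    model, _ = generate_fixture("grid2d", seed=seed, nx=nx, ny=ny)
    n = model.n_beads
    center = (nx // 2) * ny + ny // 2
    forces = np.zeros((n, 3))
    forces[center, 0] = 1.0
    rows = []
    disp = {}
    for kind in ("full-rpy", "oa-rpy"):
        tensor = assemble_tensor(model, env, kind)
        disp[kind] = apply_DF(tensor, forces)
    for i in range(n):
        rows.append({
            "bead": i,
            "x": model.positions[i, 0], "y": model.positions[i, 1],
            "dist_to_forced": float(
                np.linalg.norm(model.positions[i] - model.positions[center])
            ),
            "full_dx": disp["full-rpy"][i, 0], "full_dy": disp["full-rpy"][i, 1],
            "full_dz": disp["full-rpy"][i, 2],
            "oa_dx": disp["oa-rpy"][i, 0], "oa_dy": disp["oa-rpy"][i, 1],
            "oa_dz": disp["oa-rpy"][i, 2],
        })
    return {
        "table": pd.DataFrame(rows),
        "forced_bead": center,
        "provenance": ExperimentRecipe("figure1-demo", seed, {"nx": nx, "ny": ny}).provenance(),
    }


def _sim(model, topo, params, *, n_steps, kind, divergence, seed, update=100,
         save_interval=None):
    config = SimulationConfig(
        n_steps=n_steps,
        tensor_kind=kind,
        include_divergence=divergence,
        tensor_update_interval=update,
        rng_seed=seed,
        save_interval=save_interval,
    )
    return run_simulation(model, topo, params, config)


def divergence_ablation(
    seed: int = 0,
    n_residues: int = 60,
    n_steps: int = 1_000_000,
    n_replicas: int = 3,
    save_interval: int = 2000,
    tensor_update_interval: int = 100,
) -> dict:
    """Unfolded-chain R_gyr with and without the OA divergence drift.

    Runs a weak-contact (ε = 0.05 kcal/mol) chain with the full RPY tensor,
    the OA tensor with the divergence term, and the OA tensor without it.
    Omitting the drift leaves a net inward bias and the chain collapses;
    with the drift the OA chain matches the full-tensor R_gyr.
    """
    params = ForceFieldParams(eps_native=UNFOLDED_EPS)
    model, topo = generate_fixture("chain", seed=seed, n=n_residues)
    conditions = {
        "full-rpy": ("full-rpy", False),
        "oa-rpy+div": ("oa-rpy", True),
        "oa-rpy-no-div": ("oa-rpy", False),
    }
    rows = []
    for label, (kind, div) in conditions.items():
        for rep in range(n_replicas):
            traj = _sim(
                model, topo, params,
                n_steps=n_steps, kind=kind, divergence=div,
                seed=seed + 1000 * (rep + 1),
                update=tensor_update_interval, save_interval=save_interval,
            )
            mean, std, blocks = block_errors(traj, mean_rgyr, burn_in_frac=0.1)
            rows.append({
                "condition": label, "replica": rep,
                "rgyr_mean": mean, "rgyr_block_std": std,
            })
    table = pd.DataFrame(rows)
    summary = table.groupby("condition")["rgyr_mean"].agg(["mean", "std"])
    return {
        "table": table,
        "summary": summary,
        "provenance": ExperimentRecipe(
            "divergence-ablation", seed,
            {"n_residues": n_residues, "n_steps": n_steps, "n_replicas": n_replicas},
        ).provenance(),
    }


def rotation_benchmark(
    seed: int = 0,
    n_beads: int = 40,
    n_steps: int = 40_000_000,
    extent: float = 38.0,
    tensor_update_interval: int = 100,
    save_interval: int = 4000,
    fit_horizon_ns: float = 10.0,
    observation_interval_ns: float = 1.0,
) -> dict:
    """Rigid-cluster D_trans / per-axis D_rot with both tensor kinds.

    The headline comparison: the OA tensor reproduces translational
    diffusion closely while underestimating rotational diffusion by roughly
    a quarter.  Returns per-axis values, block errors and the mean percent
    rotational deficit of the OA run relative to the full run.
    """
    model, topo = generate_fixture("rigid_cluster", seed=seed, n=n_beads, extent=extent)
    # soft springs on the braced network keep the 25 fs Euler step well
    # inside the stability limit of the stiffest OA-coupled mode while the
    # cluster stays rigid (thermal internal RMSD ~0.3 Å)
    params = ForceFieldParams(k_b=1.5)
    native = model.positions.copy()
    results = {}
    for kind in ("full-rpy", "oa-rpy"):
        traj = _sim(
            model, topo, params,
            n_steps=n_steps, kind=kind, divergence=True,
            # noise streams disjoint from the fixture-seed space
            seed=(10007 * seed + (1 if kind == "full-rpy" else 2)) % 2**31,
            update=tensor_update_interval, save_interval=save_interval,
        )
        results[kind] = diffusion_report(
            traj, native_frame=native, fit_horizon_ns=fit_horizon_ns,
            observation_interval_ns=observation_interval_ns,
        )
    full, oa = results["full-rpy"], results["oa-rpy"]
    deficits = []
    for axis in range(3):
        if full.D_rot[axis] and oa.D_rot[axis]:
            deficits.append(100.0 * (1.0 - oa.D_rot[axis] / full.D_rot[axis]))
    return {
        "full": full, "oa": oa,
        "rot_deficit_pct_per_axis": deficits,
        "rot_deficit_pct": float(np.mean(deficits)) if deficits else None,
        "dtrans_ratio": oa.D_trans / full.D_trans,
        "provenance": ExperimentRecipe(
            "rotation-benchmark", seed,
            {"n_beads": n_beads, "n_steps": n_steps, "extent": extent},
        ).provenance(),
    }


RECIPES = {
    "figure1-demo": figure1_demo,
    "divergence-ablation": divergence_ablation,
    "rotation-benchmark": rotation_benchmark,
}


def run_recipe(recipe: ExperimentRecipe | str, **options) -> dict:
    """Execute a named preset recipe; options override its defaults."""
    if isinstance(recipe, ExperimentRecipe):
        name, seed, opts = recipe.name, recipe.seed, dict(recipe.options)
    else:
        name, seed, opts = recipe, options.pop("seed", 0), {}
    opts.update(options)
    if name not in RECIPES:
        raise ValueError(f"unknown recipe {name!r}; available: {sorted(RECIPES)}")
    return RECIPES[name](seed=seed, **opts)
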