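"""Plain-text (JSON) serialization of bead models and topologies.

The format is a single JSON object; arrays are nested lists.  Keys mirror
the in-memory dataclass fields, plus a ``format`` tag for sanity checking.
"""

from __future__ import annotations

import json

import numpy as np

from .forcefield import Topology
from .hydro import BeadModel

__all__ = ["save_system", "load_system"]

_FORMAT = "bdhi-system-1"


def save_system(path, model: BeadModel, topology: Topology | None = None) -> None:
    obj = {
        "format": _FORMAT,
        "positions": model.positions.tolist(),
        "hydro_radius": model.hydro_radius,
        "labels": model.labels,
    }
    if topology is not None:
        obj["topology"] = {
            "n_beads": topology.n_beads,
            "bonds": topology.bonds.tolist(),
            "bond_req": topology.bond_req.tolist(),
            "angles": topology.angles.tolist(),
            "angle_eq": topology.angle_eq.tolist(),
            "dihedrals": topology.dihedrals.tolist(),
            "dihedral_phi1": topology.dihedral_phi1.tolist(),
            "dihedral_phi3": topology.dihedral_phi3.tolist(),
            "native_pairs": topology.native_pairs.tolist(),
            "native_sigma": topology.native_sigma.tolist(),
        }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def load_system(path) -> tuple[BeadModel, Topology | None]:
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("format") != _FORMAT:
        raise ValueError(f"{path}: not a {_FORMAT} file")
    model = BeadModel(
        positions=np.asarray(obj["positions"], dtype=np.float64),
        hydro_radius=float(obj["hydro_radius"]),
        labels=obj.get("labels"),
    )
    topo = None
    if "topology" in obj:
        t = obj["topology"]
        topo = Topology(
            n_beads=int(t["n_beads"]),
            bonds=np.asarray(t["bonds"], dtype=np.int64).reshape(-1, 2),
            bond_req=np.asarray(t["bond_req"]),
            angles=np.asarray(t["angles"], dtype=np.int64).reshape(-1, 3),
            angle_eq=np.asarray(t["angle_eq"]),
            dihedrals=np.asarray(t["dihedrals"], dtype=np.int64).reshape(-1, 4),
            dihedral_phi1=np.asarray(t["dihedral_phi1"]),
            dihedral_phi3=np.asarray(t["dihedral_phi3"]),
            native_pairs=np.asarray(t["native_pairs"], dtype=np.int64).reshape(-1, 2),
            native_sigma=np.asarray(t["native_sigma"]),
        )
    return model, topo
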