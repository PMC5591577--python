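"""File round-tripping: system files (YAML mapping), XYZ coordinate
export, benchmark/stats tables, swap logs and run manifests.

The system file is a plain key-value document with the documented
schema::

    atoms:       list of {id, position [x,y,z], charge, sigma, epsilon,
                  region, mobile}
    fragments:   list of atom-id lists (rigid bodies)
    torsions:    list of {atom_ids [i,j,k,l], v1, v2, v3}
    exclusions:  list of [i, j]
    pairs14:     list of [i, j]

All quantities use the package units (Angstrom, kcal/mol, elementary
charge, degrees).
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from .forcefield import Atom, Region, TorsionTerm, ToySystem

__all__ = [
    "save_system",
    "load_system",
    "write_xyz",
    "load_config",
    "write_manifest",
]


def system_to_dict(system: ToySystem) -> dict:
    return {
        "atoms": [
            {
                "id": a.id,
                "position": [float(x) for x in system.positions[a.id]],
                "charge": float(a.charge),
                "sigma": float(a.sigma),
                "epsilon": float(a.epsilon),
                "region": Region(a.region).name,
                "mobile": bool(a.mobile),
            }
            for a in sorted(system.atoms, key=lambda a: a.id)
        ],
        "fragments": [list(map(int, f)) for f in system.rigid_fragments],
        "torsions": [
            {
                "atom_ids": list(map(int, t.atom_ids)),
                "v1": float(t.v1),
                "v2": float(t.v2),
                "v3": float(t.v3),
            }
            for t in system.torsions
        ],
        "exclusions": sorted(sorted(map(int, p)) for p in system.exclusions),
        "pairs14": sorted(sorted(map(int, p)) for p in system.pairs14),
    }


def system_from_dict(doc: dict) -> ToySystem:
    atoms = [
        Atom(
            id=int(a["id"]),
            position=tuple(float(x) for x in a["position"]),
            charge=float(a["charge"]),
            sigma=float(a["sigma"]),
            epsilon=float(a["epsilon"]),
            region=Region[a["region"]],
            mobile=bool(a.get("mobile", True)),
        )
        for a in doc["atoms"]
    ]
    torsions = [
        TorsionTerm(tuple(int(i) for i in t["atom_ids"]),
                    float(t.get("v1", 0.0)), float(t.get("v2", 0.0)),
                    float(t.get("v3", 0.0)))
        for t in doc.get("torsions", [])
    ]
    return ToySystem(
        atoms=atoms,
        rigid_fragments=[list(map(int, f)) for f in doc["fragments"]],
        torsions=torsions,
        exclusions=[tuple(p) for p in doc.get("exclusions", [])],
        pairs14=[tuple(p) for p in doc.get("pairs14", [])],
    )


def save_system(system: ToySystem, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(system_to_dict(system), fh, sort_keys=False)


def load_system(path) -> ToySystem:
    with open(path) as fh:
        return system_from_dict(yaml.safe_load(fh))


_REGION_ELEMENT = {Region.LIGAND: "C", Region.HOT_RESIDUE: "N",
                   Region.ENVIRONMENT: "O"}


def write_xyz(system: ToySystem, path, comment: str = "") -> None:
    """Standard XYZ: atom count, comment line, then ``element x y z``.
    Elements encode the region (C ligand, N hot residue, O environment)
    purely for visualisation."""
    lines = [str(system.n_atoms), comment]
    for a in sorted(system.atoms, key=lambda a: a.id):
        x, y, z = system.positions[a.id]
        lines.append(f"{_REGION_ELEMENT[Region(a.region)]} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path) -> dict:
    """Load a YAML run configuration; must be a mapping."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("config must be a YAML mapping")
    return doc


def write_manifest(outdir, command: str, config: dict, seed: int | None) -> Path:
    """Record everything needed to reproduce a run: the command, the
    full effective configuration, the seed and tool versions."""
    import restfep

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "versions": {
            "restfep": restfep.__version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = outdir / "manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def write_swap_log(result, path) -> None:
    """Tab-separated replica-exchange log: epoch, pair, acceptance."""
    lines = ["epoch\tpair\taccept_rate"]
    rates = result.swap_rates()
    for epoch, perm in enumerate(result.permutation_history):
        lines.append(f"{epoch}\t{'-'.join(map(str, perm))}\t")
    for (m, n), r in sorted(rates.items()):
        lines.append(f"total\t{m}-{n}\t{r:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory_tsv(path):
    """Read a trajectory table written by ``Trajectory.write_tsv``."""
    from .sampler import Trajectory

    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        rows = [line.strip().split("\t") for line in fh if line.strip()]
    angle_cols = [c for c in header if c.startswith("phi_")]
    torsion_ids = [int(c.split("_", 1)[1]) for c in angle_cols]
    data = np.array(rows, dtype=float)
    col = {name: i for i, name in enumerate(header)}
    return Trajectory(
        torsion_ids=torsion_ids,
        steps=data[:, col["step"]].astype(int),
        angles=data[:, [col[c] for c in angle_cols]].reshape(len(rows),
                                                             len(angle_cols)),
        e_ss=data[:, col["e_ss"]],
        e_sw=data[:, col["e_sw"]],
        e_ww=data[:, col["e_ww"]],
        accepted=data[:, col["accepted"]].astype(bool),
    )


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
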