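"""Configuration, logging and archive I/O.

Configs round-trip through YAML with field names transliterated from the
model symbols (sigma_max, t0_cap, r_np, p_np, h_np, phi_L, ...). Scalar time
series go to CSV, field snapshots to an HDF5 archive, and a JSON manifest
records the configuration echo and library versions. Meshes can be exchanged
in Gmsh MSH v2 ASCII (volume tags: 1 = NE shell, 2 = nucleoplasm).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .driver import SimulationConfig, SimulationResult
from .geometry import NanopillarArraySpec, ReferenceMesh, ShellGeometrySpec
from .mechanics import MaterialParams
from .signaling import KineticParams

__all__ = [
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "save_config",
    "write_result",
    "read_scalar_log",
    "write_msh",
    "read_msh",
]

_SUBSPECS = {
    "shell": ShellGeometrySpec,
    "pillars": NanopillarArraySpec,
    "material": MaterialParams,
    "kinetics": KineticParams,
}


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    kw = dict(d)
    for name, cls in _SUBSPECS.items():
        if name in kw and kw[name] is not None and not isinstance(kw[name], cls):
            kw[name] = cls(**kw[name])
    return SimulationConfig(**kw)


def save_config(cfg: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path) -> SimulationConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def _config_hash(cfg: SimulationConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_result(res: SimulationResult, outdir, fields: bool = True) -> dict:
    """Write CSV scalar log, JSON manifest and (optionally) an HDF5 archive."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "scalars.csv"
    res.table.to_csv(csv_path, index=False)
    manifest = {
        "config": config_to_dict(res.config),
        "config_hash": _config_hash(res.config),
        "alpha_init": res.alpha_init,
        "measures0": res.measures0,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "h5py": h5py.__version__,
        },
        "seed": res.config.seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if fields:
        with h5py.File(outdir / "fields.h5", "w") as f:
            m = res.mesh
            g = f.create_group("mesh")
            g.create_dataset("points", data=m.points)
            g.create_dataset("tets", data=m.tets)
            g.create_dataset("region", data=m.region)
            s = f.create_group("final")
            st = res.final
            s.create_dataset("u_vertices", data=st.u_vertices)
            s.create_dataset("lamin", data=st.species.lamin)
            s.create_dataset("npc", data=st.species.npc)
            s.create_dataset("npc_a", data=st.species.npc_a)
            s.create_dataset("lamin_phos", data=st.species.lamin_phos)
            s.create_dataset("yap_nuc", data=st.species.yap_nuc)
            s.attrs["t"] = st.t
            s.attrs["y_cyto"] = st.y_cyto
            s.attrs["y_free"] = st.y_free
    return manifest


def read_scalar_log(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_msh(mesh: ReferenceMesh, path) -> None:
    """Write the tetrahedral mesh in Gmsh MSH v2.2 ASCII."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes", str(len(mesh.points))]
    for i, p in enumerate(mesh.points, start=1):
        lines.append(f"{i} {p[0]:.12g} {p[1]:.12g} {p[2]:.12g}")
    lines += ["$EndNodes", "$Elements", str(len(mesh.tets))]
    for i, (tet, reg) in enumerate(zip(mesh.tets, mesh.region), start=1):
        a, b, c, d = tet + 1
        lines.append(f"{i} 4 2 {reg} {reg} {a} {b} {c} {d}")
    lines += ["$EndElements", ""]
    Path(path).write_text("\n".join(lines))


def read_msh(path):
    """Read nodes/tet elements (with physical tags) from Gmsh MSH v2 ASCII.

    Returns (points (n,3), tets (m,4) 0-based, tags (m,)).
    """
    txt = Path(path).read_text().splitlines()
    it = iter(txt)
    points, tets, tags = [], [], []
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                points.append([float(x) for x in parts[1:4]])
        elif line.strip() == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                if etype == 4:  # linear tetrahedron
                    tags.append(int(parts[3]) if ntags else 0)
                    tets.append([int(v) - 1 for v in parts[3 + ntags :]])
    return np.asarray(points), np.asarray(tets, dtype=np.int64), np.asarray(tags)
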