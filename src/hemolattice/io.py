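"""Configuration, tagged-mesh files, VTK output and the run manifest.

Config files are flat YAML; every stability threshold and heuristic is a
key with the production default, so the no-expertise contract is a default
rather than a hard-coding.  Unknown keys are an error (no silent typos).

Tagged meshes travel as an OBJ (or ASCII STL) plus a sidecar CSV mapping
face index -> tag; volume fields are written as legacy-ASCII VTK
structured-points files covering the full Cartesian grid.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import yaml

from .autotune import NU_MIN_DEFAULT, U_LIM_DEFAULT
from .boundaries import Waveform
from .engine import SimulationConfig
from .voxelize import TaggedSurfaceMesh

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "read_tagged_mesh",
    "write_tagged_mesh",
    "write_vtk_fields",
    "read_vtk_fields",
    "write_outputs",
    "manifest",
]


class ConfigError(ValueError):
    pass


_CONFIG_KEYS = {
    "cycles": 3,
    "nu": 4.0e-6,
    "rho": 1000.0,
    "u_lim": U_LIM_DEFAULT,
    "nu_min": NU_MIN_DEFAULT,
    "min_nodes": 15,
    "coarsening": 1.2,
    "dt_safety": 1.01,
    "refine_safety": 1.05,
    "max_refinements": 5,
    "monitor_every": 100,
    "wss_every": 10,
    "node_budget": 3.0e7,
    "steady_tol": 0.0,
    "ramp_time": 0.0,
    "peak_time": None,
    "waveform_csv": None,
    "waveform_period": None,
    "mean_flow_mlps": None,
    "rom_cycles": 2,
    "seed": 0,
}

def _check_bounds(vals):
    checks = [
        ("cycles", vals["cycles"] >= 1, "cycles must be >= 1"),
        ("nu", vals["nu"] > 0, "nu must be > 0"),
        ("rho", vals["rho"] > 0, "rho must be > 0"),
        ("u_lim", 0 < vals["u_lim"] < 1, "u_lim must lie in (0, 1)"),
        ("nu_min", vals["nu_min"] > 0, "nu_min must be > 0"),
        ("min_nodes", vals["min_nodes"] >= 1, "min_nodes must be >= 1"),
        ("max_refinements", vals["max_refinements"] >= 0,
         "max_refinements must be >= 0"),
        ("monitor_every", vals["monitor_every"] >= 1,
         "monitor_every must be >= 1"),
    ]
    for key, ok, msg in checks:
        if not ok:
            raise ConfigError(f"{msg} (got {key}={vals[key]})")


def load_config(path_or_dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file (or dict).

    Absent keys take the production defaults (3 cycles, u_lim 0.15,
    nu_min 1e-3, 15-node diameter rule, flat inlet, p = 0 outlets);
    unknown keys and out-of-range values raise :class:`ConfigError`.
    """
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
    unknown = set(raw) - set(_CONFIG_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    vals = {**_CONFIG_KEYS, **raw}
    _check_bounds(vals)
    waveform = None
    if vals["waveform_csv"]:
        waveform = Waveform.from_csv(
            vals["waveform_csv"], period=vals["waveform_period"]
        )
    elif vals["mean_flow_mlps"] is not None:
        from .fixtures import default_waveform_samples

        period = vals["waveform_period"] or 1.0
        t, q = default_waveform_samples(
            mean_mlps=vals["mean_flow_mlps"], period=period
        )
        waveform = Waveform(times=t, flow_mlps=q, period=period)
    try:
        return SimulationConfig(
            waveform=waveform,
            nu=vals["nu"],
            rho=vals["rho"],
            cycles=int(vals["cycles"]),
            u_lim=vals["u_lim"],
            nu_min=vals["nu_min"],
            min_nodes=int(vals["min_nodes"]),
            coarsening=vals["coarsening"],
            dt_safety=vals["dt_safety"],
            refine_safety=vals["refine_safety"],
            max_refinements=int(vals["max_refinements"]),
            monitor_every=int(vals["monitor_every"]),
            wss_every=int(vals["wss_every"]),
            node_budget=vals["node_budget"],
            steady_tol=vals["steady_tol"],
            ramp_time=vals["ramp_time"],
            peak_time=vals["peak_time"],
            rom_cycles=int(vals["rom_cycles"]),
            seed=int(vals["seed"]),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: SimulationConfig, path):
    """Round-trippable YAML snapshot of a configuration."""
    out = {
        "cycles": config.cycles,
        "nu": config.nu,
        "rho": config.rho,
        "u_lim": config.u_lim,
        "nu_min": config.nu_min,
        "min_nodes": config.min_nodes,
        "coarsening": config.coarsening,
        "dt_safety": config.dt_safety,
        "refine_safety": config.refine_safety,
        "max_refinements": config.max_refinements,
        "monitor_every": config.monitor_every,
        "wss_every": config.wss_every,
        "node_budget": config.node_budget,
        "steady_tol": config.steady_tol,
        "ramp_time": config.ramp_time,
        "peak_time": config.peak_time,
        "rom_cycles": config.rom_cycles,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# tagged meshes
# ---------------------------------------------------------------------------

def write_tagged_mesh(mesh: TaggedSurfaceMesh, path_obj, path_tags=None):
    """OBJ file plus a sidecar ``<name>.tags.csv`` (face_index, tag)."""
    path_tags = path_tags or os.path.splitext(path_obj)[0] + ".tags.csv"
    with open(path_obj, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
    with open(path_tags, "w") as fh:
        fh.write("face,tag\n")
        for i, t in enumerate(mesh.face_tags):
            fh.write(f"{i},{t}\n")


def read_tagged_mesh(path, path_tags=None) -> TaggedSurfaceMesh:
    """Read a tagged surface mesh.

    OBJ is parsed directly; STL (ASCII or binary) and other trimesh-readable
    formats go through trimesh.  Face tags come from the sidecar
    ``<name>.tags.csv`` (face_index, tag).
    """
    path_tags = path_tags or os.path.splitext(path)[0] + ".tags.csv"
    if not path.lower().endswith(".obj"):
        import trimesh

        tm = trimesh.load(path, force="mesh", process=False)
        # STL stores a triangle soup; weld duplicates (face order is kept,
        # so the sidecar tag table stays aligned)
        tm.merge_vertices()
        tags = _read_tag_table(path_tags, len(tm.faces))
        return TaggedSurfaceMesh(
            vertices=np.asarray(tm.vertices),
            faces=np.asarray(tm.faces),
            face_tags=tags,
        )
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                faces.append([int(p.split("/")[0]) - 1 for p in parts[1:4]])
    tags = _read_tag_table(path_tags, len(faces))
    return TaggedSurfaceMesh(
        vertices=np.asarray(verts),
        faces=np.asarray(faces),
        face_tags=tags,
    )


def _read_tag_table(path_tags, n_faces):
    tags = [None] * n_faces
    with open(path_tags) as fh:
        next(fh)
        for line in fh:
            i, t = line.strip().split(",")
            tags[int(i)] = t
    if any(t is None for t in tags):
        raise ValueError("tag table does not cover every face")
    return np.asarray(tags)


# ---------------------------------------------------------------------------
# VTK structured-points output
# ---------------------------------------------------------------------------

def write_vtk_fields(path, grid, node_flat, fields: dict):
    """Legacy-ASCII VTK structured points with the given point arrays.

    ``fields`` maps array name -> per-fluid-node values (scalars or
    3-vectors); solid nodes are written as zero.  All floats keep full
    double precision.
    """
    nx, ny, nz = grid.shape
    n = nx * ny * nz
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nhemolattice fields\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        o = grid.origin
        fh.write(f"ORIGIN {o[0]:.17g} {o[1]:.17g} {o[2]:.17g}\n")
        fh.write(f"SPACING {grid.dx:.17g} {grid.dx:.17g} {grid.dx:.17g}\n")
        fh.write(f"POINT_DATA {n}\n")
        # VTK structured points iterate x fastest; our flat order is
        # (i*ny + j)*nz + k, i.e. z fastest -> transpose on output
        def full(arr, ncomp):
            out = np.zeros((n, ncomp))
            out[node_flat] = arr.reshape(len(arr), ncomp)
            grid3 = out.reshape((nx, ny, nz, ncomp))
            return grid3.transpose(2, 1, 0, 3).reshape(n, ncomp)

        for name, arr in fields.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2 and arr.shape[1] == 3:
                fh.write(f"VECTORS {name} double\n")
                data = full(arr, 3)
                for row in data:
                    fh.write(f"{row[0]:.17g} {row[1]:.17g} {row[2]:.17g}\n")
            else:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                data = full(arr, 1)
                for row in data:
                    fh.write(f"{row[0]:.17g}\n")


def read_vtk_fields(path):
    """Read back files produced by :func:`write_vtk_fields`."""
    fields = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    dims = None
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        if parts[0] == "DIMENSIONS":
            dims = tuple(int(x) for x in parts[1:4])
        elif parts[0] in ("SCALARS", "VECTORS"):
            name = parts[1]
            ncomp = 1 if parts[0] == "SCALARS" else 3
            j = i + (2 if parts[0] == "SCALARS" else 1)
            n = dims[0] * dims[1] * dims[2]
            vals = np.array(
                [[float(x) for x in lines[j + k].split()] for k in range(n)]
            )
            nx, ny, nz = dims
            grid3 = vals.reshape((nz, ny, nx, ncomp)).transpose(2, 1, 0, 3)
            fields[name] = grid3.reshape(n, ncomp).squeeze()
            i = j + n - 1
        i += 1
    return dims, fields


# ---------------------------------------------------------------------------
# manifest + bundled outputs
# ---------------------------------------------------------------------------

def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def manifest(input_paths: dict, config: SimulationConfig, plan_audit: dict):
    """Reproducibility record: input hashes, config snapshot, plan audit."""
    from . import __version__

    return {
        "inputs": {k: _sha256(p) for k, p in input_paths.items()},
        "config": {
            k: getattr(config, k)
            for k in (
                "cycles", "nu", "rho", "u_lim", "nu_min", "min_nodes",
                "coarsening", "dt_safety", "refine_safety",
                "max_refinements", "monitor_every", "node_budget", "seed",
            )
        },
        "plan": plan_audit,
        "version": __version__,
    }


def write_outputs(result, outdir, input_paths: dict | None = None):
    """Write volume fields, summaries CSV and the JSON manifest."""
    os.makedirs(outdir, exist_ok=True)
    state = result.state
    for which in ("avg", "peak"):
        fld = result.fields[which]
        wss_full = np.zeros(state.n_fluid)
        wss_full[state.wall_nodes] = fld["wss"]
        write_vtk_fields(
            os.path.join(outdir, f"fields_{which}.vtk"),
            state.grid,
            state.node_flat,
            {
                "pressure": fld["p"],
                "velocity": fld["u"],
                "speed": np.linalg.norm(fld["u"], axis=1),
                "wss": wss_full,
            },
        )
    from .postprocess import summarize

    summary = summarize(result) if np.any(
        result.mesh.face_tags == "dome"
    ) else {}
    with open(os.path.join(outdir, "summaries.csv"), "w") as fh:
        cols = ["case", "plc_avg", "plc_peak", "avwss_avg", "avwss_peak"]
        fh.write(",".join(cols) + "\n")
        fh.write(
            ",".join(
                ["run"]
                + [f"{summary.get(c, float('nan')):.17g}" for c in cols[1:]]
            )
            + "\n"
        )
    man = manifest(input_paths or {}, result.config, result.audit())
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(man, fh, indent=2, default=float)
    return summary
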