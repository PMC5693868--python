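"""File output: tidy CSVs, JSON snapshots, run manifests, frame rendering."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, config_hash
from .geometry import DOMAIN_NAMES
from .observables import trajectory_observables
from .solver import Trajectory

__all__ = [
    "write_mesh_json",
    "write_trajectory",
    "write_results",
    "write_traces_csv",
    "read_traces_csv",
    "write_profiles_csv",
    "render_frames",
]

DOMAIN_COLORS = {
    # colour code of the cross-section panels: ectoderm grey, mesectoderm
    # dark orange, lateral mesoderm light orange, central mesoderm yellow
    "ectoderm": "#b0b0b0",
    "mesectoderm": "#c55a11",
    "lateral_mesoderm": "#f4b183",
    "central_mesoderm": "#ffd966",
}


def write_mesh_json(mesh, path: str | Path, positions=None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(mesh.to_json_dict(positions), fh)
    return path


def write_trajectory(traj: Trajectory, out_dir: str | Path) -> dict[str, Path]:
    """Per-time observable CSV plus JSON node-position snapshots."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    obs_path = out_dir / "observables.csv"
    trajectory_observables(traj).to_csv(obs_path, index=False)
    snap_path = out_dir / "snapshots.json"
    snaps = [
        {"t_min": s.t, "nodes": np.asarray(s.positions).tolist(),
         "yolk_area": s.yolk_area, "pressure": s.pressure}
        for s in traj.states
    ]
    with open(snap_path, "w") as fh:
        json.dump({"genotype": traj.genotype, "states": snaps}, fh)
    return {"observables": obs_path, "snapshots": snap_path}


def write_results(
    tables: dict[str, pd.DataFrame],
    config: RunConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write named tidy CSVs and a JSON run manifest (config hash, seed,
    library versions).  Empty tables produce header-only CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    import scipy

    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "genotype": config.genotype,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "config": config.model_dump(mode="json"),
    }
    mpath = out_dir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = mpath
    return paths


def write_traces_csv(traces, path: str | Path) -> Path:
    rows = []
    for tr in traces:
        for t, raw, norm in zip(tr.t_s, tr.raw, tr.normalized):
            rows.append((tr.cell_id, t, raw, norm))
    pd.DataFrame(rows, columns=["cell_id", "t_s", "raw", "normalized"]).to_csv(
        path, index=False
    )
    return Path(path)


def read_traces_csv(path: str | Path):
    from .pulse_analysis import IntensityTrace

    df = pd.read_csv(path)
    traces = []
    for cell, sub in df.groupby("cell_id"):
        sub = sub.sort_values("t_s")
        traces.append(
            IntensityTrace.from_raw(int(cell), sub["t_s"].values,
                                    sub["raw"].values)
        )
    return traces


def write_profiles_csv(
    schedule,
    path: str | Path,
    times=None,
    theta_grid=None,
) -> Path:
    """Tabulate the force profiles as tidy CSV (theta_deg, f_apical,
    f_lateral, f_basal, t_min)."""
    if theta_grid is None:
        theta_grid = np.linspace(-180.0, 180.0, 361)
    if times is None:
        times = np.arange(0.0, schedule.duration + 1e-9, 1.0)
    rows = []
    for t in times:
        fa = schedule.value("apical", theta_grid, t)
        fl = schedule.value("lateral", theta_grid, t)
        fb = schedule.value("basal", theta_grid, t)
        for th, a, l, b in zip(theta_grid, fa, fl, fb):
            rows.append((th, a, l, b, t))
    pd.DataFrame(
        rows, columns=["theta_deg", "f_apical", "f_lateral", "f_basal", "t_min"]
    ).to_csv(path, index=False)
    return Path(path)


def render_frames(
    traj: Trajectory,
    out_dir: str | Path,
    dpi: int = 100,
    prefix: str = "frame",
) -> list[Path]:
    """One PNG per output time: cells filled by domain colour inside the
    vitelline circle.  Deterministic for a given trajectory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mesh, labels = traj.mesh, traj.labels
    R = mesh.vitelline_radius
    paths = []
    for i, state in enumerate(traj.states):
        fig, ax = plt.subplots(figsize=(4, 4))
        for k in range(mesh.n_cells):
            poly = state.positions[mesh.loops[k]]
            ax.fill(poly[:, 0], poly[:, 1],
                    color=DOMAIN_COLORS[labels.labels[k]],
                    edgecolor="black", linewidth=0.3)
        th = np.linspace(0, 2 * np.pi, 256)
        ax.plot(R * np.cos(th), R * np.sin(th), color="navy", linewidth=0.6)
        ax.set_xlim(-1.05 * R, 1.05 * R)
        ax.set_ylim(-1.05 * R, 1.05 * R)
        ax.set_aspect("equal")
        ax.axis("off")
        ax.set_title(f"{traj.genotype}  t = {state.t:.0f} min")
        p = out_dir / f"{prefix}_{i:04d}.png"
        fig.savefig(p, dpi=dpi, metadata={"Software": None})
        plt.close(fig)
        paths.append(p)
    return paths
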