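"""Readouts of simulated trajectories and tracked-cell tables.

Trajectory observables follow the conventions of live-imaging analyses of
gastrulating embryos: apical constriction is the summed apical surface of the
central mesoderm normalized to its initial value; furrow invagination is the
radial drop of the ventral-most apical midpoint below the vitelline membrane,
normalized to the embryo radius; ventral lengthening is the mean apico-basal
height of central-mesoderm cells relative to the dorsal ectoderm.

Tracked-cell statistics (`constriction_stats`) operate on tidy tables of
(cell, time) rows with apical areas, aspect ratios and DV positions, whether
those come from a simulation, the synthetic generator, or measurements.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import (
    DomainLabels,
    EmbryoMesh,
    _apical_chain_points,
    cell_metrics,
    polygon_aspect_ratio,
    polyline_midpoint,
    shoelace_batch,
)
from .solver import Trajectory

__all__ = [
    "central_mesoderm_area",
    "invagination_depth",
    "ventral_lengthening",
    "time_to_depth",
    "trajectory_observables",
    "cell_track_table",
    "validate_track_table",
    "constriction_stats",
]

TRACK_COLUMNS = ("cell_id", "t_min", "area", "aspect_ratio", "dv_pos")


class ObservableError(ValueError):
    pass


def _metrics_per_state(traj: Trajectory) -> list[pd.DataFrame]:
    return [cell_metrics(traj.mesh, s.positions) for s in traj.states]


def central_mesoderm_area(
    traj: Trajectory, labels: DomainLabels | None = None
) -> pd.DataFrame:
    """Apical-surface measure of the central mesoderm over time.

    In the 2D cross-section the apical surface of a cell is its apical
    polyline length, so the series is the summed (and mean) apical width of
    central-mesoderm cells, normalized to t = 0.  (Cell cross-section areas
    are conserved by construction and carry no constriction signal.)
    """
    labels = labels or traj.labels
    cells = labels.cells("central_mesoderm")
    if cells.size == 0:
        raise ObservableError("no central_mesoderm cells in labels")
    rows = []
    for state, met in zip(traj.states, _metrics_per_state(traj)):
        w = met["apical_width"].values[cells]
        rows.append((state.t, w.sum(), w.mean()))
    df = pd.DataFrame(rows, columns=["t_min", "total", "mean"])
    df["total"] /= df["total"].iloc[0]
    df["mean"] /= df["mean"].iloc[0]
    return df


def invagination_depth(traj: Trajectory) -> pd.DataFrame:
    """Furrow depth over time: radial distance from the vitelline circle to
    the ventral-most cell's apical midpoint, normalized to the embryo radius
    (0 at t = 0, when the apical surface touches the vitelline membrane)."""
    if len(traj) == 0:
        raise ObservableError("empty trajectory")
    mesh = traj.mesh
    vent = int(np.argmin(np.abs(mesh.theta_cells)))
    R = mesh.vitelline_radius
    rows = []
    for state in traj.states:
        ap = _apical_chain_points(mesh, state.positions)
        mid = polyline_midpoint(ap[vent])
        rows.append((state.t, (R - float(np.linalg.norm(mid))) / R))
    df = pd.DataFrame(rows, columns=["t_min", "depth"])
    df["depth"] -= df["depth"].iloc[0]  # exact 0 at initial contact
    return df


def ventral_lengthening(
    traj: Trajectory,
    labels: DomainLabels | None = None,
    dorsal_window_deg: float = 30.0,
) -> pd.DataFrame:
    """Mean central-mesoderm cell height over mean dorsal-most ectoderm cell
    height, per output time (1 at t = 0 on the uniform initial ring)."""
    labels = labels or traj.labels
    ventral = labels.cells("central_mesoderm")
    dorsal = np.flatnonzero(
        (labels.labels == "ectoderm")
        & (np.abs(np.abs(labels.theta_deg) - 180.0) <= dorsal_window_deg)
    )
    if ventral.size == 0 or dorsal.size == 0:
        raise ObservableError("need both ventral and dorsal cells")
    rows = []
    for state, met in zip(traj.states, _metrics_per_state(traj)):
        h = met["height"].values
        rows.append((state.t, h[ventral].mean() / h[dorsal].mean()))
    return pd.DataFrame(rows, columns=["t_min", "ratio"])


def time_to_depth(traj: Trajectory, target: float) -> float:
    """First output time at which the furrow depth reaches ``target``;
    ``inf`` if never reached within the run."""
    df = invagination_depth(traj)
    hit = df[df["depth"] >= target]
    return float(hit["t_min"].iloc[0]) if len(hit) else float("inf")


def trajectory_observables(traj: Trajectory) -> pd.DataFrame:
    """Tidy frame of the three headline series plus yolk area and pressure."""
    area = central_mesoderm_area(traj)
    depth = invagination_depth(traj)
    length = ventral_lengthening(traj)
    a0 = traj.states[0].yolk_area
    return pd.DataFrame(
        {
            "t_min": area["t_min"],
            "central_mesoderm_area": area["total"],
            "invagination_depth": depth["depth"],
            "ventral_lengthening": length["ratio"],
            "yolk_area_rel": [s.yolk_area / a0 for s in traj.states],
            "pressure": [s.pressure for s in traj.states],
        }
    )


# ---------------------------------------------------------------------------
# Tracked-cell tables
# ---------------------------------------------------------------------------

def cell_track_table(traj: Trajectory, source: str = "simulation") -> pd.DataFrame:
    """Convert a trajectory into a tidy tracked-cell table.

    ``area`` is the apical width (the 2D apical-surface measure),
    ``aspect_ratio`` the best-fit-ellipse axis ratio of the cell polygon and
    ``dv_pos`` the cell's DV angle in degrees.
    """
    mesh = traj.mesh
    rows = []
    for state in traj.states:
        polys = mesh.cell_polygons(state.positions)
        ap = _apical_chain_points(mesh, state.positions)
        widths = np.sum(np.linalg.norm(np.diff(ap, axis=1), axis=2), axis=1)
        for k in range(mesh.n_cells):
            rows.append(
                (k, state.t, widths[k], polygon_aspect_ratio(polys[k]),
                 mesh.theta_cells[k])
            )
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df["source"] = source
    return df


def validate_track_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise ObservableError(f"track table missing columns: {missing}")
    if table.duplicated(["cell_id", "t_min"]).any():
        raise ObservableError("duplicate (cell_id, t_min) rows")
    if (table["area"] <= 0).any():
        raise ObservableError("non-positive areas in track table")
    return table


def constriction_stats(table: pd.DataFrame) -> dict:
    """Constriction statistics of a tracked-cell table.

    Returns a dict with

    ``per_time``
        frame of (t_min, mean_area, sd_area, mean_aspect, gradient) where
        ``gradient`` is the least-squares slope of the per-cell relative
        area change ``A(t)/A(t0) - 1`` against ``|dv_pos|``;
    ``mean_curve``
        (t_min, mean_area) series;
    ``anisotropy``
        (t_min, mean_aspect) series;
    ``gradient_slope``
        the final-time gradient (a collective, DV-graded constriction gives
        a larger magnitude than asynchronous constriction of the same mean).
    """
    table = validate_track_table(table)
    times = np.sort(table["t_min"].unique())
    if len(times) < 2 or table["cell_id"].nunique() < 2:
        raise ObservableError(
            "insufficient data: need >= 2 cells and >= 2 time points"
        )
    first = table[table["t_min"] == times[0]].set_index("cell_id")["area"]
    rows = []
    for t in times:
        sub = table[table["t_min"] == t]
        rel = sub["area"].values / first.reindex(sub["cell_id"]).values - 1.0
        x = np.abs(sub["dv_pos"].values)
        if np.ptp(x) > 0:
            slope = float(np.polyfit(x, rel, 1)[0])
        else:
            slope = 0.0
        rows.append(
            (t, sub["area"].mean(), sub["area"].std(ddof=0),
             sub["aspect_ratio"].mean(), slope)
        )
    per_time = pd.DataFrame(
        rows, columns=["t_min", "mean_area", "sd_area", "mean_aspect", "gradient"]
    )
    return {
        "per_time": per_time,
        "mean_curve": per_time[["t_min", "mean_area"]],
        "anisotropy": per_time[["t_min", "mean_aspect"]],
        "gradient_slope": float(per_time["gradient"].iloc[-1]),
    }
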