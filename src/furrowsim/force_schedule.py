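"""Normalized edge-force distributions per genotype.

Cortical contractility is represented as a tension acting along each membrane
edge, normalized per unit viscosity so that all forces lie in [0, 1]; the
maximum 1 is reached on apical edges of the central mesoderm in the wild type.
Three edge classes are driven:

* apical  -- a Gaussian bump of half-width ``width`` centred on the ventral
  midline over a small baseline (mirrors the medial myosin distribution);
* lateral -- a symmetric double sigmoid that plateaus over the whole central
  mesoderm and decays to ~0 in the ectoderm;
* basal   -- maximal in the ectoderm, fading smoothly towards the ventral
  midline.

Each class carries a piecewise-linear time course (keyframe list) multiplying
a fixed spatial shape normalized to unit maximum.  Genotypes are schedule
transformations, not molecules:

* ``wildtype`` -- apical ramps to 1 at the invagination time and holds;
* ``neur``     -- apical peak is lower and later than wild type and the
  lateral keyframes are delayed by a positive shift;
* ``brd``      -- the wild-type mesoderm schedule plus a linear ramp of
  ectodermal apical force reaching the concurrent mesodermal apical magnitude
  at the parity time (21 min by default), then continuing at the same slope
  capped at 1.

The published force tables are not available, so all shape parameters and
keyframe amplitudes are approximate re-parameterizations exposed in config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .geometry import DomainLabels, EmbryoMesh

__all__ = [
    "apical_profile",
    "lateral_profile",
    "basal_profile",
    "symmetrize_regularize",
    "ScheduleParams",
    "ForceProfile",
    "ForceSchedule",
    "build_schedule",
    "evaluate",
    "GENOTYPES",
]

GENOTYPES = ("wildtype", "neur", "brd")
EDGE_CLASSES = ("apical", "lateral", "basal")


class ForceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Spatial profiles (theta in degrees, ventral = 0)
# ---------------------------------------------------------------------------

def apical_profile(theta, amplitude: float, width: float, baseline: float = 0.0):
    """Gaussian bump over a baseline: ``baseline + amplitude*exp(-(theta/width)^2)``.

    The value at ``theta = width*sqrt(ln 2)`` is ``baseline + amplitude/2``.
    """
    if width <= 0:
        raise ForceError("width must be > 0")
    if amplitude + baseline > 1.0 + 1e-12:
        raise ForceError("amplitude + baseline must be <= 1 (normalized forces)")
    theta = np.asarray(theta, dtype=float)
    return baseline + amplitude * np.exp(-((theta / width) ** 2))


def lateral_profile(theta, amplitude: float, plateau_halfwidth: float,
                    steepness: float):
    """Symmetric double sigmoid: ~``amplitude`` for |theta| < plateau, ~0 dorsally."""
    if steepness <= 0 or plateau_halfwidth <= 0:
        raise ForceError("plateau_halfwidth and steepness must be > 0")
    theta = np.abs(np.asarray(theta, dtype=float))
    return amplitude / (1.0 + np.exp((theta - plateau_halfwidth) / steepness))


def basal_profile(theta, amplitude: float, fade_width: float,
                  baseline: float = 0.0):
    """Maximal in the ectoderm, fading continuously toward the ventral midline."""
    if fade_width <= 0:
        raise ForceError("fade_width must be > 0")
    theta = np.asarray(theta, dtype=float)
    rise = 1.0 - np.exp(-((theta / fade_width) ** 2))
    return baseline + (amplitude - baseline) * rise


def symmetrize_regularize(
    theta_grid: np.ndarray,
    values: np.ndarray,
    smoothing_window_deg: float = 10.0,
) -> np.ndarray:
    """Mirror-average a tabulated profile about theta = 0 and smooth it.

    The grid must cover the full circle (-180, 180] uniformly.  Output is the
    circular moving average (window ``smoothing_window_deg``) of
    ``(raw(theta) + raw(-theta)) / 2``, clipped to [0, 1].  With a zero-width
    window the operation is the pure mirror average and is idempotent.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if theta_grid.ndim != 1 or theta_grid.size < 4:
        raise ForceError("theta grid must be a 1D grid with >= 4 points")
    step = np.diff(theta_grid)
    if not np.allclose(step, step[0]):
        raise ForceError("theta grid must be uniform")
    span = theta_grid[-1] - theta_grid[0] + step[0]
    if not np.isclose(span, 360.0, atol=1e-6):
        raise ForceError("theta grid must cover the full circle (-180, 180]")

    # Mirror average: pair each grid angle with its negative (mod 360).
    idx = {round(t, 9): i for i, t in enumerate(((theta_grid + 180.0) % 360.0) - 180.0)}
    wrapped = ((theta_grid + 180.0) % 360.0) - 180.0
    mirrored = np.empty_like(values)
    for i, t in enumerate(wrapped):
        key = round(-t, 9)
        if np.isclose(abs(t), 180.0):
            key = round(t, 9)  # -180 and 180 are the same point
        j = idx.get(key)
        if j is None:
            raise ForceError("theta grid is not symmetric about 0")
        mirrored[i] = values[j]
    sym = 0.5 * (values + mirrored)

    if smoothing_window_deg > 0:
        half = int(round(smoothing_window_deg / (2 * step[0])))
        if half > 0:
            kernel = np.ones(2 * half + 1) / (2 * half + 1)
            ext = np.concatenate([sym[-half:], sym, sym[:half]])
            sym = np.convolve(ext, kernel, mode="valid")
    return np.clip(sym, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Schedule parameters and construction
# ---------------------------------------------------------------------------

class ShapeParams(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    apical_width: float = 30.0
    apical_baseline: float = 0.05
    lateral_plateau_halfwidth: float = 45.0
    lateral_steepness: float = 4.0
    basal_fade_width: float = 60.0
    basal_baseline_frac: float = 0.25
    # Brd ectodermal apical bump (centred on the dorsal midline).
    ecto_apical_width: float = 60.0


class Keyframes(BaseModel):
    """Piecewise-linear time course: (time_min, scale) pairs."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    times: tuple[float, ...]
    values: tuple[float, ...]

    @model_validator(mode="after")
    def _check(self) -> "Keyframes":
        if len(self.times) != len(self.values) or len(self.times) < 2:
            raise ValueError("keyframes need matching times/values, >= 2 points")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("keyframe times must be strictly increasing")
        if any(not (0.0 <= v <= 1.0) for v in self.values):
            raise ValueError("keyframe values must lie in [0, 1]")
        return self

    def __call__(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.values)

    def shifted(self, dt: float, duration: float) -> "Keyframes":
        times = [t + dt for t in self.times]
        values = list(self.values)
        if times[0] > 0:
            times = [0.0] + times
            values = [values[0]] + values
        keep = [i for i, t in enumerate(times) if t <= duration]
        times, values = [times[i] for i in keep], [values[i] for i in keep]
        if times[-1] < duration:
            times.append(duration)
            values.append(values[-1])
        return Keyframes(times=tuple(times), values=tuple(values))


class ScheduleParams(BaseModel):
    """Complete genotype-specific schedule parameters.

    Wild-type defaults: apical ramps from a small baseline to full magnitude
    at the invagination time (15 min) and holds; lateral rises later (8-18
    min) to drive cell shortening; basal holds a moderate ectodermal value.
    ``neur``: apical peak 60% of wild type, time-to-peak doubled, lateral
    shifted +8 min.  ``brd``: wild type plus the ectodermal apical ramp with
    parity at 21 min.  Amplitudes are approximate (no numeric table exists)
    and fully configurable.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    duration: float = 21.0
    shapes: ShapeParams = ShapeParams()
    apical: Keyframes = Keyframes(times=(0.0, 12.0, 21.0), values=(0.05, 1.0, 1.0))
    lateral: Keyframes = Keyframes(times=(0.0, 16.0, 21.0), values=(0.02, 0.05, 0.30))
    basal: Keyframes = Keyframes(times=(0.0, 15.0, 21.0), values=(0.02, 0.05, 0.12))
    # Brd-only: linear ectodermal apical ramp.
    ecto_ramp_start: float | None = None
    ecto_parity_time: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "ScheduleParams":
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.ecto_parity_time is not None:
            if not (0.0 < self.ecto_parity_time <= self.duration):
                raise ValueError("ecto_parity_time outside schedule duration")
            if self.ecto_ramp_start is None or not (
                0.0 <= self.ecto_ramp_start < self.ecto_parity_time
            ):
                raise ValueError("ecto_ramp_start must precede ecto_parity_time")
        return self


def default_params(genotype: str) -> ScheduleParams:
    if genotype == "wildtype":
        return ScheduleParams()
    if genotype == "neur":
        wt = ScheduleParams()
        duration = 45.0
        return ScheduleParams(
            duration=duration,
            # lower and later apical peak (60% of wild type, time-to-peak x2)
            apical=Keyframes(times=(0.0, 24.0, 45.0), values=(0.05, 0.60, 0.60)),
            lateral=wt.lateral.shifted(26.0, duration),
            basal=Keyframes(
                times=(0.0, 15.0, 21.0, 45.0), values=(0.02, 0.05, 0.12, 0.12)
            ),
        )
    if genotype == "brd":
        duration = 35.0
        return ScheduleParams(
            duration=duration,
            apical=Keyframes(times=(0.0, 12.0, 35.0), values=(0.05, 1.0, 1.0)),
            lateral=Keyframes(times=(0.0, 16.0, 21.0, 35.0),
                              values=(0.02, 0.05, 0.30, 0.30)),
            basal=Keyframes(
                times=(0.0, 15.0, 21.0, 35.0), values=(0.02, 0.05, 0.12, 0.12)
            ),
            ecto_ramp_start=8.0,
            ecto_parity_time=21.0,
        )
    raise ForceError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")


@dataclass(frozen=True)
class ForceProfile:
    """One edge class's spatial profile at a fixed time (values in [0, 1])."""

    edge_class: str
    theta_deg: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class ForceSchedule:
    """Evaluable force schedule for one genotype."""

    genotype: str
    params: ScheduleParams
    ecto_parity_scale: float = 0.0  # solved amplitude of the Brd ectoderm ramp

    @property
    def duration(self) -> float:
        return self.params.duration

    # -- normalized spatial shapes (unit maximum) --------------------------
    def _shape_apical(self, theta) -> np.ndarray:
        s = self.params.shapes
        peak = s.apical_baseline + (1.0 - s.apical_baseline)
        return apical_profile(
            theta, 1.0 - s.apical_baseline, s.apical_width, s.apical_baseline
        ) / peak

    def _shape_lateral(self, theta) -> np.ndarray:
        s = self.params.shapes
        top = lateral_profile(0.0, 1.0, s.lateral_plateau_halfwidth,
                              s.lateral_steepness)
        return lateral_profile(
            theta, 1.0, s.lateral_plateau_halfwidth, s.lateral_steepness
        ) / top

    def _shape_basal(self, theta) -> np.ndarray:
        s = self.params.shapes
        top = basal_profile(180.0, 1.0, s.basal_fade_width, s.basal_baseline_frac)
        return basal_profile(
            theta, 1.0, s.basal_fade_width, s.basal_baseline_frac
        ) / top

    def _shape_ecto_apical(self, theta) -> np.ndarray:
        w = self.params.shapes.ecto_apical_width
        t = np.abs(np.asarray(theta, dtype=float))
        return np.exp(-(((180.0 - t) / w) ** 2))

    def _ecto_scale(self, t) -> np.ndarray:
        p = self.params
        if p.ecto_parity_time is None:
            return np.zeros_like(np.asarray(t, dtype=float))
        slope = self.ecto_parity_scale / (p.ecto_parity_time - p.ecto_ramp_start)
        t = np.asarray(t, dtype=float)
        return np.clip(slope * (t - p.ecto_ramp_start), 0.0, 1.0)

    # -- evaluation --------------------------------------------------------
    def value(self, edge_class: str, theta, t) -> np.ndarray:
        """Force magnitude for one edge class at DV angle(s) and time(s)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-9) or np.any(t > self.duration + 1e-9):
            raise ForceError(f"time outside schedule duration [0, {self.duration}]")
        if edge_class == "apical":
            v = self.params.apical(t) * self._shape_apical(theta)
            v = v + self._ecto_scale(t) * self._shape_ecto_apical(theta)
        elif edge_class == "lateral":
            v = self.params.lateral(t) * self._shape_lateral(theta)
        elif edge_class == "basal":
            v = self.params.basal(t) * self._shape_basal(theta)
        else:
            raise ForceError(f"unknown edge class {edge_class!r}")
        return np.clip(v, 0.0, 1.0)

    def profile(self, edge_class: str, t: float,
                theta_grid: np.ndarray | None = None) -> ForceProfile:
        if theta_grid is None:
            theta_grid = np.linspace(-180.0, 180.0, 721)
        return ForceProfile(
            edge_class=edge_class,
            theta_deg=np.asarray(theta_grid, dtype=float),
            values=self.value(edge_class, theta_grid, t),
        )

    def supremum(self, n_theta: int = 721, n_time: int = 501):
        """Max over a dense (theta, t) grid of all three classes.

        Returns (value, edge_class, theta, t); the grid includes theta = 0,
        +-180 and every keyframe time.
        """
        thetas = np.linspace(-180.0, 180.0, n_theta)
        times = np.unique(np.concatenate([
            np.linspace(0.0, self.duration, n_time),
            np.asarray(self.params.apical.times),
            np.asarray(self.params.lateral.times),
            np.asarray(self.params.basal.times),
        ]))
        best = (-np.inf, None, None, None)
        for cls in EDGE_CLASSES:
            v = self.value(cls, thetas[:, None], times[None, :])
            i, j = np.unravel_index(np.argmax(v), v.shape)
            if v[i, j] > best[0]:
                best = (float(v[i, j]), cls, float(thetas[i]), float(times[j]))
        return best


def build_schedule(genotype: str,
                   params: ScheduleParams | None = None) -> ForceSchedule:
    """Construct the force schedule for a genotype.

    For ``brd`` the ectodermal ramp amplitude is solved so that the total
    apical force at the dorsal midline equals the total at the ventral
    midline exactly at the parity time.
    """
    if genotype not in GENOTYPES:
        raise ForceError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    params = params or default_params(genotype)
    sched = ForceSchedule(genotype=genotype, params=params)
    if params.ecto_parity_time is not None:
        tp = params.ecto_parity_time
        g0 = float(sched._shape_apical(0.0))
        g180 = float(sched._shape_apical(180.0))
        h0 = float(sched._shape_ecto_apical(0.0))
        h180 = float(sched._shape_ecto_apical(180.0))
        m = float(params.apical(tp))
        scale = m * (g0 - g180) / (h180 - h0)
        sched = ForceSchedule(genotype=genotype, params=params,
                              ecto_parity_scale=scale)
    return sched


def evaluate(
    schedule: ForceSchedule,
    mesh: EmbryoMesh,
    labels: DomainLabels,
    t: float,
) -> dict[str, np.ndarray]:
    """Per-edge force magnitudes at time ``t``.

    Apical and basal edges take the profile value at their cell's DV angle;
    shared lateral edges take the mean of the two adjacent cells' values.
    """
    theta = labels.theta_deg
    apical = schedule.value("apical", theta[mesh.apical_edge_cell], t)
    basal = schedule.value("basal", theta[mesh.basal_edge_cell], t)
    lat_pair = schedule.value(
        "lateral", theta[mesh.lateral_edge_cells], np.asarray(t)
    )
    lateral = lat_pair.mean(axis=1)
    return {"apical": apical, "lateral": lateral, "basal": basal}
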