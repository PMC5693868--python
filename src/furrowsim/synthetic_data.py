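"""Synthetic inputs with the statistical structure the analyses assume.

Three generators cover the pipeline end to end, each a pure function of its
spec and seed, and each returning the ground truth needed to score the
downstream stage:

* `gen_traces` -- per-cell intensity traces built from the same
  Gaussian-pulses-over-linear-background model the fitting stage assumes,
  with configurable pulse-count statistics.  The defaults emulate the
  wild-type ventral regime (mean 2.4, SD 1.2 pulses per cell across a
  ~10-minute window sampled every 12 s); an over-expression-like regime
  (mean 4.5, SD 2.2 over ~30 min) is a parameter change away.
* `gen_scene` -- a rectangular-grid label mask plus a two-channel image in
  which the myosin channel carries separately controlled junctional (3-px
  boundary band, taxicab distance) and medial intensities.
* `gen_area_table` -- tracked apical-area tables in a collective regime
  (every ventral cell constricts, rate graded in |DV position|) or an
  asynchronous regime (a random subset constricts at random onsets),
  matched in mean final constriction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy import ndimage

__all__ = [
    "TraceGenSpec",
    "SceneGenSpec",
    "AreaTableSpec",
    "gen_traces",
    "gen_scene",
    "gen_area_table",
]


class TraceGenSpec(BaseModel):
    """Trace-generator parameters (wild-type-like regime by default)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_cells: int = 79
    duration_min: float = 10.3
    interval_s: float = 12.0
    pulse_count_mean: float = 2.4
    pulse_count_sd: float = 1.2        # used by the gaussian count model
    count_model: str = "poisson"       # 'poisson' or 'gaussian'
    amplitude_range: tuple[float, float] = (0.4, 1.2)  # relative to initial
    width_range_samples: tuple[float, float] = (2.0, 4.0)  # c1, in samples
    # Pulses are sequential assembly-disassembly cycles, so centroids keep a
    # minimum spacing; proposals that cannot respect it are flagged crowded.
    min_separation_samples: float = 8.0
    background_intercept: float = 100.0  # raw A.U. scale
    background_slope_range: tuple[float, float] = (-0.1, 0.3)  # A.U./sample
    noise_sd: float = 2.0              # raw A.U.
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "TraceGenSpec":
        if self.n_cells < 1 or self.duration_min <= 0 or self.interval_s <= 0:
            raise ValueError("n_cells, duration and interval must be positive")
        if self.count_model not in ("poisson", "gaussian"):
            raise ValueError("count_model must be 'poisson' or 'gaussian'")
        if self.pulse_count_mean < 0 or self.noise_sd < 0:
            raise ValueError("scale parameters must be non-negative")
        for lo, hi in (self.amplitude_range, self.width_range_samples):
            if not (0 < lo <= hi):
                raise ValueError("ranges must be positive and ordered")
        return self


@dataclass(frozen=True)
class SyntheticTraces:
    """Generated traces plus ground truth sufficient to score the pipeline."""

    spec: TraceGenSpec
    t_s: np.ndarray
    raw: np.ndarray            # (n_cells, n_samples)
    initial_values: np.ndarray
    pulses: pd.DataFrame       # per-pulse truth: cell_id, a1, b1, c1, crowded
    counts: np.ndarray         # per-cell truth pulse counts


def gen_traces(spec: TraceGenSpec) -> SyntheticTraces:
    """Draw per-cell traces: linear background + Gaussian pulses + noise.

    Amplitudes are drawn relative to the cell's background intercept (the
    trace's nominal initial value).  Pulses whose centroid lies within two
    samples of a neighbour are flagged ``crowded`` in the ground truth
    (they may not be resolvable by minima segmentation).
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration_min * 60.0 / spec.interval_s)) + 1
    t = np.arange(n_samples) * spec.interval_s
    x = np.arange(n_samples, dtype=float)

    raw = np.empty((spec.n_cells, n_samples))
    init = np.empty(spec.n_cells)
    pulse_rows = []
    counts = np.empty(spec.n_cells, dtype=int)
    margin = max(spec.width_range_samples[1], 2.0)
    for c in range(spec.n_cells):
        if spec.count_model == "poisson":
            k = int(rng.poisson(spec.pulse_count_mean))
        else:
            k = max(0, int(round(rng.normal(spec.pulse_count_mean,
                                            spec.pulse_count_sd))))
        counts[c] = k
        b0 = spec.background_intercept
        a0 = rng.uniform(*spec.background_slope_range)
        y = a0 * x + b0
        centers = []
        for _ in range(k):
            placed = False
            for _try in range(200):
                c0 = rng.uniform(margin, n_samples - 1 - margin)
                if all(abs(c0 - c2) >= spec.min_separation_samples
                       for c2 in centers):
                    placed = True
                    break
            centers.append(c0)  # kept even if crowded; flagged below
            if not placed:
                pass
        centers = np.sort(np.asarray(centers)) if k else np.empty(0)
        crowded = np.zeros(k, dtype=bool)
        if k > 1:
            gaps = np.diff(centers)
            close = gaps < 2.0
            crowded[1:] |= close
            crowded[:-1] |= close
        for j in range(k):
            a1 = rng.uniform(*spec.amplitude_range) * b0
            c1 = rng.uniform(*spec.width_range_samples)
            y = y + a1 * np.exp(-(((x - centers[j]) / c1) ** 2))
            pulse_rows.append(
                {"cell_id": c, "a1": a1, "b1": centers[j], "c1": c1,
                 "crowded": bool(crowded[j])}
            )
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, size=n_samples)
        raw[c] = y
        init[c] = b0
    pulses = pd.DataFrame(
        pulse_rows, columns=["cell_id", "a1", "b1", "c1", "crowded"]
    )
    return SyntheticTraces(
        spec=spec, t_s=t, raw=raw, initial_values=init,
        pulses=pulses, counts=counts,
    )


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------

class SceneGenSpec(BaseModel):
    """Polygonal-cell scene with junctional and medial myosin intensities."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    rows: int = 4
    cols: int = 4
    cell_px: int = 32          # side length of each (square) cell
    membrane_px: int = 1       # background gap between cells
    band_px: int = 3           # junctional band width
    junctional: float = 300.0
    medial: float = 100.0
    membrane_signal: float = 500.0
    noise_sd: float = 0.0
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "SceneGenSpec":
        if self.cell_px < 7:
            raise ValueError(
                "cells smaller than 7x7 px cannot host a medial pool "
                "after 3 erosions"
            )
        if min(self.rows, self.cols) < 1 or self.membrane_px < 1:
            raise ValueError("grid and membrane sizes must be positive")
        if min(self.junctional, self.medial, self.membrane_signal) < 0:
            raise ValueError("intensities must be >= 0")
        return self


@dataclass(frozen=True)
class SyntheticScene:
    spec: SceneGenSpec
    mask: np.ndarray           # label image, 0 background
    membrane: np.ndarray       # channel 1
    myosin: np.ndarray         # channel 2
    truth: pd.DataFrame        # per-cell junctional/medial means (noise-free)


def gen_scene(spec: SceneGenSpec) -> SyntheticScene:
    """Render the label mask and the two channels.

    The junctional band is painted from the taxicab (city-block) distance to
    the cell boundary -- an independent construction from the erosion-based
    measurement it is used to validate.
    """
    rng = np.random.default_rng(spec.seed)
    pitch = spec.cell_px + spec.membrane_px
    H = spec.rows * pitch + spec.membrane_px
    W = spec.cols * pitch + spec.membrane_px
    mask = np.zeros((H, W), dtype=np.int32)
    k = 0
    for r in range(spec.rows):
        for c in range(spec.cols):
            k += 1
            y0 = spec.membrane_px + r * pitch
            x0 = spec.membrane_px + c * pitch
            mask[y0:y0 + spec.cell_px, x0:x0 + spec.cell_px] = k

    membrane = np.where(mask == 0, spec.membrane_signal, 0.0)
    dist = ndimage.distance_transform_cdt(mask > 0, metric="taxicab")
    junctional_band = (mask > 0) & (dist <= spec.band_px)
    medial_region = (mask > 0) & ~junctional_band
    myosin = np.zeros_like(membrane)
    myosin[junctional_band] = spec.junctional
    myosin[medial_region] = spec.medial

    rows = []
    for cell in range(1, k + 1):
        sel = mask == cell
        rows.append(
            {
                "cell_id": cell,
                "junctional_mean": float(myosin[sel & junctional_band].mean()),
                "medial_mean": float(myosin[sel & medial_region].mean())
                if (sel & medial_region).any() else 0.0,
                "total_mean": float(myosin[sel].mean()),
            }
        )
    truth = pd.DataFrame(rows)

    if spec.noise_sd > 0:
        membrane = membrane + rng.normal(0, spec.noise_sd, membrane.shape)
        myosin = myosin + rng.normal(0, spec.noise_sd, myosin.shape)
    return SyntheticScene(
        spec=spec, mask=mask, membrane=membrane, myosin=myosin, truth=truth
    )


# ---------------------------------------------------------------------------
# Tracked-area tables
# ---------------------------------------------------------------------------

class AreaTableSpec(BaseModel):
    """Constriction-pattern parameters for synthetic tracked-cell tables."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_cells: int = 40
    duration_min: float = 10.0
    dt_min: float = 1.0
    initial_area: float = 40.0
    mean_final_constriction: float = 0.4   # mean relative area loss at t_end
    fraction_constricting: float = 0.5     # asynchronous pattern only
    dv_extent_deg: float = 40.0
    noise_sd: float = 0.0
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "AreaTableSpec":
        if not (0 <= self.mean_final_constriction < 1):
            raise ValueError("mean_final_constriction must be in [0, 1)")
        if not (0 <= self.fraction_constricting <= 1):
            raise ValueError("fraction_constricting must be in [0, 1]")
        if self.n_cells < 2 or self.duration_min <= 0 or self.dt_min <= 0:
            raise ValueError("need >= 2 cells and positive durations")
        return self


def gen_area_table(
    pattern: str, spec: AreaTableSpec
) -> tuple[pd.DataFrame, dict]:
    """Tracked apical areas under a collective or asynchronous regime.

    collective
        every cell constricts from t = 0, with final relative loss graded
        linearly in |DV position| (strongest at the ventral midline), scaled
        so the cohort mean equals ``mean_final_constriction``;
    asynchronous
        a random subset (``fraction_constricting``) constricts starting at
        random onsets, rates independent of DV position, same cohort mean.

    Returns the tidy table (cell_id, t_min, area, aspect_ratio, dv_pos) and
    a ground-truth dict with the per-cell final relative loss.
    """
    if pattern not in ("collective", "asynchronous"):
        raise ValueError("pattern must be 'collective' or 'asynchronous'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    dv = np.linspace(-spec.dv_extent_deg, spec.dv_extent_deg, n)
    times = np.arange(0.0, spec.duration_min + 1e-9, spec.dt_min)
    T = times[-1]

    if pattern == "collective":
        # strongest at the ventral midline, fading out at the domain edge
        profile = 1.0 - np.abs(dv) / (1.05 * spec.dv_extent_deg)
        final_loss = profile * (spec.mean_final_constriction / profile.mean())
        onsets = np.zeros(n)
    else:
        m = max(1, int(round(spec.fraction_constricting * n)))
        chosen = rng.choice(n, size=m, replace=False)
        final_loss = np.zeros(n)
        per_cell = spec.mean_final_constriction * n / m
        final_loss[chosen] = np.minimum(per_cell, 0.9)
        onsets = np.zeros(n)
        onsets[chosen] = rng.uniform(0.0, 0.5 * T, size=m)
    final_loss = np.clip(final_loss, 0.0, 0.95)

    rows = []
    for i in range(n):
        prog = np.clip((times - onsets[i]) / max(T - onsets[i], 1e-9), 0, 1)
        area = spec.initial_area * (1.0 - final_loss[i] * prog)
        if spec.noise_sd > 0:
            area = np.maximum(
                area + rng.normal(0, spec.noise_sd, len(times)), 1e-3
            )
        rel = area / spec.initial_area
        aspect = 1.0 + (1.0 / np.maximum(rel, 1e-3) - 1.0) * 0.5
        for t, a, ar in zip(times, area, aspect):
            rows.append((i, t, a, ar, dv[i]))
    table = pd.DataFrame(
        rows, columns=["cell_id", "t_min", "area", "aspect_ratio", "dv_pos"]
    )
    table["source"] = "synthetic"
    truth = {
        "pattern": pattern,
        "final_loss": final_loss,
        "onsets": onsets,
        "dv_pos": dv,
        "mean_final_constriction": float(final_loss.mean()),
    }
    return table, truth
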