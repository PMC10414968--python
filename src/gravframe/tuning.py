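"""Tuning functions: trial averaging, boxcar smoothing, Catmull-Rom interpolation.

A tuning function is the mean firing rate over repetitions at each tested
screen orientation.  Curves are smoothed with a 3-point boxcar and read out at
arbitrary orientations with a uniform Catmull-Rom spline (an interpolating
cubic that passes through every control point), which is how values at
non-tested orientations are obtained when comparing conditions in the retinal
frame.

Both smoothing and spline evaluation are *linear* maps of the tuning values;
this module exposes the corresponding weight matrices so that permutation
tests can re-evaluate shuffled curves with a single matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import ExperimentGeometry, Frame, comparison_orientations, frame_offset


@dataclass(frozen=True)
class TuningFunction:
    """Mean response (spikes/s) versus orientation, in a named frame."""

    neuron_id: int
    condition_id: int
    frame: str  # "screen", "gravitational" or "retinal"
    orientations: np.ndarray
    values: np.ndarray
    smoothed: bool = False

    def __post_init__(self) -> None:
        ori = np.asarray(self.orientations, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if ori.ndim != 1 or ori.size < 3:
            raise ValueError("a tuning function needs >= 3 orientations")
        if val.shape != ori.shape:
            raise ValueError("orientations and values must have the same length")
        if not np.all(np.diff(ori) > 0):
            raise ValueError("orientations must be strictly increasing")
        object.__setattr__(self, "orientations", ori)
        object.__setattr__(self, "values", val)


@dataclass(frozen=True)
class ComparisonSet:
    """Paired cross-condition values at the comparison orientations of a frame."""

    frame: str
    orientations: np.ndarray
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.orientations) == len(self.values_a) == len(self.values_b)):
            raise ValueError("mismatched comparison-set lengths")
        if len(self.orientations) < 3:
            raise ValueError("a comparison set needs >= 3 pairs")
        if np.any(~np.isfinite(self.values_a)) or np.any(~np.isfinite(self.values_b)):
            raise ValueError("comparison values must be finite")


def mean_tuning(
    trials: pd.DataFrame,
    neuron_id: int,
    condition_id: int,
    expected_orientations=None,
) -> TuningFunction:
    """Average rates over repetitions at each tested screen orientation.

    If ``expected_orientations`` is given (normally the geometry grid), every
    one of those orientations must be present; a gap is reported by value.
    """
    sel = trials[(trials["neuron_id"] == neuron_id) & (trials["condition_id"] == condition_id)]
    if sel.empty:
        raise ValueError(f"no trials for neuron {neuron_id}, condition {condition_id}")
    means = sel.groupby("screen_orientation_deg")["rate_spk_s"].mean()
    ori = means.index.to_numpy(dtype=float)
    if expected_orientations is not None:
        expected = np.asarray(expected_orientations, dtype=float)
        missing = sorted(set(expected.tolist()) - set(ori.tolist()))
        if missing:
            raise ValueError(
                f"neuron {neuron_id}, condition {condition_id}: no trials at "
                f"orientation(s) {missing}"
            )
    return TuningFunction(
        neuron_id=int(neuron_id),
        condition_id=int(condition_id),
        frame="screen",
        orientations=ori,
        values=means.to_numpy(dtype=float),
        smoothed=False,
    )


def boxcar_matrix(n: int, width: int = 3, edge: str = "copy") -> np.ndarray:
    """Row-stochastic moving-average matrix over ``width`` neighboring points.

    Interior rows average the full window.  Points whose window would extend
    beyond the tested range are handled per ``edge``:

    * ``"copy"`` (default): left unsmoothed.  Averaging an endpoint with only
      its inner neighbor displaces the effective sample position by half a
      grid step, which measurably biases interpolated cross-condition
      comparisons near the curve ends; copying preserves the sample phase and
      fabricates nothing beyond the tested range.
    * ``"shrink"``: average over the neighbors that exist (the endpoint
      becomes the mean of itself and its one neighbor for width 3).
    """
    if width % 2 == 0:
        raise ValueError("boxcar width must be odd")
    if width > n:
        raise ValueError(f"boxcar width {width} exceeds curve length {n}")
    if edge not in ("copy", "shrink"):
        raise ValueError(f"unknown edge rule {edge!r}")
    half = width // 2
    m = np.zeros((n, n))
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if edge == "copy" and hi - lo < width:
            m[i, i] = 1.0
        else:
            m[i, lo:hi] = 1.0 / (hi - lo)
    return m


def boxcar_smooth(tf: TuningFunction, width: int = 3, edge: str = "copy") -> TuningFunction:
    """Boxcar-average a tuning function across neighboring orientations."""
    m = boxcar_matrix(len(tf.values), width, edge=edge)
    return replace(tf, values=m @ tf.values, smoothed=True)


def catmull_rom_weights(grid: np.ndarray, queries: np.ndarray) -> np.ndarray:
    """Weight matrix W with ``W @ values`` = Catmull-Rom spline at ``queries``.

    The grid must be uniform.  Uses the uniform (tension 1/2) Catmull-Rom
    basis; end segments use phantom control points linearly reflected about
    the endpoints (``p[-1] = 2 p[0] − p[1]``), which preserves the end slope.
    Queries that coincide with grid points (within 1e-9 of a grid index) get
    an exact unit row.  Queries outside the grid range raise.
    """
    grid = np.asarray(grid, dtype=float)
    queries = np.atleast_1d(np.asarray(queries, dtype=float))
    n = grid.size
    if n < 3:
        raise ValueError("need >= 3 control points")
    h = np.diff(grid)
    if not np.allclose(h, h[0]):
        raise ValueError("Catmull-Rom evaluation requires a uniform grid")
    h = h[0]
    u = (queries - grid[0]) / h  # fractional grid index
    if np.any(u < -1e-9) or np.any(u > n - 1 + 1e-9):
        bad = queries[(u < -1e-9) | (u > n - 1 + 1e-9)]
        raise ValueError(f"query orientation(s) {bad.tolist()} outside tested range "
                         f"[{grid[0]}, {grid[-1]}]; no extrapolation")

    w = np.zeros((queries.size, n))
    near = np.abs(u - np.round(u)) < 1e-9
    for row in np.flatnonzero(near):
        w[row, int(round(u[row]))] = 1.0
    for row in np.flatnonzero(~near):
        i = int(np.floor(u[row]))
        i = min(max(i, 0), n - 2)
        t = u[row] - i
        # uniform Catmull-Rom basis over p[i-1], p[i], p[i+1], p[i+2]
        b = 0.5 * np.array(
            [
                -t + 2 * t**2 - t**3,
                2 - 5 * t**2 + 3 * t**3,
                t + 4 * t**2 - 3 * t**3,
                -(t**2) + t**3,
            ]
        )
        idx = [i - 1, i, i + 1, i + 2]
        for j, bj in zip(idx, b):
            if j < 0:  # phantom p[-1] = 2 p[0] - p[1]
                w[row, 0] += 2 * bj
                w[row, 1] -= bj
            elif j > n - 1:  # phantom p[n] = 2 p[n-1] - p[n-2]
                w[row, n - 1] += 2 * bj
                w[row, n - 2] -= bj
            else:
                w[row, j] += bj
    return w


def spline_value(tf: TuningFunction, query_orientation) -> float | np.ndarray:
    """Catmull-Rom spline readout of a tuning function at query orientations."""
    w = catmull_rom_weights(tf.orientations, query_orientation)
    out = w @ tf.values
    return float(out[0]) if np.isscalar(query_orientation) else out


def comparison_weight_matrices(
    geom: ExperimentGeometry,
    frame: Frame,
    balanced: bool = False,
    trim_leftmost: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(comparison orientations, W_a, W_b) for reading paired values off
    screen-frame curves sampled on the geometry grid.

    ``W_a @ curve_a`` evaluates condition A's smoothed screen-frame tuning
    values at the screen coordinates corresponding to each comparison
    orientation (likewise ``W_b``); grid-aligned coordinates are read exactly.
    """
    rho = comparison_orientations(geom, frame, balanced=balanced, trim_leftmost=trim_leftmost)
    tilt_a, tilt_b = geom.condition_tilts
    q_a = rho + frame_offset(frame, tilt_a, geom)
    q_b = rho + frame_offset(frame, tilt_b, geom)
    grid = geom.grid
    return rho, catmull_rom_weights(grid, q_a), catmull_rom_weights(grid, q_b)


def comparison_pairs(
    tf_a: TuningFunction,
    tf_b: TuningFunction,
    geom: ExperimentGeometry,
    frame: Frame,
    balanced: bool = False,
    trim_leftmost: int = 0,
) -> ComparisonSet:
    """Paired values of the two conditions' curves at the frame's comparison
    orientations.

    Both inputs must be screen-frame tuning functions sampled on the geometry
    grid (condition A first in ``geom.condition_tilts`` order).  Frame
    transformation is applied to the query point, never by resampling whole
    curves; gravitational comparisons in body-tilt mode therefore reduce to
    direct table lookup.
    """
    for tf in (tf_a, tf_b):
        if tf.frame != "screen":
            raise ValueError("comparison_pairs expects screen-frame tuning functions")
        if not np.allclose(tf.orientations, geom.grid):
            raise ValueError("tuning function orientations must match the geometry grid")
    rho, w_a, w_b = comparison_weight_matrices(
        geom, frame, balanced=balanced, trim_leftmost=trim_leftmost
    )
    return ComparisonSet(
        frame=frame,
        orientations=rho,
        values_a=w_a @ tf_a.values,
        values_b=w_b @ tf_b.values,
    )
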