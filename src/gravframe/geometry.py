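"""Angular coordinate frames for orientation-tuning experiments under tilt.

An object is shown on an earth-fixed screen at a set of orientations while
either the observer's whole body is tilted about the line of sight
(``body_tilt`` mode) or the depicted ground surface / horizon is tilted on the
screen with the observer upright (``horizon_tilt`` mode).  Three frames are in
play:

* **screen** — orientation on the display, the coordinate in which stimuli are
  specified.  The screen is earth-fixed, so in ``body_tilt`` mode screen
  orientation *is* gravitational orientation.
* **retinal** — orientation on the retina.  Under a lateral body tilt the eyes
  counter-roll toward upright by a fixed number of degrees, so the retinal
  image rotates by (tilt − counter-roll) rather than the full tilt.
* **gravitational** — orientation relative to (actual or visually cued)
  gravity.  In ``horizon_tilt`` mode the gravitational coordinate is taken
  relative to the tilted ground surface drawn on the screen.

All angles are in degrees, counterclockwise positive in the subject's view.
Tested ranges never exceed 200°, so orientation is treated as a linear axis:
no wrapping is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

Frame = Literal["gravitational", "retinal"]
Mode = Literal["body_tilt", "horizon_tilt"]

#: Default tested screen orientations: −50° to +50° in 12.5° steps (9 values).
DEFAULT_GRID: tuple[float, ...] = tuple(float(x) for x in np.arange(-50.0, 50.1, 12.5))

#: Default ocular counter-roll magnitude (degrees) for a 25° body tilt.
DEFAULT_COUNTERROLL_DEG = 6.0


@dataclass(frozen=True)
class ExperimentGeometry:
    """Design of one tilt experiment.

    Parameters
    ----------
    mode
        ``"body_tilt"``: the observer is tilted, the screen stays earth-fixed.
        ``"horizon_tilt"``: the observer is upright and the depicted
        horizon/ground is tilted on the screen (visual cue conflict).
    tested_screen_orientations
        Strictly increasing, evenly spaced screen orientations (degrees) at
        which responses were measured.  At least three values.
    condition_tilts
        The two tilt angles (degrees) defining the two conditions; whole-body
        tilts in ``body_tilt`` mode, on-screen horizon tilts in
        ``horizon_tilt`` mode.
    counterroll_deg
        Non-negative magnitude of ocular counter-rolling per tilt.  Defaults
        to 6° in ``body_tilt`` mode; it is identically 0 in ``horizon_tilt``
        mode (the eyes do not move when only the picture tilts), and passing a
        nonzero value there is an error.
    """

    mode: Mode = "body_tilt"
    tested_screen_orientations: tuple[float, ...] = DEFAULT_GRID
    condition_tilts: tuple[float, float] = (-25.0, 25.0)
    counterroll_deg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("body_tilt", "horizon_tilt"):
            raise ValueError(f"unknown mode {self.mode!r}")
        grid = np.asarray(self.tested_screen_orientations, dtype=float)
        if grid.ndim != 1 or grid.size < 3:
            raise ValueError("tested_screen_orientations needs >= 3 values")
        steps = np.diff(grid)
        if not np.all(steps > 0):
            raise ValueError("tested_screen_orientations must be strictly increasing")
        if not np.allclose(steps, steps[0]):
            raise ValueError("tested_screen_orientations must be evenly spaced")
        object.__setattr__(self, "tested_screen_orientations", tuple(grid.tolist()))

        tilts = tuple(float(t) for t in self.condition_tilts)
        if len(tilts) != 2 or tilts[0] == tilts[1]:
            raise ValueError("condition_tilts must be two distinct angles")
        object.__setattr__(self, "condition_tilts", tilts)

        cr = self.counterroll_deg
        if self.mode == "horizon_tilt":
            if cr not in (None, 0, 0.0):
                raise ValueError("counterroll_deg must be 0 in horizon_tilt mode")
            cr = 0.0
        elif cr is None:
            cr = DEFAULT_COUNTERROLL_DEG
        cr = float(cr)
        if cr < 0:
            raise ValueError("counterroll_deg must be non-negative")
        min_abs_tilt = min(abs(t) for t in tilts if t != 0) if any(tilts) else 0.0
        if self.mode == "body_tilt" and cr >= min_abs_tilt:
            raise ValueError(
                f"counterroll_deg={cr} over-compensates the smallest tilt "
                f"({min_abs_tilt}°); must satisfy counterroll_deg < min |tilt|"
            )
        object.__setattr__(self, "counterroll_deg", cr)

    @property
    def grid(self) -> np.ndarray:
        return np.asarray(self.tested_screen_orientations, dtype=float)

    @property
    def grid_spacing(self) -> float:
        g = self.grid
        return float(g[1] - g[0])


def _check_tilt(tilt: float, geom: ExperimentGeometry) -> float:
    tilt = float(tilt)
    if tilt != 0.0 and tilt not in geom.condition_tilts:
        raise ValueError(f"tilt {tilt} is not one of the condition tilts {geom.condition_tilts}")
    return tilt


def eye_orientation(tilt: float, geom: ExperimentGeometry) -> float:
    """Torsional eye orientation (degrees) under a given tilt.

    In ``body_tilt`` mode the eyes counter-roll toward upright by a fixed
    ``counterroll_deg``, leaving them at ``tilt − sign(tilt)·counterroll_deg``
    (e.g. +19° for a +25° tilt with 6° counter-roll).  In ``horizon_tilt``
    mode the observer never moves, so the eyes stay at 0.
    """
    tilt = _check_tilt(tilt, geom)
    if geom.mode == "horizon_tilt" or tilt == 0.0:
        return 0.0
    if geom.counterroll_deg >= abs(tilt):
        raise ValueError("counter-roll magnitude must be smaller than |tilt|")
    return tilt - float(np.sign(tilt)) * geom.counterroll_deg


def frame_offset(frame: Frame, tilt: float, geom: ExperimentGeometry) -> float:
    """Offset ``c`` such that ``frame coordinate = screen orientation − c``.

    Every frame transformation here is a pure translation of the orientation
    axis, so it is fully described by this per-condition offset.
    """
    if frame == "retinal":
        return eye_orientation(tilt, geom)
    if frame == "gravitational":
        tilt = _check_tilt(tilt, geom)
        return tilt if geom.mode == "horizon_tilt" else 0.0
    raise ValueError(f"unknown frame {frame!r}")


def to_retinal(screen_orientation: float, tilt: float, geom: ExperimentGeometry) -> float:
    """Screen orientation → retinal orientation for one tilt condition."""
    return float(screen_orientation) - frame_offset("retinal", tilt, geom)


def to_gravitational(screen_orientation: float, tilt: float, geom: ExperimentGeometry) -> float:
    """Screen orientation → gravitational (or horizon-relative) orientation."""
    return float(screen_orientation) - frame_offset("gravitational", tilt, geom)


def comparison_orientations(
    geom: ExperimentGeometry,
    frame: Frame,
    balanced: bool = False,
    trim_leftmost: int = 0,
) -> np.ndarray:
    """Orientations (degrees, in ``frame`` coordinates) comparable across tilts.

    Candidate points are multiples of the grid spacing; a point qualifies if
    it lies within the closed tested interval of *both* conditions after
    transforming each condition's tested range into the requested frame.  For
    the default body-tilt design this yields 5 retinal comparison points
    (±25° tilts shrink the retinal overlap to [−31°, +31°]) and all 9 grid
    points gravitationally; the horizon-tilt design yields 5 gravitational
    and 9 retinal points.

    With ``balanced=True`` both frames are restricted to the grid indices
    common to the two frames' comparison sets, so that correlation analyses
    in the two frames use equal numbers of points.  ``trim_leftmost`` drops
    that many points from the low end of the result (a display convention
    sometimes used to equate counts without interpolating).

    Raises
    ------
    ValueError
        If fewer than 3 points qualify (a correlation over the comparison set
        would have no residual degrees of freedom).
    """
    ks = _comparison_indices(geom, frame)
    if balanced:
        other: Frame = "retinal" if frame == "gravitational" else "gravitational"
        ks = sorted(set(ks) & set(_comparison_indices(geom, other)))
    if trim_leftmost:
        ks = ks[int(trim_leftmost):]
    if len(ks) < 3:
        raise ValueError(
            f"only {len(ks)} comparison orientations available in the "
            f"{frame} frame; at least 3 are required"
        )
    return np.asarray(ks, dtype=float) * geom.grid_spacing


def _comparison_indices(geom: ExperimentGeometry, frame: Frame) -> list[int]:
    """Grid-spacing multiples lying inside both conditions' transformed ranges."""
    h = geom.grid_spacing
    lo = geom.grid[0]
    hi = geom.grid[-1]
    lo_common = -np.inf
    hi_common = np.inf
    for tilt in geom.condition_tilts:
        c = frame_offset(frame, tilt, geom)
        lo_common = max(lo_common, lo - c)
        hi_common = min(hi_common, hi - c)
    eps = 1e-9
    k_min = int(np.ceil(lo_common / h - eps))
    k_max = int(np.floor(hi_common / h + eps))
    return list(range(k_min, k_max + 1))
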