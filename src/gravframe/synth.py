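"""Simulated populations of orientation-tuned neurons with a known anchoring frame.

Each simulated neuron carries a smooth, single-peaked (von Mises-shaped)
orientation tuning curve anchored in the gravitational frame, the retinal
frame, or a convex mixture of the two.  The expected rate at a screen
orientation ``s`` under tilt ``T`` is

    rate(s, T) = baseline + amplitude * [ lam * g(theta_grav) + (1 - lam) * g(theta_ret) ]

with ``g(theta) = exp(kappa * (cos(theta - theta_pref) - 1))`` evaluated in
degrees-converted radians, ``theta_grav``/``theta_ret`` the stimulus
orientation in each frame, and ``lam`` in [0, 1] the gravitational anchoring
weight (1 = purely gravitational, 0 = purely retinal).  The mixture combines
*responses*, not coordinates, so intermediate ``lam`` neurons genuinely carry
both signals.

Trial-level rates add Poisson spike-count noise (counts over the response
window) or zero-clipped Gaussian rate noise.  The default design mirrors a
head-tilt experiment: two tilt conditions, 9 screen orientations spanning
100°, 5 repetitions each, 750 ms rate windows, with preferred orientations
near the center of the tested range (stimuli are chosen to drive the neuron
best near 0°).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .geometry import ExperimentGeometry, frame_offset

TRIAL_COLUMNS = (
    "neuron_id",
    "condition_id",
    "tilt_deg",
    "screen_orientation_deg",
    "repetition",
    "rate_spk_s",
)

NeuronClass = Literal["gravitational", "retinal", "mixed", "untuned"]


@dataclass(frozen=True)
class SimNeuronConfig:
    """Generative parameters of one simulated neuron.

    ``theta_pref`` is expressed in the neuron's anchoring frame; ``kappa`` is
    the von Mises concentration (0 = flat/untuned); ``amplitude`` and
    ``baseline`` are in spikes/s; ``sigma`` (spikes/s) applies only to the
    Gaussian noise model.
    """

    theta_pref: float = 0.0
    kappa: float = 4.0
    amplitude: float = 40.0
    baseline: float = 5.0
    frame_weight_lambda: float = 1.0
    noise_model: Literal["poisson", "gaussian"] = "poisson"
    sigma: float = 0.0
    window_ms: float = 750.0
    n_repetitions: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.frame_weight_lambda <= 1.0:
            raise ValueError("frame_weight_lambda must be in [0, 1]")
        for name in ("kappa", "amplitude", "baseline", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        if self.noise_model not in ("poisson", "gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


def _von_mises_shape(theta_deg: np.ndarray, theta_pref: float, kappa: float) -> np.ndarray:
    d = np.deg2rad(np.asarray(theta_deg, dtype=float) - theta_pref)
    return np.exp(kappa * (np.cos(d) - 1.0))


def tuning_value(
    config: SimNeuronConfig,
    screen_orientation,
    tilt: float,
    geom: ExperimentGeometry,
):
    """Expected firing rate (spikes/s) at a screen orientation under one tilt.

    Vectorized over ``screen_orientation``.
    """
    s = np.asarray(screen_orientation, dtype=float)
    theta_grav = s - frame_offset("gravitational", tilt, geom)
    theta_ret = s - frame_offset("retinal", tilt, geom)
    lam = config.frame_weight_lambda
    shape = lam * _von_mises_shape(theta_grav, config.theta_pref, config.kappa)
    shape = shape + (1.0 - lam) * _von_mises_shape(theta_ret, config.theta_pref, config.kappa)
    out = config.baseline + config.amplitude * shape
    return out if out.ndim else float(out)


def simulate_neuron(
    config: SimNeuronConfig,
    geom: ExperimentGeometry,
    rng: np.random.Generator,
    neuron_id: int = 0,
) -> pd.DataFrame:
    """Trial table for one neuron: one row per (condition, orientation, repetition).

    Poisson noise draws a spike count with mean ``rate * window`` and converts
    back to spikes/s; Gaussian noise adds N(0, sigma) to the rate and clips at
    zero.
    """
    grid = geom.grid
    frames = []
    for cond_id, tilt in enumerate(geom.condition_tilts, start=1):
        mean_rate = np.asarray(tuning_value(config, grid, tilt, geom), dtype=float)
        for rep in range(1, config.n_repetitions + 1):
            if config.noise_model == "poisson":
                window_s = config.window_ms / 1000.0
                counts = rng.poisson(mean_rate * window_s)
                rates = counts / window_s
            else:
                rates = np.clip(mean_rate + rng.normal(0.0, config.sigma, size=grid.size), 0.0, None)
            frames.append(
                pd.DataFrame(
                    {
                        "neuron_id": neuron_id,
                        "condition_id": cond_id,
                        "tilt_deg": tilt,
                        "screen_orientation_deg": grid,
                        "repetition": rep,
                        "rate_spk_s": rates,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[list(TRIAL_COLUMNS)]


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling recipe for a population of simulated neurons.

    ``proportions`` give the class mix over gravitational (lam = 1), retinal
    (lam = 0), mixed (lam drawn from ``lambda_mixed_range``) and untuned
    (kappa = 0) neurons.  Parameter ranges are uniform sampling bounds.
    Preferred orientations default to ±20° around the center of the tested
    range, reflecting a design in which the probe stimulus is pre-selected to
    drive the neuron near the central orientation.
    """

    n_neurons: int = 200
    proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "gravitational": 0.35,
            "retinal": 0.15,
            "mixed": 0.35,
            "untuned": 0.15,
        }
    )
    theta_pref_range: tuple[float, float] = (-20.0, 20.0)
    kappa_range: tuple[float, float] = (2.0, 6.0)
    amplitude_range: tuple[float, float] = (20.0, 60.0)
    baseline_range: tuple[float, float] = (2.0, 10.0)
    lambda_mixed_range: tuple[float, float] = (0.3, 0.7)
    noise_model: Literal["poisson", "gaussian"] = "poisson"
    sigma_range: tuple[float, float] = (2.0, 6.0)
    window_ms: float = 750.0
    n_repetitions: int = 5

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        props = dict(self.proportions)
        unknown = set(props) - {"gravitational", "retinal", "mixed", "untuned"}
        if unknown:
            raise ValueError(f"unknown neuron classes: {sorted(unknown)}")
        vals = np.array([props.get(k, 0.0) for k in ("gravitational", "retinal", "mixed", "untuned")])
        if np.any(vals < 0) or not np.isclose(vals.sum(), 1.0):
            raise ValueError("class proportions must be >= 0 and sum to 1")
        for name in ("theta_pref_range", "kappa_range", "amplitude_range",
                     "baseline_range", "lambda_mixed_range", "sigma_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")


_CLASS_ORDER = ("gravitational", "retinal", "mixed", "untuned")


def sample_neuron_config(
    spec: PopulationSpec, neuron_class: NeuronClass, rng: np.random.Generator
) -> SimNeuronConfig:
    """Draw one neuron's generative parameters for the given class."""
    lam = {"gravitational": 1.0, "retinal": 0.0}.get(neuron_class)
    if lam is None:
        lam = float(rng.uniform(*spec.lambda_mixed_range)) if neuron_class == "mixed" else 0.5
    kappa = 0.0 if neuron_class == "untuned" else float(rng.uniform(*spec.kappa_range))
    return SimNeuronConfig(
        theta_pref=float(rng.uniform(*spec.theta_pref_range)),
        kappa=kappa,
        amplitude=float(rng.uniform(*spec.amplitude_range)),
        baseline=float(rng.uniform(*spec.baseline_range)),
        frame_weight_lambda=lam,
        noise_model=spec.noise_model,
        sigma=float(rng.uniform(*spec.sigma_range)),
        window_ms=spec.window_ms,
        n_repetitions=spec.n_repetitions,
    )


def simulate_population(
    spec: PopulationSpec,
    geom: ExperimentGeometry,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[int, dict]]:
    """Simulate a full population.

    Returns the concatenated trial table and a ground-truth record per neuron
    (``{neuron_id: {"class": ..., "config": SimNeuronConfig}}``) for
    parameter-recovery tests.  Output is deterministic for a fixed generator
    state.
    """
    probs = np.array([dict(spec.proportions).get(k, 0.0) for k in _CLASS_ORDER])
    classes = rng.choice(len(_CLASS_ORDER), size=spec.n_neurons, p=probs)
    tables = []
    truth: dict[int, dict] = {}
    for nid, ci in enumerate(classes):
        ncls = _CLASS_ORDER[int(ci)]
        cfg = sample_neuron_config(spec, ncls, rng)
        tables.append(simulate_neuron(cfg, geom, rng, neuron_id=nid))
        truth[nid] = {"class": ncls, "config": cfg}
    return pd.concat(tables, ignore_index=True), truth
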