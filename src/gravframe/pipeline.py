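"""End-to-end orchestration: simulate → tuning → classification → decoding.

A run is a pure function of its configuration and master seed.  The master
seed spawns named child streams (simulation, permutation, decoding, sweep) so
that each stage can be re-run independently yet reproducibly.  Every exclusion
(undefined correlation, skipped sub-analysis) is counted in the run log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .geometry import DEFAULT_GRID, ExperimentGeometry
from .io import read_trials, write_trials
from .synth import PopulationSpec, simulate_population
from .refframe import (
    analyze_neurons,
    iter_condition_tunings,
    population_com_test,
    results_to_frame,
    summarize_population,
)
from .decoding import assemble_samples, enumerate_pairs, lda_cv_accuracy

log = logging.getLogger("gravframe")

_STREAMS = ("simulation", "permutation", "decoding", "sweep")


class GeometryConfig(BaseModel):
    mode: Literal["body_tilt", "horizon_tilt"] = "body_tilt"
    tested_screen_orientations: list[float] = Field(default_factory=lambda: list(DEFAULT_GRID))
    condition_tilts: tuple[float, float] = (-25.0, 25.0)
    counterroll_deg: Optional[float] = None

    def build(self) -> ExperimentGeometry:
        return ExperimentGeometry(
            mode=self.mode,
            tested_screen_orientations=tuple(self.tested_screen_orientations),
            condition_tilts=self.condition_tilts,
            counterroll_deg=self.counterroll_deg,
        )


class SimulationConfig(BaseModel):
    n_neurons: int = 200
    proportions: dict[str, float] = Field(
        default_factory=lambda: {"gravitational": 0.35, "retinal": 0.15, "mixed": 0.35, "untuned": 0.15}
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

    def build(self) -> PopulationSpec:
        return PopulationSpec(**self.model_dump())


class AnalysisConfig(BaseModel):
    smoothing_width: int = 3
    alpha: float = 0.05
    n_perm: int = 10_000
    balanced: bool = False


class DecodingConfig(BaseModel):
    nonmatch_threshold: float = 25.0
    folds: int = 10
    n_draws_per_pair: int = 20
    n_nonmatch: int = 20
    shrinkage: float = 0.1
    feature_mode: Literal["abs_diff", "signed_diff", "concat"] = "abs_diff"
    min_neither_neurons: int = 5


class RunConfig(BaseModel):
    """Validated configuration of a full analysis run."""

    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    simulation: Optional[SimulationConfig] = None
    input_csv: Optional[str] = None
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    decoding: DecodingConfig = Field(default_factory=DecodingConfig)
    seed: int = 0
    output_dir: str = "gravframe_out"

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "RunConfig":
        if (self.simulation is None) == (self.input_csv is None):
            raise ValueError("exactly one of 'simulation' or 'input_csv' must be given")
        return self

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Named, reproducible child generator of the master seed."""
    idx = _STREAMS.index(stream)
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(len(_STREAMS))[idx])


def load_or_simulate(config: RunConfig) -> tuple[pd.DataFrame, Optional[dict]]:
    geom = config.geometry.build()
    if config.input_csv is not None:
        return read_trials(config.input_csv), None
    trials, truth = simulate_population(
        config.simulation.build(), geom, child_rng(config.seed, "simulation")
    )
    return trials, truth


def run_reference_frame_analysis(config: RunConfig) -> dict:
    """Per-neuron classification plus population-level center-of-mass tests.

    Writes ``per_neuron.csv``, ``population.json`` and (for simulated data)
    ``trials.csv`` + ``ground_truth.json`` into ``config.output_dir``; returns
    the artifact bundle as a dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = config.geometry.build()
    trials, truth = load_or_simulate(config)
    ana = config.analysis

    rng = child_rng(config.seed, "permutation")
    results = analyze_neurons(
        trials, geom, alpha=ana.alpha, n_perm=ana.n_perm,
        smooth_width=ana.smoothing_width, balanced=ana.balanced, rng=rng,
    )
    summary = summarize_population(results)
    pairs = [(a, b) for _, a, b in iter_condition_tunings(trials, geom)]
    for frame, com_attr, p_attr in (
        ("gravitational", "com_grav", "p_com_grav"),
        ("retinal", "com_ret", "p_com_ret"),
    ):
        com, p = population_com_test(
            pairs, geom, frame, n_perm=ana.n_perm, rng=rng,
            smooth_width=ana.smoothing_width, balanced=ana.balanced,
        )
        setattr(summary, com_attr, com)
        setattr(summary, p_attr, p)
    summary.n_perm = ana.n_perm

    per_neuron = results_to_frame(results)
    per_neuron.to_csv(out / "per_neuron.csv", index=False)
    pop = {
        "version": __version__,
        "seed": config.seed,
        "n_total": summary.n_total,
        "counts": summary.counts,
        "n_significant": summary.n_significant,
        "n_excluded": summary.n_excluded,
        "proportions": summary.proportions,
        "com_grav": summary.com_grav,
        "p_com_grav": summary.p_com_grav,
        "com_ret": summary.com_ret,
        "p_com_ret": summary.p_com_ret,
        "n_perm": summary.n_perm,
        "alpha": ana.alpha,
        "balanced": ana.balanced,
    }
    with open(out / "population.json", "w") as fh:
        json.dump(pop, fh, indent=2)
    if truth is not None:
        write_trials(trials, out / "trials.csv")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(
                {str(nid): {"class": rec["class"], "parameters": vars(rec["config"])}
                 for nid, rec in truth.items()},
                fh, indent=2,
            )
    log.info(
        "analyzed %d neurons (seed %d): %d significant, %d excluded; "
        "com_grav=%.3f (p=%.2g), com_ret=%.3f (p=%.2g)",
        summary.n_total, config.seed, summary.n_significant, summary.n_excluded,
        summary.com_grav, summary.p_com_grav, summary.com_ret, summary.p_com_ret,
    )
    return {"results": results, "summary": summary, "per_neuron": per_neuron,
            "population": pop, "trials": trials, "truth": truth}


def run_decoding_analysis(config: RunConfig) -> dict:
    """Match/non-match LDA accuracy per frame, plus a sub-analysis restricted
    to neurons with no significant correlation in either frame."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = config.geometry.build()
    trials, _ = load_or_simulate(config)
    dec = config.decoding
    rng = child_rng(config.seed, "decoding")

    neither_ids = None
    ana = config.analysis
    results = analyze_neurons(
        trials, geom, alpha=ana.alpha, n_perm=ana.n_perm,
        smooth_width=ana.smoothing_width, balanced=ana.balanced,
        rng=child_rng(config.seed, "permutation"),
    )
    neither_ids = [r.neuron_id for r in results if r.label == "neither"]

    report: dict = {"seed": config.seed, "folds": dec.folds, "shrinkage": dec.shrinkage,
                    "feature_mode": dec.feature_mode, "frames": {}}
    for frame in ("gravitational", "retinal"):
        pairs = enumerate_pairs(
            geom, frame, nonmatch_threshold=dec.nonmatch_threshold,
            n_nonmatch=dec.n_nonmatch, rng=rng,
        )
        samples = assemble_samples(
            trials, pairs, n_draws_per_pair=dec.n_draws_per_pair,
            rng=rng, feature_mode=dec.feature_mode,
        )
        entry = {
            "n_neurons": int(trials["neuron_id"].nunique()),
            "n_match_pairs": sum(p.label == "match" for p in pairs),
            "n_nonmatch_pairs": sum(p.label == "nonmatch" for p in pairs),
            "n_samples": len(samples),
            "accuracy": lda_cv_accuracy(samples, folds=dec.folds, rng=rng,
                                        shrinkage=dec.shrinkage),
        }
        if len(neither_ids) >= dec.min_neither_neurons:
            sub = trials[trials["neuron_id"].isin(neither_ids)]
            sub_samples = assemble_samples(
                sub, pairs, n_draws_per_pair=dec.n_draws_per_pair,
                rng=rng, feature_mode=dec.feature_mode,
            )
            entry["neither_only"] = {
                "n_neurons": len(neither_ids),
                "accuracy": lda_cv_accuracy(sub_samples, folds=dec.folds, rng=rng,
                                            shrinkage=dec.shrinkage),
            }
        else:
            log.warning(
                "only %d 'neither'-labeled neurons (< %d); skipping sub-analysis",
                len(neither_ids), dec.min_neither_neurons,
            )
            entry["neither_only"] = None
        report["frames"][frame] = entry
    with open(out / "decoding.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def run_counterroll_sweep(config: RunConfig, candidate_angles=None) -> dict:
    """Counter-roll compensation sweep over retina-classified neurons."""
    from .refframe import counterroll_sweep

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = config.geometry.build()
    trials, _ = load_or_simulate(config)
    ana = config.analysis
    results = analyze_neurons(
        trials, geom, alpha=ana.alpha, n_perm=ana.n_perm,
        smooth_width=ana.smoothing_width, balanced=ana.balanced,
        rng=child_rng(config.seed, "permutation"),
    )
    retina_ids = [r.neuron_id for r in results if r.label in ("retinal", "both")]
    if not retina_ids:
        raise ValueError("no retina-classified neurons; the sweep needs at least one")
    if candidate_angles is None:
        candidate_angles = list(range(0, 13))
    sweep = counterroll_sweep(
        trials, geom, candidate_angles, selection=retina_ids,
        smooth_width=ana.smoothing_width, rng=child_rng(config.seed, "sweep"),
    )
    payload = {
        "seed": config.seed,
        "n_selected": len(retina_ids),
        "candidates_deg": sweep.candidates.tolist(),
        "mean_correlation": [None if not np.isfinite(v) else v for v in sweep.mean_correlation],
        "argmax_deg": sweep.argmax_deg,
        "informative": sweep.informative,
    }
    with open(out / "counterroll_sweep.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload
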