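"""Per-neuron reference-frame correlations, randomization tests, and population
summaries.

For each neuron, the two tilt conditions' smoothed tuning curves are compared
at the comparison orientations of the gravitational and retinal frames; the
Pearson correlation in each frame measures how well tuning is preserved there.
Significance is assessed with a one-tailed randomization test: response values
are reshuffled across the tested orientations within each condition, the full
statistic (smoothing, frame comparison, correlation t-transform) is recomputed
for each reshuffle, and the observed statistic is ranked against that null.
Because smoothing and spline readout are linear in the tuning values, each
null draw is a single matrix product, which keeps 10,000 reshuffles cheap.

Population-level bias toward positive correlation on either axis is tested by
the center of mass (mean) of the per-neuron correlations against a null that
reshuffles every neuron's values, and the ocular counter-roll magnitude is
located by sweeping the compensation angle used in the retinal transform and
finding the value that maximizes mean retinal correspondence among
retina-aligned neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import ExperimentGeometry, Frame
from .tuning import (
    TuningFunction,
    ComparisonSet,
    boxcar_matrix,
    comparison_weight_matrices,
    mean_tuning,
)

Label = Literal["gravitational", "retinal", "both", "neither", "excluded"]

#: Comparison-value variance below this (relative to scale) is "no variance".
_VAR_EPS = 1e-12


@dataclass(frozen=True)
class NeuronFrameResult:
    """Correlations and permutation p-values for one neuron in both frames."""

    neuron_id: int
    r_grav: Optional[float]
    r_ret: Optional[float]
    p_grav: Optional[float]
    p_ret: Optional[float]
    label: Label


@dataclass
class PopulationSummary:
    """Label counts and per-axis center-of-mass statistics for a population."""

    n_total: int
    counts: dict[str, int]
    n_significant: int
    proportions: Optional[dict[str, float]]
    com_grav: Optional[float] = None
    com_ret: Optional[float] = None
    p_com_grav: Optional[float] = None
    p_com_ret: Optional[float] = None
    n_perm: Optional[int] = None
    n_excluded: int = 0


@dataclass(frozen=True)
class CounterrollSweepResult:
    """Mean retinal correspondence as a function of assumed counter-roll."""

    candidates: np.ndarray
    mean_correlation: np.ndarray  # NaN where the candidate was invalid
    argmax_deg: Optional[float]
    informative: bool


def pearson_r(cs: ComparisonSet) -> Optional[float]:
    """Pearson correlation of the paired comparison values.

    Returns ``None`` (undefined) when either side has zero variance; such
    neurons are excluded from classification rather than given a number.
    """
    return _pearson_pair(cs.values_a, cs.values_b)


def _pearson_pair(a: np.ndarray, b: np.ndarray) -> Optional[float]:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    scale = max(np.abs(a).max(initial=0.0), np.abs(b).max(initial=0.0), 1.0)
    if denom <= _VAR_EPS * scale**2:
        return None
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def _pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between matching rows of A and B; NaN if degenerate."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    denom = np.sqrt((A * A).sum(axis=1) * (B * B).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (A * B).sum(axis=1) / denom
    r[denom <= _VAR_EPS] = np.nan
    return np.clip(r, -1.0, 1.0)


def corr_t_statistic(r: float, n: int) -> float:
    """t-transform of a correlation, t = r sqrt(n-2) / sqrt(1-r^2).

    Monotone in r for fixed n, so permutation ranks based on t and on r agree;
    r = ±1 maps to ±inf.
    """
    if abs(r) >= 1.0:
        return float(np.sign(r)) * np.inf
    return r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)


def _null_correlations(
    raw_a: np.ndarray,
    raw_b: np.ndarray,
    design: "_FrameDesign",
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null correlations from reshuffling each condition's raw values.

    Each draw independently permutes the unsmoothed per-orientation mean
    responses of each condition across the tested orientations, then pushes
    them through the same smoothing + comparison readout as the observed
    statistic.
    """
    n = raw_a.size
    idx_a = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    idx_b = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    null_a = raw_a[idx_a] @ design.m_a.T
    null_b = raw_b[idx_b] @ design.m_b.T
    return _pearson_rows(null_a, null_b)


@dataclass(frozen=True)
class _FrameDesign:
    """Precomputed linear readout from raw tuning values to comparison values."""

    rho: np.ndarray
    m_a: np.ndarray  # (n_comparisons, n_grid): smoothing + spline readout, condition A
    m_b: np.ndarray


def _frame_design(
    geom: ExperimentGeometry,
    frame: Frame,
    smooth_width: int = 3,
    balanced: bool = False,
) -> _FrameDesign:
    rho, w_a, w_b = comparison_weight_matrices(geom, frame, balanced=balanced)
    s = boxcar_matrix(len(geom.grid), smooth_width)
    return _FrameDesign(rho=rho, m_a=w_a @ s, m_b=w_b @ s)


def frame_correlation(
    tf_a: TuningFunction,
    tf_b: TuningFunction,
    geom: ExperimentGeometry,
    frame: Frame,
    smooth_width: int = 3,
    balanced: bool = False,
) -> Optional[float]:
    """Observed cross-tilt correlation in one frame from *unsmoothed* curves."""
    design = _frame_design(geom, frame, smooth_width, balanced)
    return _pearson_pair(design.m_a @ tf_a.values, design.m_b @ tf_b.values)


def perm_test_positive(
    tf_a: TuningFunction,
    tf_b: TuningFunction,
    geom: ExperimentGeometry,
    frame: Frame,
    n_perm: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    smooth_width: int = 3,
    balanced: bool = False,
) -> tuple[Optional[float], Optional[float]]:
    """One-tailed randomization test for positive cross-tilt correlation.

    Returns ``(r_observed, p)``.  Inputs are the two conditions' unsmoothed
    screen-frame tuning functions; smoothing is applied inside so the
    statistic can be recomputed identically for every reshuffle.  The p-value
    uses the add-one estimator ``p = (1 + #{t_null >= t_obs}) / (1 + n_perm)``
    and therefore never returns exactly 0; its resolution floor is
    ``1 / (n_perm + 1)``.  Undefined observed correlation gives ``(None,
    None)`` and the neuron is excluded.
    """
    if tf_a.smoothed or tf_b.smoothed:
        raise ValueError("perm_test_positive expects unsmoothed tuning functions")
    design = _frame_design(geom, frame, smooth_width, balanced)
    r_obs = _pearson_pair(design.m_a @ tf_a.values, design.m_b @ tf_b.values)
    if r_obs is None:
        return None, None
    if n_perm <= 0:
        return r_obs, 1.0
    rng = np.random.default_rng() if rng is None else rng
    r_null = _null_correlations(tf_a.values, tf_b.values, design, n_perm, rng)
    # t = r sqrt(n-2)/sqrt(1-r^2) is monotone in r at fixed n, so ranking on r
    # is ranking on t; the tiny tolerance counts floating-point ties as >=.
    n_ge = int(np.sum(r_null >= r_obs - 1e-12))
    return r_obs, (1 + n_ge) / (1 + n_perm)


def classify_neuron(
    p_grav: Optional[float], p_ret: Optional[float], alpha: float = 0.05
) -> Label:
    """Label a neuron by which frames show significant positive correlation."""
    if p_grav is None or p_ret is None:
        return "excluded"
    sig_g, sig_r = p_grav < alpha, p_ret < alpha
    if sig_g and sig_r:
        return "both"
    if sig_g:
        return "gravitational"
    if sig_r:
        return "retinal"
    return "neither"


def analyze_neurons(
    trials: pd.DataFrame,
    geom: ExperimentGeometry,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    smooth_width: int = 3,
    balanced: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> list[NeuronFrameResult]:
    """Full per-neuron analysis of a trial table: correlations, permutation
    p-values and a label in both reference frames for every neuron."""
    rng = np.random.default_rng() if rng is None else rng
    results = []
    for nid, tf_a, tf_b in iter_condition_tunings(trials, geom):
        r_g, p_g = perm_test_positive(tf_a, tf_b, geom, "gravitational",
                                      n_perm=n_perm, rng=rng,
                                      smooth_width=smooth_width, balanced=balanced)
        r_r, p_r = perm_test_positive(tf_a, tf_b, geom, "retinal",
                                      n_perm=n_perm, rng=rng,
                                      smooth_width=smooth_width, balanced=balanced)
        results.append(
            NeuronFrameResult(
                neuron_id=nid, r_grav=r_g, r_ret=r_r, p_grav=p_g, p_ret=p_r,
                label=classify_neuron(p_g, p_r, alpha),
            )
        )
    return results


def iter_condition_tunings(
    trials: pd.DataFrame, geom: ExperimentGeometry
) -> Iterable[tuple[int, TuningFunction, TuningFunction]]:
    """Yield (neuron_id, condition-1 curve, condition-2 curve), unsmoothed."""
    for nid in sorted(trials["neuron_id"].unique()):
        tf_a = mean_tuning(trials, nid, 1, expected_orientations=geom.grid)
        tf_b = mean_tuning(trials, nid, 2, expected_orientations=geom.grid)
        yield int(nid), tf_a, tf_b


def population_com_test(
    tuning_pairs: Sequence[tuple[TuningFunction, TuningFunction]],
    geom: ExperimentGeometry,
    frame: Frame,
    n_perm: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    smooth_width: int = 3,
    balanced: bool = False,
) -> tuple[float, float]:
    """Two-tailed randomization test for the population correlation center of mass.

    The observed statistic is the mean of the per-neuron correlations on the
    requested axis ("center of mass on the correlation domain").  Each null
    draw reshuffles every neuron's values across orientations (each condition
    independently), recomputes all correlations, and takes their mean;
    ``p = (1 + #{|com_null| >= |com_obs|}) / (1 + n_perm)``.

    Returns ``(com_observed, p)``.  Neurons with undefined correlation are
    dropped; raises if none remain.
    """
    rng = np.random.default_rng() if rng is None else rng
    design = _frame_design(geom, frame, smooth_width, balanced)
    obs = []
    nulls = []
    for tf_a, tf_b in tuning_pairs:
        r = _pearson_pair(design.m_a @ tf_a.values, design.m_b @ tf_b.values)
        if r is None:
            continue
        obs.append(r)
        nulls.append(_null_correlations(tf_a.values, tf_b.values, design, n_perm, rng))
    if not obs:
        raise ValueError("all neurons have undefined correlations on this axis")
    com_obs = float(np.mean(obs))
    com_null = np.nanmean(np.vstack(nulls), axis=0)
    n_ge = int(np.sum(np.abs(com_null) >= abs(com_obs) - 1e-12))
    return com_obs, (1 + n_ge) / (1 + n_perm)


def summarize_population(results: Sequence[NeuronFrameResult]) -> PopulationSummary:
    """Counts and proportions per label among neurons significant in >= 1 frame."""
    if not results:
        raise ValueError("no results to summarize")
    counts = {k: 0 for k in ("gravitational", "retinal", "both", "neither", "excluded")}
    for res in results:
        counts[res.label] += 1
    n_sig = counts["gravitational"] + counts["retinal"] + counts["both"]
    proportions = None
    if n_sig > 0:
        proportions = {k: counts[k] / n_sig for k in ("gravitational", "retinal", "both")}
    return PopulationSummary(
        n_total=len(results),
        counts=counts,
        n_significant=n_sig,
        proportions=proportions,
        n_excluded=counts["excluded"],
    )


def counterroll_sweep(
    trials: pd.DataFrame,
    geom: ExperimentGeometry,
    candidate_angles: Sequence[float],
    selection: Optional[Sequence[int]] = None,
    smooth_width: int = 3,
    min_curve_range: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> CounterrollSweepResult:
    """Locate the counter-roll compensation maximizing retinal correspondence.

    For each candidate compensation angle the geometry is rebuilt with that
    counter-roll, the retinal-frame correlations of the selected neurons
    (normally the retina-classified ones) are recomputed from their smoothed
    curves, and the mean correlation is recorded.  Candidates for which the
    retinal comparison set shrinks below 3 points are marked invalid (NaN) and
    excluded from the argmax.  The sweep is flagged uninformative (``argmax_deg
    = None``) when it carries no usable localization signal: either the curve
    range falls below ``min_curve_range``, or the maximum sits at the *upper*
    end of the swept range so the peak is not bracketed — the signature of a
    gravity-aligned selection, whose retinal correspondence keeps rising as
    the compensation approaches the full tilt.  (A maximum at 0 is genuine:
    the decline away from it is observed.)
    """
    if geom.mode != "body_tilt":
        raise ValueError("the counter-roll sweep applies to body-tilt experiments")
    candidates = np.asarray(list(candidate_angles), dtype=float)
    if 0.0 not in candidates:
        raise ValueError("candidate_angles must include 0")
    if selection is not None:
        trials = trials[trials["neuron_id"].isin(list(selection))]
        if trials.empty:
            raise ValueError("selection matched no neurons")
    pairs = [(tf_a, tf_b) for _, tf_a, tf_b in iter_condition_tunings(trials, geom)]

    mean_r = np.full(candidates.size, np.nan)
    for i, c in enumerate(candidates):
        try:
            geom_c = ExperimentGeometry(
                mode=geom.mode,
                tested_screen_orientations=geom.tested_screen_orientations,
                condition_tilts=geom.condition_tilts,
                counterroll_deg=float(c),
            )
            design = _frame_design(geom_c, "retinal", smooth_width)
        except ValueError:
            continue  # over-compensation or comparison set too small
        rs = [
            r
            for tf_a, tf_b in pairs
            if (r := _pearson_pair(design.m_a @ tf_a.values, design.m_b @ tf_b.values))
            is not None
        ]
        if rs:
            mean_r[i] = float(np.mean(rs))

    valid = np.isfinite(mean_r)
    if not valid.any():
        raise ValueError("no candidate compensation angle produced a valid comparison set")
    order = np.argsort(candidates)
    valid_sorted = order[valid[order]]
    best = int(np.nanargmax(mean_r))
    curve_range = float(np.nanmax(mean_r) - np.nanmin(mean_r))
    informative = curve_range >= min_curve_range and best != int(valid_sorted[-1])
    argmax = float(candidates[best]) if informative else None
    return CounterrollSweepResult(
        candidates=candidates,
        mean_correlation=mean_r,
        argmax_deg=argmax,
        informative=informative,
    )


def results_to_frame(results: Sequence[NeuronFrameResult]) -> pd.DataFrame:
    """Tabulate per-neuron results (one row per neuron), NaN for undefined."""
    return pd.DataFrame(
        {
            "neuron_id": [r.neuron_id for r in results],
            "r_grav": [np.nan if r.r_grav is None else r.r_grav for r in results],
            "r_ret": [np.nan if r.r_ret is None else r.r_ret for r in results],
            "p_grav": [np.nan if r.p_grav is None else r.p_grav for r in results],
            "p_ret": [np.nan if r.p_ret is None else r.p_ret for r in results],
            "label": [r.label for r in results],
        }
    )
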