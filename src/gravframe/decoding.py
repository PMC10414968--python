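"""Match/non-match orientation-equivalence decoding from pseudo-populations.

The task: given the responses of a neural population to two stimulus
presentations, decide whether the two presentations had the *same* orientation
in a given reference frame (match) or orientations differing by more than a
threshold (non-match).  Pairs are built from the two tilt conditions' tested
orientations; a pseudo-population sample draws one repetition per neuron per
side independently, and the classifier is a cross-validated linear
discriminant.  Because matching is defined per frame, separate decoders are
trained for the gravitational and retinal frames; a population of
mixed-anchoring neurons supports above-chance decoding in both.

Orientations are aligned across neurons by their grid position in the tested
range, so the same orientation pair is used for every neuron even when the
underlying stimuli differ between neurons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .geometry import ExperimentGeometry, Frame, comparison_orientations, frame_offset

FeatureMode = Literal["signed_diff", "abs_diff", "concat"]


@dataclass(frozen=True)
class PairSpec:
    """One orientation pair: two (condition, screen orientation) sides.

    ``frame_a``/``frame_b`` are the sides' coordinates in the tested frame;
    ``frame_diff = frame_a − frame_b``.  A match pair has |frame_diff| at the
    match tolerance or below (0 exactly when the frame transform lands on the
    grid); a non-match exceeds the non-match threshold.
    """

    frame: str
    cond_a: int
    screen_a: float
    cond_b: int
    screen_b: float
    frame_a: float
    frame_b: float
    label: Literal["match", "nonmatch"]

    @property
    def frame_diff(self) -> float:
        return self.frame_a - self.frame_b


@dataclass(frozen=True)
class PairSample:
    """One pseudo-population feature vector with its match/non-match label."""

    features: np.ndarray
    label: Literal["match", "nonmatch"]
    pair_id: int
    draw_id: int


def _side_frame_coords(geom: ExperimentGeometry, frame: Frame) -> dict[int, np.ndarray]:
    return {
        cond_id: geom.grid - frame_offset(frame, tilt, geom)
        for cond_id, tilt in enumerate(geom.condition_tilts, start=1)
    }


def enumerate_pairs(
    geom: ExperimentGeometry,
    frame: Frame,
    nonmatch_threshold: float = 25.0,
    equalize: bool = True,
    n_nonmatch: int = 20,
    match_tol: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> list[PairSpec]:
    """Enumerate match and non-match orientation pairs for one frame.

    Matches are cross-condition pairs of tested orientations whose coordinates
    in the frame agree to within ``match_tol`` (the tolerance absorbs the
    sub-grid residual left when the counter-roll angle is not a multiple of
    the grid spacing; gravitational matches are exact).  Non-matches are
    cross-condition and within-condition pairs (canonical order, no antipodal
    duplicates) whose frame difference exceeds ``nonmatch_threshold``.

    With ``equalize=True`` (default) the counts are equated across the two
    frames: one match is kept per balanced comparison orientation — the
    candidate whose frame midpoint is nearest that orientation — and
    non-matches are subsampled (seeded) to ``min(n_nonmatch, available in
    either frame)``.  For the default body-tilt design this yields 5 matches
    and 20 non-matches per frame.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    matches, nonmatches = _candidate_pairs(geom, frame, nonmatch_threshold, match_tol)
    if not matches:
        raise ValueError(f"no match pairs exist in the {frame} frame at tol {match_tol}")
    if not nonmatches:
        raise ValueError(
            f"no non-match pairs exceed {nonmatch_threshold}° in the {frame} frame"
        )
    if not equalize:
        return matches + nonmatches

    other: Frame = "retinal" if frame == "gravitational" else "gravitational"
    o_matches, o_nonmatches = _candidate_pairs(geom, other, nonmatch_threshold, match_tol)
    anchors = comparison_orientations(geom, frame, balanced=True)

    picked: list[PairSpec] = []
    used: set[int] = set()
    for rho in anchors:
        mids = np.array(
            [
                np.inf if i in used else abs(0.5 * (m.frame_a + m.frame_b) - rho)
                for i, m in enumerate(matches)
            ]
        )
        best = int(np.argmin(mids))
        used.add(best)
        picked.append(matches[best])
    n_match_target = min(len(picked), len(o_matches))
    picked = picked[:n_match_target]

    n_nm_target = min(n_nonmatch, len(nonmatches), len(o_nonmatches))
    idx = rng.choice(len(nonmatches), size=n_nm_target, replace=False)
    return picked + [nonmatches[i] for i in sorted(idx)]


def _candidate_pairs(
    geom: ExperimentGeometry, frame: Frame, nonmatch_threshold: float, match_tol: float
) -> tuple[list[PairSpec], list[PairSpec]]:
    coords = _side_frame_coords(geom, frame)
    grid = geom.grid
    matches: list[PairSpec] = []
    nonmatches: list[PairSpec] = []

    def add(ca: int, ia: int, cb: int, ib: int) -> None:
        fa, fb = coords[ca][ia], coords[cb][ib]
        spec = PairSpec(
            frame=frame, cond_a=ca, screen_a=float(grid[ia]), cond_b=cb,
            screen_b=float(grid[ib]), frame_a=float(fa), frame_b=float(fb),
            label="match" if abs(fa - fb) <= match_tol else "nonmatch",
        )
        if spec.label == "match":
            matches.append(spec)
        elif abs(fa - fb) > nonmatch_threshold:
            nonmatches.append(spec)

    n = grid.size
    for ia in range(n):  # cross-condition, canonical orientation order ia <= ib
        for ib in range(ia, n):
            add(1, ia, 2, ib)
            if ib > ia:
                add(2, ia, 1, ib)
    for c in (1, 2):  # within-condition
        for ia in range(n):
            for ib in range(ia + 1, n):
                add(c, ia, c, ib)
    return matches, nonmatches


def _rate_lookup(trials: pd.DataFrame) -> tuple[list[int], dict, int]:
    """(sorted neuron ids, {(cond, screen) -> (n_neurons, n_reps) rate array}, n_reps)."""
    neuron_ids = sorted(trials["neuron_id"].unique())
    pivot = trials.pivot_table(
        index=["condition_id", "screen_orientation_deg"],
        columns=["neuron_id", "repetition"],
        values="rate_spk_s",
    )
    lookup = {}
    reps = sorted(trials["repetition"].unique())
    for key, row in pivot.iterrows():
        try:
            arr = np.array([[row[(nid, rep)] for rep in reps] for nid in neuron_ids])
        except KeyError as exc:
            raise ValueError(f"missing trial for neuron/repetition {exc} at {key}") from exc
        if np.any(~np.isfinite(arr)):
            bad = neuron_ids[int(np.argwhere(~np.isfinite(arr))[0, 0])]
            raise ValueError(f"neuron {bad} has no trials at condition/orientation {key}")
        lookup[(int(key[0]), float(key[1]))] = arr
    return [int(n) for n in neuron_ids], lookup, len(reps)


def assemble_samples(
    trials: pd.DataFrame,
    pairs: Sequence[PairSpec],
    n_draws_per_pair: int = 20,
    rng: Optional[np.random.Generator] = None,
    feature_mode: FeatureMode = "abs_diff",
) -> list[PairSample]:
    """Build pseudo-population samples for a set of pairs.

    For each pair and draw, one repetition is selected independently per
    neuron for each side; the feature vector is the per-neuron absolute
    response difference |side A − side B| (``abs_diff``, default), the signed
    difference (``signed_diff``), or the concatenation of the two raw
    response vectors (``concat``).  The absolute difference makes the
    match/non-match magnitude problem linearly separable: match features
    concentrate at zero while non-match features lie in the positive orthant.
    Deterministic under a seeded generator.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    neuron_ids, lookup, n_reps = _rate_lookup(trials)
    n_neurons = len(neuron_ids)
    samples: list[PairSample] = []
    for pid, pair in enumerate(pairs):
        for key in ((pair.cond_a, pair.screen_a), (pair.cond_b, pair.screen_b)):
            if key not in lookup:
                raise ValueError(
                    f"no trials at condition {key[0]}, screen orientation {key[1]}"
                )
        rates_a = lookup[(pair.cond_a, pair.screen_a)]
        rates_b = lookup[(pair.cond_b, pair.screen_b)]
        for draw in range(n_draws_per_pair):
            pick_a = rates_a[np.arange(n_neurons), rng.integers(0, n_reps, n_neurons)]
            pick_b = rates_b[np.arange(n_neurons), rng.integers(0, n_reps, n_neurons)]
            if feature_mode == "signed_diff":
                feats = pick_a - pick_b
            elif feature_mode == "abs_diff":
                feats = np.abs(pick_a - pick_b)
            elif feature_mode == "concat":
                feats = np.concatenate([pick_a, pick_b])
            else:
                raise ValueError(f"unknown feature_mode {feature_mode!r}")
            samples.append(PairSample(features=feats, label=pair.label, pair_id=pid, draw_id=draw))
    return samples


def samples_to_arrays(samples: Sequence[PairSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([s.features for s in samples])
    y = np.array([1 if s.label == "match" else 0 for s in samples])
    return X, y


def lda_cv_accuracy(
    samples: Sequence[PairSample],
    folds: int = 10,
    rng: Optional[np.random.Generator] = None,
    shrinkage: float = 0.1,
) -> float:
    """Stratified k-fold cross-validated linear-discriminant accuracy.

    Uses a pooled within-class covariance with diagonal shrinkage for
    stability and returns 1 − misclassification rate averaged over folds.
    If the features carry no variance at all, every sample is assigned the
    majority class and the majority proportion is returned.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    X, y = samples_to_arrays(samples)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need both match and non-match samples")
    if int(counts.min()) < folds:
        raise ValueError(
            f"need at least {folds} samples per class for {folds}-fold CV; "
            f"got {dict(zip(classes.tolist(), counts.tolist()))}"
        )
    if np.allclose(X.var(axis=0), 0.0):
        return float(counts.max() / counts.sum())

    if shrinkage is not None and not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    if not shrinkage:
        centered = np.vstack([X[y == c] - X[y == c].mean(axis=0) for c in classes])
        if np.linalg.matrix_rank(centered) < X.shape[1]:
            raise ValueError(
                "pooled within-class covariance is singular; set shrinkage > 0"
            )
    lda = LinearDiscriminantAnalysis(
        solver="lsqr", shrinkage=None if not shrinkage else float(shrinkage)
    )
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(rng.integers(0, 2**31 - 1)))
    accs = []
    for train, test in skf.split(X, y):
        try:
            lda.fit(X[train], y[train])
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular pooled covariance; rerun with shrinkage > 0"
            ) from exc
        accs.append(float(np.mean(lda.predict(X[test]) == y[test])))
    return float(np.mean(accs))
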