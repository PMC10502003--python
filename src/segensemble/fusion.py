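"""Label fusion: combining J candidate segmentations into one consensus.

Schemes
-------
* ``average_probability`` + ``threshold_mask`` — the ensemble workhorse:
  the voxel-wise (optionally weighted) mean of the candidate masks is a
  probability map, binarised at a threshold ``p_thr`` (default 0.35, the
  value that maximises the mean Dice score in the study this package
  models; the choice matters little above 0.25).
* ``majority_vote`` — strict-majority label voting; for odd J identical
  to averaging + thresholding just above one half.
* ``staple`` — expectation–maximisation estimation of a consensus
  probability field together with each rater's sensitivity p_j and
  specificity q_j (simultaneous truth and performance level estimation).
* regression combiner — per-model linear regression predicting a model's
  ground-truth Dice from its pairwise Dices with the other models; at
  apply time the model with the highest predicted score is selected.

Thresholding convention: a voxel exactly at the threshold is foreground
(``>=``).  This is fixed and documented rather than configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES, dice, evaluate
from .volumes import BinaryMask, ProbabilityMap, check_same_geometry

__all__ = [
    "RaterPerformance",
    "StapleResult",
    "RegressionCombinerModel",
    "average_probability",
    "threshold_mask",
    "majority_vote",
    "staple",
    "staple_mask",
    "fit_regression_combiner",
    "apply_regression_combiner",
    "sweep_threshold",
    "fuse_average",
]

_EPS = 1e-7  # probability clamp avoiding log(0) when p_j or q_j saturates


def _check_stack(masks: Sequence[BinaryMask | ProbabilityMap]) -> None:
    if not masks:
        raise ValueError("at least one input mask is required")
    for m in masks[1:]:
        check_same_geometry(masks[0], m)


def average_probability(masks: Sequence[BinaryMask | ProbabilityMap],
                        weights: Sequence[float] | None = None) -> ProbabilityMap:
    """Voxel-wise weighted mean of candidate masks or probability maps.

    Weights default to equal; they must be non-negative with a positive
    sum and are normalised internally.
    """
    _check_stack(masks)
    n = len(masks)
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError(f"expected {n} weights, got shape {w.shape}")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        w = w / total
    acc = np.zeros(masks[0].shape, dtype=float)
    for wi, m in zip(w, masks):
        acc += wi * m.voxels.astype(float)
    prov = tuple(getattr(m, "label", "") or "" for m in masks)
    return ProbabilityMap(np.clip(acc, 0.0, 1.0), masks[0].spacing, prov,
                          getattr(masks[0], "affine", None))


def threshold_mask(p: ProbabilityMap, p_thr: float = 0.35,
                   label: str = "") -> BinaryMask:
    """Binarise a probability map: foreground iff value >= ``p_thr``.

    ``p_thr`` must lie in (0, 1]; ties at exactly ``p_thr`` are foreground.
    """
    if not 0.0 < p_thr <= 1.0:
        raise ValueError(f"p_thr must lie in (0, 1], got {p_thr}")
    return BinaryMask(p.voxels >= p_thr, p.spacing, label, p.affine)


def fuse_average(masks: Sequence[BinaryMask], p_thr: float = 0.35,
                 weights: Sequence[float] | None = None,
                 label: str = "ensemble") -> BinaryMask:
    """Convenience: average + threshold in one call."""
    return threshold_mask(average_probability(masks, weights), p_thr, label)


def majority_vote(masks: Sequence[BinaryMask], label: str = "vote") -> BinaryMask:
    """Strict-majority label voting: foreground where more than half of
    the masks vote foreground (an exact half is background)."""
    _check_stack(masks)
    votes = np.zeros(masks[0].shape, dtype=np.int32)
    for m in masks:
        votes += m.voxels
    return BinaryMask(votes * 2 > len(masks), masks[0].spacing, label,
                      getattr(masks[0], "affine", None))


# ---------------------------------------------------------------------------
# STAPLE


@dataclass(frozen=True)
class RaterPerformance:
    """Estimated performance level of one rater/model: sensitivity p_j
    (true-foreground voxels marked foreground) and specificity q_j
    (true-background voxels marked background)."""

    model_id: str
    sensitivity: float
    specificity: float
    iterations_used: int = 0


@dataclass(frozen=True)
class StapleResult:
    """STAPLE output: the consensus weight field W (per-voxel posterior
    probability of foreground) and per-rater performance estimates.

    Unpacks as ``(probability, performances)``; also carries the iteration
    count, convergence flag and the per-iteration observed-data
    log-likelihood trajectory (non-decreasing — the EM guarantee)."""

    probability: ProbabilityMap
    performances: tuple[RaterPerformance, ...]
    iterations: int
    converged: bool
    log_likelihood: np.ndarray = field(compare=False, default_factory=lambda: np.empty(0))

    def __iter__(self) -> Iterator:
        return iter((self.probability, self.performances))


def staple(masks: Sequence[BinaryMask], prior: float | None = None,
           init_p: float = 0.9, init_q: float = 0.9,
           tol: float = 1e-6, max_iter: int = 100,
           model_ids: Sequence[str] | None = None) -> StapleResult:
    """Simultaneous truth and performance level estimation (binary EM).

    The hidden true segmentation T is estimated iteratively as a per-voxel
    weight field W_i = P(T_i = 1 | D, p, q); the rater performances are
    re-estimated from their agreement with W.

    E-step::

        a_i = γ · Π_j p_j^{D_ij} (1−p_j)^{1−D_ij}
        b_i = (1−γ) · Π_j q_j^{1−D_ij} (1−q_j)^{D_ij}
        W_i = a_i / (a_i + b_i)

    M-step::

        p_j = Σ_i W_i D_ij / Σ_i W_i
        q_j = Σ_i (1−W_i)(1−D_ij) / Σ_i (1−W_i)

    γ is the scalar foreground prior; by default the mean foreground
    fraction of the input masks.  All products run in log space with
    probabilities clamped to [1e-7, 1−1e-7].  Convergence: the change in
    Σ_i W_i between iterations, normalised by the voxel count, drops
    below ``tol``.

    Notes
    -----
    STAPLE assumes the raters are conditionally independent given the true
    segmentation — typically violated by ensemble members trained on the
    same data, but useful in practice nonetheless.
    """
    _check_stack(masks)
    if not (0.0 < init_p < 1.0 and 0.0 < init_q < 1.0):
        raise ValueError("init_p and init_q must lie strictly in (0, 1)")
    if prior is not None and not 0.0 < prior < 1.0:
        raise ValueError(f"prior must lie strictly in (0, 1), got {prior}")
    J = len(masks)
    if model_ids is None:
        model_ids = [m.label or f"model_{j}" for j, m in enumerate(masks)]
    elif len(model_ids) != J:
        raise ValueError("model_ids length must match the number of masks")

    D = np.stack([m.voxels.reshape(-1) for m in masks]).astype(np.float64)  # (J, N)
    n_vox = D.shape[1]
    gamma = float(D.mean()) if prior is None else float(prior)
    gamma = min(max(gamma, _EPS), 1.0 - _EPS)
    log_g, log_1mg = np.log(gamma), np.log1p(-gamma)

    p = np.full(J, init_p)
    q = np.full(J, init_q)
    prev_w_sum = np.inf
    converged = False
    ll_trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        pc = np.clip(p, _EPS, 1.0 - _EPS)
        qc = np.clip(q, _EPS, 1.0 - _EPS)
        # log a_i = log γ + Σ_j D_ij·logit-ish terms; organised so the
        # voxel loop is a single matrix product over raters.
        log_a = log_g + D.T @ (np.log(pc) - np.log1p(-pc)) + np.log1p(-pc).sum()
        log_b = log_1mg + D.T @ (np.log1p(-qc) - np.log(qc)) + np.log(qc).sum()
        ll_trace.append(float(np.logaddexp(log_a, log_b).sum()))
        with np.errstate(over="ignore"):
            W = 1.0 / (1.0 + np.exp(log_b - log_a))
        w_sum = float(W.sum())
        # M-step
        denom_fg = max(w_sum, _EPS)
        denom_bg = max(n_vox - w_sum, _EPS)
        p = (D @ W) / denom_fg
        q = ((1.0 - D) @ (1.0 - W)) / denom_bg
        if abs(w_sum - prev_w_sum) / n_vox < tol:
            converged = True
            break
        prev_w_sum = w_sum

    shape = masks[0].shape
    prob = ProbabilityMap(W.reshape(shape), masks[0].spacing,
                          tuple(model_ids), getattr(masks[0], "affine", None))
    perf = tuple(RaterPerformance(model_ids[j], float(p[j]), float(q[j]), it)
                 for j in range(J))
    return StapleResult(prob, perf, it, converged, np.asarray(ll_trace))


def staple_mask(W: ProbabilityMap, p_thr: float = 0.5,
                label: str = "staple") -> BinaryMask:
    """Binarise a STAPLE weight field (default threshold 0.5; on a sharply
    converged field any threshold well inside (0, 1) gives nearly the same
    mask)."""
    return threshold_mask(W, p_thr, label)


# ---------------------------------------------------------------------------
# Regression combiner (model selection)


@dataclass(frozen=True)
class RegressionCombinerModel:
    """Per-model linear maps from pairwise Dices to predicted ground-truth
    Dice:  DSC(S_m, GT) ≈ α_m + Σ_{n≠m} β_mn · DSC(S_m, S_n)."""

    model_ids: tuple[str, ...]
    intercepts: np.ndarray          # (J,)
    coefficients: np.ndarray        # (J, J-1), row m over n != m in id order
    n_train: int
    residual_rms: np.ndarray        # (J,)

    def __post_init__(self) -> None:
        J = len(self.model_ids)
        if self.coefficients.shape != (J, max(J - 1, 0)):
            raise ValueError(
                f"coefficients must have shape ({J}, {J - 1}), "
                f"got {self.coefficients.shape}"
            )
        if not (np.all(np.isfinite(self.intercepts))
                and np.all(np.isfinite(self.coefficients))):
            raise ValueError("combiner coefficients must be finite")

    def predict(self, pairwise: np.ndarray) -> np.ndarray:
        """Predicted GT-Dice per model from a (J, J) pairwise-Dice matrix."""
        J = len(self.model_ids)
        if pairwise.shape != (J, J):
            raise ValueError(f"expected a ({J}, {J}) pairwise-Dice matrix")
        off = ~np.eye(J, dtype=bool)
        X = pairwise[off].reshape(J, J - 1)
        return self.intercepts + (self.coefficients * X).sum(axis=1)


def _pairwise_dice(masks: Sequence[BinaryMask]) -> np.ndarray:
    J = len(masks)
    M = np.ones((J, J))
    for m in range(J):
        for n in range(m + 1, J):
            M[m, n] = M[n, m] = dice(masks[m], masks[n])
    return M


def fit_regression_combiner(
    training: Sequence[tuple[Sequence[BinaryMask], BinaryMask]],
    model_ids: Sequence[str] | None = None,
    ridge: float = 0.0,
) -> RegressionCombinerModel:
    """Fit the per-model regressions on (candidate masks, reference) pairs.

    For each model m, its ground-truth Dice across the training images is
    regressed (ordinary least squares; optional ridge penalty for
    near-collinear ensembles) on its J−1 pairwise Dices with the other
    models.  Requires n_train >= J (J−1 slopes + intercept) and J >= 2.
    A rank-deficient design — e.g. all models identical on every image —
    is an error naming the offending model.
    """
    if not training:
        raise ValueError("empty training set")
    J = len(training[0][0])
    if J < 2:
        raise ValueError(f"regression combiner needs J >= 2 models, got {J}")
    n_train = len(training)
    if n_train < J:
        raise ValueError(
            f"underdetermined fit: {n_train} training images for {J} models "
            f"(need n_train >= J)"
        )
    if model_ids is None:
        model_ids = [m.label or f"model_{j}" for j, m in enumerate(training[0][0])]

    y = np.empty((n_train, J))
    X_pair = np.empty((n_train, J, J))
    for i, (cands, ref) in enumerate(training):
        if len(cands) != J:
            raise ValueError(f"training image {i}: expected {J} masks, got {len(cands)}")
        for m, cand in enumerate(cands):
            y[i, m] = dice(cand, ref)
        X_pair[i] = _pairwise_dice(cands)

    off = ~np.eye(J, dtype=bool)
    intercepts = np.empty(J)
    coefs = np.empty((J, J - 1))
    rms = np.empty(J)
    for m in range(J):
        X = np.column_stack([np.ones(n_train), X_pair[:, m, off[m]]])
        if ridge > 0:
            pen = ridge * np.eye(J)
            pen[0, 0] = 0.0  # never penalise the intercept
            beta = np.linalg.solve(X.T @ X + pen, X.T @ y[:, m])
        else:
            rank = np.linalg.matrix_rank(X)
            if rank < J:
                raise ValueError(
                    f"rank-deficient design for model {model_ids[m]!r} "
                    f"(rank {rank} < {J}); the candidate masks carry no "
                    f"independent pairwise-Dice variation"
                )
            beta, *_ = np.linalg.lstsq(X, y[:, m], rcond=None)
        intercepts[m] = beta[0]
        coefs[m] = beta[1:]
        rms[m] = float(np.sqrt(np.mean((X @ beta - y[:, m]) ** 2)))
    return RegressionCombinerModel(tuple(model_ids), intercepts, coefs, n_train, rms)


def apply_regression_combiner(
    model: RegressionCombinerModel, candidates: Sequence[BinaryMask]
) -> tuple[str, BinaryMask, np.ndarray]:
    """Select the candidate with the highest predicted ground-truth Dice.

    Ties break to the lowest model index (deterministic).  Returns
    ``(selected id, selected mask, predicted scores)``.
    """
    J = len(model.model_ids)
    if len(candidates) != J:
        raise ValueError(f"expected {J} candidate masks, got {len(candidates)}")
    scores = model.predict(_pairwise_dice(candidates))
    best = int(np.argmax(scores))  # argmax takes the first maximum
    return model.model_ids[best], candidates[best], scores


# ---------------------------------------------------------------------------
# Threshold sweep


def sweep_threshold(
    model_masks_per_image: Sequence[Sequence[BinaryMask]],
    references: Sequence[BinaryMask],
    grid: Sequence[float],
    weights: Sequence[float] | None = None,
    include_surface: bool = True,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Mean metrics of the averaged-and-thresholded ensemble as a function
    of the probability threshold.

    Returns a table with one row per threshold (columns ``p_thr`` plus the
    mean of each metric over images) and the per-metric optimal threshold:
    argmax for DSC, argmin for the loss metrics, ties resolved to the
    smallest threshold.
    """
    grid = sorted(float(g) for g in grid)
    if not grid:
        raise ValueError("empty threshold grid")
    if any(not 0.0 < g <= 1.0 for g in grid):
        raise ValueError("thresholds must lie in (0, 1]")
    if len(model_masks_per_image) != len(references):
        raise ValueError("one reference per image is required")
    if not references:
        raise ValueError("at least one image is required")

    averages = [average_probability(masks, weights)
                for masks in model_masks_per_image]
    rows = []
    for p_thr in grid:
        recs = [evaluate(threshold_mask(avg, p_thr), ref,
                         include_surface=include_surface)
                for avg, ref in zip(averages, references)]
        row = {"p_thr": p_thr}
        for name in METRIC_NAMES:
            attr = name if name == "dsc" or name == "rvd" else f"{name}_mm"
            vals = np.array([getattr(r, attr) for r in recs], dtype=float)
            row[name] = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)

    optima: dict[str, float] = {}
    for name in METRIC_NAMES:
        col = table[name].to_numpy()
        best = np.argmax(col) if name == "dsc" else np.argmin(col)
        optima[name] = float(table["p_thr"].iloc[int(best)])
    return table, optima
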