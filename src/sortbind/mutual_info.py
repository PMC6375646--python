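"""Plug-in mutual information between model predictions and expression bins.

The model selection criterion of the whole inference stage: a candidate
energy matrix is judged by the mutual information I(ε; μ) between its
per-sequence energy predictions ε and the expression bins μ the sequences
were sorted into. Predictions are continuous, so they are discretized before
building the joint histogram. Two strategies exist:

``rank``
    equal-count bins on the prediction ranks. MI is then invariant under any
    strictly monotone transform of the predictions — exactly the invariance
    a linear energy model fitted by MI maximization relies on (scale and
    sign are "diffeomorphic modes" the data cannot determine).
``uniform``
    equal-width bins on the prediction values. Deliberately NOT
    monotone-invariant; used for scaling-factor inference, where the
    curvature of the ε→p_bound map is the only handle on the scale.
"""

from __future__ import annotations

import warnings

import numpy as np


def default_mi_bins(n_records: int) -> int:
    """Histogram resolution on the prediction axis: 1000, capped at N/50."""
    return max(2, min(1000, n_records // 50))


def _joint_entropy_mi(joint: np.ndarray, bias_correction: bool = False) -> float:
    """I(X;Y) in bits from an (unnormalized, nonnegative) joint count table.

    With ``bias_correction`` the Miller–Madow null expectation
    (K−1)(B−1)/(2N ln2), with K and B the occupied marginal bin counts, is
    subtracted; the result may then be slightly negative on null data.
    """
    total = joint.sum()
    if total <= 0:
        return 0.0
    p = joint / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    mi = float(np.nansum(terms))
    if bias_correction:
        k_occ = int((px > 0).sum())
        b_occ = int((py > 0).sum())
        mi -= (k_occ - 1) * (b_occ - 1) / (2.0 * total * np.log(2.0))
    return mi


def rank_bin(predictions: np.ndarray, counts: np.ndarray, mi_bins: int,
             rng: np.random.Generator | None = None) -> np.ndarray:
    """Assign each record to one of ``mi_bins`` equal-count bins by prediction rank.

    Counts weight the quantile grid, so each energy bin holds ~equal total
    reads. Ties are broken by a stable sort over a seeded shuffle of the
    record order, making the binning deterministic yet unbiased.
    """
    n = predictions.size
    order_input = np.arange(n)
    if rng is not None:
        order_input = rng.permutation(n)
    order = order_input[np.argsort(predictions[order_input], kind="stable")]
    csum = np.cumsum(counts[order])
    total = csum[-1]
    mid = csum - counts[order] / 2.0
    idx = np.minimum((mid / total * mi_bins).astype(np.int64), mi_bins - 1)
    out = np.empty(n, dtype=np.int64)
    out[order] = idx
    return out


def value_bin(predictions: np.ndarray, mi_bins: int) -> np.ndarray:
    """Equal-width bins spanning [min, max] of the predictions."""
    lo, hi = predictions.min(), predictions.max()
    if hi == lo:
        return np.zeros(predictions.size, dtype=np.int64)
    idx = ((predictions - lo) / (hi - lo) * mi_bins).astype(np.int64)
    return np.minimum(idx, mi_bins - 1)


def estimate_mutual_information(
    predictions,
    bins,
    counts=None,
    mi_bins: int | None = None,
    strategy: str = "rank",
    rng: np.random.Generator | None = None,
    bias_correction: bool = True,
) -> float:
    """Histogram MI (bits) between discretized predictions and expression bins.

    Parameters
    ----------
    predictions : per-record continuous model outputs
    bins : per-record expression bin indices
    counts : per-record read counts (default 1 each)
    mi_bins : prediction-axis resolution (default: 1000 capped at N/50)
    strategy : "rank" (monotone-invariant) or "uniform" (value binning)
    bias_correction : subtract the Miller–Madow finite-sample bias and floor
        at 0, so label-shuffled data scores ≈ 0 instead of the plug-in bias;
        set False for the raw plug-in estimate
    """
    predictions = np.asarray(predictions, dtype=float).ravel()
    bins = np.asarray(bins, dtype=np.int64).ravel()
    counts = (np.ones_like(bins) if counts is None
              else np.asarray(counts, dtype=np.int64).ravel())
    if not (predictions.size == bins.size == counts.size):
        raise ValueError("predictions, bins and counts must have equal length")
    n_expr = int(bins.max()) + 1 if bins.size else 0
    if np.unique(bins).size < 2:
        warnings.warn("single expression bin represented: MI is 0", stacklevel=2)
        return 0.0
    if mi_bins is None:
        mi_bins = default_mi_bins(predictions.size)
    if strategy == "rank":
        e_idx = rank_bin(predictions, counts, mi_bins, rng=rng)
    elif strategy == "uniform":
        e_idx = value_bin(predictions, mi_bins)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    joint = np.zeros((mi_bins, n_expr), dtype=float)
    np.add.at(joint, (e_idx, bins), counts)
    mi = _joint_entropy_mi(joint, bias_correction=bias_correction)
    return max(mi, 0.0) if bias_correction else mi
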