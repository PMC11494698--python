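"""Evaluation of predicted strength classes against measured repression.

Measured repression is continuous; it is binned into four ordinal classes by
three thresholds chosen to maximise agreement with the predictions
(exhaustive search over midpoints between consecutive distinct values, so
the optimum is global and depends only on the ranks of the data). The fit
is summarised by a 4x4 confusion matrix and its accuracy, and compared with
two null models:

* permutation null — observed labels shuffled, thresholds held fixed;
* bootstrap random-guess null — predictions replaced by uniform guesses,
  whose expected accuracy is 1/4 regardless of the observed distribution.

Both nulls report mean, sd, the percent of null runs the real model
outperformed, an empirical two-tailed p (with +1 correction) and a
normal-approximation two-tailed p.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import (
    CLASS_ORDER,
    EvalResult,
    NullComparison,
    ParameterError,
)

logger = logging.getLogger(__name__)

N_CLASSES = 4


def class_to_ordinal(labels: Sequence[str]) -> np.ndarray:
    """Map class names (weak..strongest) to ordinal codes 1..4."""
    lut = {name: i + 1 for i, name in enumerate(CLASS_ORDER)}
    try:
        return np.array([lut[l] for l in labels], dtype=int)
    except KeyError as e:
        raise ParameterError(f"unknown class label {e.args[0]!r}") from e


def bin_observed(
    values: Sequence[float], thresholds: Sequence[float]
) -> np.ndarray:
    """Bin continuous repression values into ordinal classes 1..4.

    Intervals are left-closed: a value equal to a threshold falls in the
    higher class. Higher repression means a higher class.
    """
    t = np.asarray(thresholds, dtype=float)
    if t.shape != (3,) or not np.all(np.diff(t) > 0):
        raise ParameterError("thresholds must be 3 strictly increasing values")
    return np.searchsorted(t, np.asarray(values, dtype=float), side="right") + 1


def _boundary_values(sorted_distinct: np.ndarray) -> np.ndarray:
    """Candidate threshold value for each cut position 0..m.

    Position i cuts between distinct value i-1 and i; midpoints inside the
    range, sentinels one unit outside it at the ends.
    """
    d = sorted_distinct
    vals = np.empty(d.size + 1)
    vals[0] = d[0] - 1.0
    vals[-1] = d[-1] + 1.0
    vals[1:-1] = (d[:-1] + d[1:]) / 2.0
    return vals


def optimize_thresholds(
    values: Sequence[float], predicted: Sequence[int]
) -> tuple[float, float, float]:
    """Thresholds maximising bin-then-match accuracy against predictions.

    The search is exhaustive over all (possibly coincident) cut positions
    between consecutive sorted distinct values, including positions below
    the minimum and above the maximum, so degenerate solutions that empty
    one or more classes are admissible. Ties are broken toward the
    lexicographically smallest threshold triple. Coincident cut positions
    are realised as strictly increasing thresholds by epsilon offsets small
    enough not to cross any data point.
    """
    v = np.asarray(values, dtype=float)
    p = np.asarray(predicted, dtype=int)
    if v.size != p.size:
        raise ParameterError("values and predicted must have equal length")
    if v.size < 4:
        raise ParameterError("need at least 4 values")
    distinct = np.unique(v)
    if distinct.size < 4:
        raise ParameterError("need at least 4 distinct values")
    order = np.argsort(v, kind="stable")
    sp = p[order]
    # prefix[k, i] = number of the first i sorted items predicted class k+1
    prefix = np.zeros((N_CLASSES, v.size + 1), dtype=int)
    for k in range(N_CLASSES):
        prefix[k, 1:] = np.cumsum(sp == k + 1)
    # item-index of each candidate cut position (0..m distinct boundaries)
    cut_items = np.concatenate(([0], np.searchsorted(v[order], distinct,
                                                     side="right")))
    bvals = _boundary_values(distinct)
    m = cut_items.size
    # accuracy(b1,b2,b3) separates into X[b1] + Y[b2] + Z[b3] + const
    p1, p2, p3, p4 = (prefix[k, cut_items] for k in range(N_CLASSES))
    x = p1 - p2
    y = p2 - p3
    z = p3 - p4
    total = x[:, None, None] + y[None, :, None] + z[None, None, :]
    i1, i2, i3 = np.meshgrid(np.arange(m), np.arange(m), np.arange(m),
                             indexing="ij")
    total = np.where((i1 <= i2) & (i2 <= i3), total, np.iinfo(np.int64).min)
    best = total.max()
    # np.argwhere scans in C order, i.e. lexicographic (b1, b2, b3), and
    # boundary values increase with index, so the first hit is the
    # lexicographically smallest threshold triple.
    b1, b2, b3 = np.argwhere(total == best)[0]
    gaps = np.diff(distinct)
    eps = min(float(gaps.min()) / 2.0, 1.0) / 4.0
    t1 = bvals[b1]
    t2 = bvals[b2] if b2 > b1 else t1 + eps
    t3 = bvals[b3] if b3 > b2 else t2 + eps
    assert t1 < t2 < t3
    return (float(t1), float(t2), float(t3))


def confusion_and_accuracy(
    predicted: Sequence[int], observed: Sequence[int]
) -> tuple[np.ndarray, float]:
    """4x4 confusion matrix (rows predicted, cols observed) and accuracy."""
    p = np.asarray(predicted, dtype=int)
    o = np.asarray(observed, dtype=int)
    if p.size != o.size:
        raise ParameterError("predicted and observed must have equal length")
    if p.size == 0:
        raise ParameterError("empty inputs")
    conf = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(conf, (p - 1, o - 1), 1)
    return conf, float(np.trace(conf) / p.size)


def _summarize_null(
    null_acc: np.ndarray, real_acc: float, n_iter: int, seed: int
) -> NullComparison:
    null_mean = float(null_acc.mean())
    null_sd = float(null_acc.std(ddof=1)) if null_acc.size > 1 else 0.0
    k_ge = int(np.sum(null_acc >= real_acc))
    k_le = int(np.sum(null_acc <= real_acc))
    p_emp = min(1.0, 2.0 * min((k_ge + 1) / (n_iter + 1),
                               (k_le + 1) / (n_iter + 1)))
    if null_sd > 0:
        zval = (real_acc - null_mean) / null_sd
        p_norm = float(2.0 * stats.norm.sf(abs(zval)))
    else:
        p_norm = 1.0 if real_acc == null_mean else 0.0
    return NullComparison(
        accuracies=null_acc,
        real_accuracy=real_acc,
        null_mean=null_mean,
        null_sd=null_sd,
        percentile_outperformed=float(np.mean(null_acc < real_acc) * 100.0),
        p_two_tailed_empirical=p_emp,
        p_two_tailed_normal=p_norm,
        n_iterations=n_iter,
        seed=seed,
    )


def permutation_null(
    predicted: Sequence[int],
    observed: Sequence[int],
    n_perm: int = 1000,
    seed: int = 0,
) -> NullComparison:
    """Accuracy null from uniformly shuffling the observed labels.

    The thresholds that produced the observed classes stay fixed, so only
    the pairing of predicted and observed labels is broken.
    """
    p = np.asarray(predicted, dtype=int)
    o = np.asarray(observed, dtype=int)
    if p.size < 4:
        raise ParameterError("need at least 4 items")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    if n_perm < 100:
        logger.warning("n_perm=%d gives a coarse p-value resolution", n_perm)
    rng = np.random.default_rng(seed)
    real_acc = float(np.mean(p == o))
    null_acc = np.empty(n_perm)
    for i in range(n_perm):
        null_acc[i] = np.mean(p == rng.permutation(o))
    return _summarize_null(null_acc, real_acc, n_perm, seed)


def expected_permutation_accuracy(
    predicted: Sequence[int], observed: Sequence[int]
) -> float:
    """Closed-form permutation-null mean: sum_c n_pred(c) n_obs(c) / n^2."""
    p = np.asarray(predicted, dtype=int)
    o = np.asarray(observed, dtype=int)
    n = p.size
    return float(
        sum(np.sum(p == c) * np.sum(o == c) for c in range(1, N_CLASSES + 1))
        / n**2
    )


def bootstrap_random_null(
    observed: Sequence[int],
    real_accuracy: float,
    n_runs: int = 1000,
    seed: int = 0,
) -> NullComparison:
    """Accuracy null from uniform random guessing over the four classes.

    Each run draws n independent uniform class guesses against the fixed
    observed labels; the expected accuracy is 0.25 whatever the observed
    class distribution.
    """
    o = np.asarray(observed, dtype=int)
    if o.size < 1:
        raise ParameterError("observed must be non-empty")
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    guesses = rng.integers(1, N_CLASSES + 1, size=(n_runs, o.size))
    null_acc = (guesses == o[None, :]).mean(axis=1)
    return _summarize_null(null_acc, real_accuracy, n_runs, seed)


def evaluate_predictions(
    predicted_classes: Sequence[str] | Sequence[int],
    observed_values: Sequence[float],
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalResult:
    """Full evaluation: threshold fit, confusion matrix and both nulls.

    ``predicted_classes`` may be class names (weak..strongest) or ordinal
    codes 1..4; ``observed_values`` is the continuous repression scale
    (e.g. 1 - relative GFP). The two nulls use independent substreams of
    ``seed``.
    """
    if len(predicted_classes) and isinstance(predicted_classes[0], str):
        pred = class_to_ordinal(predicted_classes)  # type: ignore[arg-type]
    else:
        pred = np.asarray(predicted_classes, dtype=int)
    if pred.min() < 1 or pred.max() > N_CLASSES:
        raise ParameterError("predicted classes must be in 1..4")
    thresholds = optimize_thresholds(observed_values, pred)
    observed = bin_observed(observed_values, thresholds)
    conf, acc = confusion_and_accuracy(pred, observed)
    s1, s2 = np.random.SeedSequence(seed).spawn(2)
    perm = permutation_null(pred, observed, n_perm=n_perm,
                            seed=int(s1.generate_state(1)[0] % 2**31))
    boot = bootstrap_random_null(observed, acc, n_runs=n_boot,
                                 seed=int(s2.generate_state(1)[0] % 2**31))
    return EvalResult(
        thresholds=thresholds,
        confusion=conf,
        accuracy=acc,
        n=int(pred.size),
        seed=seed,
        permutation=perm,
        bootstrap=boot,
    )
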