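"""Affinity transforms and evaluation metrics for affinity regression.

Implements the standard metric suite for drug-target binding affinity
benchmarks: MSE, concordance index (CI), the external-validation statistic
rm^2, and -- after binarizing affinities at the conventional activity
thresholds (pKd >= 7 for Kd-based data, KIBA score < 12.1) -- area under the
precision-recall curve and accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

DatasetKind = Literal["davis", "kiba", "synthetic"]

#: binarization thresholds: (threshold, True if label-1 means value >= threshold)
_BINARIZATION = {
    "davis": (7.0, True),
    "kiba": (12.1, False),
    # synthetic affinities are generated on a pKd-like scale; same rule as davis
    "synthetic": (7.0, True),
}


def pkd_transform(kd: float | np.ndarray) -> float | np.ndarray:
    """Map a dissociation constant in nM to pKd = -log10(Kd / 1e9).

    Kd = 100 nM maps to pKd = 7, the conventional activity threshold.
    """
    kd = np.asarray(kd, dtype=np.float64)
    if np.any(kd <= 0):
        raise ValueError("Kd values must be positive")
    out = -np.log10(kd / 1e9)
    return float(out) if out.ndim == 0 else out


def _as_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y_true, dtype=np.float64).ravel()
    p = np.asarray(y_pred, dtype=np.float64).ravel()
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.size} observed vs {p.size} predicted")
    if y.size == 0:
        raise ValueError("empty input")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(p))):
        raise ValueError("inputs must be finite (no NaN/inf)")
    return y, p


def mse(y_true, y_pred) -> float:
    """Mean squared error, the training objective."""
    y, p = _as_pair(y_true, y_pred)
    return float(np.mean((p - y) ** 2))


def concordance_index(y_true, y_pred) -> float:
    """Probability that two pairs with distinct true affinity are ranked in
    the same order by the predictions, with half-credit for prediction ties.

    Over all ordered pairs (i, j) with y_i > y_j the step function of the
    prediction difference contributes 1 (concordant), 0.5 (tied prediction)
    or 0 (discordant); the sum is divided by the number of such comparable
    pairs.  Invariant under strictly increasing transforms of the
    predictions.  Rejects input whose true values are all equal (no
    comparable pair exists).
    """
    y, p = _as_pair(y_true, y_pred)
    if y.size < 2:
        raise ValueError("concordance index needs at least two observations")
    # all-pairs comparison; memory O(n^2) is fine at benchmark-fold sizes
    dy = y[:, None] - y[None, :]
    dp = p[:, None] - p[None, :]
    comparable = dy > 0
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("all observed values are equal; CI undefined")
    credit = np.where(dp > 0, 1.0, np.where(dp == 0, 0.5, 0.0))
    return float(credit[comparable].sum() / n_pairs)


@dataclass(frozen=True)
class RmSquared:
    """rm^2 with its intermediates: r^2 (with intercept), r0^2 (through the
    origin at slope k), and the origin slope k."""

    rm2: float
    r2: float
    r02: float
    k: float


def rm_squared(y_true, y_pred) -> RmSquared:
    """External-validation statistic rm^2 = r^2 * (1 - sqrt(r^2 - r0^2)).

    r^2 is the squared Pearson correlation of observed vs predicted; r0^2 is
    the coefficient of determination of the no-intercept regression of
    observed on predicted with slope k = sum(y*p)/sum(p^2).  Values above 0.5
    are conventionally read as an acceptable model.  When r0^2 exceeds r^2
    (possible on pathological data) the square-root argument is clamped at
    zero and a warning is issued.
    """
    y, p = _as_pair(y_true, y_pred)
    sy = y - y.mean()
    sp = p - p.mean()
    den = (sy**2).sum() * (sp**2).sum()
    if den == 0:
        raise ValueError("rm^2 undefined: zero variance in observed or predicted")
    sp2 = (p**2).sum()
    if sp2 == 0:
        raise ValueError("rm^2 undefined: predictions are identically zero")
    r2 = float((sy * sp).sum() ** 2 / den)
    k = float((y * p).sum() / sp2)
    r02 = float(1.0 - ((y - k * p) ** 2).sum() / (sy**2).sum())
    arg = r2 - r02
    if arg < 0:
        warnings.warn(
            "r0^2 exceeds r^2; clamping sqrt argument at 0 (rm^2 = r^2)",
            RuntimeWarning,
            stacklevel=2,
        )
        arg = 0.0
    return RmSquared(rm2=float(r2 * (1.0 - np.sqrt(arg))), r2=r2, r02=r02, k=k)


@dataclass(frozen=True)
class BinarizationRule:
    """Threshold rule turning affinities into binding / no-binding labels."""

    kind: DatasetKind

    def __post_init__(self) -> None:
        if self.kind not in _BINARIZATION:
            raise ValueError(f"unknown dataset kind {self.kind!r}")

    @property
    def threshold(self) -> float:
        return _BINARIZATION[self.kind][0]

    @property
    def greater_is_positive(self) -> bool:
        return _BINARIZATION[self.kind][1]

    def orient(self, scores) -> np.ndarray:
        """Continuous scores oriented so that larger means more likely label 1."""
        s = np.asarray(scores, dtype=np.float64)
        return s if self.greater_is_positive else -s


def binarize(values, rule: BinarizationRule | DatasetKind) -> np.ndarray:
    """Apply the activity threshold: pKd-like data are positive at >= 7,
    KIBA scores are positive strictly below 12.1."""
    if not isinstance(rule, BinarizationRule):
        rule = BinarizationRule(rule)
    v = np.asarray(values, dtype=np.float64)
    if rule.greater_is_positive:
        return (v >= rule.threshold).astype(np.int64)
    return (v < rule.threshold).astype(np.int64)


def auc_pr(labels, scores) -> float:
    """Area under the precision-recall curve by step-wise summation.

    Equals average precision: sum over positives, in decreasing-score order,
    of precision at each recall step (non-interpolated).  Requires both
    classes present.  Ties in score are handled by grouping: all points with
    an equal score enter the curve together.
    """
    t = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    if t.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.isin(t, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    n_pos = int(t.sum())
    if n_pos == 0 or n_pos == t.size:
        raise ValueError("AUC-PR undefined with a single class")
    order = np.argsort(-s, kind="stable")
    t_sorted = t[order]
    s_sorted = s[order]
    tp = np.cumsum(t_sorted)
    n_seen = np.arange(1, t.size + 1)
    # collapse tied scores: keep the last index of each tie group
    last_of_group = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp_g = tp[last_of_group]
    n_g = n_seen[last_of_group]
    precision = tp_g / n_g
    recall = tp_g / n_pos
    d_recall = np.diff(np.r_[0.0, recall])
    return float((precision * d_recall).sum())


def accuracy(labels, predicted_labels) -> float:
    """Fraction of matching binary labels."""
    t = np.asarray(labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if t.size == 0:
        raise ValueError("empty input")
    return float(np.mean(t == p))


def evaluate_predictions(y_true, y_pred, kind: DatasetKind) -> dict[str, float]:
    """Compute the full metric report for one prediction set.

    Returns MSE, CI, rm^2 (with intermediates r2, r02), AUC-PR and accuracy.
    CI and AUC-PR are reported as NaN when undefined (constant truths or a
    single class after binarization) rather than silently averaged.
    """
    y, p = _as_pair(y_true, y_pred)
    rule = BinarizationRule(kind)
    out: dict[str, float] = {"mse": mse(y, p)}
    try:
        out["ci"] = concordance_index(y, p)
    except ValueError:
        out["ci"] = float("nan")
    try:
        rm = rm_squared(y, p)
        out["rm2"], out["r2"] = rm.rm2, rm.r2
    except ValueError:
        out["rm2"] = out["r2"] = float("nan")
    labels = binarize(y, rule)
    try:
        out["aupr"] = auc_pr(labels, rule.orient(p))
    except ValueError:
        out["aupr"] = float("nan")
    out["acc"] = accuracy(labels, binarize(p, rule))
    return out
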