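"""Feature ranking: Fisher ratio, POE+ACC greedy selection, mutual information.

Each scheme returns the k best-discriminating features (k = 10 by
default) between the two lesion classes.  Ties are broken by
lexicographic feature-name order so output is deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .errors import ParameterError

logger = logging.getLogger(__name__)

METHODS = ("fisher", "poe_acc", "mi")
DEFAULT_K = 10
DEFAULT_MI_BINS = 10


@dataclasses.dataclass
class SelectionResult:
    method: str
    ranked: list[tuple[str, float]]  # (feature name, score or criterion)
    k: int

    @property
    def features(self) -> list[str]:
        return [name for name, _ in self.ranked]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "k": self.k,
            "ranked": [[n, float(s)] for n, s in self.ranked],
        }


def _check_groups(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ParameterError("each class needs at least 2 lesions")
    return labels, ~labels


def fisher_scores(table: pd.DataFrame, labels) -> pd.Series:
    """Fisher coefficient per feature: between- over within-class variance.

    For two classes with proportions P1, P2, class means m1, m2 and class
    population variances v1, v2:  F = P1*P2*(m1 - m2)^2 / (P1*v1 + P2*v2).
    A feature with zero pooled within-class variance gets F = inf when the
    class means differ (trivially separating) and F = 0 when they agree.
    """
    pos, neg = _check_groups(labels)
    x = table.to_numpy(dtype=np.float64)
    n = x.shape[0]
    p1, p2 = pos.sum() / n, neg.sum() / n
    m1, m2 = x[pos].mean(axis=0), x[neg].mean(axis=0)
    v1, v2 = x[pos].var(axis=0), x[neg].var(axis=0)
    within = p1 * v1 + p2 * v2
    between = p1 * p2 * (m1 - m2) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = between / within
    f[(within == 0) & (between == 0)] = 0.0
    f[(within == 0) & (between > 0)] = np.inf
    return pd.Series(f, index=table.columns, name="fisher")


def poe(values: np.ndarray, labels: np.ndarray) -> float:
    """Probability of classification error of the best single threshold.

    Scans every midpoint between consecutive distinct sorted values (plus
    the two all-one-class rules) in both orientations and returns the
    minimum misclassified fraction.
    """
    labels = np.asarray(labels, dtype=bool)
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], labels[order]
    n_pos = int(ys.sum())
    # After cutting below position i (first i values on the low side):
    # rule "high side is positive" errs on low-side positives and
    # high-side negatives.
    pos_low = np.concatenate(([0], np.cumsum(ys)))  # positives among first i
    i_all = np.arange(n + 1)
    neg_high = (n - i_all) - (n_pos - pos_low)
    err_high_pos = pos_low + neg_high
    err_low_pos = n - err_high_pos
    # Valid cut positions: between distinct values, plus both extremes.
    distinct = np.flatnonzero(xs[1:] != xs[:-1]) + 1
    cuts = np.concatenate(([0], distinct, [n]))
    best = min(err_high_pos[cuts].min(), err_low_pos[cuts].min())
    return float(best / n)


def average_correlation(
    values: np.ndarray, selected: list[np.ndarray]
) -> float:
    """Mean absolute Pearson correlation with already-selected features."""
    if not selected:
        return 0.0
    rs = []
    for s in selected:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = np.corrcoef(values, s)[0, 1]
        rs.append(abs(r))
    return float(np.mean(rs))


def poe_acc_select(table: pd.DataFrame, labels, k: int = DEFAULT_K) -> SelectionResult:
    """Greedy POE+ACC selection.

    The first pick minimizes the single-feature probability of
    classification error (POE); each later pick minimizes POE(f) +
    ACC(f, S), the error plus the mean absolute correlation with the
    already-selected set S.  Constant features are excluded (their
    correlation is undefined).  The stored score is the criterion value
    at the time of the pick.
    """
    pos, _ = _check_groups(labels)
    if k > table.shape[1]:
        raise ParameterError(
            f"k = {k} exceeds the {table.shape[1]} available features"
        )
    x = table.to_numpy(dtype=np.float64)
    names = np.asarray(table.columns)
    n = x.shape[0]
    sd = x.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "excluding %d constant feature(s) from POE+ACC", int(constant.sum())
        )
    if k > int((~constant).sum()):
        raise ParameterError("too few non-constant features for k")
    # z-scores make Pearson correlation an inner product / n
    z = np.where(constant, 0.0, (x - x.mean(axis=0)) / np.where(sd == 0, 1, sd))
    poes = np.array(
        [np.inf if constant[i] else poe(x[:, i], pos) for i in range(x.shape[1])]
    )
    acc_sum = np.zeros(x.shape[1])
    available = ~constant
    ranked: list[tuple[str, float]] = []
    for step in range(k):
        crit = poes + (acc_sum / step if step else 0.0)
        crit = np.where(available, crit, np.inf)
        best = crit.min()
        tied = np.flatnonzero(crit <= best + 1e-12)
        pick = tied[np.argsort(names[tied])[0]]  # lexicographic tie-break
        ranked.append((str(names[pick]), float(crit[pick])))
        available[pick] = False
        acc_sum += np.abs(z.T @ z[:, pick]) / n
    return SelectionResult(method="poe_acc", ranked=ranked, k=k)


def mutual_information(
    table: pd.DataFrame, labels, bins: int = DEFAULT_MI_BINS
) -> pd.Series:
    """Mutual information (bits) between each binned feature and the class.

    Features are discretized into ``bins`` equal-width bins over their
    observed range; the plug-in MI of the bin/class contingency table is
    returned in bits.  Constant features get MI = 0.
    """
    pos, _ = _check_groups(labels)
    y = np.asarray(pos, dtype=int)
    out = {}
    for name in table.columns:
        v = table[name].to_numpy(dtype=np.float64)
        lo, hi = v.min(), v.max()
        if hi == lo:
            out[name] = 0.0
            continue
        b = np.minimum((bins * (v - lo) / (hi - lo)).astype(int), bins - 1)
        out[name] = float(mutual_info_score(y, b) / np.log(2.0))
    return pd.Series(out, name="mi")


def select_top(
    table: pd.DataFrame,
    labels,
    method: str,
    k: int = DEFAULT_K,
    mi_bins: int = DEFAULT_MI_BINS,
) -> SelectionResult:
    """Top-k features under one of the three selection schemes."""
    if method not in METHODS:
        raise ParameterError(f"unknown selection method {method!r}")
    if k > table.shape[1]:
        raise ParameterError(
            f"k = {k} exceeds the {table.shape[1]} available features"
        )
    if method == "poe_acc":
        return poe_acc_select(table, labels, k=k)
    scores = (
        fisher_scores(table, labels)
        if method == "fisher"
        else mutual_information(table, labels, bins=mi_bins)
    )
    order = sorted(scores.index, key=lambda n: (-scores[n], n))
    ranked = [(n, float(scores[n])) for n in order[:k]]
    return SelectionResult(method=method, ranked=ranked, k=k)
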