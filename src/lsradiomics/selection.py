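"""Filter-based feature selection: Fisher coefficient, POE+ACC, mutual information.

Each method ranks features and keeps the top k (default 10); running all
three yields the combined 3k-feature list (duplicates kept by default, as
the downstream analyses expect a fixed count of 3 x k).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .tables import FeatureTable

logger = logging.getLogger(__name__)

METHODS = ("fisher", "poeacc", "mi")


@dataclass
class SelectionResult:
    method: str
    ranked: list[str]  # best first
    scores: dict[str, float]
    selected: list[str]  # top-k slice of ranked


def fisher_score(x: np.ndarray, labels: np.ndarray) -> float:
    """Between-class over within-class variance ratio F = D / V.

    D = sum_k P_k (mu_k - mu)^2 and V = sum_k P_k sigma_k^2 with class priors
    P_k and population variances. Perfect separation (V = 0, D > 0) returns
    +inf so such features rank first; scale-invariant by construction.
    """
    x = np.asarray(x, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ConfigurationError("Fisher score needs >= 2 classes")
    n = len(x)
    mu = float(x.mean())
    d = 0.0
    v = 0.0
    for k in classes:
        xk = x[labels == k]
        pk = len(xk) / n
        d += pk * (float(xk.mean()) - mu) ** 2
        v += pk * float(xk.var())
    if v == 0.0:
        return float("inf") if d > 0 else 0.0
    return d / v


def poe(x: np.ndarray, labels: np.ndarray) -> float:
    """Probability of classification error of the best single threshold on x.

    Both polarities are evaluated at every cut between sorted values; the
    minimal misclassified fraction is returned.
    """
    x = np.asarray(x, dtype=np.float64)
    labels = np.asarray(labels)
    n = len(x)
    order = np.argsort(x, kind="stable")
    lab = labels[order]
    n1 = int((labels == 1).sum())
    n2 = n - n1
    # class-1 counts in the left part after each possible cut (0..n)
    c1_left = np.r_[0, np.cumsum(lab == 1)]
    c2_left = np.arange(n + 1) - c1_left
    # polarity A: left -> class 1, right -> class 2; errors = c2_left + (n1 - c1_left)
    err_a = c2_left + (n1 - c1_left)
    err_b = c1_left + (n2 - c2_left)
    # cuts between ties are invalid; mask positions splitting equal values
    valid = np.ones(n + 1, dtype=bool)
    xs = x[order]
    valid[1:n] = xs[1:] > xs[:-1]
    best = min(err_a[valid].min(), err_b[valid].min())
    return float(best) / n


def within_class_abs_corr(a: np.ndarray, b: np.ndarray, labels: np.ndarray) -> float:
    """|Pearson correlation| pooled within classes (class means removed).

    This measures redundancy between two features beyond the class signal:
    two features that both separate the classes are not penalised for that
    shared separation, only for co-varying within each class. Exact
    duplicates still score 1.
    """
    num = va = vb = 0.0
    for k in np.unique(labels):
        aa = a[labels == k]
        bb = b[labels == k]
        aa = aa - aa.mean()
        bb = bb - bb.mean()
        num += float((aa * bb).sum())
        va += float((aa * aa).sum())
        vb += float((bb * bb).sum())
    if va == 0.0 or vb == 0.0:
        # class-constant feature: fall back to the pooled correlation so
        # exact duplicates are still recognised as fully redundant
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return abs(float(np.corrcoef(a, b)[0, 1]))
    return abs(num / np.sqrt(va * vb))


def poe_acc_rank(table: FeatureTable, k: int = 10) -> SelectionResult:
    """Greedy forward selection minimising POE(f) + ACC(f | selected).

    ACC is the mean absolute within-class Pearson correlation between the
    candidate and the already-selected features (0 for the first pick); ties
    break on feature-name order.
    """
    if k <= 0:
        raise ConfigurationError("k must be > 0")
    names = table.feature_names
    x = table.matrix()
    labels = table.labels
    poes = {name: poe(x[:, j], labels) for j, name in enumerate(names)}
    cols = {name: x[:, j] for j, name in enumerate(names)}

    remaining = sorted(names)
    selected: list[str] = []
    scores: dict[str, float] = {}
    while remaining and len(selected) < min(k, len(names)):
        best_name, best_score = None, np.inf
        for name in remaining:
            acc = (
                np.mean(
                    [within_class_abs_corr(cols[name], cols[s], labels) for s in selected]
                )
                if selected
                else 0.0
            )
            score = poes[name] + float(acc)
            if score < best_score:  # ties keep the lexicographically first
                best_name, best_score = name, score
        selected.append(best_name)
        scores[best_name] = best_score
        remaining.remove(best_name)
    # lower greedy score = better; ranked is selection order
    return SelectionResult(method="poeacc", ranked=selected + remaining, scores=scores, selected=selected)


def mutual_information_score(x: np.ndarray, labels: np.ndarray, n_bins: int = 10) -> float:
    """Mutual information (bits) between equal-frequency-binned x and the labels.

    Equal-frequency binning makes the score invariant to monotone transforms
    of the feature; a constant feature scores 0.
    """
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    x = np.asarray(x, dtype=np.float64)
    labels = np.asarray(labels)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    bins = np.searchsorted(edges, x, side="right")
    joint = np.zeros((bins.max() + 1, 2))
    for b, lab in zip(bins, labels):
        joint[b, int(lab == 2)] += 1
    joint /= joint.sum()
    pb = joint.sum(axis=1, keepdims=True)
    pc = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (pb * pc))
    return float(np.nansum(terms[joint > 0]))


def select_top(table: FeatureTable, method: str, k: int = 10, n_bins: int = 10) -> SelectionResult:
    """Rank all features by one method and keep the top k."""
    if k <= 0:
        raise ConfigurationError("k must be > 0")
    if method not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}; choose from {METHODS}")
    names = table.feature_names
    if k > len(names):
        warnings.warn(f"k={k} exceeds the {len(names)} available features; returning all")
        k = len(names)
    if method == "poeacc":
        return poe_acc_rank(table, k)
    x = table.matrix()
    if method == "fisher":
        scores = {n: fisher_score(x[:, j], table.labels) for j, n in enumerate(names)}
    else:
        scores = {
            n: mutual_information_score(x[:, j], table.labels, n_bins)
            for j, n in enumerate(names)
        }
    ranked = sorted(names, key=lambda n: (-scores[n], n))
    return SelectionResult(method=method, ranked=ranked, scores=scores, selected=ranked[:k])


def select_all_methods(
    table: FeatureTable, k: int = 10, *, dedup: bool = False
) -> tuple[dict[str, SelectionResult], list[str]]:
    """Top-k per method plus the combined list (3k names, duplicates kept
    unless ``dedup``)."""
    results = {m: select_top(table, m, k) for m in METHODS}
    combined: list[str] = []
    for m in METHODS:
        combined += results[m].selected
    dupes = len(combined) - len(set(combined))
    if dupes:
        logger.info("combined selection contains %d duplicate feature(s)", dupes)
    if dedup:
        combined = list(dict.fromkeys(combined))
    return results, combined
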