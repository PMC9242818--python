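"""The four B11-style analyses and the misclassification-rate report.

All four classifiers are validated leave-one-out (LOO) by default, matching
a single reported misclassification rate (MCR) on one cohort with no held-out
set. Features are z-scored inside each training fold only (no leakage from
the held-out sample):

* RDA ("raw data analysis"): 1-nearest-neighbour on the z-scored features.
* PCA: principal components capturing >= 95% training variance, then 1-NN.
* LDA: Fisher linear discriminant with pooled covariance (ridge-regularised
  when singular).
* NDA (nonlinear): a single-hidden-layer feed-forward network with logistic
  activations, fixed architecture and seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .errors import ConfigurationError
from .tables import FeatureTable

logger = logging.getLogger(__name__)

METHODS = ("rda", "pca", "lda", "nda")


@dataclass
class ClassifyResult:
    method: str
    misclassified: int
    total: int
    mcr: float  # percent
    predictions: np.ndarray

    def cell(self) -> str:
        return format_mcr_cell(self.misclassified, self.total)


def format_mcr_cell(misclassified: int, total: int) -> str:
    """Render ``k/n (pp.pp%)`` with two decimals, half-up rounding."""
    pct = (Decimal(100) * Decimal(misclassified) / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return f"{misclassified}/{total} ({pct}%)"


def _result(method: str, predictions: np.ndarray, labels: np.ndarray) -> ClassifyResult:
    wrong = int((predictions != labels).sum())
    total = len(labels)
    return ClassifyResult(
        method=method,
        misclassified=wrong,
        total=total,
        mcr=100.0 * wrong / total,
        predictions=predictions,
    )


def _zscore(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (other - mu) / sd


def _nn_predict(train_x: np.ndarray, train_y: np.ndarray, query: np.ndarray) -> int:
    d2 = ((train_x - query) ** 2).sum(axis=1)
    return int(train_y[int(np.argmin(d2))])


def rda(table: FeatureTable) -> ClassifyResult:
    """Raw-data analysis: LOO 1-nearest-neighbour on z-scored features."""
    x, y = table.matrix(), table.labels
    preds = np.empty(len(y), dtype=int)
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        tr, te = _zscore(x[keep], x[i : i + 1])
        preds[i] = _nn_predict(tr, y[keep], te[0])
    return _result("rda", preds, y)


def pca_analysis(table: FeatureTable, n_components: int | float | None = None) -> ClassifyResult:
    """PCA (default: components reaching 95% variance) then LOO 1-NN."""
    x, y = table.matrix(), table.labels
    if n_components is None:
        n_components = 0.95
    preds = np.empty(len(y), dtype=int)
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        tr, te = _zscore(x[keep], x[i : i + 1])
        nc = n_components
        if isinstance(nc, float) and not (0 < nc < 1):
            raise ConfigurationError("fractional n_components must be in (0, 1)")
        if isinstance(nc, (int, np.integer)):
            nc = min(int(nc), min(tr.shape))
        pca = PCA(n_components=nc, svd_solver="full")
        tr_p = pca.fit_transform(tr)
        preds[i] = _nn_predict(tr_p, y[keep], pca.transform(te)[0])
    return _result("pca", preds, y)


def _lda_fit_predict(tr: np.ndarray, ytr: np.ndarray, te: np.ndarray) -> int:
    classes = np.unique(ytr)
    n, p = tr.shape
    means = {k: tr[ytr == k].mean(axis=0) for k in classes}
    pooled = np.zeros((p, p))
    for k in classes:
        xk = tr[ytr == k] - means[k]
        pooled += xk.T @ xk
    pooled /= max(n - len(classes), 1)
    # ridge-regularise when singular / ill-conditioned (e.g. p > n)
    if p >= n or np.linalg.cond(pooled) > 1e8:
        logger.warning("LDA pooled covariance ill-conditioned; applying ridge")
        pooled = pooled + 1e-3 * (np.trace(pooled) / p + 1e-12) * np.eye(p)
    inv = np.linalg.pinv(pooled)
    best_k, best_score = None, -np.inf
    for k in classes:
        prior = float((ytr == k).mean())
        mk = means[k]
        score = float(te @ inv @ mk - 0.5 * mk @ inv @ mk + np.log(prior))
        if score > best_score:
            best_k, best_score = int(k), score
    return best_k


def lda(table: FeatureTable) -> ClassifyResult:
    """Fisher linear discriminant (pooled covariance), LOO."""
    x, y = table.matrix(), table.labels
    preds = np.empty(len(y), dtype=int)
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        tr, te = _zscore(x[keep], x[i : i + 1])
        preds[i] = _lda_fit_predict(tr, y[keep], te[0])
    return _result("lda", preds, y)


def nda(
    table: FeatureTable,
    hidden_units: int = 6,
    seed: int = 0,
    scheme: str = "loo",
    n_folds: int = 10,
    max_iter: int = 300,
) -> ClassifyResult:
    """Nonlinear discriminant analysis: small logistic-activation network.

    Deterministic for a fixed seed. ``scheme`` selects leave-one-out or
    stratified k-fold validation (k-fold is much cheaper when the analysis is
    repeated many times, e.g. in permutation nulls).
    """
    if scheme not in ("loo", "kfold"):
        raise ConfigurationError(f"unknown validation scheme {scheme!r}")
    x, y = table.matrix(), table.labels
    preds = np.empty(len(y), dtype=int)

    def _fit_predict(tr, ytr, te):
        clf = MLPClassifier(
            hidden_layer_sizes=(hidden_units,),
            activation="logistic",
            solver="lbfgs",
            max_iter=max_iter,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings on tiny folds
            clf.fit(tr, ytr)
        return clf.predict(te)

    if scheme == "loo":
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            tr, te = _zscore(x[keep], x[i : i + 1])
            preds[i] = _fit_predict(tr, y[keep], te)[0]
    else:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for tr_idx, te_idx in skf.split(x, y):
            tr, te = _zscore(x[tr_idx], x[te_idx])
            preds[te_idx] = _fit_predict(tr, y[tr_idx], te)
    return _result("nda", preds, y)


def run_method(table: FeatureTable, method: str, **kwargs) -> ClassifyResult:
    if method == "rda":
        return rda(table)
    if method == "pca":
        return pca_analysis(table, **kwargs)
    if method == "lda":
        return lda(table)
    if method == "nda":
        return nda(table, **kwargs)
    raise ConfigurationError(f"unknown method {method!r}; choose from {METHODS}")


def mcr_report(grid: dict[str, dict[str, ClassifyResult]]) -> str:
    """Render the selection x classifier grid with ``k/n (pp.pp%)`` cells.

    ``grid`` maps selection-method name -> classifier name -> result.
    """
    classifiers = ["rda", "pca", "lda", "nda"]
    header = [""] + [c.upper() for c in classifiers]
    rows = [header]
    for sel_name, results in grid.items():
        row = [sel_name]
        for c in classifiers:
            row.append(results[c].cell() if c in results else "-")
        rows.append(row)
    widths = [max(len(r[j]) for r in rows) for j in range(len(header))]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip() for r in rows]
    return "\n".join(lines)
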