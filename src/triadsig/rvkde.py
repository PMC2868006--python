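"""Relaxed variable kernel density estimation (RVKDE) classification.

Each training sample ``s_i`` gets its own Gaussian bandwidth derived from
``R(s_i)``, the distance to its ``ks``-th nearest other training sample:

    sigma_i = beta * (V_m(R(s_i)) / ks) ** (1/m)

where ``V_m(R) = pi^(m/2) R^m / Gamma(m/2 + 1)`` is the volume of the
m-ball of radius R -- beta times the per-neighbour volume share of the
ks-NN ball, radius-equivalenced.  This closed form is a reconstruction
built from the estimator's stated ingredients (R(s_i), ks, the Gamma
function); all volume terms are evaluated in log-space because m can be
large (686 for pair features).

The estimated density at a query v is the average of per-sample Gaussian
kernels; for efficiency only the ``kt`` nearest training samples of v
enter the sum (``kt = n`` recovers the full estimator).

Binary classification builds one estimator per class and predicts the
class with the larger likelihood ``L_j(v) = |S_j|**alpha * f_j(v)``,
``|S_j|`` the class size; ``alpha`` exponentiates the class prior
(alpha = 1 is plain prior weighting, smaller values temper imbalance).
The continuous decision score is the log-likelihood ratio, positive for
the interacting class; ties score 0 and are resolved to the negative
(majority) class.  Hyperparameters (alpha, beta, ks, kt) are selected by
grid search maximising the F-measure of a stratified k-fold
cross-validation.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: Default hyperparameter grid for cross-validated selection.
DEFAULT_GRID: dict[str, list] = {
    "alpha": [0.5, 1.0],
    "beta": [0.25, 0.5, 1.0, 2.0],
    "ks": [1, 3, 7],
    "kt": [20, 50, 100],
}


@dataclass
class KDEModel:
    """Per-class density estimator: samples plus per-sample bandwidths."""

    samples: np.ndarray      # (n, m)
    bandwidths: np.ndarray   # (n,), all > 0
    beta: float
    ks: int

    def __post_init__(self):
        self._nn = NearestNeighbors().fit(self.samples)
        # Per-sample log of the kernel normalisation (2*pi)^(-m/2) sigma^(-m).
        m = self.dim
        self._log_const = -0.5 * m * np.log(2 * np.pi) - m * np.log(self.bandwidths)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def dim(self) -> int:
        return self.samples.shape[1]


def _bandwidths_from_radii(R: np.ndarray, m: int, beta: float, ks: int,
                           floor_scale: float = 1e-8) -> np.ndarray:
    """sigma_i = beta * (V_m(R_i)/ks)^(1/m), computed in log-space.

    Duplicate training points give R_i = 0; their bandwidth is floored at
    ``floor_scale`` times the mean positive bandwidth to avoid singular
    kernels.
    """
    with np.errstate(divide="ignore"):
        log_sigma = (
            np.log(beta)
            + 0.5 * np.log(np.pi)
            + np.log(R)
            - (gammaln(m / 2 + 1) + np.log(ks)) / m
        )
    sigma = np.exp(log_sigma)
    positive = sigma > 0
    if not positive.all():
        if not positive.any():
            raise ValueError(
                "all ks-NN radii are zero (every training point duplicated); "
                "cannot derive bandwidths"
            )
        floor = floor_scale * sigma[positive].mean()
        sigma = np.where(positive, sigma, floor)
        logger.warning("floored %d zero bandwidth(s) from duplicate points",
                       int((~positive).sum()))
    return sigma


def fit_kde(samples: np.ndarray, *, beta: float = 1.0, ks: int = 5) -> KDEModel:
    """Fit an RVKDE to a sample set.

    ``R(s_i)`` is the distance from ``s_i`` to its ks-th nearest *other*
    training sample (Euclidean), requiring at least ks + 1 samples.
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2:
        raise ValueError("samples must be a 2-D array (n, m)")
    n = X.shape[0]
    if ks < 1:
        raise ValueError("ks must be >= 1")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if n < ks + 1:
        raise ValueError(f"need at least ks + 1 = {ks + 1} samples, got {n}")
    nn = NearestNeighbors(n_neighbors=ks + 1).fit(X)
    dist, _ = nn.kneighbors(X)
    R = dist[:, ks]  # ks-th neighbour excluding self
    sigma = _bandwidths_from_radii(R, X.shape[1], beta, ks)
    return KDEModel(samples=X, bandwidths=sigma, beta=float(beta), ks=int(ks))


def _as_queries(model: KDEModel, v: np.ndarray) -> tuple[np.ndarray, bool]:
    V = np.asarray(v, dtype=float)
    single = V.ndim == 1
    if single:
        V = V[None, :]
    if V.ndim != 2 or V.shape[1] != model.dim:
        raise ValueError(
            f"query dimension {V.shape[-1] if V.ndim else '?'} does not match "
            f"model dimension {model.dim}"
        )
    return V, single


def log_density_at(model: KDEModel, v: np.ndarray, kt: int | None = None
                   ) -> np.ndarray:
    """Natural log of the kt-truncated density estimate at queries v.

    Only the kt nearest training samples of each query contribute;
    ``kt = None`` (or kt >= n) evaluates the full estimator.  The sum is
    still normalised by the total sample count n, so truncation can only
    under-estimate the full density.  Returns -inf where every kernel
    underflows.
    """
    V, single = _as_queries(model, v)
    n = model.n_samples
    kt = n if kt is None else int(kt)
    if kt < 1:
        raise ValueError("kt must be >= 1")
    kt = min(kt, n)
    dist, idx = model._nn.kneighbors(V, n_neighbors=kt)
    sigma = model.bandwidths[idx]
    with np.errstate(over="ignore", divide="ignore"):
        log_terms = model._log_const[idx] - 0.5 * (dist / sigma) ** 2
        logf = logsumexp(log_terms, axis=1) - np.log(n)
    return logf[0] if single else logf


def density_at(model: KDEModel, v: np.ndarray, kt: int | None = None
               ) -> np.ndarray:
    """kt-truncated density estimate f_hat(v) (may underflow to 0 at high m)."""
    return np.exp(log_density_at(model, v, kt))


@dataclass
class ClassifierModel:
    """Two-class RVKDE classifier with class-size-weighted likelihoods."""

    kde_pos: KDEModel
    kde_neg: KDEModel
    n_pos: int
    n_neg: int
    alpha: float
    kt: int


def fit_classifier(
    pos: np.ndarray,
    neg: np.ndarray,
    *,
    alpha: float = 1.0,
    beta: float = 1.0,
    ks: int = 5,
    kt: int = 50,
) -> ClassifierModel:
    """Fit one RVKDE per class; both classes must be non-empty."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    if pos.shape[1] != neg.shape[1]:
        raise ValueError("class sample dimensions differ")
    if kt < 1:
        raise ValueError("kt must be >= 1")
    return ClassifierModel(
        kde_pos=fit_kde(pos, beta=beta, ks=ks),
        kde_neg=fit_kde(neg, beta=beta, ks=ks),
        n_pos=pos.shape[0],
        n_neg=neg.shape[0],
        alpha=float(alpha),
        kt=int(kt),
    )


def decision_score(model: ClassifierModel, v: np.ndarray) -> np.ndarray:
    """log L_pos(v) - log L_neg(v) with L_j(v) = |S_j|**alpha * f_j(v).

    Positive scores favour the interacting class.  Queries where both
    class likelihoods underflow to zero are scored 0 (and therefore
    predicted negative under the tie rule) with a warning.
    """
    V, single = _as_queries(model.kde_pos, v)
    lp = model.alpha * np.log(model.n_pos) + log_density_at(model.kde_pos, V,
                                                            model.kt)
    ln = model.alpha * np.log(model.n_neg) + log_density_at(model.kde_neg, V,
                                                            model.kt)
    score = lp - ln
    degenerate = np.isneginf(lp) & np.isneginf(ln)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} query point(s) had zero likelihood in "
            "both classes; scored 0 (predicted negative)",
            RuntimeWarning,
            stacklevel=2,
        )
        score = np.where(degenerate, 0.0, score)
    return score[0] if single else score


def predict(model: ClassifierModel, v: np.ndarray) -> np.ndarray:
    """Class labels: True (interacting) iff score > 0; ties go negative."""
    return decision_score(model, v) > 0


@dataclass
class GridSearchResult:
    best_params: dict
    best_score: float
    table: pd.DataFrame  # one row per parameter combination


def _fold_f_measure(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum(y_true & y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: Mapping[str, Sequence] | None = None,
    *,
    folds: int = 5,
    seed: int = 0,
) -> GridSearchResult:
    """Select (alpha, beta, ks, kt) maximising mean CV F-measure.

    Stratified ``folds``-fold CV with shuffling seeded by ``seed``; the
    combination with the highest mean F-measure wins, earlier grid order
    breaking exact ties.  Duplicate candidate values are deduplicated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    grid = dict(grid or DEFAULT_GRID)
    candidates = {
        name: sorted(set(grid.get(name, DEFAULT_GRID[name][:1])))
        for name in ("alpha", "beta", "ks", "kt")
    }
    if any(len(v) == 0 for v in candidates.values()):
        raise ValueError("empty candidate list in grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    for tr, va in splits:
        for part, name in ((tr, "training"), (va, "validation")):
            if y[part].all() or not y[part].any():
                raise ValueError(
                    f"a CV {name} fold contains a single class; stratify the "
                    "input or regenerate the dataset with both classes per fold"
                )

    rows = []
    best_params: dict | None = None
    best_score = -np.inf
    combos = itertools.product(candidates["alpha"], candidates["beta"],
                               candidates["ks"], candidates["kt"])
    for alpha, beta, ks, kt in combos:
        fold_scores = []
        for tr, va in splits:
            model = fit_classifier(X[tr][y[tr]], X[tr][~y[tr]],
                                   alpha=alpha, beta=beta, ks=ks, kt=kt)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                y_hat = predict(model, X[va])
            fold_scores.append(_fold_f_measure(y[va], y_hat))
        mean_score = float(np.mean(fold_scores))
        rows.append({"alpha": alpha, "beta": beta, "ks": ks, "kt": kt,
                     **{f"fold{i}": s for i, s in enumerate(fold_scores)},
                     "mean_f_measure": mean_score})
        if mean_score > best_score:
            best_score = mean_score
            best_params = {"alpha": alpha, "beta": beta, "ks": ks, "kt": kt}
    assert best_params is not None
    return GridSearchResult(best_params=best_params, best_score=best_score,
                            table=pd.DataFrame(rows))


def save_classifier(model: ClassifierModel, path: str | Path) -> None:
    """Persist a classifier as a versioned .npz archive."""
    np.savez_compressed(
        Path(path),
        format_version=MODEL_FORMAT_VERSION,
        pos_samples=model.kde_pos.samples,
        pos_bandwidths=model.kde_pos.bandwidths,
        neg_samples=model.kde_neg.samples,
        neg_bandwidths=model.kde_neg.bandwidths,
        params=np.array([model.alpha, model.kde_pos.beta, model.kde_pos.ks,
                         model.kt], dtype=float),
        class_sizes=np.array([model.n_pos, model.n_neg], dtype=np.int64),
    )


def load_classifier(path: str | Path) -> ClassifierModel:
    with np.load(Path(path)) as data:
        version = int(data["format_version"])
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version}")
        alpha, beta, ks, kt = data["params"]
        n_pos, n_neg = data["class_sizes"]
        kde_pos = KDEModel(samples=data["pos_samples"],
                           bandwidths=data["pos_bandwidths"],
                           beta=float(beta), ks=int(ks))
        kde_neg = KDEModel(samples=data["neg_samples"],
                           bandwidths=data["neg_bandwidths"],
                           beta=float(beta), ks=int(ks))
    return ClassifierModel(kde_pos=kde_pos, kde_neg=kde_neg,
                           n_pos=int(n_pos), n_neg=int(n_neg),
                           alpha=float(alpha), kt=int(kt))
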