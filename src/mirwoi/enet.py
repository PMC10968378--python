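"""Ordinal elastic-net score model and the thresholded three-state call.

The response is the ordinal encoding 108h -> -1, 120h -> 0, 144h -> +1 treated
as a single continuous regression target. The penalty follows the convention
in which ``alpha`` weights the SQUARED (ridge) term:

    RSS + lam * ( alpha * ||beta||_2^2 + (1 - alpha) * ||beta||_1 )

Note this is the REVERSE of the usual glmnet convention: here ``alpha = 1`` is
pure ridge and ``alpha = 0`` is pure lasso. The overall strength ``lam`` is a
free hyperparameter tuned by cross-validation.

Class calls derive solely from the fitted score: score > +1 -> 144h,
score < -1 -> 108h, otherwise 120h (strict inequalities at both cutpoints).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import VALID_LABELS
from .matrix import FeatureMatrix
from .preprocess import (
    PCAParams,
    drop_zero_variance,
    PreprocessConfig,
    PreprocessParams,
    apply_pca,
    apply_preprocess,
    apply_scaler,
    fit_pca,
    fit_scaler,
    filter_low_amplification,
    impute_missing,
    quantile_normalize,
)

MODEL_SCHEMA_VERSION = 1

LABEL_TO_Y = {108: -1.0, 120: 0.0, 144: 1.0}
Y_TO_LABEL = {-1: 108, 0: 120, 1: 144}


class ConvergenceWarning(UserWarning):
    pass


def encode_labels(labels: list[int]) -> np.ndarray:
    """Map transfer-time labels to the ordinal response (108->-1, 120->0, 144->+1)."""
    out = np.empty(len(labels))
    for i, lab in enumerate(labels):
        if lab not in LABEL_TO_Y:
            raise ValueError(f"unknown label {lab!r}; expected one of {VALID_LABELS}")
        out[i] = LABEL_TO_Y[lab]
    return out


def enet_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                   intercept: float, alpha: float, lam: float) -> float:
    """Reference objective: RSS + lam*(alpha*L2^2 + (1-alpha)*L1)."""
    r = y - intercept - X @ beta
    return float(r @ r + lam * (alpha * beta @ beta + (1 - alpha) * np.sum(np.abs(beta))))


def _soft_threshold(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def fit_enet(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray, int, bool]:
    """Cyclic coordinate descent for the elastic-net objective.

    Single-coordinate update: soft-threshold at lam*(1-alpha)/2, shrink by the
    ridge term lam*alpha; intercept unpenalized and updated each sweep.
    Returns (beta, intercept, residuals, n_sweeps, converged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not (0 <= alpha <= 1) or lam < 0:
        raise ValueError("require 0 <= alpha <= 1 and lam >= 0")

    col_sq = np.einsum("ij,ij->j", X, X)
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    intercept = float(np.mean(y - X @ beta))
    r = y - intercept - X @ beta
    soft = lam * (1 - alpha) / 2.0
    ridge = lam * alpha

    converged = False
    sweep = 0
    for sweep in range(1, max_iter + 1):
        max_delta = 0.0
        for j in range(p):
            denom = col_sq[j] + ridge
            if denom == 0.0:
                continue
            bj = beta[j]
            z = X[:, j] @ r + col_sq[j] * bj
            bnew = _soft_threshold(z, soft) / denom
            if bnew != bj:
                r -= X[:, j] * (bnew - bj)
                beta[j] = bnew
                max_delta = max(max_delta, abs(bnew - bj))
        shift = float(np.mean(r))
        if shift != 0.0:
            intercept += shift
            r -= shift
            max_delta = max(max_delta, abs(shift))
        if max_delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {max_iter} sweeps "
            f"(alpha={alpha}, lam={lam}, last max coefficient change "
            f"{max_delta:.3e} >= tol {tol:.1e})",
            ConvergenceWarning,
        )
    return beta, intercept, r, sweep, converged


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lam at which the pure-lasso (alpha=0) solution is all-zero."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return float(2.0 * np.max(np.abs(Xc.T @ yc))) if X.shape[1] else 0.0


def predict_score(beta: np.ndarray, intercept: float, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(beta):
        raise ValueError(f"X has {X.shape[1]} columns, beta has {len(beta)}")
    return intercept + X @ beta


def score_to_es(score: float, thresholds: tuple[float, float] = (-1.0, 1.0)) -> int:
    """Map a score to the endometrial-state call.

    Strictly above the upper cutpoint -> 144h; strictly below the lower
    cutpoint -> 108h; otherwise (boundaries included) -> 120h.
    """
    lower, upper = thresholds
    if not lower < upper:
        raise ValueError("thresholds must satisfy lower < upper")
    if np.isnan(score):
        raise ValueError("cannot classify a NaN score")
    if score > upper:
        return 144
    if score < lower:
        return 108
    return 120


def scores_to_es(scores: np.ndarray,
                 thresholds: tuple[float, float] = (-1.0, 1.0)) -> list[int]:
    return [score_to_es(float(s), thresholds) for s in scores]


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class GridCell:
    alpha: float
    lam: float
    variance_target: float


@dataclass
class CVResult:
    grid: list[GridCell]
    fold_metrics: list[list[float]]   # per cell, k fold accuracies
    best: GridCell
    seed: int
    k: int
    warnings: list[str] = field(default_factory=list)

    def mean_accuracy(self, cell_index: int) -> float:
        return float(np.mean(self.fold_metrics[cell_index]))

    @property
    def best_accuracy(self) -> float:
        i = self.grid.index(self.best)
        return self.mean_accuracy(i)


def default_grid(
    X_scaled: np.ndarray,
    y: np.ndarray,
    alphas: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_lam: int = 30,
    lam_decades: float = 4.0,
    variance_targets: tuple[float, ...] = (0.8, 0.9, 0.95),
) -> list[GridCell]:
    """Hyperparameter grid: lam log-spaced down from lambda_max, per alpha/target."""
    lmax = max(lambda_max(X_scaled, y), 1e-8)
    lams = np.logspace(np.log10(lmax), np.log10(lmax) - lam_decades, n_lam)
    return [GridCell(alpha=a, lam=float(l), variance_target=v)
            for v in variance_targets for a in alphas for l in lams]


def _fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def cross_validate(
    scaled: FeatureMatrix,
    y: np.ndarray,
    grid: list[GridCell] | None = None,
    k: int = 10,
    seed: int = 0,
    thresholds: tuple[float, float] = (-1.0, 1.0),
    metric: str = "accuracy",
) -> CVResult:
    """Seeded k-fold CV over (alpha, lam, variance_target).

    PCA is refit inside each fold on the fold-training rows only (no leakage);
    the cell metric is mean held-out accuracy after thresholding (or negative
    MSE with ``metric="mse"``). Ties are broken toward smaller variance target,
    then larger lam, then larger alpha.
    """
    scaled.require_stage("scaled")
    X = scaled.values
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if grid is None:
        grid = default_grid(X, y)
    if not grid:
        raise ValueError("empty hyperparameter grid")

    folds = _fold_indices(n, k, seed)
    labels_true = np.array([Y_TO_LABEL[int(round(v))] for v in y])
    notes: list[str] = []
    cell_scores: dict[tuple[float, float, float], list[float]] = {
        (c.alpha, c.lam, c.variance_target): [] for c in grid
    }
    targets = sorted({c.variance_target for c in grid})
    pairs = sorted({(c.alpha, c.lam) for c in grid})

    for fi, val_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        Xtr, Xval = X[mask], X[val_idx]
        ytr = y[mask]
        if len(np.unique(ytr)) < 2:
            notes.append(f"fold {fi} training portion has a single class")
        tr_fm = FeatureMatrix([f"s{i}" for i in range(Xtr.shape[0])],
                              list(scaled.feature_ids), Xtr, "scaled")
        val_fm = FeatureMatrix([f"v{i}" for i in range(Xval.shape[0])],
                               list(scaled.feature_ids), Xval, "scaled")
        for v in targets:
            pca = fit_pca(tr_fm, variance_target=v)
            Ztr = apply_pca(tr_fm, pca).values
            Zval = apply_pca(val_fm, pca).values
            # warm-start along the lam path within each alpha
            by_alpha: dict[float, list[float]] = {}
            for a, l in pairs:
                by_alpha.setdefault(a, []).append(l)
            for a, lams in by_alpha.items():
                beta = None
                for l in sorted(lams, reverse=True):
                    if (a, l, v) not in cell_scores:
                        continue
                    beta, intercept, _, _, _ = fit_enet(Ztr, ytr, a, l, beta0=beta)
                    s = predict_score(beta, intercept, Zval)
                    if metric == "accuracy":
                        pred = np.array(scores_to_es(s, thresholds))
                        score = float(np.mean(pred == labels_true[val_idx]))
                    elif metric == "mse":
                        score = -float(np.mean((s - y[val_idx]) ** 2))
                    else:
                        raise ValueError(f"unknown metric {metric!r}")
                    cell_scores[(a, l, v)].append(score)

    fold_metrics = [cell_scores[(c.alpha, c.lam, c.variance_target)] for c in grid]
    order = sorted(
        range(len(grid)),
        key=lambda i: (-float(np.mean(fold_metrics[i])),
                       grid[i].variance_target, -grid[i].lam, -grid[i].alpha),
    )
    return CVResult(grid=grid, fold_metrics=fold_metrics, best=grid[order[0]],
                    seed=seed, k=k, warnings=notes)


# ---------------------------------------------------------------------------
# Frozen model
# ---------------------------------------------------------------------------

@dataclass
class ScoreModel:
    """Frozen preprocessing chain + elastic-net coefficients + ES cutpoints."""

    beta: np.ndarray
    intercept: float
    alpha: float
    lam: float
    preprocess: PreprocessParams
    residuals: np.ndarray
    thresholds: tuple[float, float] = (-1.0, 1.0)
    cv: CVResult | None = None
    schema_version: int = MODEL_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1) or self.lam < 0:
            raise ValueError("require 0 <= alpha <= 1 and lam >= 0")
        lower, upper = self.thresholds
        if not lower < upper:
            raise ValueError("thresholds must satisfy lower < upper")
        if len(self.beta) != self.preprocess.pca.n_components:
            raise ValueError("beta length must match the PCA component count")

    def score(self, raw_mean: FeatureMatrix) -> np.ndarray:
        Z = apply_preprocess(raw_mean, self.preprocess)
        return predict_score(self.beta, self.intercept, Z.values)

    def predict(self, raw_mean: FeatureMatrix) -> list[int]:
        return scores_to_es(self.score(raw_mean), self.thresholds)

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "beta": np.asarray(self.beta).tolist(),
            "intercept": float(self.intercept),
            "alpha": float(self.alpha),
            "lam": float(self.lam),
            "thresholds": list(self.thresholds),
            "residuals": np.asarray(self.residuals).tolist(),
            "preprocess": self.preprocess.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreModel":
        if d.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unknown model schema_version {d.get('schema_version')!r}")
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            intercept=float(d["intercept"]),
            alpha=float(d["alpha"]),
            lam=float(d["lam"]),
            thresholds=tuple(d["thresholds"]),
            residuals=np.asarray(d["residuals"], dtype=float),
            preprocess=PreprocessParams.from_dict(d["preprocess"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ScoreModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class TrainConfig:
    max_missing_fraction: float = 0.10
    per_feature_imputation: bool = False
    alphas: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_lam: int = 30
    lam_decades: float = 4.0
    variance_targets: tuple[float, ...] = (0.8, 0.9, 0.95)
    k: int = 10
    seed: int = 0
    thresholds: tuple[float, float] = (-1.0, 1.0)
    cv_metric: str = "accuracy"


def train_classifier(
    raw_mean: FeatureMatrix,
    labels: list[int],
    config: TrainConfig | None = None,
) -> ScoreModel:
    """Full training pipeline on a patient-averaged raw_mean matrix.

    Fits quantile reference, amplification filter, imputation and scaler on
    the training data; cross-validates (alpha, lam, PCA variance target); then
    refits PCA and the elastic net on the whole training set with the winning
    hyperparameters.
    """
    config = config or TrainConfig()
    if len(labels) != raw_mean.n_samples:
        raise ValueError("one label per training patient required")
    y = encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")

    qn, reference = quantile_normalize(raw_mean)
    filtered, _ = filter_low_amplification(qn, config.max_missing_fraction)
    imputed, imp_value = impute_missing(filtered, per_feature=config.per_feature_imputation)
    imputed, dropped = drop_zero_variance(imputed)
    if dropped and config.per_feature_imputation:
        gone = set(dropped)
        keep = [i for i, f in enumerate(filtered.feature_ids) if f not in gone]
        imp_value = np.asarray(imp_value)[keep]
    means, sds = fit_scaler(imputed)
    scaled = apply_scaler(imputed, means, sds)

    grid = default_grid(scaled.values, y, alphas=config.alphas, n_lam=config.n_lam,
                        lam_decades=config.lam_decades,
                        variance_targets=config.variance_targets)
    cv = cross_validate(scaled, y, grid=grid, k=min(config.k, scaled.n_samples),
                        seed=config.seed, thresholds=config.thresholds,
                        metric=config.cv_metric)

    pca = fit_pca(scaled, variance_target=cv.best.variance_target)
    Z = apply_pca(scaled, pca)
    beta, intercept, residuals, _, _ = fit_enet(Z.values, y, cv.best.alpha, cv.best.lam)

    params = PreprocessParams(
        quantile_reference=reference,
        retained_features=list(imputed.feature_ids),
        imputation_value=imp_value,
        scaler_means=means,
        scaler_sds=sds,
        pca=pca,
    )
    return ScoreModel(beta=beta, intercept=intercept, alpha=cv.best.alpha,
                      lam=cv.best.lam, preprocess=params, residuals=residuals,
                      thresholds=config.thresholds, cv=cv)
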