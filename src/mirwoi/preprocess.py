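"""Cq preprocessing chain: quantile normalization, low-amplification filtering,
max-value imputation, standardization, and PCA.

All parameters are fitted on training data, frozen into :class:`PreprocessParams`
and re-applied verbatim to held-out profiles. Normalized Cq values keep the Cq
orientation throughout: higher value = lower expression, so the global maximum
used for imputation is the "undetectable" end of the scale.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .matrix import FeatureMatrix

SCHEMA_VERSION = 1


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def _row_reference_values(reference: np.ndarray, m: int) -> np.ndarray:
    """Reference values at the m rank positions of a row with m observed values."""
    k = len(reference)
    if m == k:
        return reference
    if m == 1:
        return np.array([float(np.mean(reference))])
    grid = np.linspace(0.0, 1.0, k)
    q = np.linspace(0.0, 1.0, m)
    return np.interp(q, grid, reference)


def _map_row_to_reference(row: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Replace a row's non-missing values by reference values at their ranks.

    Ties receive the mean of the reference values at the tied rank positions.
    Missing entries stay missing.
    """
    out = np.full_like(row, np.nan)
    obs = np.flatnonzero(~np.isnan(row))
    m = obs.size
    if m == 0:
        return out
    vals = row[obs]
    order = np.argsort(vals, kind="stable")
    row_ref = _row_reference_values(reference, m)
    mapped = np.empty(m)
    i = 0
    while i < m:
        j = i
        while j + 1 < m and vals[order[j + 1]] == vals[order[i]]:
            j += 1
        mapped[order[i:j + 1]] = float(np.mean(row_ref[i:j + 1]))
        i = j + 1
    out[obs] = mapped
    return out


def compute_quantile_reference(matrix: FeatureMatrix) -> np.ndarray:
    """Mean, across rows, of row-wise sorted non-missing values on a common grid."""
    p = matrix.n_features
    stacked = np.empty((matrix.n_samples, p))
    for r in range(matrix.n_samples):
        row = matrix.values[r]
        vals = np.sort(row[~np.isnan(row)])
        if vals.size < 2:
            raise PreprocessError(
                f"profile {matrix.patient_ids[r]!r} has fewer than 2 non-missing values"
            )
        stacked[r] = _row_reference_values(vals, p) if vals.size != p else vals
    return np.mean(stacked, axis=0)


def quantile_normalize(matrix: FeatureMatrix) -> tuple[FeatureMatrix, np.ndarray]:
    """Quantile-normalize rows to their common mean distribution."""
    matrix.require_stage("raw_mean")
    if matrix.n_samples < 2:
        raise PreprocessError("quantile normalization needs at least 2 rows")
    reference = compute_quantile_reference(matrix)
    out = np.vstack([_map_row_to_reference(matrix.values[r], reference)
                     for r in range(matrix.n_samples)])
    return matrix.with_values(out, "quantile_normalized"), reference


def apply_quantile_reference(matrix: FeatureMatrix,
                             reference: np.ndarray) -> FeatureMatrix:
    """Map rows onto a frozen reference distribution (for held-out profiles)."""
    matrix.require_stage("raw_mean")
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise PreprocessError("empty quantile reference")
    out = np.vstack([_map_row_to_reference(matrix.values[r], reference)
                     for r in range(matrix.n_samples)])
    return matrix.with_values(out, "quantile_normalized")


# ---------------------------------------------------------------------------
# Filtering and imputation
# ---------------------------------------------------------------------------

def filter_low_amplification(
    matrix: FeatureMatrix, max_missing_fraction: float = 0.10
) -> tuple[FeatureMatrix, list[str]]:
    """Drop features missing in more than ``max_missing_fraction`` of rows.

    A feature is retained iff present in at least (1 - threshold) of the rows;
    the boundary (exactly the threshold) is retained.
    """
    matrix.require_stage("quantile_normalized")
    frac = np.mean(np.isnan(matrix.values), axis=0)
    keep = frac <= max_missing_fraction
    removed = [f for f, k in zip(matrix.feature_ids, keep) if not k]
    if not keep.any():
        raise PreprocessError("amplification filter removed every feature")
    kept_ids = [f for f, k in zip(matrix.feature_ids, keep) if k]
    return matrix.with_values(matrix.values[:, keep], "filtered", kept_ids), removed


def impute_missing(
    matrix: FeatureMatrix, per_feature: bool = False
) -> tuple[FeatureMatrix, np.ndarray | float]:
    """Replace missing cells by the global maximum observed value.

    The maximum normalized Cq is the lowest observable expression, so missing
    (non-amplified) cells are set to it. ``per_feature`` substitutes each
    feature's own maximum instead (returns a vector).
    """
    matrix.require_stage("filtered")
    if np.all(np.isnan(matrix.values)):
        raise PreprocessError("cannot impute an entirely missing matrix")
    if per_feature:
        with np.errstate(all="ignore"):
            value = np.nanmax(matrix.values, axis=0)
        if np.isnan(value).any():
            raise PreprocessError("a feature has no observed values to impute from")
        out = np.where(np.isnan(matrix.values), value[None, :], matrix.values)
    else:
        value = float(np.nanmax(matrix.values))
        out = np.where(np.isnan(matrix.values), value, matrix.values)
    return matrix.with_values(out, "imputed"), value


def apply_imputation(matrix: FeatureMatrix,
                     value: np.ndarray | float) -> FeatureMatrix:
    matrix.require_stage("filtered")
    if np.isscalar(value):
        out = np.where(np.isnan(matrix.values), float(value), matrix.values)
    else:
        out = np.where(np.isnan(matrix.values), np.asarray(value)[None, :], matrix.values)
    return matrix.with_values(out, "imputed")


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

def fit_scaler(matrix: FeatureMatrix, ddof: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and sample standard deviation (ddof=1 by default)."""
    matrix.require_stage("imputed")
    means = matrix.values.mean(axis=0)
    sds = matrix.values.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = [matrix.feature_ids[i] for i in zero]
        raise PreprocessError(f"zero-variance features cannot be scaled: {names}")
    return means, sds


def apply_scaler(matrix: FeatureMatrix, means: np.ndarray,
                 sds: np.ndarray) -> FeatureMatrix:
    matrix.require_stage("imputed")
    return matrix.with_values((matrix.values - means) / sds, "scaled")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAParams:
    means: np.ndarray
    loadings: np.ndarray         # (p, k), columns orthonormal
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(matrix: FeatureMatrix, n_components: int | None = None,
            variance_target: float | None = None) -> PCAParams:
    """PCA via SVD of the centered matrix.

    Component sign is fixed by forcing the largest-magnitude loading element
    of each component positive. ``variance_target`` in (0, 1] picks the
    smallest k whose cumulative explained-variance fraction reaches it.
    """
    matrix.require_stage("scaled")
    X = matrix.values
    means = X.mean(axis=0)
    Xc = X - means
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    var = s ** 2
    total = var.sum()
    ratios = var / total if total > 0 else np.zeros_like(var)

    if n_components is None:
        if variance_target is None:
            variance_target = 0.90
        if not (0 < variance_target <= 1):
            raise PreprocessError("variance_target must be in (0, 1]")
        cum = np.cumsum(ratios)
        k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        k = min(k, rank)
    else:
        k = int(n_components)
        if k > rank:
            raise PreprocessError(f"n_components {k} exceeds matrix rank {rank}")
    if k < 1:
        raise PreprocessError("PCA needs at least one component")

    loadings = vt[:k].T.copy()
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCAParams(means=means, loadings=loadings,
                     explained_variance_ratio=ratios[:k].copy())


def apply_pca(matrix: FeatureMatrix, params: PCAParams) -> FeatureMatrix:
    matrix.require_stage("scaled")
    scores = (matrix.values - params.means) @ params.loadings
    names = [f"PC{i + 1}" for i in range(params.n_components)]
    return matrix.with_values(scores, "pca", names)


# ---------------------------------------------------------------------------
# Frozen end-to-end parameters
# ---------------------------------------------------------------------------

@dataclass
class PreprocessParams:
    """Everything needed to replay the fitted preprocessing chain bit-exactly."""

    quantile_reference: np.ndarray
    retained_features: list[str]
    imputation_value: float | np.ndarray
    scaler_means: np.ndarray
    scaler_sds: np.ndarray
    pca: PCAParams
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        p = len(self.retained_features)
        if len(self.scaler_means) != p or len(self.scaler_sds) != p:
            raise PreprocessError("scaler parameter length mismatch")
        if np.any(np.asarray(self.scaler_sds) <= 0):
            raise PreprocessError("scaler sds must be positive")
        gram = self.pca.loadings.T @ self.pca.loadings
        if not np.allclose(gram, np.eye(self.pca.n_components), atol=1e-8):
            raise PreprocessError("PCA loadings are not orthonormal")

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "quantile_reference": np.asarray(self.quantile_reference).tolist(),
            "retained_features": list(self.retained_features),
            "imputation_value": (
                float(self.imputation_value) if np.isscalar(self.imputation_value)
                else np.asarray(self.imputation_value).tolist()
            ),
            "scaler_means": np.asarray(self.scaler_means).tolist(),
            "scaler_sds": np.asarray(self.scaler_sds).tolist(),
            "pca_means": np.asarray(self.pca.means).tolist(),
            "pca_loadings": np.asarray(self.pca.loadings).tolist(),
            "explained_variance_ratio": np.asarray(self.pca.explained_variance_ratio).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessParams":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise PreprocessError(
                f"unknown preprocess schema_version {d.get('schema_version')!r}"
            )
        imp = d["imputation_value"]
        return cls(
            quantile_reference=np.asarray(d["quantile_reference"], dtype=float),
            retained_features=list(d["retained_features"]),
            imputation_value=imp if np.isscalar(imp) else np.asarray(imp, dtype=float),
            scaler_means=np.asarray(d["scaler_means"], dtype=float),
            scaler_sds=np.asarray(d["scaler_sds"], dtype=float),
            pca=PCAParams(
                means=np.asarray(d["pca_means"], dtype=float),
                loadings=np.asarray(d["pca_loadings"], dtype=float),
                explained_variance_ratio=np.asarray(d["explained_variance_ratio"], dtype=float),
            ),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "PreprocessParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def drop_zero_variance(imputed: FeatureMatrix) -> tuple[FeatureMatrix, list[str]]:
    """Remove constant features (e.g. a miRNA pinned to the top rank by
    normalization + imputation); returns (matrix, dropped feature ids)."""
    imputed.require_stage("imputed")
    sds = imputed.values.std(axis=0, ddof=1)
    keep = sds > 0
    if keep.all():
        return imputed, []
    if not keep.any():
        raise PreprocessError("every feature is constant")
    dropped = [f for f, k in zip(imputed.feature_ids, keep) if not k]
    kept_ids = [f for f, k in zip(imputed.feature_ids, keep) if k]
    return imputed.with_values(imputed.values[:, keep], "imputed", kept_ids), dropped


@dataclass
class PreprocessConfig:
    max_missing_fraction: float = 0.10
    per_feature_imputation: bool = False
    n_components: int | None = None
    variance_target: float | None = 0.90
    scaler_ddof: int = 1


def fit_preprocess(train: FeatureMatrix,
                   config: PreprocessConfig | None = None) -> PreprocessParams:
    """Fit the full chain on training data and freeze its parameters."""
    config = config or PreprocessConfig()
    qn, reference = quantile_normalize(train)
    filtered, _removed = filter_low_amplification(qn, config.max_missing_fraction)
    imputed, imp_value = impute_missing(filtered, per_feature=config.per_feature_imputation)
    imputed, dropped = drop_zero_variance(imputed)
    if dropped and config.per_feature_imputation:
        gone = set(dropped)
        keep = [i for i, f in enumerate(filtered.feature_ids) if f not in gone]
        imp_value = np.asarray(imp_value)[keep]
    means, sds = fit_scaler(imputed, ddof=config.scaler_ddof)
    scaled = apply_scaler(imputed, means, sds)
    pca = fit_pca(scaled, n_components=config.n_components,
                  variance_target=config.variance_target)
    return PreprocessParams(
        quantile_reference=reference,
        retained_features=list(imputed.feature_ids),
        imputation_value=imp_value,
        scaler_means=means,
        scaler_sds=sds,
        pca=pca,
    )


def apply_preprocess(matrix: FeatureMatrix, params: PreprocessParams,
                     stop_at: str = "pca") -> FeatureMatrix:
    """Replay the frozen chain on any raw_mean matrix (training or held-out).

    ``stop_at`` may name an intermediate stage to return early (e.g. "scaled"
    for cross-validation, where PCA is refit per fold).
    """
    matrix.require_stage("raw_mean")
    qn = apply_quantile_reference(matrix, params.quantile_reference)
    missing = [f for f in params.retained_features if f not in qn.feature_ids]
    if missing:
        raise PreprocessError(f"input lacks retained features: {missing[:5]}")
    idx = [qn.feature_ids.index(f) for f in params.retained_features]
    filtered = qn.with_values(qn.values[:, idx], "filtered",
                              list(params.retained_features))
    if stop_at == "filtered":
        return filtered
    imputed = apply_imputation(filtered, params.imputation_value)
    if stop_at == "imputed":
        return imputed
    scaled = apply_scaler(imputed, params.scaler_means, params.scaler_sds)
    if stop_at == "scaled":
        return scaled
    return apply_pca(scaled, params.pca)
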