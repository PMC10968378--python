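"""Differential-expression screen on normalized (un-imputed) Cq values.

Comparisons are 120h vs 108h and 120h vs 144h. Because Cq is inversely
proportional to log2 abundance at 100% efficiency, log2 fold change of group a
over group b is mean(Cq_b) - mean(Cq_a): one cycle lower = two-fold higher.
Selection uses the inclusive criteria |log2FC| >= 0.585 and p <= 0.05;
variance handling follows a Shapiro-Wilk gate (pooled t when both groups look
normal, Welch otherwise). Missing entries are dropped per miRNA per group,
never imputed, so placeholder values cannot bias the group means.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .matrix import FeatureMatrix
from .preprocess import apply_scaler, fit_pca, apply_pca, fit_scaler

FC_THRESHOLD = 0.585
P_THRESHOLD = 0.05


@dataclass
class DEResult:
    mirna_id: str
    log2fc_120v108: float | None
    log2fc_120v144: float | None
    p_120v108: float | None
    p_120v144: float | None
    variance_mode_120v108: str | None
    variance_mode_120v144: str | None
    presence_fraction: dict[int, float] = field(default_factory=dict)
    passed_presence: bool = True
    selected: bool = False


def group_presence_filter(
    matrix: FeatureMatrix,
    groups: dict[str, int],
    max_absent_fraction: float = 0.05,
    exclude_if_any_group: bool = False,
) -> list[str]:
    """Presence filter on pre-imputation values.

    Default: a miRNA is excluded only when its missing fraction exceeds the
    threshold in EVERY group; ``exclude_if_any_group`` switches to the stricter
    reading (excluded if any single group exceeds it).
    """
    classes = sorted(set(groups.values()))
    masks = {}
    for cls in classes:
        rows = [i for i, pid in enumerate(matrix.patient_ids) if groups.get(pid) == cls]
        if not rows:
            raise ValueError(f"group {cls} has no samples")
        masks[cls] = np.array(rows)
    retained = []
    for j, fid in enumerate(matrix.feature_ids):
        fracs = [float(np.mean(np.isnan(matrix.values[masks[cls], j]))) for cls in classes]
        exceeds = [f > max_absent_fraction for f in fracs]
        excluded = any(exceeds) if exclude_if_any_group else all(exceeds)
        if not excluded:
            retained.append(fid)
    return retained


def log2_fold_change(matrix: FeatureMatrix, group_a: Sequence[str],
                     group_b: Sequence[str]) -> np.ndarray:
    """Per-feature log2 FC of group a over group b on the Cq scale."""
    ia = [matrix.patient_ids.index(p) for p in group_a]
    ib = [matrix.patient_ids.index(p) for p in group_b]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(matrix.values[ia], axis=0)
        mean_b = np.nanmean(matrix.values[ib], axis=0)
    return mean_b - mean_a


def de_test(
    matrix: FeatureMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    normality_alpha: float = 0.05,
) -> tuple[np.ndarray, list[str]]:
    """Two-sided two-sample t-test per feature with a normality gate.

    Both groups passing Shapiro-Wilk (p > normality_alpha) selects the
    pooled-variance Student t; otherwise Welch. Returns (p-values, mode per
    feature). Degenerate features (zero variance in both groups, equal means)
    get p = 1 and mode "degenerate".
    """
    ia = [matrix.patient_ids.index(p) for p in group_a]
    ib = [matrix.patient_ids.index(p) for p in group_b]
    pvals = np.full(matrix.n_features, np.nan)
    modes: list[str] = []
    for j in range(matrix.n_features):
        a = matrix.values[ia, j]
        b = matrix.values[ib, j]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            modes.append("insufficient")
            continue
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                pvals[j] = 1.0
                modes.append("degenerate")
                continue
            pvals[j] = 0.0
            modes.append("degenerate")
            continue
        pooled = False
        if a.size >= 3 and b.size >= 3:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pa = stats.shapiro(a).pvalue if a.std(ddof=1) > 0 else 0.0
                pb = stats.shapiro(b).pvalue if b.std(ddof=1) > 0 else 0.0
            pooled = pa > normality_alpha and pb > normality_alpha
        res = stats.ttest_ind(a, b, equal_var=pooled)
        pvals[j] = float(res.pvalue)
        modes.append("pooled" if pooled else "welch")
    return pvals, modes


def select_de(fc: np.ndarray, p: np.ndarray, fc_thresh: float = FC_THRESHOLD,
              p_thresh: float = P_THRESHOLD) -> np.ndarray:
    """Inclusive selection: |log2FC| >= fc_thresh AND p <= p_thresh."""
    fc = np.asarray(fc, dtype=float)
    p = np.asarray(p, dtype=float)
    if fc.shape != p.shape:
        raise ValueError("fc and p must be aligned")
    with np.errstate(invalid="ignore"):
        return (np.abs(fc) >= fc_thresh) & (p <= p_thresh)


def run_de_screen(
    matrix: FeatureMatrix,
    groups: dict[str, int],
    fc_thresh: float = FC_THRESHOLD,
    p_thresh: float = P_THRESHOLD,
    max_absent_fraction: float = 0.05,
    exclude_if_any_group: bool = False,
    normality_alpha: float = 0.05,
) -> list[DEResult]:
    """Full screen: presence filter, then both comparisons, then selection.

    ``matrix`` must be normalized but UN-imputed (stage quantile_normalized or
    filtered). A miRNA is selected when it passes the presence filter and meets
    both criteria in at least one comparison.
    """
    matrix.require_stage("quantile_normalized", "filtered")
    classes = (108, 120, 144)
    members = {cls: [p for p in matrix.patient_ids if groups.get(p) == cls]
               for cls in classes}
    for cls in classes:
        if not members[cls]:
            raise ValueError(f"group {cls} has no samples")

    present = set(group_presence_filter(matrix, groups, max_absent_fraction,
                                        exclude_if_any_group))
    fc_108 = log2_fold_change(matrix, members[120], members[108])
    fc_144 = log2_fold_change(matrix, members[120], members[144])
    p_108, mode_108 = de_test(matrix, members[120], members[108], normality_alpha)
    p_144, mode_144 = de_test(matrix, members[120], members[144], normality_alpha)
    sel_108 = select_de(fc_108, p_108, fc_thresh, p_thresh)
    sel_144 = select_de(fc_144, p_144, fc_thresh, p_thresh)

    results = []
    for j, fid in enumerate(matrix.feature_ids):
        ok = fid in present
        presence = {
            cls: float(np.mean(~np.isnan(
                matrix.values[[matrix.patient_ids.index(p) for p in members[cls]], j])))
            for cls in classes
        }
        results.append(DEResult(
            mirna_id=fid,
            log2fc_120v108=float(fc_108[j]) if np.isfinite(fc_108[j]) else None,
            log2fc_120v144=float(fc_144[j]) if np.isfinite(fc_144[j]) else None,
            p_120v108=float(p_108[j]) if np.isfinite(p_108[j]) else None,
            p_120v144=float(p_144[j]) if np.isfinite(p_144[j]) else None,
            variance_mode_120v108=mode_108[j],
            variance_mode_120v144=mode_144[j],
            presence_fraction=presence,
            passed_presence=ok,
            selected=bool(ok and (sel_108[j] or sel_144[j])),
        ))
    return results


def pca_cluster_de(
    matrix: FeatureMatrix,
    groups: dict[str, int],
    de_ids: Sequence[str],
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """2-D PCA of the DE submatrix plus per-group centroids (for inspection).

    Missing cells are filled with the submatrix maximum before scaling; no hard
    cluster assignment is made.
    """
    de_ids = list(de_ids)
    if len(de_ids) < 2:
        raise ValueError("need at least 2 DE features for PCA clustering")
    idx = [matrix.feature_ids.index(f) for f in de_ids]
    vals = matrix.values[:, idx].copy()
    if np.isnan(vals).all():
        raise ValueError("DE submatrix is entirely missing")
    vals[np.isnan(vals)] = np.nanmax(vals)
    sub = FeatureMatrix(list(matrix.patient_ids), de_ids, vals, "imputed")

    sds = vals.std(axis=0, ddof=1)
    if (sds == 0).all():
        return np.zeros((len(matrix.patient_ids), 2)), {
            cls: np.zeros(2) for cls in sorted(set(groups.values()))}
    keep = sds > 0
    sub = FeatureMatrix(list(matrix.patient_ids),
                        [f for f, k in zip(de_ids, keep) if k],
                        vals[:, keep], "imputed")
    means, sds = fit_scaler(sub)
    scaled = apply_scaler(sub, means, sds)
    k = min(2, min(scaled.n_samples - 1, scaled.n_features))
    pca = fit_pca(scaled, n_components=k)
    coords = apply_pca(scaled, pca).values
    if coords.shape[1] < 2:
        coords = np.hstack([coords, np.zeros((coords.shape[0], 2 - coords.shape[1]))])
    centroids = {}
    for cls in sorted(set(groups.values())):
        rows = [i for i, p in enumerate(matrix.patient_ids) if groups.get(p) == cls]
        centroids[cls] = coords[rows].mean(axis=0) if rows else np.full(2, np.nan)
    return coords, centroids
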