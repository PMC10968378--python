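"""Shared feature-matrix container used across the pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Pipeline stages in the only order transitions are allowed to follow.
STAGES = ("raw_mean", "quantile_normalized", "filtered", "imputed", "scaled", "pca")


class StageError(ValueError):
    """Raised when an operation receives a matrix at the wrong pipeline stage."""


@dataclass
class FeatureMatrix:
    """Samples x features matrix of Cq-derived values.

    Rows are patients (or profiles, before replicate averaging), columns are
    features (miRNA assays, or principal components after transformation).
    Missing (non-amplified) entries are NaN. ``stage`` records which pipeline
    step last touched the values; operations check it so the chain can only be
    applied in order.
    """

    patient_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    stage: str = "raw_mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if n != len(self.patient_ids) or p != len(self.feature_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.feature_ids)} features"
            )
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        if len(set(self.patient_ids)) != n:
            raise ValueError("duplicate patient ids")
        if len(set(self.feature_ids)) != p:
            raise ValueError("duplicate feature ids")
        if self.stage == "imputed" or STAGES.index(self.stage) > STAGES.index("imputed"):
            if np.isnan(self.values).any():
                raise ValueError(f"stage {self.stage!r} must not contain missing entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"expected matrix at stage {' or '.join(allowed)}, got {self.stage!r}"
            )

    def with_values(self, values: np.ndarray, stage: str,
                    feature_ids: list[str] | None = None) -> "FeatureMatrix":
        """Return a copy with new values at a later (or equal) stage."""
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise StageError(f"cannot move backwards from {self.stage!r} to {stage!r}")
        return FeatureMatrix(
            patient_ids=list(self.patient_ids),
            feature_ids=list(feature_ids if feature_ids is not None else self.feature_ids),
            values=np.asarray(values, dtype=float),
            stage=stage,
        )
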