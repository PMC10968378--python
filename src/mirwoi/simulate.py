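"""Synthetic panel-qPCR cohort generator.

Produces Cq profile sets with the structure the pipeline assumes: per-patient
true expression = per-miRNA baseline + ordinal class shift (informative miRNAs
only) + patient random effect; replicate Cq adds Gaussian measurement noise;
non-amplification probability rises logistically with Cq, so low-expression
(high-Cq) features drop out more, reproducing the mechanism behind the
amplification filter. Endogenous controls are near-constant and spike-ins
constant plus noise.

The default cohort has 200 patients: 150 with successful implantation (class
sizes 20/116/14, i.e. the 12/91/12 training plus 8/25/2 testing groups) and 50
with failed implantation whose class mix follows the same proportions.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data import AssayRole, CqProfileSet, SampleMetadata

TRAIN_GROUP_SIZES = {108: 12, 120: 91, 144: 12}
TEST_GROUP_SIZES = {108: 8, 120: 25, 144: 2}


@dataclass
class SyntheticConfig:
    n_mirnas: int = 167
    n_endogenous: int = 3
    n_spikein: int = 3
    group_sizes: dict[int, int] = field(
        default_factory=lambda: {
            cls: TRAIN_GROUP_SIZES[cls] + TEST_GROUP_SIZES[cls] for cls in (108, 120, 144)
        })
    n_failed: int = 50
    replicates_min: int = 2
    replicates_max: int = 3
    baseline_cq_mean: float = 27.0
    baseline_cq_sd: float = 3.0
    n_informative: int = 21
    effect_size_cycles: float = 1.0
    patient_effect_sd: float = 0.5
    replicate_noise_sd: float = 0.3
    missing_midpoint_cq: float = 36.0
    missing_scale_cq: float = 1.5
    n_always_low: int = 24
    always_low_cq_range: tuple[float, float] = (37.5, 39.5)
    endogenous_cq: float = 18.0
    spikein_cq: float = 22.0
    control_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        if self.n_informative + self.n_always_low > self.n_mirnas:
            raise ValueError("informative + always-low features exceed panel size")
        if not (self.replicates_min >= 1 and self.replicates_max >= self.replicates_min):
            raise ValueError("invalid replicate range")


@dataclass
class GroundTruth:
    informative: list[str]
    directions: dict[str, int]      # +1: Cq rises with the ordinal label
    always_low: list[str]
    effect_size_cycles: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self)))


def _missing_probability(cq: np.ndarray, midpoint: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(cq - midpoint) / scale))


def generate_cohort(
    config: SyntheticConfig | None = None,
) -> tuple[CqProfileSet, list[SampleMetadata], GroundTruth]:
    """Generate a reproducible synthetic cohort from ``config.seed``."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    mirna_ids = [f"hsa-miR-sim-{i + 1:04d}" for i in range(config.n_mirnas)]
    endo_ids = ["RNU6B", "RNU43", "18s-rRNA"][: config.n_endogenous] + [
        f"endo-{i}" for i in range(max(0, config.n_endogenous - 3))
    ]
    spike_ids = [f"spike-in-{i + 1}" for i in range(config.n_spikein)]
    assay_ids = mirna_ids + endo_ids + spike_ids
    roles = {a: AssayRole.TARGET for a in mirna_ids}
    roles.update({a: AssayRole.ENDOGENOUS_CONTROL for a in endo_ids})
    roles.update({a: AssayRole.SPIKE_IN for a in spike_ids})

    baselines = rng.normal(config.baseline_cq_mean, config.baseline_cq_sd,
                           config.n_mirnas)
    # planted high-Cq features: chosen first so they never overlap informative ones
    order = rng.permutation(config.n_mirnas)
    always_low_idx = order[: config.n_always_low]
    informative_idx = order[config.n_always_low:
                            config.n_always_low + config.n_informative]
    baselines[always_low_idx] = rng.uniform(*config.always_low_cq_range,
                                            size=config.n_always_low)
    directions = np.zeros(config.n_mirnas, dtype=int)
    # symmetric shifts: half the informative panel rises with the ordinal label,
    # half falls, keeping the linear score model well-specified
    for k, j in enumerate(informative_idx):
        directions[j] = 1 if k % 2 == 0 else -1

    # patient roster: successful cohort by class, then failed-implantation patients
    labels: list[int] = []
    success: list[bool] = []
    for cls in sorted(config.group_sizes):
        labels.extend([cls] * config.group_sizes[cls])
        success.extend([True] * config.group_sizes[cls])
    if config.n_failed:
        total = sum(config.group_sizes.values())
        probs = np.array([config.group_sizes[c] / total for c in sorted(config.group_sizes)])
        failed_labels = rng.choice(sorted(config.group_sizes), size=config.n_failed, p=probs)
        labels.extend(int(v) for v in failed_labels)
        success.extend([False] * config.n_failed)
    n_patients = len(labels)
    patient_ids = [f"P{i + 1:04d}" for i in range(n_patients)]

    y_of = {108: -1.0, 120: 0.0, 144: 1.0}
    profile_ids: list[str] = []
    patient_of_profile: dict[str, str] = {}
    columns: list[np.ndarray] = []
    metadata: list[SampleMetadata] = []

    n_assays = len(assay_ids)
    for pid, label, ok in zip(patient_ids, labels, success):
        y = y_of[label]
        patient_effect = rng.normal(0.0, config.patient_effect_sd)
        truth = baselines + directions * config.effect_size_cycles * y + patient_effect
        n_rep = int(rng.integers(config.replicates_min, config.replicates_max + 1))
        for r in range(n_rep):
            prof = f"{pid}-r{r + 1}"
            col = np.empty(n_assays)
            cq_targets = truth + rng.normal(0.0, config.replicate_noise_sd,
                                            config.n_mirnas)
            p_missing = _missing_probability(cq_targets, config.missing_midpoint_cq,
                                             config.missing_scale_cq)
            dropout = rng.random(config.n_mirnas) < p_missing
            cq_targets = np.clip(cq_targets, 1.0, None)
            cq_targets[dropout] = np.nan
            col[: config.n_mirnas] = cq_targets
            col[config.n_mirnas:config.n_mirnas + config.n_endogenous] = (
                config.endogenous_cq
                + rng.normal(0.0, config.control_noise_sd, config.n_endogenous)
            )
            col[config.n_mirnas + config.n_endogenous:] = (
                config.spikein_cq
                + rng.normal(0.0, config.control_noise_sd, config.n_spikein)
            )
            profile_ids.append(prof)
            patient_of_profile[prof] = pid
            columns.append(col)
        metadata.append(SampleMetadata(
            patient_id=pid,
            label=label,
            implantation_success=ok,
            n_pif=int(rng.poisson(0.5)),
        ))

    profiles = CqProfileSet(
        assay_ids=assay_ids,
        roles=roles,
        profile_ids=profile_ids,
        patient_of_profile=patient_of_profile,
        cq=np.column_stack(columns),
    )
    truth = GroundTruth(
        informative=[mirna_ids[j] for j in informative_idx],
        directions={mirna_ids[j]: int(directions[j]) for j in informative_idx},
        always_low=[mirna_ids[j] for j in always_low_idx],
        effect_size_cycles=config.effect_size_cycles,
    )
    return profiles, metadata, truth


def make_paper_shaped_splits(
    metadata: list[SampleMetadata],
    seed: int = 0,
    train_sizes: dict[int, int] | None = None,
    test_sizes: dict[int, int] | None = None,
) -> tuple[list[str], list[str]]:
    """Draw disjoint train/test patient sets with exact per-class sizes.

    Defaults reproduce the study cohort shape: train 12/91/12 and test 8/25/2
    for classes 108/120/144. Only successful-implantation patients are used.
    """
    train_sizes = train_sizes or dict(TRAIN_GROUP_SIZES)
    test_sizes = test_sizes or dict(TEST_GROUP_SIZES)
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(train_sizes):
        pool = [m.patient_id for m in metadata
                if m.label == cls and m.implantation_success]
        need = train_sizes[cls] + test_sizes.get(cls, 0)
        if len(pool) < need:
            raise ValueError(
                f"class {cls} has {len(pool)} successful patients, need {need}")
        perm = rng.permutation(len(pool))
        train.extend(pool[i] for i in perm[: train_sizes[cls]])
        test.extend(pool[i] for i in perm[train_sizes[cls]: need])
    return train, test
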