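"""Data model and I/O for panel-qPCR Cq profiles.

A profile is one chip run (one replicate) of one patient's biopsy. The raw
matrix is assays x profiles; non-amplification is represented internally as
NaN, never as a sentinel Cq value. Values at or above the configurable
amplification ceiling (default 40 cycles, the cycler's cycle count) are
converted to missing on read.
"""
from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import FeatureMatrix

DEFAULT_CEILING = 40.0

VALID_LABELS = (108, 120, 144)


class FormatError(ValueError):
    """Malformed input table."""


class ConfigurationError(ValueError):
    """Invalid or incomplete configuration for an operation."""


class AssayRole(str, enum.Enum):
    TARGET = "target"
    ENDOGENOUS_CONTROL = "endogenous_control"
    SPIKE_IN = "spike_in"


@dataclass
class CqProfileSet:
    """Raw per-replicate Cq matrix with assay roles and patient mapping.

    ``cq`` has shape (n_assays, n_profiles); missing amplification is NaN.
    """

    assay_ids: list[str]
    roles: dict[str, AssayRole]
    profile_ids: list[str]
    patient_of_profile: dict[str, str]
    cq: np.ndarray

    def __post_init__(self) -> None:
        self.cq = np.asarray(self.cq, dtype=float)
        if self.cq.shape != (len(self.assay_ids), len(self.profile_ids)):
            raise FormatError(
                f"cq shape {self.cq.shape} does not match "
                f"{len(self.assay_ids)} assays x {len(self.profile_ids)} profiles"
            )
        if len(set(self.assay_ids)) != len(self.assay_ids):
            raise FormatError("duplicate assay ids")
        if len(set(self.profile_ids)) != len(self.profile_ids):
            raise FormatError("duplicate profile ids")
        missing_roles = set(self.assay_ids) - set(self.roles)
        if missing_roles:
            raise FormatError(f"assays without a role: {sorted(missing_roles)}")
        for pid in self.profile_ids:
            if pid not in self.patient_of_profile:
                raise FormatError(f"profile {pid!r} has no patient")
        observed = self.cq[~np.isnan(self.cq)]
        if observed.size and (not np.all(np.isfinite(observed)) or np.any(observed <= 0)):
            raise FormatError("non-missing Cq values must be finite and > 0")

    @property
    def patients(self) -> list[str]:
        """Unique patient ids in first-appearance order of their profiles."""
        seen: dict[str, None] = {}
        for pid in self.profile_ids:
            seen.setdefault(self.patient_of_profile[pid], None)
        return list(seen)

    def assays_with_role(self, *roles: AssayRole) -> list[str]:
        return [a for a in self.assay_ids if self.roles[a] in roles]

    def subset_profiles(self, profile_ids: list[str]) -> "CqProfileSet":
        idx = [self.profile_ids.index(p) for p in profile_ids]
        return CqProfileSet(
            assay_ids=list(self.assay_ids),
            roles=dict(self.roles),
            profile_ids=list(profile_ids),
            patient_of_profile={p: self.patient_of_profile[p] for p in profile_ids},
            cq=self.cq[:, idx].copy(),
        )

    def subset_patients(self, patient_ids: list[str]) -> "CqProfileSet":
        wanted = set(patient_ids)
        profs = [p for p in self.profile_ids if self.patient_of_profile[p] in wanted]
        return self.subset_profiles(profs)


@dataclass
class SampleMetadata:
    patient_id: str
    label: int | None = None  # 108 / 120 / 144 hours, or None if unknown
    implantation_success: bool | None = None
    n_pif: int | None = None
    age: float | None = None
    bmi: float | None = None
    p4_level: float | None = None
    endometrial_thickness_mm: float | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in VALID_LABELS:
            raise FormatError(f"label must be one of {VALID_LABELS} or unknown, got {self.label}")
        if self.n_pif is not None and self.n_pif < 0:
            raise FormatError(f"n_pif must be >= 0, got {self.n_pif}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_roles(path: str | Path) -> dict[str, AssayRole]:
    """Read a two-column (assay_id, role) table; header optional."""
    path = Path(path)
    sep = _sniff_sep(path)
    roles: dict[str, AssayRole] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter=sep):
            if not row or not row[0].strip():
                continue
            aid, role = row[0].strip(), row[1].strip()
            if aid.lower() == "assay_id":
                continue
            try:
                parsed = AssayRole(role)
            except ValueError as exc:
                raise FormatError(f"unknown assay role {role!r} for {aid!r}") from exc
            if aid in roles:
                raise FormatError(f"duplicate assay id in roles file: {aid!r}")
            roles[aid] = parsed
    return roles


def read_cq_table(
    path: str | Path,
    roles_path: str | Path,
    ceiling: float = DEFAULT_CEILING,
    profile_to_patient: dict[str, str] | None = None,
) -> CqProfileSet:
    """Read a wide Cq table (rows = assays, columns = profiles).

    Missing amplification may be encoded as an empty cell, ``NA``, or any Cq at
    or above ``ceiling``; all are converted to the internal missing marker.
    Profile ids of the form ``<patient>-r<k>`` derive the patient id from the
    prefix unless an explicit ``profile_to_patient`` map is given.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    profile_ids = [h.strip() for h in header[1:]]
    if len(set(profile_ids)) != len(profile_ids):
        raise FormatError("duplicate profile columns in Cq table")

    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    assay_ids = [str(a) for a in df.index]
    if len(set(assay_ids)) != len(assay_ids):
        raise FormatError("duplicate assay rows in Cq table")

    cq = np.empty((len(assay_ids), len(profile_ids)))
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            cell = str(raw).strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                cq[i, j] = np.nan
                continue
            try:
                val = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"non-numeric Cq cell {cell!r} at assay {assay_ids[i]!r}, "
                    f"profile {profile_ids[j]!r}"
                ) from exc
            cq[i, j] = np.nan if (math.isnan(val) or val >= ceiling) else val

    if profile_to_patient is None:
        profile_to_patient = {p: p.rsplit("-r", 1)[0] for p in profile_ids}

    roles = read_roles(roles_path)
    return CqProfileSet(
        assay_ids=assay_ids,
        roles=roles,
        profile_ids=profile_ids,
        patient_of_profile=profile_to_patient,
        cq=cq,
    )


def write_cq_table(profiles: CqProfileSet, path: str | Path,
                   roles_path: str | Path | None = None, sep: str = "\t") -> None:
    """Write a Cq table (and optionally its roles companion) back to disk.

    Non-missing values round-trip bit-exactly (shortest-repr float formatting);
    missing entries are written as empty cells.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["assay_id"] + list(profiles.profile_ids))
        for i, aid in enumerate(profiles.assay_ids):
            row = [aid] + [
                "" if np.isnan(v) else repr(float(v)) for v in profiles.cq[i]
            ]
            writer.writerow(row)
    if roles_path is not None:
        with open(roles_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter=sep)
            writer.writerow(["assay_id", "role"])
            for aid in profiles.assay_ids:
                writer.writerow([aid, profiles.roles[aid].value])


_OUTCOMES = {
    "success": True, "1": True, "true": True, "yes": True,
    "fail": False, "failure": False, "0": False, "false": False, "no": False,
}


def _opt_float(cell: str) -> float | None:
    cell = cell.strip()
    if cell == "" or cell.upper() in ("NA", "NAN", "UNKNOWN"):
        return None
    return float(cell)


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read per-patient metadata (patient_id, label, outcome, n_pif[, ...])."""
    path = Path(path)
    sep = _sniff_sep(path)
    records: list[SampleMetadata] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        for row in reader:
            pid = row["patient_id"].strip()
            raw_label = (row.get("label") or "").strip().lower()
            if raw_label in ("", "na", "unknown"):
                label = None
            else:
                try:
                    label = int(float(raw_label))
                except ValueError as exc:
                    raise FormatError(f"invalid label {raw_label!r} for {pid!r}") from exc
                if label not in VALID_LABELS:
                    raise FormatError(f"label {label} for {pid!r} not in {VALID_LABELS}")
            raw_outcome = (row.get("outcome") or "").strip().lower()
            outcome = _OUTCOMES.get(raw_outcome) if raw_outcome not in ("", "na", "unknown") else None
            if raw_outcome not in ("", "na", "unknown") and outcome is None:
                raise FormatError(f"invalid outcome {raw_outcome!r} for {pid!r}")
            raw_pif = (row.get("n_pif") or "").strip()
            if raw_pif in ("", "na", "unknown", "NA"):
                n_pif = None
            else:
                n_pif = int(float(raw_pif))
            records.append(SampleMetadata(
                patient_id=pid,
                label=label,
                implantation_success=outcome,
                n_pif=n_pif,
                age=_opt_float(row.get("age", "") or ""),
                bmi=_opt_float(row.get("bmi", "") or ""),
                p4_level=_opt_float(row.get("p4", "") or ""),
                endometrial_thickness_mm=_opt_float(row.get("emt", "") or ""),
            ))
    if len({r.patient_id for r in records}) != len(records):
        raise FormatError("duplicate patient ids in metadata")
    return records


def write_metadata(records: list[SampleMetadata], path: str | Path, sep: str = "\t") -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["patient_id", "label", "outcome", "n_pif", "age", "bmi", "p4", "emt"])
        for r in records:
            writer.writerow([
                r.patient_id,
                "" if r.label is None else r.label,
                "" if r.implantation_success is None else ("success" if r.implantation_success else "fail"),
                "" if r.n_pif is None else r.n_pif,
                "" if r.age is None else r.age,
                "" if r.bmi is None else r.bmi,
                "" if r.p4_level is None else r.p4_level,
                "" if r.endometrial_thickness_mm is None else r.endometrial_thickness_mm,
            ])


# ---------------------------------------------------------------------------
# Replicate handling, QC, splitting
# ---------------------------------------------------------------------------

def average_replicates(
    profiles: CqProfileSet,
    include_roles: tuple[AssayRole, ...] = (AssayRole.TARGET,),
) -> FeatureMatrix:
    """Average each patient's replicate profiles into one row per patient.

    Each cell is the arithmetic mean of the patient's non-missing replicate
    values; a cell is missing only when ALL replicates are missing. Only
    assays with a role in ``include_roles`` become features (controls are QC
    plumbing, not model features).
    """
    feature_ids = profiles.assays_with_role(*include_roles)
    fidx = [profiles.assay_ids.index(a) for a in feature_ids]
    patients = profiles.patients
    values = np.full((len(patients), len(feature_ids)), np.nan)
    for r, patient in enumerate(patients):
        cols = [j for j, p in enumerate(profiles.profile_ids)
                if profiles.patient_of_profile[p] == patient]
        block = profiles.cq[np.ix_(fidx, cols)]
        with np.errstate(invalid="ignore"):
            counts = np.sum(~np.isnan(block), axis=1)
            sums = np.nansum(block, axis=1)
        values[r] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return FeatureMatrix(patient_ids=patients, feature_ids=feature_ids,
                         values=values, stage="raw_mean")


def qc_controls(profiles: CqProfileSet,
                spec: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Per-profile control QC: fail when any control is missing or out of range.

    ``spec`` maps every control assay id to its acceptable (low, high) Cq range.
    Returns a frame with columns profile_id, passed, reasons.
    """
    controls = profiles.assays_with_role(AssayRole.ENDOGENOUS_CONTROL, AssayRole.SPIKE_IN)
    absent = [c for c in controls if c not in spec]
    if absent:
        raise ConfigurationError(f"QC spec missing control assays: {absent}")
    rows = []
    for j, prof in enumerate(profiles.profile_ids):
        reasons = []
        for c in controls:
            i = profiles.assay_ids.index(c)
            v = profiles.cq[i, j]
            kind = "spike-in" if profiles.roles[c] is AssayRole.SPIKE_IN else "endogenous control"
            if np.isnan(v):
                reasons.append(f"{kind} {c} not amplified")
            else:
                lo, hi = spec[c]
                if not (lo <= v <= hi):
                    reasons.append(f"{kind} {c} Cq {v:g} outside [{lo:g}, {hi:g}]")
        rows.append({"profile_id": prof, "passed": not reasons, "reasons": "; ".join(reasons)})
    return pd.DataFrame(rows)


def split_train_test(
    patients: list[str],
    fraction_train: float | None = 0.75,
    seed: int = 0,
    train_size: int | None = None,
    labels: dict[str, int] | None = None,
    stratify: bool = False,
) -> tuple[list[str], list[str]]:
    """Randomly partition patients into train/test sets.

    ``train_size`` (explicit count) overrides ``fraction_train``; the fraction
    path uses round-to-nearest (half away from zero). With ``stratify`` the
    split is performed per class using ``labels``.
    """
    n = len(patients)
    if n < 2:
        raise ValueError("need at least 2 patients to split")
    if train_size is None:
        if fraction_train is None or not (0 < fraction_train < 1):
            raise ValueError("fraction_train must be in (0, 1)")
        train_size = int(math.floor(fraction_train * n + 0.5))
    if not (0 < train_size < n):
        raise ValueError(f"train_size {train_size} out of range for n={n}")

    rng = np.random.default_rng(seed)
    if stratify:
        if labels is None:
            raise ConfigurationError("stratified split requires labels")
        train: list[str] = []
        test: list[str] = []
        classes = sorted({labels[p] for p in patients})
        # proportional allocation, largest-remainder on the train side
        quotas = {}
        for cls in classes:
            members = [p for p in patients if labels[p] == cls]
            quotas[cls] = train_size * len(members) / n
        floors = {cls: int(math.floor(q)) for cls, q in quotas.items()}
        leftover = train_size - sum(floors.values())
        order = sorted(classes, key=lambda c: quotas[c] - floors[c], reverse=True)
        for cls in order[:leftover]:
            floors[cls] += 1
        for cls in classes:
            members = [p for p in patients if labels[p] == cls]
            perm = rng.permutation(len(members))
            k = min(floors[cls], len(members))
            train.extend(members[i] for i in perm[:k])
            test.extend(members[i] for i in perm[k:])
        return sorted(train, key=patients.index), sorted(test, key=patients.index)

    perm = rng.permutation(n)
    train_idx = sorted(perm[:train_size])
    test_idx = sorted(perm[train_size:])
    return [patients[i] for i in train_idx], [patients[i] for i in test_idx]
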