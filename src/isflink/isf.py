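"""Derived Indigenous Status Flag (ISF): the two-step multi-stage median algorithm.

A person may hold many administrative records across five linked datasets
(midwives' notifications, birth registrations, hospital morbidity, emergency
department, death registrations), each carrying a recorded Indigenous status
that can disagree between records.  The ISF collapses these into a single
consistent status per person in two steps:

1. within each dataset, derive one status from that dataset's records;
2. combine the per-dataset derived statuses with the same thresholds.

The shared threshold rule, applied to ``k`` non-missing inputs of which ``m``
are Indigenous, is:

* ``k == 0`` -> missing;
* ``k == 1`` -> the recorded status;
* ``k == 2`` -> Indigenous iff ``m >= 1``;
* ``k >= 3`` -> Indigenous iff ``m >= 2``.

Missing statuses never count toward any threshold.  The fixed ``m >= 2``
threshold (rather than a strict majority) makes the flag robust to a single
misclassified record while still letting two independent identifications
dominate any number of negative records.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "StatusValue",
    "INDIGENOUS",
    "NON_INDIGENOUS",
    "MISSING",
    "ISF_DATASETS",
    "DatasetDerivedStatus",
    "ISFlag",
    "derive_dataset_status",
    "derive_isf",
    "derive_all_isf",
]


class StatusValue(str, enum.Enum):
    """Three-valued recorded Indigenous status."""

    INDIGENOUS = "indigenous"
    NON_INDIGENOUS = "non_indigenous"
    MISSING = "missing"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


INDIGENOUS = StatusValue.INDIGENOUS
NON_INDIGENOUS = StatusValue.NON_INDIGENOUS
MISSING = StatusValue.MISSING

#: The five datasets feeding the ISF.
ISF_DATASETS = ("MNS", "BIRTHREG", "HMDC", "EDDC", "DEATH")

#: Datasets whose child records carry a dedicated child-status field.
PERINATAL_DATASETS = ("MNS", "BIRTHREG")


def _coerce(status: object) -> StatusValue:
    """Normalise str/enum/None/NaN to a StatusValue."""
    if isinstance(status, StatusValue):
        return status
    if status is None:
        return MISSING
    if isinstance(status, float) and np.isnan(status):
        return MISSING
    if status is pd.NA:
        return MISSING
    return StatusValue(status)


def _threshold_rule(n_nonmissing: int, n_indigenous: int) -> StatusValue:
    """The shared multi-stage-median threshold applied at both steps."""
    if n_nonmissing == 0:
        return MISSING
    if n_nonmissing == 1:
        return INDIGENOUS if n_indigenous == 1 else NON_INDIGENOUS
    if n_nonmissing == 2:
        return INDIGENOUS if n_indigenous >= 1 else NON_INDIGENOUS
    return INDIGENOUS if n_indigenous >= 2 else NON_INDIGENOUS


@dataclass(frozen=True)
class DatasetDerivedStatus:
    """Step-1 output: one derived status per (person, dataset)."""

    person_id: str
    dataset: str
    n_nonmissing_records: int
    n_indigenous_records: int
    derived: StatusValue


@dataclass(frozen=True)
class ISFlag:
    """Step-2 output: the person-level flag."""

    person_id: str
    n_datasets_with_status: int
    n_datasets_indigenous: int
    flag: StatusValue


def derive_dataset_status(statuses: Iterable[object]) -> StatusValue:
    """Derive a single status from one person's records within one dataset.

    Parameters
    ----------
    statuses
        Recorded statuses of the person's records in the dataset, in any
        order; each may be a :class:`StatusValue`, its string value, ``None``
        or NaN (the latter two treated as missing).

    Returns
    -------
    StatusValue
        Missing entries are discarded; the threshold rule is applied to the
        remainder.
    """
    vals = [_coerce(s) for s in statuses]
    nonmissing = [v for v in vals if v is not MISSING]
    n_ind = sum(1 for v in nonmissing if v is INDIGENOUS)
    return _threshold_rule(len(nonmissing), n_ind)


def derive_isf(dataset_statuses: Iterable[object]) -> StatusValue:
    """Combine per-dataset derived statuses into the person-level flag.

    ``dataset_statuses`` may be :class:`DatasetDerivedStatus` objects or bare
    status values (at most one per dataset).  Duplicate dataset entries are a
    structural error.
    """
    seen: set[str] = set()
    vals: list[StatusValue] = []
    for item in dataset_statuses:
        if isinstance(item, DatasetDerivedStatus):
            if item.dataset in seen:
                raise ValueError(
                    f"duplicate dataset entry {item.dataset!r} for person "
                    f"{item.person_id!r}"
                )
            seen.add(item.dataset)
            vals.append(item.derived)
        else:
            vals.append(_coerce(item))
    return derive_dataset_status(vals)


def _status_used(records: pd.DataFrame, roles: pd.Series) -> pd.Series:
    """Pick, per record, the status field that feeds the subject's own ISF.

    A child's midwives'-notification and birth-registration records carry the
    child's dedicated status field (structurally missing before the year the
    field was introduced); every other record contributes the subject's own
    recorded status.  Parental status fields on a child's records never feed
    anyone's ISF.
    """
    role = records["person_id"].map(roles)
    is_child_perinatal = (role == "child") & records["dataset"].isin(PERINATAL_DATASETS)
    return records["child_status"].where(is_child_perinatal, records["self_status"])


def derive_all_isf(admin_records: pd.DataFrame, persons: pd.DataFrame) -> pd.DataFrame:
    """Derive the ISF for every person in ``persons``.

    Parameters
    ----------
    admin_records
        Long-format records table with columns ``person_id``, ``dataset``,
        ``child_status``, ``self_status`` (status columns hold the string
        values of :class:`StatusValue` or NaN for missing).
    persons
        Person table with columns ``person_id`` and ``role``.  A parent's or
        grandparent's flag uses only records on which they are the subject,
        never status fields on their children's records.

    Returns
    -------
    pandas.DataFrame
        One row per person: ``person_id``, a ``status_<DATASET>`` column per
        ISF dataset with the step-1 derived status, ``n_datasets_with_status``,
        ``n_datasets_indigenous`` and ``flag``.
    """
    persons = persons.reset_index(drop=True)
    pids = persons["person_id"]
    if pids.duplicated().any():
        raise ValueError("person_id not unique in persons table")

    out = pd.DataFrame({"person_id": pids})
    for ds in ISF_DATASETS:
        out[f"status_{ds}"] = np.nan

    if len(admin_records) == 0:
        out["n_datasets_with_status"] = 0
        out["n_datasets_indigenous"] = 0
        out["flag"] = MISSING.value
        return out

    unknown = ~admin_records["person_id"].isin(set(pids))
    if unknown.any():
        bad = admin_records.loc[unknown, "person_id"].iloc[0]
        raise KeyError(f"admin record references unknown person {bad!r}")

    roles = persons.set_index("person_id")["role"]
    recs = admin_records[["person_id", "dataset"]].copy()
    recs["status"] = _status_used(admin_records, roles)
    recs = recs.dropna(subset=["status"])

    # step 1: per (person, dataset)
    recs["is_ind"] = (recs["status"] == INDIGENOUS.value).astype(np.int64)
    step1 = (
        recs.groupby(["person_id", "dataset"], sort=False)
        .agg(n_nonmissing=("status", "size"), n_indigenous=("is_ind", "sum"))
        .reset_index()
    )
    step1["derived"] = _vector_threshold(
        step1["n_nonmissing"].to_numpy(), step1["n_indigenous"].to_numpy()
    )

    # step 2: per person over dataset-derived statuses
    step1["ds_ind"] = (step1["derived"] == INDIGENOUS.value).astype(np.int64)
    step2 = step1.groupby("person_id", sort=False).agg(
        n_datasets_with_status=("derived", "size"),
        n_datasets_indigenous=("ds_ind", "sum"),
    )
    step2["flag"] = _vector_threshold(
        step2["n_datasets_with_status"].to_numpy(),
        step2["n_datasets_indigenous"].to_numpy(),
    )

    wide = step1.pivot(index="person_id", columns="dataset", values="derived")
    for ds in ISF_DATASETS:
        if ds in wide.columns:
            out[f"status_{ds}"] = out["person_id"].map(wide[ds])

    out["n_datasets_with_status"] = (
        out["person_id"].map(step2["n_datasets_with_status"]).fillna(0).astype(int)
    )
    out["n_datasets_indigenous"] = (
        out["person_id"].map(step2["n_datasets_indigenous"]).fillna(0).astype(int)
    )
    out["flag"] = out["person_id"].map(step2["flag"]).fillna(MISSING.value)
    return out


def _vector_threshold(n_nonmissing: np.ndarray, n_indigenous: np.ndarray) -> np.ndarray:
    """Vectorised threshold rule over count arrays (n_nonmissing >= 1)."""
    need = np.where(n_nonmissing == 1, 1, np.where(n_nonmissing == 2, 1, 2))
    ind = n_indigenous >= need
    return np.where(ind, INDIGENOUS.value, NON_INDIGENOUS.value)
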