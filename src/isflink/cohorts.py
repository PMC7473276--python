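"""Cohort identification: Methods A, B and C, inclusion rules and Venn cells.

Three ways of ascertaining Aboriginal and Torres Strait Islander children
from linked administrative data:

* **Method A** — the child's own derived Indigenous Status Flag (ISF);
* **Method B** — the ISF of the child, either parent or any linked
  grandparent (A is a subset of B by construction);
* **Method C** — recorded Indigenous status on the child's perinatal records
  (midwives' notification or birth registration): the child's own status
  where the dataset collects it, otherwise falling back to the maternal
  status (both datasets) or paternal status (birth registration only).
  A non-missing non-Indigenous child status on a dataset suppresses the
  parental fallback for that dataset; the two datasets are evaluated
  independently and OR-ed.

Children enter the analysis only if born inside the study window and linked
to a mother.  A person whose ISF is missing is treated as not identified.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .isf import INDIGENOUS, MISSING

__all__ = [
    "apply_inclusion",
    "method_A",
    "method_B",
    "method_C",
    "assign_cohorts",
    "venn_summary",
    "RELATIVE_COLUMNS",
]

RELATIVE_COLUMNS = (
    "mother_id", "father_id",
    "maternal_gm_id", "maternal_gf_id", "paternal_gm_id", "paternal_gf_id",
)

I = INDIGENOUS.value


def apply_inclusion(
    persons: pd.DataFrame,
    family_links: pd.DataFrame,
    birth_year_range: tuple[int, int] = (2000, 2013),
) -> pd.DataFrame:
    """Inclusion rule: born within the window and mother linked.

    Returns the child rows of ``persons`` with an ``included`` boolean and
    the count of exclusions available via its attrs (``n_motherless``,
    ``n_outside_window``) for audit logging.
    """
    children = persons[persons["role"] == "child"].copy()
    lo, hi = birth_year_range
    in_window = children["birth_year"].between(lo, hi)
    has_mother = children["person_id"].map(
        family_links.set_index("child_id")["mother_id"]
    ).notna()
    children["included"] = (in_window & has_mother).to_numpy()
    children.attrs["n_motherless"] = int((in_window & ~has_mother).sum())
    children.attrs["n_outside_window"] = int((~in_window).sum())
    return children


def _flag_of(isf_table: pd.DataFrame, person_id) -> str:
    flags = isf_table.set_index("person_id")["flag"]
    if person_id not in flags.index:
        raise KeyError(f"no ISF entry for person {person_id!r}")
    return flags.loc[person_id]


def method_A(child_id, isf_table: pd.DataFrame) -> bool:
    """True iff the child's own ISF is Indigenous."""
    return _flag_of(isf_table, child_id) == I


def method_B(child_id, isf_table: pd.DataFrame, family_links: pd.DataFrame) -> bool:
    """True iff the child or any linked parent/grandparent has an Indigenous ISF."""
    if method_A(child_id, isf_table):
        return True
    flags = isf_table.set_index("person_id")["flag"]
    row = family_links.set_index("child_id").loc[child_id]
    for col in RELATIVE_COLUMNS:
        rel = row[col]
        if pd.notna(rel) and flags.get(rel, MISSING.value) == I:
            return True
    return False


def _perinatal_contribution(records: pd.DataFrame, dataset: str) -> pd.Series:
    """Per-child Method-C contribution of one perinatal dataset.

    If the dataset holds any non-missing child status for the child, the
    contribution is "any record with child status Indigenous"; otherwise it
    falls back to the parental fields (maternal on both datasets, paternal on
    the birth registration only).
    """
    recs = records[records["dataset"] == dataset]
    if len(recs) == 0:
        return pd.Series(dtype=bool)
    flags = pd.DataFrame({
        "person_id": recs["person_id"],
        "has_child": recs["child_status"].notna(),
        "child_ind": recs["child_status"] == I,
        "parent_ind": recs["maternal_status"] == I,
    })
    if dataset == "BIRTHREG":
        flags["parent_ind"] |= recs["paternal_status"] == I
    g = flags.groupby("person_id").any()
    return g["child_ind"].where(g["has_child"], g["parent_ind"]).astype(bool)


def method_C(child_id, admin_records: pd.DataFrame) -> bool:
    """True iff the child's perinatal records identify them (with fallback)."""
    recs = admin_records[admin_records["person_id"] == child_id]
    for ds in ("MNS", "BIRTHREG"):
        contrib = _perinatal_contribution(recs, ds)
        if child_id in contrib.index and contrib.loc[child_id]:
            return True
    return False


def _map_bool(keys: pd.Series, mapping: pd.Series) -> np.ndarray:
    """Map ids through a boolean Series; unmapped ids are False."""
    v = keys.map(mapping)
    return np.where(pd.isna(v), False, v).astype(bool)


def _venn_label(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    labels = np.full(len(a), "NONE", dtype=object)
    name = np.char.add(
        np.char.add(np.where(a, "A", ""), np.where(b, "B", "")),
        np.where(c, "C", ""),
    ).astype(object)
    single = {"A": "A-only", "B": "B-only", "C": "C-only"}
    any_in = a | b | c
    labels[any_in] = [single.get(s, s) for s in name[any_in]]
    return labels


def _composition_labels(links: pd.DataFrame, flags: pd.Series) -> np.ndarray:
    """Parental Aboriginality from each parent's own ISF.

    ``parent-missing`` when a parent is unlinked or has a missing flag;
    otherwise the both/mother-only/father-only/neither split.
    """
    mother_flag = links["mother_id"].map(flags)
    father_flag = links["father_id"].map(flags)
    m_miss = links["mother_id"].isna() | mother_flag.isna() | (mother_flag == MISSING.value)
    f_miss = links["father_id"].isna() | father_flag.isna() | (father_flag == MISSING.value)
    m_ind = (mother_flag == I).to_numpy()
    f_ind = (father_flag == I).to_numpy()
    out = np.where(
        (m_miss | f_miss).to_numpy(), "parent-missing",
        np.where(m_ind & f_ind, "both",
                 np.where(m_ind, "mother_only",
                          np.where(f_ind, "father_only", "neither"))),
    )
    return out.astype(object)


def assign_cohorts(
    persons: pd.DataFrame,
    isf_table: pd.DataFrame,
    family_links: pd.DataFrame,
    admin_records: pd.DataFrame,
    birth_year_range: tuple[int, int] = (2000, 2013),
) -> pd.DataFrame:
    """Per-child cohort membership for all three methods (vectorised).

    Returns one row per included child with columns ``child_id``,
    ``birth_year``, ``in_A``, ``in_B``, ``in_C``, ``venn_cell``,
    ``parental_composition``, ``included`` plus an ``mns_child_pathway``
    helper column: true when the child is in Method C but would not be were
    the midwives' child-status field masked, i.e. identification is
    attributable to that field and no other route.  Used by the step-change
    decomposition.
    """
    children = apply_inclusion(persons, family_links, birth_year_range)
    included = children[children["included"]].copy()
    links = family_links.set_index("child_id").reindex(included["person_id"])
    links = links.reset_index().rename(columns={"person_id": "child_id"})

    flags = isf_table.set_index("person_id")["flag"]
    missing_children = set(included["person_id"]) - set(flags.index)
    if missing_children:
        raise KeyError(
            f"no ISF entry for {len(missing_children)} included children, "
            f"e.g. {sorted(missing_children)[:3]}"
        )

    in_a = (included["person_id"].map(flags) == I).to_numpy()
    in_b = in_a.copy()
    for col in RELATIVE_COLUMNS:
        rel_flag = links[col].map(flags)
        in_b |= (rel_flag == I).to_numpy()

    child_recs = admin_records[admin_records["person_id"].isin(included["person_id"])]
    contrib = {}
    for ds in ("MNS", "BIRTHREG"):
        s = _perinatal_contribution(child_recs, ds)
        contrib[ds] = _map_bool(included["person_id"], s)
    in_c = contrib["MNS"] | contrib["BIRTHREG"]

    # Method C re-evaluated with the midwives' child-status field masked: the
    # MNS contribution degrades to the maternal fallback.  Children in C but
    # not in this variant owe their identification to the MNS child status.
    mns = child_recs[child_recs["dataset"] == "MNS"]
    if len(mns):
        mat = (mns["maternal_status"] == I).groupby(mns["person_id"]).any()
        mns_fallback = _map_bool(included["person_id"], mat)
    else:
        mns_fallback = np.zeros(len(included), dtype=bool)
    c_without_mns_child = mns_fallback | contrib["BIRTHREG"]

    out = pd.DataFrame({
        "child_id": included["person_id"].to_numpy(),
        "birth_year": included["birth_year"].to_numpy(),
        "in_A": in_a,
        "in_B": in_b,
        "in_C": in_c,
        "venn_cell": _venn_label(in_a, in_b, in_c),
        "parental_composition": _composition_labels(links, flags),
        "mns_child_pathway": in_c & ~c_without_mns_child,
        "included": True,
    })
    return out


def venn_summary(cohorts: pd.DataFrame) -> pd.DataFrame:
    """Counts and union percentages for the 7 Venn cells plus NONE."""
    order = ["A-only", "B-only", "C-only", "AB", "AC", "BC", "ABC", "NONE"]
    counts = cohorts["venn_cell"].value_counts()
    union = int((cohorts["venn_cell"] != "NONE").sum())
    rows = []
    for cell in order:
        n = int(counts.get(cell, 0))
        pct = 100.0 * n / union if union and cell != "NONE" else np.nan
        rows.append({"venn_cell": cell, "count": n, "pct_of_union": pct})
    rows.append({"venn_cell": "UNION", "count": union, "pct_of_union": 100.0 if union else np.nan})
    return pd.DataFrame(rows)
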