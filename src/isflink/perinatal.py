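"""Perinatal outcome classification: preterm categories, LBW, SGA, Apgar.

Categories follow the conventions used for reporting Australian perinatal
outcomes:

* preterm: extremely (<28 weeks), very ([28, 32)), moderate-to-late
  ([32, 37)) and term (>=37 completed weeks) — half-open intervals, so a
  birth at exactly 32.0 weeks is moderate-to-late preterm;
* low birth weight (LBW): birthweight strictly below 2,500 g;
* small for gestational age (SGA): birthweight strictly below the 10th
  percentile for sex and completed gestational week.  The reference grid of
  cut-offs can be estimated empirically from a population or loaded from an
  external table (sex, week, cutoff_g);
* Apgar: score >= 9 at one minute, among live births.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PRETERM_CATEGORIES",
    "classify_preterm",
    "classify_lbw",
    "SGAReference",
    "build_sga_reference",
    "classify_sga",
    "classify_all",
]

PRETERM_CATEGORIES = (
    "extremely_preterm", "very_preterm", "moderate_late_preterm", "term", "missing",
)

_PRETERM_EDGES = np.array([28.0, 32.0, 37.0])
_PRETERM_LABELS = np.array(
    ["extremely_preterm", "very_preterm", "moderate_late_preterm", "term"],
    dtype=object,
)


def classify_preterm(gestational_age_weeks):
    """Preterm category for a gestational age in weeks (scalar or array).

    Missing inputs map to ``"missing"``; negative values or values above 45
    weeks raise a validation error.
    """
    ga = np.asarray(gestational_age_weeks, dtype=float)
    scalar = ga.ndim == 0
    ga = np.atleast_1d(ga)
    valid = ~np.isnan(ga)
    if (ga[valid] < 0).any() or (ga[valid] > 45).any():
        bad = ga[valid][(ga[valid] < 0) | (ga[valid] > 45)][0]
        raise ValueError(f"gestational age out of range [0, 45] weeks: {bad}")
    out = np.full(ga.shape, "missing", dtype=object)
    out[valid] = _PRETERM_LABELS[np.searchsorted(_PRETERM_EDGES, ga[valid], side="right")]
    return out[0] if scalar else out


def classify_lbw(birthweight_g):
    """Low birth weight: strictly below 2,500 g; missing stays missing."""
    bw = np.asarray(birthweight_g, dtype=float)
    scalar = bw.ndim == 0
    bw = np.atleast_1d(bw)
    valid = ~np.isnan(bw)
    if (bw[valid] <= 0).any():
        raise ValueError("birthweight must be positive")
    out = np.where(valid, bw < 2500.0, np.nan).astype(object)
    out[valid] = bw[valid] < 2500.0
    out[~valid] = np.nan
    if scalar:
        v = out[0]
        return v if v is np.nan else bool(v)
    return out


@dataclass
class SGAReference:
    """10th-percentile birthweight cut-offs by sex and completed week.

    ``table`` has columns ``sex``, ``week`` (completed gestational week) and
    ``cutoff_g``.  Cut-offs are non-decreasing in week within sex (enforced
    when built empirically).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sex", "week", "cutoff_g"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"SGA reference needs columns {sorted(required)}")

    def cutoff(self, sex, week):
        """Cut-off for one (sex, completed week) cell; KeyError if uncovered."""
        t = self.table
        row = t[(t["sex"] == sex) & (t["week"] == week)]
        if len(row) == 0:
            raise KeyError(f"SGA reference does not cover cell (sex={sex!r}, week={week})")
        return float(row["cutoff_g"].iloc[0])

    @classmethod
    def from_file(cls, path: str | Path) -> "SGAReference":
        return cls(pd.read_csv(path))


def build_sga_reference(
    perinatal_records: pd.DataFrame,
    min_cell_count: int = 50,
    quantile: float = 0.10,
) -> SGAReference:
    """Empirical sex x completed-week percentile cut-offs.

    One perinatal row per child is used (midwives' record preferred).  Weeks
    with fewer than ``min_cell_count`` births are pooled with the adjacent
    earlier week(s); the pooled cut-off is assigned to every pooled week.
    Cut-offs are made non-decreasing in week within sex (monotone envelope),
    reflecting that the 10th percentile of birthweight rises with gestation.
    """
    recs = _one_row_per_child(perinatal_records)
    recs = recs.dropna(subset=["gestational_age_weeks", "birthweight_g"])
    if len(recs) == 0:
        raise ValueError("no usable perinatal records to build SGA reference")
    recs = recs.assign(week=np.floor(recs["gestational_age_weeks"].astype(float)).astype(int))
    rows = []
    for sex, grp in recs.groupby("sex"):
        weeks = sorted(grp["week"].unique())
        pooled_weeks: list[int] = []
        pooled_values: list[np.ndarray] = []
        for wk in weeks:
            pooled_weeks.append(wk)
            pooled_values.append(grp.loc[grp["week"] == wk, "birthweight_g"].to_numpy(float))
            if sum(len(v) for v in pooled_values) >= min_cell_count:
                cut = float(np.quantile(np.concatenate(pooled_values), quantile))
                rows += [{"sex": sex, "week": w, "cutoff_g": cut} for w in pooled_weeks]
                pooled_weeks, pooled_values = [], []
        if pooled_weeks:  # trailing underfull pool: merge into the last cut-off
            vals = np.concatenate(pooled_values)
            if rows and rows[-1]["sex"] == sex:
                prev = rows[-1]["cutoff_g"]
                cut = max(prev, float(np.quantile(vals, quantile)))
            else:
                cut = float(np.quantile(vals, quantile))
            rows += [{"sex": sex, "week": w, "cutoff_g": cut} for w in pooled_weeks]
    table = pd.DataFrame(rows)
    table["cutoff_g"] = table.groupby("sex")["cutoff_g"].cummax()
    return SGAReference(table)


def classify_sga(birthweight_g, sex, gestational_age_weeks, reference: SGAReference):
    """SGA indicator: birthweight strictly below the reference cut-off.

    Scalar or array inputs; any missing input yields missing.  An uncovered
    (sex, week) cell raises a KeyError naming the cell.
    """
    bw = np.atleast_1d(np.asarray(birthweight_g, dtype=float))
    ga = np.atleast_1d(np.asarray(gestational_age_weeks, dtype=float))
    sx = np.atleast_1d(np.asarray(sex, dtype=object))
    scalar = np.asarray(birthweight_g).ndim == 0
    valid = ~np.isnan(bw) & ~np.isnan(ga) & pd.notna(sx)
    week = np.full(len(bw), -1, dtype=int)
    week[valid] = np.floor(ga[valid]).astype(int)

    cells = pd.DataFrame({"sex": sx, "week": week})
    merged = cells.merge(reference.table, on=["sex", "week"], how="left")
    cut = merged["cutoff_g"].to_numpy(float)
    uncovered = valid & np.isnan(cut)
    if uncovered.any():
        i = int(np.flatnonzero(uncovered)[0])
        raise KeyError(
            f"SGA reference does not cover cell (sex={sx[i]!r}, week={week[i]})"
        )
    out = np.full(len(bw), np.nan, dtype=object)
    out[valid] = bw[valid] < cut[valid]
    if scalar:
        v = out[0]
        return v if v is np.nan else bool(v)
    return out


def _one_row_per_child(perinatal_records: pd.DataFrame) -> pd.DataFrame:
    """Midwives' row per child, falling back to the birth registration."""
    order = pd.Categorical(
        perinatal_records["source"], categories=["MNS", "BIRTHREG"], ordered=True
    )
    recs = perinatal_records.assign(_order=order).sort_values(["child_id", "_order"])
    return recs.drop_duplicates("child_id", keep="first").drop(columns="_order")


def classify_all(
    perinatal_records: pd.DataFrame,
    reference: SGAReference | None = None,
    min_cell_count: int = 50,
) -> pd.DataFrame:
    """Classify every child: one row of PerinatalClassification per child.

    The SGA reference defaults to an empirical self-reference built from the
    supplied records; pass an external :class:`SGAReference` to override.
    """
    recs = _one_row_per_child(perinatal_records).reset_index(drop=True)
    if reference is None:
        reference = build_sga_reference(perinatal_records, min_cell_count=min_cell_count)
    ga = recs["gestational_age_weeks"].astype(float)
    bw = recs["birthweight_g"].astype(float)
    apgar = recs["apgar_1min"].astype(float)
    out = pd.DataFrame({
        "child_id": recs["child_id"],
        "preterm_category": classify_preterm(ga.to_numpy()),
        "lbw": classify_lbw(bw.to_numpy()),
        "sga": classify_sga(bw.to_numpy(), recs["sex"].to_numpy(),
                            ga.to_numpy(), reference),
        "apgar_ge9": np.where(apgar.notna(), apgar >= 9, np.nan).astype(object),
        "gestational_age_weeks": ga,
        "birthweight_g": bw,
        "live_born": recs["live_born"].astype(bool),
    })
    out.loc[apgar.isna(), "apgar_ge9"] = np.nan
    return out
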