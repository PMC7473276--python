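"""Tests for inclusion rules, Methods A/B/C and Venn-cell assignment."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from isflink import (
    SimulationConfig,
    apply_inclusion,
    assign_cohorts,
    derive_all_isf,
    generate_population,
    make_fixture,
    method_A,
    method_B,
    method_C,
    venn_summary,
)

I, N = "indigenous", "non_indigenous"

RECORD_COLS = ["record_id", "person_id", "dataset", "record_year",
               "child_status", "maternal_status", "paternal_status", "self_status"]
LINK_COLS = ["child_id", "mother_id", "father_id", "maternal_gm_id",
             "maternal_gf_id", "paternal_gm_id", "paternal_gf_id"]


def _rec(rid, pid, ds, year, child=np.nan, mat=np.nan, pat=np.nan, self_=np.nan):
    return dict(zip(RECORD_COLS, [rid, pid, ds, year, child, mat, pat, self_]))


def _links(rows):
    return pd.DataFrame(rows).reindex(columns=LINK_COLS)


@pytest.fixture()
def four_child_population():
    """Hand-built population realising A={c1,c2}, B={c1,c2,c3}, C={c2,c3,c4}."""
    persons = pd.DataFrame({
        "person_id": ["c1", "c2", "c3", "c4", "m1", "m2", "m3", "m4", "f3"],
        "role": ["child"] * 4 + ["mother"] * 4 + ["father"],
        "birth_year": [2005.0, 2005.0, 2005.0, 2005.0] + [np.nan] * 5,
    })
    links = _links([
        {"child_id": "c1", "mother_id": "m1"},
        {"child_id": "c2", "mother_id": "m2"},
        {"child_id": "c3", "mother_id": "m3", "father_id": "f3"},
        {"child_id": "c4", "mother_id": "m4"},
    ])
    records = pd.DataFrame([
        # c1: own flag indigenous via hospital records; perinatal silent
        _rec("r1", "c1", "HMDC", 2006, self_=I),
        _rec("r2", "c1", "MNS", 2005, mat=N),
        # c2: own flag indigenous AND maternal fallback on the midwives' record
        _rec("r3", "c2", "HMDC", 2006, self_=I),
        _rec("r4", "c2", "MNS", 2005, mat=I),
        # c3: own flag non-indigenous; indigenous father; maternal fallback
        _rec("r5", "c3", "HMDC", 2006, self_=N),
        _rec("r6", "c3", "MNS", 2005, mat=I),
        _rec("r7", "f3", "HMDC", 2001, self_=I),
        _rec("r8", "m3", "HMDC", 2001, self_=N),
        # c4: no indigenous relative flag, identified only by the maternal
        # status recorded on the midwives' notification
        _rec("r9", "c4", "HMDC", 2006, self_=N),
        _rec("r10", "c4", "MNS", 2005, mat=I),
        _rec("r11", "m4", "HMDC", 2001, self_=N),
        # remaining mothers: one non-indigenous record each
        _rec("r12", "m1", "HMDC", 2001, self_=N),
        _rec("r13", "m2", "HMDC", 2001, self_=N),
    ])
    isf = derive_all_isf(records, persons)
    return persons, links, records, isf


class TestInclusion:
    def test_motherless_and_out_of_window_children_excluded(self):
        persons = pd.DataFrame({
            "person_id": ["a", "b", "c", "m"],
            "role": ["child", "child", "child", "mother"],
            "birth_year": [2005.0, 2005.0, 1999.0, np.nan],
        })
        links = _links([
            {"child_id": "a", "mother_id": "m"},
            {"child_id": "b"},
            {"child_id": "c", "mother_id": "m"},
        ])
        out = apply_inclusion(persons, links).set_index("person_id")
        assert out.loc["a", "included"]
        assert not out.loc["b", "included"]       # no linked mother
        assert not out.loc["c", "included"]       # outside the birth window
        assert out.attrs["n_motherless"] == 1

    def test_all_mothers_linked_means_all_included(self, small_population):
        _, persons, links, _, _ = small_population
        out = apply_inclusion(persons, links)
        assert out["included"].all()


class TestMethodRules:
    def test_father_only_fixture_in_B_not_A_not_C(self):
        persons, links, records, _ = make_fixture("father-only-indigenous")
        isf = derive_all_isf(records, persons)
        assert not method_A("C1", isf)
        assert method_B("C1", isf, links)
        assert not method_C("C1", records)

    def test_method_A_ignores_relatives(self, four_child_population):
        persons, links, records, isf = four_child_population
        assert not method_A("c3", isf)  # indigenous father does not matter
        assert method_A("c1", isf)

    def test_method_B_disjunction_over_grandparents(self):
        persons = pd.DataFrame({
            "person_id": ["c", "m", "pgf"],
            "role": ["child", "mother", "grandparent"],
            "birth_year": [2005.0, np.nan, np.nan],
        })
        links = _links([{"child_id": "c", "mother_id": "m", "paternal_gf_id": "pgf"}])
        records = pd.DataFrame([
            _rec("r1", "c", "HMDC", 2006, self_=N),
            _rec("r2", "m", "HMDC", 2001, self_=N),
            _rec("r3", "pgf", "HMDC", 1999, self_=I),
        ])
        isf = derive_all_isf(records, persons)
        assert method_B("c", isf, links)
        assert not method_A("c", isf)

    def test_method_C_maternal_fallback_when_child_status_missing(self):
        records = pd.DataFrame([_rec("r", "c", "MNS", 2005, mat=I)])
        assert method_C("c", records)

    def test_method_C_nonmissing_child_status_blocks_parental_fallback(self):
        records = pd.DataFrame([_rec("r", "c", "BIRTHREG", 2010, child=N, pat=I)])
        assert not method_C("c", records)

    def test_method_C_ignores_paternal_field_on_midwives_record(self):
        records = pd.DataFrame([_rec("r", "c", "MNS", 2005, pat=I)])
        assert not method_C("c", records)

    def test_method_C_datasets_evaluated_independently_and_ored(self):
        records = pd.DataFrame([
            _rec("r1", "c", "MNS", 2013, child=I),
            _rec("r2", "c", "BIRTHREG", 2013, child=N),
        ])
        assert method_C("c", records)

    def test_method_C_no_perinatal_records_is_false(self):
        assert not method_C("c", pd.DataFrame(columns=RECORD_COLS))


class TestAssignCohorts:
    def test_four_child_set_algebra(self, four_child_population):
        persons, links, records, isf = four_child_population
        cohorts = assign_cohorts(persons, isf, links, records).set_index("child_id")
        assert cohorts["in_A"].sum() == 2
        assert cohorts["in_B"].sum() == 3
        assert cohorts["in_C"].sum() == 3
        assert cohorts.loc["c1", "venn_cell"] == "AB"
        assert cohorts.loc["c2", "venn_cell"] == "ABC"
        assert cohorts.loc["c3", "venn_cell"] == "BC"
        assert cohorts.loc["c4", "venn_cell"] == "C-only"
        summary = venn_summary(cohorts.reset_index())
        union = summary.set_index("venn_cell")
        assert union.loc["UNION", "count"] == 4
        cells = ["A-only", "B-only", "C-only", "AB", "AC", "BC", "ABC"]
        assert union.loc[cells, "count"].sum() == 4

    def test_A_subset_of_B_structurally(self, study_regime):
        coh = study_regime["cohorts"]
        assert not (coh["in_A"] & ~coh["in_B"]).any()
        assert (coh["venn_cell"] != "A-only").all()
        assert (coh["venn_cell"] != "AC").all()

    def test_parental_composition_from_parents_own_flags(self, four_child_population):
        persons, links, records, isf = four_child_population
        cohorts = assign_cohorts(persons, isf, links, records).set_index("child_id")
        # c3 has a linked indigenous father and non-indigenous mother
        assert cohorts.loc["c3", "parental_composition"] == "father_only"
        # the others have no linked father at all
        assert cohorts.loc["c1", "parental_composition"] == "parent-missing"

    def test_missing_isf_entry_for_child_raises(self, four_child_population):
        persons, links, records, isf = four_child_population
        with pytest.raises(KeyError):
            assign_cohorts(persons, isf[isf["person_id"] != "c1"], links, records)


def test_raising_child_propensity_grows_A_and_shrinks_B_minus_A():
    """With a shared seed the record draws are coupled, so raising the
    child-record propensity can only add indigenous records: Method A grows
    and the relatives-only remainder B-minus-A shrinks."""
    base = SimulationConfig(n_families=2000, seed=13)
    boosted = dataclasses.replace(
        base,
        recording=dataclasses.replace(
            base.recording,
            composition_mult={k: 1.0 for k in base.recording.composition_mult},
        ),
    )
    sizes = {}
    for name, cfg in (("base", base), ("boosted", boosted)):
        persons, links, records, _ = generate_population(cfg)
        isf = derive_all_isf(records, persons)
        coh = assign_cohorts(persons, isf, links, records)
        sizes[name] = (int(coh["in_A"].sum()),
                       int((coh["in_B"] & ~coh["in_A"]).sum()))
    assert sizes["boosted"][0] >= sizes["base"][0]
    assert sizes["boosted"][1] <= sizes["base"][1]
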