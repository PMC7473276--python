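"""Seeded synthetic generator for multi-generational linked administrative data.

Produces four tables mirroring a de-identified linked extract:

``persons``
    one row per person (child, mother, father, grandparents) with ground-truth
    Indigenous status (simulator-only) and area attributes;
``family_links``
    one row per child with optional links to mother, father and four
    grandparents;
``admin_records``
    long format, one row per administrative record across the five datasets
    feeding the derived status flag, with three-valued recorded status fields;
``perinatal_records``
    gestational age, birthweight, Apgar and live-birth flag on the child's
    midwives' notification and (optional) birth registration.

The generative model is deliberately simple: per-field Bernoulli recording of
Indigenous status conditioned on the subject's ground truth, with propensity
reduced for children's own fields in urban / less-disadvantaged areas and in
father-only-Indigenous families.  Ground truth means "would identify given
full opportunity"; it exists to support recovery tests of the identification
algorithms, not as a claim about real-world validity.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import COMPOSITIONS, REMOTENESS_LEVELS, SimulationConfig

__all__ = [
    "generate_population",
    "make_fixture",
    "FIXTURES",
    "write_tables",
    "read_tables",
    "disadvantage_score",
]

PERSON_COLUMNS = [
    "person_id", "role", "true_indigenous", "birth_year",
    "irsd_quintile", "remoteness", "indigenous_region", "sex",
]
LINK_COLUMNS = [
    "child_id", "mother_id", "father_id",
    "maternal_gm_id", "maternal_gf_id", "paternal_gm_id", "paternal_gf_id",
]
RECORD_COLUMNS = [
    "record_id", "person_id", "dataset", "record_year",
    "child_status", "maternal_status", "paternal_status", "self_status",
]
PERINATAL_COLUMNS = [
    "child_id", "source", "gestational_age_weeks", "birthweight_g",
    "apgar_1min", "live_born", "sex",
]

I, N = "indigenous", "non_indigenous"

# area profiles: (irsd quintile probs 1..5, remoteness probs in REMOTENESS_LEVELS order)
_URBAN_PROFILE = (
    np.array([0.08, 0.15, 0.22, 0.27, 0.28]),
    np.array([0.70, 0.12, 0.10, 0.05, 0.03]),
)
_DISADVANTAGED_PROFILE = (
    np.array([0.50, 0.22, 0.13, 0.09, 0.06]),
    np.array([0.30, 0.06, 0.17, 0.20, 0.27]),
)
_GENERAL_PROFILE = (
    np.array([0.18, 0.20, 0.20, 0.21, 0.21]),
    np.array([0.75, 0.11, 0.08, 0.04, 0.02]),
)

_REGIONS_BY_REMOTENESS = {
    "major_city": ["Perth"],
    "inner_regional": ["South-Western", "Perth"],
    "outer_regional": ["Geraldton", "South-Western", "Kalgoorlie"],
    "remote": ["Kalgoorlie", "South Hedland", "Broome", "Geraldton"],
    "very_remote": ["Kununurra", "West-Kimberley", "Broome", "South Hedland"],
}

_IRSD_SCORE = {1: 1.0, 2: 0.75, 3: 0.5, 4: 0.25, 5: 0.0}
_REMOTE_SCORE = {
    "very_remote": 1.0, "remote": 0.8, "outer_regional": 0.55,
    "inner_regional": 0.3, "major_city": 0.0,
}


def disadvantage_score(irsd_quintile, remoteness) -> np.ndarray:
    """Combined area-disadvantage score in [0, 1]; missing geography -> 0.5."""
    irsd = pd.Series(irsd_quintile).map(_IRSD_SCORE)
    rem = pd.Series(remoteness).map(_REMOTE_SCORE)
    d = 0.6 * irsd + 0.4 * rem
    return d.fillna(0.5).to_numpy()


def _empty_tables():
    return (
        pd.DataFrame(columns=PERSON_COLUMNS),
        pd.DataFrame(columns=LINK_COLUMNS),
        pd.DataFrame(columns=RECORD_COLUMNS),
        pd.DataFrame(columns=PERINATAL_COLUMNS),
    )


def _draw_status(rng, truth, propensity, p_missing):
    """Recorded status for one field: Bernoulli(propensity) given truth, then
    independently blanked to missing with ``p_missing``."""
    n = len(truth)
    rec = np.where(truth & (rng.random(n) < propensity), I, N).astype(object)
    if p_missing > 0:
        rec[rng.random(n) < p_missing] = np.nan
    return rec


def generate_population(config: SimulationConfig):
    """Draw one synthetic population.

    Returns ``(persons, family_links, admin_records, perinatal_records)`` as
    pandas DataFrames.  Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    n = config.n_families
    if n == 0:
        return _empty_tables()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.birth_year_range
    rec = config.recording
    fam = np.arange(n)

    # ---------------------------------------------------------------- families
    year_values = np.arange(lo, hi + 1)
    weights = 1.0 + config.birth_year_weight_growth * (year_values - lo)
    birth_year = rng.choice(year_values, size=n, p=weights / weights.sum())
    heritage = rng.random(n) < config.p_indigenous_family
    comp_probs = np.array(
        [config.parental_composition_probs[c] for c in COMPOSITIONS]
    )
    comp_draw = rng.choice(len(COMPOSITIONS), size=n, p=comp_probs)
    composition = np.where(
        heritage, np.array(COMPOSITIONS, dtype=object)[comp_draw], "none"
    ).astype(object)

    # geography: father-only / neither heritage families skew urban,
    # both / mother-only skew disadvantaged, non-heritage follow the state profile
    irsd = np.empty(n, dtype=object)
    remoteness = np.empty(n, dtype=object)
    masks = {
        "urban": np.isin(composition, ("father_only", "neither")),
        "disadv": np.isin(composition, ("both", "mother_only")),
        "general": composition == "none",
    }
    profiles = {
        "urban": _URBAN_PROFILE,
        "disadv": _DISADVANTAGED_PROFILE,
        "general": _GENERAL_PROFILE,
    }
    for key, mask in masks.items():
        m = int(mask.sum())
        if m == 0:
            continue
        irsd_p, rem_p = profiles[key]
        irsd[mask] = rng.choice(np.arange(1, 6), size=m, p=irsd_p)
        remoteness[mask] = rng.choice(
            np.array(REMOTENESS_LEVELS, dtype=object), size=m, p=rem_p
        )
    region = np.empty(n, dtype=object)
    for level, choices in _REGIONS_BY_REMOTENESS.items():
        mask = remoteness == level
        m = int(mask.sum())
        if m:
            region[mask] = rng.choice(np.array(choices, dtype=object), size=m)
    geo_missing = rng.random(n) < config.missing_geography_prob
    irsd[geo_missing] = np.nan
    remoteness[geo_missing] = np.nan
    region[geo_missing] = np.nan

    # ------------------------------------------------------------------ links
    mother_linked = rng.random(n) < config.p_mother_linked
    father_linked = rng.random(n) < config.p_father_linked
    maternal_gp_linked = mother_linked & (rng.random(n) < config.p_maternal_gp_linked)
    # paternal grandparents can only be linked through a linked father; the
    # conditional rate is chosen so the unconditional rate matches the config
    p_pgp_cond = (
        min(1.0, config.p_paternal_gp_linked / config.p_father_linked)
        if config.p_father_linked > 0 else 0.0
    )
    paternal_gp_linked = father_linked & (rng.random(n) < p_pgp_cond)

    # ------------------------------------------------------------------ truth
    child_true = heritage
    mother_true = np.isin(composition, ("both", "mother_only"))
    father_true = np.isin(composition, ("both", "father_only"))
    p_gp = config.p_grandparent_indigenous_given_parent
    gp_true = {
        "MGM": mother_true & (rng.random(n) < p_gp),
        "MGF": mother_true & (rng.random(n) < p_gp),
        "PGM": father_true & (rng.random(n) < p_gp),
        "PGF": father_true & (rng.random(n) < p_gp),
    }

    # ---------------------------------------------------------------- persons
    width = max(6, len(str(n)))
    fid = np.char.zfill(fam.astype(str), width)
    child_id = np.char.add("F", np.char.add(fid, "_C")).astype(object)
    child_sex = np.where(rng.random(n) < config.p_male, "male", "female").astype(object)

    def _ids(suffix):
        return np.char.add("F", np.char.add(fid, "_" + suffix)).astype(object)

    person_frames = [
        pd.DataFrame({
            "person_id": child_id, "role": "child", "true_indigenous": child_true,
            "birth_year": birth_year.astype(float), "irsd_quintile": irsd,
            "remoteness": remoteness, "indigenous_region": region, "sex": child_sex,
        })
    ]
    adult_specs = [  # (suffix, role, linked mask, truth, sex)
        ("M", "mother", mother_linked, mother_true, "female"),
        ("F", "father", father_linked, father_true, "male"),
        ("MGM", "grandparent", maternal_gp_linked, gp_true["MGM"], "female"),
        ("MGF", "grandparent", maternal_gp_linked, gp_true["MGF"], "male"),
        ("PGM", "grandparent", paternal_gp_linked, gp_true["PGM"], "female"),
        ("PGF", "grandparent", paternal_gp_linked, gp_true["PGF"], "male"),
    ]
    adult_ids = {}
    adult_fam = {}
    for suffix, role, linked, truth, sex in adult_specs:
        ids = _ids(suffix)
        adult_ids[suffix] = ids
        adult_fam[suffix] = fam[linked]
        person_frames.append(pd.DataFrame({
            "person_id": ids[linked], "role": role,
            "true_indigenous": truth[linked], "birth_year": np.nan,
            "irsd_quintile": irsd[linked], "remoteness": remoteness[linked],
            "indigenous_region": region[linked], "sex": sex,
        }))
    persons = pd.concat(person_frames, ignore_index=True)[PERSON_COLUMNS]

    def _opt(ids, linked):
        out = ids.copy()
        out[~linked] = np.nan
        return out

    family_links = pd.DataFrame({
        "child_id": child_id,
        "mother_id": _opt(adult_ids["M"], mother_linked),
        "father_id": _opt(adult_ids["F"], father_linked),
        "maternal_gm_id": _opt(adult_ids["MGM"], maternal_gp_linked),
        "maternal_gf_id": _opt(adult_ids["MGF"], maternal_gp_linked),
        "paternal_gm_id": _opt(adult_ids["PGM"], paternal_gp_linked),
        "paternal_gf_id": _opt(adult_ids["PGF"], paternal_gp_linked),
    })[LINK_COLUMNS]

    # ----------------------------------------------------- recording propensity
    irsd_mult = pd.Series(irsd).map(rec.irsd_mult).fillna(1.0).to_numpy()
    rem_mult = pd.Series(remoteness).map(rec.remoteness_mult).fillna(1.0).to_numpy()
    comp_mult = pd.Series(composition).map(rec.composition_mult).fillna(1.0).to_numpy()
    # area modifiers and the family frailty act on the whole family; the
    # composition modifier is specific to the child's own fields
    frailty = (
        np.exp(rng.normal(0.0, rec.family_frailty_sd, size=n))
        if rec.family_frailty_sd > 0 else np.ones(n)
    )
    area_mult = irsd_mult * rem_mult * frailty
    context_mult = area_mult * comp_mult

    def child_propensity(dataset):
        return np.clip(rec.child_base[dataset] * context_mult, 0.0, 1.0)

    pm = rec.p_status_missing
    record_frames = []

    # ------------------------------------------------------- child MNS record
    mns_child_status = np.full(n, np.nan, dtype=object)
    in_era = birth_year >= config.mns_child_status_from
    p_mns_child = np.clip(
        rec.child_base["MNS"] * context_mult ** rec.mns_child_context_damping,
        0.0, 1.0,
    )
    drawn = _draw_status(rng, child_true, p_mns_child, pm)
    mns_child_status[in_era] = drawn[in_era]
    p_maternal = np.clip(rec.p_record_maternal * area_mult, 0.0, 1.0)
    p_paternal = np.clip(rec.p_record_paternal * area_mult, 0.0, 1.0)
    p_adult_self = np.clip(rec.p_record_adult_self * area_mult, 0.0, 1.0)
    mns_maternal = _draw_status(rng, mother_true, p_maternal, pm)
    mns_maternal[~mother_linked] = np.nan
    record_frames.append(pd.DataFrame({
        "person_id": child_id, "dataset": "MNS", "record_year": birth_year,
        "child_status": mns_child_status, "maternal_status": mns_maternal,
        "paternal_status": np.nan, "self_status": np.nan,
    }))

    # ------------------------------------------------- child birth registration
    has_br = rng.random(n) < config.p_birthreg_record
    br_child_status = np.full(n, np.nan, dtype=object)
    in_era = birth_year >= config.birthreg_child_status_from
    drawn = _draw_status(rng, child_true, child_propensity("BIRTHREG"), pm)
    br_child_status[in_era] = drawn[in_era]
    br_maternal = _draw_status(rng, mother_true, p_maternal, pm)
    br_maternal[~mother_linked] = np.nan
    br_paternal = _draw_status(rng, father_true, p_paternal, pm)
    br_paternal[~father_linked] = np.nan
    record_frames.append(pd.DataFrame({
        "person_id": child_id[has_br], "dataset": "BIRTHREG",
        "record_year": birth_year[has_br],
        "child_status": br_child_status[has_br],
        "maternal_status": br_maternal[has_br],
        "paternal_status": br_paternal[has_br], "self_status": np.nan,
    }))

    # --------------------------------------------------- child morbidity/death
    for ds, rate in config.child_morbidity_rate.items():
        counts = rng.poisson(rate, size=n)
        idx = np.repeat(fam, counts)
        if len(idx):
            years = birth_year[idx] + rng.integers(0, 6, size=len(idx))
            record_frames.append(pd.DataFrame({
                "person_id": child_id[idx], "dataset": ds, "record_year": years,
                "child_status": np.nan, "maternal_status": np.nan,
                "paternal_status": np.nan,
                "self_status": _draw_status(
                    rng, child_true[idx], child_propensity(ds)[idx], pm),
            }))
    died = rng.random(n) < config.p_child_death_record
    if died.any():
        idx = fam[died]
        record_frames.append(pd.DataFrame({
            "person_id": child_id[idx], "dataset": "DEATH",
            "record_year": birth_year[idx] + rng.integers(0, 5, size=len(idx)),
            "child_status": np.nan, "maternal_status": np.nan,
            "paternal_status": np.nan,
            "self_status": _draw_status(
                rng, child_true[idx], child_propensity("DEATH")[idx], pm),
        }))

    # ----------------------------------------------------------- adult records
    truth_by_suffix = {
        "M": mother_true, "F": father_true,
        "MGM": gp_true["MGM"], "MGF": gp_true["MGF"],
        "PGM": gp_true["PGM"], "PGF": gp_true["PGF"],
    }
    for suffix, _, linked, truth, _ in adult_specs:
        afam = adult_fam[suffix]
        if len(afam) == 0:
            continue
        for ds, rate in config.adult_morbidity_rate.items():
            counts = rng.poisson(rate, size=len(afam))
            idx = np.repeat(afam, counts)
            if len(idx):
                record_frames.append(pd.DataFrame({
                    "person_id": adult_ids[suffix][idx], "dataset": ds,
                    "record_year": rng.integers(lo, hi + 1, size=len(idx)),
                    "child_status": np.nan, "maternal_status": np.nan,
                    "paternal_status": np.nan,
                    "self_status": _draw_status(
                        rng, truth_by_suffix[suffix][idx],
                        p_adult_self[idx], pm),
                }))
        adied = rng.random(len(afam)) < config.p_adult_death_record
        if adied.any():
            idx = afam[adied]
            record_frames.append(pd.DataFrame({
                "person_id": adult_ids[suffix][idx], "dataset": "DEATH",
                "record_year": rng.integers(lo, hi + 1, size=len(idx)),
                "child_status": np.nan, "maternal_status": np.nan,
                "paternal_status": np.nan,
                "self_status": _draw_status(
                    rng, truth_by_suffix[suffix][idx],
                    p_adult_self[idx], pm),
            }))

    admin_records = pd.concat(record_frames, ignore_index=True)
    admin_records.insert(
        0, "record_id",
        np.char.add("R", np.char.zfill(
            np.arange(len(admin_records)).astype(str), 8)),
    )
    admin_records = admin_records[RECORD_COLUMNS]

    # ------------------------------------------------------- perinatal outcomes
    eff = config.perinatal_effects
    d = disadvantage_score(irsd, remoteness)
    ga = rng.normal(eff.ga_mean_base + eff.ga_mean_slope * d,
                    eff.ga_sd_base + eff.ga_sd_slope * d)
    ga = np.clip(ga, 20.0, 44.0).round(1)
    male = (child_sex == "male")
    bw = rng.normal(
        eff.bw_mean_base + eff.bw_male_shift * male
        + eff.bw_disadvantage_slope * d + eff.bw_per_week * (ga - 40.0),
        eff.bw_sd,
    )
    bw = np.clip(bw, 200.0, 6500.0).round(0)
    p_ge9 = np.clip(eff.apgar_ge9_base + eff.apgar_ge9_slope * d, 0.01, 0.99)
    ge9 = rng.random(n) < p_ge9
    low_apgar = np.clip(np.rint(rng.normal(7.0, 1.5, size=n)), 0, 8)
    apgar = np.where(ge9, 9 + (rng.random(n) < 0.5), low_apgar).astype(float)
    p_still = np.clip(eff.p_stillbirth_base + eff.p_stillbirth_slope * d, 0.0, 1.0)
    live_born = rng.random(n) >= p_still

    ga = ga.astype(object)
    bw = bw.astype(object)
    apgar = apgar.astype(object)
    ga[rng.random(n) < eff.p_ga_missing] = np.nan
    bw[rng.random(n) < eff.p_bw_missing] = np.nan
    apgar[(rng.random(n) < eff.p_apgar_missing) | ~live_born] = np.nan

    mns_peri = pd.DataFrame({
        "child_id": child_id, "source": "MNS", "gestational_age_weeks": ga,
        "birthweight_g": bw, "apgar_1min": apgar, "live_born": live_born,
        "sex": child_sex,
    })
    br_peri = mns_peri[has_br].copy()
    br_peri["source"] = "BIRTHREG"
    br_peri["apgar_1min"] = np.nan  # Apgar collected on the midwives' record only
    perinatal = pd.concat([mns_peri, br_peri], ignore_index=True)[PERINATAL_COLUMNS]

    return persons, family_links, admin_records, perinatal


# ---------------------------------------------------------------------------
# hand-built micro-populations with known expected outputs
# ---------------------------------------------------------------------------

def _fixture_single_child_three_datasets():
    """One child born 2012 with statuses I, I, non-I across three datasets.

    Expected: per-dataset statuses MNS=I, HMDC=I, EDDC=non-I; the flag rule at
    three datasets needs >= 2 Indigenous, so the child's ISF is Indigenous and
    the child is in Methods A, B and C.
    """
    persons = pd.DataFrame([
        {"person_id": "C1", "role": "child", "true_indigenous": True,
         "birth_year": 2012.0, "irsd_quintile": 1, "remoteness": "remote",
         "indigenous_region": "Broome", "sex": "female"},
        {"person_id": "M1", "role": "mother", "true_indigenous": True,
         "birth_year": np.nan, "irsd_quintile": 1, "remoteness": "remote",
         "indigenous_region": "Broome", "sex": "female"},
    ], columns=PERSON_COLUMNS)
    links = pd.DataFrame(
        [{"child_id": "C1", "mother_id": "M1"}], columns=LINK_COLUMNS)
    records = pd.DataFrame([
        {"record_id": "R1", "person_id": "C1", "dataset": "MNS",
         "record_year": 2012, "child_status": I, "maternal_status": I,
         "paternal_status": np.nan, "self_status": np.nan},
        {"record_id": "R2", "person_id": "C1", "dataset": "HMDC",
         "record_year": 2013, "child_status": np.nan, "maternal_status": np.nan,
         "paternal_status": np.nan, "self_status": I},
        {"record_id": "R3", "person_id": "C1", "dataset": "EDDC",
         "record_year": 2014, "child_status": np.nan, "maternal_status": np.nan,
         "paternal_status": np.nan, "self_status": N},
    ], columns=RECORD_COLUMNS)
    perinatal = pd.DataFrame([
        {"child_id": "C1", "source": "MNS", "gestational_age_weeks": 39.0,
         "birthweight_g": 3300.0, "apgar_1min": 9.0, "live_born": True,
         "sex": "female"},
    ], columns=PERINATAL_COLUMNS)
    return persons, links, records, perinatal


def _fixture_father_only_indigenous():
    """Child born 2010 recorded non-Indigenous everywhere; Indigenous father.

    Expected: child ISF non-Indigenous (not Method A); father's own ISF
    Indigenous, so the child is in Method B.  Method C is false: the birth
    registration carries a non-missing non-Indigenous child status (blocking
    the paternal fallback on that dataset) and the midwives' fallback sees
    only the non-Indigenous maternal status.
    """
    persons = pd.DataFrame([
        {"person_id": "C1", "role": "child", "true_indigenous": True,
         "birth_year": 2010.0, "irsd_quintile": 5, "remoteness": "major_city",
         "indigenous_region": "Perth", "sex": "male"},
        {"person_id": "M1", "role": "mother", "true_indigenous": False,
         "birth_year": np.nan, "irsd_quintile": 5, "remoteness": "major_city",
         "indigenous_region": "Perth", "sex": "female"},
        {"person_id": "F1", "role": "father", "true_indigenous": True,
         "birth_year": np.nan, "irsd_quintile": 5, "remoteness": "major_city",
         "indigenous_region": "Perth", "sex": "male"},
    ], columns=PERSON_COLUMNS)
    links = pd.DataFrame(
        [{"child_id": "C1", "mother_id": "M1", "father_id": "F1"}],
        columns=LINK_COLUMNS)
    records = pd.DataFrame([
        # child: non-indigenous on every non-missing field
        {"record_id": "R1", "person_id": "C1", "dataset": "MNS",
         "record_year": 2010, "child_status": np.nan, "maternal_status": N,
         "paternal_status": np.nan, "self_status": np.nan},
        {"record_id": "R2", "person_id": "C1", "dataset": "BIRTHREG",
         "record_year": 2010, "child_status": N, "maternal_status": N,
         "paternal_status": I, "self_status": np.nan},
        {"record_id": "R3", "person_id": "C1", "dataset": "HMDC",
         "record_year": 2012, "child_status": np.nan, "maternal_status": np.nan,
         "paternal_status": np.nan, "self_status": N},
        # father: consistently indigenous on his own records
        {"record_id": "R4", "person_id": "F1", "dataset": "HMDC",
         "record_year": 2005, "child_status": np.nan, "maternal_status": np.nan,
         "paternal_status": np.nan, "self_status": I},
        {"record_id": "R5", "person_id": "F1", "dataset": "HMDC",
         "record_year": 2008, "child_status": np.nan, "maternal_status": np.nan,
         "paternal_status": np.nan, "self_status": I},
        {"record_id": "R6", "person_id": "F1", "dataset": "EDDC",
         "record_year": 2011, "child_status": np.nan, "maternal_status": np.nan,
         "paternal_status": np.nan, "self_status": I},
        # mother: one non-indigenous record
        {"record_id": "R7", "person_id": "M1", "dataset": "HMDC",
         "record_year": 2009, "child_status": np.nan, "maternal_status": np.nan,
         "paternal_status": np.nan, "self_status": N},
    ], columns=RECORD_COLUMNS)
    perinatal = pd.DataFrame([
        {"child_id": "C1", "source": "MNS", "gestational_age_weeks": 40.0,
         "birthweight_g": 3600.0, "apgar_1min": 10.0, "live_born": True,
         "sex": "male"},
        {"child_id": "C1", "source": "BIRTHREG", "gestational_age_weeks": 40.0,
         "birthweight_g": 3600.0, "apgar_1min": np.nan, "live_born": True,
         "sex": "male"},
    ], columns=PERINATAL_COLUMNS)
    return persons, links, records, perinatal


def _fixture_pre_post_2012():
    """Two children with identical records except birth year (2010 vs 2013).

    Only the 2013 child has a populated midwives' child status (the field was
    introduced in 2012).  Both carry two non-Indigenous morbidity datasets, so
    the 2013 child's ISF is still non-Indigenous (one Indigenous dataset of
    three); neither child is in Method B.  Method C identifies exactly the
    2013 child, via the midwives' child-status pathway — the step-change
    attribution picks up that child only.
    """
    rows = []
    persons_rows = []
    links_rows = []
    peri_rows = []
    rid = 0
    for cid, year, mns_child in (("C2010", 2010, np.nan), ("C2013", 2013, I)):
        mid = "M" + cid
        persons_rows += [
            {"person_id": cid, "role": "child", "true_indigenous": True,
             "birth_year": float(year), "irsd_quintile": 4,
             "remoteness": "major_city", "indigenous_region": "Perth",
             "sex": "female"},
            {"person_id": mid, "role": "mother", "true_indigenous": False,
             "birth_year": np.nan, "irsd_quintile": 4,
             "remoteness": "major_city", "indigenous_region": "Perth",
             "sex": "female"},
        ]
        links_rows.append({"child_id": cid, "mother_id": mid})
        for ds, year_off, kwargs in (
            ("MNS", 0, {"child_status": mns_child, "maternal_status": N}),
            ("HMDC", 1, {"self_status": N}),
            ("EDDC", 2, {"self_status": N}),
        ):
            rid += 1
            row = {"record_id": f"R{rid}", "person_id": cid, "dataset": ds,
                   "record_year": year + year_off, "child_status": np.nan,
                   "maternal_status": np.nan, "paternal_status": np.nan,
                   "self_status": np.nan}
            row.update(kwargs)
            rows.append(row)
        rid += 1
        rows.append({"record_id": f"R{rid}", "person_id": mid, "dataset": "HMDC",
                     "record_year": year, "child_status": np.nan,
                     "maternal_status": np.nan, "paternal_status": np.nan,
                     "self_status": N})
        peri_rows.append({
            "child_id": cid, "source": "MNS", "gestational_age_weeks": 38.5,
            "birthweight_g": 3100.0, "apgar_1min": 9.0, "live_born": True,
            "sex": "female"})
    persons = pd.DataFrame(persons_rows, columns=PERSON_COLUMNS)
    links = pd.DataFrame(links_rows, columns=LINK_COLUMNS)
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    perinatal = pd.DataFrame(peri_rows, columns=PERINATAL_COLUMNS)
    return persons, links, records, perinatal


FIXTURES = {
    "single-child-three-datasets": _fixture_single_child_three_datasets,
    "father-only-indigenous": _fixture_father_only_indigenous,
    "pre-post-2012": _fixture_pre_post_2012,
}


def make_fixture(name: str):
    """Return a tiny hand-specified population with documented expectations.

    See each fixture builder's docstring for the expected downstream outputs.
    """
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return builder()


# ---------------------------------------------------------------------------
# CSV round-trip (missing values encoded as empty fields)
# ---------------------------------------------------------------------------

TABLE_NAMES = ("persons", "family_links", "admin_records", "perinatal_records")

_STRING_COLUMNS = {
    "person_id", "record_id", "child_id", "mother_id", "father_id",
    "maternal_gm_id", "maternal_gf_id", "paternal_gm_id", "paternal_gf_id",
    "role", "dataset", "source", "sex", "remoteness", "indigenous_region",
    "child_status", "maternal_status", "paternal_status", "self_status",
    "flag", "venn_cell", "parental_composition", "cohort", "variable", "level",
}


def write_tables(out_dir: str | Path, tables: dict[str, pd.DataFrame],
                 parquet: bool = False) -> dict[str, Path]:
    """Write tables to ``<out_dir>/<name>.csv`` (optionally also Parquet)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
        if parquet:
            df.to_parquet(out_dir / f"{name}.parquet", index=False)
    return paths


def read_tables(in_dir: str | Path, names=TABLE_NAMES) -> dict[str, pd.DataFrame]:
    """Read tables written by :func:`write_tables`, preserving string ids."""
    in_dir = Path(in_dir)
    out = {}
    for name in names:
        path = in_dir / f"{name}.csv"
        head = pd.read_csv(path, nrows=0)
        dtypes = {c: "object" for c in head.columns if c in _STRING_COLUMNS}
        out[name] = pd.read_csv(path, dtype=dtypes)
    return out
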