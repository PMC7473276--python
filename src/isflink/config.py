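"""Simulation configuration for the synthetic linked-population generator.

The generator emulates a multi-generational linked administrative data
extract: families of one study child plus mother, father and four
grandparents, each person carrying records across five datasets with
three-valued recorded Indigenous status, plus perinatal fields on the
child's midwives' notification and birth registration.

Defaults encode the study conditions the generator is meant to reproduce:

* birth years 2000-2013; child status collected on birth registrations from
  2007 and on midwives' notifications from 2012;
* family-link completeness of 93% for fathers, 80% for maternal and 62% for
  paternal grandparent pairs (implying ~91% of children with at least one
  grandparent linked);
* recording propensity for a child's own status that falls with urban
  residence, lower area disadvantage, and father-only-Indigenous parental
  composition — the under-ascertainment mechanism the cohort comparison is
  designed to expose;
* perinatal outcome gradients (gestational age, birthweight, Apgar) driven
  by the same area-disadvantage score, so that differentially ascertained
  subgroups differ in measured outcomes.

Where the emulated study reports no value (per-dataset record counts,
status-field missingness rates, false-identification rates) the defaults are
plain placeholders chosen for realism and are documented as such.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from collections.abc import Mapping

import yaml

__all__ = ["SimulationConfig", "RecordingModel", "PerinatalEffects", "ConfigError"]

REMOTENESS_LEVELS = (
    "major_city",
    "inner_regional",
    "outer_regional",
    "remote",
    "very_remote",
)
COMPOSITIONS = ("both", "mother_only", "father_only", "neither")
DATASETS = ("MNS", "BIRTHREG", "HMDC", "EDDC", "DEATH")


class ConfigError(ValueError):
    """Raised when a configuration value is out of range or inconsistent."""


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"{name} must be a probability in [0, 1], got {p!r}")


@dataclass
class RecordingModel:
    """Bernoulli recording propensities for Indigenous status fields.

    A status field referring to a truly Indigenous subject records
    ``indigenous`` with the applicable propensity, otherwise
    ``non_indigenous``; fields referring to non-Indigenous subjects always
    record ``non_indigenous`` (false identification is not modelled — the
    phenomenon of interest is under-identification).  Independently of the
    value, each field is blanked to missing with ``p_status_missing``.

    Children's own status fields use ``child_base[dataset]`` multiplied by
    parental-composition, disadvantage-quintile and remoteness modifiers.
    Adults' fields (their own records, and the maternal/paternal fields on a
    child's perinatal records) use per-role base propensities multiplied by
    the same quintile and remoteness modifiers — under-identification is a
    family-level, area-correlated phenomenon, not specific to children.
    """

    #: the midwives' child field is collected by direct interview at the birth
    #: and is more complete than the parent-completed registration form
    child_base: dict[str, float] = field(
        default_factory=lambda: {
            "MNS": 0.92,
            "BIRTHREG": 0.78,
            "HMDC": 0.78,
            "EDDC": 0.72,
            "DEATH": 0.92,
        }
    )
    composition_mult: dict[str, float] = field(
        default_factory=lambda: {
            "both": 1.0,
            "mother_only": 0.90,
            "father_only": 0.42,
            "neither": 0.60,
        }
    )
    irsd_mult: dict[int, float] = field(
        default_factory=lambda: {1: 1.0, 2: 0.95, 3: 0.88, 4: 0.80, 5: 0.72}
    )
    remoteness_mult: dict[str, float] = field(
        default_factory=lambda: {
            "very_remote": 1.0,
            "remote": 1.0,
            "outer_regional": 0.96,
            "inner_regional": 0.90,
            "major_city": 0.84,
        }
    )
    p_record_adult_self: float = 0.90
    p_record_maternal: float = 0.95
    p_record_paternal: float = 0.90
    p_status_missing: float = 0.04
    #: SD of a log-normal family-level frailty multiplying every propensity in
    #: the family (median 1): identification behaviour clusters in families,
    #: and the mid-propensity band it creates is what produces record-level
    #: inconsistency within a person
    family_frailty_sd: float = 0.40
    #: exponent damping the context multiplier for the midwives' child field
    #: (0 = context-free, 1 = fully modified): the status question is asked
    #: of the mother directly at the birth, so completeness of this field
    #: depends far less on family and area context than other collections
    mns_child_context_damping: float = 0.35

    def validate(self) -> None:
        for ds in DATASETS:
            if ds not in self.child_base:
                raise ConfigError(f"child_base missing dataset {ds!r}")
            _check_prob(f"child_base[{ds}]", self.child_base[ds])
        for comp in COMPOSITIONS:
            if comp not in self.composition_mult:
                raise ConfigError(f"composition_mult missing {comp!r}")
        for name in ("p_record_adult_self", "p_record_maternal",
                     "p_record_paternal", "p_status_missing"):
            _check_prob(name, getattr(self, name))
        if self.family_frailty_sd < 0:
            raise ConfigError("family_frailty_sd must be >= 0")
        if not (0.0 <= self.mns_child_context_damping <= 1.0):
            raise ConfigError("mns_child_context_damping must be in [0, 1]")

    @classmethod
    def perfect(cls) -> "RecordingModel":
        """Propensity 1 everywhere and no status missingness."""
        return cls(
            child_base={ds: 1.0 for ds in DATASETS},
            composition_mult={c: 1.0 for c in COMPOSITIONS},
            irsd_mult={q: 1.0 for q in range(1, 6)},
            remoteness_mult={r: 1.0 for r in REMOTENESS_LEVELS},
            p_record_adult_self=1.0,
            p_record_maternal=1.0,
            p_record_paternal=1.0,
            p_status_missing=0.0,
            family_frailty_sd=0.0,
        )


@dataclass
class PerinatalEffects:
    """Effect sizes linking the area-disadvantage score to perinatal outcomes.

    The disadvantage score ``d`` in [0, 1] combines the disadvantage quintile
    (1 = most disadvantaged -> 1.0) and remoteness (very remote -> 1.0,
    major city -> 0.0); missing geography scores 0.5.  Units: gestational age
    in completed weeks, birthweight in grams.
    """

    ga_mean_base: float = 39.2       # mean gestational age at d = 0
    ga_mean_slope: float = -1.2      # weeks per unit d
    ga_sd_base: float = 1.7
    ga_sd_slope: float = 0.7
    bw_mean_base: float = 3350.0     # grams at d = 0, female, 40 weeks
    bw_male_shift: float = 115.0
    bw_disadvantage_slope: float = -240.0
    bw_per_week: float = 165.0       # grams per gestational week vs 40
    bw_sd: float = 420.0
    apgar_ge9_base: float = 0.64     # P(Apgar >= 9 at 1 min) at d = 0
    apgar_ge9_slope: float = -0.11
    p_stillbirth_base: float = 0.006
    p_stillbirth_slope: float = 0.008
    p_ga_missing: float = 0.005
    p_bw_missing: float = 0.002
    p_apgar_missing: float = 0.01

    def validate(self) -> None:
        for name in ("p_ga_missing", "p_bw_missing", "p_apgar_missing",
                     "p_stillbirth_base"):
            _check_prob(name, getattr(self, name))


@dataclass
class SimulationConfig:
    """Full configuration of one synthetic population draw."""

    n_families: int = 1000
    birth_year_range: tuple[int, int] = (2000, 2013)
    p_indigenous_family: float = 0.10
    p_mother_linked: float = 1.0
    p_father_linked: float = 0.93
    p_any_grandparent_linked: float = 0.91  # implied by the pair rates; reported, not sampled
    p_maternal_gp_linked: float = 0.80
    p_paternal_gp_linked: float = 0.62
    parental_composition_probs: dict[str, float] = field(
        default_factory=lambda: {
            "both": 0.40,
            "mother_only": 0.26,
            "father_only": 0.22,
            "neither": 0.12,
        }
    )
    p_grandparent_indigenous_given_parent: float = 0.92
    recording: RecordingModel = field(default_factory=RecordingModel)
    birthreg_child_status_from: int = 2007
    mns_child_status_from: int = 2012
    p_birthreg_record: float = 0.90
    child_morbidity_rate: dict[str, float] = field(
        default_factory=lambda: {"HMDC": 1.1, "EDDC": 1.3}
    )
    adult_morbidity_rate: dict[str, float] = field(
        default_factory=lambda: {"HMDC": 1.3, "EDDC": 1.3}
    )
    birth_year_weight_growth: float = 0.02  # relative rise in births per year
    p_child_death_record: float = 0.004
    p_adult_death_record: float = 0.02
    perinatal_effects: PerinatalEffects = field(default_factory=PerinatalEffects)
    missing_geography_prob: float = 0.05
    p_male: float = 0.514
    seed: int = 0

    # ------------------------------------------------------------------ util
    def validate(self) -> None:
        if self.n_families < 0:
            raise ConfigError(f"n_families must be >= 0, got {self.n_families}")
        lo, hi = self.birth_year_range
        if lo > hi:
            raise ConfigError(f"birth_year_range reversed: {self.birth_year_range}")
        for name in (
            "p_indigenous_family", "p_mother_linked", "p_father_linked",
            "p_any_grandparent_linked", "p_maternal_gp_linked",
            "p_paternal_gp_linked", "p_grandparent_indigenous_given_parent",
            "p_birthreg_record", "p_child_death_record", "p_adult_death_record",
            "missing_geography_prob", "p_male",
        ):
            _check_prob(name, getattr(self, name))
        comp = self.parental_composition_probs
        missing = [c for c in COMPOSITIONS if c not in comp]
        if missing:
            raise ConfigError(f"parental_composition_probs missing {missing}")
        total = sum(comp.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"parental_composition_probs must sum to 1, got {total}"
            )
        if 1.0 + self.birth_year_weight_growth * (hi - lo) <= 0:
            raise ConfigError(
                "birth_year_weight_growth too negative: year weights must stay positive"
            )
        for name, year in (
            ("birthreg_child_status_from", self.birthreg_child_status_from),
            ("mns_child_status_from", self.mns_child_status_from),
        ):
            if year < lo:
                raise ConfigError(
                    f"{name}={year} precedes birth_year_range start {lo}"
                )
        self.recording.validate()
        self.perinatal_effects.validate()

    @classmethod
    def perfect_recording(cls, **kwargs) -> "SimulationConfig":
        """A configuration under which recorded data equal the ground truth.

        Every status propensity is 1, no status/geography missingness, all
        relatives linked, and child-status fields collected from the start of
        the birth-year window, so all downstream identification methods can
        recover the simulated truth exactly.
        """
        lo = kwargs.get("birth_year_range", (2000, 2013))[0]
        defaults = dict(
            recording=RecordingModel.perfect(),
            p_mother_linked=1.0,
            p_father_linked=1.0,
            p_maternal_gp_linked=1.0,
            p_paternal_gp_linked=1.0,
            p_any_grandparent_linked=1.0,
            birthreg_child_status_from=lo,
            mns_child_status_from=lo,
            missing_geography_prob=0.0,
        )
        defaults.update(kwargs)
        return cls(**defaults)

    # -------------------------------------------------------------- (de)serialise
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["birth_year_range"] = list(self.birth_year_range)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        if "birth_year_range" in data:
            data["birth_year_range"] = tuple(data["birth_year_range"])
        if "recording" in data and isinstance(data["recording"], Mapping):
            rec = dict(data["recording"])
            if "irsd_mult" in rec:
                rec["irsd_mult"] = {int(k): v for k, v in rec["irsd_mult"].items()}
            data["recording"] = RecordingModel(**rec)
        if "perinatal_effects" in data and isinstance(data["perinatal_effects"], Mapping):
            data["perinatal_effects"] = PerinatalEffects(**data["perinatal_effects"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load from a YAML or JSON file (JSON is a subset of YAML)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        import hashlib

        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()
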