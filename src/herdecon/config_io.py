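"""Breed calibration and price-book configuration.

Breed files carry the herd-recording phenotypes (305-d ECM by parity
class, reproduction means, treatment incidences per 100 cow-years) and
two assumption blocks that no recording scheme publishes: per-disease
effect magnitudes and a feed model. Assumption blocks are optional in
the files; defaulted values are logged at WARN because they are model
assumptions, not recorded data.

All probabilities are stored as fractions in [0, 1]; incidences are
cases per 100 cow-years; monetary values are EUR.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError, ValidationError

log = logging.getLogger(__name__)

#: Canonical disease order used throughout the package (index positions
#: matter to the simulator's state arrays).
DISEASES = ("milk_fever", "dystocia", "metritis", "ketosis", "mastitis", "lameness")
#: Diseases drawn from a weekly hazard; dystocia is drawn at calving.
WEEKLY_DISEASES = ("milk_fever", "metritis", "ketosis", "mastitis", "lameness")
#: Diseases with a per-case treatment cost in the price book (lameness
#: has none).
TREATED_DISEASES = ("mastitis", "milk_fever", "dystocia", "metritis", "ketosis")
PARITY_CLASSES = ("1", "2", "3+")

#: Fallback stillbirth rate (% of calvings) used when a breed file omits
#: the value; the nearest-kin breed value, overridable in the file.
DEFAULT_STILLBIRTH_RATE = 5.2


def _require(mapping: Mapping, key: str, where: str):
    try:
        return mapping[key]
    except (KeyError, TypeError):
        raise ConfigurationError(f"missing mandatory key {key!r} in {where}") from None


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be a probability in [0, 1], got {value}")
    return value


def _check_nonneg(name: str, value: float) -> float:
    value = float(value)
    if value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value}")
    return value


def _check_pos(name: str, value: float) -> float:
    value = float(value)
    if value <= 0:
        raise ValidationError(f"{name} must be > 0, got {value}")
    return value


@dataclass(frozen=True)
class DiseaseEffect:
    """Assumed consequences of one clinical case.

    milk_loss_frac_of_305d
        Total milk lost over the episode, as a fraction of the cow's
        305-d ECM.
    conception_multiplier
        Multiplier on conception probability per insemination while the
        episode is active.
    added_mortality_risk
        Added probability of death over the episode, in percentage
        points (for dystocia: applied once, in the calving week).
    added_cull_risk
        Added probability of being culled over the episode, in
        percentage points.
    effect_duration_weeks
        Length of the episode; a cow cannot start a second episode of
        the same disease while one is active.
    stillbirth_risk_add
        Extra stillbirth probability (percentage points of calvings)
        when the case occurs at calving; only meaningful for dystocia.
    """

    milk_loss_frac_of_305d: float = 0.0
    conception_multiplier: float = 1.0
    added_mortality_risk: float = 0.0
    added_cull_risk: float = 0.0
    effect_duration_weeks: int = 8
    stillbirth_risk_add: float = 0.0

    def __post_init__(self):
        _check_prob("milk_loss_frac_of_305d", self.milk_loss_frac_of_305d)
        _check_prob("conception_multiplier", self.conception_multiplier)
        _check_nonneg("added_mortality_risk", self.added_mortality_risk)
        _check_nonneg("added_cull_risk", self.added_cull_risk)
        if self.effect_duration_weeks < 1:
            raise ValidationError("effect_duration_weeks must be >= 1")


#: Default disease-effect assumptions (model assumptions, configurable).
#: Lameness carries an added cull risk because it has no treatment cost
#: in the price book and its milk/fertility/mortality consequences are
#: all mediator-corrected; culling is its direct economic channel.
DEFAULT_DISEASE_EFFECTS: dict[str, DiseaseEffect] = {
    "mastitis": DiseaseEffect(0.05, 1.00, 0.5, 1.5, 8),
    "milk_fever": DiseaseEffect(0.02, 1.00, 0.5, 0.5, 8),
    "metritis": DiseaseEffect(0.02, 0.85, 0.0, 0.0, 8),
    "ketosis": DiseaseEffect(0.03, 0.85, 0.0, 0.0, 8),
    "lameness": DiseaseEffect(0.03, 0.85, 0.0, 6.0, 8),
    "dystocia": DiseaseEffect(0.01, 0.90, 1.0, 0.0, 4, stillbirth_risk_add=10.0),
}


@dataclass(frozen=True)
class FeedModel:
    """Energy requirement and ration-composition assumptions (SFU =
    Scandinavian feed unit)."""

    maintenance_sfu_per_day: float = 5.0
    sfu_per_kg_ecm: float = 0.43
    concentrate_share: float = 0.35
    heifer_sfu_per_day: float = 5.0
    heifer_concentrate_share: float = 0.20
    calf_milk_powder_kg_per_day: float = 0.6
    milk_feeding_weeks: int = 8

    def __post_init__(self):
        _check_pos("maintenance_sfu_per_day", self.maintenance_sfu_per_day)
        _check_nonneg("sfu_per_kg_ecm", self.sfu_per_kg_ecm)
        _check_prob("concentrate_share", self.concentrate_share)
        _check_prob("heifer_concentrate_share", self.heifer_concentrate_share)


@dataclass(frozen=True)
class HerdParameters:
    """Breed-level calibration of the herd model."""

    breed_id: str
    herd_size_target: int
    ecm_305d: Mapping[str, float]  # keys "1", "2", "3+"
    fat_pct: float
    protein_pct: float
    calving_interval_days: float
    age_first_calving_months: float
    heat_obs_rate_cows: float
    heat_obs_rate_heifers: float
    conception_rate_cows: float
    conception_rate_heifers: float
    start_breeding_days: float
    incidence_per_100cy: Mapping[str, float]
    stillbirth_rate: float
    early_calf_mortality: float
    late_calf_mortality: float
    cow_mortality: float
    cow_live_weight_kg: float = 550.0
    disease_effects: Mapping[str, DiseaseEffect] = field(
        default_factory=lambda: dict(DEFAULT_DISEASE_EFFECTS)
    )
    feed_model: FeedModel = field(default_factory=FeedModel)
    # Frozen reproduction calibration (set by the scenario engine before
    # perturbing, so CR/HO scenarios keep their causal effect on days
    # open). When None the simulator solves them from the fields above.
    oestrus_scale_cows: float | None = None
    heifer_breeding_start_weeks: float | None = None

    def __post_init__(self):
        if int(self.herd_size_target) <= 0:
            raise ValidationError("herd_size_target must be positive")
        for cls in PARITY_CLASSES:
            if cls not in self.ecm_305d:
                raise ConfigurationError(f"ecm_305d missing parity class {cls!r}")
            _check_pos(f"ecm_305d[{cls}]", self.ecm_305d[cls])
        _check_pos("calving_interval_days", self.calving_interval_days)
        _check_pos("age_first_calving_months", self.age_first_calving_months)
        for name in (
            "heat_obs_rate_cows",
            "heat_obs_rate_heifers",
            "conception_rate_cows",
            "conception_rate_heifers",
        ):
            _check_prob(name, getattr(self, name))
        _check_nonneg("start_breeding_days", self.start_breeding_days)
        for disease in DISEASES:
            if disease not in self.incidence_per_100cy:
                raise ConfigurationError(f"incidence_per_100cy missing {disease!r}")
            _check_nonneg(f"incidence_per_100cy[{disease}]", self.incidence_per_100cy[disease])
        for name in (
            "stillbirth_rate",
            "early_calf_mortality",
            "late_calf_mortality",
            "cow_mortality",
        ):
            rate = _check_nonneg(name, getattr(self, name))
            if rate > 100:
                raise ValidationError(f"{name} is a percentage, got {rate}")
        _check_pos("cow_live_weight_kg", self.cow_live_weight_kg)
        for disease in DISEASES:
            if disease not in self.disease_effects:
                raise ConfigurationError(f"disease_effects missing {disease!r}")

    def ecm_for_parity(self, parity: int) -> float:
        """305-d ECM (kg) for an integer parity (3 and above share a class)."""
        if parity < 1:
            raise ValueError(f"parity must be >= 1, got {parity}")
        return float(self.ecm_305d["1" if parity == 1 else "2" if parity == 2 else "3+"])

    def to_dict(self) -> dict:
        d = {
            "breed": self.breed_id,
            "herd_size_target": int(self.herd_size_target),
            "production": {
                "ecm_305d": {k: float(v) for k, v in self.ecm_305d.items()},
                "fat_pct": self.fat_pct,
                "protein_pct": self.protein_pct,
            },
            "reproduction": {
                "calving_interval_days": self.calving_interval_days,
                "age_first_calving_months": self.age_first_calving_months,
                "heat_obs_rate_cows": self.heat_obs_rate_cows,
                "heat_obs_rate_heifers": self.heat_obs_rate_heifers,
                "conception_rate_cows": self.conception_rate_cows,
                "conception_rate_heifers": self.conception_rate_heifers,
                "start_breeding_days": self.start_breeding_days,
            },
            "incidence_per_100cy": {k: float(v) for k, v in self.incidence_per_100cy.items()},
            "stillbirth_rate": self.stillbirth_rate,
            "mortality": {
                "early_calf": self.early_calf_mortality,
                "late_calf": self.late_calf_mortality,
                "cow": self.cow_mortality,
            },
            "cow_live_weight_kg": self.cow_live_weight_kg,
            "disease_effects": {
                k: dataclasses.asdict(v) for k, v in self.disease_effects.items()
            },
            "feed_model": dataclasses.asdict(self.feed_model),
        }
        if self.oestrus_scale_cows is not None:
            d["oestrus_scale_cows"] = self.oestrus_scale_cows
        if self.heifer_breeding_start_weeks is not None:
            d["heifer_breeding_start_weeks"] = self.heifer_breeding_start_weeks
        return d

    @classmethod
    def from_dict(cls, raw: Mapping, source: str = "<dict>") -> "HerdParameters":
        prod = _require(raw, "production", source)
        repro = _require(raw, "reproduction", source)
        ecm = {str(k): float(v) for k, v in _require(prod, "ecm_305d", source).items()}
        incidence = {
            str(k): float(v)
            for k, v in _require(raw, "incidence_per_100cy", source).items()
        }
        stillbirth = raw.get("stillbirth_rate")
        if stillbirth is None:
            log.warning(
                "%s: stillbirth_rate not given; defaulting to %.1f%% of calvings "
                "(nearest-kin breed value)",
                source,
                DEFAULT_STILLBIRTH_RATE,
            )
            stillbirth = DEFAULT_STILLBIRTH_RATE
        mortality = raw.get("mortality", {})
        effects = dict(DEFAULT_DISEASE_EFFECTS)
        if "disease_effects" in raw:
            for name, eff in raw["disease_effects"].items():
                effects[str(name)] = DiseaseEffect(**eff)
        else:
            log.warning(
                "%s: disease_effects not given; using model-assumption defaults",
                source,
            )
        if "feed_model" in raw:
            feed = FeedModel(**raw["feed_model"])
        else:
            log.warning("%s: feed_model not given; using defaults", source)
            feed = FeedModel()
        if "mortality" not in raw:
            log.warning(
                "%s: mortality block not given; using default cow/calf rates", source
            )
        return cls(
            breed_id=str(_require(raw, "breed", source)),
            herd_size_target=int(_require(raw, "herd_size_target", source)),
            ecm_305d=ecm,
            fat_pct=float(_require(prod, "fat_pct", source)),
            protein_pct=float(_require(prod, "protein_pct", source)),
            calving_interval_days=float(_require(repro, "calving_interval_days", source)),
            age_first_calving_months=float(
                _require(repro, "age_first_calving_months", source)
            ),
            heat_obs_rate_cows=float(_require(repro, "heat_obs_rate_cows", source)),
            heat_obs_rate_heifers=float(_require(repro, "heat_obs_rate_heifers", source)),
            conception_rate_cows=float(_require(repro, "conception_rate_cows", source)),
            conception_rate_heifers=float(
                _require(repro, "conception_rate_heifers", source)
            ),
            start_breeding_days=float(_require(repro, "start_breeding_days", source)),
            incidence_per_100cy=incidence,
            stillbirth_rate=float(stillbirth),
            early_calf_mortality=float(mortality.get("early_calf", 3.5)),
            late_calf_mortality=float(mortality.get("late_calf", 2.0)),
            cow_mortality=float(mortality.get("cow", 5.0)),
            cow_live_weight_kg=float(raw.get("cow_live_weight_kg", 550.0)),
            disease_effects=effects,
            feed_model=feed,
            oestrus_scale_cows=raw.get("oestrus_scale_cows"),
            heifer_breeding_start_weeks=raw.get("heifer_breeding_start_weeks"),
        )


@dataclass(frozen=True)
class PriceTable:
    """Price/cost book (EUR). One field per monetary constant.

    ``other_costs_per_cow_year`` / ``other_costs_per_heifer_year`` are
    calibration constants for the residual cost lines of the annual
    statement; the cow-ration SFU prices are free calibration constants
    (the published book prices heifer feed only).
    """

    milk_price_per_kg_ecm: float
    slaughter_price_per_kg_live: float
    dead_cow_disposal: float
    dead_heifer_disposal: float
    dead_calf_disposal: float
    pregnant_heifer_price: float
    open_heifer_price: float
    bull_calf_price: float
    milk_powder_per_kg: float
    heifer_concentrate_per_sfu: float
    heifer_roughage_per_sfu: float
    treatment_cost: Mapping[str, float]
    semen_cost: float
    cow_concentrate_per_sfu: float = 0.40
    cow_roughage_per_sfu: float = 0.12
    other_costs_per_cow_year: float = 202.0
    other_costs_per_heifer_year: float = 50.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if f.name == "treatment_cost":
                for disease in TREATED_DISEASES:
                    if disease not in value:
                        raise ConfigurationError(f"treatment_cost missing {disease!r}")
                    _check_nonneg(f"treatment_cost[{disease}]", value[disease])
            else:
                _check_nonneg(f.name, value)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["treatment_cost"] = {k: float(v) for k, v in self.treatment_cost.items()}
        return d

    @classmethod
    def from_dict(cls, raw: Mapping, source: str = "<dict>") -> "PriceTable":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown price keys in {source}: {sorted(unknown)}")
        kwargs = dict(raw)
        for f in dataclasses.fields(cls):
            if f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING:
                _require(raw, f.name, source)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# file I/O


def _load_yaml(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path} does not contain a mapping")
    return raw


def load_breed_config(path) -> HerdParameters:
    """Load and validate a breed calibration file (YAML)."""
    return HerdParameters.from_dict(_load_yaml(path), source=str(path))


def save_breed_config(params: HerdParameters, path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def load_price_table(path) -> PriceTable:
    """Load and validate a price book file (YAML)."""
    return PriceTable.from_dict(_load_yaml(path), source=str(path))


def save_price_table(prices: PriceTable, path) -> None:
    Path(path).write_text(yaml.safe_dump(prices.to_dict(), sort_keys=False))


def bundled_config_path(name: str) -> Path:
    """Path of a config shipped with the package (e.g. ``"lbw"`` or
    ``"prices_lr"``)."""
    path = Path(__file__).parent / "data" / f"{name.lower()}.yaml"
    if not path.exists():
        raise ConfigurationError(f"no bundled config named {name!r}")
    return path


# ---------------------------------------------------------------------------
# small derived quantities


def conception_rate_from_inseminations(n_inseminations: float) -> float:
    """Conception rate (%) from the mean number of inseminations per
    conception: (1 / n) x 100."""
    if n_inseminations <= 0:
        raise ValueError(f"n_inseminations must be > 0, got {n_inseminations}")
    return 100.0 / float(n_inseminations)


def conception_rate_rounded(n_inseminations: float) -> int:
    """Integer-rounded variant of :func:`conception_rate_from_inseminations`."""
    return round(conception_rate_from_inseminations(n_inseminations))
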