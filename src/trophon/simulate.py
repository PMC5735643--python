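"""Synthetic gillnet-survey generator for stomach-content analyses.

The generator emulates the statistical structure a trophic-niche pipeline
assumes: two (or more) sympatric carnivore populations of unequal
abundance, skewed fish-dominated diets that may shift between the flood
and dry seasons, configurable sex ratios, a large fraction of void
stomachs, and capture rhythms over the eight 3-h net checks that are
either uniform or nocturnal-bimodal.

Sampling model, per species and season:

* the number of specimens is Poisson with mean abundance/len(seasons),
  each specimen assigned a sampling day uniformly and a net check from the
  species' activity weights;
* sex is Bernoulli(sex_ratio female); total length and weight are
  truncated normal (resampled until positive); gutted and stomach weights
  are plausible fractions of the total weight;
* repletion is categorical per season; non-void stomachs receive
  1 + Binomial(3, 0.3) items whose categories follow the season's diet
  vector and whose volumes are i.i.d. lognormal around a common base
  volume — so the expected volumetric composition converges to the diet
  vector itself (volumes are raw, never percentages; the analysis side
  normalises).

All outputs satisfy the domain invariants and round-trip through the
delimited-text readers unchanged.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_data import (
    CATEGORIES,
    INTERVALS,
    REPLETION_CLASSES,
    SEASONS,
    SpecimenRecord,
    StomachItem,
)

__all__ = [
    "SpeciesProfile",
    "ScenarioConfig",
    "generate",
    "preset_paper_like",
    "NOCTURNAL_BIMODAL_WEIGHTS",
]

#: Default activity weights for a nocturnally bimodal species over the
#: checks (18:00, 21:00, 24:00, 03:00, 06:00, 09:00, 12:00, 15:00):
#: peaks at 21:00 and 03:00, 87% of captures in the five nocturnal checks.
NOCTURNAL_BIMODAL_WEIGHTS: tuple[float, ...] = (
    0.07, 0.28, 0.17, 0.26, 0.09, 0.045, 0.04, 0.045,
)

#: Mid-month sampling dates used when a scenario does not supply its own.
_SEASON_MONTHS = {"flood": (1, 3, 5), "dry": (7, 9, 11)}


class ConfigError(ValueError):
    """A scenario or species profile is internally inconsistent."""


@dataclass(frozen=True)
class SpeciesProfile:
    """Generating parameters for one species population."""

    label: str
    abundance: float  # expected total specimen count across simulated seasons
    sex_ratio: float  # probability a specimen is female
    length_mean: float  # mm
    length_sd: float
    weight_mean: float  # g
    weight_sd: float
    #: "uniform", "nocturnal_bimodal", or an explicit 8-vector of weights
    activity: str | Sequence[float] = "uniform"
    #: per season, utilization vector over the six food categories
    diet: Mapping[str, Sequence[float]] = field(default_factory=dict)
    #: per season, probabilities of {void, partly_full, full}
    repletion_probs: Mapping[str, Sequence[float]] = field(default_factory=dict)

    def activity_weights(self) -> np.ndarray:
        if isinstance(self.activity, str):
            if self.activity == "uniform":
                w = np.full(len(INTERVALS), 1.0)
            elif self.activity == "nocturnal_bimodal":
                w = np.asarray(NOCTURNAL_BIMODAL_WEIGHTS)
            else:
                raise ConfigError(f"unknown activity pattern {self.activity!r}")
        else:
            w = np.asarray(self.activity, dtype=float)
            if w.shape != (len(INTERVALS),) or np.any(w < 0) or w.sum() <= 0:
                raise ConfigError("custom activity must be 8 nonnegative weights")
        return w / w.sum()

    def validate(self, seasons: Sequence[str]) -> None:
        if self.abundance <= 0:
            raise ConfigError(f"{self.label}: abundance must be > 0")
        if not 0 <= self.sex_ratio <= 1:
            raise ConfigError(f"{self.label}: sex_ratio must be in [0, 1]")
        for v, name in ((self.length_mean, "length"), (self.weight_mean, "weight")):
            if v <= 0:
                raise ConfigError(f"{self.label}: {name}_mean must be > 0")
        self.activity_weights()
        for season in seasons:
            d = np.asarray(self.diet.get(season, ()), dtype=float)
            if d.shape != (len(CATEGORIES),) or np.any(d < 0) or d.sum() <= 0:
                raise ConfigError(
                    f"{self.label}: diet[{season!r}] must be {len(CATEGORIES)} "
                    "nonnegative values with positive sum"
                )
            r = np.asarray(self.repletion_probs.get(season, ()), dtype=float)
            if r.shape != (len(REPLETION_CLASSES),) or np.any(r < 0) or not np.isclose(r.sum(), 1.0):
                raise ConfigError(
                    f"{self.label}: repletion_probs[{season!r}] must be "
                    f"{len(REPLETION_CLASSES)} probabilities summing to 1"
                )


@dataclass(frozen=True)
class ScenarioConfig:
    """A full simulation scenario: species profiles plus sampling layout."""

    species: tuple[SpeciesProfile, ...]
    seasons: tuple[str, ...] = SEASONS
    n_days: int = 3  # sampling days per season
    year: int = 2012
    seed: int = 0  # reproducibility requires an explicit seed
    volume_noise: float = 0.5  # lognormal sigma of item volumes
    mean_extra_items: float = 0.9  # items per non-void stomach = 1 + Binom(3, p)

    def validate(self) -> None:
        if not self.species:
            raise ConfigError("at least one species profile required")
        bad = set(self.seasons) - set(SEASONS)
        if bad or not self.seasons:
            raise ConfigError(f"seasons must be drawn from {SEASONS}, got {self.seasons}")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if self.volume_noise < 0:
            raise ConfigError("volume_noise must be >= 0")
        for sp in self.species:
            sp.validate(self.seasons)

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScenarioConfig":
        species = tuple(
            SpeciesProfile(**{**sp, "activity": sp.get("activity", "uniform")})
            for sp in data["species"]
        )
        kwargs = {k: v for k, v in data.items() if k != "species"}
        if "seasons" in kwargs:
            kwargs["seasons"] = tuple(kwargs["seasons"])
        cfg = cls(species=species, **kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sampling_dates(season: str, n_days: int, year: int) -> list[dt.date]:
    months = _SEASON_MONTHS[season]
    dates = []
    day, month_idx = 10, 0
    while len(dates) < n_days:
        dates.append(dt.date(year, months[month_idx], day))
        month_idx += 1
        if month_idx == len(months):
            month_idx, day = 0, day + 7
    return dates


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Truncated-normal draws by resampling (no clipping spike at the floor).

    The floor is 5% of the mean: gillnets do not catch near-zero-size fish,
    and it keeps rounded morphometrics strictly positive.
    """
    low = 0.05 * mean
    out = rng.normal(mean, sd, size)
    while True:
        bad = out <= low
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))


def generate(
    config: ScenarioConfig, seed: int | None = None
) -> tuple[list[SpecimenRecord], list[StomachItem]]:
    """Draw one synthetic survey dataset from a scenario.

    ``seed`` overrides the scenario's seed; identical (config, seed) pairs
    produce identical output.
    """
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed)
    )
    specimens: list[SpecimenRecord] = []
    items: list[StomachItem] = []
    counter = 0
    for sp in config.species:
        weights = sp.activity_weights()
        tag = "".join(w[0] for w in sp.label.replace(".", " ").split()).upper()
        for season in config.seasons:
            diet = np.asarray(sp.diet[season], dtype=float)
            diet = diet / diet.sum()
            repl = np.asarray(sp.repletion_probs[season], dtype=float)
            dates = _sampling_dates(season, config.n_days, config.year)
            n = rng.poisson(sp.abundance / len(config.seasons))
            if n == 0:
                continue
            day_idx = rng.integers(0, len(dates), n)
            interval_idx = rng.choice(len(INTERVALS), size=n, p=weights)
            female = rng.random(n) < sp.sex_ratio
            lengths = _truncated_normal(rng, sp.length_mean, sp.length_sd, n)
            weights_g = _truncated_normal(rng, sp.weight_mean, sp.weight_sd, n)
            gut_frac = rng.uniform(0.82, 0.95, n)
            repletion_idx = rng.choice(len(REPLETION_CLASSES), size=n, p=repl)
            for i in range(n):
                counter += 1
                sid = f"{tag}-{counter:05d}"
                repletion = REPLETION_CLASSES[repletion_idx[i]]
                stomach_frac = (
                    rng.uniform(0.001, 0.004)
                    if repletion == "void"
                    else rng.uniform(0.008, 0.04)
                )
                specimens.append(
                    SpecimenRecord(
                        specimen_id=sid,
                        species=sp.label,
                        sex="female" if female[i] else "male",
                        total_length=round(float(lengths[i]), 1),
                        total_weight=round(float(weights_g[i]), 2),
                        gutted_weight=round(float(weights_g[i] * gut_frac[i]), 2),
                        stomach_weight=round(float(weights_g[i] * stomach_frac), 3),
                        capture_date=dates[day_idx[i]],
                        interval=INTERVALS[interval_idx[i]],
                        repletion=repletion,
                    )
                )
                if repletion == "void":
                    continue
                n_items = 1 + rng.binomial(3, config.mean_extra_items / 3.0)
                cats = rng.choice(len(CATEGORIES), size=n_items, p=diet)
                vols = rng.lognormal(0.0, config.volume_noise, n_items)
                for c, v in zip(cats, vols):
                    items.append(
                        StomachItem(
                            specimen_id=sid,
                            category=CATEGORIES[c],
                            volume=round(float(v), 4),
                        )
                    )
    return specimens, items


def preset_paper_like() -> ScenarioConfig:
    """Two sympatric piranha-like populations of unequal abundance.

    Mimics the headline structure of the motivating survey: ~341 vs ~61
    specimens, near-even vs female-biased sex ratios, fish-dominated diets
    (the rarer species purely piscivorous in the dry season, forcing its
    dry-season niche breadth to zero, and the common species taking plant
    matter in the flood season), uniform vs nocturnal-bimodal activity,
    and a high proportion of void stomachs.  Diet vectors follow the
    category order: fish, crustacean, microcrustacean, insect, plant, other.
    """
    gibbus = SpeciesProfile(
        label="S. gibbus",
        abundance=341,
        sex_ratio=0.48,
        length_mean=123.0, length_sd=29.0,
        weight_mean=110.0, weight_sd=45.0,
        activity="uniform",
        diet={
            "flood": (0.78, 0.06, 0.02, 0.06, 0.08, 0.0),
            "dry": (0.88, 0.05, 0.01, 0.04, 0.02, 0.0),
        },
        repletion_probs={
            "flood": (0.62, 0.10, 0.28),
            "dry": (0.62, 0.10, 0.28),
        },
    )
    rhombeus = SpeciesProfile(
        label="S. rhombeus",
        abundance=61,
        sex_ratio=0.64,
        length_mean=310.0, length_sd=60.0,
        weight_mean=735.0, weight_sd=300.0,
        activity="nocturnal_bimodal",
        diet={
            "flood": (0.90, 0.05, 0.02, 0.03, 0.0, 0.0),
            "dry": (1.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        },
        repletion_probs={
            "flood": (0.66, 0.10, 0.24),
            "dry": (0.30, 0.32, 0.38),
        },
    )
    return ScenarioConfig(species=(gibbus, rhombeus), seed=20120915)
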