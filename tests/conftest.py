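"""Shared fixtures: a tiny handcrafted survey and the two-species preset."""

import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from trophon import GroupKey, SpecimenRecord, StomachItem, generate, preset_paper_like

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

#: Published diet table this analysis reproduces: printed FO (%) and VF (%)
#: per food category, with the printed feeding-importance values, for two
#: piranha species in the flood and dry seasons.
PRINTED_DIET_TABLE = {
    ("S. gibbus", "flood"): {
        "fish": (65.517, 22.014, 0.9671),
        "crustacean": (10.345, 2.510, 0.0174),
        "insect": (20.689, 1.089, 0.0151),
        "plant": (3.448, 0.138, 0.0003),
        "microcrustacean": (3.448, 0.055, 0.0001),
    },
    ("S. gibbus", "dry"): {
        "fish": (96.429, 37.118, 0.9588),
        "crustacean": (10.714, 3.857, 0.0111),
        "insect": (14.286, 0.843, 0.0032),
        "plant": (25.000, 4.007, 0.0268),
        "microcrustacean": (3.571, 0.075, 0.0001),
    },
    ("S. rhombeus", "flood"): {
        "fish": (80.000, 0.906, 0.9747),
        "crustacean": (20.000, 0.089, 0.0239),
        "insect": (20.000, 0.004, 0.0011),
        "microcrustacean": (20.000, 0.001, 0.0003),
    },
    ("S. rhombeus", "dry"): {
        "fish": (100.000, 1.000, 1.000),
    },
}


def make_specimen(
    sid: str = "S1",
    species: str = "S. gibbus",
    sex: str = "female",
    interval: str = "18:00",
    date: dt.date = dt.date(2012, 3, 15),
    repletion: str = "full",
    total_weight: float = 100.0,
) -> SpecimenRecord:
    return SpecimenRecord(
        specimen_id=sid,
        species=species,
        sex=sex,
        total_length=120.0,
        total_weight=total_weight,
        gutted_weight=0.9 * total_weight,
        stomach_weight=0.02 * total_weight,
        capture_date=date,
        interval=interval,
        repletion=repletion,
    )


@pytest.fixture
def tiny_survey():
    """Four stomachs with known composition: fish in 3/4, insect in 1/4."""
    specimens = [
        make_specimen("S1"),
        make_specimen("S2", sex="male", interval="12:00"),
        make_specimen("S3", interval="03:00"),
        make_specimen("S4", repletion="void"),
        make_specimen("S5", repletion="partly_full"),
    ]
    items = [
        StomachItem("S1", "fish", 3.0),
        StomachItem("S2", "fish", 2.0),
        StomachItem("S2", "insect", 1.0),
        StomachItem("S3", "fish", 1.0),
        StomachItem("S5", "insect", 2.0),
    ]
    return specimens, items


@pytest.fixture
def gibbus_group():
    return GroupKey(species="S. gibbus")


@pytest.fixture(scope="session")
def preset_dataset():
    """One draw from the two-species preset scenario (fixed seed)."""
    config = preset_paper_like()
    return generate(config)
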