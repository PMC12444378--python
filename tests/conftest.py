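"""Shared fixtures: the bundled practice map and small hand-built farms."""

from __future__ import annotations

import numpy as np
import pytest

from regenscore import FarmHistory, FieldSeason, default_practice_map


@pytest.fixture(scope="session")
def pmap():
    return default_practice_map()


def make_farm(farm_id, years, field_specs, group=None, landscape=None):
    """Build a FarmHistory from {field_id: (area, crop, practices-per-year)}.

    ``field_specs`` maps field_id -> (area, crop, {year: set of practice ids}).
    """
    seasons = []
    for field_id, (area, crop, per_year) in field_specs.items():
        for year in years:
            seasons.append(
                FieldSeason(
                    farm_id=farm_id,
                    year=year,
                    field_id=field_id,
                    area=area,
                    crop=crop if not callable(crop) else crop(year),
                    practices=frozenset(per_year.get(year, set())),
                )
            )
    return FarmHistory(farm_id, seasons, group=group, landscape=landscape)


@pytest.fixture()
def regen_farm():
    """A committed regenerative farm: most practices on most fields, every year."""
    years = range(2018, 2023)
    all_years = {
        y: {
            "no_till",
            "residue_retention",
            "cover_crops",
            "compaction_reduction",
            "livestock_grazing",
            "organic_matter",
            "spring_cropping",
            "crop_diversification",
        }
        for y in years
    }
    ley_years = {y: set(all_years[y]) | {"herbal_leys"} for y in years}
    return make_farm(
        "regen-1",
        years,
        {
            "f1": (15.0, "winter_wheat", all_years),
            "f2": (15.0, "spring_beans", all_years),
            "f3": (15.0, "oats", all_years),
            "f4": (15.0, "herbal_ley", ley_years),
        },
        group="regenerative",
        landscape="clay_arable",
    )


@pytest.fixture()
def conv_farm():
    """A conventional farm: residues retained some years, little else."""
    years = range(2018, 2023)
    residue = {y: {"residue_retention"} for y in (2019, 2021)}
    return make_farm(
        "conv-1",
        years,
        {
            "f1": (20.0, "winter_wheat", residue),
            "f2": (20.0, "winter_wheat", {}),
            "f3": (20.0, "winter_wheat", residue),
        },
        group="control",
        landscape="clay_arable",
    )


def random_small_farm(rng: np.random.Generator, pmap, farm_id="rand"):
    """A random farm with <=5 fields and <=5 years, for oracle comparisons."""
    n_fields = int(rng.integers(1, 6))
    n_years = int(rng.integers(1, 6))
    years = list(range(2018, 2018 + n_years))
    crops = ["wheat", "barley", "beans", "oats", ""]
    practice_ids = pmap.practice_ids
    seasons = []
    for year in years:
        for i in range(n_fields):
            k = int(rng.integers(0, len(practice_ids) + 1))
            chosen = rng.choice(practice_ids, size=k, replace=False) if k else []
            seasons.append(
                FieldSeason(
                    farm_id=farm_id,
                    year=year,
                    field_id=f"f{i}",
                    area=float(rng.uniform(0.5, 30.0)),
                    crop=str(rng.choice(crops)),
                    practices=frozenset(str(p) for p in chosen),
                )
            )
    return FarmHistory(farm_id, seasons)
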