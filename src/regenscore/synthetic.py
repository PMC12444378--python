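"""Synthetic farm panels emulating a farmer-led regenerative transition study.

The generator mimics the structure of a landscape-scale quasi-experiment:
~60 ha blocks of commercial farmland enrolled in one of three groups —
long-term conventional (control), long-term regenerative, or transitioning
from 2022/23 — replicated across two contrasting landscapes, with five years
of management history per block and an ecological outcome (earthworm density,
worms per site) responding linearly to the recency-weighted principle scores.

Randomness protocol: one user seed is expanded into per-farm child seeds with
``numpy.random.SeedSequence`` in enrolment order, so generating more farms
never reshuffles the ones already drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .practice_model import FarmHistory, FieldSeason, PracticeMap, default_practice_map
from .scoring import (
    WeightConfig,
    default_recency_weights,
    weighted_scores_table,
)

__all__ = [
    "ArchetypeConfig",
    "OutcomeModel",
    "LandscapeConfig",
    "default_archetypes",
    "generate_farm_history",
    "generate_landscape",
    "generate_outcomes",
    "gradient_farms",
    "simulate_baci_panel",
]

#: crops available everywhere; regenerative rotations draw from a longer list
BASE_CROPS = ("winter_wheat", "winter_barley", "oilseed_rape")
DIVERSE_CROPS = BASE_CROPS + ("spring_barley", "spring_beans", "oats", "herbal_ley")


@dataclass(frozen=True)
class ArchetypeConfig:
    """Stochastic management profile of one experimental farm group.

    ``adoption`` maps practice id → annual probability the practice is in use.
    ``persistence`` is the probability of carrying last year's state forward
    unchanged (temporal autocorrelation in management).  For the transition
    group, ``post_adoption`` probabilities replace ``adoption`` from
    ``transition_year`` onward.
    """

    group: str | None
    adoption: Mapping[str, float]
    persistence: float = 0.3
    transition_year: int | None = None
    post_adoption: Mapping[str, float] | None = None
    crops: tuple[str, ...] = BASE_CROPS

    def __post_init__(self) -> None:
        probs = dict(self.adoption)
        if self.post_adoption:
            probs.update(self.post_adoption)
        probs["__persistence__"] = self.persistence
        for key, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{self.group}: probability {key}={p} not in [0,1]")
        if self.transition_year is not None and self.post_adoption is None:
            raise ConfigError("transition_year set without post_adoption probabilities")

    def probs_for(self, year: int) -> Mapping[str, float]:
        if (
            self.transition_year is not None
            and self.post_adoption is not None
            and year >= self.transition_year
        ):
            return self.post_adoption
        return self.adoption


@dataclass(frozen=True)
class OutcomeModel:
    """Linear-additive outcome response to weighted principle scores.

    y = intercept + Σ_p slope_p · score_p + Normal(0, noise_sd²), in outcome
    units (default worms per site for earthworm density).
    """

    intercept: float = 5.0
    slopes: Mapping[str, float] = field(
        default_factory=lambda: {
            "soil-cover": 13.4,
            "minimize-disturbance": 11.1,
            "living-roots": 3.0,
            "diversity": 2.0,
            "livestock": 1.0,
        }
    )
    noise_sd: float = 5.0
    outcome_name: str = "earthworm_density"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LandscapeConfig:
    """Block geometry of the simulated study.

    Defaults follow the enrolled design: two landscapes × three groups × four
    60 ha blocks, plus one extra replicate (25 blocks total); which group gets
    the extra block is configurable, and ``extra_block_group=None`` gives the
    balanced 24-block layout.
    """

    landscapes: tuple[str, ...] = ("clay_arable", "chalk_mixed")
    blocks_per_group: int = 4
    extra_block_group: str | None = "transition"
    block_area: float = 60.0
    n_fields: tuple[int, int] = (3, 10)
    years: tuple[int, int] = (2018, 2022)

    def __post_init__(self) -> None:
        if self.blocks_per_group < 1 or self.block_area <= 0:
            raise ConfigError("blocks_per_group and block_area must be positive")
        lo, hi = self.n_fields
        if not 1 <= lo <= hi:
            raise ConfigError("n_fields range must satisfy 1 <= lo <= hi")
        if self.years[1] < self.years[0]:
            raise ConfigError("years range reversed")

    @property
    def n_farms(self) -> int:
        n = len(self.landscapes) * 3 * self.blocks_per_group
        return n + (1 if self.extra_block_group else 0)


def default_archetypes(pmap: PracticeMap | None = None,
                       transition_year: int = 2023) -> dict[str, ArchetypeConfig]:
    """Management profiles for the three groups.

    Control farms use regenerative practices sparingly, except residue
    retention and compaction control which are common on conventional farms
    too; regenerative farms use most practices most years (tillage still
    occasionally needed to move out of leys); transition farms behave like
    controls until ``transition_year``, then like regenerative farms.
    """
    if pmap is None:
        pmap = default_practice_map()
    ids = pmap.practice_ids
    control = {pid: 0.1 for pid in ids}
    control.update({"residue_retention": 0.5, "compaction_reduction": 0.4})
    regen = {pid: 0.9 for pid in ids}
    regen.update({"no_till": 0.8})
    control = {pid: control.get(pid, 0.1) for pid in ids}
    regen = {pid: regen.get(pid, 0.9) for pid in ids}
    return {
        "control": ArchetypeConfig("control", control),
        "regenerative": ArchetypeConfig("regenerative", regen, crops=DIVERSE_CROPS),
        "transition": ArchetypeConfig(
            "transition",
            control,
            transition_year=transition_year,
            post_adoption=regen,
            crops=DIVERSE_CROPS,
        ),
    }


def gradient_farms(n: int,
                   seed: int = 0,
                   pmap: PracticeMap | None = None,
                   years: tuple[int, int] = (2018, 2022),
                   n_fields: tuple[int, int] = (3, 10),
                   block_area: float = 60.0,
                   prob_range: tuple[float, float] = (0.05, 0.95)) -> list[FarmHistory]:
    """Simulate a continuous gradient of practice implementation.

    Each farm draws its own per-practice adoption probability independently
    and uniformly from ``prob_range``, emulating the observed baseline
    situation in which every enrolled farm sits somewhere on a spectrum of
    regenerative practice use rather than in clean groups.  Because the
    probabilities are independent across practices, principle scores vary
    much more independently than under the three clustered group archetypes —
    this is the population to use when a regression must attribute an outcome
    to a specific principle.
    """
    if pmap is None:
        pmap = default_practice_map()
    if n < 1:
        raise ConfigError("n must be >= 1")
    prob_rng = np.random.default_rng(np.random.SeedSequence([seed, 4_000_001]))
    year_list = list(range(years[0], years[1] + 1))
    farms = []
    for i in range(n):
        probs = {
            pid: float(prob_rng.uniform(*prob_range)) for pid in pmap.practice_ids
        }
        arche = ArchetypeConfig(None, probs, persistence=0.3,
                                crops=DIVERSE_CROPS)
        n_f = int(prob_rng.integers(n_fields[0], n_fields[1] + 1))
        farms.append(
            generate_farm_history(
                arche, "gradient", n_f, year_list, seed=seed,
                farm_id=f"grad-{i + 1:03d}", pmap=pmap,
                block_area=block_area, farm_index=i,
            )
        )
    return farms


def _rng_for_farm(seed: int, farm_index: int) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(farm_index + 1)
    return np.random.default_rng(children[farm_index])


def generate_farm_history(archetype: ArchetypeConfig,
                          landscape: str,
                          n_fields: int,
                          years: Sequence[int],
                          seed: int,
                          farm_id: str = "farm-1",
                          pmap: PracticeMap | None = None,
                          block_area: float = 60.0,
                          farm_index: int = 0) -> FarmHistory:
    """Simulate one farm block's multi-year practice history.

    Per year and practice, adoption is Bernoulli with persistence blending
    (with probability ``persistence`` the previous year's state carries over,
    otherwise a fresh draw).  An adopted practice is placed on a random
    non-empty subset of fields, so area-proportional practices cover a random
    share of the block.  Crop rotations draw from the archetype's crop list,
    widened whenever crop diversification is active.
    """
    if pmap is None:
        pmap = default_practice_map()
    if n_fields < 1:
        raise ConfigError("n_fields must be >= 1")
    rng = _rng_for_farm(seed, farm_index)

    # field areas fixed over years: Dirichlet split of the block
    shares = rng.dirichlet(np.full(n_fields, 5.0))
    areas = shares * block_area
    field_ids = [f"f{i + 1:02d}" for i in range(n_fields)]

    practice_ids = pmap.practice_ids
    state = {pid: False for pid in practice_ids}
    seasons: list[FieldSeason] = []
    for t, year in enumerate(years):
        probs = archetype.probs_for(year)
        applied_fields: dict[str, set[int]] = {}
        for pid in practice_ids:
            p = probs.get(pid, 0.0)
            if t > 0 and rng.random() < archetype.persistence:
                active = state[pid]
            else:
                active = rng.random() < p
            state[pid] = active
            if active:
                k = int(rng.integers(1, n_fields + 1))
                applied_fields[pid] = set(
                    rng.choice(n_fields, size=k, replace=False)
                )
        pool = list(archetype.crops)
        if "crop_diversification" in applied_fields:
            pool = list(dict.fromkeys(archetype.crops + DIVERSE_CROPS))
        crops = rng.choice(pool, size=n_fields, replace=True)
        for i in range(n_fields):
            practices = frozenset(
                pid for pid, idx in applied_fields.items() if i in idx
            )
            seasons.append(
                FieldSeason(
                    farm_id=farm_id,
                    year=int(year),
                    field_id=field_ids[i],
                    area=float(areas[i]),
                    crop=str(crops[i]),
                    practices=practices,
                )
            )
    return FarmHistory(farm_id, seasons, group=archetype.group, landscape=landscape)


def generate_landscape(cfg: LandscapeConfig | None = None,
                       archetypes: Mapping[str, ArchetypeConfig] | None = None,
                       seed: int = 0,
                       pmap: PracticeMap | None = None) -> list[FarmHistory]:
    """Simulate the full enrolled landscape: all blocks, all groups.

    Farms are enumerated landscape-major, then group, then replicate; each
    gets its own child seed so the panel is reproducible and extension-stable.
    """
    if cfg is None:
        cfg = LandscapeConfig()
    if pmap is None:
        pmap = default_practice_map()
    if archetypes is None:
        archetypes = default_archetypes(pmap)
    missing = [g for g in ("control", "transition", "regenerative") if g not in archetypes]
    if missing:
        raise ConfigError(f"archetypes missing group(s): {missing}")
    if cfg.extra_block_group is not None and cfg.extra_block_group not in archetypes:
        raise ConfigError(f"extra_block_group {cfg.extra_block_group!r} unknown")

    years = list(range(cfg.years[0], cfg.years[1] + 1))
    plan: list[tuple[str, str]] = []  # (landscape, group)
    for land in cfg.landscapes:
        for group in ("control", "transition", "regenerative"):
            plan.extend((land, group) for _ in range(cfg.blocks_per_group))
    if cfg.extra_block_group:
        plan.append((cfg.landscapes[0], cfg.extra_block_group))

    size_rng = np.random.default_rng(np.random.SeedSequence([seed, 1_000_001]))
    histories = []
    for idx, (land, group) in enumerate(plan):
        n_fields = int(size_rng.integers(cfg.n_fields[0], cfg.n_fields[1] + 1))
        histories.append(
            generate_farm_history(
                archetypes[group],
                landscape=land,
                n_fields=n_fields,
                years=years,
                seed=seed,
                farm_id=f"{land[:4]}-{group[:4]}-{idx + 1:02d}",
                pmap=pmap,
                block_area=cfg.block_area,
                farm_index=idx,
            )
        )
    return histories


def generate_outcomes(histories: Sequence[FarmHistory],
                      pmap: PracticeMap | None = None,
                      weights: WeightConfig | None = None,
                      model: OutcomeModel | None = None,
                      seed: int = 0,
                      window: tuple[int, int] | None = None,
                      year: int | None = None) -> pd.DataFrame:
    """Draw one outcome per farm from the linear score-response model.

    Scores are the recency-weighted principle scores over ``window`` (default:
    the trailing window ending at the last observed year).  Returns a tidy
    frame with columns farm_id, year, outcome, value.
    """
    if pmap is None:
        pmap = default_practice_map()
    if weights is None:
        weights = default_recency_weights(pmap.window_years)
    if model is None:
        model = OutcomeModel()
    scores = weighted_scores_table(histories, pmap, weights, window=window)
    if year is None:
        year = window[1] if window else max(y for h in histories for y in h.years)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2_000_001]))
    values = np.full(len(scores), model.intercept, dtype=float)
    for pid, slope in model.slopes.items():
        if pid in scores.columns:
            values += slope * scores[pid].to_numpy()
    values += rng.normal(0.0, model.noise_sd, size=len(scores))
    return pd.DataFrame(
        {
            "farm_id": scores["farm_id"],
            "year": year,
            "outcome": model.outcome_name,
            "value": values,
        }
    )


def simulate_baci_panel(cfg: LandscapeConfig | None = None,
                        delta: float = 0.0,
                        seed: int = 0,
                        archetypes: Mapping[str, ArchetypeConfig] | None = None,
                        model: OutcomeModel | None = None,
                        pmap: PracticeMap | None = None,
                        transition_year: int = 2023,
                        n_before: int = 2,
                        n_after: int = 2) -> pd.DataFrame:
    """Simulate a before–after control–impact outcome panel.

    Each farm keeps a persistent outcome level set by its baseline weighted
    principle scores; the transition group gains ``delta`` in every year from
    ``transition_year`` on.  Panel years are the ``n_before`` years before the
    transition and ``n_after`` years from it (inclusive).  Columns: farm_id,
    group, landscape, year, period (before/after), outcome, value.
    """
    if n_after < 1:
        raise ConfigError("panel needs at least one post-transition year")
    if n_before < 1:
        raise ConfigError("panel needs at least one pre-transition year")
    if cfg is None:
        cfg = LandscapeConfig()
    if pmap is None:
        pmap = default_practice_map()
    if model is None:
        model = OutcomeModel()
    histories = generate_landscape(cfg, archetypes, seed=seed, pmap=pmap)
    scores = weighted_scores_table(histories, pmap)
    meta = scores.set_index("farm_id")
    base = pd.Series(model.intercept, index=meta.index, dtype=float)
    for pid, slope in model.slopes.items():
        if pid in meta.columns:
            base = base + slope * meta[pid]

    years = list(range(transition_year - n_before, transition_year + n_after))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3_000_001]))
    rows = []
    for farm_id in meta.index:
        group = meta.loc[farm_id, "group"]
        for year in years:
            after = year >= transition_year
            value = base[farm_id] + rng.normal(0.0, model.noise_sd)
            if after and group == "transition":
                value += delta
            rows.append(
                {
                    "farm_id": farm_id,
                    "group": group,
                    "landscape": meta.loc[farm_id, "landscape"],
                    "year": year,
                    "period": "after" if after else "before",
                    "outcome": model.outcome_name,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)
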