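"""Per-year practice scores, principle scores and recency-weighted aggregates.

The scoring pipeline has four stages:

1. each practice gets an annual relative-frequency score in [0, 1] for every
   farm-year (how much of the farm it was applied on, by its scoring mode);
2. each principle's annual score is the unweighted mean of its constituent
   practice scores, so a principle maxes out at 1 when every mapped practice
   is applied at full relative frequency;
3. annual principle scores over a multi-year window are combined with
   recency-increasing weights (recent implementation counts more, reflecting
   the cumulative build-up of benefits from sustained practice);
4. the combined farm score is the sum of the weighted principle scores,
   ranging from 0 to the number of principles (a normalized mean variant is
   carried alongside for cross-context comparability).

Years for which a farm has no rows are "no data", not "no practices": the
recency weights are renormalized over observed years and the fraction of the
window covered is reported with every weighted score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ScoreError
from .practice_model import FarmHistory, FieldSeason, PracticeDefinition, PracticeMap

__all__ = [
    "PracticeYearScore",
    "PrincipleYearScore",
    "WeightConfig",
    "WeightedPrincipleScore",
    "CombinedScore",
    "practice_year_score",
    "principle_year_score",
    "default_recency_weights",
    "exponential_recency_weights",
    "weighted_principle_score",
    "combined_score",
    "score_trajectory",
    "farm_year_principle_scores",
    "weighted_scores_table",
]


@dataclass(frozen=True)
class PracticeYearScore:
    farm_id: str
    year: int
    practice_id: str
    score: float


@dataclass(frozen=True)
class PrincipleYearScore:
    farm_id: str
    year: int
    principle_id: str
    score: float


@dataclass(frozen=True)
class WeightedPrincipleScore:
    farm_id: str
    principle_id: str
    window: tuple[int, int]
    score: float
    coverage: float


@dataclass(frozen=True)
class CombinedScore:
    """Cumulative score across principles; ``normalized`` = score / #principles."""

    farm_id: str
    window: tuple[int, int]
    score: float
    normalized: float


@dataclass(frozen=True)
class WeightConfig:
    """Recency weights over a scoring window, oldest year first.

    Weights are non-negative, non-decreasing oldest→newest and sum to 1, so a
    weighted score is a convex combination of annual scores and stays in
    [0, 1].
    """

    window_years: int
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if self.window_years < 1 or len(w) != self.window_years:
            raise ScoreError("weights length must equal window_years >= 1")
        if (w < 0).any():
            raise ScoreError("weights must be non-negative")
        if not np.isclose(w.sum(), 1.0):
            raise ScoreError("weights must sum to 1")
        if (np.diff(w) < -1e-12).any():
            raise ScoreError("weights must be non-decreasing oldest to newest")


def default_recency_weights(window_years: int) -> WeightConfig:
    """Linear recency weights w_k = k / (1 + 2 + ... + Y), k = 1 oldest."""
    if window_years < 1:
        raise ScoreError("window_years must be >= 1")
    k = np.arange(1, window_years + 1, dtype=float)
    return WeightConfig(window_years, tuple(k / k.sum()))


def exponential_recency_weights(window_years: int, rate: float = 0.5) -> WeightConfig:
    """Exponential recency weights w_k ∝ exp(rate · k); rate >= 0.

    ``rate`` = 0 degenerates to a flat average; larger rates concentrate
    weight on the most recent years.
    """
    if window_years < 1:
        raise ScoreError("window_years must be >= 1")
    if rate < 0:
        raise ScoreError("rate must be >= 0")
    k = np.arange(1, window_years + 1, dtype=float)
    w = np.exp(rate * k)
    return WeightConfig(window_years, tuple(w / w.sum()))


# ---------------------------------------------------------------------------
# stage 1+2: annual scores


def practice_year_score(seasons: Sequence[FieldSeason],
                        practice: PracticeDefinition) -> PracticeYearScore:
    """Annual relative frequency of one practice on one farm-year.

    ``seasons`` must be all (and only) the field-seasons of a single farm in a
    single year.  The rule depends on the practice's scoring mode; see
    :class:`~regenscore.practice_model.PracticeDefinition`.
    """
    if not seasons:
        raise ScoreError("no data for farm-year")
    farm_years = {(s.farm_id, s.year) for s in seasons}
    if len(farm_years) != 1:
        raise ScoreError(f"seasons span multiple farm-years: {sorted(farm_years)}")
    (farm_id, year), = farm_years

    if practice.mode == "binary_rotational":
        score = 1.0 if any(practice.id in s.practices for s in seasons) else 0.0
    elif practice.mode == "area_proportional":
        total = sum(s.area for s in seasons)
        applied = sum(s.area for s in seasons if practice.id in s.practices)
        score = applied / total
    else:  # diversity_scaled
        n_fields = len(seasons)
        if n_fields == 1:
            score = 0.0  # a single field cannot express within-farm diversity
        else:
            crops = {s.crop for s in seasons if s.crop}
            score = min(max((len(crops) - 1) / (n_fields - 1), 0.0), 1.0)
    return PracticeYearScore(farm_id, year, practice.id, score)


def principle_year_score(practice_scores: Iterable[PracticeYearScore],
                         principle_id: str,
                         pmap: PracticeMap) -> PrincipleYearScore:
    """Mean of constituent practice scores for one principle in one farm-year.

    Practices mapped to the principle but absent from ``practice_scores``
    count as 0 (not implemented anywhere that year).
    """
    constituents = pmap.practices_for(principle_id)
    if not constituents:
        raise ScoreError(f"principle {principle_id} has no mapped practices")
    by_id = {}
    farm_year = None
    for ps in practice_scores:
        key = (ps.farm_id, ps.year)
        if farm_year is None:
            farm_year = key
        elif key != farm_year:
            raise ScoreError("practice scores span multiple farm-years")
        by_id[ps.practice_id] = ps.score
    if farm_year is None:
        raise ScoreError("no practice scores supplied")
    mean = float(np.mean([by_id.get(pr.id, 0.0) for pr in constituents]))
    return PrincipleYearScore(farm_year[0], farm_year[1], principle_id, mean)


def farm_year_principle_scores(history: FarmHistory,
                               pmap: PracticeMap) -> list[PrincipleYearScore]:
    """All per-year principle scores for one farm, every year with data."""
    out = []
    for year in history.years:
        seasons = history.seasons_in(year)
        pscores = [practice_year_score(seasons, pr) for pr in pmap.practices]
        for pid in pmap.principle_ids:
            out.append(principle_year_score(pscores, pid, pmap))
    return out


# ---------------------------------------------------------------------------
# stage 3+4: multi-year aggregation


def weighted_principle_score(series: Iterable[PrincipleYearScore],
                             window: tuple[int, int],
                             weights: WeightConfig) -> WeightedPrincipleScore:
    """Recency-weighted principle score over ``window`` (first, last year).

    Weights are renormalized over the years that actually have data; the
    reported ``coverage`` is the fraction of window years observed.
    """
    first, last = window
    if last - first + 1 != weights.window_years:
        raise ScoreError(
            f"window {window} does not match weight length {weights.window_years}"
        )
    scores: dict[int, PrincipleYearScore] = {}
    for s in series:
        if not first <= s.year <= last:
            raise ScoreError(f"year {s.year} outside window {window}")
        scores[s.year] = s
    if not scores:
        raise ScoreError(f"no data inside window {window}")
    ids = {(s.farm_id, s.principle_id) for s in scores.values()}
    if len(ids) != 1:
        raise ScoreError(f"series mixes farms/principles: {sorted(ids)}")
    (farm_id, principle_id), = ids

    years = sorted(scores)
    w = np.array([weights.weights[y - first] for y in years])
    w = w / w.sum()
    value = float(np.dot(w, [scores[y].score for y in years]))
    coverage = len(years) / weights.window_years
    return WeightedPrincipleScore(farm_id, principle_id, window, value, coverage)


def combined_score(per_principle: Sequence[WeightedPrincipleScore],
                   pmap: PracticeMap) -> CombinedScore:
    """Cumulative score across principles: the sum of weighted principle scores."""
    have = {s.principle_id for s in per_principle}
    missing = [pid for pid in pmap.principle_ids if pid not in have]
    if missing:
        raise ScoreError(f"missing weighted scores for principle(s): {missing}")
    farms = {s.farm_id for s in per_principle}
    windows = {s.window for s in per_principle}
    if len(farms) != 1 or len(windows) != 1:
        raise ScoreError("scores must come from one farm and one window")
    wanted = [s for s in per_principle if s.principle_id in set(pmap.principle_ids)]
    total = float(sum(s.score for s in wanted))
    return CombinedScore(
        farms.pop(), windows.pop(), total, total / len(pmap.principle_ids)
    )


def score_trajectory(history: FarmHistory,
                     pmap: PracticeMap,
                     weights: WeightConfig | None = None) -> pd.DataFrame:
    """Per-year principle scores plus the rolling windowed combined score.

    Returns a DataFrame indexed by year with one column per principle (that
    year's score), plus ``combined`` (windowed score ending that year),
    ``normalized`` and ``coverage``.
    """
    if weights is None:
        weights = default_recency_weights(pmap.window_years)
    annual = farm_year_principle_scores(history, pmap)
    by_year: dict[int, dict[str, PrincipleYearScore]] = {}
    for s in annual:
        by_year.setdefault(s.year, {})[s.principle_id] = s

    rows = []
    for year in history.years:
        window = (year - weights.window_years + 1, year)
        per_principle = []
        for pid in pmap.principle_ids:
            series = [
                by_year[y][pid]
                for y in by_year
                if window[0] <= y <= window[1]
            ]
            per_principle.append(weighted_principle_score(series, window, weights))
        comb = combined_score(per_principle, pmap)
        row = {"year": year}
        row.update({pid: by_year[year][pid].score for pid in pmap.principle_ids})
        row["combined"] = comb.score
        row["normalized"] = comb.normalized
        row["coverage"] = per_principle[0].coverage
        rows.append(row)
    return pd.DataFrame(rows).set_index("year")


def weighted_scores_table(histories: Sequence[FarmHistory],
                          pmap: PracticeMap,
                          weights: WeightConfig | None = None,
                          window: tuple[int, int] | None = None) -> pd.DataFrame:
    """One row per farm: weighted principle scores, combined score, coverage.

    ``window`` defaults to the window of length ``weights.window_years``
    ending at the latest year observed across all farms.  Farms with no data
    in the window are omitted.
    """
    if weights is None:
        weights = default_recency_weights(pmap.window_years)
    if window is None:
        last = max(y for h in histories for y in h.years)
        window = (last - weights.window_years + 1, last)

    rows = []
    for h in histories:
        annual = [
            s
            for s in farm_year_principle_scores(h, pmap)
            if window[0] <= s.year <= window[1]
        ]
        if not annual:
            continue
        per_principle = []
        for pid in pmap.principle_ids:
            series = [s for s in annual if s.principle_id == pid]
            per_principle.append(weighted_principle_score(series, window, weights))
        comb = combined_score(per_principle, pmap)
        row: dict = {"farm_id": h.farm_id, "group": h.group, "landscape": h.landscape}
        row.update({s.principle_id: s.score for s in per_principle})
        row["combined"] = comb.score
        row["normalized"] = comb.normalized
        row["coverage"] = per_principle[0].coverage
        rows.append(row)
    return pd.DataFrame(rows)
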