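"""Domain model for practices, principles and farm histories.

The scoring system is anchored on five regenerative principles (minimize soil
disturbance, keep soil covered, increase diversity, maintain living roots,
integrate livestock).  Concrete management practices are mapped to one or more
principles via a :class:`PracticeMap`; farm management is recorded as
long-format field-season rows (one field in one farm-year, with the set of
practices applied).  This module owns those types plus the readers/writers for
the YAML map format and the farm-history CSV format.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, LoadError

__all__ = [
    "Principle",
    "PracticeDefinition",
    "PracticeMap",
    "FieldSeason",
    "FarmHistory",
    "SCORING_MODES",
    "FARM_GROUPS",
    "default_practice_map",
    "load_practice_map",
    "load_practice_map_csv",
    "save_practice_map",
    "load_farm_histories",
    "save_farm_histories",
]

#: The three ways a practice's annual relative frequency is computed.
SCORING_MODES = ("area_proportional", "binary_rotational", "diversity_scaled")

#: Experimental farm groups in the quasi-experimental design.
FARM_GROUPS = ("control", "transition", "regenerative")

HISTORY_COLUMNS = ["farm_id", "year", "field_id", "area_ha", "crop", "practices"]

#: Delimiter used inside the ``practices`` CSV cell.
PRACTICE_DELIM = ";"


@dataclass(frozen=True)
class Principle:
    """One of the high-level regenerative goals (e.g. keep soil covered)."""

    id: str
    name: str


@dataclass(frozen=True)
class PracticeDefinition:
    """A concrete management action and how its annual score is computed.

    ``mode`` selects the scoring rule:

    - ``area_proportional``: share of recorded farm area on which the
      practice was applied that year.
    - ``binary_rotational``: 1 if applied on at least one field (rotational
      practices such as herbal leys that only ever occupy a few fields).
    - ``diversity_scaled``: scaled count of distinct crops relative to the
      number of fields, so small farms are not penalized.
    """

    id: str
    name: str
    mode: str
    principles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mode not in SCORING_MODES:
            raise ConfigError(
                f"practice {self.id!r}: mode {self.mode!r} not one of {SCORING_MODES}"
            )
        if not self.principles:
            raise ConfigError(f"practice {self.id!r} maps to no principles")


@dataclass
class PracticeMap:
    """A validated practice → principle mapping for one farming context."""

    principles: list[Principle]
    practices: list[PracticeDefinition]
    window_years: int = 5

    def __post_init__(self) -> None:
        if self.window_years < 1:
            raise ConfigError("window_years must be >= 1")
        pids = [p.id for p in self.principles]
        if len(set(pids)) != len(pids):
            raise ConfigError("duplicate principle ids")
        prids = [p.id for p in self.practices]
        if len(set(prids)) != len(prids):
            raise ConfigError("duplicate practice ids")
        known = set(pids)
        bad = {
            pr.id: [q for q in pr.principles if q not in known]
            for pr in self.practices
            if any(q not in known for q in pr.principles)
        }
        if bad:
            detail = "; ".join(f"{k} -> {v}" for k, v in sorted(bad.items()))
            raise ConfigError(f"practices reference unknown principles: {detail}")
        n_div = sum(1 for pr in self.practices if pr.mode == "diversity_scaled")
        if n_div > 1:
            raise ConfigError("at most one practice may use mode diversity_scaled")
        served = {q for pr in self.practices for q in pr.principles}
        for pid in pids:
            if pid not in served:
                warnings.warn(f"principle {pid} unserved by any practice", stacklevel=2)

    @property
    def principle_ids(self) -> list[str]:
        return [p.id for p in self.principles]

    @property
    def practice_ids(self) -> list[str]:
        return [p.id for p in self.practices]

    def practice(self, practice_id: str) -> PracticeDefinition:
        for pr in self.practices:
            if pr.id == practice_id:
                return pr
        raise KeyError(practice_id)

    def practices_for(self, principle_id: str) -> list[PracticeDefinition]:
        """All practices mapped to ``principle_id`` (order as configured)."""
        if principle_id not in self.principle_ids:
            raise KeyError(principle_id)
        return [pr for pr in self.practices if principle_id in pr.principles]

    def to_dict(self) -> dict:
        return {
            "window_years": self.window_years,
            "principles": [{"id": p.id, "name": p.name} for p in self.principles],
            "practices": [
                {
                    "id": pr.id,
                    "name": pr.name,
                    "mode": pr.mode,
                    "principles": list(pr.principles),
                }
                for pr in self.practices
            ],
        }


@dataclass(frozen=True)
class FieldSeason:
    """One field in one farm-year: the atomic management record."""

    farm_id: str
    year: int
    field_id: str
    area: float
    crop: str = ""
    practices: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (math.isfinite(self.area) and self.area > 0):
            raise LoadError(
                f"field {self.farm_id}/{self.year}/{self.field_id}: "
                f"area must be finite and positive, got {self.area}"
            )


@dataclass
class FarmHistory:
    """All field-seasons recorded for one farm, with its experimental group."""

    farm_id: str
    seasons: list[FieldSeason]
    group: str | None = None
    landscape: str | None = None

    def __post_init__(self) -> None:
        if self.group is not None and self.group not in FARM_GROUPS:
            raise ConfigError(
                f"farm {self.farm_id}: group {self.group!r} not one of {FARM_GROUPS}"
            )
        for s in self.seasons:
            if s.farm_id != self.farm_id:
                raise LoadError(
                    f"season for farm {s.farm_id!r} attached to history {self.farm_id!r}"
                )
        yrs = self.years
        if yrs and set(range(min(yrs), max(yrs) + 1)) - set(yrs):
            gaps = sorted(set(range(min(yrs), max(yrs) + 1)) - set(yrs))
            warnings.warn(
                f"farm {self.farm_id}: no data for year(s) {gaps}; "
                "treated as missing, not as zero implementation",
                stacklevel=2,
            )

    @property
    def years(self) -> list[int]:
        return sorted({s.year for s in self.seasons})

    def seasons_in(self, year: int) -> list[FieldSeason]:
        return [s for s in self.seasons if s.year == year]


# ---------------------------------------------------------------------------
# practice map I/O


def _map_from_dict(doc: Mapping) -> PracticeMap:
    try:
        principles = [Principle(str(d["id"]), str(d.get("name", d["id"])))
                      for d in doc["principles"]]
        practices = [
            PracticeDefinition(
                str(d["id"]),
                str(d.get("name", d["id"])),
                str(d["mode"]),
                tuple(str(q) for q in d["principles"]),
            )
            for d in doc["practices"]
        ]
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed practice map: missing key {exc}") from exc
    return PracticeMap(principles, practices, int(doc.get("window_years", 5)))


def default_practice_map() -> PracticeMap:
    """The bundled nine-practice, five-principle map for UK arable systems."""
    text = resources.files("regenscore.data").joinpath("h3_core.yaml").read_text()
    return _map_from_dict(yaml.safe_load(text))


def load_practice_map(path: str | Path) -> PracticeMap:
    """Load and validate a practice map from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"practice map not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse {path}{line}: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return _map_from_dict(doc)


def load_practice_map_csv(practices_path: str | Path,
                          mapping_path: str | Path,
                          window_years: int = 5) -> PracticeMap:
    """Load a map from two CSVs: practices (id,name,mode) and mapping
    (practice_id,principle_id,principle_name)."""
    prac = pd.read_csv(practices_path, dtype=str, comment="#")
    mapping = pd.read_csv(mapping_path, dtype=str, comment="#")
    for frame, need, where in (
        (prac, {"id", "name", "mode"}, practices_path),
        (mapping, {"practice_id", "principle_id"}, mapping_path),
    ):
        if missing := need - set(frame.columns):
            raise ConfigError(f"{where}: missing columns {sorted(missing)}")
    names = {}
    if "principle_name" in mapping.columns:
        names = dict(zip(mapping["principle_id"], mapping["principle_name"]))
    principles = [
        Principle(pid, names.get(pid, pid) or pid)
        for pid in dict.fromkeys(mapping["principle_id"])
    ]
    by_practice = mapping.groupby("practice_id", sort=False)["principle_id"].agg(list)
    practices = [
        PracticeDefinition(r.id, r.name, r.mode, tuple(by_practice.get(r.id, ())))
        for r in prac.itertuples()
    ]
    return PracticeMap(principles, practices, window_years)


def save_practice_map(pmap: PracticeMap, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(pmap.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# farm history I/O


def _parse_practices(cell: object, known: set[str], row: int) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return frozenset()
    ids = [tok.strip() for tok in str(cell).split(PRACTICE_DELIM) if tok.strip()]
    unknown = [tok for tok in ids if tok not in known]
    if unknown:
        raise LoadError(f"unknown practice id(s) {unknown}", row=row)
    return frozenset(ids)


def load_farm_histories(path: str | Path,
                        pmap: PracticeMap | None = None) -> list[FarmHistory]:
    """Read long-format farm histories from CSV.

    Required columns: ``farm_id,year,field_id,area_ha,crop,practices``;
    optional ``group`` and ``landscape`` columns (constant per farm).  The
    ``practices`` cell holds semicolon-delimited practice ids; when ``pmap``
    is given, unknown ids are rejected with the offending row number.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"farm history file not found: {path}")
    df = pd.read_csv(path, comment="#", dtype={"farm_id": str, "field_id": str})
    if missing := set(HISTORY_COLUMNS) - set(df.columns):
        raise LoadError(f"{path}: missing columns {sorted(missing)}")
    known = set(pmap.practice_ids) if pmap is not None else None

    dup = df.duplicated(subset=["farm_id", "year", "field_id"])
    if dup.any():
        first = int(df.index[dup][0]) + 2  # header + 1-based
        raise LoadError("duplicate (farm_id, year, field_id)", row=first)

    histories: dict[str, list[FieldSeason]] = {}
    meta: dict[str, tuple[str | None, str | None]] = {}
    for idx, rec in enumerate(df.itertuples(index=False)):
        row = idx + 2
        area = float(rec.area_ha)
        if not (math.isfinite(area) and area > 0):
            raise LoadError(f"area_ha must be positive, got {rec.area_ha}", row=row)
        if known is not None:
            practices = _parse_practices(rec.practices, known, row)
        else:
            cell = "" if pd.isna(rec.practices) else str(rec.practices)
            practices = frozenset(
                tok.strip() for tok in cell.split(PRACTICE_DELIM) if tok.strip()
            )
        crop = "" if pd.isna(rec.crop) else str(rec.crop)
        season = FieldSeason(
            farm_id=str(rec.farm_id),
            year=int(rec.year),
            field_id=str(rec.field_id),
            area=area,
            crop=crop,
            practices=practices,
        )
        histories.setdefault(season.farm_id, []).append(season)
        group = getattr(rec, "group", None)
        landscape = getattr(rec, "landscape", None)
        meta.setdefault(
            season.farm_id,
            (
                None if group is None or pd.isna(group) else str(group),
                None if landscape is None or pd.isna(landscape) else str(landscape),
            ),
        )

    out = []
    for farm_id in sorted(histories):
        seasons = sorted(histories[farm_id], key=lambda s: (s.year, s.field_id))
        group, landscape = meta[farm_id]
        out.append(FarmHistory(farm_id, seasons, group=group, landscape=landscape))
    return out


def histories_to_frame(histories: Iterable[FarmHistory]) -> pd.DataFrame:
    """Long-format DataFrame view of a set of farm histories."""
    rows = []
    for h in histories:
        for s in sorted(h.seasons, key=lambda s: (s.year, s.field_id)):
            rows.append(
                {
                    "farm_id": s.farm_id,
                    "year": s.year,
                    "field_id": s.field_id,
                    "area_ha": s.area,
                    "crop": s.crop,
                    "practices": PRACTICE_DELIM.join(sorted(s.practices)),
                    "group": h.group,
                    "landscape": h.landscape,
                }
            )
    return pd.DataFrame(rows)


def save_farm_histories(histories: Sequence[FarmHistory], path: str | Path,
                        header_lines: Sequence[str] = ()) -> None:
    df = histories_to_frame(histories)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
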