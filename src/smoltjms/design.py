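"""Study topology, colony metadata, and capture-recapture-recovery histories.

The study system is a river divided into ``J`` sequential reaches (segments)
delineated by ``J - 1`` in-river PIT-tag recapture sites; site ``j`` sits at the
downstream end of reach ``j``.  There is no recapture opportunity downstream of
the final reach.  Tagged juvenile salmonids (smolts) released at the head of
reach 1 may be detected alive at recapture sites, removed from the river at a
transport site (barged/trucked past the remaining dams), or consumed by birds
from one of ``D - 1`` breeding colonies and later recovered as a tag on that
colony; fate ``D`` is "never recovered".

Each colony forages in at most two of the river reaches, which is what makes
the partitioning of its consumption across reaches estimable.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

POPULATIONS = ("steelhead", "yearling_chinook", "subyearling_chinook", "sockeye")
BIRD_SPECIES = ("tern", "cormorant", "gull")

#: history CSV schema, one row per fish; site columns appended as site_1..site_{J-1}
BASE_COLUMNS = ("fish_id", "population", "year", "cohort_week",
                "transport_site", "recovery", "adult_return")


class SchemaError(ValueError):
    """The input table does not conform to the documented column schema."""


class ConsistencyError(ValueError):
    """Rows violate capture-recapture-recovery invariants."""


@dataclass(frozen=True)
class StudyDesign:
    """Topology of reaches, recapture sites, transport sites and colonies.

    Parameters
    ----------
    n_reaches : int
        Number of sequential river segments ``J``; there are ``J - 1``
        recapture sites, site ``j`` ending segment ``j``.
    colony_ids : tuple of str
        Ordered identifiers of the ``D - 1`` bird colonies.
    forage_map : mapping
        ``colony_id -> tuple of reach indices`` (1-based, length 1 or 2) the
        colony is known to forage within.
    transport_sites : tuple of int
        Recapture sites at which fish may be collected and removed from the
        river; restricted to the first three sites.
    """

    n_reaches: int
    colony_ids: tuple[str, ...]
    forage_map: Mapping[str, tuple[int, ...]]
    transport_sites: tuple[int, ...] = ()
    site_labels: tuple[str, ...] = ()
    reach_labels: tuple[str, ...] = ()

    def __post_init__(self):
        J = self.n_reaches
        if J < 1:
            raise ValueError("need at least one reach")
        object.__setattr__(self, "colony_ids", tuple(self.colony_ids))
        object.__setattr__(self, "transport_sites", tuple(self.transport_sites))
        object.__setattr__(
            self, "forage_map",
            {c: tuple(sorted(self.forage_map[c])) for c in self.colony_ids})
        for c in self.colony_ids:
            reaches = self.forage_map[c]
            if not 1 <= len(reaches) <= 2:
                raise ValueError(f"colony {c}: forage set must have 1 or 2 reaches")
            if any(not 1 <= r <= J for r in reaches):
                raise ValueError(f"colony {c}: forage reach outside 1..{J}")
        if any(m not in (1, 2, 3) or m > self.n_sites for m in self.transport_sites):
            raise ValueError("transport sites restricted to existing sites among {1,2,3}")

    @property
    def n_sites(self) -> int:
        return self.n_reaches - 1

    @property
    def n_colonies(self) -> int:
        return len(self.colony_ids)

    @property
    def not_recovered_index(self) -> int:
        """1-based fate index D meaning 'tag never recovered'."""
        return self.n_colonies + 1

    def colony_index(self, colony_id: str) -> int:
        """0-based index of a colony in fate order."""
        return self.colony_ids.index(colony_id)

    def to_yaml(self, path) -> None:
        doc = {
            "n_reaches": self.n_reaches,
            "colony_ids": list(self.colony_ids),
            "forage_map": {c: list(v) for c, v in self.forage_map.items()},
            "transport_sites": list(self.transport_sites),
            "site_labels": list(self.site_labels),
            "reach_labels": list(self.reach_labels),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            n_reaches=doc["n_reaches"],
            colony_ids=tuple(doc["colony_ids"]),
            forage_map={c: tuple(v) for c, v in doc["forage_map"].items()},
            transport_sites=tuple(doc.get("transport_sites", ())),
            site_labels=tuple(doc.get("site_labels", ())),
            reach_labels=tuple(doc.get("reach_labels", ())),
        )


@dataclass(frozen=True)
class ColonyMeta:
    """Species, location and monitoring record of one breeding colony.

    A colony may be active (birds nesting) in a year without having been
    scanned for tags after the season, in which case no recoveries exist for
    it that year and no consumption estimate can be produced.
    """

    colony_id: str
    bird_species: str
    location_label: str = ""
    active_years: frozenset[int] = frozenset()
    scanned_years: frozenset[int] = frozenset()

    def __post_init__(self):
        if self.bird_species not in BIRD_SPECIES:
            raise ValueError(f"bird_species must be one of {BIRD_SPECIES}")
        object.__setattr__(self, "active_years", frozenset(self.active_years))
        object.__setattr__(self, "scanned_years", frozenset(self.scanned_years))


@dataclass(frozen=True)
class FishHistory:
    """One tagged fish's recapture/recovery record.

    ``y`` is a binary vector of length ``J`` whose entry ``j-1`` indicates a
    live detection at recapture site ``j``; the last entry is structurally 0
    (no site ends the terminal reach).  ``recovery`` is the 1-based fate index:
    ``1..D-1`` a colony, ``D`` never recovered.  A transported fish was
    detected and removed at ``transport_site``; its history is truncated
    there, so it carries no downstream detections and no recovery.
    """

    fish_id: str
    population: str
    year: int
    cohort_week: int
    y: tuple[int, ...]
    recovery: int
    transport_site: Optional[int] = None
    adult_return: bool = False

    def validate(self, design: StudyDesign) -> None:
        J = design.n_reaches
        D = design.not_recovered_index
        if self.population not in POPULATIONS:
            raise ConsistencyError(f"unknown population {self.population!r}")
        if len(self.y) != J:
            raise ConsistencyError(f"y must have length {J}")
        if any(v not in (0, 1) for v in self.y):
            raise ConsistencyError("y entries must be 0/1")
        if self.y[J - 1] != 0:
            raise ConsistencyError("y at the terminal reach is structurally 0")
        if not 1 <= self.recovery <= D:
            raise ConsistencyError(f"recovery must be in 1..{D}")
        if self.cohort_week < 0:
            raise ConsistencyError("cohort_week must be >= 0")
        if self.transport_site is not None:
            m = self.transport_site
            if m not in design.transport_sites:
                raise ConsistencyError(f"site {m} is not a transport site")
            if self.y[m - 1] != 1:
                raise ConsistencyError("removal requires capture: y at the transport site must be 1")
            if any(self.y[j] for j in range(m, J)):
                raise ConsistencyError("transported fish cannot be detected downstream of removal")
            if self.recovery != D:
                raise ConsistencyError("transported fish cannot be recovered on a colony")
            if self.adult_return:
                raise ConsistencyError("in-river adult returns undefined for transported fish")
        if self.recovery != D and self.adult_return:
            raise ConsistencyError("a fish recovered dead cannot return as an adult")


# A history stripped to its likelihood-sufficient statistic.
HistoryKey = tuple[tuple[int, ...], int, Optional[int]]


def history_key(h: FishHistory) -> HistoryKey:
    return (tuple(h.y), h.recovery, h.transport_site)


@dataclass
class CohortCounts:
    """Histories aggregated to sufficient statistics per weekly release cohort.

    ``counts[(population, year, week)]`` maps each distinct
    ``(y, recovery, transport_site)`` pattern to its multiplicity.  Fish with
    identical patterns are exchangeable in the likelihood, so aggregation
    loses nothing.  Adult-return tallies (used for SAR only) are kept
    alongside, as they play no role in the juvenile likelihood.
    """

    design: StudyDesign
    counts: dict[tuple[str, int, int], Counter] = field(default_factory=dict)
    adults: dict[tuple[str, int, int], int] = field(default_factory=dict)

    def add(self, h: FishHistory, n: int = 1) -> None:
        key = (h.population, h.year, h.cohort_week)
        self.counts.setdefault(key, Counter())[history_key(h)] += n
        self.adults[key] = self.adults.get(key, 0) + (n if h.adult_return else 0)

    @property
    def n_fish(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def cohorts(self):
        return sorted(self.counts)

    def subset(self, population: str, year: int) -> "CohortCounts":
        out = CohortCounts(self.design)
        for key, ctr in self.counts.items():
            if key[0] == population and key[1] == year:
                out.counts[key] = Counter(ctr)
                out.adults[key] = self.adults.get(key, 0)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Expand to the canonical one-row-per-pattern table (with 'count')."""
        J = self.design.n_reaches
        rows = []
        for (pop, year, week), ctr in sorted(self.counts.items()):
            for (y, rec, tr), n in sorted(ctr.items()):
                row = {"population": pop, "year": year, "cohort_week": week,
                       "transport_site": tr if tr is not None else "",
                       "recovery": ("" if rec == self.design.not_recovered_index
                                    else self.design.colony_ids[rec - 1]),
                       "count": n}
                for j in range(1, J):
                    row[f"site_{j}"] = y[j - 1]
                rows.append(row)
        return pd.DataFrame(rows)


def histories_to_frame(histories: Iterable[FishHistory], design: StudyDesign) -> pd.DataFrame:
    J = design.n_reaches
    rows = []
    for h in histories:
        row = {"fish_id": h.fish_id, "population": h.population, "year": h.year,
               "cohort_week": h.cohort_week,
               "transport_site": h.transport_site if h.transport_site is not None else "",
               "recovery": ("" if h.recovery == design.not_recovered_index
                            else design.colony_ids[h.recovery - 1]),
               "adult_return": int(h.adult_return)}
        for j in range(1, J):
            row[f"site_{j}"] = h.y[j - 1]
        rows.append(row)
    return pd.DataFrame(rows, columns=list(BASE_COLUMNS) + [f"site_{j}" for j in range(1, J)])


def write_histories(histories: Iterable[FishHistory], path, design: StudyDesign) -> None:
    histories_to_frame(histories, design).to_csv(path, index=False)


def read_histories(path, design: StudyDesign) -> CohortCounts:
    """Read and validate a one-row-per-fish history CSV, aggregating to cohorts.

    Rows violating history invariants are rejected collectively with their
    (1-based, header-exclusive) row numbers reported.
    """
    df = pd.read_csv(path, dtype={"fish_id": str}, keep_default_na=False)
    J = design.n_reaches
    site_cols = [f"site_{j}" for j in range(1, J)]
    missing = [c for c in list(BASE_COLUMNS) + site_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")

    counts = CohortCounts(design)
    bad: list[tuple[int, str]] = []
    colony_to_index = {c: i + 1 for i, c in enumerate(design.colony_ids)}
    D = design.not_recovered_index
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        row = rec._asdict()
        try:
            recovery_raw = str(row["recovery"]).strip()
            if recovery_raw == "":
                recovery = D
            elif recovery_raw in colony_to_index:
                recovery = colony_to_index[recovery_raw]
            else:
                raise ConsistencyError(f"unknown recovery colony {recovery_raw!r}")
            tr_raw = str(row["transport_site"]).strip()
            transport = None if tr_raw == "" else int(float(tr_raw))
            y = tuple(int(row[c]) for c in site_cols) + (0,)
            h = FishHistory(
                fish_id=str(row["fish_id"]), population=str(row["population"]),
                year=int(row["year"]), cohort_week=int(row["cohort_week"]),
                y=y, recovery=recovery, transport_site=transport,
                adult_return=bool(int(row["adult_return"])))
            h.validate(design)
        except (ValueError, ConsistencyError) as e:
            bad.append((i, str(e)))
            continue
        counts.add(h)
    if bad:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad[:20])
        raise ConsistencyError(f"{len(bad)} invalid rows: {detail}")
    return counts


def write_colonies(colonies: Sequence[ColonyMeta], path) -> None:
    rows = [{"colony_id": c.colony_id, "bird_species": c.bird_species,
             "location_label": c.location_label,
             "active_years": ";".join(str(y) for y in sorted(c.active_years)),
             "scanned_years": ";".join(str(y) for y in sorted(c.scanned_years))}
            for c in colonies]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_colonies(path) -> list[ColonyMeta]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        def _years(s):
            s = str(s).strip()
            return frozenset(int(v) for v in s.split(";") if v)
        out.append(ColonyMeta(colony_id=str(row["colony_id"]),
                              bird_species=str(row["bird_species"]),
                              location_label=str(row.get("location_label", "")),
                              active_years=_years(row.get("active_years", "")),
                              scanned_years=_years(row.get("scanned_years", ""))))
    return out


def table1_summary(histories: CohortCounts) -> pd.DataFrame:
    """Release / live-detection / dead-recovery / adult-return tallies.

    One row per (population, year).  ``Rel`` counts fish; ``Live`` counts live
    detections (a fish detected at two sites contributes 2, so Live may exceed
    Rel); ``Dead`` counts fish recovered on a colony; ``SAR_count`` counts
    fish later detected as returning adults.
    """
    D = histories.design.not_recovered_index
    acc: dict[tuple[str, int], list[int]] = {}
    for (pop, year, _week), ctr in histories.counts.items():
        cell = acc.setdefault((pop, year), [0, 0, 0, 0])
        for (y, recovery, _tr), n in ctr.items():
            cell[0] += n
            cell[1] += n * sum(y)
            if recovery != D:
                cell[2] += n
    for (pop, year, _week), n_ad in histories.adults.items():
        acc.setdefault((pop, year), [0, 0, 0, 0])[3] += n_ad
    rows = [{"population": p, "year": yr, "Rel": a, "Live": b, "Dead": c, "SAR_count": d}
            for (p, yr), (a, b, c, d) in sorted(acc.items())]
    df = pd.DataFrame(rows, columns=["population", "year", "Rel", "Live", "Dead", "SAR_count"])
    return df.set_index(["population", "year"])


def compute_sar(rel: int, adults: int) -> float:
    """Smolt-to-adult return rate: adults detected returning / smolts released."""
    if rel <= 0:
        raise ValueError("SAR undefined for a release count of zero")
    if adults > rel:
        raise ValueError("more adults than released smolts")
    return adults / rel


def load_study_counts() -> pd.DataFrame:
    """Released/live/dead/adult count table for the four Snake River
    populations, 2008-2018 (one row per population-year).

    Columns: population, year, Rel, Live, Dead, SAR_count (SAR_count is NaN
    for years whose adult returns were incomplete).
    """
    text = resources.files("smoltjms.data").joinpath(
        "snake_river_counts_2008_2018.csv").read_text()
    return pd.read_csv(io.StringIO(text))
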