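"""Synthetic capture-recapture-recovery data with known generating truth.

The generator mirrors the generative reading of the likelihood: each fish
walks the reaches in sequence; in each reach it is consumed by one of the
colonies foraging there, dies of another cause, or survives to the next
recapture site, where it is detected imperfectly and (at the first dams) may
be collected for transport and removed from the river.  Consumed fish leave a
recoverable tag on the colony with probability ``gamma`` (deposition x
post-season detection); other deaths are never observed.

Weekly release cohorts share a year-level reach partition but their cumulative
fate simplex and detection probabilities follow a first-order random walk on
transformed scales (additive-log-ratio for the fate simplex, logit for
detection and recovery), so cohorts closer in time are more alike.

Scenario-specific wrinkles emulated from the study system: colony-years that
were active but never scanned for tags (consumption happens, recoveries are
suppressed), and a mid-season drop in a colony's recovery probability
mimicking temporary colony abandonment by estuary cormorants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .design import (ColonyMeta, CohortCounts, FishHistory, StudyDesign,
                     write_colonies, write_histories)
from .likelihood import ParameterState

__all__ = ["ScenarioConfig", "TrueParameters", "draw_true_parameters",
           "simulate_histories", "generate_fixture", "SCENARIOS", "get_scenario"]

#: species-level tag deposition probabilities used as scenario defaults.
#: Synthetic stand-ins chosen to be realistic for the three predator guilds
#: (terns deposit most ingested tags on-colony, gulls the fewest).
DEFAULT_DEPOSITION = {"tern": 0.7, "cormorant": 0.5, "gull": 0.2}


@dataclass
class ScenarioConfig:
    """Generating conditions for one synthetic population-year."""

    name: str
    design: StudyDesign
    colonies: tuple[ColonyMeta, ...]
    population: str = "steelhead"
    year: int = 2015
    weeks: int = 1
    n_fish_per_week: tuple[int, ...] = (5000,)
    #: baseline cumulative fate probabilities, colony order then other-cause
    theta_cum: tuple[float, ...] = ()
    #: per-colony reach partition over the full reach axis (rows sum to 1)
    rho: tuple[tuple[float, ...], ...] = ()
    rho_other: tuple[float, ...] = ()
    #: baseline detection probability per recapture site (length J-1)
    p: tuple[float, ...] = ()
    #: baseline per-colony recovery probability (deposition x detection)
    gamma: tuple[float, ...] = ()
    transport_prob: float = 0.0
    sigma_fate: float = 0.0
    sigma_p: float = 0.0
    sigma_gamma: float = 0.0
    first_calendar_week: int = 18
    #: colony ids active but not scanned in this year: recoveries suppressed
    unscanned: tuple[str, ...] = ()
    #: colony id -> (first_week, last_week, factor): within-season gamma drop
    dispersal: Mapping[str, tuple[int, int, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.sigma_fate < 0 or self.sigma_p < 0 or self.sigma_gamma < 0:
            raise ValueError("random-walk scales must be non-negative")
        if len(self.n_fish_per_week) != self.weeks:
            if len(self.n_fish_per_week) == 1:
                self.n_fish_per_week = self.n_fish_per_week * self.weeks
            else:
                raise ValueError("n_fish_per_week must match the number of weeks")


@dataclass
class TrueParameters:
    """Known generating truth: one :class:`ParameterState` per weekly cohort."""

    design: StudyDesign
    scenario: ScenarioConfig
    theta_cum: np.ndarray        # (W, C+1)
    rho: np.ndarray              # (C, J), year-level
    rho_other: np.ndarray        # (J,)
    p: np.ndarray                # (W, J), terminal entry 0
    gamma: np.ndarray            # (W, C), effective (0 where unscanned)
    transport_prob: float = 0.0

    @property
    def weeks(self) -> int:
        return self.theta_cum.shape[0]

    def state(self, week: int) -> ParameterState:
        return ParameterState.from_partition(
            self.theta_cum[week], self.rho, self.rho_other,
            self.p[week], self.gamma[week], design=self.design)

    def states(self) -> dict[int, ParameterState]:
        return {w: self.state(w) for w in range(self.weeks)}

    def cumulative_consumption(self, week: int = 0,
                               colonies: Optional[Sequence[str]] = None) -> float:
        """Generating all-colonies (or subset) cumulative consumption."""
        idx = (range(self.design.n_colonies) if colonies is None
               else [self.design.colony_index(c) for c in colonies])
        return float(self.theta_cum[week, list(idx)].sum())

    def to_dict(self) -> dict:
        return {
            "population": self.scenario.population,
            "year": self.scenario.year,
            "weeks": self.weeks,
            "transport_prob": self.transport_prob,
            "theta_cum": self.theta_cum.tolist(),
            "rho": self.rho.tolist(),
            "rho_other": self.rho_other.tolist(),
            "p": self.p.tolist(),
            "gamma": self.gamma.tolist(),
            "colony_ids": list(self.design.colony_ids),
        }


def _alr(q: np.ndarray) -> np.ndarray:
    """Additive log-ratio transform with the last entry as reference.
    Zero components map to a large negative coordinate rather than -inf so
    degenerate baselines stay usable."""
    q = np.clip(q, 1e-290, None)
    return np.log(q[:-1]) - np.log(q[-1])


def _alr_inv(z: np.ndarray) -> np.ndarray:
    e = np.exp(np.concatenate([z, [0.0]]))
    return e / e.sum()


def _logit(x):
    return np.log(x) - np.log1p(-x)


def _expit(z):
    return 1.0 / (1.0 + np.exp(-z))


def draw_true_parameters(design: StudyDesign, scenario: ScenarioConfig,
                         seed: int) -> TrueParameters:
    """Realise weekly generating parameters under the scenario's random walk.

    Baselines come from the scenario; weeks > 1 follow first-order random
    walks with step SD ``sigma_*`` on the transformed scales.  ``sigma = 0``
    collapses to identical weeks.  The same seed always yields the same truth.
    """
    rng = np.random.default_rng(seed)
    J, C, W = design.n_reaches, design.n_colonies, scenario.weeks
    q0 = np.asarray(scenario.theta_cum, dtype=float)
    if q0.size != C + 1:
        raise ValueError("theta_cum must list every colony plus other-cause death")
    surv0 = 1.0 - q0.sum()
    if surv0 <= 0:
        raise ValueError("baseline fate mass leaves no survival")
    simplex0 = np.concatenate([q0, [surv0]])

    z_fate = _alr(simplex0)
    p0 = np.asarray(scenario.p, dtype=float)
    if p0.size != J - 1:
        raise ValueError("p must give one detection probability per recapture site")
    z_p = _logit(np.clip(p0, 1e-12, 1 - 1e-12))
    g0 = np.asarray(scenario.gamma, dtype=float)
    if g0.size != C:
        raise ValueError("gamma must give one recovery probability per colony")
    z_g = _logit(np.clip(g0, 1e-12, 1 - 1e-12))

    theta_cum = np.empty((W, C + 1))
    p = np.zeros((W, J))
    gamma = np.empty((W, C))
    for w in range(W):
        if w > 0:
            z_fate = z_fate + rng.normal(0.0, scenario.sigma_fate, size=z_fate.shape)
            z_p = z_p + rng.normal(0.0, scenario.sigma_p, size=z_p.shape)
            z_g = z_g + rng.normal(0.0, scenario.sigma_gamma, size=z_g.shape)
        simplex = _alr_inv(z_fate)
        theta_cum[w] = simplex[:-1]
        p[w, :J - 1] = _expit(z_p)
        gamma[w] = _expit(z_g)

    # year-level reach partitions
    if scenario.rho:
        rho = np.asarray(scenario.rho, dtype=float)
    else:
        rho = np.zeros((C, J))
        for d, cid in enumerate(design.colony_ids):
            reaches = design.forage_map[cid]
            w_ = rng.dirichlet(np.ones(len(reaches)))
            for r, v in zip(reaches, w_):
                rho[d, r - 1] = v
    rho_other = (np.asarray(scenario.rho_other, dtype=float) if scenario.rho_other
                 else np.full(J, 1.0 / J))

    # observational wrinkles: unscanned colony-years and mid-season dispersal
    scanned = {c.colony_id: scenario.year in c.scanned_years for c in scenario.colonies}
    for d, cid in enumerate(design.colony_ids):
        if cid in scenario.unscanned or not scanned.get(cid, True):
            gamma[:, d] = 0.0
        if cid in scenario.dispersal:
            w0, w1, factor = scenario.dispersal[cid]
            for w in range(W):
                if w0 <= w <= w1:
                    gamma[w, d] *= factor

    return TrueParameters(design=design, scenario=scenario,
                          theta_cum=theta_cum, rho=rho, rho_other=rho_other,
                          p=p, gamma=gamma, transport_prob=scenario.transport_prob)


def simulate_histories(params: TrueParameters,
                       n_fish_per_week: Optional[Sequence[int]] = None,
                       seed: int = 0,
                       return_fish: bool = False):
    """Simulate every fish's life path and aggregate to cohort counts.

    Each fish draws a fate in each reach from the reach's conditional fate
    simplex; survivors are detected at the next site with probability ``p``,
    detected fish at a transport site are removed with ``transport_prob``
    (truncating the history), and consumed fish are recovered on the colony
    with probability ``gamma``.
    """
    rng = np.random.default_rng(seed)
    design = params.design
    scenario = params.scenario
    J, C = design.n_reaches, design.n_colonies
    D = C + 1
    if n_fish_per_week is None:
        n_fish_per_week = scenario.n_fish_per_week
    counts = CohortCounts(design)
    fish: list[FishHistory] = []
    transport_sites = set(design.transport_sites)
    fid = 0
    for w in range(params.weeks):
        state = params.state(w)
        n = int(n_fish_per_week[w])
        y = np.zeros((n, J), dtype=int)
        alive = np.ones(n, dtype=bool)
        recovery = np.full(n, design.not_recovered_index, dtype=int)
        transport = np.full(n, -1, dtype=int)
        for j in range(J):
            idx = np.nonzero(alive)[0]
            if idx.size == 0:
                break
            # conditional fate draw: colonies, other death, survive
            probs = np.concatenate([state.phi[j], [state.survive[j]]])
            fate = rng.choice(D + 1, size=idx.size, p=probs)
            for d in range(C):
                eaten = idx[fate == d]
                if eaten.size:
                    alive[eaten] = False
                    rec = eaten[rng.random(eaten.size) < params.gamma[w, d]]
                    recovery[rec] = d + 1
            other = idx[fate == C]
            alive[other] = False
            survivors = idx[fate == D]
            if j < J - 1 and survivors.size:
                det = survivors[rng.random(survivors.size) < state.p[j]]
                y[det, j] = 1
                if (j + 1) in transport_sites and params.transport_prob > 0:
                    removed = det[rng.random(det.size) < params.transport_prob]
                    transport[removed] = j + 1
                    alive[removed] = False
        for i in range(n):
            tr = int(transport[i]) if transport[i] > 0 else None
            h = FishHistory(fish_id=f"F{fid:07d}", population=scenario.population,
                            year=scenario.year, cohort_week=w,
                            y=tuple(int(v) for v in y[i]),
                            recovery=int(recovery[i]) if tr is None else design.not_recovered_index,
                            transport_site=tr)
            counts.add(h)
            if return_fish:
                fish.append(h)
            fid += 1
    return (counts, fish) if return_fish else counts


# ---------------------------------------------------------------------------
# named scenarios


def _years(a, b):
    return frozenset(range(a, b + 1))


def _small_2reach() -> ScenarioConfig:
    design = StudyDesign(n_reaches=2, colony_ids=("CSI_tern",),
                         forage_map={"CSI_tern": (1, 2)})
    colonies = (ColonyMeta("CSI_tern", "tern", "Crescent Island",
                           _years(2008, 2018), _years(2008, 2018)),)
    return ScenarioConfig(
        name="small_2reach", design=design, colonies=colonies,
        weeks=1, n_fish_per_week=(5000,),
        theta_cum=(0.2, 0.15), rho=((0.6, 0.4),), rho_other=(0.5, 0.5),
        p=(0.5,), gamma=(0.5,))


def _small_3reach_transport() -> ScenarioConfig:
    design = StudyDesign(n_reaches=3, colony_ids=("FDI_cormorant",),
                         forage_map={"FDI_cormorant": (2, 3)},
                         transport_sites=(1,))
    colonies = (ColonyMeta("FDI_cormorant", "cormorant", "Foundation Island",
                           _years(2008, 2018), _years(2008, 2018)),)
    return ScenarioConfig(
        name="small_3reach_transport", design=design, colonies=colonies,
        weeks=3, n_fish_per_week=(2000,),
        theta_cum=(0.15, 0.2), rho=((0.0, 0.7, 0.3),), rho_other=(0.4, 0.3, 0.3),
        p=(0.4, 0.3), gamma=(0.4,), transport_prob=0.2,
        sigma_fate=0.2, sigma_p=0.2)


def _unscanned_colony() -> ScenarioConfig:
    design = StudyDesign(n_reaches=3, colony_ids=("CSI_tern", "I20_gull"),
                         forage_map={"CSI_tern": (1, 2), "I20_gull": (2, 3)})
    colonies = (
        ColonyMeta("CSI_tern", "tern", "Crescent Island",
                   _years(2008, 2018), _years(2008, 2018)),
        # active through the study but never scanned in the scenario year
        ColonyMeta("I20_gull", "gull", "Island 20",
                   _years(2008, 2018), _years(2013, 2018)),
    )
    return ScenarioConfig(
        name="unscanned_colony", design=design, colonies=colonies,
        year=2010, weeks=2, n_fish_per_week=(3000,),
        theta_cum=(0.12, 0.1, 0.15), rho=((0.5, 0.5, 0.0), (0.0, 0.4, 0.6)),
        rho_other=(0.4, 0.3, 0.3), p=(0.5, 0.4), gamma=(0.45, 0.12),
        sigma_fate=0.1, sigma_p=0.1)


def _cormorant_dispersal() -> ScenarioConfig:
    design = StudyDesign(n_reaches=3, colony_ids=("ESI_cormorant",),
                         forage_map={"ESI_cormorant": (2, 3)})
    colonies = (ColonyMeta("ESI_cormorant", "cormorant", "East Sand Island",
                           _years(2008, 2018), _years(2008, 2018)),)
    return ScenarioConfig(
        name="cormorant_dispersal", design=design, colonies=colonies,
        year=2016, weeks=8, n_fish_per_week=(1500,),
        theta_cum=(0.18, 0.15), rho=((0.0, 0.5, 0.5),), rho_other=(0.4, 0.3, 0.3),
        p=(0.4, 0.35), gamma=(0.4,),
        sigma_fate=0.15, sigma_p=0.15,
        # colony abandoned mid-season: recoveries thinned during weeks 2..5
        dispersal={"ESI_cormorant": (2, 5, 0.3)})


def _paper_like() -> ScenarioConfig:
    """Full-size system: 9 reaches, 8 sites, 14 colonies, 3 transport dams."""
    spec = [
        # colony_id, species, location, forage reaches
        ("BLI_tern", "tern", "Banks Lake Island", (3, 4)),
        ("PTI_tern", "tern", "Potholes Reservoir", (3, 4)),
        ("LLI_tern", "tern", "Lenore Lake Island", (3, 4)),
        ("CSI_tern", "tern", "Crescent Island", (3, 4)),
        ("CBI_tern", "tern", "Central Blalock Islands", (5, 6)),
        ("ESI_tern", "tern", "East Sand Island", (8, 9)),
        ("FDI_cormorant", "cormorant", "Foundation Island", (3, 4)),
        ("ESI_cormorant", "cormorant", "East Sand Island", (8, 9)),
        ("I20_gull", "gull", "Island 20", (3, 4)),
        ("BGI_gull", "gull", "Badger Island", (3, 4)),
        ("CSI_gull", "gull", "Crescent Island", (3, 4)),
        ("CBI_gull", "gull", "Central Blalock Islands", (5, 6)),
        ("MRI_gull", "gull", "Miller Rocks Island", (6, 7)),
        ("PTI_gull", "gull", "Potholes Reservoir", (3, 4)),
    ]
    design = StudyDesign(
        n_reaches=9,
        colony_ids=tuple(s[0] for s in spec),
        forage_map={s[0]: s[3] for s in spec},
        transport_sites=(1, 2, 3),
        site_labels=("LGO", "LMN", "IHR", "MCN", "JDA", "TDA", "BON", "NET"),
    )
    colonies = tuple(ColonyMeta(s[0], s[1], s[2], _years(2008, 2018),
                                _years(2008, 2018)) for s in spec)
    # steelhead-like magnitudes: heavy tern/cormorant consumption, detection
    # probabilities at juvenile bypasses modest, total consumption ~ 0.3
    theta = {"BLI_tern": 0.005, "PTI_tern": 0.005, "LLI_tern": 0.005,
             "CSI_tern": 0.05, "CBI_tern": 0.03, "ESI_tern": 0.12,
             "FDI_cormorant": 0.035, "ESI_cormorant": 0.06,
             "I20_gull": 0.01, "BGI_gull": 0.01, "CSI_gull": 0.04,
             "CBI_gull": 0.02, "MRI_gull": 0.04, "PTI_gull": 0.005}
    dep = DEFAULT_DEPOSITION
    gamma = tuple(dep[s[1]] * 0.8 for s in spec)  # on-colony detection ~0.8
    return ScenarioConfig(
        name="paper_like_9reach_14colony", design=design, colonies=colonies,
        weeks=10, n_fish_per_week=(2000,),
        theta_cum=tuple(theta[s[0]] for s in spec) + (0.25,),
        rho_other=(0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1),
        p=(0.3, 0.3, 0.25, 0.25, 0.2, 0.2, 0.25, 0.15),
        gamma=gamma, transport_prob=0.05,
        sigma_fate=0.15, sigma_p=0.2)


SCENARIOS = {
    "small_2reach": _small_2reach,
    "small_3reach_transport": _small_3reach_transport,
    "unscanned_colony": _unscanned_colony,
    "cormorant_dispersal": _cormorant_dispersal,
    "paper_like_9reach_14colony": _paper_like,
}


def get_scenario(name: str) -> ScenarioConfig:
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    return SCENARIOS[name]()


def generate_fixture(scenario_name: str, seed: int, out_dir) -> dict[str, Path]:
    """Write a complete runnable dataset plus its generating truth.

    Emits ``histories.csv`` (one row per fish), ``colonies.csv``,
    ``design.yaml`` and ``truth.yaml`` under ``out_dir``.
    """
    scenario = get_scenario(scenario_name)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = draw_true_parameters(scenario.design, scenario, seed)
    _, fish = simulate_histories(truth, seed=seed + 1, return_fish=True)
    paths = {
        "histories": out / "histories.csv",
        "colonies": out / "colonies.csv",
        "design": out / "design.yaml",
        "truth": out / "truth.yaml",
    }
    write_histories(fish, paths["histories"], scenario.design)
    write_colonies(scenario.colonies, paths["colonies"])
    scenario.design.to_yaml(paths["design"])
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth.to_dict(), fh, sort_keys=False)
    return paths
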