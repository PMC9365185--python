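"""Derived posterior quantities: consumption, total mortality, avian share.

Everything here is computed draw-wise and only then summarised as posterior
median + 95% highest-density interval — the only order of operations that
yields valid intervals for ratios such as the avian share of mortality.

Quantities are "proportions of available fish": conditional on a fish being
alive entering the first reach of the requested span.  Annual values combine
weekly-cohort draws by availability weighting (release size x survival to the
span) within each draw.  Total mortality is only estimable over spans that
end at a live-detection boundary; the terminal reach (downstream of the last
recapture site) has no survival estimate, so spans ending there yield an
explicit not-estimable result rather than a number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diagnostics import hdi
from .model import JMSResults

NO_ESTIMATE = "no estimate"


class NotEstimableError(ValueError):
    pass


@dataclass
class PosteriorQuantity:
    """A scalar derived quantity with its posterior draws and summary."""

    name: str
    draws: np.ndarray
    median: float = field(init=False)
    hdi_low: float = field(init=False)
    hdi_high: float = field(init=False)
    flag: str = ""

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float).ravel()
        self.median = float(np.median(self.draws))
        self.hdi_low, self.hdi_high = hdi(self.draws, 0.95)

    def __repr__(self):
        s = f"{self.name}: {self.median:.3f} (95% HDI {self.hdi_low:.3f}-{self.hdi_high:.3f})"
        return s + (f" [{self.flag}]" if self.flag else "")


def _span(results: JMSResults, reach_span) -> tuple[int, int]:
    J = results.model.design.n_reaches
    lo, hi = (1, J) if reach_span is None else reach_span
    if not (1 <= lo <= hi <= J):
        raise ValueError(f"reach span must lie within 1..{J}")
    return lo, hi


def _weights_and_survival(results: JMSResults):
    """Per-draw from-release survival entering each reach, plus release sizes."""
    Theta = results.flat("Theta")              # (N, W, J, D)
    mass = Theta.sum(axis=3)                   # (N, W, J)
    S_after = 1.0 - np.cumsum(mass, axis=2)
    S_enter = np.concatenate([np.ones(S_after.shape[:2] + (1,)),
                              S_after[:, :, :-1]], axis=2)
    n_week = np.asarray([wd.n_fish for wd in results.model._week_data], dtype=float)
    return Theta, S_enter, S_after, n_week


def _weekly_to_annual(values, avail):
    """Availability-weighted combination of weekly conditional values, per draw."""
    w = np.maximum(avail, 1e-300)
    return (values * w).sum(axis=1) / w.sum(axis=1)


def consumption_draws(results: JMSResults,
                      colony_subset: Optional[Sequence[str]] = None,
                      reach_span=None) -> np.ndarray:
    """Per-draw consumption by the colony subset within the span, as a
    proportion of fish available at the span's head."""
    d = results.model.design
    lo, hi = _span(results, reach_span)
    idx = (list(range(d.n_colonies)) if colony_subset is None
           else [d.colony_index(c) for c in colony_subset])
    Theta, S_enter, _, n_week = _weights_and_survival(results)
    mass = Theta[:, :, lo - 1:hi, :][..., idx].sum(axis=(2, 3))   # (N, W)
    enter = S_enter[:, :, lo - 1]
    weekly = mass / np.maximum(enter, 1e-300)
    return _weekly_to_annual(weekly, n_week * enter)


def cumulative_consumption(results: JMSResults,
                           colony_subset: Optional[Sequence[str]] = None,
                           reach_span=None) -> PosteriorQuantity:
    """Posterior summary of (cumulative) consumption for a colony subset."""
    label = "all colonies" if colony_subset is None else "+".join(colony_subset)
    lo, hi = _span(results, reach_span)
    return PosteriorQuantity(
        name=f"consumption[{label}, reaches {lo}-{hi}]",
        draws=consumption_draws(results, colony_subset, reach_span))


def mortality_draws(results: JMSResults, reach_span=None) -> np.ndarray:
    d = results.model.design
    lo, hi = _span(results, reach_span)
    if hi >= d.n_reaches:
        raise NotEstimableError(
            "total mortality is not estimable over a span ending in the "
            "terminal reach (no live-detection boundary downstream)")
    _, S_enter, S_after, n_week = _weights_and_survival(results)
    enter = S_enter[:, :, lo - 1]
    weekly = 1.0 - S_after[:, :, hi - 1] / np.maximum(enter, 1e-300)
    return _weekly_to_annual(weekly, n_week * enter)


def total_mortality(results: JMSResults, reach_span=None) -> PosteriorQuantity:
    """Posterior summary of total mortality (1 - survival) across a span."""
    lo, hi = _span(results, reach_span)
    return PosteriorQuantity(name=f"total_mortality[reaches {lo}-{hi}]",
                             draws=mortality_draws(results, reach_span))


def avian_fraction(results: JMSResults, reach_span=None,
                   colony_subset: Optional[Sequence[str]] = None,
                   cap: bool = True) -> PosteriorQuantity:
    """Share of all mortality in the span attributable to avian consumption.

    Computed per draw as consumption / (1 - survival), then summarised; the
    reported scale is a proportion in [0, 1], capped at 1.  If an appreciable
    share of draws has near-zero mortality the ratio is numerically unstable
    and the result is flagged.
    """
    cons = consumption_draws(results, colony_subset, reach_span)
    mort = mortality_draws(results, reach_span)
    unstable = float(np.mean(mort < 1e-6))
    ratio = cons / np.maximum(mort, 1e-6)
    if cap:
        ratio = np.minimum(ratio, 1.0)
    lo, hi = _span(results, reach_span)
    return PosteriorQuantity(
        name=f"avian_fraction[reaches {lo}-{hi}]", draws=ratio,
        flag="unstable: mortality near zero in some draws" if unstable > 0.01 else "")


@dataclass
class DerivedEstimates:
    """Long-format table of derived estimates for one or more fits."""

    table: pd.DataFrame

    COLUMNS = ("population", "year", "kind", "group", "span_start", "span_end",
               "median", "hdi_low", "hdi_high", "note")

    @classmethod
    def empty(cls) -> "DerivedEstimates":
        return cls(pd.DataFrame(columns=list(cls.COLUMNS)))


def derive_estimates(results: JMSResults,
                     spans: Optional[Sequence[tuple[int, int]]] = None
                     ) -> DerivedEstimates:
    """Standard report: per-colony, per-species-group and combined cumulative
    consumption, plus consumption / total mortality / avian share per span.

    Colony-years that were active but unscanned get a "no estimate" row
    (their consumption is not identified), and they are excluded from group
    and combined totals, making those minimum estimates.
    """
    m = results.model
    d = m.design
    J = d.n_reaches
    spans = list(spans) if spans else ([(1, J)] if J == 1 else [(1, J), (1, J - 1)])
    scanned = set(m.scanned_indices)
    species = {c.colony_id: c.bird_species for c in m.colonies}
    rows = []

    def add(kind, group, lo, hi, pq: Optional[PosteriorQuantity], note=""):
        rows.append({
            "population": m.population, "year": m.year, "kind": kind,
            "group": group, "span_start": lo, "span_end": hi,
            "median": pq.median if pq else np.nan,
            "hdi_low": pq.hdi_low if pq else np.nan,
            "hdi_high": pq.hdi_high if pq else np.nan,
            "note": note or (pq.flag if pq else "")})

    for k, cid in enumerate(d.colony_ids):
        if k not in scanned:
            add("consumption", cid, 1, J, None, NO_ESTIMATE)
        else:
            add("consumption", cid, 1, J, cumulative_consumption(results, [cid]))
    groups: dict[str, list[str]] = {}
    for k in sorted(scanned):
        cid = d.colony_ids[k]
        groups.setdefault(species.get(cid, "unknown"), []).append(cid)
    for sp in sorted(groups):
        add("consumption", f"{sp}s combined", 1, J,
            cumulative_consumption(results, groups[sp]))
    scanned_ids = [d.colony_ids[k] for k in sorted(scanned)]
    add("consumption", "all colonies", 1, J,
        cumulative_consumption(results, scanned_ids))

    for lo, hi in spans:
        if (lo, hi) != (1, J):  # full-span combined row already added
            add("consumption", "all colonies", lo, hi,
                cumulative_consumption(results, scanned_ids, (lo, hi)))
        try:
            add("total_mortality", "", lo, hi, total_mortality(results, (lo, hi)))
            add("avian_fraction", "all colonies", lo, hi,
                avian_fraction(results, (lo, hi), scanned_ids))
        except NotEstimableError:
            add("total_mortality", "", lo, hi, None, NO_ESTIMATE)
            add("avian_fraction", "all colonies", lo, hi, None, NO_ESTIMATE)

    df = pd.DataFrame(rows, columns=list(DerivedEstimates.COLUMNS))
    df = df.sort_values(["population", "year", "kind", "span_start",
                         "span_end", "group"], kind="stable").reset_index(drop=True)
    return DerivedEstimates(df)


def report_tables(estimates: DerivedEstimates, out_dir) -> dict[str, Path]:
    """Write one CSV per derived kind (deterministic row order)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind in ("consumption", "total_mortality", "avian_fraction"):
        sub = estimates.table[estimates.table["kind"] == kind] \
            if len(estimates.table) else estimates.table
        path = out / f"{kind}.csv"
        cols = list(DerivedEstimates.COLUMNS)
        (sub[cols] if len(sub) else
         pd.DataFrame(columns=cols)).to_csv(path, index=False)
        paths[kind] = path
    return paths


def read_report_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    for c in ("median", "hdi_low", "hdi_high"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df
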