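"""Joint mortality-and-survival likelihood for capture-recapture-recovery data.

One weekly release cohort is governed by:

* ``Theta`` — a ``J x D`` matrix of *from-release* joint probabilities:
  ``Theta[j, d]`` is the probability a fish survives to the head of reach
  ``j+1`` is wrong — precisely, survives through reaches ``1..j`` and then dies
  in reach ``j+1`` of fate ``d`` (0-based), where fates ``0..C-1`` are the bird
  colonies and fate ``C`` is death from any other, unrecoverable cause.
  ``1 - Theta.sum()`` is survival through all ``J`` reaches.
* ``p`` — detection probability at the recapture site ending each reach
  (``p[J-1] = 0``: no site ends the terminal reach).
* ``gamma`` — per-colony recovery probability (deposition x detection) of a
  consumed tag; the other-cause fate is never recoverable.

The colony columns of ``Theta`` factor as ``theta_cum[d] * rho[d]`` where
``rho[d]`` is the colony's partition of its cumulative consumption across the
reaches it forages ("informed partitioning" shares ``rho`` across years via a
Dirichlet hyper-distribution; that lives in the prior, not here).

The recapture/recovery probabilities are computed with the recursive ``chi``
functions: ``chi[j, d]`` is the probability that a fish alive entering reach
``j+1`` (0-based row ``j``) is never recaptured again and ends in recovery
fate ``d``.  The recursion is expressed in per-reach *conditional* fate
probabilities (``conditional_fates``), under which every ``chi`` row is a
proper conditional distribution once the probability of a later recapture is
added back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .design import CohortCounts, FishHistory, HistoryKey, StudyDesign

NEG_INF = float("-inf")


class ModelStructureError(ValueError):
    """Parameters inconsistent with the study design (e.g. consumption mass
    outside a colony's foraged reaches)."""


def build_theta(theta_cum: np.ndarray,
                rho: np.ndarray,
                rho_other: np.ndarray,
                design: Optional[StudyDesign] = None,
                *, atol: float = 1e-9) -> np.ndarray:
    """Assemble the J x D from-release fate matrix from cumulative fate
    probabilities and reach-partition simplexes.

    Parameters
    ----------
    theta_cum : (C+1,) array
        Cumulative probability of each fate (C colonies + other-cause death).
        Must sum to <= 1; the remainder is survival through all reaches.
    rho : (C, J) array
        Row ``d`` is colony ``d``'s partition of its consumption across
        reaches (sums to 1, supported on the colony's forage set).
    rho_other : (J,) array
        Partition of other-cause mortality across reaches.
    """
    theta_cum = np.asarray(theta_cum, dtype=float)
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    rho_other = np.asarray(rho_other, dtype=float)
    C = theta_cum.size - 1
    J = rho_other.size
    if rho.shape != (C, J):
        raise ValueError(f"rho must be ({C}, {J}), got {rho.shape}")
    if np.any(theta_cum < -atol) or theta_cum.sum() > 1 + atol:
        raise ValueError("cumulative fate probabilities must be >= 0 and sum to <= 1")
    for d in range(C):
        if abs(rho[d].sum() - 1) > 1e-6:
            raise ValueError(f"rho for colony {d} does not sum to 1")
    if abs(rho_other.sum() - 1) > 1e-6:
        raise ValueError("rho_other does not sum to 1")
    if design is not None:
        if design.n_colonies != C or design.n_reaches != J:
            raise ValueError("design dimensions do not match parameters")
        for d, cid in enumerate(design.colony_ids):
            allowed = np.zeros(J, dtype=bool)
            for r in design.forage_map[cid]:
                allowed[r - 1] = True
            if np.any(rho[d][~allowed] > atol):
                raise ModelStructureError(
                    f"colony {cid}: partition mass outside foraged reaches")
    Theta = np.empty((J, C + 1))
    Theta[:, :C] = rho.T * theta_cum[:C]
    Theta[:, C] = rho_other * theta_cum[C]
    return Theta


def conditional_fates(Theta: np.ndarray, *, atol: float = 1e-12):
    """Re-express from-release fates as per-reach conditional probabilities.

    Returns ``(phi, survive)`` where ``phi[j, d] = Theta[j, d] / S_{j-1}`` is
    the probability a fish alive entering reach ``j+1`` dies there of fate
    ``d``, ``survive[j]`` the probability it survives the reach, and
    ``S_{j-1} = 1 - sum(Theta[:j])`` is from-release survival to the reach.
    """
    Theta = np.asarray(Theta, dtype=float)
    J = Theta.shape[0]
    phi = np.zeros_like(Theta)
    survive = np.zeros(J)
    S_prev = 1.0
    for j in range(J):
        row_mass = Theta[j].sum()
        if S_prev <= atol:
            if row_mass > atol or np.any(Theta[j + 1:] > atol):
                raise ModelStructureError(
                    f"no survival into reach {j + 1} but downstream fate mass present")
            survive[j:] = 0.0
            break
        phi[j] = Theta[j] / S_prev
        survive[j] = 1.0 - phi[j].sum()
        S_prev -= row_mass
    return phi, survive


def cumulative_from_conditional(phi: np.ndarray) -> np.ndarray:
    """Inverse of :func:`conditional_fates`: rebuild the from-release matrix."""
    phi = np.asarray(phi, dtype=float)
    Theta = np.empty_like(phi)
    S = 1.0
    for j in range(phi.shape[0]):
        Theta[j] = S * phi[j]
        S *= 1.0 - phi[j].sum()
    return Theta


@dataclass
class ParameterState:
    """All parameters of one weekly cohort, with derived quantities cached.

    ``Theta`` is the J x (C+1) from-release fate matrix; ``p`` the length-J
    detection vector (terminal entry 0); ``gamma`` the length-C per-colony
    recovery probability (the other-cause fate is structurally unrecoverable).
    ``alpha`` and ``sigma`` are carried as metadata when the state comes from
    a hierarchical fit.
    """

    Theta: np.ndarray
    p: np.ndarray
    gamma: np.ndarray
    design: Optional[StudyDesign] = None
    alpha: Optional[np.ndarray] = None
    sigma: Optional[Mapping[str, float]] = None
    _phi: np.ndarray = field(init=False, repr=False, default=None)
    _survive: np.ndarray = field(init=False, repr=False, default=None)
    _chi: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.Theta = np.asarray(self.Theta, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        J, D = self.Theta.shape
        if self.p.shape != (J,):
            raise ValueError(f"p must have length {J}")
        if self.gamma.shape == (D,):
            # accept a D-length recovery vector whose last entry is the
            # (structurally zero) other-cause fate
            if self.gamma[-1] != 0:
                raise ValueError("recovery probability of the other-cause fate must be 0")
            self.gamma = self.gamma[:-1]
        if self.gamma.shape != (D - 1,):
            raise ValueError(f"gamma must have length {D - 1}")
        if abs(self.p[-1]) > 0:
            raise ValueError("no recapture opportunity ends the terminal reach: p[-1] must be 0")
        for name, arr in (("Theta", self.Theta), ("p", self.p), ("gamma", self.gamma)):
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if self.Theta.sum() > 1 + 1e-9:
            raise ValueError("total fate mass exceeds 1")
        self._phi, self._survive = conditional_fates(self.Theta)

    @property
    def n_reaches(self) -> int:
        return self.Theta.shape[0]

    @property
    def n_colonies(self) -> int:
        return self.Theta.shape[1] - 1

    @property
    def theta_cum(self) -> np.ndarray:
        """Cumulative per-fate probabilities (column sums of Theta)."""
        return self.Theta.sum(axis=0)

    @property
    def phi(self) -> np.ndarray:
        return self._phi

    @property
    def survive(self) -> np.ndarray:
        return self._survive

    @property
    def survival_to_reach(self) -> np.ndarray:
        """From-release survival to the head of each reach, length J+1
        (entry 0 is 1; entry J is survival through everything)."""
        return np.concatenate([[1.0], np.cumprod(self._survive)])

    @property
    def chi(self) -> np.ndarray:
        if self._chi is None:
            self._chi = chi_recursion(self)
        return self._chi

    @classmethod
    def from_partition(cls, theta_cum, rho, rho_other, p, gamma,
                       design: Optional[StudyDesign] = None, **kw) -> "ParameterState":
        Theta = build_theta(theta_cum, rho, rho_other, design)
        return cls(Theta=Theta, p=p, gamma=gamma, design=design, **kw)

    @classmethod
    def from_conditional(cls, phi, p, gamma,
                         design: Optional[StudyDesign] = None, **kw) -> "ParameterState":
        return cls(Theta=cumulative_from_conditional(phi), p=p, gamma=gamma,
                   design=design, **kw)


def chi_recursion(state: ParameterState) -> np.ndarray:
    """Probability of 'never recaptured again, recovery fate d'.

    Returns a ``(J+1) x D`` matrix whose row ``j`` (0-based) conditions on the
    fish being alive at the head of reach ``j+1``; ``D - 1`` is the
    never-recovered fate.  Termination: a fish alive past the last reach is
    never reseen and never recovered (``chi[J] = [0, .., 0, 1]``).
    """
    phi, survive, p, gamma = state.phi, state.survive, state.p, state.gamma
    J, D = phi.shape
    chi = np.zeros((J + 1, D))
    chi[J, D - 1] = 1.0
    for j in range(J - 1, -1, -1):
        pass_on = survive[j] * (1.0 - p[j])
        chi[j, :D - 1] = phi[j, :D - 1] * gamma + pass_on * chi[j + 1, :D - 1]
        chi[j, D - 1] = (phi[j, :D - 1] * (1.0 - gamma)).sum() + phi[j, D - 1] \
            + pass_on * chi[j + 1, D - 1]
        if not np.all(np.isfinite(chi[j])):
            raise FloatingPointError(f"non-finite recovery probability at reach {j + 1}")
    return chi


def _log(x: float) -> float:
    return math.log(x) if x > 0 else NEG_INF


def history_log_likelihood(history: FishHistory | HistoryKey,
                           state: ParameterState) -> float:
    """Exact log-probability of one (non-transported) recapture/recovery history.

    The detection product runs over sites up to the final detection ``m``
    (with survival through each of those reaches folded in); the tail is the
    recursive probability of the observed recovery fate from reach ``m+1``.
    Structural zeros return ``-inf``.
    """
    y, recovery, transport = _as_key(history)
    if transport is not None:
        raise ValueError("transported fish use truncated_log_likelihood")
    J, D = state.phi.shape
    m = _last_detection(y)
    ll = 0.0
    for j in range(m):  # fish known alive through reach j+1
        ll += _log(state.survive[j])
        ll += _log(state.p[j]) if y[j] else _log(1.0 - state.p[j])
    ll += _log(state.chi[m, recovery - 1])
    return ll


def truncated_log_likelihood(history: FishHistory | HistoryKey,
                             state: ParameterState,
                             *, include_removal_detection: bool = True) -> float:
    """Log-likelihood of a history truncated by transport removal at site m.

    The fish is known to have survived to site ``m`` and, under the default
    convention, to have been detected there (removal requires capture); with
    ``include_removal_detection=False`` the detection factor at the removal
    site is dropped, the alternative reading of the truncated product.
    """
    y, recovery, m = _as_key(history)
    if m is None:
        raise ValueError("history carries no transport site")
    if state.design is not None and m not in state.design.transport_sites:
        raise ModelStructureError(f"site {m} is not a transport site")
    ll = 0.0
    for j in range(m):
        ll += _log(state.survive[j])
        last = j == m - 1
        if last and not include_removal_detection:
            continue
        ll += _log(state.p[j]) if y[j] else _log(1.0 - state.p[j])
    return ll


def total_log_likelihood(counts: CohortCounts,
                         states: Mapping,
                         *, include_removal_detection: bool = True) -> float:
    """Aggregate log-likelihood: sum of multiplicity x per-history terms.

    ``states`` maps either full cohort keys ``(population, year, week)`` or
    bare week indices to a :class:`ParameterState`.
    """
    total = 0.0
    for key, ctr in counts.counts.items():
        state = states.get(key) if hasattr(states, "get") else None
        if state is None:
            state = states[key[2]] if key[2] in states else None
        if state is None:
            raise KeyError(f"no parameter state for cohort {key}")
        for hkey, n in ctr.items():
            _, _, transport = hkey
            if transport is None:
                ll = history_log_likelihood(hkey, state)
            else:
                ll = truncated_log_likelihood(
                    hkey, state, include_removal_detection=include_removal_detection)
            if ll == NEG_INF:
                return NEG_INF
            total += n * ll
    return total


def enumerate_outcome_probabilities(
        state: ParameterState,
        design: Optional[StudyDesign] = None,
        transport_prob: float | Mapping[int, float] = 0.0,
        *, max_reaches: int = 4, max_fates: int = 4,
) -> dict[HistoryKey, float]:
    """Exhaustive forward enumeration of every possible life path.

    Walks the probability tree reach by reach (fate draw, then detection,
    then possible transport removal) and returns the probability of every
    observable ``(y, recovery, transport_site)`` outcome.  Intended as an
    independent oracle on small instances; refuses instances above the
    enumeration bound.
    """
    J, D = state.phi.shape
    if J > max_reaches or D > max_fates:
        raise ValueError(f"enumeration restricted to J <= {max_reaches}, D <= {max_fates}")
    design = design or state.design
    transport_sites = set(design.transport_sites) if design is not None else set()

    def tau(site_1b: int) -> float:
        if site_1b not in transport_sites:
            return 0.0
        if isinstance(transport_prob, Mapping):
            return float(transport_prob.get(site_1b, 0.0))
        return float(transport_prob)

    out: dict[HistoryKey, float] = {}

    def emit(y, recovery, transport, prob):
        if prob <= 0.0:
            return
        key = (tuple(y), recovery, transport)
        out[key] = out.get(key, 0.0) + prob

    def walk(j: int, y: list[int], prob: float):
        # fish alive entering reach j+1 (0-based j)
        if j == J:
            emit(y, D, None, prob)  # survived everything, never recovered
            return
        for d in range(D - 1):  # consumed by colony d
            pd = prob * state.phi[j, d]
            if pd > 0:
                emit(y, d + 1, None, pd * state.gamma[d])
                emit(y, D, None, pd * (1.0 - state.gamma[d]))
        emit(y, D, None, prob * state.phi[j, D - 1])  # other-cause death
        ps = prob * state.survive[j]
        if ps <= 0:
            return
        if j == J - 1:  # terminal reach has no site
            walk(J, y, ps)
            return
        walk(j + 1, y, ps * (1.0 - state.p[j]))  # undetected
        p_det = ps * state.p[j]
        if p_det > 0:
            t = tau(j + 1)
            if t > 0:
                y_tr = y.copy()
                y_tr[j] = 1
                emit(y_tr, D, j + 1, p_det * t)
            y2 = y.copy()
            y2[j] = 1
            walk(j + 1, y2, p_det * (1.0 - t))

    walk(0, [0] * J, 1.0)
    return out


def _as_key(history) -> HistoryKey:
    if isinstance(history, FishHistory):
        return (tuple(history.y), history.recovery, history.transport_site)
    y, recovery, transport = history
    return tuple(y), recovery, transport


def _last_detection(y) -> int:
    m = 0
    for j, v in enumerate(y, start=1):
        if v:
            m = j
    return m
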