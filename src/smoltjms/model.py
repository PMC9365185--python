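"""Model/Results interface for fitting the joint mortality-and-survival model.

:class:`JMSModel` binds one population-year of aggregated
capture-recapture-recovery histories to a study design and a prior
specification; :meth:`JMSModel.fit` draws from the joint posterior and
returns a :class:`JMSResults` carrying posterior draws, medians, 95% highest
density intervals, convergence diagnostics and posterior-predictive checks.

Sampling uses an affine-invariant ensemble MCMC sampler (emcee) on an
unconstrained transformed parameter space; four independent ensembles play
the role of chains for the split-R-hat diagnostic.  The ensemble sampler has
no divergent-transition failure mode, so the divergence count it reports is
zero and fit acceptance rests on R-hat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

import emcee

from .design import CohortCounts, ColonyMeta, StudyDesign, read_histories
from .diagnostics import effective_sample_size, gelman_rubin, hdi
from .likelihood import ParameterState
from .priors import PriorSpec

_LOG_TINY = 1e-300


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# packed data: per-week sufficient statistics in matrix form


@dataclass
class _WeekData:
    week: int
    My: np.ndarray       # (npat, J) detected-site indicator within the product range
    Mn: np.ndarray       # (npat, J) undetected-site indicator within the product range
    m: np.ndarray        # (npat,) number of reaches the fish is known to have survived
    fate: np.ndarray     # (npat,) 0-based recovery fate, -1 for transported
    count: np.ndarray    # (npat,)
    n_fish: int

    @classmethod
    def build(cls, week, counter, design: StudyDesign,
              include_removal_detection: bool) -> "_WeekData":
        J = design.n_reaches
        My, Mn, ms, fates, counts = [], [], [], [], []
        for (y, recovery, transport), n in sorted(counter.items()):
            y = np.asarray(y, dtype=int)
            if transport is None:
                m = int(max([j + 1 for j in range(J) if y[j]], default=0))
                rng_j = range(m)
                fate = recovery - 1
            else:
                m = int(transport)
                last = m - 1
                rng_j = [j for j in range(m)
                         if include_removal_detection or j != last]
                fate = -1
            my = np.zeros(J)
            mn = np.zeros(J)
            for j in rng_j:
                (my if y[j] else mn)[j] = 1.0
            My.append(my)
            Mn.append(mn)
            ms.append(m)
            fates.append(fate)
            counts.append(n)
        return cls(week=week, My=np.array(My), Mn=np.array(Mn),
                   m=np.array(ms, dtype=int), fate=np.array(fates, dtype=int),
                   count=np.array(counts, dtype=float), n_fish=int(sum(counts)))

    def loglik(self, phi, survive, p, gamma) -> float:
        J = survive.shape[0]
        chi = _chi(phi, survive, p, gamma)
        log_s = np.log(np.maximum(survive, _LOG_TINY))
        cum = np.concatenate([[0.0], np.cumsum(log_s)])
        logp = np.log(np.maximum(p, _LOG_TINY))
        log1mp = np.log(np.maximum(1.0 - p, _LOG_TINY))
        ll = cum[self.m] + self.My @ logp + self.Mn @ log1mp
        tail = np.zeros(self.m.size)
        obs = self.fate >= 0
        tail[obs] = np.log(np.maximum(chi[self.m[obs], self.fate[obs]], _LOG_TINY))
        return float(np.dot(self.count, ll + tail))


def _chi(phi, survive, p, gamma):
    J, D = phi.shape
    chi = np.zeros((J + 1, D))
    chi[J, D - 1] = 1.0
    for j in range(J - 1, -1, -1):
        pass_on = survive[j] * (1.0 - p[j])
        chi[j, :D - 1] = phi[j, :D - 1] * gamma + pass_on * chi[j + 1, :D - 1]
        chi[j, D - 1] = (phi[j, :D - 1] * (1.0 - gamma)).sum() + phi[j, D - 1] \
            + pass_on * chi[j + 1, D - 1]
    return chi


def _conditional(Theta):
    """Fast conditional-fates used inside the sampler's inner loop."""
    J = Theta.shape[0]
    phi = np.zeros_like(Theta)
    survive = np.zeros(J)
    S = 1.0
    for j in range(J):
        if S <= 1e-300:
            return None
        phi[j] = Theta[j] / S
        survive[j] = 1.0 - phi[j].sum()
        S -= Theta[j].sum()
    return phi, survive


# ---------------------------------------------------------------------------
# parameter layout


class _Layout:
    """Maps the unconstrained sampler vector to natural parameters and back."""

    def __init__(self, model: "JMSModel"):
        d = model.design
        self.J, self.C = d.n_reaches, d.n_colonies
        self.K = self.C + 2                # fate simplex size incl. survival
        self.S = self.J - 1                # recapture sites
        self.weeks = model.weeks
        self.W = len(self.weeks)
        self.gaps = np.diff(self.weeks) if self.W > 1 else np.array([])
        self.two_reach = [i for i, c in enumerate(d.colony_ids)
                          if len(d.forage_map[c]) == 2]
        self.scanned = model.scanned_indices
        fixed = model.fixed
        self.blocks: list[tuple[str, int]] = []
        if "theta" not in fixed:
            self.blocks.append(("fate", self.W * (self.K - 1)))
        if "p" not in fixed:
            self.blocks.append(("p", self.W * self.S))
        if "rho" not in fixed:
            self.blocks.append(("rho", len(self.two_reach)))
            self.blocks.append(("log_alpha", 2 * len(self.two_reach)))
        if "rho_other" not in fixed and self.J > 1:
            self.blocks.append(("rho_other", self.J - 1))
        if self.W > 1 and ("theta" not in fixed or "p" not in fixed):
            self.blocks.append(("log_sigma", 2))
        if "gamma" not in fixed:
            self.blocks.append(("gamma", 3 * len(self.scanned)))
        self.ndim = sum(n for _, n in self.blocks)
        self.model = model

    def split(self, z: np.ndarray) -> dict[str, np.ndarray]:
        out, i = {}, 0
        for name, n in self.blocks:
            out[name] = z[i:i + n]
            i += n
        return out

    # -- transforms ---------------------------------------------------------

    def natural(self, z: np.ndarray) -> Optional[dict]:
        """Unconstrained vector -> dict of natural parameter arrays."""
        m = self.model
        parts = self.split(z)
        W, J, C, K, S = self.W, self.J, self.C, self.K, self.S
        nat: dict[str, np.ndarray] = {}

        if "fate" in parts:
            zf = parts["fate"].reshape(W, K - 1)
            e = np.exp(np.concatenate([zf, np.zeros((W, 1))], axis=1)
                       - np.max(zf, axis=1, keepdims=True).clip(min=0))
            q = e / e.sum(axis=1, keepdims=True)
            nat["fate_simplex"] = q              # (W, K): fates then survival
            nat["theta_cum"] = q[:, :K - 1]
        else:
            nat["theta_cum"] = m.fixed["theta"]
            nat["fate_simplex"] = np.concatenate(
                [nat["theta_cum"], 1 - nat["theta_cum"].sum(axis=1, keepdims=True)],
                axis=1)

        if "p" in parts:
            pw = expit(parts["p"].reshape(W, S))
            p = np.zeros((W, J))
            p[:, :S] = pw
            nat["p"] = p
        else:
            nat["p"] = m.fixed["p"]

        rho = np.zeros((C, J))
        if "rho" in parts:
            for k, d in enumerate(self.two_reach):
                r1, r2 = m.design.forage_map[m.design.colony_ids[d]]
                v = expit(parts["rho"][k])
                rho[d, r1 - 1] = v
                rho[d, r2 - 1] = 1.0 - v
            for d, cid in enumerate(m.design.colony_ids):
                if d not in self.two_reach:
                    rho[d, m.design.forage_map[cid][0] - 1] = 1.0
            nat["rho"] = rho
            alpha = np.zeros((C, J))
            av = np.exp(parts["log_alpha"]).reshape(len(self.two_reach), 2)
            for k, d in enumerate(self.two_reach):
                r1, r2 = m.design.forage_map[m.design.colony_ids[d]]
                alpha[d, r1 - 1], alpha[d, r2 - 1] = av[k]
            nat["alpha"] = alpha
        else:
            nat["rho"] = m.fixed["rho"]
            nat["alpha"] = np.zeros((C, J))

        if "rho_other" in parts:
            zo = np.concatenate([parts["rho_other"], [0.0]])
            e = np.exp(zo - zo.max())
            nat["rho_other"] = e / e.sum()
        elif "rho_other" in m.fixed:
            nat["rho_other"] = m.fixed["rho_other"]
        else:
            nat["rho_other"] = np.ones(J) / J

        if "log_sigma" in parts:
            nat["sigma"] = np.exp(parts["log_sigma"])
        else:
            nat["sigma"] = np.zeros(2)

        gamma = np.zeros((W, C))
        if "gamma" in parts:
            g = parts["gamma"].reshape(len(self.scanned), 3)
            cal = np.array([m.priors.calendar_week(w) for w in self.weeks], dtype=float)
            for k, d in enumerate(self.scanned):
                dep = expit(g[k, 0])
                det = expit(g[k, 1] + g[k, 2] * (cal - m.priors.week_center))
                gamma[:, d] = dep * det
            nat["gamma_raw"] = g
        else:
            gamma = np.array(m.fixed["gamma"], dtype=float)
        nat["gamma"] = gamma
        return nat

    # -- prior --------------------------------------------------------------

    def log_prior(self, parts: dict, nat: dict) -> float:
        m = self.model
        lp = 0.0
        if "fate" in parts:
            q = nat["fate_simplex"]
            if np.any(q <= 0):
                return -np.inf
            lp += gammaln(self.K) + np.log(q[0]).sum()  # dirichlet(1) + ALR Jacobian
            if self.W > 1:
                zf = parts["fate"].reshape(self.W, self.K - 1)
                sd = nat["sigma"][0]
                if sd <= 0:
                    return -np.inf
                for i, gap in enumerate(self.gaps):
                    step_sd = sd * math.sqrt(gap)
                    diff = zf[i + 1] - zf[i]
                    lp += float(-0.5 * np.sum((diff / step_sd) ** 2)
                                - diff.size * math.log(step_sd * math.sqrt(2 * math.pi)))
        if "p" in parts:
            pw = nat["p"][:, :self.S]
            if np.any(pw <= 0) or np.any(pw >= 1):
                return -np.inf
            lp += float(np.sum(np.log(pw[0]) + np.log1p(-pw[0])))  # uniform + Jacobian
            if self.W > 1:
                zp = parts["p"].reshape(self.W, self.S)
                sd = nat["sigma"][1]
                if sd <= 0:
                    return -np.inf
                for i, gap in enumerate(self.gaps):
                    step_sd = sd * math.sqrt(gap)
                    diff = zp[i + 1] - zp[i]
                    lp += float(-0.5 * np.sum((diff / step_sd) ** 2)
                                - diff.size * math.log(step_sd * math.sqrt(2 * math.pi)))
        if "rho" in parts:
            for k, d in enumerate(self.two_reach):
                cid = m.design.colony_ids[d]
                r1, r2 = m.design.forage_map[cid]
                rho1 = nat["rho"][d, r1 - 1]
                rho2 = nat["rho"][d, r2 - 1]
                if rho1 <= 0.0 or rho2 <= 0.0:
                    return -np.inf
                a1 = nat["alpha"][d, r1 - 1]
                a2 = nat["alpha"][d, r2 - 1]
                if a1 <= 0.0 or a2 <= 0.0:
                    return -np.inf
                # dirichlet(alpha) on (rho1, rho2) + logistic Jacobian
                lp += (gammaln(a1 + a2) - gammaln(a1) - gammaln(a2)
                       + (a1 - 1) * math.log(rho1) + (a2 - 1) * math.log(rho2)
                       + math.log(rho1) + math.log(rho2))
                # Gamma(shape, rate) hyper-prior on alpha + log Jacobian
                sh, rt = m.priors.alpha_shape, m.priors.alpha_rate
                for a in (a1, a2):
                    lp += (sh * math.log(rt) - gammaln(sh)
                           + (sh - 1) * math.log(a) - rt * a + math.log(a))
        if "rho_other" in parts:
            ro = nat["rho_other"]
            if np.any(ro <= 0):
                return -np.inf
            lp += gammaln(self.J) + float(np.log(ro).sum())
        if "log_sigma" in parts:
            scale = m.priors.sigma_scale
            for s, v in zip(nat["sigma"], parts["log_sigma"]):
                # half-normal(0, scale) + log Jacobian of exp
                lp += (-0.5 * (s / scale) ** 2
                       + math.log(2.0 / (scale * math.sqrt(2 * math.pi))) + v)
        if "gamma" in parts:
            g = nat["gamma_raw"]
            for k, d in enumerate(self.scanned):
                cid = m.design.colony_ids[d]
                rp = m.priors.recovery.get(cid)
                if rp is None:
                    return -np.inf
                dep = expit(g[k, 0])
                if dep <= 0 or dep >= 1:
                    return -np.inf
                lp += ((rp.dep_a - 1) * math.log(dep)
                       + (rp.dep_b - 1) * math.log1p(-dep)
                       + gammaln(rp.dep_a + rp.dep_b)
                       - gammaln(rp.dep_a) - gammaln(rp.dep_b)
                       + math.log(dep) + math.log1p(-dep))
                mu = np.asarray(rp.beta_mean)
                cov = np.asarray(rp.beta_cov)
                diff = g[k, 1:] - mu
                prec = np.linalg.inv(cov)
                _, logdet = np.linalg.slogdet(cov)
                lp += float(-0.5 * diff @ prec @ diff
                            - 0.5 * logdet - math.log(2 * math.pi))
        return lp

    # -- prior sampling (for walker initialisation) -------------------------

    def sample_init(self, rng: np.random.Generator) -> np.ndarray:
        m = self.model
        z = []
        sigma_f = min(abs(rng.normal(0, 0.3)) + 0.05, 1.0)
        sigma_p = min(abs(rng.normal(0, 0.3)) + 0.05, 1.0)
        for name, n in self.blocks:
            if name == "fate":
                q = rng.dirichlet(np.ones(self.K))
                z0 = np.log(q[:-1] / q[-1])
                rows = [z0]
                for gap in self.gaps:
                    rows.append(rows[-1] + rng.normal(0, sigma_f * math.sqrt(gap),
                                                      size=self.K - 1))
                z.append(np.concatenate(rows))
            elif name == "p":
                p0 = rng.uniform(0.05, 0.95, size=self.S)
                rows = [logit(p0)]
                for gap in self.gaps:
                    rows.append(rows[-1] + rng.normal(0, sigma_p * math.sqrt(gap),
                                                      size=self.S))
                z.append(np.concatenate(rows))
            elif name == "rho":
                z.append(rng.normal(0, 1, size=n))
            elif name == "log_alpha":
                z.append(np.log(rng.gamma(m.priors.alpha_shape,
                                          1.0 / m.priors.alpha_rate, size=n) + 1e-3))
            elif name == "rho_other":
                q = rng.dirichlet(np.ones(self.J))
                z.append(np.log(q[:-1] / q[-1]))
            elif name == "log_sigma":
                z.append(np.log([sigma_f, sigma_p]))
            elif name == "gamma":
                g = []
                for d in self.scanned:
                    rp = m.priors.recovery[m.design.colony_ids[d]]
                    dep = rng.beta(rp.dep_a, rp.dep_b)
                    beta = rng.multivariate_normal(rp.beta_mean,
                                                   np.asarray(rp.beta_cov))
                    g.extend([logit(np.clip(dep, 1e-6, 1 - 1e-6)), *beta])
                z.append(np.asarray(g))
        return np.concatenate(z) if z else np.zeros(0)


# ---------------------------------------------------------------------------
# the model


class JMSModel:
    """Joint mortality-and-survival model for one population-year.

    Parameters
    ----------
    counts : CohortCounts
        Aggregated histories for exactly one (population, year).
    design : StudyDesign
    priors : PriorSpec
        Structural and informative-recovery prior settings.
    colonies : sequence of ColonyMeta, optional
        Used to mark colony-years that were active but unscanned; their
        recovery probability is structurally zero and no consumption estimate
        is reported for them.
    fixed : dict, optional
        Pin parameter blocks at known values instead of sampling them.  Keys:
        ``"p"`` ((W, J) or (J,) or scalar), ``"gamma"`` ((W, C) or (C,)),
        ``"rho"`` ((C, J)), ``"rho_other"`` ((J,)).
    """

    def __init__(self, counts: CohortCounts, design: StudyDesign,
                 priors: PriorSpec,
                 colonies: Optional[Sequence[ColonyMeta]] = None,
                 fixed: Optional[Mapping] = None,
                 include_removal_detection: bool = True,
                 prior_only: bool = False):
        keys = {(p, y) for (p, y, _w) in counts.counts}
        if len(keys) == 0:
            raise FitError("no fish: nothing to fit")
        if len(keys) > 1:
            raise ValueError("model covers one population-year; use counts.subset()")
        (self.population, self.year), = keys
        self.prior_only = prior_only
        self.counts = counts
        self.design = design
        self.priors = priors
        self.colonies = tuple(colonies) if colonies else ()
        self.include_removal_detection = include_removal_detection
        self.weeks = sorted(w for (_p, _y, w) in counts.counts)

        scanned = []
        meta = {c.colony_id: c for c in self.colonies}
        for d, cid in enumerate(design.colony_ids):
            c = meta.get(cid)
            if c is not None and c.scanned_years and self.year not in c.scanned_years:
                continue
            scanned.append(d)
        self.scanned_indices = scanned

        self.fixed = dict(fixed or {})
        W, J, C = len(self.weeks), design.n_reaches, design.n_colonies
        if "p" in self.fixed:
            p = np.asarray(self.fixed["p"], dtype=float)
            if p.ndim == 0:
                p = np.full(J - 1, float(p))
            if p.ndim == 1:
                if p.size == J - 1:
                    p = np.concatenate([p, [0.0]])
                p = np.tile(p, (W, 1))
            self.fixed["p"] = p
        if "gamma" in self.fixed:
            g = np.asarray(self.fixed["gamma"], dtype=float)
            if g.ndim == 0:
                g = np.full(C, float(g))
            if g.ndim == 1:
                g = np.tile(g, (W, 1))
            self.fixed["gamma"] = g
        elif not all(design.colony_ids[d] in priors.recovery
                     for d in self.scanned_indices):
            missing = [design.colony_ids[d] for d in self.scanned_indices
                       if design.colony_ids[d] not in priors.recovery]
            raise ValueError(f"no recovery prior for scanned colonies: {missing}")

        self._week_data = [
            _WeekData.build(w, counts.counts[(self.population, self.year, w)],
                            design, include_removal_detection)
            for w in self.weeks]
        self.layout = _Layout(self)

    @classmethod
    def from_csv(cls, path, design: StudyDesign, priors: PriorSpec,
                 population: str, year: int, **kw) -> "JMSModel":
        counts = read_histories(path, design).subset(population, year)
        return cls(counts, design, priors, **kw)

    # -- posterior ----------------------------------------------------------

    def log_prob(self, z: np.ndarray) -> float:
        layout = self.layout
        parts = layout.split(np.asarray(z, dtype=float))
        nat = layout.natural(np.asarray(z, dtype=float))
        lp = layout.log_prior(parts, nat)
        if not np.isfinite(lp):
            return -np.inf
        if self.prior_only:
            return lp
        ll = 0.0
        for i, wd in enumerate(self._week_data):
            Theta = self._theta_week(nat, i)
            cond = _conditional(Theta)
            if cond is None:
                return -np.inf
            phi, survive = cond
            ll += wd.loglik(phi, survive, nat["p"][i], nat["gamma"][i])
        if not np.isfinite(ll):
            return -np.inf
        return lp + ll

    def _theta_week(self, nat: dict, i: int) -> np.ndarray:
        C, J = self.design.n_colonies, self.design.n_reaches
        tc = nat["theta_cum"][i]
        Theta = np.empty((J, C + 1))
        Theta[:, :C] = nat["rho"].T * tc[:C]
        Theta[:, C] = nat["rho_other"] * tc[C]
        return Theta

    def state(self, nat: dict, i: int) -> ParameterState:
        return ParameterState(self._theta_week(nat, i), nat["p"][i],
                              nat["gamma"][i], design=self.design)

    # -- fitting ------------------------------------------------------------

    def fit(self, chains: int = 4, warmup: int = 500, draws: int = 500,
            thin: int = 4, walkers: Optional[int] = None, seed: int = 0,
            max_stored: int = 1000, rhat_threshold: float = 1.1,
            moves=None, progress: bool = False) -> "JMSResults":
        """Sample the posterior with ``chains`` independent ensembles.

        ``warmup``/``draws`` count ensemble steps (each step moves every
        walker); kept draws are thinned by ``thin`` and capped at
        ``max_stored`` per chain.  The default move mixture (differential
        evolution + snooker) handles the correlated ridges this posterior
        develops when survival and other-cause mortality are only weakly
        separated by the data.
        """
        if moves is None:
            moves = [(emcee.moves.DEMove(), 0.8),
                     (emcee.moves.DESnookerMove(), 0.2)]
        layout = self.layout
        ndim = layout.ndim
        if ndim == 0:
            raise FitError("all parameters fixed: nothing to sample")
        if chains < 2:
            raise FitError("need at least two chains for convergence diagnostics")
        nw = walkers or max(2 * ndim + 2, 32)
        nw += nw % 2
        seeds = np.random.SeedSequence(seed).spawn(chains)
        chain_draws = []
        for c in range(chains):
            rng = np.random.default_rng(seeds[c])
            p0 = []
            tries = 0
            while len(p0) < nw:
                z = layout.sample_init(rng)
                if np.isfinite(self.log_prob(z)):
                    p0.append(z)
                tries += 1
                if tries > 200 * nw:
                    raise FitError("could not initialise walkers at finite posterior")
            sampler = emcee.EnsembleSampler(nw, ndim, self.log_prob, moves=moves)
            sampler._random = np.random.RandomState(
                int(seeds[c].generate_state(1)[0]) % (2 ** 32 - 1))
            sampler.run_mcmc(np.array(p0), warmup + draws, progress=progress,
                             skip_initial_state_check=True)
            kept = sampler.get_chain(discard=warmup, thin=thin)  # (n, nw, ndim)
            flat = kept.reshape(-1, ndim)
            if flat.shape[0] > max_stored:
                stride = flat.shape[0] / max_stored
                idx = (np.arange(max_stored) * stride).astype(int)
                flat = flat[idx]
            chain_draws.append(flat)
        n = min(f.shape[0] for f in chain_draws)
        zdraws = np.stack([f[:n] for f in chain_draws])  # (chains, n, ndim)
        return JMSResults(self, zdraws, seed=seed,
                          rhat_threshold=rhat_threshold)


# ---------------------------------------------------------------------------
# results


class JMSResults:
    """Posterior draws, summaries and diagnostics for a fitted model.

    Natural-parameter draws are exposed as arrays with a leading
    ``(chain, draw)`` axis pair:

    * ``theta_cum`` — (W, C+1) cumulative fate probabilities per week;
    * ``Theta`` — (W, J, C+1) from-release fate matrix per week;
    * ``p`` — (W, J) detection probabilities;
    * ``gamma`` — (W, C) recovery probabilities;
    * ``rho`` / ``rho_other`` — reach partitions; ``alpha``; ``sigma``.
    """

    def __init__(self, model: JMSModel, zdraws: np.ndarray, seed: int,
                 rhat_threshold: float = 1.1):
        self.model = model
        self.zdraws = zdraws
        self.seed = seed
        self.rhat_threshold = rhat_threshold
        self.n_chains, self.n_draws, _ = zdraws.shape
        self.divergences = 0  # ensemble sampler: no divergent transitions
        self._transform_all()

    def _transform_all(self):
        m = self.model
        layout = m.layout
        W, J, C = layout.W, layout.J, layout.C
        shape = (self.n_chains, self.n_draws)
        self.draws: dict[str, np.ndarray] = {
            "theta_cum": np.empty(shape + (W, C + 1)),
            "Theta": np.empty(shape + (W, J, C + 1)),
            "p": np.empty(shape + (W, J)),
            "gamma": np.empty(shape + (W, C)),
            "rho": np.empty(shape + (C, J)),
            "rho_other": np.empty(shape + (J,)),
            "alpha": np.empty(shape + (C, J)),
            "sigma": np.empty(shape + (2,)),
        }
        for c in range(self.n_chains):
            for i in range(self.n_draws):
                nat = layout.natural(self.zdraws[c, i])
                self.draws["theta_cum"][c, i] = nat["theta_cum"]
                self.draws["p"][c, i] = nat["p"]
                self.draws["gamma"][c, i] = nat["gamma"]
                self.draws["rho"][c, i] = nat["rho"]
                self.draws["rho_other"][c, i] = nat["rho_other"]
                self.draws["alpha"][c, i] = nat["alpha"]
                self.draws["sigma"][c, i] = nat["sigma"]
                for w in range(W):
                    self.draws["Theta"][c, i, w] = m._theta_week(nat, w)

    # -- access -------------------------------------------------------------

    def flat(self, name: str) -> np.ndarray:
        a = self.draws[name]
        return a.reshape((self.n_chains * self.n_draws,) + a.shape[2:])

    def scalar_series(self) -> dict[str, np.ndarray]:
        """Named scalar traces (chain, draw) for diagnostics and summaries."""
        m = self.model
        d = m.design
        layout = m.layout
        fate_labels = list(d.colony_ids) + ["other"]
        out: dict[str, np.ndarray] = {}
        tc = self.draws["theta_cum"]
        for w, wk in enumerate(layout.weeks):
            for f, lab in enumerate(fate_labels):
                out[f"theta_cum[w{wk},{lab}]"] = tc[:, :, w, f]
            out[f"survival[w{wk}]"] = 1.0 - tc[:, :, w, :].sum(axis=-1)
            for s in range(layout.S):
                out[f"p[w{wk},site{s + 1}]"] = self.draws["p"][:, :, w, s]
            for k in layout.scanned:
                out[f"gamma[w{wk},{d.colony_ids[k]}]"] = self.draws["gamma"][:, :, w, k]
        for k in layout.two_reach:
            cid = d.colony_ids[k]
            for r in d.forage_map[cid]:
                out[f"rho[{cid},reach{r}]"] = self.draws["rho"][:, :, k, r - 1]
                if "rho" not in m.fixed:
                    out[f"alpha[{cid},reach{r}]"] = self.draws["alpha"][:, :, k, r - 1]
        for r in range(d.n_reaches):
            out[f"rho_other[reach{r + 1}]"] = self.draws["rho_other"][:, :, r]
        if layout.W > 1:
            out["sigma_fate"] = self.draws["sigma"][:, :, 0]
            out["sigma_p"] = self.draws["sigma"][:, :, 1]
        return out

    # -- diagnostics & summaries --------------------------------------------

    def rhat(self) -> pd.Series:
        return pd.Series({k: gelman_rubin(v) for k, v in self.scalar_series().items()})

    @property
    def accepted(self) -> bool:
        """Paper-style acceptance: no divergences and converged chains."""
        r = self.rhat()
        return self.divergences == 0 and bool((r < self.rhat_threshold).all())

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        rows = []
        for name, trace in self.scalar_series().items():
            flatv = trace.reshape(-1)
            lo, hi = hdi(flatv, mass)
            rows.append({
                "parameter": name,
                "median": float(np.median(flatv)),
                f"hdi_{mass:.0%}_low": lo,
                f"hdi_{mass:.0%}_high": hi,
                "rhat": gelman_rubin(trace),
                "ess": effective_sample_size(trace),
            })
        return pd.DataFrame(rows).set_index("parameter")

    # -- posterior predictive -----------------------------------------------

    def posterior_predictive_check(self, seed: int = 0, n_sims: int = 100,
                                   mass: float = 0.95) -> pd.DataFrame:
        """Simulate datasets from posterior draws and compare aggregate
        recapture counts per site and recovery counts per colony with the
        observed data.

        Returns a table with one row per aggregate statistic: observed value,
        predictive interval, and an ``inside`` flag.
        """
        from .simulate import ScenarioConfig, TrueParameters, simulate_histories

        m = self.model
        d = m.design
        layout = m.layout
        rng = np.random.default_rng(seed)
        obs_recap, obs_recov, n_week, transported = self._observed_aggregates()
        total_det = sum(obs_recap)
        tau = (transported / total_det) if total_det else 0.0

        sims_recap = np.zeros((n_sims, d.n_sites))
        sims_recov = np.zeros((n_sims, d.n_colonies))
        idx_c = rng.integers(0, self.n_chains, size=n_sims)
        idx_i = rng.integers(0, self.n_draws, size=n_sims)
        scenario = ScenarioConfig(
            name="ppc", design=d, colonies=m.colonies,
            population=m.population, year=m.year, weeks=layout.W,
            n_fish_per_week=tuple(n_week),
            theta_cum=tuple(self.draws["theta_cum"][0, 0, 0]),
            p=tuple(self.draws["p"][0, 0, 0, :d.n_sites]),
            gamma=tuple(np.clip(self.draws["gamma"][0, 0, 0], 1e-9, 1)),
        )
        for s in range(n_sims):
            c, i = idx_c[s], idx_i[s]
            truth = TrueParameters(
                design=d, scenario=scenario,
                theta_cum=self.draws["theta_cum"][c, i],
                rho=self.draws["rho"][c, i],
                rho_other=self.draws["rho_other"][c, i],
                p=self.draws["p"][c, i],
                gamma=self.draws["gamma"][c, i],
                transport_prob=float(tau))
            sim = simulate_histories(truth, n_week,
                                     seed=int(rng.integers(2 ** 31)))
            recap, recov, _, _ = _aggregates(sim, d)
            sims_recap[s] = recap
            sims_recov[s] = recov

        lo_q, hi_q = (1 - mass) / 2, 1 - (1 - mass) / 2
        rows = []
        for j in range(d.n_sites):
            lo, hi = np.quantile(sims_recap[:, j], [lo_q, hi_q])
            rows.append({"statistic": f"recaptures_site_{j + 1}",
                         "observed": obs_recap[j], "pred_low": lo,
                         "pred_high": hi,
                         "pred_median": float(np.median(sims_recap[:, j])),
                         "inside": bool(lo <= obs_recap[j] <= hi)})
        for k, cid in enumerate(d.colony_ids):
            lo, hi = np.quantile(sims_recov[:, k], [lo_q, hi_q])
            rows.append({"statistic": f"recoveries_{cid}",
                         "observed": obs_recov[k], "pred_low": lo,
                         "pred_high": hi,
                         "pred_median": float(np.median(sims_recov[:, k])),
                         "inside": bool(lo <= obs_recov[k] <= hi)})
        return pd.DataFrame(rows).set_index("statistic")

    def _observed_aggregates(self):
        return _aggregates(self.model.counts, self.model.design)

    # -- persistence ---------------------------------------------------------

    def draws_frame(self) -> pd.DataFrame:
        """All named scalar traces as a long-format table."""
        recs = {}
        for name, trace in self.scalar_series().items():
            recs[name] = trace.reshape(-1)
        df = pd.DataFrame(recs)
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.n_draws))
        df.insert(1, "draw", np.tile(np.arange(self.n_draws), self.n_chains))
        return df


def _aggregates(counts: CohortCounts, design: StudyDesign):
    """(recaptures per site, recoveries per colony, fish per week, n transported)."""
    recap = np.zeros(design.n_sites)
    recov = np.zeros(design.n_colonies)
    weeks = sorted(w for (_p, _y, w) in counts.counts)
    n_week = []
    transported = 0
    for w in weeks:
        key = next(k for k in counts.counts if k[2] == w)
        ctr = counts.counts[key]
        n_week.append(sum(ctr.values()))
        for (y, recovery, transport), n in ctr.items():
            recap += n * np.asarray(y[:design.n_sites], dtype=float)
            if transport is not None:
                transported += n
            elif recovery != design.not_recovered_index:
                recov[recovery - 1] += n
    return recap, recov, n_week, transported
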