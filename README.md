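# smoltjms

Joint mortality-and-survival (JMS) estimation for PIT-tagged juvenile
salmonids (smolts) exposed to predation by piscivorous colonial waterbirds —
Caspian terns, double-crested cormorants, and California/ring-billed gulls —
during seaward migration through a dammed river corridor.

## The problem

Out-migrating smolts tagged with passive integrated transponder (PIT) tags
can be observed in two ways: *recaptured* alive at in-river detection arrays
(dam bypasses, an estuary net detector), or *recovered* dead as a tag found
on a bird breeding colony after the nesting season. Both observation
processes are imperfect: bypass detection probabilities are low, and a
consumed tag is only found if it was deposited on-colony (deposition) and
then located during post-season scanning (detection). The JMS model uses
both data streams jointly to estimate, per river reach and per colony, the
probability that an available fish is consumed by birds, dies of another
cause, or survives — and hence what share of all mortality (1 − survival)
is avian.

## The model

The river is divided into `J` sequential reaches delineated by `J − 1`
recapture sites; fish only move downstream. For each weekly release cohort:

- `Θ` (`J × D`): from-release probabilities that a fish survives to reach
  `j` and there succumbs to fate `d` — consumption by one of the `D − 1`
  colonies, or other-cause death (column `D`). Survival through reach `k`
  is `1 − Σ_{j≤k} Σ_d Θ_{j,d}`.
- `p` (length `J`): detection probability at the site ending each reach,
  with `p_J = 0` (no site downstream of the last reach).
- `γ` (length `D`): recovery probability of a consumed tag
  (deposition × detection), `γ_D = 0` for unrecoverable other-cause deaths.

Recapture/recovery histories `(y, r)` enter an exact likelihood through the
recursive functions `χ_{j,d}` — the probability that a fish entering reach
`j` is never recaptured again and ends in recovery fate `d`:

    χ_{j,d} = φ_{j,d} γ_d + s_j (1 − p_j) χ_{j+1,d}

with per-reach conditional fates `φ` and conditional survival `s` derived
from `Θ`, and a truncated likelihood for fish collected for barge/truck
transport at one of the first three dams. Each colony forages in at most
two reaches; its column of `Θ` factors as `θ_d^cum · ρ_d`, and the
*informed partitioning* prior `ρ_d ~ Dirichlet(α_d)` with `Gamma(2, 4)`
hyper-priors shares each colony's reach allocation across years. First-week
detection gets a `uniform(0,1)` prior, first-week life-path simplexes
`Dirichlet(1)`, inter-weekly random-walk scales `half-normal(0, 5)`, and
`γ` gets informative priors: a species-level deposition Beta times a
per-colony logistic detection model `logit(det) = β₁ + β₂ (week − 22)` with
a multivariate-normal prior on `(β₁, β₂)` estimated elsewhere from sown
test tags.

Posteriors are sampled with ensemble MCMC (emcee, differential-evolution
moves) over four independent chains; convergence is checked with the
split Gelman–Rubin statistic and fits are summarised as posterior medians
with 95% highest-density intervals (HDI). Derived quantities — cumulative
consumption per colony/species group, total mortality per reach span, and
the avian share of mortality — are computed draw-wise before summarising.

## Worked example

Simulate a small two-reach system with one tern colony (true cumulative
consumption 0.2 split 60/40 across the reaches, detection 0.5, recovery
probability 0.5, 5 000 fish), fit it, and summarise:

```python
import smoltjms as sj
from smoltjms.simulate import DEFAULT_DEPOSITION
from smoltjms.summaries import (avian_fraction, cumulative_consumption,
                                total_mortality)

sc = sj.get_scenario("small_2reach")
truth = sj.draw_true_parameters(sc.design, sc, seed=1)
counts = sj.simulate_histories(truth, seed=2)
priors = sj.PriorSpec.from_truth(truth, DEFAULT_DEPOSITION, sc.colonies)
model = sj.JMSModel(counts, sc.design, priors, colonies=sc.colonies)
res = model.fit(chains=4, warmup=2000, draws=2000, thin=8, seed=3)
print(res.summary().round(3))
print(cumulative_consumption(res))
print(total_mortality(res, reach_span=(1, 1)))
print(avian_fraction(res, reach_span=(1, 1)))
```

which prints

```
                        median  hdi_95%_low  hdi_95%_high   rhat       ess
parameter
theta_cum[w0,CSI_tern]   0.204        0.170         0.236  1.021  3475.793
theta_cum[w0,other]      0.322        0.035         0.638  1.038  4000.000
survival[w0]             0.473        0.165         0.777  1.036  4000.000
p[w0,site1]              0.538        0.456         0.771  1.050  4000.000
gamma[w0,CSI_tern]       0.491        0.421         0.560  1.022  3793.849
rho[CSI_tern,reach1]     0.643        0.519         0.746  1.062  4000.000
rho[CSI_tern,reach2]     0.357        0.254         0.481  1.062  4000.000
rho_other[reach1]        0.406        0.031         0.907  1.024  4000.000
rho_other[reach2]        0.594        0.093         0.969  1.024  4000.000

consumption[all colonies, reaches 1-2]: 0.204 (95% HDI 0.170-0.236)
total_mortality[reaches 1-1]: 0.239 (95% HDI 0.111-0.468)
avian_fraction[reaches 1-1]: 0.537 (95% HDI 0.298-0.924)
```

The cumulative consumption estimate (0.204, HDI 0.170–0.236) brackets the
generating value 0.2, the reach partition recovers the 60/40 split, and the
reach-1 mortality HDI brackets the generating 0.195. The avian-fraction
line answers the management question directly: roughly half of reach-1
mortality is attributable to the colony. With a single recapture site the
split between other-cause death and survival is only weakly identified —
its wide, honest interval is the expected behaviour, and is why multi-site
designs are needed to pin down total mortality.

The same pipeline is scriptable from a shell:

```
jms simulate --scenario small_2reach --seed 3 --out sim1
jms fit --data sim1 --out fit1
jms summarize --data sim1 --out report1
```

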