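# Methods

## Model

One population-year is modelled as a set of weekly release cohorts moving
through `J` sequential river reaches delineated by `J − 1` recapture sites
(site `j` ends reach `j`; fish move only downstream). Per cohort the
parameters are the from-release fate matrix `Θ` (`J × D`; `D − 1` bird
colonies plus an other-cause-death column), the detection vector `p`
(`p_J = 0`), and the per-colony recovery probability
`γ = deposition × on-colony detection` (other-cause deaths are never
recoverable). The likelihood of a history is the product of detection terms
up to the final live detection `m` — with survival through each of those
reaches folded in — times the recursive tail probability `χ_{m+1,d}` of the
observed recovery fate.

Two readings of the `χ` recursion are possible because `Θ` is from-release
while the recursion conditions on "entering reach j". We evaluate it with
*per-reach conditional* fates `φ_{j,d} = Θ_{j,d} / S_{j−1}`
(`S_{j−1}` = from-release survival to reach `j`) and conditional survival
`s_j`; under this reading every `χ` row, together with the probability of a
later recapture, sums to exactly 1, which an exhaustive enumeration oracle
verifies to 1e-10 on small instances. The termination row is
`χ_{J+1} = (0, …, 0, 1)`: a fish surviving all reaches is never reseen and
never recovered.

Fish collected for transport at one of the first three dams have truncated
histories with likelihood `Π_{j≤m} s_j × detection terms`. Because removal
requires capture, the detection factor `p_m` at the removal site is included
by default; `include_removal_detection=False` gives the alternative
convention (the two differ by a constant per transported fish and do not
change inference about fates).

Structural zeros are handled in log space with an explicit `−inf`; inside
the sampler, probabilities are floored at 1e-300 before logging, which is
numerically indistinguishable from `−inf` for posterior purposes but avoids
NaN arithmetic in vectorised products.

## Informed partitioning

Each colony forages at most two reaches. Its `Θ` column factors as
`θ_d^cum · ρ_d` with `ρ_d` supported on the foraged reaches. `ρ_d` is
year-level and drawn from a colony-specific `Dirichlet(α_d)`
hyper-distribution whose non-zero elements get `Gamma(2, 4)` priors; this
shares the spatial allocation across years while letting the magnitude
`θ_d^cum` vary. The other-cause column is partitioned by its own year-level
simplex over all `J` reaches with a `Dirichlet(1)` prior — informed
partitioning is a statement about colony foraging geometry and is not
applied to non-avian mortality. Weekly variation therefore enters through
the cumulative life-path simplex and the detection probabilities, not
through the reach partitions; this keeps the weekly block identifiable at
realistic recapture rates.

## Priors and temporal structure

- First-week detection probabilities: `uniform(0, 1)`.
- First-week life-path (cumulative fate) simplexes: `Dirichlet(1)`.
- Weeks `w > 1`: first-order Gaussian random walks on transformed scales
  (logit for `p`, additive-log-ratio for the fate simplex), step SD `σ`
  scaled by `sqrt(gap)` for non-adjacent observed weeks; `σ` has
  `half-normal(0, 5)` priors. The random walk is the simplest structure
  under which cohorts closer in time are more alike.
- Recovery: `γ_d(week) = δ_d · logit⁻¹(β₁ + β₂ (week − 22))`, with a
  species-level Beta prior on deposition `δ_d` and a bivariate-normal prior
  on `(β₁, β₂)` per colony, the form in which sown-test-tag experiments
  summarise on-colony detection. Week 22 is the calendar centring week of
  that regression; cohort weeks are mapped to calendar weeks via
  `first_calendar_week` (default 18, mid-release-season). The actual
  experiment coefficients are not shipped; `PriorSpec.from_truth` builds
  synthetic informative priors centred on a generating truth for
  simulation studies, and all such fixture values are labelled synthetic.
- Colony-years that were active but not scanned have `γ = 0` structurally:
  consumption still occurs in the generative model, but no estimate is
  reported for them ("no estimate" rows, not zeros), and group totals
  excluding them are minimum estimates.

## Sampling and diagnostics

The joint posterior is sampled on an unconstrained space (additive-log-ratio
and logit transforms, log scales for `σ` and `α`, with the corresponding
Jacobians in the prior) by an ensemble MCMC sampler (emcee) using a
differential-evolution + snooker move mixture, which handles the correlated
ridges this posterior develops when survival, other-cause death and
detection are only weakly separated. Four independent ensembles play the
role of chains: split Gelman–Rubin `R̂` is computed per parameter across
them, and a fit is *accepted* when all `R̂ < 1.1` (the classic rule of
thumb) with zero divergent transitions — the ensemble sampler has no
divergence failure mode, so that count is structurally 0 and acceptance
rests on `R̂`. Test-scale defaults are 4 chains × 500 warm-up + 500 kept
steps thinned by 4; the full-scale protocol (4 × 4000/4000, thin 4) is a
matter of passing larger arguments. Walker initial positions are drawn from
the priors (with moderated random-walk scales) and re-drawn until the
posterior is finite.

`hdi` is the sorted-window shortest-interval algorithm with ties broken by
the lowest starting index (deterministic); it matches a brute-force scan
over all candidate windows exactly. `gelman_rubin` is split-`R̂` with the
zero-variance convention `R̂ = 1` for constant chains. The reported `ess`
is a crude pooled-autocorrelation estimate adequate for bookkeeping; for
the stored ensemble draws (step-major interleaving of walkers) it is
optimistic, and Monte-Carlo error statements in the tests therefore use
chain-replicate spread or analytic references instead.

Posterior-predictive checks re-simulate datasets from randomly drawn
posterior parameter vectors (via the synthetic-data generator, with the
empirical transport fraction) and compare observed aggregate recaptures per
site and recoveries per colony against 95% predictive intervals.

## Synthetic-data generator

The generator is the generative mirror of the likelihood: per fish and
reach, a conditional fate draw (colony, other death, survive), detection at
the next site, possible transport removal at the first dams, and recovery of
consumed tags with probability `γ`. Weekly truths follow the same
transformed-scale random walks the model assumes. Scenarios emulate the
study system's observational wrinkles: an active-but-unscanned colony-year
(recoveries suppressed while consumption continues) and a mid-season
dispersal event that thins a cormorant colony's recovery probability for
part of the season. The full-size scenario has 9 reaches, 8 recapture
sites, 14 colonies (each foraging ≤ 2 reaches), transport at the first
three dams, 10 weekly cohorts and steelhead-like magnitudes (cumulative
avian consumption ≈ 0.3, other-cause mortality 0.25, bypass detection
0.15–0.3, deposition 0.7/0.5/0.2 for terns/cormorants/gulls times ≈ 0.8
on-colony detection). Transport fraction defaults to 0.05 where enabled; it
is a free scenario parameter.

What the generator does *not* emulate: travel time within reaches (reaches
are discrete states, so no arrival-timing or flow covariates), fish-level
heterogeneity in vulnerability, tag loss or tag-induced mortality,
off-colony deposition recovered elsewhere, and upstream movement. Passing
parameter-recovery tests therefore demonstrate self-consistency of model
and generator under the stated assumptions, not robustness to these
real-data features.

## Problem sizes and numerical choices

Tests and the acceptance script run deliberately small problems chosen as
the smallest instances that exercise every code path: exhaustive oracle
comparisons on `J ≤ 3, D ≤ 3`; a 2-reach/1-colony scenario with 5 000 fish
for fits (one cohort week, so the random-walk block is exercised separately
by the generator tests); 20-seed refit studies at 2 chains × 250/250. With
a single interior recapture site, the split between other-cause death and
survival is intrinsically weakly identified — the model reports it with
honest, wide intervals, and coverage checks include it deliberately.
Enumeration is bounded at `J ≤ 4, D ≤ 4` (the tree is exponential).
Derived annual quantities combine weekly cohorts per draw by availability
weighting (release size × survival to the span head); ratios such as the
avian share of mortality are computed per draw, capped at 100%, and flagged
unstable when a non-negligible share of draws has near-zero mortality.
Total mortality is only estimable over spans ending at a live-detection
boundary; spans ending in the terminal reach return an explicit
not-estimable result.

## Known limitations

- The sampler is a generic ensemble method, not Hamiltonian Monte Carlo;
  posteriors with many weeks and colonies will need long runs. The
  acceptance contract is diagnostic-based, so any sampler meeting it is
  interchangeable.
- `α_d` hyper-parameters are only weakly informed by a single year of data;
  multi-year joint fitting (shared `α`, per-year `ρ`) is the intended use
  of informed partitioning, and single-year fits effectively marginalise a
  funnel that slows mixing of `ρ`.
- Recovery priors must be externally supplied; consumption and recovery
  probability are only jointly identified through them.
- Adult-return (SAR) counts pass through summaries only; no ocean-phase
  survival model is attempted.
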