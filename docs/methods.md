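# Methods

## The estimand and why routine data bias it

The *lifetime risk* of cancer is the probability that a person ever
receives a (first) cancer diagnosis, under the fiction that today's
age-specific rates apply to a whole birth cohort. In the four-state model
used throughout this package — alive never-cancer [0], alive with/after
cancer [C], dead of cancer [D], dead of other causes [X], with transition
hazards λ<sub>0C</sub>, λ<sub>0X</sub>, λ<sub>CC</sub>, λ<sub>CD</sub>,
λ<sub>CX</sub> and λ<sub>0D</sub> ≡ 0 — it is

    risk = ∫ λ_0C(u) · S_0(u) du,   S_0(u) = exp(−∫_0^u (λ_0C + λ_0X)).

Neither λ<sub>0C</sub> nor S<sub>0</sub> is observable from routine
registry publications: the published incidence rate λ<sub>C</sub> mixes
first and subsequent primaries,

    λ_C = (λ_0C·S_0 + λ_CC·P) / (S_0 + P),

where P(u) is the prevalence of being alive with a cancer history, and the
published non-cancer death rate λ<sub>X</sub> mixes the two alive states
the same way. The classical current-probability (CP) calculation integrates
λ<sub>C</sub> against all-cause survival and therefore estimates the
expected number of registrations per lifetime, not a probability.

## The AMP estimator

The adjusted-for-multiple-primaries estimator replaces all-cause survival
with the proxy

    S*(u) = exp(−∫_0^u (λ_C + λ_X)),

built entirely from observable rates, and estimates

    risk ≈ ∫ λ_C(u) · S*(u) du.

S\* treats a registration like a removal from the at-risk pool, which is
exactly right for first cancers; the approximation error comes from using
population-mixed rates instead of never-cancer rates. The estimator is
exact when λ<sub>CC</sub> = λ<sub>0C</sub> and λ<sub>CX</sub> =
λ<sub>0X</sub> (prior cancer changes nothing), and close whenever those
ratios are near 1 *or* prevalence P is small against S<sub>0</sub> — the
latter is why the adjustment works well even for lung cancer, where
survivors have clearly elevated rates but are few. The known failure mode
is the opposite corner: sites with essentially no repeat primaries and good
survival (prostate-like), where S\* discounts registrations that never
recur and AMP under-corrects slightly; for such sites CP on its own is the
better choice. Both behaviours are exercised by the simulation tests.

On age bands [a<sub>i</sub>, a<sub>i+1</sub>) with per-band rates
λ<sub>C,i</sub> = R<sub>i</sub>/N<sub>i</sub> and λ<sub>X,i</sub> =
(M<sub>i</sub> − D<sub>i</sub>)/N<sub>i</sub>, S\* is a product of
exponential steps and each band contributes
[λ<sub>C,i</sub>/(λ<sub>C,i</sub>+λ<sub>X,i</sub>)]·[S\*(a<sub>i</sub>) −
S\*(a<sub>i+1</sub>)]. The CP integral is the same construction with
attrition λ<sub>M,i</sub> = M<sub>i</sub>/N<sub>i</sub>. The three classical
quantities differ only in what multiplies the incidence inside the
integral: the probability of being cancer-free (cumulative risk), of being
alive (CP), or of being alive and cancer-free (AMP).

## Numerical choices

- **Exact-within-band integration.** Hazards are taken as constant within
  bands, so every band integral has a closed form; no quadrature rule is
  involved and splitting bands changes nothing (refinement invariance).
  A trapezoid variant (`amp_estimate(..., rule="trapezoid")`) exists purely
  as a sensitivity check.
- **Open final band.** An 85+/90+ band is integrated to infinity with its
  constant rates, contributing λ<sub>C</sub>/(λ<sub>C</sub>+λ<sub>X</sub>)
  · S\*(a<sub>K</sub>) (CP analogously with λ<sub>M</sub>). A tail with
  positive incidence but zero attrition is non-integrable and raises.
  Age-truncated estimates stop at a band boundary with no tail term.
  `cap_final_band` re-pools a table at a lower cap (85 vs 90) for
  sensitivity analyses.
- **Degenerate bands.** Both hazards zero: the 0/0 occurrence ratio is
  taken as its continuity limit, 0. Zero population with zero counts:
  hazards 0 with a warning; with nonzero counts: an error.
- **CP > 1.** Legitimate (a mean count); warned about, never clipped —
  except on the gold-standard label, where values are capped at 1 after
  warning so the probability-typed result stays in range.
- **Percent display** rounds half away from zero at the displayed
  precision; internal values are never rounded.
- **Ground truth by matrix exponentials.** State occupancies, expected
  primaries, and the rates a registry would observe are computed by exact
  matrix-exponential propagation of each band's constant generator
  (augmented with person-year accumulator states), so oracle comparisons
  carry no ODE-solver tolerance. Observable rates are occupancy-weighted
  band averages — event integrals over person-year integrals — matching how
  registry rates are formed from counts.
- **Independent oracle.** `fine_grid_oracle` re-evaluates the AMP integral
  by composite Simpson quadrature inside each band (tail truncated once the
  survivor mass is below ~1e−18). It shares no code path with the banded
  estimator and agrees with it to better than 1e−10 relative error.

## The microsimulator

Individuals start in state [0] at age 0. Waiting times are drawn by
inverting the piecewise-constant cumulative exit hazard across band
boundaries (exact, no rejection); the event type is multinomial in the
cause-specific hazards at the event age; repeat diagnoses keep the person
in [C]. Everyone is followed to death, with a forced other-cause death at a
cap age (default 120) guaranteeing termination. Individual *k* draws from
`SeedSequence(entropy=seed, spawn_key=(k,))`, making cohorts reproducible
and partition-invariant (one call of size 2k equals two concatenated
k-calls via `start_index`).

Aggregation treats the cohort as a stationary population observed for one
calendar year: a closed band of width *w* pools *w* single-year birth
cohorts, so annual counts are cohort totals divided by *w* and the
"mid-year population" N<sub>i</sub> is person-years in the band divided by
*w* (the open band keeps raw totals). Count/N ratios are then exactly
events per person-year, and Σ N<sub>i</sub>w<sub>i</sub> equals total
life-years.

## Fixture profiles

The four archetypes use Gompertz-type age curves at magnitudes typical of
an industrialised-country population: all-cancer-like incidence
7·10⁻⁵·e^(0.072·age) (≈0.8%/yr at 65, ≈3%/yr at 85) and non-cancer
mortality 3·10⁻⁴ + 2.5·10⁻⁵·e^(0.095·age) (≈1%/yr at 65, ≈8%/yr at 85), on
1-year bands to an open 90+ band by default.

- `baseline` — λ<sub>CC</sub>=λ<sub>0C</sub>, λ<sub>CX</sub>=λ<sub>0X</sub>,
  cancer-death hazard 0.12/yr (5-year cancer-specific survival ≈55%,
  matching the all-cancer order of magnitude). True lifetime risk 0.328,
  expected primaries 0.369. The equal-rates assumption holds exactly, so
  AMP is consistent here.
- `lung_like` — incidence ×0.25, repeat incidence ×2, non-cancer mortality
  ×3 in survivors (shared smoking risk), cancer-death hazard 0.45/yr.
  Assumptions clearly violated, but survivors are so few that AMP still
  recovers the truth (risk 0.104).
- `prostate_like` — no within-site repeats, late-age incidence, low
  fatality (risk 0.148): the under-correction corner.
- `breast_like` — doubled incidence after a first cancer, good survival
  (risk 0.116, mean 0.127): the setting where routine rates most overstate
  risk.

These are qualitative archetypes, not calibrations to any registry; they
reproduce the *directions* and rough magnitudes of the site-specific
behaviour discussed above.

## What the synthetic data does and does not show

The simulator generates exactly the world the estimators assume between
events: Markov transitions, piecewise-constant hazards, a closed cohort
with complete follow-up, and no period effects. Passing recovery tests
therefore demonstrates correctness of the estimators *given their
assumptions*, including their behaviour when the equal-rates assumption is
broken — not robustness to features real registries have and the model
lacks: calendar-time trends and screening shocks (cross-sectional rates can
misstate any real cohort's risk, e.g. a transient screening-induced
incidence spike inflates every method here), migration in and out of the
catchment, registration delay and under-ascertainment, and the common
convention of incidence excluding NMSC while mortality includes it (the
reader warns on mismatched site labels but cannot correct for it).

## Validation surface and problem sizes

The test suite checks, at fixed seeds: closed-form limits (constant-hazard
risk c/(c+x) and mean count c/x, analytically to 1e−10 and by simulation
within 3 standard errors); AMP-vs-quadrature agreement to 1e−10 relative on
100 random tables; the equal-rates consistency theorem to 1e−6; estimator
recovery within 3 Monte-Carlo standard errors on simulated cohorts of
100 000 individuals (a size at which the Monte-Carlo error of a ~0.3 risk
is ≈0.0015, small enough to resolve the CP bias yet quick to simulate); the
1-year vs 5-year banding agreement to <1% relative; and the reading of the
CP − AMP gap as the probability of two or more primaries (within 20%
relative on the baseline profile, where multiplicities above two are rare
but not absent).
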