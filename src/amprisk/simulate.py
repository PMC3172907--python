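"""Continuous-time microsimulation of individual cancer histories.

Each simulated person starts at age 0 alive and cancer-free, and moves
through the four-state model (:mod:`amprisk.multistate`): waiting times
are drawn by inverting the piecewise-constant cumulative exit hazard
across age bands, the event kind is drawn in proportion to the
cause-specific hazards at the event age, and repeat diagnoses keep the
person in the with/after-cancer state.  Everyone is followed to death;
a configurable cap (default 120 years) forces a non-cancer death so
lifetime summaries are always defined.

Histories aggregate into registry-style tables on any band grid, in two
flavours at once: ``counts_all`` registers every diagnosis (the routine
registry convention) and ``counts_first`` only each person's first — the
pair that lets the adjusted estimator be validated against the gold
standard on identical underlying lives.

Reproducibility and partition invariance: individual ``k`` (globally
indexed) draws from ``numpy`` ``SeedSequence(entropy=seed,
spawn_key=(k,))``, so simulating ``n`` people in one call is identical
to concatenating calls over any partition of ``0..n-1`` via the
``start_index`` argument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .multistate import MultiStateHazards, expected_primaries, true_lifetime_risk
from .registry import (
    ALL_PRIMARIES,
    FIRST_PRIMARIES,
    AgeBand,
    AgeBandCountsTable,
    make_bands,
    validate_bands,
)

__all__ = [
    "DIAGNOSIS",
    "DEATH_CANCER",
    "DEATH_OTHER",
    "EventHistory",
    "SimulatedRegistry",
    "simulate_cohort",
    "aggregate_registry",
    "empirical_summaries",
    "make_fixture",
    "profile_model",
    "PROFILES",
]

DIAGNOSIS = "diagnosis"
DEATH_CANCER = "death_cancer"
DEATH_OTHER = "death_other"
_DEATHS = (DEATH_CANCER, DEATH_OTHER)


@dataclass(frozen=True)
class EventHistory:
    """One simulated life: ordered (age, kind) events, death always last."""

    events: tuple[tuple[float, str], ...]
    censor_age: float | None = None

    def __post_init__(self) -> None:
        ages = [a for a, _ in self.events]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("event ages must be strictly increasing")
        kinds = [k for _, k in self.events]
        unknown = set(kinds) - {DIAGNOSIS, DEATH_CANCER, DEATH_OTHER}
        if unknown:
            raise ValueError(f"unknown event kind(s) {unknown}")
        deaths = [i for i, k in enumerate(kinds) if k in _DEATHS]
        if len(deaths) > 1 or (deaths and deaths[0] != len(kinds) - 1):
            raise ValueError("at most one death event, and it must be last")
        if DEATH_CANCER in kinds and DIAGNOSIS not in kinds[: deaths[0]]:
            raise ValueError("cancer death requires a prior diagnosis")
        if self.censor_age is not None and deaths:
            raise ValueError("a history cannot be both censored and dead")

    @property
    def n_diagnoses(self) -> int:
        return sum(1 for _, k in self.events if k == DIAGNOSIS)

    @property
    def death_age(self) -> float | None:
        if self.events and self.events[-1][1] in _DEATHS:
            return self.events[-1][0]
        return None


@dataclass(frozen=True)
class SimulatedRegistry:
    """Registry tables aggregated from one simulated cohort.

    ``counts_all`` and ``counts_first`` differ only in their case counts;
    deaths and person-years are identical.  When produced by
    :func:`make_fixture`, the generating truth rides along so validation
    reports are self-describing.
    """

    counts_all: AgeBandCountsTable
    counts_first: AgeBandCountsTable
    n_individuals: int
    seed: int | None = None
    profile: str | None = None
    true_lifetime_risk: float | None = None
    expected_primaries: float | None = None

    def __post_init__(self) -> None:
        if np.any(self.counts_first.cases > self.counts_all.cases + 1e-9):
            raise ValueError("first-primary cases exceed all-primary cases in some band")

    def sidecar(self) -> dict:
        return {
            "profile": self.profile,
            "n": self.n_individuals,
            "seed": self.seed,
            "true_lifetime_risk": self.true_lifetime_risk,
            "expected_primaries": self.expected_primaries,
        }


def _cumulative_exit(bounds: np.ndarray, rates: np.ndarray, age: float, draw: float) -> float:
    """Age at which the integrated exit hazard from ``age`` reaches ``draw``.

    ``bounds`` are the band starts (open band last); returns ``inf`` when
    the hazard integral never reaches the target.
    """
    i = int(np.searchsorted(bounds, age, side="right")) - 1
    acc = 0.0
    t = age
    while True:
        nxt = bounds[i + 1] if i + 1 < len(bounds) else math.inf
        r = rates[i]
        if nxt == math.inf:
            return t + (draw - acc) / r if r > 0 else math.inf
        seg = r * (nxt - t)
        if acc + seg >= draw:
            return t + (draw - acc) / r
        acc += seg
        t = nxt
        i += 1


def simulate_cohort(
    model: MultiStateHazards,
    n: int,
    seed: int,
    *,
    start_index: int = 0,
    max_age: float | None = 120.0,
) -> list[EventHistory]:
    """Simulate ``n`` complete lives under ``model``.

    ``max_age`` forces a non-cancer death at that age (survival past it
    is astronomically unlikely under realistic hazards; the cap
    guarantees termination).  With ``max_age=None`` a model whose open
    band has no exit hazard raises, since individuals would be immortal.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tail = model.n_bands - 1
    if max_age is None:
        if model.h0C[tail] + model.h0X[tail] <= 0 or model.hCD[tail] + model.hCX[tail] <= 0:
            raise ValueError("zero exit hazard on the open band: set max_age to cap lifetimes")
        max_age = math.inf

    bounds = model.boundaries
    exit0 = model.h0C + model.h0X
    exitC = model.hCD + model.hCX + model.hCC

    histories: list[EventHistory] = []
    for k in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(start_index + k,)))
        events: list[tuple[float, str]] = []
        age = 0.0
        in_cancer = False
        while True:
            rates = exitC if in_cancer else exit0
            t = _cumulative_exit(bounds, rates, age, rng.exponential())
            if t >= max_age:
                events.append((max_age, DEATH_OTHER))
                break
            i = int(np.searchsorted(bounds, t, side="right")) - 1
            u = rng.random() * rates[i]
            if in_cancer:
                if u < model.hCC[i]:
                    kind = DIAGNOSIS
                elif u < model.hCC[i] + model.hCD[i]:
                    kind = DEATH_CANCER
                else:
                    kind = DEATH_OTHER
            else:
                kind = DIAGNOSIS if u < model.h0C[i] else DEATH_OTHER
            events.append((t, kind))
            if kind != DIAGNOSIS:
                break
            in_cancer = True
            age = t
        histories.append(EventHistory(events=tuple(events)))
    return histories


def _person_years_per_band(death_ages: np.ndarray, boundaries: np.ndarray, open_final: bool) -> np.ndarray:
    """Total years lived inside each band, summed over individuals."""
    lo = boundaries[:-1] if not open_final else boundaries
    hi = np.append(boundaries[1:], math.inf) if open_final else boundaries[1:]
    d = death_ages[:, None]
    return np.clip(np.minimum(d, hi[None, :]) - lo[None, :], 0.0, None).sum(axis=0)


def aggregate_registry(
    histories: Sequence[EventHistory],
    bands: Sequence[AgeBand],
    *,
    sex: str = "persons",
    site: str = "all cancers",
    seed: int | None = None,
) -> SimulatedRegistry:
    """Bin a cohort's events and exposure into registry-style tables.

    The cohort plays the role of a stationary population observed for one
    calendar year: a closed band of width ``w`` pools ``w`` single-year
    birth cohorts, so its annual counts are the cohort totals divided by
    ``w`` and its mid-year population ``N_i`` is the person-years lived in
    the band divided by ``w`` (the open band, having no width, carries raw
    totals and person-years).  Count/population ratios are then exactly
    events per person-year, and ``sum_i N_i * w_i`` is the cohort's total
    life-years.
    """
    bands = validate_bands(bands)
    open_final = bands[-1].is_open
    starts = np.array([b.start for b in bands])
    boundaries = np.append(starts, bands[-1].end) if not open_final else starts

    death_ages = []
    diag_ages_all: list[float] = []
    diag_ages_first: list[float] = []
    cancer_death_ages: list[float] = []
    for hist in histories:
        d = hist.death_age
        if d is None:
            raise ValueError("aggregate_registry needs complete (uncensored) histories")
        death_ages.append(d)
        if hist.events[-1][1] == DEATH_CANCER:
            cancer_death_ages.append(d)
        first = True
        for a, kind in hist.events:
            if kind == DIAGNOSIS:
                diag_ages_all.append(a)
                if first:
                    diag_ages_first.append(a)
                    first = False
    death_arr = np.asarray(death_ages, dtype=float) if death_ages else np.zeros(0)

    limit = math.inf if open_final else boundaries[-1]
    for name, ages in (("deaths", death_arr), ("diagnoses", np.asarray(diag_ages_all))):
        if len(ages) and np.max(ages) >= limit:
            raise ValueError(f"{name} at age >= {limit:g}, beyond the closed band grid")

    def bin_events(ages: Iterable[float]) -> np.ndarray:
        arr = np.asarray(list(ages), dtype=float)
        if arr.size == 0:
            return np.zeros(len(bands))
        # boundary ages belong to the upper band
        idx = np.searchsorted(starts, arr, side="right") - 1
        return np.bincount(idx, minlength=len(bands)).astype(float)

    M = bin_events(death_arr)
    D = bin_events(cancer_death_ages)
    R_all = bin_events(diag_ages_all)
    R_first = bin_events(diag_ages_first)
    py = (
        _person_years_per_band(death_arr, boundaries, open_final)
        if len(death_arr)
        else np.zeros(len(bands))
    )

    widths = np.array([1.0 if b.is_open else b.width for b in bands])
    kwargs = dict(
        bands=bands,
        population=py / widths,
        deaths_all=M / widths,
        deaths_cancer=D / widths,
        sex=sex,
        site=site,
    )
    counts_all = AgeBandCountsTable(
        cases=R_all / widths, registration_mode=ALL_PRIMARIES, **kwargs
    )
    counts_first = AgeBandCountsTable(
        cases=R_first / widths, registration_mode=FIRST_PRIMARIES, **kwargs
    )
    return SimulatedRegistry(
        counts_all=counts_all,
        counts_first=counts_first,
        n_individuals=len(histories),
        seed=seed,
    )


def empirical_summaries(histories: Sequence[EventHistory]) -> dict[str, float]:
    """Lifetime summaries of a fully followed cohort.

    Returns ``p_first`` (fraction with at least one diagnosis),
    ``p_two_plus`` (fraction with two or more) and ``mean_primaries``
    (mean diagnosis count).  Raises if any history is censored — lifetime
    quantities are undefined without complete follow-up.
    """
    if any(h.censor_age is not None for h in histories):
        raise ValueError("censored histories present: lifetime summaries undefined")
    counts = np.array([h.n_diagnoses for h in histories])
    n = len(counts)
    if n == 0:
        return {"p_first": 0.0, "p_two_plus": 0.0, "mean_primaries": 0.0}
    return {
        "p_first": float(np.mean(counts >= 1)),
        "p_two_plus": float(np.mean(counts >= 2)),
        "mean_primaries": float(np.mean(counts)),
    }


# ---------------------------------------------------------------------------
# Hazard profiles for fixtures
# ---------------------------------------------------------------------------

def _default_grid(width: float = 1.0, cap: float = 90.0) -> tuple[AgeBand, ...]:
    return make_bands(np.arange(0.0, cap + width / 2, width), open_ended=True)


def _gompertz(mid: np.ndarray, floor: float, scale: float, slope: float) -> np.ndarray:
    return floor + scale * np.exp(slope * mid)


def _midpoints(bands: Sequence[AgeBand]) -> np.ndarray:
    # the open band takes the value 2.5 years past its start
    return np.array([b.start + (2.5 if b.is_open else b.width / 2) for b in bands])


def profile_model(profile: str, band_width: float = 1.0, cap: float = 90.0) -> MultiStateHazards:
    """Piecewise-constant hazard archetypes for the four fixture profiles.

    All use a Gompertz-type rise of incidence and background mortality
    with age, at magnitudes typical of an industrialised-country
    population (all-cancer incidence ~2%/yr and non-cancer mortality
    ~10%/yr in the mid-80s; see docs/methods.md):

    - ``baseline``: the equal-rates assumption holds exactly (prior
      cancer changes neither future incidence nor non-cancer mortality),
      with moderate cancer case fatality.
    - ``lung_like``: rarer but aggressive — high cancer fatality, clearly
      elevated repeat incidence and non-cancer mortality in survivors
      (shared-cause risk), yet few survivors to express them.
    - ``prostate_like``: no within-site repeat primaries at all, low
      fatality, incidence concentrated at old age.
    - ``breast_like``: doubled incidence after a first cancer with good
      survival — the setting where routine rates most overstate risk.
    """
    bands = _default_grid(band_width, cap)
    mid = _midpoints(bands)
    base_inc = _gompertz(mid, 0.0, 7e-5, 0.072)  # all-cancer-like incidence
    base_mort = _gompertz(mid, 3e-4, 2.5e-5, 0.095)  # non-cancer mortality
    if profile == "baseline":
        h0C, hCC = base_inc, base_inc
        h0X, hCX = base_mort, base_mort
        hCD = np.full_like(mid, 0.12)
    elif profile == "lung_like":
        h0C = 0.25 * base_inc
        hCC = 2.0 * h0C
        h0X = base_mort
        hCX = 3.0 * base_mort
        hCD = np.full_like(mid, 0.45)
    elif profile == "prostate_like":
        h0C = _gompertz(mid, 0.0, 3e-6, 0.10)
        hCC = np.zeros_like(mid)
        h0X, hCX = base_mort, base_mort
        hCD = np.full_like(mid, 0.02)
    elif profile == "breast_like":
        h0C = _gompertz(mid, 2e-5, 4.5e-4, 0.025)
        hCC = 2.0 * h0C
        h0X, hCX = base_mort, base_mort
        hCD = np.full_like(mid, 0.02)
    else:
        raise ValueError(f"unknown profile {profile!r}; valid: {sorted(PROFILES)}")
    return MultiStateHazards(bands=bands, h0C=h0C, h0X=h0X, hCC=hCC, hCD=hCD, hCX=hCX)


PROFILES = ("baseline", "lung_like", "prostate_like", "breast_like")


def make_fixture(
    profile: str,
    n: int = 100_000,
    seed: int = 0,
    *,
    band_width: float = 1.0,
    cap: float = 90.0,
) -> SimulatedRegistry:
    """Simulate a cohort under a named profile and aggregate it.

    The returned registry carries the generating model's true lifetime
    risk and expected primaries, so tests and the ``validate`` command
    can score estimators without re-deriving the truth.
    """
    model = profile_model(profile, band_width=band_width, cap=cap)
    histories = simulate_cohort(model, n, seed)
    reg = aggregate_registry(histories, model.bands, site=profile, seed=seed)
    return SimulatedRegistry(
        counts_all=reg.counts_all,
        counts_first=reg.counts_first,
        n_individuals=n,
        seed=seed,
        profile=profile,
        true_lifetime_risk=true_lifetime_risk(model),
        expected_primaries=expected_primaries(model),
    )
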