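"""Shared fixtures: random banded tables and session-scoped simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from amprisk import (
    AgeBandCountsTable,
    HazardTable,
    SimulatedRegistry,
    aggregate_registry,
    empirical_summaries,
    expected_primaries,
    make_bands,
    make_fixture,
    profile_model,
    simulate_cohort,
    true_lifetime_risk,
)

N_COHORT = 100_000  # default cohort size for stochastic recovery checks


def random_hazard_table(rng: np.random.Generator, n_bands: int = 18, width: float = 5.0) -> HazardTable:
    """Random piecewise-constant hazards on an open-ended banded grid."""
    bands = make_bands(np.arange(0.0, n_bands * width + width / 2, width))
    k = len(bands)
    lam_C = rng.uniform(0.0, 0.05, k)
    lam_X = rng.uniform(0.0, 0.08, k)
    lam_M = lam_X + rng.uniform(0.0, 0.02, k)  # cancer deaths on top of lam_X
    return HazardTable(bands=bands, lambda_C=lam_C, lambda_X=lam_X, lambda_M=lam_M)


def counts_from_hazards(h: HazardTable, population: float = 1e5) -> AgeBandCountsTable:
    """Counts table whose derived hazards reproduce ``h`` exactly."""
    n = np.full(h.n_bands, population)
    return AgeBandCountsTable(
        bands=h.bands,
        population=n,
        deaths_all=h.lambda_M * n,
        deaths_cancer=(h.lambda_M - h.lambda_X) * n,
        cases=h.lambda_C * n,
        sex=h.sex,
        site=h.site,
    )


@pytest.fixture(scope="session")
def baseline_sim():
    """One large baseline cohort shared by all recovery checks."""
    model = profile_model("baseline")
    histories = simulate_cohort(model, N_COHORT, seed=11)
    registry = aggregate_registry(histories, model.bands, seed=11)
    return {
        "model": model,
        "histories": histories,
        "registry": registry,
        "summaries": empirical_summaries(histories),
    }


@pytest.fixture(scope="session")
def profile_registries(baseline_sim):
    """Simulated registries (with sidecar truth) for all four hazard archetypes."""
    reg = baseline_sim["registry"]
    model = baseline_sim["model"]
    out = {
        "baseline": SimulatedRegistry(
            counts_all=reg.counts_all,
            counts_first=reg.counts_first,
            n_individuals=N_COHORT,
            seed=11,
            profile="baseline",
            true_lifetime_risk=true_lifetime_risk(model),
            expected_primaries=expected_primaries(model),
        )
    }
    for profile in ("lung_like", "prostate_like", "breast_like"):
        out[profile] = make_fixture(profile, n=N_COHORT, seed=11)
    return out
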