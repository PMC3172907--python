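"""Lifetime cancer-risk estimators on age-banded registry data.

Five methods, all driven by the same band-level hazards:

cumulative rate
    ``sum_i w_i * lambda_C,i`` up to a chosen age — a directly
    standardised rate, not a probability (it can exceed 1).

cumulative risk
    ``1 - exp(-cumulative rate)`` — a probability only under a
    single-event model with no competing mortality.  The folklore rule
    of thumb: a rate of '1 in x' corresponds to a risk of about
    '1 in (x + 1/2)'.

current probability (CP)
    Life-table method: apply the age-specific registration rate to
    all-cause survival ``S_all`` built from ``lambda_M``.  On routine
    (all-primaries) registry data this estimates the *mean number of
    primary tumours per lifetime*, which may exceed 1 and overstates the
    probability of ever getting cancer.

AMP (adjusted for multiple primaries)
    Applies the registration rate to a proxy survival
    ``S*(t) = exp(-int_0^t (lambda_C + lambda_X))`` that discounts both
    death and prior registration, so repeat primaries in the same person
    no longer inflate the estimate.  Always a probability in [0, 1].

gold standard
    The CP algorithm run on a first-primaries-only table; an excellent
    estimate of true lifetime risk when such data exist.

Within each band hazards are constant, so band contributions are
integrated exactly: for CP the band adds
``(lambda_C/lambda_M) * (S_all(a_i) - S_all(a_i+1))`` and for AMP
``(lambda_C/(lambda_C+lambda_X)) * (S*(a_i) - S*(a_i+1))``.  This
exact-within-band form is refinement-invariant (splitting bands changes
nothing when the underlying hazards are piecewise constant) and matches
the continuous-time definitions without quadrature error.  An open final
band contributes the closed-form tail of the constant-hazard integral to
infinity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .registry import (
    FIRST_PRIMARIES,
    AgeBandCountsTable,
    HazardTable,
    hazards_from_counts,
)

__all__ = [
    "LIFETIME",
    "RiskEstimate",
    "ProxySurvivalCurve",
    "cumulative_rate",
    "cumulative_risk",
    "one_in_x",
    "current_probability",
    "amp_estimate",
    "amp_proxy_survival",
    "gold_standard",
    "method_comparison",
    "format_percent",
]

#: sentinel upper age for full-lifetime estimates
LIFETIME = math.inf

_PROBABILITY_METHODS = {"cumulative_risk", "amp", "gold_standard"}


@dataclass(frozen=True)
class RiskEstimate:
    """A method-labelled risk value with its upper-age scope.

    ``value`` is a probability in [0, 1] for cumulative_risk, amp and
    gold_standard; cumulative_rate and current_probability are mean
    counts and may exceed 1.
    """

    method: str
    value: float
    upper_age: float  # inf == lifetime
    site: str = "all cancers"
    sex: str = "persons"

    def __post_init__(self) -> None:
        if self.method in _PROBABILITY_METHODS and not -1e-12 <= self.value <= 1 + 1e-12:
            raise ValueError(f"{self.method} produced value outside [0,1]: {self.value}")

    @property
    def percent(self) -> str:
        return format_percent(self.value)

    @property
    def one_in(self) -> str:
        return one_in_x(self.value)[1]


@dataclass(frozen=True)
class ProxySurvivalCurve:
    """S*(a_i) at band boundaries: probability-scale proxy for 'alive and not yet registered'."""

    knots: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "knots", k)
        object.__setattr__(self, "values", v)
        if k.shape != v.shape:
            raise ValueError("knots and values must align")
        if v[0] != 1.0:
            raise ValueError("S*(0) must be 1")
        if np.any(np.diff(v) > 1e-15) or np.any((v < -1e-15) | (v > 1 + 1e-15)):
            raise ValueError("S* must be non-increasing within [0, 1]")


def _as_hazards(table: AgeBandCountsTable | HazardTable) -> HazardTable:
    if isinstance(table, HazardTable):
        return table
    return hazards_from_counts(table)


def _bands_up_to(hazards: HazardTable, upper_age: float) -> int:
    """Number of leading bands covering [0, upper_age); errors off-boundary."""
    ends = [b.end for b in hazards.bands if not b.is_open]
    if upper_age in ends:
        return ends.index(upper_age) + 1
    lower = max([0.0] + [e for e in ends if e < upper_age], default=0.0)
    higher = min([e for e in ends if e > upper_age], default=None)
    raise ValueError(
        f"upper age {upper_age:g} is not a band boundary "
        f"(nearest: {lower:g}" + (f", {higher:g})" if higher is not None else ")")
    )


def cumulative_rate(
    hazards: HazardTable | AgeBandCountsTable, upper_age: float
) -> RiskEstimate:
    """Sum of width times age-specific registration rate up to ``upper_age``.

    ``upper_age`` must be a band boundary and all bands below it closed.
    """
    h = _as_hazards(hazards)
    if not math.isfinite(upper_age):
        raise ValueError("cumulative rate needs a finite upper age (it has no lifetime form)")
    k = _bands_up_to(h, upper_age)
    value = float(np.sum(h.widths[:k] * h.lambda_C[:k]))
    return RiskEstimate("cumulative_rate", value, upper_age, h.site, h.sex)


def cumulative_risk(cum_rate: float) -> float:
    """Convert a cumulative rate into a cumulative risk, ``1 - exp(-rate)``."""
    if cum_rate < 0:
        raise ValueError(f"cumulative rate must be >= 0, got {cum_rate}")
    return -math.expm1(-cum_rate)


def one_in_x(value: float, decimals: int = 1) -> tuple[float, str]:
    """Express a positive rate or risk as '1 in x', with x rounded for display."""
    if not value > 0:
        raise ValueError(f"'1 in x' needs a positive value, got {value}")
    x = 1.0 / value
    return x, f"1 in {x:.{decimals}f}"


def _lifetable_integral(
    h: HazardTable,
    attrition: np.ndarray,
    upper_age: float,
    *,
    rule: str = "exact",
) -> float:
    """Integrate lambda_C(u) * exp(-int attrition) band by band.

    ``attrition`` is the per-band hazard that depletes the survival curve
    (``lambda_M`` for CP, ``lambda_C + lambda_X`` for AMP).  Exact within
    bands by default; ``rule='trapezoid'`` averages the survival endpoints
    instead (a sensitivity check, not refinement-invariant).
    """
    if rule not in ("exact", "trapezoid"):
        raise ValueError(f"unknown rule {rule!r}")
    lifetime = not math.isfinite(upper_age)
    if lifetime:
        k = len([b for b in h.bands if not b.is_open])
        open_tail = h.bands[-1].is_open
    else:
        k = _bands_up_to(h, upper_age)
        open_tail = False

    total = 0.0
    S = 1.0
    for i in range(k):
        w = h.bands[i].width
        lam_c = h.lambda_C[i]
        a = attrition[i]
        S_next = S * math.exp(-a * w)
        if rule == "trapezoid":
            total += lam_c * w * 0.5 * (S + S_next)
        elif a > 0:
            total += (lam_c / a) * (S - S_next)
        else:  # no attrition: survival flat across the band
            total += lam_c * w * S
        S = S_next

    if lifetime and open_tail:
        lam_c = h.lambda_C[-1]
        a = attrition[-1]
        if lam_c > 0 and a <= 0:
            raise ValueError(
                f"open band {h.bands[-1]}: registration rate positive but no "
                "attrition hazard — the lifetime integral does not converge"
            )
        if a > 0:
            total += (lam_c / a) * S
    return total


def current_probability(
    table: AgeBandCountsTable | HazardTable,
    upper_age: float = LIFETIME,
    *,
    _method: str = "current_probability",
) -> RiskEstimate:
    """Life-table estimate: registration rate applied to all-cause survival.

    On an all-primaries table the result is the expected number of
    registrations per lifetime; values above 1 are legitimate and only
    warned about.
    """
    h = _as_hazards(table)
    value = _lifetable_integral(h, h.lambda_M, upper_age)
    if value > 1:
        warnings.warn(
            f"{_method} = {value:.4f} exceeds 1: it is a mean number of "
            "registrations, not a probability",
            stacklevel=2,
        )
        if _method == "gold_standard":
            value = min(value, 1.0)  # keep the probability-method invariant
    return RiskEstimate(_method, value, upper_age, h.site, h.sex)


def amp_estimate(
    table: AgeBandCountsTable | HazardTable,
    upper_age: float = LIFETIME,
    *,
    rule: str = "exact",
) -> RiskEstimate:
    """Adjusted-for-multiple-primaries lifetime risk.

    The registration rate is integrated against the proxy survival
    ``S* = exp(-int (lambda_C + lambda_X))``, so that both death and a
    prior registration remove a person from the at-risk pool.  The result
    is always a probability in [0, 1]; bands where both hazards vanish
    contribute 0 (the 0/0 ratio is taken as its continuity limit).
    """
    h = _as_hazards(table)
    value = _lifetable_integral(h, h.lambda_C + h.lambda_X, upper_age, rule=rule)
    return RiskEstimate("amp", min(value, 1.0), upper_age, h.site, h.sex)


def amp_proxy_survival(hazards: HazardTable | AgeBandCountsTable) -> ProxySurvivalCurve:
    """S* evaluated at every closed band boundary (and the open band start)."""
    h = _as_hazards(hazards)
    widths = h.widths
    k = len(widths)
    log_steps = -(h.lambda_C[:k] + h.lambda_X[:k]) * widths
    values = np.exp(np.concatenate([[0.0], np.cumsum(log_steps)]))
    knots = np.concatenate([[h.bands[0].start], [b.end for b in h.bands[:k]]])
    return ProxySurvivalCurve(knots=knots, values=values)


def gold_standard(
    first_primaries_counts: AgeBandCountsTable, upper_age: float = LIFETIME
) -> RiskEstimate:
    """CP algorithm on a first-primaries-only table — the reference estimate.

    Refuses all-primaries tables: running it on routine incidence silently
    reverts to the biased mean-count estimate.
    """
    if not isinstance(first_primaries_counts, AgeBandCountsTable):
        raise TypeError("gold_standard needs a counts table carrying its registration mode")
    if first_primaries_counts.registration_mode != FIRST_PRIMARIES:
        raise ValueError(
            "gold_standard requires registration_mode="
            f"{FIRST_PRIMARIES!r}, got {first_primaries_counts.registration_mode!r}"
        )
    return current_probability(first_primaries_counts, upper_age, _method="gold_standard")


def format_percent(value: float, decimals: int = 1) -> str:
    """Percentage string, rounding half away from zero at the displayed precision."""
    scaled = value * 100.0
    q = 10.0**decimals
    rounded = math.floor(abs(scaled) * q + 0.5) / q * math.copysign(1.0, scaled)
    return f"{rounded:.{decimals}f}"


def method_comparison(
    counts_all: AgeBandCountsTable,
    counts_first: AgeBandCountsTable | None = None,
    ages: Sequence[float] = (65, 75, 85, LIFETIME),
    *,
    percent_decimals: int = 1,
) -> pd.DataFrame:
    """Method-by-age grid of estimates, one row per (method, upper age).

    Cumulative rate/risk have no lifetime form and get NaN in lifetime
    columns; the gold standard row appears only when a first-primaries
    table is supplied (on identical bands).
    """
    if counts_first is not None and counts_first.bands != counts_all.bands:
        raise ValueError("all-primaries and first-primaries tables are on different bands")
    h = hazards_from_counts(counts_all)

    rows = []

    def add(est: RiskEstimate | None, method: str, age: float) -> None:
        value = math.nan if est is None else est.value
        rows.append(
            {
                "method": method,
                "sex": counts_all.sex,
                "site": counts_all.site,
                "upper_age": age,
                "value": value,
                "percent": "" if est is None else format_percent(value, percent_decimals),
                "one_in_x": "" if est is None or value <= 0 else one_in_x(value)[1],
            }
        )

    methods: list[str] = ["cumulative_rate", "cumulative_risk", "current_probability", "amp"]
    if counts_first is not None:
        methods.append("gold_standard")
    for method in methods:
        for age in ages:
            if method in ("cumulative_rate", "cumulative_risk") and not math.isfinite(age):
                add(None, method, age)
                continue
            if method == "cumulative_rate":
                est = cumulative_rate(h, age)
            elif method == "cumulative_risk":
                rate = cumulative_rate(h, age).value
                est = RiskEstimate("cumulative_risk", cumulative_risk(rate), age, h.site, h.sex)
            elif method == "current_probability":
                est = current_probability(counts_all, age)
            elif method == "amp":
                est = amp_estimate(counts_all, age)
            else:
                est = gold_standard(counts_first, age)
            add(est, method, age)
    return pd.DataFrame(rows)
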