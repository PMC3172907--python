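"""Age-banded registry count tables and their observable hazard rates.

Cancer registries publish sex-specific annual counts on contiguous age
bands: the mid-year population ``N_i``, all-cause deaths ``M_i``, cancer
deaths ``D_i`` and registered cancer cases ``R_i``.  This module provides
the validated in-memory containers for those extracts
(:class:`AgeBandCountsTable`), the CSV reader/writer, and the conversion
to per-person-year hazard rates (:class:`HazardTable`):

* cancer registration rate      ``lambda_C = R_i / N_i``
* non-cancer mortality rate     ``lambda_X = (M_i - D_i) / N_i``
* all-cause mortality rate      ``lambda_M = M_i / N_i``

Age bands are half-open intervals ``[start, end)`` in continuous years;
an event at an exact boundary age belongs to the upper band.  The final
band may be open-ended (``85+`` style), which lifetime-risk integrals
treat as extending to infinity with constant hazards.

The mid-year population is interpreted as person-years of exposure per
calendar year.  Multi-year period extracts (e.g. five pooled calendar
years) must be pre-averaged to an annual scale by the caller; counts are
therefore accepted as non-negative reals, not just integers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgeBand",
    "AgeBandCountsTable",
    "HazardTable",
    "ALL_PRIMARIES",
    "FIRST_PRIMARIES",
    "make_bands",
    "read_counts_csv",
    "write_counts_csv",
    "hazards_from_counts",
    "cap_final_band",
]

#: registration-mode labels
ALL_PRIMARIES = "all-primaries"
FIRST_PRIMARIES = "first-primaries-only"

_CSV_COLUMNS = ["age_start", "age_end", "population", "deaths_all", "deaths_cancer", "cases"]


@dataclass(frozen=True, order=True)
class AgeBand:
    """Half-open age interval ``[start, end)``; ``end=None`` marks the open final band."""

    start: float
    end: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"age band start must be >= 0, got {self.start}")
        if self.end is not None and not self.end > self.start:
            raise ValueError(f"age band end must exceed start: [{self.start}, {self.end})")

    @property
    def is_open(self) -> bool:
        return self.end is None

    @property
    def width(self) -> float:
        """Band width in years; undefined (raises) for the open band."""
        if self.end is None:
            raise ValueError(f"open band {self.start}+ has no width")
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.is_open:
            return f"{self.start:g}+"
        return f"{self.start:g}-{self.end:g}"


def validate_bands(bands: Sequence[AgeBand]) -> tuple[AgeBand, ...]:
    """Check contiguity: ascending, starting at 0, each end equal to the next start."""
    bands = tuple(bands)
    if not bands:
        raise ValueError("band list is empty")
    if bands[0].start != 0:
        raise ValueError(f"first band must start at age 0, got {bands[0].start}")
    for lo, hi in zip(bands, bands[1:]):
        if lo.is_open:
            raise ValueError(f"open band {lo} must be last")
        if lo.end != hi.start:
            raise ValueError(f"bands {lo} and {hi} are not contiguous")
    return bands


def make_bands(boundaries: Iterable[float], open_ended: bool = True) -> tuple[AgeBand, ...]:
    """Build contiguous bands from ascending boundaries ``[0, a_1, ..., a_K]``.

    With ``open_ended`` the final boundary opens an ``a_K+`` band; otherwise
    the table is capped at the last boundary.
    """
    bs = [float(b) for b in boundaries]
    bands = [AgeBand(lo, hi) for lo, hi in zip(bs, bs[1:])]
    if open_ended:
        bands.append(AgeBand(bs[-1], None))
    return validate_bands(bands)


def _as_array(values: Sequence[float], name: str, n: int) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have one value per band ({n}), got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class AgeBandCountsTable:
    """Registry extract: per-band annual counts and mid-year population.

    ``registration_mode`` records whether ``cases`` counts every primary
    tumour ('all-primaries', the routine registry convention) or only each
    person's first ('first-primaries-only', needed for the gold standard).

    ``site_mortality`` covers the common registry convention of publishing
    incidence for one grouping but mortality for a slightly different one
    (e.g. incidence excluding non-melanoma skin cancer while mortality
    includes it); a mismatch with ``site`` triggers a warning on
    construction, never an automatic correction.
    """

    bands: tuple[AgeBand, ...]
    population: np.ndarray  # N_i, mid-year persons (person-years / calendar year)
    deaths_all: np.ndarray  # M_i per year
    deaths_cancer: np.ndarray  # D_i per year
    cases: np.ndarray  # R_i per year
    sex: str = "persons"
    site: str = "all cancers"
    registration_mode: str = ALL_PRIMARIES
    site_mortality: str | None = None

    def __post_init__(self) -> None:
        bands = validate_bands(self.bands)
        object.__setattr__(self, "bands", bands)
        n = len(bands)
        for name in ("population", "deaths_all", "deaths_cancer", "cases"):
            arr = _as_array(getattr(self, name), name, n)
            object.__setattr__(self, name, arr)
            if np.any(arr < 0):
                i = int(np.argmax(arr < 0))
                raise ValueError(f"negative {name} in band {bands[i]}")
        if self.registration_mode not in (ALL_PRIMARIES, FIRST_PRIMARIES):
            raise ValueError(f"unknown registration_mode {self.registration_mode!r}")
        bad = self.deaths_cancer > self.deaths_all
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"band {bands[i]}: cancer deaths ({self.deaths_cancer[i]:g}) exceed "
                f"all-cause deaths ({self.deaths_all[i]:g})"
            )
        any_count = (self.deaths_all > 0) | (self.cases > 0)
        zero_pop = self.population <= 0
        if np.any(any_count & zero_pop):
            i = int(np.argmax(any_count & zero_pop))
            raise ValueError(f"band {bands[i]}: zero population but nonzero counts")
        if self.site_mortality is not None and self.site_mortality != self.site:
            warnings.warn(
                f"incidence site {self.site!r} and mortality site "
                f"{self.site_mortality!r} differ (e.g. the NMSC convention); "
                "rates mix two case definitions",
                stacklevel=3,
            )

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def boundaries(self) -> np.ndarray:
        """Closed boundaries ``a_0=0, ..., a_K`` (the open band start is the last)."""
        return np.array([b.start for b in self.bands] + ([] if self.bands[-1].is_open else [self.bands[-1].end]))

    def with_mode(self, mode: str) -> "AgeBandCountsTable":
        return replace(self, registration_mode=mode)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_start": [b.start for b in self.bands],
                "age_end": [b.end for b in self.bands],
                "population": self.population,
                "deaths_all": self.deaths_all,
                "deaths_cancer": self.deaths_cancer,
                "cases": self.cases,
            }
        )


@dataclass(frozen=True)
class HazardTable:
    """Piecewise-constant observable hazards per band (per person-year)."""

    bands: tuple[AgeBand, ...]
    lambda_C: np.ndarray
    lambda_X: np.ndarray
    lambda_M: np.ndarray | None = None  # defaults to lambda_X (no cancer deaths)
    sex: str = "persons"
    site: str = "all cancers"

    def __post_init__(self) -> None:
        bands = validate_bands(self.bands)
        object.__setattr__(self, "bands", bands)
        n = len(bands)
        object.__setattr__(self, "lambda_C", _as_array(self.lambda_C, "lambda_C", n))
        object.__setattr__(self, "lambda_X", _as_array(self.lambda_X, "lambda_X", n))
        if self.lambda_M is None:
            object.__setattr__(self, "lambda_M", self.lambda_X.copy())
        else:
            object.__setattr__(self, "lambda_M", _as_array(self.lambda_M, "lambda_M", n))
        for name in ("lambda_C", "lambda_X", "lambda_M"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"negative {name}")
        if np.any(self.lambda_M < self.lambda_X - 1e-12 * np.maximum(self.lambda_X, 1.0)):
            raise ValueError("all-cause hazard lambda_M below non-cancer hazard lambda_X")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def widths(self) -> np.ndarray:
        """Widths of the closed bands (open final band excluded)."""
        return np.array([b.width for b in self.bands if not b.is_open])


def hazards_from_counts(counts: AgeBandCountsTable) -> HazardTable:
    """Convert annual counts to per-person-year hazards, band by band.

    Bands with zero population (and, by table invariant, zero counts) get
    zero hazards with a warning: no exposure means the rate is unidentified.
    """
    N = counts.population
    zero = N <= 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} band(s) with zero population: hazards set to 0",
            stacklevel=2,
        )
    safe_N = np.where(zero, 1.0, N)
    lam_C = np.where(zero, 0.0, counts.cases / safe_N)
    lam_X = np.where(zero, 0.0, (counts.deaths_all - counts.deaths_cancer) / safe_N)
    lam_M = np.where(zero, 0.0, counts.deaths_all / safe_N)
    return HazardTable(
        bands=counts.bands,
        lambda_C=lam_C,
        lambda_X=lam_X,
        lambda_M=lam_M,
        sex=counts.sex,
        site=counts.site,
    )


def cap_final_band(counts: AgeBandCountsTable, cap: float) -> AgeBandCountsTable:
    """Merge all bands from ``cap`` upwards into a single open final band.

    Lets the same extract be analysed with an 85+ or 90+ tail: counts and
    population above the cap are pooled, so the tail hazards become the
    exposure-weighted averages of the merged bands.  ``cap`` must be an
    existing band boundary below the current final band.
    """
    starts = [b.start for b in counts.bands]
    if cap not in starts:
        raise ValueError(f"cap {cap:g} is not a band boundary (starts: {starts})")
    k = starts.index(cap)
    if k == len(counts.bands) - 1 and counts.bands[-1].is_open:
        return counts  # already capped there
    bands = tuple(list(counts.bands[:k]) + [AgeBand(cap, None)])

    def pooled(arr: np.ndarray) -> np.ndarray:
        return np.append(arr[:k], arr[k:].sum())

    return replace(
        counts,
        bands=bands,
        population=pooled(counts.population),
        deaths_all=pooled(counts.deaths_all),
        deaths_cancer=pooled(counts.deaths_cancer),
        cases=pooled(counts.cases),
    )


def _parse_age_end(value) -> float | None:
    if value is None or pd.isna(value):
        return None
    s = str(value).strip()
    if s in ("", "+", "open", "inf", "Inf"):
        return None
    if s.endswith("+"):
        return None
    return float(s)


def read_counts_csv(
    path: str | Path,
    *,
    per_100k: bool = False,
    sex: str = "persons",
    site: str = "all cancers",
    registration_mode: str = ALL_PRIMARIES,
    site_mortality: str | None = None,
) -> AgeBandCountsTable:
    """Read a registry extract from CSV.

    Expected header: ``age_start, age_end, population, deaths_all,
    deaths_cancer, cases``.  Rows may be in any order (sorted by
    ``age_start``); an empty or ``+`` ``age_end`` on the highest band marks
    it open-ended.

    With ``per_100k`` the three count columns are interpreted as rates per
    100 000 person-years rather than raw counts and are converted back to
    counts against the population column (``count = rate * N / 1e5``), so
    downstream hazards come out as ``rate / 1e5`` per person-year.
    """
    df = pd.read_csv(path, dtype={"age_end": "string"})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; expected {_CSV_COLUMNS}")
    df = df.sort_values("age_start", kind="stable").reset_index(drop=True)

    ends = [_parse_age_end(v) for v in df["age_end"]]
    bands = []
    for idx, (start, end) in enumerate(zip(df["age_start"], ends)):
        if end is None and idx != len(df) - 1:
            raise ValueError(f"{path}: row with age_start={start} is open-ended but not last")
        try:
            bands.append(AgeBand(float(start), end))
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx}: {exc}") from exc

    pop = df["population"].to_numpy(dtype=float)
    counts = {c: df[c].to_numpy(dtype=float) for c in ("deaths_all", "deaths_cancer", "cases")}
    if per_100k:
        for c in counts:
            counts[c] = counts[c] * pop / 1e5

    try:
        return AgeBandCountsTable(
            bands=tuple(bands),
            population=pop,
            deaths_all=counts["deaths_all"],
            deaths_cancer=counts["deaths_cancer"],
            cases=counts["cases"],
            sex=sex,
            site=site,
            registration_mode=registration_mode,
            site_mortality=site_mortality,
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_counts_csv(counts: AgeBandCountsTable, path: str | Path) -> None:
    """Write a table back to the CSV schema; the open band gets an empty age_end."""
    df = counts.to_frame()
    df["age_end"] = ["" if e is None else f"{e:g}" for e in df["age_end"]]
    df.to_csv(path, index=False)
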