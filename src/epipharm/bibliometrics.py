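"""Citation-trend statistics and the citation-expectation model.

A publication cohort observed Δt years after publication has accrued only
part of the citations it will eventually collect.  Citation accrual is
modelled as a saturating exponential

    C(t) = N * (1 - exp(-t / beta)),

where N is the eventual total and beta is the discipline-specific time (in
years) for an article to reach 63% (1 - 1/e) of its total citations.
Inverting the model at the observed mean extrapolates the cohort's expected
eventual citations:

    <N_cit> = n_mean / (1 - exp(-dt / beta)).

Two discipline presets are provided: biochemistry / molecular biology
(beta = 5.4 y) and pharmacology (beta = 7.1 y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: Discipline constants: years to reach 63% of eventual citations.
BETA_BIOCHEMISTRY = 5.4
BETA_PHARMACOLOGY = 7.1


@dataclass(frozen=True)
class CitationObservation:
    """Mean cumulative citations of a cohort, Δt years after publication."""

    mean_cumulative_citations: float
    years_since_publication: float

    def __post_init__(self) -> None:
        if self.years_since_publication <= 0:
            raise ValueError("years_since_publication must be > 0")
        if self.mean_cumulative_citations < 0:
            raise ValueError("mean_cumulative_citations must be >= 0")

    @property
    def reported_mean(self) -> int:
        """Display value: the mean truncated toward zero (tabular convention)."""
        return math.trunc(self.mean_cumulative_citations)


@dataclass(frozen=True)
class CitationModel:
    """Saturating citation-accrual model with discipline constant beta (years)."""

    beta: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


MODEL_BIOCHEMISTRY = CitationModel(beta=BETA_BIOCHEMISTRY, label="biochemistry")
MODEL_PHARMACOLOGY = CitationModel(beta=BETA_PHARMACOLOGY, label="pharmacology")


def expected_total_citations(obs: CitationObservation, model: CitationModel) -> float:
    """Expected eventual citations <N_cit> = mean / (1 - exp(-dt/beta)).

    Always >= the observed mean; the exact value is returned, rounding to
    integer being a display concern of the caller.
    """
    dt = obs.years_since_publication
    if dt <= 0 or model.beta <= 0:
        raise ValueError("years_since_publication and beta must be > 0")
    return obs.mean_cumulative_citations / (1.0 - math.exp(-dt / model.beta))


def mean_cumulative_citations(
    counts: Sequence[int], years_since_publication: float
) -> CitationObservation:
    """Average the cumulative citation counts of one publication-year cohort."""
    if len(counts) == 0:
        raise ValueError("cannot average an empty citation collection")
    return CitationObservation(
        mean_cumulative_citations=float(np.mean(counts)),
        years_since_publication=years_since_publication,
    )


def citation_trend(
    records,
    models: Sequence[CitationModel],
    query_year: int,
) -> pd.DataFrame:
    """Per-publication-year observed mean citations plus model expectations.

    ``records`` are publication records with ``year`` and
    ``cumulative_citations``; Δt for a cohort is ``query_year - year`` (whole
    years).  Years with no publications are omitted; the ``query_year``
    itself is skipped since Δt would be zero.  One ``expected_<label>``
    column is produced per model.
    """
    by_year: dict[int, list[int]] = {}
    for r in records:
        by_year.setdefault(r.year, []).append(r.cumulative_citations)
    rows = []
    for year in sorted(by_year):
        dt = query_year - year
        if dt <= 0:
            continue
        obs = mean_cumulative_citations(by_year[year], dt)
        row = {
            "year": year,
            "n_publications": len(by_year[year]),
            "delta_t": dt,
            "observed_mean": obs.mean_cumulative_citations,
        }
        for model in models:
            label = model.label or f"beta_{model.beta}"
            row[f"expected_{label}"] = expected_total_citations(obs, model)
        rows.append(row)
    return pd.DataFrame(rows)


def fit_beta(
    times: Sequence[float], cumulative: Sequence[float]
) -> tuple[float, float]:
    """Least-squares fit of C(t) = N (1 - exp(-t/beta)); returns (N, beta).

    Requires at least three time points.  A non-monotone series triggers a
    warning (noise is expected to be mild); a constant series is degenerate
    and rejected.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(cumulative, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points to fit the accrual model")
    if np.ptp(c) == 0:
        raise ValueError("degenerate (constant) citation series")
    if np.any(np.diff(c[np.argsort(t)]) < 0):
        import warnings

        warnings.warn("cumulative citation series is not monotone", stacklevel=2)

    def model(tt, n_total, beta):
        return n_total * (1.0 - np.exp(-tt / beta))

    n0 = float(c.max())
    beta0 = max(float(t.mean()), 1.0)
    popt, _ = curve_fit(model, t, c, p0=(n0, beta0), maxfev=20000)
    return float(popt[0]), float(popt[1])


@dataclass(frozen=True)
class CountryNormalization:
    country: str
    hit_count: int
    denominator: float
    normalized_rate: float


def normalize_country_counts(
    hits: Mapping[str, int],
    denominator_table: Mapping[str, float] | pd.DataFrame,
    mode: str = "per_capita",
) -> tuple[list[CountryNormalization], list[str]]:
    """Normalize per-country publication hits by population or national output.

    ``denominator_table`` is either a mapping country -> denominator, or a
    DataFrame: for ``per_capita`` a (country, year, population) long table
    whose per-country mean population over the listed years is used; for
    ``per_output`` a (country, publications) table.  Countries lacking a
    denominator are excluded and returned as warnings.  The result is ranked
    by decreasing normalized rate.
    """
    if mode not in ("per_capita", "per_output"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if isinstance(denominator_table, pd.DataFrame):
        if mode == "per_capita":
            denom = denominator_table.groupby("country")["population"].mean().to_dict()
        else:
            denom = denominator_table.set_index("country")["publications"].to_dict()
    else:
        denom = dict(denominator_table)
    results: list[CountryNormalization] = []
    warnings_out: list[str] = []
    for country, n in hits.items():
        d = denom.get(country)
        if d is None or d <= 0:
            warnings_out.append(f"{country}: no usable denominator; excluded")
            continue
        results.append(
            CountryNormalization(
                country=country,
                hit_count=n,
                denominator=float(d),
                normalized_rate=n / float(d),
            )
        )
    results.sort(key=lambda r: (-r.normalized_rate, r.country))
    return results, warnings_out
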