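"""Descriptive mapping metrics for a filtered trial registry.

Implements the country-level and group-level summaries used to map a registry:
trial density (trials per million inhabitants, reported only for countries with
more than 250,000 inhabitants), sponsorship and internationality shares
(reported only for countries with at least 50 trials in the relevant
denominator), geographic scope of each trial, and annual distributions of
country trial locations over regions or income groups.

Counting convention: an international trial contributes one count to *each* of
its countries, so a trial run simultaneously in two South American countries
counts twice toward South America's share of locations.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

from .registry import INDUSTRY, NON_INDUSTRY, CountryTable, TrialRecord

POPULATION_THRESHOLD = 250_000  # density reported only above this population
TRIALS_THRESHOLD = 50  # shares reported only at or above this many trials

SINGLE_COUNTRY = "single_country"
INTERNATIONAL_UNICONTINENTAL = "international_unicontinental"
INTERNATIONAL_INTERCONTINENTAL = "international_intercontinental"

Grouping = Literal["income_group", "region"]


@dataclass(frozen=True)
class DensityRecord:
    country: str
    n_trials: int
    density: float  # trials per million inhabitants
    eligible: bool  # population above the reporting threshold


@dataclass(frozen=True)
class ShareRecord:
    country: str
    numerator: int
    denominator: int
    share: float | None  # None when the denominator is zero
    reportable: bool  # denominator at or above the 50-trial threshold


@dataclass(frozen=True)
class AnnualDistribution:
    year: int
    grouping: Grouping
    shares: Mapping[str, float]  # group -> share of country locations
    n_locations: int


def trial_density(n_trials: int, population: int) -> float:
    """Trials per million inhabitants."""
    if population <= 0:
        raise ValueError("population must be positive")
    return n_trials * 1e6 / population


def country_trial_counts(records: Iterable[TrialRecord]) -> Counter:
    """Number of trials per country (each trial counts once per location)."""
    counts: Counter = Counter()
    for rec in records:
        counts.update(rec.countries)
    return counts


def density_table(records: Iterable[TrialRecord], table: CountryTable) -> list[DensityRecord]:
    counts = country_trial_counts(records)
    out = []
    for info in sorted(table, key=lambda c: c.code):
        n = counts.get(info.code, 0)
        out.append(
            DensityRecord(
                country=info.code,
                n_trials=n,
                density=trial_density(n, info.population_2012),
                eligible=info.population_2012 > POPULATION_THRESHOLD,
            )
        )
    return out


def group_median_density(
    densities: Iterable[DensityRecord], table: CountryTable, grouping: Grouping = "income_group"
) -> dict[str, float]:
    """Median density across countries within each group (eligible countries only).

    Countries are weighted equally; an even-sized group's median is the midpoint
    of the two central values.  Empty groups are absent from the result.
    """
    per_group: dict[str, list[float]] = {}
    for rec in densities:
        if not rec.eligible:
            continue
        group = getattr(table[rec.country], grouping)
        per_group.setdefault(group, []).append(rec.density)
    return {g: statistics.median(vals) for g, vals in per_group.items()}


def classify_scope(record: TrialRecord, table: CountryTable) -> str:
    """Single-country / international within one continent / intercontinental."""
    continents = set()
    for code in record.countries:
        if code not in table:
            raise KeyError(f"country {code} has no continent assignment")
        continents.add(table[code].continent)
    if len(record.countries) == 1:
        return SINGLE_COUNTRY
    return INTERNATIONAL_UNICONTINENTAL if len(continents) == 1 else INTERNATIONAL_INTERCONTINENTAL


def sponsorship_share(records: Iterable[TrialRecord], country: str) -> ShareRecord:
    """Share of industry-sponsored trials among all trials located in ``country``."""
    total = 0
    industry = 0
    for rec in records:
        if country in rec.countries:
            total += 1
            if rec.sponsor_type == INDUSTRY:
                industry += 1
    return ShareRecord(
        country=country,
        numerator=industry,
        denominator=total,
        share=industry / total if total else None,
        reportable=total >= TRIALS_THRESHOLD,
    )


def international_share(
    records: Iterable[TrialRecord], country: str, sponsor_type: str
) -> ShareRecord:
    """Share of international trials among ``sponsor_type`` trials in ``country``.

    The 50-trial reporting threshold applies to the sponsor-specific
    denominator, matching the mapping convention of per-sponsor analyses.
    """
    total = 0
    international = 0
    for rec in records:
        if country in rec.countries and rec.sponsor_type == sponsor_type:
            total += 1
            if rec.is_international:
                international += 1
    return ShareRecord(
        country=country,
        numerator=international,
        denominator=total,
        share=international / total if total else None,
        reportable=total >= TRIALS_THRESHOLD,
    )


def annual_distribution(
    records: Iterable[TrialRecord],
    table: CountryTable,
    grouping: Grouping = "region",
    sponsor_type: str | None = None,
    first_year: int = 2006,
    last_year: int = 2012,
) -> list[AnnualDistribution]:
    """Yearly distribution of country trial locations over regions/income groups.

    Every country location of every trial counts individually; shares within a
    year sum to one (years with no locations are omitted).
    """
    per_year: dict[int, Counter] = {}
    for rec in records:
        if rec.start_year is None or not first_year <= rec.start_year <= last_year:
            continue
        if sponsor_type is not None and rec.sponsor_type != sponsor_type:
            continue
        counter = per_year.setdefault(rec.start_year, Counter())
        for code in rec.countries:
            counter[getattr(table[code], grouping)] += 1
    out = []
    for year in sorted(per_year):
        counter = per_year[year]
        total = sum(counter.values())
        out.append(
            AnnualDistribution(
                year=year,
                grouping=grouping,
                shares={g: c / total for g, c in sorted(counter.items())},
                n_locations=total,
            )
        )
    return out


def intercontinental_share_by_year(
    records: Iterable[TrialRecord],
    table: CountryTable,
    sponsor_type: str,
    first_year: int = 2006,
    last_year: int = 2012,
) -> dict[int, float]:
    """Among international trials of a sponsor type, the yearly share spanning >1 continent."""
    totals: Counter = Counter()
    inter: Counter = Counter()
    for rec in records:
        if rec.start_year is None or not first_year <= rec.start_year <= last_year:
            continue
        if rec.sponsor_type != sponsor_type or not rec.is_international:
            continue
        totals[rec.start_year] += 1
        if classify_scope(rec, table) == INTERNATIONAL_INTERCONTINENTAL:
            inter[rec.start_year] += 1
    return {y: inter[y] / totals[y] for y in sorted(totals)}


def mapping_summary(records: list[TrialRecord], table: CountryTable) -> dict:
    """Headline mapping numbers for a filtered registry."""
    n = len(records)
    by_sponsor = Counter(r.sponsor_type for r in records)
    intl = [r for r in records if r.is_international]
    intl_by_sponsor = Counter(r.sponsor_type for r in intl)
    scope = Counter(classify_scope(r, table) for r in records)

    def _share(num: int, den: int) -> float | None:
        return num / den if den else None

    medians = {
        st: (statistics.median([r.n_countries for r in intl if r.sponsor_type == st]) if any(
            r.sponsor_type == st for r in intl) else None)
        for st in (INDUSTRY, NON_INDUSTRY)
    }
    return {
        "n_trials": n,
        "industry_fraction": _share(by_sponsor[INDUSTRY], n),
        "international_fraction": _share(len(intl), n),
        "international_share_industry": _share(intl_by_sponsor[INDUSTRY], by_sponsor[INDUSTRY]),
        "international_share_non_industry": _share(
            intl_by_sponsor[NON_INDUSTRY], by_sponsor[NON_INDUSTRY]
        ),
        "median_countries_per_international_trial": medians,
        "intercontinental_share_among_international": _share(
            scope[INTERNATIONAL_INTERCONTINENTAL], len(intl)
        ),
    }


def density_frame(densities: Iterable[DensityRecord]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in densities])


def shares_frame(shares: Iterable[ShareRecord]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in shares])


def annual_frame(dists: Iterable[AnnualDistribution]) -> pd.DataFrame:
    rows = []
    for d in dists:
        for group, share in d.shares.items():
            rows.append(
                {"year": d.year, "grouping": d.grouping, "group": group, "share": share,
                 "n_locations": d.n_locations}
            )
    return pd.DataFrame(rows)
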