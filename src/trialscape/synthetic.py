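"""Synthetic trial registries with the statistical structure the pipeline assumes.

The generator emulates an ICTRP-style extract: per-country trial volumes
scale with population and differ by World Bank income group; the sponsor mix
varies by income group; industry-sponsored trials are international far more
often than non-industry ones (defaults 30% vs 3%); international trials
involve a shifted-geometric number of countries with median two (industry)
and five (non-industry); and optional *blocks* of countries co-participate
more than expected by a tunable affinity multiplier — the planted signal that
the null model should recover.

Default rates are the per-income-group median densities and industry shares
of the mapped 2006-2013 registry landscape, so a registry generated at
``rate_scale=1`` over the bundled 41-country table reproduces realistic
volumes; tests and examples scale the rate down.

The module also enumerates *fill classes* (all binary matrices with given
margins) by backtracking, the exact oracle for the permutation null model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .collaboration import IncidenceMatrix
from .registry import (
    INDUSTRY,
    NON_INDUSTRY,
    CountryInfo,
    CountryTable,
    TrialRecord,
    load_country_table,
)

DEFAULT_RATE_PER_MILLION = {  # expected trials per million inhabitants, 2006-2013
    "high": 116.0,
    "upper_middle": 13.8,
    "lower_middle": 1.8,
    "low": 1.1,
}
DEFAULT_INDUSTRY_FRACTION = {  # share of industry-sponsored trials by income group
    "high": 0.516,
    "upper_middle": 0.66,
    "lower_middle": 0.654,
    "low": 0.093,
}
DEFAULT_P_INTERNATIONAL = {INDUSTRY: 0.30, NON_INDUSTRY: 0.03}
# countries per international trial: K = 1 + Geometric(p), support {2, 3, ...};
# median(K) = 2 for p in (0.5, 1], = 5 for p in (0.159, 0.206); interior values
# keep the sample median stable
DEFAULT_K_GEOMETRIC_P = {INDUSTRY: 0.55, NON_INDUSTRY: 0.18}

_INDUSTRY_NAMES = ("{} Pharmaceuticals Inc.", "{} Biotech Ltd.", "{} Therapeutics Corp.")
_NON_INDUSTRY_NAMES = ("University of {}", "{} Research Institute", "{} National Hospital")
_SYLLABLES = ("Alva", "Boreal", "Cedra", "Dolm", "Ekto", "Fennor", "Galen", "Hestia")


@dataclass(frozen=True)
class Block:
    """Countries that co-participate ``affinity`` times more than size predicts."""

    members: frozenset[str]
    affinity: float

    def __post_init__(self) -> None:
        if self.affinity < 1:
            raise ValueError("affinity multiplier must be >= 1")


@dataclass(frozen=True)
class SyntheticConfig:
    countries: tuple[CountryInfo, ...]
    years: tuple[int, int] = (2006, 2013)
    rate_per_million: dict = field(default_factory=lambda: dict(DEFAULT_RATE_PER_MILLION))
    rate_scale: float = 1.0
    industry_fraction: dict = field(default_factory=lambda: dict(DEFAULT_INDUSTRY_FRACTION))
    p_international: dict = field(default_factory=lambda: dict(DEFAULT_P_INTERNATIONAL))
    k_geometric_p: dict = field(default_factory=lambda: dict(DEFAULT_K_GEOMETRIC_P))
    blocks: tuple[Block, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.countries:
            raise ValueError("config needs at least one country")
        codes = [c.code for c in self.countries]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate country codes in config")
        for st, p in self.p_international.items():
            if not 0 <= p <= 1:
                raise ValueError(f"p_international[{st}] outside [0, 1]")


def default_config(**overrides) -> SyntheticConfig:
    """A config over the bundled 41-country metadata table."""
    table = load_country_table()
    return SyntheticConfig(countries=tuple(sorted(table, key=lambda c: c.code)), **overrides)


def _partner_weights(config: SyntheticConfig, anchor: str, codes: Sequence[str], size_w: np.ndarray) -> np.ndarray:
    w = size_w.copy()
    for block in config.blocks:
        if anchor in block.members:
            for j, code in enumerate(codes):
                if code != anchor and code in block.members:
                    w[j] *= block.affinity
    return w


def generate_registry(config: SyntheticConfig, seed: int | None = None) -> list[TrialRecord]:
    """Draw a synthetic registry; identical output for identical config and seed.

    Per country, the number of anchored trials is Poisson with mean
    rate_per_million[income] * population_millions * rate_scale.  Each trial
    gets a sponsor type (income-group mix), a uniform start year, and is
    international with the sponsor's probability, in which case K - 1 partner
    countries are drawn without replacement with probability proportional to
    sqrt(population in millions), boosted by the block affinity for partners
    sharing a block with the anchor country.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    countries = sorted(config.countries, key=lambda c: c.code)
    codes = [c.code for c in countries]
    pop_m = np.array([c.population_2012 / 1e6 for c in countries])
    size_w = np.sqrt(pop_m)

    records: list[TrialRecord] = []
    trial_no = 0
    for idx, info in enumerate(countries):
        mean = config.rate_per_million[info.income_group] * pop_m[idx] * config.rate_scale
        n_trials = rng.poisson(mean)
        for _ in range(n_trials):
            trial_no += 1
            sponsor = (
                INDUSTRY
                if rng.random() < config.industry_fraction[info.income_group]
                else NON_INDUSTRY
            )
            year = int(rng.integers(config.years[0], config.years[1] + 1))
            members = {info.code}
            if rng.random() < config.p_international[sponsor]:
                k = 1 + int(rng.geometric(config.k_geometric_p[sponsor]))
                k = min(k, len(codes))
                weights = _partner_weights(config, info.code, codes, size_w)
                weights[idx] = 0.0
                weights = weights / weights.sum()
                partners = rng.choice(len(codes), size=k - 1, replace=False, p=weights)
                members.update(codes[j] for j in partners)
            template_pool = _INDUSTRY_NAMES if sponsor == INDUSTRY else _NON_INDUSTRY_NAMES
            name = template_pool[int(rng.integers(len(template_pool)))].format(
                _SYLLABLES[int(rng.integers(len(_SYLLABLES)))]
            )
            records.append(
                TrialRecord(
                    trial_id=f"SYN{trial_no:07d}",
                    start_year=year,
                    sponsor_type=sponsor,
                    countries=frozenset(members),
                    sponsor_name=name,
                )
            )
    return records


def synthetic_country_table(n: int, seed: int = 0, population_range=(1e6, 150e6)) -> CountryTable:
    """A purely synthetic country table of ``n`` countries (codes C00, C01, ...).

    Used when an analysis needs more countries than the bundled real-world
    table, e.g. large calibration matrices.  Income groups and regions cycle
    deterministically; populations are log-uniform.
    """
    rng = np.random.default_rng(seed)
    incomes = ("high", "upper_middle", "lower_middle", "low")
    regions = (
        ("Western Europe", "Europe"),
        ("Eastern Europe", "Europe"),
        ("North America", "North America"),
        ("South America", "South America"),
        ("Asia", "Asia"),
        ("Africa", "Africa"),
        ("Oceania", "Oceania"),
    )
    lo, hi = np.log(population_range[0]), np.log(population_range[1])
    infos = []
    for i in range(n):
        region, continent = regions[i % len(regions)]
        infos.append(
            CountryInfo(
                code=f"C{i:02d}" if n <= 100 else f"C{i:03d}",
                name=f"Synthetica {i}",
                population_2012=int(np.exp(rng.uniform(lo, hi))),
                income_group=incomes[i % len(incomes)],
                region=region,
                continent=continent,
            )
        )
    return CountryTable(infos)


# ---------------------------------------------------------------------------
# fill-class enumeration (exact oracle for the fixed-margin null model)
# ---------------------------------------------------------------------------


class FillClassTooLarge(RuntimeError):
    pass


def enumerate_fill_class(data: np.ndarray, max_size: int = 100_000) -> list[np.ndarray]:
    """All binary matrices with the row and column sums of ``data``.

    Backtracking row by row over column subsets, pruning branches whose
    remaining column sums cannot be realized.  Raises FillClassTooLarge when
    more than ``max_size`` matrices exist.
    """
    data = np.asarray(data, dtype=np.int64)
    n_rows, n_cols = data.shape
    row_sums = data.sum(axis=1)
    col_sums = data.sum(axis=0)
    results: list[np.ndarray] = []
    current = np.zeros_like(data)

    def recurse(r: int, remaining: np.ndarray) -> None:
        if r == n_rows:
            if (remaining == 0).all():
                results.append(current.copy())
                if len(results) > max_size:
                    raise FillClassTooLarge(f"fill class exceeds {max_size}")
            return
        rows_left = n_rows - r - 1
        candidates = [j for j in range(n_cols) if remaining[j] > 0]
        need = int(row_sums[r])
        if len(candidates) < need:
            return
        for subset in itertools.combinations(candidates, need):
            for j in subset:
                remaining[j] -= 1
            # prune: no remaining column may need more rows than are left
            if remaining.max(initial=0) <= rows_left and remaining.sum() == row_sums[r + 1 :].sum():
                for j in subset:
                    current[r, j] = 1
                recurse(r + 1, remaining)
                for j in subset:
                    current[r, j] = 0
            for j in subset:
                remaining[j] += 1

    recurse(0, col_sums.copy())
    return results


def generate_fill_class_fixture(
    n_rows: int = 3, n_cols: int = 3, seed: int = 0, max_size: int = 100_000
) -> tuple[IncidenceMatrix, list[np.ndarray]]:
    """A small random incidence matrix plus its exhaustively enumerated fill class."""
    rng = np.random.default_rng(seed)
    while True:
        data = np.zeros((n_rows, n_cols), dtype=np.uint8)
        for r in range(n_rows):
            # full rows are invariant under any trade; keep k < n_cols so the
            # class is non-trivial
            k = int(rng.integers(2, max(n_cols, 3)))
            cols = rng.choice(n_cols, size=k, replace=False)
            data[r, cols] = 1
        if (data.sum(axis=0) > 0).all() and len(enumerate_fill_class(data, max_size=max_size)) > 1:
            break
    matrix = IncidenceMatrix(
        trial_ids=tuple(f"T{r}" for r in range(n_rows)),
        countries=tuple(chr(ord("A") + j) for j in range(n_cols)),
        data=data,
    )
    return matrix, enumerate_fill_class(data, max_size=max_size)


def exact_pair_distributions(fill_class: Iterable[np.ndarray]) -> dict[tuple[int, int], np.ndarray]:
    """Exact null distribution of co-occurrence per column pair, as histograms.

    Uniform over the fill class: histogram[v] = number of class members in
    which the pair co-occurs in exactly v rows.
    """
    matrices = list(fill_class)
    n_cols = matrices[0].shape[1]
    out: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n_cols):
        for j in range(i + 1, n_cols):
            values = [int((m[:, i] * m[:, j]).sum()) for m in matrices]
            hist = np.bincount(values, minlength=max(values) + 1)
            out[(i, j)] = hist
    return out
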