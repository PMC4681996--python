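"""Registry ingestion: parsing, sponsor classification, filtering, deduplication.

Trial registries (ICTRP-style exports) arrive as flat tables with one row per
registered trial carrying a unique identifier, a start date, a free-text primary
sponsor and a delimited list of country locations.  This module turns such a
table into validated :class:`TrialRecord` objects, classifies the primary
sponsor as industry vs non-industry from a keyword list, restricts to a study
period, and deduplicates on the trial identifier.

Country names are resolved against a bundled metadata table (2012 populations,
World Bank income groups, geographic regions and continents) extended by an
editable alias list; locations that cannot be resolved are dropped from the
trial (and reported), the trial itself only when no location survives.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

INDUSTRY = "industry"
NON_INDUSTRY = "non_industry"
UNKNOWN = "unknown"
SPONSOR_TYPES = (INDUSTRY, NON_INDUSTRY, UNKNOWN)

INCOME_GROUPS = ("high", "upper_middle", "lower_middle", "low")
REGIONS = (
    "Western Europe",
    "Eastern Europe",
    "North America",
    "South America",
    "Asia",
    "Africa",
    "Oceania",
)

_YEAR_RE = re.compile(r"(?:19|20)\d{2}")


@dataclass(frozen=True)
class TrialRecord:
    """One registered clinical trial.

    ``countries`` is a frozenset of ISO 3166-1 alpha-2 codes; a trial is
    *international* iff it has locations in at least two countries.
    """

    trial_id: str
    start_year: int | None
    sponsor_type: str
    countries: frozenset[str]
    sponsor_name: str | None = None

    def __post_init__(self) -> None:
        if self.sponsor_type not in SPONSOR_TYPES:
            raise ValueError(f"invalid sponsor_type {self.sponsor_type!r}")

    @property
    def is_international(self) -> bool:
        return len(self.countries) >= 2

    @property
    def n_countries(self) -> int:
        return len(self.countries)


@dataclass(frozen=True)
class CountryInfo:
    """Static per-country metadata (population and classifications as of 2012)."""

    code: str
    name: str
    population_2012: int
    income_group: str
    region: str
    continent: str

    def __post_init__(self) -> None:
        if self.population_2012 <= 0:
            raise ValueError(f"{self.code}: population must be positive")
        if self.income_group not in INCOME_GROUPS:
            raise ValueError(f"{self.code}: bad income group {self.income_group!r}")


class CountryTable:
    """Lookup of country metadata plus name/alias -> ISO code resolution."""

    def __init__(self, countries: Iterable[CountryInfo], aliases: Mapping[str, str] | None = None):
        self._by_code: dict[str, CountryInfo] = {}
        self._by_name: dict[str, str] = {}
        for info in countries:
            if info.code in self._by_code:
                raise ValueError(f"duplicate country code {info.code}")
            self._by_code[info.code] = info
            self._by_name[info.name.strip().lower()] = info.code
        if aliases:
            for alias, code in aliases.items():
                self._by_name.setdefault(alias.strip().lower(), code)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> CountryInfo:
        return self._by_code[code]

    def __iter__(self):
        return iter(self._by_code.values())

    def __len__(self) -> int:
        return len(self._by_code)

    @property
    def codes(self) -> list[str]:
        return sorted(self._by_code)

    def resolve(self, name_or_code: str) -> str | None:
        """Resolve a country name, alias or ISO code; None when unresolvable.

        A resolved alias pointing at a country missing from the metadata table
        (e.g. an alias file broader than the table) also returns None: every
        downstream computation needs the population/classification row.
        """
        token = name_or_code.strip()
        if not token:
            return None
        if len(token) == 2 and token.upper() in self._by_code:
            return token.upper()
        code = self._by_name.get(token.lower())
        if code is not None and code in self._by_code:
            return code
        return None

    def add_aliases(self, aliases: Mapping[str, str]) -> None:
        for alias, code in aliases.items():
            self._by_name[alias.strip().lower()] = code


def load_country_table(
    path: str | Path | None = None, alias_path: str | Path | None = None
) -> CountryTable:
    """Load the bundled (or a user-supplied) country metadata table."""
    if path is None:
        source = resources.files("trialscape.data").joinpath("countries.csv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    countries = [
        CountryInfo(
            code=row["code"].strip(),
            name=row["name"].strip(),
            population_2012=int(row["population_2012"]),
            income_group=row["income_group"].strip(),
            region=row["region"].strip(),
            continent=row["continent"].strip(),
        )
        for row in csv.DictReader(text.splitlines())
    ]
    if alias_path is None:
        alias_text = (
            resources.files("trialscape.data").joinpath("country_aliases.csv").read_text("utf-8")
        )
    else:
        alias_text = Path(alias_path).read_text(encoding="utf-8")
    aliases = {row["alias"]: row["code"] for row in csv.DictReader(alias_text.splitlines())}
    return CountryTable(countries, aliases)


@dataclass(frozen=True)
class SponsorKeywordConfig:
    """Keyword lists for industry vs non-industry sponsor classification.

    Tokens of at most ``short_token_max`` characters are matched with word
    boundaries (letters may not touch the token on either side), so "inc"
    matches "Acme Pharma Inc." but not "Provincial"; longer keywords use plain
    case-insensitive substring matching.
    """

    industry_keywords: tuple[str, ...]
    non_industry_keywords: tuple[str, ...]
    short_token_max: int = 4

    def __post_init__(self) -> None:
        ind = {k.lower() for k in self.industry_keywords}
        non = {k.lower() for k in self.non_industry_keywords}
        overlap = ind & non
        if overlap:
            raise ValueError(f"keyword lists overlap: {sorted(overlap)}")

    def _matches(self, keywords: Sequence[str], name: str) -> bool:
        for kw in keywords:
            kw = kw.lower()
            if len(kw) <= self.short_token_max:
                if re.search(rf"(?<![a-z]){re.escape(kw)}(?![a-z])", name):
                    return True
            elif kw in name:
                return True
        return False

    def classify(self, sponsor_name: str | None) -> str:
        if not sponsor_name:
            return UNKNOWN
        name = sponsor_name.strip().lower()
        ind = self._matches(self.industry_keywords, name)
        non = self._matches(self.non_industry_keywords, name)
        if ind and not non:
            return INDUSTRY
        if non and not ind:
            return NON_INDUSTRY
        return UNKNOWN  # no hit, or conflicting hits


def load_default_keywords(path: str | Path | None = None) -> SponsorKeywordConfig:
    if path is None:
        text = resources.files("trialscape.data").joinpath("keywords.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    return SponsorKeywordConfig(
        industry_keywords=tuple(raw["industry"]),
        non_industry_keywords=tuple(raw["non_industry"]),
        short_token_max=int(raw.get("short_token_max", 4)),
    )


def classify_sponsor(sponsor_name: str | None, config: SponsorKeywordConfig) -> str:
    """Classify a free-text primary-sponsor name as industry / non_industry / unknown."""
    return config.classify(sponsor_name)


@dataclass
class ExclusionReport:
    """Counts of everything dropped or degraded during ingestion/filtering."""

    unparseable_year: int = 0
    unresolved_locations: Counter = field(default_factory=Counter)
    trials_without_locations: int = 0
    out_of_period: int = 0
    unknown_sponsor: int = 0
    duplicates_removed: int = 0

    def as_dict(self) -> dict:
        return {
            "unparseable_year": self.unparseable_year,
            "unresolved_locations": dict(self.unresolved_locations),
            "trials_without_locations": self.trials_without_locations,
            "out_of_period": self.out_of_period,
            "unknown_sponsor": self.unknown_sponsor,
            "duplicates_removed": self.duplicates_removed,
        }


@dataclass
class ReadResult:
    records: list[TrialRecord]
    report: ExclusionReport

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


DEFAULT_COLUMNS = {
    "trial_id": "trial_id",
    "start_date": "start_date",
    "sponsor": "sponsor",
    "countries": "countries",
    "sponsor_type": "sponsor_type",  # optional pre-classified column
}


def parse_year(text: str | None) -> int | None:
    """Extract a calendar year from a date string; None when absent."""
    if not text:
        return None
    m = _YEAR_RE.search(text)
    return int(m.group()) if m else None


def read_trials(
    path: str | Path,
    *,
    delimiter: str = ",",
    country_delimiter: str = ";",
    columns: Mapping[str, str] | None = None,
    country_table: CountryTable | None = None,
    keyword_config: SponsorKeywordConfig | None = None,
) -> ReadResult:
    """Read trial records from a registry CSV export.

    The sponsor type is taken from a pre-classified ``sponsor_type`` column when
    present, otherwise derived from the sponsor name via ``keyword_config``.
    Rows with unparseable start dates are kept (``start_year=None``) and
    reported; unresolvable country names drop the location (reported), and the
    whole trial only when no location resolves.
    """
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    table = country_table if country_table is not None else load_country_table()
    keywords = keyword_config if keyword_config is not None else load_default_keywords()

    report = ExclusionReport()
    records: list[TrialRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, no header row")
        missing = [
            cols[k] for k in ("trial_id", "start_date", "countries") if cols[k] not in reader.fieldnames
        ]
        if cols["sponsor"] not in reader.fieldnames and cols["sponsor_type"] not in reader.fieldnames:
            missing.append(cols["sponsor"])
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")

        for row in reader:
            year = parse_year(row.get(cols["start_date"]))
            if year is None:
                report.unparseable_year += 1
            sponsor_name = (row.get(cols["sponsor"]) or "").strip() or None
            stype = (row.get(cols["sponsor_type"]) or "").strip()
            if stype not in SPONSOR_TYPES:
                stype = classify_sponsor(sponsor_name, keywords)
            countries = set()
            for token in (row.get(cols["countries"]) or "").split(country_delimiter):
                token = token.strip()
                if not token:
                    continue
                code = table.resolve(token)
                if code is None:
                    report.unresolved_locations[token] += 1
                else:
                    countries.add(code)
            if not countries:
                report.trials_without_locations += 1
                continue
            records.append(
                TrialRecord(
                    trial_id=row[cols["trial_id"]].strip(),
                    start_year=year,
                    sponsor_type=stype,
                    countries=frozenset(countries),
                    sponsor_name=sponsor_name,
                )
            )
    return ReadResult(records, report)


def write_trials(records: Iterable[TrialRecord], path: str | Path, *, country_delimiter: str = ";") -> None:
    """Write records to a flat CSV that :func:`read_trials` round-trips."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["trial_id", "start_date", "sponsor", "sponsor_type", "countries"])
        for rec in records:
            writer.writerow(
                [
                    rec.trial_id,
                    "" if rec.start_year is None else str(rec.start_year),
                    rec.sponsor_name or "",
                    rec.sponsor_type,
                    country_delimiter.join(sorted(rec.countries)),
                ]
            )


def filter_period(
    records: Iterable[TrialRecord],
    first_year: int = 2006,
    last_year: int = 2013,
    *,
    report: ExclusionReport | None = None,
) -> tuple[list[TrialRecord], ExclusionReport]:
    """Keep trials started within [first_year, last_year] with a known sponsor type.

    Each exclusion reason is counted independently, so a record can increment
    both counters; the kept list is what satisfies every condition.
    """
    rep = report if report is not None else ExclusionReport()
    kept: list[TrialRecord] = []
    for rec in records:
        in_period = rec.start_year is not None and first_year <= rec.start_year <= last_year
        known = rec.sponsor_type != UNKNOWN
        if not in_period:
            rep.out_of_period += 1
        if not known:
            rep.unknown_sponsor += 1
        if in_period and known:
            kept.append(rec)
    return kept, rep


def _dedup_key(rec: TrialRecord):
    return (
        rec.n_countries,
        tuple(sorted(rec.countries)),
        rec.start_year if rec.start_year is not None else -1,
        rec.sponsor_type,
        rec.sponsor_name or "",
    )


def deduplicate(
    records: Iterable[TrialRecord], *, report: ExclusionReport | None = None
) -> list[TrialRecord]:
    """Keep one record per trial_id: the one with the most country locations.

    Remaining ties are broken on (sorted country codes, year, sponsor fields) so
    the result is independent of input order.  Output preserves first-seen
    order of trial ids.
    """
    best: dict[str, TrialRecord] = {}
    order: list[str] = []
    n_in = 0
    for rec in records:
        n_in += 1
        cur = best.get(rec.trial_id)
        if cur is None:
            best[rec.trial_id] = rec
            order.append(rec.trial_id)
        elif _dedup_key(rec) > _dedup_key(cur):
            best[rec.trial_id] = rec
    if report is not None:
        report.duplicates_removed += n_in - len(best)
    return [best[tid] for tid in order]
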