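"""End-to-end orchestration: ingest -> map -> network -> trim -> null model -> clusters.

A single :class:`RunConfig` drives the whole analysis for both sponsor types,
with per-sponsor trim fractions (0.95 industry, 0.90 non-industry by default).
All randomness flows from one root seed, split per stage and sponsor with
``numpy.random.SeedSequence`` and recorded in the run report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import Partition, detect_clusters
from .collaboration import (
    build_incidence,
    cooccurrence,
    trim,
    write_edgelist_tsv,
    write_graphml,
)
from .mapping import (
    annual_distribution,
    annual_frame,
    density_frame,
    density_table,
    group_median_density,
    mapping_summary,
)
from .nullmodel import (
    NullSummary,
    build_cooccurrence_network,
    null_distributions,
    summaries_frame,
)
from .registry import (
    INDUSTRY,
    NON_INDUSTRY,
    CountryTable,
    ExclusionReport,
    TrialRecord,
    deduplicate,
    filter_period,
    load_country_table,
    read_trials,
)
from .synthetic import SyntheticConfig, generate_registry

log = logging.getLogger("trialscape")

DEFAULT_TRIM = {INDUSTRY: 0.95, NON_INDUSTRY: 0.90}


@dataclass
class RunConfig:
    input_csv: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    first_year: int = 2006
    last_year: int = 2013
    trim_fractions: dict = field(default_factory=lambda: dict(DEFAULT_TRIM))
    n_reps: int = 90_000
    seed: int = 0
    n_restarts: int = 8
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of input_csv or synthetic")
        for st, f in self.trim_fractions.items():
            if not 0 < f <= 1:
                raise ValueError(f"trim fraction for {st} outside (0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class SponsorStageReport:
    sponsor_type: str
    n_international: int = 0
    n_countries: int = 0
    n_countries_trimmed: int = 0
    n_pairs: int = 0
    n_flagged: int = 0
    n_clusters: int = 0
    seed: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class RunReport:
    seed: int
    version: str
    n_read: int = 0
    n_after_dedup: int = 0
    n_kept: int = 0
    exclusions: dict = field(default_factory=dict)
    mapping: dict = field(default_factory=dict)
    sponsors: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "version": self.version,
            "n_read": self.n_read,
            "n_after_dedup": self.n_after_dedup,
            "n_kept": self.n_kept,
            "exclusions": self.exclusions,
            "mapping": self.mapping,
            "sponsors": self.sponsors,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2, default=str))


@dataclass
class SponsorResult:
    summaries: list[NullSummary]
    partition: Partition | None
    report: SponsorStageReport


@dataclass
class RunResult:
    records: list[TrialRecord]
    report: RunReport
    sponsor_results: dict


def _stage_seed(root: int, *key: int) -> int:
    return int(np.random.SeedSequence(root, spawn_key=key).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, country_table: CountryTable | None = None) -> RunResult:
    """Execute the full analysis; raises with the failing stage name on error."""
    table = country_table if country_table is not None else load_country_table()
    report = RunReport(seed=config.seed, version=__version__)
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    stage = "ingest"
    try:
        if config.input_csv is not None:
            result = read_trials(config.input_csv, country_table=table)
            records, excl = result.records, result.report
        else:
            records = generate_registry(config.synthetic, seed=_stage_seed(config.seed, 0))
            excl = ExclusionReport()
        report.n_read = len(records)
        records = deduplicate(records, report=excl)
        report.n_after_dedup = len(records)
        records, excl = filter_period(records, config.first_year, config.last_year, report=excl)
        report.n_kept = len(records)
        report.exclusions = excl.as_dict()
        log.info("ingest: read %d, kept %d", report.n_read, report.n_kept)

        stage = "map"
        report.mapping = mapping_summary(records, table)
        densities = density_table(records, table)
        report.mapping["median_density_by_income_group"] = group_median_density(
            densities, table, "income_group"
        )
        if out_dir:
            density_frame(densities).to_csv(out_dir / "density.csv", index=False)
            for grouping in ("region", "income_group"):
                annual_frame(
                    annual_distribution(records, table, grouping=grouping)
                ).to_csv(out_dir / f"annual_{grouping}.csv", index=False)

        sponsor_results = {}
        for s_idx, sponsor in enumerate((INDUSTRY, NON_INDUSTRY)):
            stage = f"network[{sponsor}]"
            sp_seed = _stage_seed(config.seed, 1, s_idx)
            sp_report = SponsorStageReport(sponsor_type=sponsor, seed=sp_seed)
            matrix = build_incidence(records, sponsor)
            sp_report.n_international = matrix.n_trials
            sp_report.n_countries = matrix.n_countries
            if out_dir:
                write_graphml(cooccurrence(matrix), out_dir / f"network_{sponsor}.graphml")
                write_edgelist_tsv(cooccurrence(matrix), out_dir / f"network_{sponsor}.tsv")
            if matrix.n_trials == 0 or matrix.n_countries < 2:
                log.info("%s: no international trials, skipping null model", sponsor)
                sponsor_results[sponsor] = SponsorResult([], None, sp_report)
                report.sponsors[sponsor] = sp_report.as_dict()
                continue

            stage = f"trim[{sponsor}]"
            trimmed = trim(matrix, config.trim_fractions[sponsor])
            sp_report.n_countries_trimmed = trimmed.n_countries

            stage = f"nullmodel[{sponsor}]"
            summaries = null_distributions(trimmed, n_reps=config.n_reps, seed=sp_seed)
            sp_report.n_pairs = len(summaries)
            sp_report.n_flagged = sum(s.flagged for s in summaries)
            graph = build_cooccurrence_network(summaries)
            if out_dir:
                summaries_frame(summaries).to_csv(out_dir / f"summaries_{sponsor}.csv", index=False)
                write_graphml(graph, out_dir / f"cooccur_{sponsor}.graphml")

            stage = f"cluster[{sponsor}]"
            partition = None
            if graph.number_of_edges() > 0:
                partition = detect_clusters(
                    graph, seed=_stage_seed(config.seed, 2, s_idx), n_restarts=config.n_restarts
                )
                sp_report.n_clusters = partition.n_clusters
                if out_dir:
                    (out_dir / f"partition_{sponsor}.json").write_text(
                        json.dumps(
                            {
                                "codelength_bits": partition.codelength,
                                "clusters": partition.clusters(),
                            },
                            indent=2,
                        )
                    )
            sponsor_results[sponsor] = SponsorResult(summaries, partition, sp_report)
            report.sponsors[sponsor] = sp_report.as_dict()
            log.info(
                "%s: %d intl trials, %d/%d flagged pairs, %d clusters",
                sponsor,
                sp_report.n_international,
                sp_report.n_flagged,
                sp_report.n_pairs,
                sp_report.n_clusters,
            )

        if out_dir:
            report.to_json(out_dir / "report.json")
            Path(out_dir / "exclusions.json").write_text(json.dumps(report.exclusions, indent=2))
        return RunResult(records=records, report=report, sponsor_results=sponsor_results)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
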