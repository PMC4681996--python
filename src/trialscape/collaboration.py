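"""Country collaboration structure of international trials.

The central object is the binary incidence matrix of international trials by
countries: cell (t, c) is 1 when trial t has a location in country c.  Its row
sums are the number of countries per trial (all >= 2 by construction) and its
column sums the number of international trials per country — the margins that
the fixed-margin null model preserves.

The weighted collaboration network projects this matrix onto countries: the
edge weight w(i, j) counts the trials conducted simultaneously in at least
countries i and j, so the total edge weight equals sum_t C(k_t, 2) over row
sums k_t.

Sparse matrices are avoided at the test stage by trimming: the country with the
fewest international trials is removed repeatedly (ties broken alphabetically,
column sums re-evaluated after each removal) while at least a given fraction of
the total pairwise collaboration weight survives.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .registry import TrialRecord


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary trials x countries participation matrix."""

    trial_ids: tuple[str, ...]
    countries: tuple[str, ...]
    data: np.ndarray  # uint8, shape (n_trials, n_countries)

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.trial_ids), len(self.countries)):
            raise ValueError("matrix shape inconsistent with labels")
        if self.data.size and not np.isin(self.data, (0, 1)).all():
            raise ValueError("incidence matrix must be binary")

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)

    @property
    def n_countries(self) -> int:
        return len(self.countries)

    @property
    def row_sums(self) -> np.ndarray:
        return self.data.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.data.sum(axis=0)

    def total_pair_weight(self) -> int:
        """Total pairwise collaboration weight, sum_t C(k_t, 2)."""
        k = self.row_sums.astype(np.int64)
        return int((k * (k - 1) // 2).sum())

    def rows_as_indices(self) -> list[np.ndarray]:
        return [np.flatnonzero(row).astype(np.int64) for row in self.data]


def build_incidence(records: Iterable[TrialRecord], sponsor_type: str | None = None) -> IncidenceMatrix:
    """Incidence matrix of international trials, optionally for one sponsor type.

    Single-country trials contribute no row; columns are the countries that
    appear in at least one included trial, sorted by ISO code.
    """
    selected = [
        r
        for r in records
        if r.is_international and (sponsor_type is None or r.sponsor_type == sponsor_type)
    ]
    selected.sort(key=lambda r: r.trial_id)
    countries = sorted({c for r in selected for c in r.countries})
    index = {c: j for j, c in enumerate(countries)}
    data = np.zeros((len(selected), len(countries)), dtype=np.uint8)
    for i, rec in enumerate(selected):
        for c in rec.countries:
            data[i, index[c]] = 1
    return IncidenceMatrix(
        trial_ids=tuple(r.trial_id for r in selected),
        countries=tuple(countries),
        data=data,
    )


def cooccurrence_counts(matrix: IncidenceMatrix) -> np.ndarray:
    """Symmetric country x country matrix of pairwise co-occurrence counts."""
    a = matrix.data.astype(np.int64)
    counts = a.T @ a
    np.fill_diagonal(counts, 0)
    return counts


def cooccurrence(matrix: IncidenceMatrix) -> nx.Graph:
    """Weighted collaboration network: w(i, j) trials containing both i and j."""
    counts = cooccurrence_counts(matrix)
    g = nx.Graph()
    g.add_nodes_from(matrix.countries)
    ii, jj = np.nonzero(np.triu(counts, k=1))
    for i, j in zip(ii, jj):
        g.add_edge(matrix.countries[i], matrix.countries[j], weight=int(counts[i, j]))
    return g


def _weight_after_removal(data: np.ndarray, keep_cols: np.ndarray) -> int:
    k = data[:, keep_cols].sum(axis=1).astype(np.int64)
    k = k[k >= 2]  # rows below two countries drop out entirely
    return int((k * (k - 1) // 2).sum())


def trim(matrix: IncidenceMatrix, retain_fraction: float) -> IncidenceMatrix:
    """Remove least-connected countries while retaining a fraction of total weight.

    At each step the country participating in the fewest international trials
    (current column sum over surviving rows; ties broken alphabetically) is a
    removal candidate; it is removed only if the retained pairwise weight stays
    at or above ``retain_fraction`` times the original total.  Rows left with
    fewer than two countries are dropped.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must be in (0, 1]")
    if matrix.n_trials == 0:
        return matrix
    original_weight = matrix.total_pair_weight()
    threshold = retain_fraction * original_weight

    data = matrix.data
    col_alive = np.ones(matrix.n_countries, dtype=bool)
    row_alive = data.sum(axis=1) >= 2

    while col_alive.sum() > 1:
        sub = data[np.ix_(row_alive, col_alive)]
        col_sums = sub.sum(axis=0)
        # candidate: min column sum, alphabetical tie-break (countries sorted)
        cand_local = int(np.argmin(col_sums))
        cand = np.flatnonzero(col_alive)[cand_local]
        trial_cols = col_alive.copy()
        trial_cols[cand] = False
        new_weight = _weight_after_removal(data[row_alive], np.flatnonzero(trial_cols))
        if new_weight < threshold:
            break
        col_alive = trial_cols
        row_alive &= data[:, col_alive].sum(axis=1) >= 2

    keep_cols = np.flatnonzero(col_alive)
    keep_rows = np.flatnonzero(row_alive)
    return IncidenceMatrix(
        trial_ids=tuple(matrix.trial_ids[i] for i in keep_rows),
        countries=tuple(matrix.countries[j] for j in keep_cols),
        data=np.ascontiguousarray(data[np.ix_(keep_rows, keep_cols)]),
    )


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def write_edgelist_tsv(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in sorted(graph.edges(data="weight")):
            fh.write(f"{u}\t{v}\t{w}\n")


def write_matrix_market(matrix: IncidenceMatrix, path: str | Path) -> None:
    """Sparse triplet (MatrixMarket) export of the incidence matrix."""
    sp_mat = sp.coo_matrix(matrix.data)
    from scipy.io import mmwrite

    mmwrite(str(path), sp_mat)


def read_edgelist_tsv(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.lower().startswith("source"):
            raise ValueError("expected a source/target/weight header")
        for line in fh:
            u, v, w = line.rstrip("\n").split("\t")
            g.add_edge(u, v, weight=float(w))
    return g
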