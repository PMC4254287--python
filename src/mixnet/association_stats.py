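"""Association statistics and their fixed-margin randomization tests.

Three statistics, all functions of the pairwise co-occurrence counts
w_ij (number of clusters containing both species i and j):

* ASSS (global association): sum over species pairs of squared
  co-occurrence counts, Sigma_{i<j} w_ij^2.  Large when species tend to
  co-occur with specific partners.
* dyadic count: w_ij for one named pair.
* node strength: s_i = Sigma_j w_ij, the total edge weight incident to
  species i; measures heterospecific gregariousness.  Its lower tail
  detects avoidance of mixed groups, its upper tail gregariousness.

Because the randomization conditions on per-species sighting counts, the
raw (absolute) counts are valid test statistics: a rare species can reach
significance with few co-occurrences while an abundant one may not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_data import OccurrenceMatrix, UnknownSpeciesError
from .margin_randomizer import BCTestResult, bc_pvalue


@dataclass
class CoOccurrenceCounts:
    """Symmetric pairwise co-occurrence counts; diagonal unused (zero)."""

    w: np.ndarray
    species: list[str]

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.int64)
        if self.w.shape != (len(self.species), len(self.species)):
            raise ValueError("count matrix shape does not match species list")
        if (self.w != self.w.T).any():
            raise ValueError("co-occurrence counts must be symmetric")

    def index(self, species_id: str) -> int:
        try:
            return self.species.index(species_id)
        except ValueError:
            raise UnknownSpeciesError(f"species {species_id!r} not in counts") from None

    def pair_count(self, a: str, b: str) -> int:
        return int(self.w[self.index(a), self.index(b)])

    @property
    def total(self) -> int:
        """Total number of co-occurrences over all pairs."""
        return int(np.triu(self.w, 1).sum())


def co_occurrence_counts(matrix: OccurrenceMatrix) -> CoOccurrenceCounts:
    """w_ij = number of clusters containing both species i and j."""
    x = matrix.cells.astype(np.int64)
    w = x.T @ x
    np.fill_diagonal(w, 0)
    return CoOccurrenceCounts(w, list(matrix.col_labels))


def counts_from_clusters(clusters: list[list[str]], species: list[str]) -> CoOccurrenceCounts:
    """Co-occurrence counts straight from species sets (no matrix needed)."""
    idx = {s: i for i, s in enumerate(species)}
    w = np.zeros((len(species), len(species)), dtype=np.int64)
    for members in clusters:
        ids = [idx[s] for s in members]
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                w[ids[a], ids[b]] += 1
                w[ids[b], ids[a]] += 1
    return CoOccurrenceCounts(w, list(species))


def asss(counts: CoOccurrenceCounts) -> int:
    """Global association score: Sigma_{i<j} w_ij^2."""
    upper = np.triu(counts.w, 1)
    return int((upper.astype(np.int64) ** 2).sum())


def node_strength(counts: CoOccurrenceCounts, species_id: str) -> int:
    """s_i = Sigma_{j != i} w_ij (diagonal is zero by construction)."""
    return int(counts.w[counts.index(species_id)].sum())


@dataclass(frozen=True)
class AssociationReport:
    """One randomization test: statistic label(s) and both tail p-values."""

    test: str
    labels: tuple[str, ...]
    result: BCTestResult

    @property
    def observed_stat(self) -> float:
        return self.result.observed_stat

    @property
    def p_upper(self) -> float:
        return self.result.p_upper

    @property
    def p_lower(self) -> float:
        return self.result.p_lower

    def to_row(self) -> dict:
        return {
            "test": self.test,
            "labels": "|".join(self.labels),
            "observed_stat": self.observed_stat,
            "p_lower": self.p_lower,
            "p_upper": self.p_upper,
            "m": self.result.m,
            "thin": self.result.thin,
            "seed": self.result.seed,
        }


def _strata(matrix: OccurrenceMatrix, stratify: bool) -> dict[str, str] | None:
    if not stratify:
        return None
    if len(matrix.habitat_of_row) != matrix.n_clusters:
        raise ValueError("matrix carries no habitat labels; cannot stratify")
    return dict(matrix.habitat_of_row)


def test_global_association(
    matrix: OccurrenceMatrix,
    m: int,
    thin: int | None = None,
    seed=None,
    stratify_by_habitat: bool = False,
) -> AssociationReport:
    """BC test with the ASSS score; the upper tail is the reported signal."""
    res = bc_pvalue(
        matrix,
        lambda mat: asss(co_occurrence_counts(mat)),
        m=m,
        thin=thin,
        seed=seed,
        stratum_of_row=_strata(matrix, stratify_by_habitat),
    )
    return AssociationReport("global_asss", (), res)


def test_dyad(
    matrix: OccurrenceMatrix,
    pair: tuple[str, str],
    m: int,
    thin: int | None = None,
    seed=None,
    stratify_by_habitat: bool = False,
) -> AssociationReport:
    """BC test with statistic w_ij for one named species pair."""
    i = matrix.col_index(pair[0])
    j = matrix.col_index(pair[1])
    if i == j:
        raise ValueError("dyad must name two distinct species")
    res = bc_pvalue(
        matrix,
        lambda mat: int((mat.cells[:, i] & mat.cells[:, j]).sum()),
        m=m,
        thin=thin,
        seed=seed,
        stratum_of_row=_strata(matrix, stratify_by_habitat),
    )
    return AssociationReport("dyad", tuple(pair), res)


def test_node_strength(
    matrix: OccurrenceMatrix,
    species_id: str,
    m: int,
    thin: int | None = None,
    seed=None,
    stratify_by_habitat: bool = False,
) -> AssociationReport:
    """BC test with statistic s_i; report both tails (avoidance vs gregariousness)."""
    j = matrix.col_index(species_id)
    res = bc_pvalue(
        matrix,
        lambda mat: int((mat.cells[:, j][:, None] & mat.cells).sum()) - int(mat.cells[:, j].sum()),
        m=m,
        thin=thin,
        seed=seed,
        stratum_of_row=_strata(matrix, stratify_by_habitat),
    )
    return AssociationReport("node_strength", (species_id,), res)


def all_dyad_tests(
    matrix: OccurrenceMatrix,
    m: int,
    thin: int | None = None,
    seed=None,
    stratify_by_habitat: bool = False,
    adjust: str | None = None,
    min_observed: int = 1,
) -> pd.DataFrame:
    """Dyad tests for every pair co-occurring at least `min_observed` times.

    `adjust="bh"` appends Benjamini-Hochberg adjusted upper-tail p-values;
    raw p-values are the default (no multiple-testing correction).
    """
    counts = co_occurrence_counts(matrix)
    ss = np.random.SeedSequence(seed)
    rows = []
    pairs = [
        (a, b)
        for ai, a in enumerate(matrix.col_labels)
        for b in matrix.col_labels[ai + 1 :]
        if counts.pair_count(a, b) >= min_observed
    ]
    for child, (a, b) in zip(ss.spawn(len(pairs)), pairs):
        rep = test_dyad(
            matrix, (a, b), m=m, thin=thin,
            seed=np.random.default_rng(child),
            stratify_by_habitat=stratify_by_habitat,
        )
        rows.append(rep.to_row())
    df = pd.DataFrame(rows)
    if adjust == "bh" and not df.empty:
        df["p_upper_bh"] = multipletests(df["p_upper"], method="fdr_bh")[1]
    elif adjust is not None and adjust != "bh":
        raise ValueError(f"unknown adjustment {adjust!r}")
    if not df.empty:
        df["seed"] = seed
    return df
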