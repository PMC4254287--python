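"""Three-step generative model for cluster sets.

The simulator separates abundance-driven from preference-driven network
structure:

* step 1 — draw N species occurrences i.i.d. from the relative sighting
  frequencies;
* step 2 — form clusters by repeatedly drawing a target cluster size from
  a geometric model, P(n) = (1-p)^(n-1) p, truncated at the number of
  species, and filling the cluster with occurrences drawn without
  replacement, skipping species already present; ends when every
  occurrence is assigned;
* step 3 (optional, "preference mode") — perform k random swaps of species
  occurrences between clusters, immediately reversing any swap that would
  duplicate a species within a cluster or strictly increase the squared
  distance between the simulated and the observed *relative* association
  strengths.  Swaps conserve cluster sizes and per-species occurrence
  totals, so only the pairing structure moves toward the observation.

Steps 1-2 alone generate preference-free ("abundance only") cluster sets
that on average reproduce the observed species frequencies and the
observed number and sizes of clusters.  Repeating the simulation many
times and ranking node betweenness in each replicate network yields
per-species rank bands whose spread measures the robustness of observed
network positions.

Tail handling in step 2: when the drawn size cannot be filled without a
duplicate species (near pool exhaustion), the cluster closes at the
largest feasible size and leftover occurrences seed new clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .association_stats import CoOccurrenceCounts, co_occurrence_counts, counts_from_clusters
from .core_data import ClusterRecord, build_occurrence_matrix
from .species_network import betweenness, network_from_counts


@dataclass(frozen=True)
class GeometricSizeModel:
    """Cluster-size model P(n) = (1-p)^(n-1) p, n >= 1, truncated at max_size.

    Sampling resamples until the draw is feasible, preserving the pmf shape
    below the truncation point.
    """

    p: float
    max_size: int

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError("p must be in (0, 1]")
        if self.max_size < 1:
            raise ValueError("max_size must be >= 1")

    def sample(self, rng: np.random.Generator) -> int:
        while True:
            n = int(rng.geometric(self.p))
            if n <= self.max_size:
                return n

    def pmf(self) -> np.ndarray:
        """Truncated, renormalized pmf over sizes 1..max_size."""
        n = np.arange(1, self.max_size + 1)
        raw = (1 - self.p) ** (n - 1) * self.p
        return raw / raw.sum()


def estimate_geometric_p(cluster_sizes) -> float:
    """Moment estimator p = 1 / mean(cluster sizes)."""
    sizes = np.asarray(cluster_sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("no cluster sizes")
    if (sizes < 1).any():
        raise ValueError("cluster sizes must be >= 1")
    return float(1.0 / sizes.mean())


@dataclass(frozen=True)
class SimulationConfig:
    """Inputs of the cluster simulator.

    frequencies are relative sighting frequencies over `species` (they are
    normalized on construction); N is the total number of occurrences per
    replicate; k the swap count of step 3; target_counts the observed
    co-occurrence counts that step 3 moves toward.
    """

    species: tuple[str, ...]
    frequencies: tuple[float, ...]
    N: int
    size_model: GeometricSizeModel
    k: int = 10_000
    target_counts: CoOccurrenceCounts | None = None
    include_preferences: bool = False
    n_reps: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if (f < 0).any() or f.sum() <= 0:
            raise ValueError("frequencies must be non-negative with positive sum")
        if len(self.species) != f.size:
            raise ValueError("species and frequencies length mismatch")
        object.__setattr__(self, "frequencies", tuple(f / f.sum()))
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.include_preferences and self.target_counts is None:
            raise ValueError("preference mode needs target_counts")
        if self.target_counts is not None and list(self.target_counts.species) != list(
            self.species
        ):
            raise ValueError("target_counts species do not match config species")

    @classmethod
    def from_observation(
        cls,
        records: list[ClusterRecord],
        species_subset: list[str] | None = None,
        k: int = 10_000,
        include_preferences: bool = False,
        n_reps: int = 1000,
        seed: int | None = None,
    ) -> "SimulationConfig":
        """Estimate frequencies, N, and the size model from observed clusters.

        With a detectability subset, frequencies are re-normalized over the
        retained species and cluster sizes are counted among them.
        """
        matrix = build_occurrence_matrix(records, species_subset=species_subset)
        col = matrix.col_sums.astype(float)
        sizes = matrix.row_sums
        return cls(
            species=tuple(matrix.col_labels),
            frequencies=tuple(col / col.sum()),
            N=int(col.sum()),
            size_model=GeometricSizeModel(
                p=estimate_geometric_p(sizes), max_size=matrix.n_species
            ),
            k=k,
            target_counts=co_occurrence_counts(matrix),
            include_preferences=include_preferences,
            n_reps=n_reps,
            seed=seed,
        )


def _weighted_pick(weights: np.ndarray, rng: np.random.Generator) -> int:
    c = np.cumsum(weights)
    return int(np.searchsorted(c, rng.random() * c[-1], side="right"))


def fill_clusters(
    pool: np.ndarray,
    size_model: GeometricSizeModel,
    rng: np.random.Generator,
) -> list[list[int]]:
    """Step 2: assign a pool of per-species occurrence counts to clusters.

    Each member is drawn without replacement, proportionally to the
    remaining occurrence counts, skipping species already in the cluster.
    """
    remaining = np.asarray(pool, dtype=float).copy()
    clusters: list[list[int]] = []
    while remaining.sum() > 0:
        target = size_model.sample(rng)
        members: list[int] = []
        while len(members) < target:
            w = remaining.copy()
            if members:
                w[members] = 0.0
            if w.sum() <= 0:
                break  # tail: close at the largest feasible size
            s = _weighted_pick(w, rng)
            members.append(s)
            remaining[s] -= 1
        clusters.append(members)
    return clusters


def generate_null_clusters(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[list[str]]:
    """Steps 1-2: abundance-only cluster sets (lists of species ids)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pool = rng.multinomial(config.N, np.asarray(config.frequencies))
    clusters = fill_clusters(pool, config.size_model, rng)
    return [[config.species[i] for i in members] for members in clusters]


def _relative(counts: CoOccurrenceCounts) -> np.ndarray:
    w = np.triu(counts.w, 1).astype(float)
    tot = w.sum()
    return w / tot if tot > 0 else w


def association_difference(
    sim_counts: CoOccurrenceCounts, obs_counts: CoOccurrenceCounts
) -> float:
    """Sum of squared differences between *relative* association strengths.

    Each count matrix is normalized by its own total number of
    co-occurrences (an all-zero matrix has all-zero relative strengths), so
    the score is invariant to uniform scaling of either set.
    """
    if list(sim_counts.species) != list(obs_counts.species):
        raise ValueError("species sets differ")
    d = _relative(sim_counts) - _relative(obs_counts)
    return float((d**2).sum())


def apply_preference_swaps(
    clusters: list[list[str]],
    target_counts: CoOccurrenceCounts,
    k: int,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Step 3: k occurrence swaps between clusters, rejecting any swap that
    would duplicate a species within a cluster or strictly increase the
    association-difference score.  Conserves cluster sizes and per-species
    occurrence totals; the score never increases.
    """
    species = list(target_counts.species)
    idx = {s: i for i, s in enumerate(species)}
    work = [[idx[s] for s in members] for members in clusters]
    if len(work) < 2 or k == 0:
        return [list(c) for c in clusters]
    n_sp = len(species)
    w = counts_from_clusters(clusters, species).w.astype(np.int64)
    t_sim = np.triu(w, 1).sum()  # invariant under swaps (cluster sizes fixed)
    rel_obs = _relative(target_counts)
    rel_obs = rel_obs + rel_obs.T  # symmetric lookup
    n_clusters = len(work)
    member_sets = [set(c) for c in work]
    for _ in range(k):
        x = int(rng.integers(n_clusters))
        y = int(rng.integers(n_clusters - 1))
        y += y >= x
        cx, cy = work[x], work[y]
        a = cx[int(rng.integers(len(cx)))]
        b = cy[int(rng.integers(len(cy)))]
        if a == b:
            continue
        if b in member_sets[x] or a in member_sets[y]:
            continue  # would duplicate a species within a cluster
        if t_sim > 0:
            delta = 0.0
            changes: dict[tuple[int, int], int] = {}

            def _add(i: int, j: int, dw: int) -> None:
                key = (i, j) if i < j else (j, i)
                changes[key] = changes.get(key, 0) + dw

            for u in cx:
                if u != a:
                    _add(a, u, -1)
                    _add(b, u, +1)
            for v in cy:
                if v != b:
                    _add(b, v, -1)
                    _add(a, v, +1)
            for (i, j), dw in changes.items():
                if dw == 0:
                    continue
                old = w[i, j] / t_sim - rel_obs[i, j]
                new = (w[i, j] + dw) / t_sim - rel_obs[i, j]
                delta += new * new - old * old
            if delta > 1e-15:
                continue  # reversed: swap would increase the difference
            for (i, j), dw in changes.items():
                w[i, j] += dw
                w[j, i] += dw
        cx[cx.index(a)] = b
        cy[cy.index(b)] = a
        member_sets[x].discard(a)
        member_sets[x].add(b)
        member_sets[y].discard(b)
        member_sets[y].add(a)
    assert n_sp == len(species)
    return [[species[i] for i in members] for members in work]


@dataclass
class RankPercentiles:
    """Per-species betweenness-rank summary over simulation replicates."""

    table: pd.DataFrame  # columns: species, mean_rank, q05, q95, mode
    mode: str

    def mean_rank(self, species_id: str) -> float:
        return float(self.table.set_index("species").loc[species_id, "mean_rank"])


def simulate_betweenness_ranks(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> RankPercentiles:
    """Replicate betweenness ranks under the configured simulator mode.

    For each of n_reps replicates: generate clusters (steps 1-2, plus step
    3 iff `include_preferences`), build the weighted network, rank node
    betweenness (1 = most central).  Returns per-species mean rank and the
    5%/95% percentiles across replicates.
    """
    if config.n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    species = list(config.species)
    if rng is None:
        ss = np.random.SeedSequence(config.seed)
        rngs = [np.random.default_rng(c) for c in ss.spawn(config.n_reps)]
    else:
        rngs = [rng] * config.n_reps
    ranks = np.empty((config.n_reps, len(species)), dtype=float)
    for r, rep_rng in enumerate(rngs):
        clusters = generate_null_clusters(config, rep_rng)
        if config.include_preferences:
            clusters = apply_preference_swaps(
                clusters, config.target_counts, config.k, rep_rng
            )
        counts = counts_from_clusters(clusters, species)
        net = network_from_counts(counts, min_weight=1)
        report = betweenness(net)
        ranks[r] = report.ranks.reindex(species).to_numpy()
    mode = "preference" if config.include_preferences else "abundance_only"
    table = pd.DataFrame(
        {
            "species": species,
            "mean_rank": ranks.mean(axis=0),
            "q05": np.percentile(ranks, 5, axis=0),
            "q95": np.percentile(ranks, 95, axis=0),
            "mode": mode,
        }
    )
    return RankPercentiles(table=table, mode=mode)


def abundance_and_preference_ranks(
    config: SimulationConfig,
) -> pd.DataFrame:
    """Convenience: run both modes with the same config and stack the tables."""
    null_cfg = replace(config, include_preferences=False)
    pref_cfg = replace(config, include_preferences=True)
    out = [simulate_betweenness_ranks(null_cfg).table]
    out.append(simulate_betweenness_ranks(pref_cfg).table)
    return pd.concat(out, ignore_index=True)
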