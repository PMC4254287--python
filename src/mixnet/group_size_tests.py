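"""Permutation tests on conspecific group sizes.

For one species with k_s observed occurrences, the group sizes
g_1, ..., g_ks are permuted over the fixed context labels of the
occurrences (single- vs mixed-species cluster, or partner-present vs
partner-absent).  The test statistic is the difference of context medians,

    T = median(g | context B) - median(g | context A),

two-sided via |T|.  Permuting sizes over fixed labels keeps the per-species
size multiset (and hence the total number of individuals) constant, so the
test conditions on the species' observed abundance.

Below a combinatorial threshold all C(k_s, n_B) label assignments are
enumerated exactly; above it a seeded Monte-Carlo permutation scheme with
the add-one correction p = (1 + #{|T*| >= |T|}) / (n_perm + 1) is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .core_data import SightingSeries

#: Exact enumeration is used when C(k_s, n_B) is at most this.
EXACT_ENUMERATION_LIMIT = 20_000


@dataclass(frozen=True)
class GroupSizeTestResult:
    species: str
    context: str
    median_a: float | None
    median_b: float | None
    n_a: int
    n_b: int
    observed_stat: float | None
    p_two_sided: float | None
    n_perm: int | None
    mode: str  # "exact", "mc", or "untestable"
    seed: int | None

    @property
    def testable(self) -> bool:
        return self.mode != "untestable"

    def to_row(self) -> dict:
        return {
            "species": self.species,
            "context": self.context,
            "median_a": self.median_a,
            "median_b": self.median_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "observed_stat": self.observed_stat,
            "p_two_sided": self.p_two_sided,
            "n_perm": self.n_perm,
            "mode": self.mode,
            "seed": self.seed,
        }


def _median_diff(sizes: np.ndarray, in_b: np.ndarray) -> float:
    # even-length medians use the midpoint convention (numpy default)
    return float(np.median(sizes[in_b]) - np.median(sizes[~in_b]))


def _permutation_test(
    species: str,
    context: str,
    sizes: np.ndarray,
    in_b: np.ndarray,
    n_perm: int,
    seed: int | None,
    mode: str,
) -> GroupSizeTestResult:
    k = sizes.size
    n_b = int(in_b.sum())
    n_a = k - n_b
    if n_a == 0 or n_b == 0:
        return GroupSizeTestResult(
            species, context,
            None if n_a == 0 else float(np.median(sizes[~in_b])),
            None if n_b == 0 else float(np.median(sizes[in_b])),
            n_a, n_b, None, None, None, "untestable", seed,
        )
    t_obs = _median_diff(sizes, in_b)
    if mode == "auto":
        mode = "exact" if comb(k, n_b) <= EXACT_ENUMERATION_LIMIT else "mc"
    if mode == "exact":
        n_ge = 0
        total = 0
        mask = np.zeros(k, dtype=bool)
        for picked in combinations(range(k), n_b):
            mask[:] = False
            mask[list(picked)] = True
            if abs(_median_diff(sizes, mask)) >= abs(t_obs) - 1e-12:
                n_ge += 1
            total += 1
        p = n_ge / total
        n_perm_out = total
    elif mode == "mc":
        rng = np.random.default_rng(seed)
        n_ge = 0
        work = sizes.copy()
        for _ in range(n_perm):
            rng.shuffle(work)
            if abs(float(np.median(work[:n_b]) - np.median(work[n_b:]))) >= abs(t_obs) - 1e-12:
                n_ge += 1
        p = (1 + n_ge) / (n_perm + 1)
        n_perm_out = n_perm
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GroupSizeTestResult(
        species, context,
        float(np.median(sizes[~in_b])), float(np.median(sizes[in_b])),
        n_a, n_b, t_obs, p, n_perm_out, mode, seed,
    )


def test_group_size_context(
    series: SightingSeries,
    n_perm: int = 100_000,
    seed: int | None = None,
    mode: str = "auto",
) -> GroupSizeTestResult:
    """Do group sizes differ between single- and mixed-species occurrences?

    Context A = single-species clusters, context B = mixed clusters; a
    positive statistic means larger groups in mixed clusters.  A context
    with zero occurrences yields an explicit "untestable" result.
    """
    return _permutation_test(
        series.species_id, "single_vs_mixed",
        series.group_sizes, series.is_mixed, n_perm, seed, mode,
    )


def test_group_size_dyad(
    series: SightingSeries,
    partner: str,
    n_perm: int = 100_000,
    seed: int | None = None,
    mode: str = "auto",
) -> GroupSizeTestResult:
    """Do group sizes depend on the presence of one specific partner species?

    Context A = partner absent, context B = partner present.  Note the test
    is asymmetric in (species, partner): swapping the roles permutes a
    different size list and need not give the same p-value.
    """
    return _permutation_test(
        series.species_id, f"partner_presence({partner})",
        series.group_sizes, series.partner_present(partner), n_perm, seed, mode,
    )
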