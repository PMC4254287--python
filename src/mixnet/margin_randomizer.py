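"""Fixed-margin randomization of binary occurrence matrices.

The null hypothesis of "no association" is the uniform distribution over
all binary matrices with the observed row sums (cluster sizes) and column
sums (per-species sighting counts).  The sampler is the standard reversible
Markov chain on that class: propose a uniformly random (row pair, column
pair); if the 2x2 submatrix is a checkerboard, flip it, otherwise stay.
The proposal kernel is symmetric and the stationary distribution uniform.

P-values follow the Besag-Clifford serial Monte-Carlo scheme, which yields
valid p-values from a chain *started at the observed matrix*, without any
burn-in or convergence requirement: draw an offset U uniform on {0..m}, run
U*thin steps from the observed matrix to obtain a start state (by kernel
symmetry a backward run equals a forward run), then run m*thin steps
forward recording the statistic every `thin` steps, and report

    p_upper = (1 + #{T_i >= T_obs}) / (m + 1)

(ties count as exceedances; the mirror for the lower tail).  The add-one
form never returns 0.

An optional stratification restricts swaps to row pairs within the same
stratum (habitat), conditioning the null on per-habitat cluster
composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable

import numpy as np
from numba import njit

from .core_data import OccurrenceMatrix

_PROPOSAL_CHUNK = 1 << 20


@njit(cache=True)
def _apply_proposals(cells, strata, r1, r2, c1, c2):  # pragma: no cover - numba
    n_flips = 0
    for t in range(r1.shape[0]):
        i = r1[t]
        j = r2[t]
        if strata[i] != strata[j]:
            continue
        k = c1[t]
        l = c2[t]
        a = cells[i, k]
        b = cells[i, l]
        c = cells[j, k]
        d = cells[j, l]
        if a == d and b == c and a != b:
            cells[i, k] = b
            cells[i, l] = a
            cells[j, k] = d
            cells[j, l] = c
            n_flips += 1
    return n_flips


@njit(cache=True)
def _apply_proposals_tilted(cells, logphi, r1, r2, c1, c2, unif):  # pragma: no cover - numba
    """Metropolis checkerboard chain for P(M) ~ prod_ij phi_ij^w_ij.

    With logphi all zero this is the plain symmetric chain (uniform
    stationary distribution on the fixed-margin class).
    """
    n_cols = cells.shape[1]
    n_flips = 0
    for t in range(r1.shape[0]):
        i = r1[t]
        j = r2[t]
        k = c1[t]
        l = c2[t]
        a = cells[i, k]
        b = cells[i, l]
        c = cells[j, k]
        d = cells[j, l]
        if not (a == d and b == c and a != b):
            continue
        # orient so row `hi` holds column k (loses k, gains l); row `lo` mirrors
        if a == 1:
            hi, lo = i, j
        else:
            hi, lo = j, i
        dlog = 0.0
        for s in range(n_cols):
            if s == k or s == l:
                continue
            # cast before subtracting: uint8 arithmetic would wrap at 0-1
            diff = float(cells[hi, s]) - float(cells[lo, s])
            if diff != 0.0:
                dlog += diff * (logphi[l, s] - logphi[k, s])
        if dlog < 0.0 and unif[t] >= np.exp(dlog):
            continue
        cells[i, k] = b
        cells[i, l] = a
        cells[j, k] = d
        cells[j, l] = c
        n_flips += 1
    return n_flips


def sample_tilted_matrix(
    cells: np.ndarray,
    logphi: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample from the phi-tilted fixed-margin family, starting at `cells`.

    Runs `n_steps` Metropolis checkerboard proposals in place and returns
    the matrix.  Margins are preserved exactly; the stationary law weights
    each matrix by prod_{i<j} phi_ij^w_ij (uniform when phi is all ones).
    """
    cells = np.ascontiguousarray(cells, dtype=np.uint8)
    logphi = np.ascontiguousarray(logphi, dtype=np.float64)
    done = 0
    while done < n_steps:
        chunk = min(_PROPOSAL_CHUNK, n_steps - done)
        r1, r2 = _draw_pairs(rng, cells.shape[0], chunk)
        c1, c2 = _draw_pairs(rng, cells.shape[1], chunk)
        unif = rng.random(chunk)
        _apply_proposals_tilted(cells, logphi, r1, r2, c1, c2, unif)
        done += chunk
    return cells


def _draw_pairs(rng: np.random.Generator, n: int, size: int) -> tuple[np.ndarray, np.ndarray]:
    """`size` uniform ordered pairs of distinct indices in [0, n)."""
    a = rng.integers(0, n, size=size, dtype=np.int64)
    b = rng.integers(0, n - 1, size=size, dtype=np.int64)
    b += b >= a
    return a, b


@dataclass
class MarginChainState:
    """Current state of the checkerboard chain.

    Row and column sums are invariant for the lifetime of the state; when
    strata are set, swaps never pair rows from different strata.
    """

    matrix: OccurrenceMatrix
    step_count: int = 0
    stratum_of_row: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.matrix.n_clusters < 2 or self.matrix.n_species < 2:
            raise ValueError("chain needs at least a 2x2 matrix")
        if self.stratum_of_row is None:
            self._strata = np.zeros(self.matrix.n_clusters, dtype=np.int64)
        else:
            labels = [self.stratum_of_row[r] for r in self.matrix.row_labels]
            uniq = {s: i for i, s in enumerate(sorted(set(labels)))}
            self._strata = np.array([uniq[s] for s in labels], dtype=np.int64)

    @property
    def strata_codes(self) -> np.ndarray:
        return self._strata

    def advance(self, n_steps: int, rng: np.random.Generator) -> int:
        """Apply `n_steps` proposals in place; returns the number of flips."""
        cells = self.matrix.cells
        n_flips = 0
        done = 0
        while done < n_steps:
            chunk = min(_PROPOSAL_CHUNK, n_steps - done)
            r1, r2 = _draw_pairs(rng, cells.shape[0], chunk)
            c1, c2 = _draw_pairs(rng, cells.shape[1], chunk)
            n_flips += _apply_proposals(cells, self._strata, r1, r2, c1, c2)
            done += chunk
        self.step_count += n_steps
        return n_flips


def checkerboard_step(state: MarginChainState, rng: np.random.Generator) -> MarginChainState:
    """One proposal of the chain, applied in place (state is also returned).

    Reference single-step form of the batched :meth:`MarginChainState.advance`.
    """
    cells = state.matrix.cells
    i, j = _draw_pairs(rng, cells.shape[0], 1)
    k, l = _draw_pairs(rng, cells.shape[1], 1)
    i, j, k, l = int(i[0]), int(j[0]), int(k[0]), int(l[0])
    if state.strata_codes[i] == state.strata_codes[j]:
        a, b = cells[i, k], cells[i, l]
        c, d = cells[j, k], cells[j, l]
        if a == d and b == c and a != b:
            cells[i, k], cells[i, l] = b, a
            cells[j, k], cells[j, l] = d, c
    state.step_count += 1
    return state


@dataclass(frozen=True)
class BCTestResult:
    """Result of a Besag-Clifford randomization test."""

    observed_stat: float
    p_upper: float
    p_lower: float
    n_steps: int
    n_exceed: int
    seed: int | None
    m: int
    thin: int


def bc_pvalue(
    matrix: OccurrenceMatrix,
    statistic: Callable[[OccurrenceMatrix], float],
    m: int,
    thin: int | None = None,
    seed: int | np.random.Generator | None = None,
    stratum_of_row: dict[str, str] | None = None,
) -> BCTestResult:
    """Besag-Clifford serial Monte-Carlo p-values for an arbitrary statistic.

    Parameters
    ----------
    m : number of Monte-Carlo samples; the p-value resolution is 1/(m+1).
    thin : chain steps between samples; defaults to the number of matrix
        cells (one expected sweep).
    seed : int seed or numpy Generator.
    stratum_of_row : optional cluster_id -> habitat map restricting swaps.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if thin is None:
        thin = matrix.n_clusters * matrix.n_species
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if isinstance(seed, np.random.Generator):
        rng, seed_out = seed, None
    else:
        rng, seed_out = np.random.default_rng(seed), seed
    try:
        t_obs = float(statistic(matrix))
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise RuntimeError("statistic failed on the observed matrix") from exc
    state = MarginChainState(matrix.copy(), stratum_of_row=stratum_of_row)
    u = int(rng.integers(0, m + 1))
    state.advance(u * thin, rng)
    stats = np.empty(m, dtype=np.float64)
    for i in range(m):
        state.advance(thin, rng)
        try:
            stats[i] = float(statistic(state.matrix))
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"statistic failed at sample {i}") from exc
    n_up = int((stats >= t_obs).sum())
    n_lo = int((stats <= t_obs).sum())
    return BCTestResult(
        observed_stat=t_obs,
        p_upper=(1 + n_up) / (m + 1),
        p_lower=(1 + n_lo) / (m + 1),
        n_steps=state.step_count,
        n_exceed=n_up,
        seed=seed_out,
        m=m,
        thin=thin,
    )


def enumerate_margin_class(row_sums, col_sums) -> list[np.ndarray]:
    """All binary matrices with the given margins, by row-wise backtracking.

    Exhaustive-enumeration oracle for small matrices; independent of the
    Markov chain.
    """
    row_sums = list(map(int, row_sums))
    col_sums = np.asarray(col_sums, dtype=np.int64)
    n_cols = len(col_sums)
    out: list[np.ndarray] = []
    rows: list[np.ndarray] = []

    def rec(i: int, remaining: np.ndarray) -> None:
        if i == len(row_sums):
            if (remaining == 0).all():
                out.append(np.array(rows, dtype=np.uint8))
            return
        # feasibility prune: remaining demand must fit in remaining rows
        if remaining.sum() != sum(row_sums[i:]):
            return
        avail = [j for j in range(n_cols) if remaining[j] > 0]
        for cols in combinations(avail, row_sums[i]):
            v = np.zeros(n_cols, dtype=np.uint8)
            v[list(cols)] = 1
            rows.append(v)
            rec(i + 1, remaining - v)
            rows.pop()

    rec(0, col_sums.copy())
    return out


def exact_tail_probabilities(
    row_sums, col_sums, statistic: Callable[[np.ndarray], float], t_obs: float
) -> tuple[float, float, int]:
    """Exact (p_upper, p_lower, class size) under the uniform fixed-margin null."""
    stats = np.array([statistic(mat) for mat in enumerate_margin_class(row_sums, col_sums)])
    if stats.size == 0:
        raise ValueError("empty fixed-margin class")
    return (
        float((stats >= t_obs).mean()),
        float((stats <= t_obs).mean()),
        int(stats.size),
    )
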