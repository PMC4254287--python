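import numpy as np
import pytest
from scipy import stats

from mixnet.association_stats import counts_from_clusters
from mixnet.cluster_simulator import (
    GeometricSizeModel,
    SimulationConfig,
    apply_preference_swaps,
    association_difference,
    estimate_geometric_p,
    generate_null_clusters,
    simulate_betweenness_ranks,
)
from mixnet.experiments import small_species
from mixnet.synthetic_data import default_frequencies


def null_config(n_species=8, N=5000, mean_size=1.28, **kw):
    sp = small_species(n_species)
    f = np.array(list(default_frequencies(sp).values()))
    return SimulationConfig(
        species=tuple(sp),
        frequencies=tuple(f),
        N=N,
        size_model=GeometricSizeModel(p=1 / mean_size, max_size=n_species),
        **kw,
    )


class TestGeometricSizeModel:
    def test_truncated_pmf_normalized(self):
        m = GeometricSizeModel(p=0.8, max_size=6)
        assert m.pmf().sum() == pytest.approx(1.0)

    def test_samples_within_truncation(self, rng):
        m = GeometricSizeModel(p=0.3, max_size=4)
        draws = [m.sample(rng) for _ in range(2000)]
        assert min(draws) >= 1 and max(draws) <= 4

    @pytest.mark.parametrize(
        "sizes, expected",
        [([1.223] , None), ([1, 1, 1], 1.0), ([1, 3], 0.5)],
    )
    def test_estimator(self, sizes, expected):
        if expected is None:
            # mean cluster size 1.223 -> p = 1/1.223
            assert estimate_geometric_p([1.223]) == pytest.approx(0.8177, abs=2e-4)
        else:
            assert estimate_geometric_p(sizes) == pytest.approx(expected)

    def test_estimator_rejects_empty(self):
        with pytest.raises(ValueError):
            estimate_geometric_p([])


class TestNullGenerator:
    def test_p_one_gives_all_singletons(self, rng):
        cfg = null_config(N=500, mean_size=1.0)
        clusters = generate_null_clusters(cfg, rng)
        assert len(clusters) == 500
        assert all(len(c) == 1 for c in clusters)

    def test_no_duplicate_species_within_cluster(self, rng):
        cfg = null_config(N=3000)
        for c in generate_null_clusters(cfg, rng):
            assert len(c) == len(set(c))

    def test_all_occurrences_assigned(self, rng):
        cfg = null_config(N=4000)
        clusters = generate_null_clusters(cfg, rng)
        assert sum(len(c) for c in clusters) == 4000

    def test_species_frequencies_within_three_se(self, rng):
        cfg = null_config(N=30_000)
        clusters = generate_null_clusters(cfg, rng)
        counts = {s: 0 for s in cfg.species}
        for c in clusters:
            for s in c:
                counts[s] += 1
        f = np.array(cfg.frequencies)
        obs = np.array([counts[s] for s in cfg.species], dtype=float)
        z = (obs - cfg.N * f) / np.sqrt(cfg.N * f * (1 - f))
        assert np.abs(z).max() < 3.5

    def test_cluster_sizes_follow_truncated_geometric(self, rng):
        cfg = null_config(N=30_000)
        clusters = generate_null_clusters(cfg, rng)
        sizes = np.array([len(c) for c in clusters])
        obs = np.bincount(sizes, minlength=cfg.size_model.max_size + 1)[1:].astype(float)
        exp = cfg.size_model.pmf() * sizes.size
        while exp.size > 2 and exp[-1] < 5:
            exp[-2] += exp[-1]
            obs[-2] += obs[-1]
            exp, obs = exp[:-1], obs[:-1]
        res = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert res.pvalue > 0.01


class TestAssociationDifference:
    def test_identical_counts_score_zero(self):
        sp = ["A", "B", "C"]
        c = counts_from_clusters([["A", "B"], ["A", "C"]], sp)
        assert association_difference(c, c) == 0.0

    def test_disjoint_unit_masses_score_two(self):
        sp = ["A", "B", "C"]
        sim = counts_from_clusters([["A", "B"]], sp)
        obs = counts_from_clusters([["A", "C"]], sp)
        assert association_difference(sim, obs) == pytest.approx(2.0)

    def test_scale_invariance(self):
        sp = ["A", "B", "C"]
        sim = counts_from_clusters([["A", "B"], ["A", "B"], ["B", "C"]], sp)
        obs = counts_from_clusters([["A", "C"], ["B", "C"]], sp)
        scaled = type(sim)(sim.w * 7, sim.species)
        assert association_difference(scaled, obs) == pytest.approx(
            association_difference(sim, obs)
        )

    def test_species_mismatch_rejected(self):
        a = counts_from_clusters([["A", "B"]], ["A", "B"])
        b = counts_from_clusters([["A", "B"]], ["B", "A"])
        with pytest.raises(ValueError):
            association_difference(a, b)


class TestPreferenceSwaps:
    def test_k_zero_returns_input_unchanged(self, rng):
        cfg = null_config(N=800)
        clusters = generate_null_clusters(cfg, rng)
        target = counts_from_clusters(clusters, list(cfg.species))
        out = apply_preference_swaps(clusters, target, 0, rng)
        assert out == clusters

    def test_swaps_conserve_margins_and_never_increase_score(self, rng):
        cfg = null_config(N=1500)
        clusters = generate_null_clusters(cfg, rng)
        other = generate_null_clusters(cfg, rng)
        target = counts_from_clusters(other, list(cfg.species))
        occ_before = sorted(s for c in clusters for s in c)
        sizes_before = sorted(len(c) for c in clusters)
        score = association_difference(
            counts_from_clusters(clusters, list(cfg.species)), target
        )
        work = clusters
        for _ in range(5):
            work = apply_preference_swaps(work, target, 400, rng)
            now = association_difference(
                counts_from_clusters(work, list(cfg.species)), target
            )
            assert now <= score + 1e-12
            score = now
        assert sorted(s for c in work for s in c) == occ_before
        assert sorted(len(c) for c in work) == sizes_before

    def test_swaps_move_toward_target(self, rng):
        cfg = null_config(N=1500)
        clusters = generate_null_clusters(cfg, rng)
        target = counts_from_clusters(generate_null_clusters(cfg, rng), list(cfg.species))
        before = association_difference(
            counts_from_clusters(clusters, list(cfg.species)), target
        )
        after_cl = apply_preference_swaps(clusters, target, 4000, rng)
        after = association_difference(
            counts_from_clusters(after_cl, list(cfg.species)), target
        )
        assert after < before


class TestRankSimulation:
    def test_two_reps_percentiles_bracket_the_two_ranks(self):
        cfg = null_config(N=400, n_reps=2, seed=4)
        rp = simulate_betweenness_ranks(cfg)
        t = rp.table
        assert (t["q05"] <= t["mean_rank"] + 1e-12).all()
        assert (t["mean_rank"] <= t["q95"] + 1e-12).all()

    def test_uniform_frequencies_give_symmetric_mean_ranks(self):
        sp = small_species(5)
        cfg = SimulationConfig(
            species=tuple(sp),
            frequencies=tuple([0.2] * 5),
            N=300,
            size_model=GeometricSizeModel(p=1 / 1.3, max_size=5),
            n_reps=300,
            seed=7,
        )
        rp = simulate_betweenness_ranks(cfg)
        assert rp.table["mean_rank"].to_numpy() == pytest.approx(
            np.full(5, 3.0), abs=0.35
        )

    def test_same_seed_reproduces(self):
        cfg = null_config(N=400, n_reps=5, seed=99)
        a = simulate_betweenness_ranks(cfg).table
        b = simulate_betweenness_ranks(cfg).table
        assert a.equals(b)

    def test_from_observation_recovers_scale(self, rng):
        cfg = null_config(N=2000)
        clusters = generate_null_clusters(cfg, rng)
        from tests.conftest import make_records

        records = make_records(clusters)
        est = SimulationConfig.from_observation(records)
        assert est.N == 2000
        assert est.size_model.p == pytest.approx(
            1 / np.mean([len(c) for c in clusters])
        )
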