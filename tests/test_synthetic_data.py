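import numpy as np
import pytest

from mixnet.association_stats import test_dyad as dyad_test
from mixnet.association_stats import test_node_strength as strength_test
from mixnet.core_data import (
    SpeciesCatalog,
    build_occurrence_matrix,
    read_clusters,
)
from mixnet.experiments import small_species
from mixnet.synthetic_data import (
    GroundTruth,
    default_frequencies,
    generate_community,
    load_truth,
    write_fixture,
)


def null_truth(n=10, **kw):
    sp = small_species(n)
    return GroundTruth(species=sp, frequencies=default_frequencies(sp), **kw)


class TestGroundTruth:
    def test_frequencies_normalized(self):
        t = GroundTruth(species=["A", "B"], frequencies={"A": 2.0, "B": 2.0})
        assert t.frequencies == {"A": 0.5, "B": 0.5}

    def test_phi_below_one_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(
                species=["A", "B"],
                frequencies={"A": 1, "B": 1},
                planted_dyads=[(("A", "B"), 0.5)],
            )

    def test_phi_matrix_symmetric_with_solitary_suppression(self):
        t = null_truth(4)
        t.planted_dyads = [(("S01", "S02"), 4.0)]
        t.planted_solitaries = {"S03"}
        phi = t.phi_matrix()
        assert (phi == phi.T).all()
        assert phi[0, 1] == 4.0
        assert phi[2, 0] == pytest.approx(1 / 8)

    def test_yaml_round_trip(self, tmp_path):
        t = null_truth(5, seed=77)
        t.planted_dyads = [(("S01", "S03"), 6.0)]
        t.partner_multipliers = {("S01", "S03"): 2.5}
        records = generate_community(t, 50, seed=1)
        paths = write_fixture(records, t, tmp_path / "fx")
        back = load_truth(paths["truth"])
        assert back.seed == 77
        assert back.planted_dyads == t.planted_dyads
        assert back.partner_multipliers == t.partner_multipliers


class TestGenerateCommunity:
    def test_exact_cluster_count_and_no_duplicates(self):
        records = generate_community(null_truth(), 250, seed=0)
        assert len(records) == 250
        for r in records:
            assert len(r.species) == len(r.members)

    def test_null_embedding_matches_abundance_model(self):
        """phi = 1 communities reproduce the configured frequencies and the
        truncated-geometric cluster sizes (same machinery as the simulator)."""
        truth = null_truth()
        records = generate_community(truth, 4000, seed=5)
        occ = {}
        for r in records:
            for s in r.species:
                occ[s] = occ.get(s, 0) + 1
        total = sum(occ.values())
        f = np.array([truth.frequencies[s] for s in truth.species])
        obs = np.array([occ.get(s, 0) for s in truth.species]) / total
        z = (obs - f) * np.sqrt(total) / np.sqrt(f * (1 - f))
        assert np.abs(z).max() < 3.5
        mean_size = np.mean([r.n_species for r in records])
        assert mean_size == pytest.approx(truth.mean_cluster_size, rel=0.05)

    def test_group_sizes_at_least_one_and_overdispersed(self):
        truth = null_truth()
        truth.group_size_mean = {s: 6.0 for s in truth.species}
        records = generate_community(truth, 2000, seed=2)
        sizes = np.array([g for r in records for _, g in r.members])
        assert sizes.min() >= 1
        assert sizes.mean() == pytest.approx(6.0, rel=0.1)
        assert sizes.var() > sizes.mean()  # negative binomial: var > mean

    def test_partner_multiplier_shifts_conditional_sizes(self):
        truth = null_truth(6)
        truth.planted_dyads = [(("S01", "S02"), 8.0)]
        truth.partner_multipliers = {("S01", "S02"): 3.0}
        records = generate_community(truth, 3000, seed=3)
        with_p, without_p = [], []
        for r in records:
            if "S01" in r.species:
                (with_p if "S02" in r.species else without_p).append(r.group_size("S01"))
        assert np.mean(with_p) > 1.8 * np.mean(without_p)

    def test_habitats_follow_mixture(self):
        truth = null_truth()
        truth.habitat_mixture = {"grassland": 0.8, "woodland": 0.2}
        records = generate_community(truth, 1000, seed=4)
        share = np.mean([r.habitat == "grassland" for r in records])
        assert share == pytest.approx(0.8, abs=0.05)

    def test_planted_solitary_detected_by_lower_tail_strength(self):
        """A frequent species planted to avoid all others should show a
        significantly small node strength in most datasets."""
        hits = 0
        n_data = 25
        for d in range(n_data):
            truth = null_truth()
            truth.planted_solitaries = {"S02"}
            records = generate_community(truth, 1000, seed=1000 + d)
            matrix = build_occurrence_matrix(records, species_subset=truth.species)
            rep = strength_test(matrix, "S02", m=199, seed=d)
            hits += rep.p_lower <= 0.05
        assert hits >= 0.8 * n_data

    def test_dyad_power_increases_with_preference_strength(self):
        """Rejection of the planted pair must not decrease along
        phi = 1, 2, 4, 8 (Monte-Carlo slack of 5 points per step)."""
        sp = small_species(10)
        rates = []
        n_data = 60
        for level, phi in enumerate([1.0, 2.0, 4.0, 8.0]):
            hits = 0
            for d in range(n_data):
                truth = GroundTruth(
                    species=sp,
                    frequencies=default_frequencies(sp),
                    planted_dyads=[] if phi == 1 else [(("S01", "S02"), phi)],
                )
                records = generate_community(truth, 400, seed=20_000 + 100 * level + d)
                matrix = build_occurrence_matrix(records, species_subset=sp)
                hits += dyad_test(matrix, ("S01", "S02"), m=99, seed=d).p_upper <= 0.05
            rates.append(100 * hits / n_data)
        for lo, hi in zip(rates, rates[1:]):
            assert hi >= lo - 5.0
        assert rates[-1] > rates[0] + 30


class TestWriteFixture:
    def test_clusters_round_trip_through_reader(self, tmp_path):
        truth = null_truth(5)
        records = generate_community(truth, 80, seed=9)
        paths = write_fixture(records, truth, tmp_path / "fx")
        catalog = SpeciesCatalog.from_csv(paths["catalog"])
        back = read_clusters(paths["clusters"], catalog)
        assert back == records

    def test_study_species_fixture_validates_against_shipped_catalog(self, tmp_path):
        truth = GroundTruth.study_community(seed=11)
        records = generate_community(truth, 120, seed=11)
        paths = write_fixture(records, truth, tmp_path / "fx")
        back = read_clusters(paths["clusters"], SpeciesCatalog.default())
        assert {s for r in back for s in r.species} <= set(
            SpeciesCatalog.default().species_ids
        )
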