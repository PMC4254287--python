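"""Ground-truth community generator for end-to-end testing.

Emulates the structure of the field data — a couple dozen species with
heterogeneous sighting frequencies, cluster sizes roughly geometric with
mean around 1.2-1.35, heavy-tailed conspecific group sizes, and habitat
labels from six categories — with *known* planted structure: pairwise
association preferences (phi), solitary (avoidant) species, and
partner-conditional group-size effects.

Preference injection works on the fixed-margin class directly: cluster
sizes and per-species occurrence totals come from the simulator's steps
1-2, and the species-to-cluster assignment is then drawn from the
exponentially tilted family

    P(M) ∝ prod_{i<j} phi_ij^{w_ij(M)}

over all binary matrices with those margins, sampled with a Metropolis
checkerboard chain.  At phi = 1 this is *exactly* the uniform fixed-margin
distribution — the null of the randomization tests — so planted effects
nest the test null cleanly.  (A plain sequential fill is measurably
non-uniform conditional on margins, which would contaminate calibration
studies.)  The analysis-side swap procedure of the cluster simulator is
never used for generation.

Group sizes are 1-shifted negative binomial (overdispersed, >= 1), with a
multiplicative mean effect when a named partner is present in the cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .cluster_simulator import GeometricSizeModel, fill_clusters
from .margin_randomizer import sample_tilted_matrix
from .core_data import (
    HABITATS,
    ClusterRecord,
    SpeciesCatalog,
    write_clusters,
)

#: Default mean cluster size (species per cluster); mid-range of the
#: study's four strata (1.223-1.346).
DEFAULT_MEAN_CLUSTER_SIZE = 1.28


def default_frequencies(species: list[str], concentration: float = 1.0) -> dict[str, float]:
    """Heterogeneous relative sighting frequencies (Zipf-like, deterministic).

    A power-law profile over the species list emulates the uneven sighting
    counts of real surveys: a few very common grazers, many rare species.
    The default concentration puts roughly a quarter to a third of all
    sightings on the most common species, as in surveys dominated by zebra
    and wildebeest.
    """
    w = 1.0 / np.arange(1, len(species) + 1, dtype=float) ** concentration
    w /= w.sum()
    return dict(zip(species, w))


@dataclass
class GroundTruth:
    """Known data-generating structure for a synthetic community."""

    species: list[str]
    frequencies: dict[str, float]
    planted_dyads: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    planted_solitaries: set[str] = field(default_factory=set)
    solitary_strength: float = 8.0
    mean_cluster_size: float = DEFAULT_MEAN_CLUSTER_SIZE
    group_size_mean: dict[str, float] = field(default_factory=dict)  # default 3.0
    group_size_dispersion: float = 1.5  # negative-binomial shape r
    partner_multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    habitat_mixture: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        f = np.array([self.frequencies[s] for s in self.species], dtype=float)
        if (f < 0).any() or f.sum() <= 0:
            raise ValueError("frequencies must be non-negative with positive sum")
        self.frequencies = dict(zip(self.species, f / f.sum()))
        for (pair, phi) in self.planted_dyads:
            if phi < 1:
                raise ValueError("preference strength phi must be >= 1")
            if pair[0] not in self.frequencies or pair[1] not in self.frequencies:
                raise ValueError(f"planted dyad {pair} names unknown species")
        if not self.habitat_mixture:
            self.habitat_mixture = {h: 1.0 / len(HABITATS) for h in HABITATS}
        if any(v <= 0 for v in self.partner_multipliers.values()):
            raise ValueError("partner multipliers must be positive")
        if not self.mean_cluster_size >= 1:
            raise ValueError("mean cluster size must be >= 1")

    @property
    def size_model(self) -> GeometricSizeModel:
        return GeometricSizeModel(
            p=1.0 / self.mean_cluster_size, max_size=len(self.species)
        )

    def phi_matrix(self) -> np.ndarray:
        """Symmetric pairwise preference weights; 1 = no preference."""
        n = len(self.species)
        idx = {s: i for i, s in enumerate(self.species)}
        phi = np.ones((n, n), dtype=float)
        for (a, b), strength in self.planted_dyads:
            phi[idx[a], idx[b]] = strength
            phi[idx[b], idx[a]] = strength
        for s in self.planted_solitaries:
            i = idx[s]
            phi[i, :] /= self.solitary_strength
            phi[:, i] /= self.solitary_strength
            phi[i, i] = 1.0
        return phi

    def is_null(self) -> bool:
        return not self.planted_dyads and not self.planted_solitaries

    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "frequencies": {s: float(f) for s, f in self.frequencies.items()},
            "planted_dyads": [
                {"pair": list(pair), "phi": float(phi)} for pair, phi in self.planted_dyads
            ],
            "planted_solitaries": sorted(self.planted_solitaries),
            "solitary_strength": float(self.solitary_strength),
            "mean_cluster_size": float(self.mean_cluster_size),
            "group_size_mean": {s: float(v) for s, v in self.group_size_mean.items()},
            "group_size_dispersion": float(self.group_size_dispersion),
            "partner_multipliers": [
                {"species": s, "partner": p, "multiplier": float(v)}
                for (s, p), v in self.partner_multipliers.items()
            ],
            "habitat_mixture": {h: float(v) for h, v in self.habitat_mixture.items()},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            species=list(d["species"]),
            frequencies=dict(d["frequencies"]),
            planted_dyads=[
                ((p["pair"][0], p["pair"][1]), float(p["phi"]))
                for p in d.get("planted_dyads", [])
            ],
            planted_solitaries=set(d.get("planted_solitaries", [])),
            solitary_strength=float(d.get("solitary_strength", 8.0)),
            mean_cluster_size=float(d.get("mean_cluster_size", DEFAULT_MEAN_CLUSTER_SIZE)),
            group_size_mean=dict(d.get("group_size_mean", {})),
            group_size_dispersion=float(d.get("group_size_dispersion", 1.5)),
            partner_multipliers={
                (e["species"], e["partner"]): float(e["multiplier"])
                for e in d.get("partner_multipliers", [])
            },
            habitat_mixture=dict(d.get("habitat_mixture", {})),
            seed=d.get("seed"),
        )

    @classmethod
    def study_community(cls, seed: int | None = None) -> "GroundTruth":
        """A 26-species null community shaped like the study system."""
        species = SpeciesCatalog.default().species_ids
        return cls(species=species, frequencies=default_frequencies(species), seed=seed)


def _draw_group_size(
    mean: float, dispersion: float, rng: np.random.Generator
) -> int:
    """1-shifted negative binomial with the given mean (>= 1)."""
    extra = mean - 1.0
    if extra <= 0:
        return 1
    r = dispersion
    p = r / (r + extra)
    return 1 + int(rng.negative_binomial(r, p))


#: Metropolis sweeps (proposals per matrix cell) used to equilibrate the
#: tilted assignment; the plain chain decorrelates well within a few
#: sweeps on matrices of this shape.
MIXING_SWEEPS = 50


def generate_community(
    truth: GroundTruth,
    n_clusters: int,
    seed: int | np.random.Generator | None = None,
    ecosystem: str = "TME",
    season: str = "wet",
) -> list[ClusterRecord]:
    """Generate exactly `n_clusters` cluster records with known structure.

    Margins (cluster sizes, per-species occurrence totals) come from the
    simulator's steps 1-2; occurrence pools are topped up until enough
    clusters exist, then the list is truncated (clusters are
    exchangeable).  The species-to-cluster assignment is then resampled
    from the phi-tilted fixed-margin family, which at phi = 1 is the
    uniform fixed-margin null.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(truth.seed if seed is None else seed)
    freqs = np.array([truth.frequencies[s] for s in truth.species])
    size_model = truth.size_model
    clusters: list[list[int]] = []
    while len(clusters) < n_clusters:
        shortfall = n_clusters - len(clusters)
        n_occ = max(8, int(np.ceil(shortfall * truth.mean_cluster_size)))
        pool = rng.multinomial(n_occ, freqs)
        clusters.extend(fill_clusters(pool, size_model, rng))
    clusters = clusters[:n_clusters]

    n_species = len(truth.species)
    if n_clusters >= 2 and n_species >= 2:
        cells = np.zeros((n_clusters, n_species), dtype=np.uint8)
        for c, members in enumerate(clusters):
            cells[c, members] = 1
        logphi = np.log(truth.phi_matrix())
        sample_tilted_matrix(cells, logphi, MIXING_SWEEPS * cells.size, rng)
        clusters = [list(np.flatnonzero(cells[c])) for c in range(n_clusters)]

    habitats = list(truth.habitat_mixture)
    hab_p = np.array([truth.habitat_mixture[h] for h in habitats], dtype=float)
    hab_p /= hab_p.sum()
    hab_draws = rng.choice(len(habitats), size=n_clusters, p=hab_p)
    width = len(str(n_clusters))
    records = []
    for c, members_idx in enumerate(clusters):
        members_sp = [truth.species[i] for i in members_idx]
        members = []
        for s in members_sp:
            mean = truth.group_size_mean.get(s, 3.0)
            for partner in members_sp:
                if partner != s:
                    mean *= truth.partner_multipliers.get((s, partner), 1.0)
            members.append((s, _draw_group_size(mean, truth.group_size_dispersion, rng)))
        records.append(
            ClusterRecord(
                cluster_id=f"{ecosystem}-{season}-{c + 1:0{width}d}",
                ecosystem=ecosystem,
                season=season,
                habitat=habitats[int(hab_draws[c])],
                members=members,
            )
        )
    return records


def write_fixture(records: list[ClusterRecord], truth: GroundTruth, outdir) -> dict:
    """Write clusters.csv, truth.yaml and catalog.csv under `outdir`.

    The catalog is the shipped study catalog when every species id belongs
    to it; otherwise a minimal synthetic catalog is written.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clusters_path = outdir / "clusters.csv"
    write_clusters(records, clusters_path)
    truth_path = outdir / "truth.yaml"
    with open(truth_path, "w") as fh:
        yaml.safe_dump(truth.to_dict(), fh, sort_keys=False)
    catalog_path = outdir / "catalog.csv"
    default = SpeciesCatalog.default()
    if all(s in default for s in truth.species):
        rows = [default[s] for s in truth.species]
        header = "species_id,common_name,scientific_name,guild,esw_m\n"
        body = "".join(
            f'{e.species_id},"{e.common_name}","{e.scientific_name}",{e.guild},{e.esw_m}\n'
            for e in rows
        )
    else:
        # synthetic stand-in catalog for invented species ids
        header = "species_id,common_name,scientific_name,guild,esw_m\n"
        body = "".join(
            f"{s},synthetic species {s},Syntheticus {s.lower()},mixed,300\n"
            for s in truth.species
        )
    catalog_path.write_text(header + body)
    return {"clusters": clusters_path, "truth": truth_path, "catalog": catalog_path}


def load_truth(path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_dict(yaml.safe_load(fh))
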