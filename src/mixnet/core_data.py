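"""Data model for cluster sightings of savannah mammals.

A *cluster* is one independent sighting of one or more species whose
individuals were within 50 m of each other (the 50 m co-membership rule and
the 500 m scan radius are field conventions of the survey; cluster
membership is taken as given here, never re-derived from coordinates).
Sightings are stored in long format: one CSV row per species occurrence
within a cluster, carrying the conspecific group size of that species.

The central analysis object is the binary :class:`OccurrenceMatrix`
(clusters x species): row sums are cluster sizes (numbers of species),
column sums are per-species sighting counts.  All randomization tests
condition on both margins.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ECOSYSTEMS = ("TME", "SNE")
SEASONS = ("wet", "dry")
HABITATS = (
    "grassland",
    "open_bushland",
    "closed_bushland",
    "woodland",
    "riverine",
    "shrubland",
)
GUILDS = ("grazer", "browser", "mixed", "omnivore", "carnivore")

CLUSTER_COLUMNS = ["cluster_id", "ecosystem", "season", "habitat", "species", "group_size"]

#: Effective-strip-width cutoff (metres) for the high-detectability species
#: subset used for network construction.  Inclusive: a species whose ESW
#: equals the cutoff is retained.
DEFAULT_ESW_THRESHOLD_M = 230.0


class ValidationError(ValueError):
    """Input data violates the cluster-record contract."""


class UnknownSpeciesError(ValidationError):
    """A species id is not present in the catalog."""


class DuplicateOccurrenceError(ValidationError):
    """The same species appears twice within one cluster."""


@dataclass(frozen=True)
class CatalogEntry:
    species_id: str
    common_name: str
    scientific_name: str
    guild: str
    esw_m: float

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise ValidationError(f"unknown feeding guild {self.guild!r} for {self.species_id}")
        if not self.esw_m > 0:
            raise ValidationError(f"ESW must be positive, got {self.esw_m} for {self.species_id}")


@dataclass
class SpeciesCatalog:
    """Catalog of the study species with detectability (ESW, metres).

    Sympatric taxa pooled in the field protocol (the three jackal species)
    appear as a single entry; pooling lives in the catalog, not the reader.
    """

    entries: list[CatalogEntry]

    def __post_init__(self) -> None:
        ids = [e.species_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate species_id in catalog")
        self._by_id = {e.species_id: e for e in self.entries}

    @property
    def species_ids(self) -> list[str]:
        return [e.species_id for e in self.entries]

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._by_id

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, species_id: str) -> CatalogEntry:
        try:
            return self._by_id[species_id]
        except KeyError:
            raise UnknownSpeciesError(f"species {species_id!r} not in catalog") from None

    @classmethod
    def from_csv(cls, path) -> "SpeciesCatalog":
        df = pd.read_csv(path)
        required = {"species_id", "common_name", "scientific_name", "guild", "esw_m"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"catalog missing columns: {sorted(missing)}")
        entries = [
            CatalogEntry(
                species_id=str(r.species_id),
                common_name=str(r.common_name),
                scientific_name=str(r.scientific_name),
                guild=str(r.guild),
                esw_m=float(r.esw_m),
            )
            for r in df.itertuples()
        ]
        return cls(entries)

    @classmethod
    def default(cls) -> "SpeciesCatalog":
        """The shipped 26-species study catalog."""
        with importlib.resources.as_file(
            importlib.resources.files("mixnet.data") / "catalog.csv"
        ) as p:
            return cls.from_csv(p)


@dataclass
class ClusterRecord:
    """One observed cluster: member species and their conspecific group sizes."""

    cluster_id: str
    ecosystem: str
    season: str
    habitat: str
    members: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if self.ecosystem not in ECOSYSTEMS:
            raise ValidationError(f"cluster {self.cluster_id}: unknown ecosystem {self.ecosystem!r}")
        if self.season not in SEASONS:
            raise ValidationError(f"cluster {self.cluster_id}: unknown season {self.season!r}")
        if self.habitat not in HABITATS:
            raise ValidationError(f"cluster {self.cluster_id}: unknown habitat {self.habitat!r}")
        if not self.members:
            raise ValidationError(f"cluster {self.cluster_id}: no members")
        sp = [s for s, _ in self.members]
        if len(sp) != len(set(sp)):
            raise DuplicateOccurrenceError(f"cluster {self.cluster_id}: duplicate species in {sp}")
        for s, g in self.members:
            if not (isinstance(g, (int, np.integer)) and g >= 1):
                raise ValidationError(
                    f"cluster {self.cluster_id}: group size for {s} must be an integer >= 1, got {g!r}"
                )

    @property
    def species(self) -> set[str]:
        return {s for s, _ in self.members}

    @property
    def n_species(self) -> int:
        return len(self.members)

    @property
    def is_mixed(self) -> bool:
        return len(self.members) >= 2

    def group_size(self, species_id: str) -> int:
        for s, g in self.members:
            if s == species_id:
                return g
        raise UnknownSpeciesError(f"species {species_id!r} not in cluster {self.cluster_id}")


@dataclass
class OccurrenceMatrix:
    """Binary clusters x species matrix; the object that is randomized."""

    cells: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    habitat_of_row: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.uint8)
        if self.cells.ndim != 2:
            raise ValidationError("occurrence matrix must be 2-D")
        if self.cells.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("label lengths do not match matrix shape")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValidationError("occurrence matrix entries must be 0/1")

    @property
    def n_clusters(self) -> int:
        return self.cells.shape[0]

    @property
    def n_species(self) -> int:
        return self.cells.shape[1]

    @property
    def row_sums(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    def col_index(self, species_id: str) -> int:
        try:
            return self.col_labels.index(species_id)
        except ValueError:
            raise UnknownSpeciesError(f"species {species_id!r} not in matrix") from None

    def copy(self) -> "OccurrenceMatrix":
        return OccurrenceMatrix(
            self.cells.copy(), list(self.row_labels), list(self.col_labels), dict(self.habitat_of_row)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.row_labels, columns=self.col_labels)

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("cluster_id").to_csv(path)


@dataclass
class SightingSeries:
    """All occurrences of one species, with group sizes and cluster context."""

    species_id: str
    # (cluster_id, group_size, is_mixed, partners)
    occurrences: list[tuple[str, int, bool, frozenset]]

    @property
    def k(self) -> int:
        return len(self.occurrences)

    @property
    def group_sizes(self) -> np.ndarray:
        return np.array([g for _, g, _, _ in self.occurrences], dtype=np.int64)

    @property
    def is_mixed(self) -> np.ndarray:
        return np.array([m for _, _, m, _ in self.occurrences], dtype=bool)

    def partner_present(self, partner: str) -> np.ndarray:
        return np.array([partner in p for _, _, _, p in self.occurrences], dtype=bool)


def read_clusters(path, catalog: SpeciesCatalog) -> list[ClusterRecord]:
    """Read long-format cluster sightings, merging rows that share a cluster_id.

    Raises a named validation error for unknown species or duplicate
    (cluster_id, species) rows, citing the offending row.
    """
    df = pd.read_csv(path, dtype={"cluster_id": str, "species": str})
    missing = set(CLUSTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"clusters file missing columns: {sorted(missing)}")
    records: dict[str, dict] = {}
    seen: set[tuple[str, str]] = set()
    for idx, row in enumerate(df.itertuples(), start=2):  # header is line 1
        cid, sp = row.cluster_id, row.species
        if sp not in catalog:
            raise UnknownSpeciesError(f"line {idx}: species {sp!r} not in catalog")
        if (cid, sp) in seen:
            raise DuplicateOccurrenceError(
                f"line {idx}: duplicate occurrence of species {sp!r} in cluster {cid!r}"
            )
        seen.add((cid, sp))
        meta = (row.ecosystem, row.season, row.habitat)
        if cid not in records:
            records[cid] = {"meta": meta, "members": []}
        elif records[cid]["meta"] != meta:
            raise ValidationError(
                f"line {idx}: cluster {cid!r} has inconsistent ecosystem/season/habitat"
            )
        records[cid]["members"].append((sp, int(row.group_size)))
    return [
        ClusterRecord(
            cluster_id=cid,
            ecosystem=r["meta"][0],
            season=r["meta"][1],
            habitat=r["meta"][2],
            members=r["members"],
        )
        for cid, r in records.items()
    ]


def write_clusters(records: list[ClusterRecord], path) -> None:
    """Write records as long-format CSV (inverse of :func:`read_clusters`)."""
    rows = [
        {
            "cluster_id": r.cluster_id,
            "ecosystem": r.ecosystem,
            "season": r.season,
            "habitat": r.habitat,
            "species": s,
            "group_size": g,
        }
        for r in records
        for s, g in r.members
    ]
    pd.DataFrame(rows, columns=CLUSTER_COLUMNS).to_csv(path, index=False)


def build_occurrence_matrix(
    records: list[ClusterRecord], species_subset: list[str] | None = None
) -> OccurrenceMatrix:
    """Build the binary clusters x species matrix.

    With a ``species_subset``, columns follow the subset order and clusters
    containing none of the retained species are dropped (no all-zero rows).
    Without a subset, columns are sorted species ids.
    """
    if not records:
        raise ValidationError("no cluster records")
    if species_subset is not None:
        cols = list(species_subset)
        if len(cols) != len(set(cols)):
            raise ValidationError("species_subset contains duplicates")
    else:
        cols = sorted({s for r in records for s in r.species})
    col_idx = {s: j for j, s in enumerate(cols)}
    rows, row_labels, habitat_of_row = [], [], {}
    for r in records:
        v = np.zeros(len(cols), dtype=np.uint8)
        for s in r.species:
            j = col_idx.get(s)
            if j is not None:
                v[j] = 1
        if species_subset is not None and not v.any():
            continue
        rows.append(v)
        row_labels.append(r.cluster_id)
        habitat_of_row[r.cluster_id] = r.habitat
    if not rows:
        raise ValidationError("species_subset leaves no clusters")
    return OccurrenceMatrix(np.vstack(rows), row_labels, cols, habitat_of_row)


def filter_by_detectability(
    catalog: SpeciesCatalog, threshold_m: float = DEFAULT_ESW_THRESHOLD_M
) -> list[str]:
    """Species whose effective strip width meets the cutoff, in catalog order."""
    if not threshold_m > 0:
        raise ValidationError("threshold must be positive")
    return [e.species_id for e in catalog.entries if e.esw_m >= threshold_m]


def sighting_series(records: list[ClusterRecord], species_id: str) -> SightingSeries:
    """Per-occurrence group sizes and cluster context for one species."""
    occ = []
    for r in records:
        if species_id in r.species:
            partners = frozenset(r.species - {species_id})
            occ.append((r.cluster_id, r.group_size(species_id), r.is_mixed, partners))
    if not occ:
        raise UnknownSpeciesError(f"species {species_id!r} never observed")
    return SightingSeries(species_id, occ)


def stratum_cluster_counts(records: list[ClusterRecord]) -> pd.DataFrame:
    """Cluster counts per (ecosystem, season) stratum, plus the grand total row."""
    df = pd.DataFrame(
        [(r.ecosystem, r.season) for r in records], columns=["ecosystem", "season"]
    )
    counts = (
        df.value_counts(["ecosystem", "season"]).rename("n_clusters").reset_index()
    )
    return counts.sort_values(["ecosystem", "season"]).reset_index(drop=True)


def load_survey_design() -> pd.DataFrame:
    """Shipped survey design: per-stratum cluster counts and mean cluster sizes."""
    with importlib.resources.as_file(
        importlib.resources.files("mixnet.data") / "survey_strata.csv"
    ) as p:
        return pd.read_csv(p)
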