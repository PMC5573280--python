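"""Interaction-data containers and I/O.

The central container is :class:`InteractionDataset`: a plant-individual ×
animal-species count matrix together with the map from each plant individual
to its plant species.  Keeping the individual level (rather than aggregating
to a species × species matrix immediately) is what lets the model separate an
animal's abundance from its preference for a plant species.

Data augmentation for richness estimation — appending all-zero pseudo-species
to form a "supercommunity" — lives here as :func:`augment_dataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InteractionDataset",
    "SpeciesMatrix",
    "ValidationError",
    "read_interactions",
    "write_interactions",
    "aggregate_to_species",
    "augment_dataset",
    "observation_effort_hours",
]

AUGMENTED_PREFIX = "aug_"


class ValidationError(ValueError):
    """Raised when an input table violates the dataset invariants."""


@dataclass
class InteractionDataset:
    """Counts of animal species on individual plants.

    Parameters
    ----------
    counts
        Non-negative integer matrix, rows = plant individuals, columns =
        animal species.  Columns beyond ``n_observed`` are augmented
        (identically zero) pseudo-species.
    plant_species_of
        Integer array mapping each row (individual) to a plant-species index.
    plant_labels, animal_labels, individual_labels
        Identifiers for plant species, animal species and individuals.
    n_observed
        Number of animal species actually recorded (columns with data).
    m_augmented
        Number of appended all-zero pseudo-species.
    """

    counts: np.ndarray
    plant_species_of: np.ndarray
    plant_labels: list[str]
    animal_labels: list[str]
    individual_labels: list[str]
    n_observed: int
    m_augmented: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.plant_species_of = np.asarray(self.plant_species_of, dtype=int)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(np.equal(np.mod(c, 1), 0)):
                raise ValidationError("counts must be integers")
            self.counts = c = c.astype(np.int64)
        if (c < 0).any():
            i, j = np.argwhere(c < 0)[0]
            raise ValidationError(
                f"negative count at individual {self.individual_labels[i]!r}, "
                f"animal {self.animal_labels[j]!r}"
            )
        if len(self.plant_species_of) != c.shape[0]:
            raise ValidationError("plant_species_of must map every row")
        if len(self.animal_labels) != c.shape[1]:
            raise ValidationError("animal_labels must label every column")
        if self.n_observed + self.m_augmented != c.shape[1]:
            raise ValidationError("S must equal n_observed + m_augmented")
        if self.m_augmented and c[:, self.n_observed:].any():
            raise ValidationError("augmented columns must be identically zero")
        present = np.unique(self.plant_species_of)
        if len(self.plant_labels) != present.size or not np.array_equal(
            present, np.arange(len(self.plant_labels))
        ):
            raise ValidationError("every plant species needs >= 1 individual")

    # -- convenience --------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_plant_species(self) -> int:
        return len(self.plant_labels)

    @property
    def supercommunity_size(self) -> int:
        return self.counts.shape[1]

    def individuals_per_plant(self) -> np.ndarray:
        """Number of observed individuals for each plant species."""
        return np.bincount(self.plant_species_of, minlength=self.n_plant_species)

    def species_totals(self) -> np.ndarray:
        """Summed counts per (plant species, animal species) pair."""
        K = self.n_plant_species
        T = np.zeros((K, self.supercommunity_size), dtype=np.int64)
        np.add.at(T, self.plant_species_of, self.counts)
        return T

    def copy(self) -> "InteractionDataset":
        return InteractionDataset(
            counts=self.counts.copy(),
            plant_species_of=self.plant_species_of.copy(),
            plant_labels=list(self.plant_labels),
            animal_labels=list(self.animal_labels),
            individual_labels=list(self.individual_labels),
            n_observed=self.n_observed,
            m_augmented=self.m_augmented,
            metadata=dict(self.metadata),
        )


@dataclass
class SpeciesMatrix:
    """Weighted plant-species × animal-species interaction matrix."""

    weights: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.isnan(self.weights).any():
            raise ValidationError("species matrix contains NaN")

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.row_labels, columns=self.col_labels)


# ---------------------------------------------------------------------------
# construction and I/O


def from_long_frame(df: pd.DataFrame, *, sort_labels: bool = True) -> InteractionDataset:
    """Build a dataset from a long-format table.

    Expected columns: ``individual``, ``plant_species``, ``animal_species``,
    ``count``.  Duplicate (individual, animal) rows are summed; pairs absent
    from the table are zero.  A zero-count row still registers its individual
    and animal species.
    """
    required = {"individual", "plant_species", "animal_species", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    counts_col = pd.to_numeric(df["count"], errors="raise")
    bad = ~np.equal(np.mod(counts_col, 1), 0) | (counts_col < 0)
    if bad.any():
        row = df.index[bad.to_numpy()][0]
        raise ValidationError(f"invalid count in row {row}: {df.loc[row, 'count']!r}")

    # an individual must belong to exactly one plant species
    mapping = df.groupby("individual")["plant_species"].nunique()
    if (mapping > 1).any():
        ind = mapping.index[mapping > 1][0]
        raise ValidationError(f"individual {ind!r} is mapped to two plant species")

    key = [str(x) for x in df["individual"]]
    ind_labels = sorted(set(key)) if sort_labels else list(dict.fromkeys(key))
    animal_labels = (
        sorted({str(a) for a in df["animal_species"]})
        if sort_labels
        else list(dict.fromkeys(str(a) for a in df["animal_species"]))
    )
    ind_idx = {l: i for i, l in enumerate(ind_labels)}
    ani_idx = {l: j for j, l in enumerate(animal_labels)}

    plant_of_ind = {str(i): str(p) for i, p in zip(df["individual"], df["plant_species"])}
    plant_labels = sorted(set(plant_of_ind.values())) if sort_labels else list(
        dict.fromkeys(plant_of_ind[l] for l in ind_labels)
    )
    plant_idx = {l: k for k, l in enumerate(plant_labels)}

    counts = np.zeros((len(ind_labels), len(animal_labels)), dtype=np.int64)
    np.add.at(
        counts,
        (
            [ind_idx[str(i)] for i in df["individual"]],
            [ani_idx[str(a)] for a in df["animal_species"]],
        ),
        counts_col.to_numpy(dtype=np.int64),
    )
    plant_species_of = np.array([plant_idx[plant_of_ind[l]] for l in ind_labels])
    return InteractionDataset(
        counts=counts,
        plant_species_of=plant_species_of,
        plant_labels=plant_labels,
        animal_labels=animal_labels,
        individual_labels=ind_labels,
        n_observed=len(animal_labels),
    )


def read_interactions(path, format: str = "long", *, map_path=None,
                      sort_labels: bool = True) -> InteractionDataset:
    """Read a dataset from disk.

    ``format="long"`` expects a CSV with columns (individual, plant_species,
    animal_species, count).  ``format="matrix"`` expects a counts CSV (rows =
    individuals, columns = animal species) plus a companion CSV mapping
    ``individual`` → ``plant_species`` (default ``<path>.map.csv``).
    All-zero columns in matrix form are treated as augmented pseudo-species.
    """
    if format == "long":
        return from_long_frame(pd.read_csv(path), sort_labels=sort_labels)
    if format == "matrix":
        mat = pd.read_csv(path, index_col=0)
        if map_path is None:
            map_path = str(path) + ".map.csv"
        mapping = pd.read_csv(map_path)
        mapping = dict(zip(mapping["individual"].astype(str),
                           mapping["plant_species"].astype(str)))
        ind_labels = [str(i) for i in mat.index]
        animal_labels = [str(c) for c in mat.columns]
        counts = mat.to_numpy()
        if not np.all(np.equal(np.mod(counts, 1), 0)) or (counts < 0).any():
            raise ValidationError("matrix counts must be non-negative integers")
        counts = counts.astype(np.int64)
        # augmented pseudo-species are recognised by the label convention;
        # they must be all-zero and are moved to the trailing block
        augmented = np.array([
            lab.startswith(AUGMENTED_PREFIX) and not counts[:, j].any()
            for j, lab in enumerate(animal_labels)
        ])
        order = np.argsort(augmented, kind="stable")
        counts = counts[:, order]
        animal_labels = [animal_labels[j] for j in order]
        n_obs = int((~augmented).sum())
        plant_labels = sorted(set(mapping.values()))
        plant_idx = {l: k for k, l in enumerate(plant_labels)}
        plant_species_of = np.array([plant_idx[mapping[l]] for l in ind_labels])
        return InteractionDataset(
            counts=counts,
            plant_species_of=plant_species_of,
            plant_labels=plant_labels,
            animal_labels=animal_labels,
            individual_labels=ind_labels,
            n_observed=n_obs,
            m_augmented=counts.shape[1] - n_obs,
        )
    raise ValueError(f"unknown format {format!r}")


def to_long_frame(ds: InteractionDataset) -> pd.DataFrame:
    """Long-format table of the observed part of a dataset.

    Nonzero cells are written explicitly; individuals with no captures get a
    single zero-count row so they round-trip.  Augmented columns are dropped
    (they are reproducible with :func:`augment_dataset`).
    """
    rows = []
    obs = ds.counts[:, : ds.n_observed]
    for i in range(ds.n_individuals):
        nz = np.nonzero(obs[i])[0]
        plant = ds.plant_labels[ds.plant_species_of[i]]
        if nz.size == 0:
            rows.append((ds.individual_labels[i], plant, ds.animal_labels[0], 0))
        for j in nz:
            rows.append((ds.individual_labels[i], plant, ds.animal_labels[j], int(obs[i, j])))
    # observed species recorded only at zero (e.g. a zero-count record in the
    # source table) still need one explicit row to survive the round trip
    plant0 = ds.plant_labels[ds.plant_species_of[0]]
    for j in np.nonzero(~obs.any(axis=0))[0]:
        rows.append((ds.individual_labels[0], plant0, ds.animal_labels[j], 0))
    return pd.DataFrame(rows, columns=["individual", "plant_species", "animal_species", "count"])


def write_interactions(ds: InteractionDataset, path, format: str = "long") -> None:
    """Write a dataset to CSV (see :func:`read_interactions` for layouts)."""
    if format == "long":
        to_long_frame(ds).to_csv(path, index=False)
    elif format == "matrix":
        pd.DataFrame(ds.counts, index=ds.individual_labels,
                     columns=ds.animal_labels).to_csv(path)
        pd.DataFrame({
            "individual": ds.individual_labels,
            "plant_species": [ds.plant_labels[k] for k in ds.plant_species_of],
        }).to_csv(str(path) + ".map.csv", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# transformations


def aggregate_to_species(ds: InteractionDataset) -> SpeciesMatrix:
    """Collapse individuals into the conventional species × species matrix."""
    return SpeciesMatrix(
        weights=ds.species_totals().astype(float),
        row_labels=list(ds.plant_labels),
        col_labels=list(ds.animal_labels),
    )


def augment_dataset(ds: InteractionDataset, m: int) -> InteractionDataset:
    """Append ``m`` all-zero pseudo-species to form a supercommunity.

    Total richness can then be estimated as the posterior sum of the latent
    availability indicators over observed plus augmented species; the
    supercommunity size ``S = n + m`` is an upper bound on estimable richness.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if m == 0:
        return ds.copy()
    out = ds.copy()
    out.counts = np.hstack([ds.counts, np.zeros((ds.n_individuals, m), dtype=ds.counts.dtype)])
    out.animal_labels = list(ds.animal_labels) + [
        f"{AUGMENTED_PREFIX}{i + ds.m_augmented:04d}" for i in range(m)
    ]
    out.m_augmented = ds.m_augmented + m
    out.validate()
    return out


def observation_effort_hours(n_individuals: int, minutes_per_observation: float = 15.0) -> float:
    """Total observation effort in hours for a fixed per-individual watch time."""
    return n_individuals * minutes_per_observation / 60.0
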