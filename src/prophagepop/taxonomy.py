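"""Species/genus delineation of phages from a tANI matrix.

Phages are partitioned by single-linkage threshold clustering: two genomes
belong to the same cluster when they are connected by a path of pairwise
similarities at or above the threshold.  With the conventional viral cutoffs
(species >= 95% tANI, genus >= 70% tANI) every species-level edge is also a
genus-level edge, so the species partition refines the genus partition by
construction.  Cluster labels are deterministic: each cluster is named by
its lexicographically smallest member id.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io_formats import LabeledMatrix

__all__ = [
    "TaxonomicPartition",
    "ClusterSummary",
    "SPECIES_THRESHOLD",
    "GENUS_THRESHOLD",
    "threshold_clusters",
    "assign_taxa",
    "singleton_stats",
    "filter_by_cluster_size",
    "export_species_network",
]

SPECIES_THRESHOLD = 95.0
GENUS_THRESHOLD = 70.0


def threshold_clusters(matrix: LabeledMatrix, threshold: float) -> dict[str, str]:
    """Single-linkage clusters: connected components of the graph whose
    edges are pairs with similarity >= threshold.

    Returns a mapping phage_id -> cluster label, the label being the
    lexicographically smallest member of the component.
    """
    if len(matrix) == 0:
        raise ValueError("empty similarity matrix")
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must be in [0, 100]")
    adj = csr_matrix(matrix.values >= threshold)
    _, comp = connected_components(adj, directed=False)
    members: dict[int, list[str]] = {}
    for label, c in zip(matrix.labels, comp):
        members.setdefault(int(c), []).append(label)
    out: dict[str, str] = {}
    for labs in members.values():
        name = min(labs)
        for lab in labs:
            out[lab] = name
    return out


@dataclass
class TaxonomicPartition:
    """Species- and genus-level cluster labels per phage."""

    species_label: dict[str, str]
    genus_label: dict[str, str]
    thresholds: tuple[float, float] = (SPECIES_THRESHOLD, GENUS_THRESHOLD)

    def __post_init__(self) -> None:
        if set(self.species_label) != set(self.genus_label):
            raise ValueError("species and genus partitions cover different phages")
        # species must refine genus: equal species label => equal genus label
        genus_of_species: dict[str, str] = {}
        for phage, sp in self.species_label.items():
            g = self.genus_label[phage]
            if genus_of_species.setdefault(sp, g) != g:
                raise ValueError(f"species {sp!r} spans multiple genera")

    @property
    def phage_ids(self) -> list[str]:
        return sorted(self.species_label)

    def species_sizes(self) -> Counter:
        return Counter(self.species_label.values())

    def genus_sizes(self) -> Counter:
        return Counter(self.genus_label.values())

    @property
    def n_species(self) -> int:
        return len(set(self.species_label.values()))

    @property
    def n_genera(self) -> int:
        return len(set(self.genus_label.values()))

    def to_frame(self) -> pd.DataFrame:
        ids = self.phage_ids
        return pd.DataFrame(
            {
                "species_label": [self.species_label[i] for i in ids],
                "genus_label": [self.genus_label[i] for i in ids],
            },
            index=pd.Index(ids, name="phage_id"),
        )


def assign_taxa(
    matrix: LabeledMatrix,
    species_threshold: float = SPECIES_THRESHOLD,
    genus_threshold: float = GENUS_THRESHOLD,
) -> TaxonomicPartition:
    """Partition phages into species and genera by tANI thresholds."""
    if species_threshold < genus_threshold:
        raise ValueError("species threshold must be >= genus threshold")
    species = threshold_clusters(matrix, species_threshold)
    genus = threshold_clusters(matrix, genus_threshold)
    return TaxonomicPartition(species, genus, thresholds=(species_threshold, genus_threshold))


@dataclass
class ClusterSummary:
    n_species: int
    n_genera: int
    n_singletons: int
    singleton_fraction: float
    singleton_density_by_host: dict[str, float | None]


def singleton_stats(
    partition: TaxonomicPartition,
    metadata: pd.DataFrame | None = None,
    genomes_per_host: Mapping[str, int] | None = None,
) -> ClusterSummary:
    """Singleton accounting.

    A singleton is a species cluster of size one; the singleton fraction is
    singletons over species clusters.  Per-host singleton density divides
    the number of singleton prophages found in a host species by the number
    of genomes analysed for that host species; hosts with zero genomes get
    ``None`` (undefined), never 0.
    """
    sizes = partition.species_sizes()
    n_species = len(sizes)
    n_singletons = sum(1 for s in sizes.values() if s == 1)
    density: dict[str, float | None] = {}
    if metadata is not None and genomes_per_host is not None:
        missing = [p for p in partition.species_label if p not in metadata.index]
        if missing:
            raise KeyError(f"phages without metadata: {sorted(missing)[:5]}")
        singleton_species = {sp for sp, s in sizes.items() if s == 1}
        singles_by_host: Counter = Counter()
        for phage, sp in partition.species_label.items():
            if sp in singleton_species:
                singles_by_host[str(metadata.loc[phage, "host_species"])] += 1
        for host, n_genomes in genomes_per_host.items():
            if n_genomes <= 0:
                density[host] = None
            else:
                density[host] = singles_by_host.get(host, 0) / n_genomes
    return ClusterSummary(
        n_species=n_species,
        n_genera=partition.n_genera,
        n_singletons=n_singletons,
        singleton_fraction=n_singletons / n_species,
        singleton_density_by_host=density,
    )


def filter_by_cluster_size(
    partition: TaxonomicPartition, level: str, min_size: int
) -> set[str]:
    """Ids of phages whose cluster at ``level`` ('species' or 'genus') has
    at least ``min_size`` members."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if level == "species":
        labels, sizes = partition.species_label, partition.species_sizes()
    elif level == "genus":
        labels, sizes = partition.genus_label, partition.genus_sizes()
    else:
        raise ValueError(f"unknown level {level!r}")
    return {p for p, lab in labels.items() if sizes[lab] >= min_size}


def export_species_network(
    matrix: LabeledMatrix,
    partition: TaxonomicPartition,
    min_size: int = 7,
    path: str | Path | None = None,
) -> list[tuple[str, str, float]]:
    """Undirected species-level similarity network.

    Edges are pairs with tANI >= the species threshold whose members both
    belong to species clusters of size >= ``min_size``; suitable for import
    into network-visualisation tools.
    """
    threshold = partition.thresholds[0]
    keep = filter_by_cluster_size(partition, "species", min_size)
    edges: list[tuple[str, str, float]] = []
    labels = matrix.labels
    vals = matrix.values
    for i in range(len(labels)):
        if labels[i] not in keep:
            continue
        for j in range(i + 1, len(labels)):
            if labels[j] not in keep:
                continue
            if vals[i, j] >= threshold:
                edges.append((labels[i], labels[j], float(vals[i, j])))
    if path is not None:
        with Path(path).open("w") as fh:
            fh.write("source\ttarget\ttani\n")
            for s, t, v in edges:
                fh.write(f"{s}\t{t}\t{v:.10g}\n")
    return edges
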