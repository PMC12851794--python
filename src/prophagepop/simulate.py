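"""Synthetic datasets with full ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* a Yule (pure-birth) host phylogeny;
* prophage families that codiverge with their hosts, with a planted
  per-association probability of a host jump (the phage keeps its
  ancestral position in the phage tree but its current host is reassigned
  uniformly among the other hosts);
* phage genome sequences whose pairwise identities are planted at
  controlled within-species / between-species levels, so threshold
  clustering is checkable against exact truth (substitutions only — true
  identity is exact Hamming identity);
* categorical metadata (country, isolation source) drawn from a mixture
  with a planted strength of association to the phage species, together
  with the analytic uncertainty coefficient of the generating mixture.

Everything is deterministic under a fixed seed; child seeds for the
independent stages are derived from the master seed by one integer draw
stream.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_formats import (
    AssociationTable,
    LabeledMatrix,
    SequenceRecord,
    save_newick,
    write_associations_tsv,
    write_fasta,
    write_metadata_tsv,
)
from .taxonomy import GENUS_THRESHOLD, threshold_clusters

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_host_tree",
    "simulate_prophage_history",
    "evolve_sequences",
    "plant_family_sequences",
    "simulate_metadata",
    "insert_indels",
    "build_dataset",
]

_BASES = np.array(list("ACGT"))

DEFAULT_COUNTRIES = ("China", "USA", "Japan", "Mexico", "Germany", "Brazil")
DEFAULT_SOURCES = ("human", "animal", "clinical", "environmental")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study conditions.

    Defaults are chosen to be recoverable at desk scale: a dozen host
    lineages, a handful of prophages per host (Poisson), a 10% host-jump
    probability, and planted 97% within-species / 80% between-species
    sequence identities — comfortably separated from the 95/70 taxonomy
    thresholds.
    """

    n_hosts: int = 12
    birth_rate: float = 1.0
    prophages_per_host_mean: float = 3.0
    jump_probability: float = 0.1
    substitution_rate: float = 0.1
    root_sequence_length: int = 2000
    within_species_identity: float = 97.0
    between_genus_identity: float = 80.0
    metadata_association_strength: float = 0.7
    tip_branch_length: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.jump_probability <= 1.0:
            raise ValueError("jump_probability must be in [0, 1]")
        if not 0.0 <= self.metadata_association_strength <= 1.0:
            raise ValueError("metadata_association_strength must be in [0, 1]")
        if self.birth_rate <= 0 or self.substitution_rate <= 0:
            raise ValueError("rates must be > 0")
        if self.root_sequence_length < 200:
            raise ValueError("root_sequence_length must be >= 200")


@dataclass
class SimulatedTruth:
    """Planted ground truth sufficient to score every downstream stage."""

    config: SimulationConfig
    host_tree: dendropy.Tree
    phage_tree: dendropy.Tree
    associations: AssociationTable
    jump_flags: dict[str, bool]  # phage_id -> planted jump
    origin_host: dict[str, str]  # phage_id -> codivergent host
    species_label: dict[str, str]
    genus_label: dict[str, str]
    records: list[SequenceRecord]
    true_identity: LabeledMatrix
    metadata: pd.DataFrame
    analytic_u: dict[str, dict[str, float]]


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# Host tree

def simulate_host_tree(n_hosts: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """Yule pure-birth tree with exactly ``n_hosts`` leaves.

    Growth starts from the first split (no stem edge): while k lineages
    are extant the waiting time to the next speciation is Exp(k * rate),
    the splitting lineage is chosen uniformly, and after the (n-1)-th
    split one further waiting time Exp(n * rate) is added to every pendant
    branch.  Leaves are labelled H01.. in preorder.
    """
    if n_hosts < 3:
        raise ValueError("n_hosts must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    root = dendropy.Node()
    active: list[dendropy.Node] = []
    grow: dict[int, float] = {}
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append(child)
        grow[id(child)] = 0.0
    while len(active) < n_hosts:
        k = len(active)
        wait = rng.exponential(1.0 / (k * birth_rate))
        for node in active:
            grow[id(node)] += wait
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        parent.edge.length = grow.pop(id(parent))
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            active.append(child)
            grow[id(child)] = 0.0
    wait = rng.exponential(1.0 / (len(active) * birth_rate))
    for node in active:
        node.edge.length = grow[id(node)] + wait

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    width = max(2, len(str(n_hosts)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(f"H{i:0{width}d}")
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Prophage history

def simulate_prophage_history(
    host_tree: dendropy.Tree,
    prophages_per_host_mean: float,
    jump_probability: float,
    seed: int,
    tip_branch_length: float = 0.02,
) -> tuple[dendropy.Tree, AssociationTable, dict[str, bool], dict[str, str]]:
    """Codiverging prophage families with planted host jumps.

    Each host leaf carries Poisson(mean) prophages; the phage tree mirrors
    the host tree with the prophages of a host attached as short tips
    under that host's position (codivergence).  Independently per
    association, with probability ``jump_probability`` the phage's
    *current* host is reassigned uniformly among the other hosts and the
    association is flagged as a true jump — the phage keeps its ancestral
    tree position, which is exactly the signature Procrustes residuals
    detect.

    Returns ``(phage_tree, associations, jump_flags, origin_host)``.
    """
    rng = np.random.default_rng(seed)
    host_labels = [leaf.taxon.label for leaf in host_tree.leaf_node_iter()]
    counts = {h: int(rng.poisson(prophages_per_host_mean)) for h in host_labels}

    # independent copy of the host tree to be rewritten into the phage tree
    phage_tree = dendropy.Tree.get(
        data=host_tree.as_string(schema="newick", suppress_rooting=True),
        schema="newick",
        preserve_underscores=True,
    )
    taxa = dendropy.TaxonNamespace()
    links: list[tuple[str, str]] = []
    jump_flags: dict[str, bool] = {}
    origin_host: dict[str, str] = {}
    drop: list[dendropy.Node] = []
    for leaf in list(phage_tree.leaf_node_iter()):
        host = leaf.taxon.label
        c = counts[host]
        if c == 0:
            drop.append(leaf)
            continue
        leaf.taxon = None
        for i in range(1, c + 1):
            phage_id = f"{host}_p{i}"
            child = dendropy.Node()
            leaf.add_child(child)
            child.edge.length = tip_branch_length
            child.taxon = taxa.new_taxon(phage_id)
            origin_host[phage_id] = host
            jumped = bool(rng.random() < jump_probability)
            jump_flags[phage_id] = jumped
            if jumped:
                others = [h for h in host_labels if h != host]
                current = others[int(rng.integers(len(others)))]
            else:
                current = host
            links.append((current, phage_id))
    for leaf in drop:
        leaf.parent_node.remove_child(leaf)
    if not links:
        raise ValueError("no prophages generated; increase prophages_per_host_mean")
    # dropping a whole cherry of empty hosts can strand taxonless leaves
    pruned = True
    while pruned:
        pruned = False
        for node in list(phage_tree.leaf_node_iter()):
            if node.taxon is None and node.parent_node is not None:
                node.parent_node.remove_child(node)
                pruned = True
    phage_tree.taxon_namespace = taxa
    phage_tree.suppress_unifurcations()
    assoc = AssociationTable(links)
    return phage_tree, assoc, jump_flags, origin_host


# ---------------------------------------------------------------------------
# Sequence evolution

def _mutate(seq: np.ndarray, n_sub: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute ``n_sub`` distinct positions to a different base."""
    out = seq.copy()
    if n_sub == 0:
        return out
    n_sub = min(n_sub, len(seq))
    sites = rng.choice(len(seq), size=n_sub, replace=False)
    shifts = rng.integers(1, 4, size=n_sub)
    out[sites] = (out[sites] + shifts) % 4
    return out


def _to_string(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


def _identity_matrix(ids: list[str], seqs: list[np.ndarray]) -> LabeledMatrix:
    n = len(ids)
    length = len(seqs[0])
    vals = np.full((n, n), 100.0)
    arr = np.stack(seqs)
    for i in range(n):
        diff = (arr[i] != arr[i + 1 :]).sum(axis=1)
        ident = 100.0 * (length - diff) / length
        vals[i, i + 1 :] = ident
        vals[i + 1 :, i] = ident
    return LabeledMatrix(ids, vals)


def evolve_sequences(
    phage_tree: dendropy.Tree,
    root_length: int,
    substitution_rate: float,
    seed: int,
) -> tuple[list[SequenceRecord], LabeledMatrix]:
    """Evolve sequences down a tree: per-branch substitution counts are
    Poisson(rate * branch_length) at uniformly chosen positions.

    True pairwise identities are computed exactly from the realized leaf
    sequences (no indels, so identity is Hamming identity).
    """
    if root_length < 200:
        raise ValueError("root_length must be >= 200")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=root_length)
    seqs: dict[int, np.ndarray] = {id(phage_tree.seed_node): root_seq}
    for node in phage_tree.preorder_node_iter():
        if node is phage_tree.seed_node:
            continue
        blen = node.edge.length or 0.0
        n_sub = int(rng.poisson(substitution_rate * blen * root_length))
        seqs[id(node)] = _mutate(seqs[id(node.parent_node)], n_sub, rng)
    leaves = list(phage_tree.leaf_node_iter())
    ids = [leaf.taxon.label for leaf in leaves]
    arrays = [seqs[id(leaf)] for leaf in leaves]
    records = [SequenceRecord(i, _to_string(a)) for i, a in zip(ids, arrays)]
    return records, _identity_matrix(ids, arrays)


def plant_family_sequences(
    species_of_phage: Mapping[str, str],
    root_length: int,
    within_identity: float,
    between_identity: float,
    seed: int,
) -> tuple[list[SequenceRecord], LabeledMatrix]:
    """Sequences with planted within/between-species identities.

    A two-level family tree is used with *fixed* per-branch substitution
    counts: every species ancestor differs from the root at
    ``L*(100-between)/200`` positions and every member from its ancestor
    at ``L*(100-within)/200`` positions (uniform sites, so realized
    identities sit at the targets up to rare site collisions).  True
    identities are exact Hamming identities of the realized sequences.
    """
    if not 0.0 < within_identity <= 100.0 or not 0.0 < between_identity <= 100.0:
        raise ValueError("identity targets must be in (0, 100]")
    if within_identity <= between_identity:
        raise ValueError("within-species identity must exceed between-species identity")
    rng = np.random.default_rng(seed)
    L = root_length
    delta_species = int(round(L * (100.0 - between_identity) / 200.0))
    delta_member = int(round(L * (100.0 - within_identity) / 200.0))
    root = rng.integers(0, 4, size=L)
    species = sorted(set(species_of_phage.values()))
    ancestors = {sp: _mutate(root, delta_species, rng) for sp in species}
    ids = sorted(species_of_phage)
    seqs = [_mutate(ancestors[species_of_phage[p]], delta_member, rng) for p in ids]
    records = [SequenceRecord(i, _to_string(s)) for i, s in zip(ids, seqs)]
    return records, _identity_matrix(ids, seqs)


def insert_indels(
    sequence: str, n_events: int, max_length: int, seed: int
) -> str:
    """Apply random short insertions/deletions (robustness testing only;
    planted identities are no longer exact afterwards)."""
    rng = np.random.default_rng(seed)
    seq = list(sequence)
    for _ in range(n_events):
        length = int(rng.integers(1, max_length + 1))
        pos = int(rng.integers(0, max(1, len(seq))))
        if rng.random() < 0.5 and len(seq) > length + 200:
            del seq[pos : pos + length]
        else:
            seq[pos:pos] = list(_BASES[rng.integers(0, 4, size=length)])
    return "".join(seq)


# ---------------------------------------------------------------------------
# Metadata

def simulate_metadata(
    phage_species_labels: Mapping[str, str],
    categories: Sequence[str],
    association_strength: float,
    seed: int,
) -> tuple[pd.Series, dict[str, float]]:
    """Categorical labels associated with phage species at planted strength.

    Each species gets a uniformly chosen "home" category; each phage draws
    the home category with probability ``strength`` and otherwise a
    uniform category.  The analytic uncertainty coefficients of the
    generating mixture (given the realized species sizes and home
    assignments) are returned alongside the labels.
    """
    if not 0.0 <= association_strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    categories = list(categories)
    if len(categories) < 2:
        raise ValueError("need at least 2 categories")
    rng = np.random.default_rng(seed)
    species = sorted(set(phage_species_labels.values()))
    home = {sp: categories[int(rng.integers(len(categories)))] for sp in species}
    k = len(categories)
    labels: dict[str, str] = {}
    for phage in sorted(phage_species_labels):
        if rng.random() < association_strength:
            labels[phage] = home[phage_species_labels[phage]]
        else:
            labels[phage] = categories[int(rng.integers(k))]

    # analytic U of the mixture, at the realized species-size distribution
    n = len(phage_species_labels)
    p_s = np.array(
        [sum(1 for v in phage_species_labels.values() if v == sp) / n for sp in species]
    )
    cond = np.full((len(species), k), (1.0 - association_strength) / k)
    for i, sp in enumerate(species):
        cond[i, categories.index(home[sp])] += association_strength
    joint = p_s[:, None] * cond
    p_y = joint.sum(axis=0)

    def ent(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    h_s, h_y, h_joint = ent(p_s), ent(p_y), ent(joint.ravel())
    mi = max(0.0, h_s + h_y - h_joint)
    analytic = {
        "mutual_information": mi,
        "U_species_given_category": mi / h_s if h_s > 0 else 1.0,
        "U_category_given_species": mi / h_y if h_y > 0 else 1.0,
    }
    return pd.Series(labels, name="category"), analytic


# ---------------------------------------------------------------------------
# Full dataset

def build_dataset(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SimulatedTruth:
    """Generate a complete dataset plus truth; optionally write it to disk.

    Files written (all plain text): ``phages.fasta``, ``metadata.tsv``,
    ``host_tree.nwk``, ``phage_tree.nwk``, ``associations.tsv``,
    ``true_identity.tsv`` and ``truth.json``.  Re-running with the same
    seed reproduces byte-identical outputs.
    """
    seeds = _child_seeds(config.seed, 6)
    host_tree = simulate_host_tree(config.n_hosts, config.birth_rate, seeds[0])
    phage_tree, assoc, jump_flags, origin_host = simulate_prophage_history(
        host_tree,
        config.prophages_per_host_mean,
        config.jump_probability,
        seeds[1],
        tip_branch_length=config.tip_branch_length,
    )
    species_label = {p: f"sp_{h}" for p, h in origin_host.items()}
    records, true_identity = plant_family_sequences(
        species_label,
        config.root_sequence_length,
        config.within_species_identity,
        config.between_genus_identity,
        seeds[2],
    )
    genus_label = threshold_clusters(true_identity, GENUS_THRESHOLD)
    current_host = dict((p, h) for h, p in assoc.links)
    countries, u_country = simulate_metadata(
        species_label, DEFAULT_COUNTRIES, config.metadata_association_strength, seeds[3]
    )
    sources, u_source = simulate_metadata(
        species_label, DEFAULT_SOURCES, config.metadata_association_strength, seeds[4]
    )
    phage_ids = sorted(species_label)
    metadata = pd.DataFrame(
        {
            "genome_id": [f"G_{current_host[p]}" for p in phage_ids],
            "host_species": [current_host[p] for p in phage_ids],
            "country": [countries[p] for p in phage_ids],
            "isolation_source": [sources[p] for p in phage_ids],
        },
        index=pd.Index(phage_ids, name="phage_id"),
    )
    truth = SimulatedTruth(
        config=config,
        host_tree=host_tree,
        phage_tree=phage_tree,
        associations=assoc,
        jump_flags=jump_flags,
        origin_host=origin_host,
        species_label=species_label,
        genus_label=genus_label,
        records=records,
        true_identity=true_identity,
        metadata=metadata,
        analytic_u={"country": u_country, "isolation_source": u_source},
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, outdir / "phages.fasta")
        write_metadata_tsv(metadata, outdir / "metadata.tsv")
        save_newick(host_tree, outdir / "host_tree.nwk")
        save_newick(phage_tree, outdir / "phage_tree.nwk")
        assoc_out = AssociationTable(
            list(assoc.links),
            jump_flag=[jump_flags[p] for _, p in assoc.links],
        )
        write_associations_tsv(assoc_out, outdir / "associations.tsv")
        from .io_formats import write_matrix_tsv

        write_matrix_tsv(true_identity, outdir / "true_identity.tsv")
        payload = {
            "config": asdict(config),
            "species_label": species_label,
            "genus_label": genus_label,
            "origin_host": origin_host,
            "jump_flags": jump_flags,
            "analytic_u": truth.analytic_u,
        }
        (outdir / "truth.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
    return truth
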