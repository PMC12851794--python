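"""Self-validation measurements: recompute the pipeline's headline
quantities from scratch on constructed or simulated inputs.

Each function runs one stage of the package under controlled conditions —
the printed dataset-level counts (association totals, cluster sizes,
genome counts) as direct inputs, or synthetic data with planted truth —
and returns the measured quantity.  They are used both by the test suite
and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pandas as pd

from . import ani, cophylogeny, diversity, phylo, taxonomy
from .io_formats import AssociationTable
from .pipeline import summarize_prophage_burden
from .simulate import (
    SimulationConfig,
    build_dataset,
    simulate_host_tree,
    simulate_metadata,
    simulate_prophage_history,
)

__all__ = [
    "host_jump_classification",
    "singleton_fraction_from_counts",
    "burden_mean",
    "nj_additive_recovery",
    "cophylogeny_calibration",
    "planted_species_recovery",
    "jump_residual_separation",
    "rarefaction_exactness",
    "uc_recovery",
    "tani_oracle_agreement",
]


def host_jump_classification(n_associations: int = 1650, quantile: float = 0.95,
                             seed: int = 0) -> dict:
    """Apply the strictly-above interpolated-quantile rule to a set of
    distinct residuals and count flagged host jumps."""
    rng = np.random.default_rng(seed)
    residuals = rng.permutation(np.linspace(1e-4, 2.0, n_associations))
    assert len(np.unique(residuals)) == n_associations
    flags, threshold = cophylogeny.classify_host_jumps(residuals, quantile)
    n_jumps = int(flags.sum())
    return {
        "n_associations": n_associations,
        "n_jumps": n_jumps,
        "jump_pct": 100.0 * n_jumps / n_associations,
        "codivergent_pct": 100.0 * (n_associations - n_jumps) / n_associations,
        "threshold": threshold,
    }


def singleton_fraction_from_counts(n_species: int = 2423, n_singletons: int = 1938) -> dict:
    """Singleton fraction of a partition with the given cluster-size
    profile (size-one clusters plus the rest as pairs)."""
    species: dict[str, str] = {}
    genus: dict[str, str] = {}
    k = 0
    for ci in range(n_species):
        size = 1 if ci < n_singletons else 2
        for _ in range(size):
            species[f"p{k}"] = f"c{ci}"
            genus[f"p{k}"] = f"c{ci}"
            k += 1
    partition = taxonomy.TaxonomicPartition(species, genus)
    summary = taxonomy.singleton_stats(partition)
    return {
        "n_species": summary.n_species,
        "n_singletons": summary.n_singletons,
        "singleton_pct": 100.0 * summary.singleton_fraction,
    }


def burden_mean(n_phages: int = 3661, n_genomes: int = 747) -> dict:
    """Mean prophages per genome for a census of n_phages distributed over
    n_genomes (the mean depends only on the totals)."""
    genome_of = [f"g{i % n_genomes}" for i in range(n_phages)]
    metadata = pd.DataFrame(
        {
            "genome_id": genome_of,
            "host_species": ["sp"] * n_phages,
            "country": ["N/A"] * n_phages,
            "isolation_source": ["N/A"] * n_phages,
        },
        index=pd.Index([f"p{i}" for i in range(n_phages)], name="phage_id"),
    )
    burden = summarize_prophage_burden(metadata)
    return {
        "n_phages": burden.n_phages,
        "n_genomes": burden.n_genomes,
        "mean": burden.mean,
        "mean_rounded": burden.mean_rounded,
    }


def nj_additive_recovery(n_trees: int = 100, seed: int = 0) -> dict:
    """Exact recovery of random additive matrices: max patristic error over
    random 4-10-taxon Yule trees."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    exact = 0
    for _ in range(n_trees):
        n = int(rng.integers(4, 11))
        tree = simulate_host_tree(n, 1.0, int(rng.integers(2**31)))
        d = phylo.patristic_matrix(tree)
        recovered = phylo.patristic_matrix(phylo.neighbor_joining(d)).reorder(d.labels)
        err = float(np.max(np.abs(recovered.values - d.values)))
        max_err = max(max_err, err)
        exact += err < 1e-9
    return {"n_trees": n_trees, "max_error": max_err, "exact_pct": 100.0 * exact / n_trees}


def _mirrored_pair(n_taxa: int, seed: int):
    host = simulate_host_tree(n_taxa, 1.0, seed)
    phage = dendropy.Tree.get(
        data=host.as_string(schema="newick"),
        schema="newick",
        preserve_underscores=True,
    )
    for leaf in phage.leaf_node_iter():
        leaf.taxon.label = "P" + leaf.taxon.label
    hosts = [l.taxon.label for l in host.leaf_node_iter()]
    assoc = AssociationTable([(h, "P" + h) for h in hosts])
    return phylo.patristic_matrix(host), phylo.patristic_matrix(phage), assoc


def cophylogeny_calibration(
    n_sims: int = 200, n_perm: int = 99, n_taxa: int = 8, seed: int = 0
) -> dict:
    """Type-I error of PACo and ParaFit on independent random trees with a
    random one-to-one association, plus mirrored-tree positive controls."""
    rng = np.random.default_rng(seed)
    rej_paco = rej_parafit = 0
    for _ in range(n_sims):
        host = simulate_host_tree(n_taxa, 1.0, int(rng.integers(2**31)))
        phage = simulate_host_tree(n_taxa, 1.0, int(rng.integers(2**31)))
        for leaf in phage.leaf_node_iter():
            leaf.taxon.label = "P" + leaf.taxon.label
        hosts = [l.taxon.label for l in host.leaf_node_iter()]
        phages = [l.taxon.label for l in phage.leaf_node_iter()]
        perm = rng.permutation(n_taxa)
        assoc = AssociationTable([(hosts[i], phages[perm[i]]) for i in range(n_taxa)])
        hd, pd_ = phylo.patristic_matrix(host), phylo.patristic_matrix(phage)
        res = cophylogeny.paco_global(hd, pd_, assoc, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rej_paco += res.p_value <= 0.05
        _, p2 = cophylogeny.parafit_global(hd, pd_, assoc, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rej_parafit += p2 <= 0.05
    hd, pd_, assoc = _mirrored_pair(n_taxa, int(rng.integers(2**31)))
    pos_paco = cophylogeny.paco_global(hd, pd_, assoc, n_perm=999, seed=int(rng.integers(2**31))).p_value
    _, pos_parafit = cophylogeny.parafit_global(hd, pd_, assoc, n_perm=999, seed=int(rng.integers(2**31)))
    return {
        "n_sims": n_sims,
        "paco_type1": rej_paco / n_sims,
        "parafit_type1": rej_parafit / n_sims,
        "paco_positive_control_p": pos_paco,
        "parafit_positive_control_p": pos_parafit,
    }


def planted_species_recovery(seed: int = 3) -> dict:
    """End-to-end species recovery on the default synthetic dataset:
    adjusted Rand index between planted and tANI-estimated species."""
    truth = build_dataset(SimulationConfig(seed=seed))
    matrix = ani.tani_matrix(truth.records)
    partition = taxonomy.assign_taxa(matrix)
    ids = partition.phage_ids
    ari = _adjusted_rand_index(
        [truth.species_label[i] for i in ids],
        [partition.species_label[i] for i in ids],
    )
    return {"n_phages": len(ids), "ari": ari, "n_species": partition.n_species}


def _adjusted_rand_index(a: list, b: list) -> float:
    """Adjusted Rand index from the pair-counting contingency table."""
    from collections import Counter

    def comb2(x: int) -> float:
        return x * (x - 1) / 2.0

    contingency = Counter(zip(a, b))
    sum_ij = sum(comb2(v) for v in contingency.values())
    sum_a = sum(comb2(v) for v in Counter(a).values())
    sum_b = sum(comb2(v) for v in Counter(b).values())
    total = comb2(len(a))
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def jump_residual_separation(
    n_replicates: int = 20, jump_probability: float = 0.1, seed: int = 0
) -> dict:
    """Fraction of replicates in which planted-jump associations have a
    larger mean Procrustes residual than codivergent ones."""
    rng = np.random.default_rng(seed)
    wins = 0
    for _ in range(n_replicates):
        while True:
            host = simulate_host_tree(12, 1.0, int(rng.integers(2**31)))
            phage_tree, assoc, jumps, _ = simulate_prophage_history(
                host, 3.0, jump_probability, int(rng.integers(2**31))
            )
            flags = np.array([jumps[p] for _, p in assoc.links])
            if flags.any() and (~flags).any() and len(assoc) >= 6:
                break
        hd = phylo.patristic_matrix(host)
        pd_ = phylo.patristic_matrix(phage_tree)
        res = cophylogeny.paco_global(hd, pd_, assoc, n_perm=9, seed=int(rng.integers(2**31)))
        wins += res.residuals_sq[flags].mean() > res.residuals_sq[~flags].mean()
    return {"n_replicates": n_replicates, "separation_rate": wins / n_replicates}


def _integer_partitions(n: int):
    """All multisets of positive integers summing to n."""
    if n == 0:
        yield ()
        return
    def rec(remaining, largest):
        if remaining == 0:
            yield ()
            return
        for first in range(min(remaining, largest), 0, -1):
            for rest in rec(remaining - first, first):
                yield (first, *rest)
    yield from rec(n, n)


def _enumerated_richness(counts, m: int) -> float:
    individuals = []
    for sp, c in enumerate(counts):
        individuals.extend([sp] * c)
    values = [
        len({individuals[i] for i in subset})
        for subset in itertools.combinations(range(len(individuals)), m)
    ]
    return float(np.mean(values))


def rarefaction_exactness(max_total: int = 12, mc_draws: int = 10000, seed: int = 0) -> dict:
    """Hypergeometric expected richness vs exhaustive enumeration for every
    community with N <= max_total, and vs Monte-Carlo for a larger one."""
    max_err = 0.0
    n_checked = 0
    for n in range(1, max_total + 1):
        for counts in _integer_partitions(n):
            for m in range(0, n + 1):
                exact = diversity.rarefy_expected_richness(counts, m)
                enum = _enumerated_richness(counts, m)
                max_err = max(max_err, abs(exact - enum))
                n_checked += 1
    rng = np.random.default_rng(seed)
    counts = np.array([40, 25, 10, 5, 3, 1, 1])
    pool = np.repeat(np.arange(len(counts)), counts)
    max_z = 0.0
    for m in (5, 20, 60):
        draws = np.array(
            [
                len(np.unique(rng.choice(pool, size=m, replace=False)))
                for _ in range(mc_draws)
            ]
        )
        se = draws.std(ddof=1) / np.sqrt(mc_draws)
        z = abs(diversity.rarefy_expected_richness(counts, m) - draws.mean()) / se
        max_z = max(max_z, z)
    return {"n_checked": n_checked, "max_abs_error": max_err, "mc_max_z": max_z}


def uc_recovery(
    strengths: tuple[float, ...] = (0.0, 0.3, 0.7, 1.0),
    n_phages: int = 2000,
    seed: int = 0,
) -> dict:
    """Estimated vs analytic uncertainty coefficient for labels generated
    at planted association strengths."""
    rng = np.random.default_rng(seed)
    species = {f"p{i}": f"sp{i % 20}" for i in range(n_phages)}
    ids = sorted(species)
    max_err = 0.0
    per_strength = {}
    for strength in strengths:
        labels, analytic = simulate_metadata(
            species, ["c1", "c2", "c3", "c4"], strength, int(rng.integers(2**31))
        )
        res = diversity.uncertainty_coefficient(
            [species[p] for p in ids], [labels[p] for p in ids]
        )
        err = abs(res.U_x_given_y - analytic["U_species_given_category"])
        per_strength[strength] = err
        max_err = max(max_err, err)
    return {"n": n_phages, "max_abs_error": max_err, "per_strength": per_strength}


def tani_oracle_agreement(
    n_pairs: int = 50, tolerance: float = 3.0, seed: int = 0
) -> dict:
    """Fraction of simulated >=85%-identity pairs (1-3 kb) on which the
    seed-chain tANI estimator agrees with the alignment oracle within
    ``tolerance`` percentage points."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    agree = 0
    worst = 0.0
    for _ in range(n_pairs):
        length = int(rng.integers(1000, 3001))
        arr = rng.integers(0, 4, size=length)
        identity = rng.uniform(85.0, 99.5)
        n_sub = int(round(length * (100.0 - identity) / 100.0))
        sites = rng.choice(length, size=n_sub, replace=False)
        mutated = arr.copy()
        mutated[sites] = (mutated[sites] + rng.integers(1, 4, size=n_sub)) % 4
        a = "".join(bases[arr])
        b = "".join(bases[mutated])
        diff = abs(ani.tani(a, b).tani - ani.nw_identity_oracle(a, b))
        worst = max(worst, diff)
        agree += diff <= tolerance
    return {"n_pairs": n_pairs, "agree_rate": agree / n_pairs, "worst_diff": worst}
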