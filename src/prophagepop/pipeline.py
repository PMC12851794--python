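"""End-to-end orchestration: similarity -> taxonomy -> trees -> cophylogeny
-> diversity, with a machine-readable report.

The report logs every parameter that affects the result (thresholds,
permutation counts, quantile, seeds) for provenance, and runs internal
consistency checks (counts, fractions, partition refinement) that fail
loudly rather than silently producing an inconsistent summary.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import ani, cophylogeny, diversity, phylo, taxonomy
from .io_formats import (
    AssociationTable,
    load_newick,
    read_fasta,
    read_associations_tsv,
    read_matrix_tsv,
    read_metadata_tsv,
    save_newick,
    write_associations_tsv,
    write_matrix_tsv,
)
from .simulate import SimulationConfig, build_dataset

__all__ = [
    "PipelineConfig",
    "BurdenSummary",
    "summarize_prophage_burden",
    "attribute_jumps_by_genus",
    "run_full_analysis",
]


@dataclass
class BurdenSummary:
    n_phages: int
    n_genomes: int
    mean: float
    mean_rounded: float
    mode: int
    histogram: dict[int, int]
    fraction_with_prophage: float
    kruskal: diversity.GroupTestResult | None = None
    pairwise: diversity.GroupTestResult | None = None


def summarize_prophage_burden(
    metadata: pd.DataFrame,
    genome_list: Sequence[str] | None = None,
    group_col: str = "host_species",
) -> BurdenSummary:
    """Prophages-per-genome statistics and cross-group tests.

    Genomes with zero prophages are only counted when supplied through
    ``genome_list``; otherwise the summary covers the genomes appearing in
    the metadata.  The mode is the most frequent count (smallest on ties);
    the mean is also reported rounded to one decimal.
    """
    if metadata.empty:
        raise ValueError("empty metadata table")
    counts = metadata.groupby("genome_id").size().to_dict()
    if genome_list is not None:
        for g in genome_list:
            counts.setdefault(str(g), 0)
    values = np.array(list(counts.values()))
    hist = Counter(int(v) for v in values)
    max_freq = max(hist.values())
    mode = min(k for k, v in hist.items() if v == max_freq)
    mean = float(values.mean())

    group_of_genome: dict[str, str] = {}
    for genome, sub in metadata.groupby("genome_id"):
        group_of_genome[str(genome)] = str(sub[group_col].iloc[0])
    groups: dict[str, list[int]] = {}
    for genome, count in counts.items():
        group = group_of_genome.get(genome, "unknown")
        groups.setdefault(group, []).append(count)
    kruskal = pairwise = None
    usable = {g: v for g, v in groups.items() if len(v) >= 1}
    if len(usable) >= 2:
        kruskal = diversity.kruskal_wallis(list(usable.values()))
        pairwise = diversity.mann_whitney_pairwise_holm(usable)
    return BurdenSummary(
        n_phages=int(len(metadata)),
        n_genomes=int(len(counts)),
        mean=mean,
        mean_rounded=round(mean, 1),
        mode=int(mode),
        histogram={int(k): int(v) for k, v in sorted(hist.items())},
        fraction_with_prophage=float((values > 0).mean()),
        kruskal=kruskal,
        pairwise=pairwise,
    )


def attribute_jumps_by_genus(
    assoc: AssociationTable,
    jump_flags: Sequence[bool],
    partition: taxonomy.TaxonomicPartition,
) -> pd.DataFrame:
    """Per-genus counts and fractions of flagged (host-jump) associations,
    sorted by descending count."""
    if len(jump_flags) != len(assoc):
        raise ValueError("jump_flags length does not match associations")
    flagged = [p for (h, p), f in zip(assoc.links, jump_flags) if f]
    missing = [p for p in flagged if p not in partition.genus_label]
    if missing:
        raise KeyError(f"flagged phages missing from partition: {sorted(missing)[:5]}")
    counts = Counter(partition.genus_label[p] for p in flagged)
    total = sum(counts.values())
    rows = [
        {"genus": g, "n_jumps": n, "fraction": n / total}
        for g, n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["genus", "n_jumps", "fraction"])
    return df.sort_values(["n_jumps", "genus"], ascending=[False, True]).reset_index(drop=True)


@dataclass
class PipelineConfig:
    """Inputs and parameters for a full run.

    Exactly one input route must be set: a simulation config, or paths to
    FASTA + metadata (+ optional host tree / associations), or a
    precomputed similarity matrix + metadata.
    """

    outdir: str = "results/run"
    simulation: SimulationConfig | None = None
    fasta: str | None = None
    metadata_tsv: str | None = None
    host_tree_nwk: str | None = None
    associations_tsv: str | None = None
    similarity_tsv: str | None = None
    genome_list: tuple[str, ...] | None = None
    species_threshold: float = 95.0
    genus_threshold: float = 70.0
    min_genus_size: int = 5
    min_species_network: int = 7
    paco_permutations: int = 10000
    parafit_permutations: int = 999
    jump_quantile: float = 0.95
    rarefy_fraction: float = 0.75
    min_host_total: int | None = None
    kmer_size: int = 15
    seed: int = 0


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    return obj


def _uc_table(metadata: pd.DataFrame, partition: taxonomy.TaxonomicPartition) -> list[dict]:
    """Uncertainty coefficients between phage taxa and metadata variables,
    both directions, for every pair."""
    ids = [p for p in partition.phage_ids if p in metadata.index]
    phage_vars = {
        "phage_species": [partition.species_label[p] for p in ids],
        "phage_genus": [partition.genus_label[p] for p in ids],
    }
    meta_vars = {
        col: [str(metadata.loc[p, col]) for p in ids]
        for col in ("host_species", "country", "isolation_source")
    }
    rows = []
    for pname, pvals in phage_vars.items():
        for mname, mvals in meta_vars.items():
            res = diversity.uncertainty_coefficient(pvals, mvals)
            rows.append(
                {
                    "x": pname,
                    "y": mname,
                    "mutual_information": res.mutual_information,
                    "U_x_given_y": res.U_x_given_y,
                    "U_y_given_x": res.U_y_given_x,
                    "residual_U_x_given_y": 1.0 - res.U_x_given_y,
                }
            )
    return rows


def _rarefaction_block(
    partition: taxonomy.TaxonomicPartition,
    metadata: pd.DataFrame,
    group_col: str,
    fraction: float,
    min_total: int | None,
) -> dict:
    ids = [p for p in partition.phage_ids if p in metadata.index]
    community = diversity.community_matrix(
        {p: partition.species_label[p] for p in ids},
        {p: str(metadata.loc[p, group_col]) for p in ids},
    )
    totals = community.sum(axis=1).to_dict()
    depth, retained = diversity.rarefaction_depth_rule(
        totals, fraction=fraction, min_total=min_total
    )
    depth = max(depth, 1)
    richness = {
        g: diversity.rarefy_expected_richness(community.loc[g].values, depth)
        for g in retained
    }
    return {
        "group_col": group_col,
        "depth": depth,
        "totals": {str(k): int(v) for k, v in totals.items()},
        "retained": retained,
        "expected_richness": richness,
    }


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run every stage in order and write all artifacts under
    ``config.outdir``; returns the report dict (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": _jsonify(asdict(config))}

    # ------------------------------------------------------------- inputs
    stage = "inputs"
    try:
        truth = None
        host_tree = None
        assoc = None
        if config.simulation is not None:
            truth = build_dataset(config.simulation, outdir / "simulated")
            records = truth.records
            metadata = truth.metadata
            host_tree = truth.host_tree
            assoc = truth.associations
            similarity = None
        else:
            if config.metadata_tsv is None:
                raise ValueError("metadata_tsv is required")
            metadata = read_metadata_tsv(config.metadata_tsv)
            records = read_fasta(config.fasta) if config.fasta else None
            similarity = (
                read_matrix_tsv(config.similarity_tsv) if config.similarity_tsv else None
            )
            if records is None and similarity is None:
                raise ValueError("either fasta or similarity_tsv is required")
            if config.host_tree_nwk:
                host_tree = load_newick(config.host_tree_nwk)
            if config.associations_tsv:
                assoc = read_associations_tsv(config.associations_tsv)

        # ------------------------------------------------------ similarity
        stage = "ani"
        if similarity is None:
            similarity = ani.tani_matrix(records, k=config.kmer_size)
        write_matrix_tsv(similarity, outdir / "tani_matrix.tsv")
        missing_meta = [l for l in similarity.labels if l not in metadata.index]
        if missing_meta:
            raise KeyError(f"phages without metadata: {sorted(missing_meta)[:5]}")

        # -------------------------------------------------------- taxonomy
        stage = "taxonomy"
        partition = taxonomy.assign_taxa(
            similarity, config.species_threshold, config.genus_threshold
        )
        partition.to_frame().to_csv(outdir / "partition.tsv", sep="\t")
        genomes_per_host = (
            metadata.reset_index()
            .groupby("host_species")["genome_id"]
            .nunique()
            .to_dict()
        )
        summary = taxonomy.singleton_stats(partition, metadata, genomes_per_host)
        taxonomy.export_species_network(
            similarity,
            partition,
            min_size=config.min_species_network,
            path=outdir / "species_network.tsv",
        )
        report["taxonomy"] = {
            "n_phages": len(similarity),
            "n_species": summary.n_species,
            "n_genera": summary.n_genera,
            "n_singletons": summary.n_singletons,
            "singleton_fraction": summary.singleton_fraction,
            "singleton_density_by_host": summary.singleton_density_by_host,
        }

        # ---------------------------------------------------------- burden
        stage = "burden"
        burden = summarize_prophage_burden(metadata, genome_list=config.genome_list)
        report["burden"] = {
            "n_phages": burden.n_phages,
            "n_genomes": burden.n_genomes,
            "mean": burden.mean,
            "mean_rounded": burden.mean_rounded,
            "mode": burden.mode,
            "histogram": burden.histogram,
            "fraction_with_prophage": burden.fraction_with_prophage,
            "kruskal_H": burden.kruskal.statistic if burden.kruskal else None,
            "kruskal_p": burden.kruskal.p_value if burden.kruskal else None,
        }

        # ------------------------------------------------------ phage tree
        stage = "phylo"
        genus_members = taxonomy.filter_by_cluster_size(
            partition, "genus", config.min_genus_size
        )
        phage_nj_tree = None
        if len(genus_members) >= 3:
            sub = similarity.reorder(sorted(genus_members))
            phage_nj_tree = phylo.neighbor_joining(phylo.similarity_to_distance(sub))
            save_newick(phage_nj_tree, outdir / "phage_nj_tree.nwk")
        report["phylo"] = {
            "n_phages_in_tree": len(genus_members) if phage_nj_tree is not None else 0
        }

        # ----------------------------------------------------- cophylogeny
        stage = "cophylogeny"
        if host_tree is not None and assoc is not None:
            host_d = phylo.patristic_matrix(host_tree)
            phage_tree = (
                truth.phage_tree
                if truth is not None
                else phylo.neighbor_joining(phylo.similarity_to_distance(similarity))
            )
            phage_d = phylo.patristic_matrix(phage_tree)
            paco = cophylogeny.paco_global(
                host_d,
                phage_d,
                assoc,
                n_perm=config.paco_permutations,
                seed=config.seed,
            )
            flags, threshold = cophylogeny.classify_host_jumps(
                paco.residuals_sq, config.jump_quantile
            )
            parafit_stat, parafit_p = cophylogeny.parafit_global(
                host_d,
                phage_d,
                assoc,
                n_perm=config.parafit_permutations,
                seed=config.seed + 1,
            )
            annotated = AssociationTable(
                list(assoc.links),
                residual_sq=[float(r) for r in paco.residuals_sq],
                jump_flag=[bool(f) for f in flags],
            )
            write_associations_tsv(annotated, outdir / "associations_residuals.tsv")
            attribution = attribute_jumps_by_genus(assoc, list(flags), partition)
            attribution.to_csv(outdir / "jump_attribution.tsv", sep="\t", index=False)
            report["cophylogeny"] = {
                "m2_observed": paco.m2_observed,
                "p_value_paco": paco.p_value,
                "paco_permutations": config.paco_permutations,
                "parafit_global": parafit_stat,
                "p_value_parafit": parafit_p,
                "parafit_permutations": config.parafit_permutations,
                "threshold_value": threshold,
                "n_associations": len(assoc),
                "n_jumps": int(flags.sum()),
                "jump_fraction": float(flags.mean()),
                "jump_attribution": attribution.to_dict(orient="records"),
            }
        else:
            report["cophylogeny"] = None

        # ------------------------------------------------------- diversity
        stage = "diversity"
        report["uncertainty_coefficients"] = _uc_table(metadata, partition)
        rarefaction = {}
        for group_col, min_total in (
            ("isolation_source", None),
            ("host_species", config.min_host_total),
        ):
            try:
                rarefaction[group_col] = _rarefaction_block(
                    partition, metadata, group_col, config.rarefy_fraction, min_total
                )
            except ValueError as exc:
                rarefaction[group_col] = {"error": str(exc)}
        report["rarefaction"] = rarefaction
        rows = []
        for block in rarefaction.values():
            if "expected_richness" in block:
                for g, r in block["expected_richness"].items():
                    rows.append(
                        {
                            "group_col": block["group_col"],
                            "group": g,
                            "depth": block["depth"],
                            "expected_richness": r,
                        }
                    )
        pd.DataFrame(rows).to_csv(outdir / "rarefaction.tsv", sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _check_report(report)
    report = _jsonify(report)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


def _check_report(report: dict) -> None:
    """Internal consistency checks; raise on any violation."""
    tax = report["taxonomy"]
    if not (tax["n_singletons"] <= tax["n_species"] <= tax["n_phages"]):
        raise AssertionError("taxonomy counts inconsistent")
    if not 0.0 <= tax["singleton_fraction"] <= 1.0:
        raise AssertionError("singleton fraction out of range")
    if abs(tax["singleton_fraction"] - tax["n_singletons"] / tax["n_species"]) > 1e-12:
        raise AssertionError("singleton fraction does not match counts")
    cop = report.get("cophylogeny")
    if cop:
        if cop["n_jumps"] > cop["n_associations"]:
            raise AssertionError("jump count exceeds association count")
        attributed = sum(r["n_jumps"] for r in cop["jump_attribution"])
        if attributed != cop["n_jumps"]:
            raise AssertionError("jump attribution does not sum to jump count")
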