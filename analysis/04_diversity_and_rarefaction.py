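#!/usr/bin/env python
"""Prophage burden, metadata association and rarefied species richness.

Computes, on the simulated dataset: prophages-per-genome statistics with
Kruskal-Wallis and pairwise Mann-Whitney (Holm-adjusted) group tests;
uncertainty coefficients between phage taxa and host species / country /
isolation source in both directions; and hypergeometric rarefaction of
species richness per isolation source at 75% of the least-sampled group.
"""

import json
from pathlib import Path

import pandas as pd

from prophagepop import diversity, taxonomy
from prophagepop.io_formats import read_matrix_tsv, read_metadata_tsv
from prophagepop.pipeline import summarize_prophage_burden

SIM = Path("results/simulated")
TAX = Path("results/taxonomy")
OUT = Path("results/diversity")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    metadata = read_metadata_tsv(SIM / "metadata.tsv")
    partition = taxonomy.assign_taxa(read_matrix_tsv(TAX / "tani_matrix.tsv"))
    truth = json.loads((SIM / "truth.json").read_text())

    burden = summarize_prophage_burden(metadata)
    print(
        f"burden: {burden.n_phages} prophages over {burden.n_genomes} genomes, "
        f"mean {burden.mean_rounded}, mode {burden.mode}"
    )
    if burden.kruskal is not None:
        print(
            f"  Kruskal-Wallis across hosts: H = {burden.kruskal.statistic:.2f}, "
            f"p = {burden.kruskal.p_value:.3g}"
        )

    ids = partition.phage_ids
    rows = []
    for meta_col in ("host_species", "country", "isolation_source"):
        res = diversity.uncertainty_coefficient(
            [partition.species_label[p] for p in ids],
            [str(metadata.loc[p, meta_col]) for p in ids],
        )
        rows.append(
            {
                "pair": f"species|{meta_col}",
                "U_x_given_y": res.U_x_given_y,
                "U_y_given_x": res.U_y_given_x,
                "MI": res.mutual_information,
            }
        )
    uc = pd.DataFrame(rows)
    uc.to_csv(OUT / "uncertainty_coefficients.tsv", sep="\t", index=False)
    print("uncertainty coefficients (species vs metadata):")
    print(uc.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    analytic = truth["analytic_u"]["country"]["U_species_given_category"]
    print(f"  analytic U(species|country) of the generator: {analytic:.3f}")

    community = diversity.community_matrix(
        {p: partition.species_label[p] for p in ids},
        {p: str(metadata.loc[p, "isolation_source"]) for p in ids},
    )
    totals = community.sum(axis=1).to_dict()
    depth, retained = diversity.rarefaction_depth_rule(totals, fraction=0.75)
    depth = max(depth, 1)
    rows = [
        {
            "source": g,
            "total": totals[g],
            "depth": depth,
            "expected_richness": diversity.rarefy_expected_richness(
                community.loc[g].values, depth
            ),
        }
        for g in retained
    ]
    rare = pd.DataFrame(rows)
    rare.to_csv(OUT / "rarefaction_by_source.tsv", sep="\t", index=False)
    print(f"rarefaction by isolation source (depth {depth} = 75% of least-sampled):")
    print(rare.to_string(index=False, float_format=lambda v: f"{v:.2f}"))


if __name__ == "__main__":
    main()
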