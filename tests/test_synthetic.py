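import json

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from prophagepop import ani, phylo, taxonomy
from prophagepop import io_formats as iof
from prophagepop import simulate as sim


class TestHostTree:
    def test_three_leaves_have_two_internal_nodes_four_branches(self):
        tree = sim.simulate_host_tree(3, 1.0, seed=1)
        leaves = list(tree.leaf_node_iter())
        internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert len(leaves) == 3
        assert len(internal) == 2
        branches = [
            n for n in tree.preorder_node_iter() if n is not tree.seed_node
        ]
        assert len(branches) == 4
        assert all(n.edge.length is not None for n in branches)

    def test_same_seed_reproduces_newick(self):
        t1 = sim.simulate_host_tree(10, 1.0, seed=9)
        t2 = sim.simulate_host_tree(10, 1.0, seed=9)
        assert iof.write_newick(t1) == iof.write_newick(t2)

    def test_total_branch_length_matches_yule_expectation(self):
        # phases with k lineages last Exp(k*rate), adding k*Exp(k*rate)
        # branch length each, so E[total] = (n - 1) / rate
        n, rate, n_rep = 8, 2.0, 400
        totals = []
        for s in range(n_rep):
            tree = sim.simulate_host_tree(n, rate, seed=5000 + s)
            totals.append(tree.length())
        totals = np.array(totals)
        expected = (n - 1) / rate
        se = totals.std(ddof=1) / np.sqrt(n_rep)
        assert abs(totals.mean() - expected) <= 3 * se

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            sim.simulate_host_tree(2, 1.0, seed=0)
        with pytest.raises(ValueError):
            sim.simulate_host_tree(5, -1.0, seed=0)


class TestProphageHistory:
    def test_zero_jump_probability_keeps_codivergent_hosts(self):
        host = sim.simulate_host_tree(8, 1.0, seed=3)
        _, assoc, jumps, origin = sim.simulate_prophage_history(host, 3.0, 0.0, seed=4)
        assert not any(jumps.values())
        for h, p in assoc.links:
            assert origin[p] == h

    def test_jump_probability_one_moves_every_phage(self):
        host = sim.simulate_host_tree(8, 1.0, seed=3)
        _, assoc, jumps, origin = sim.simulate_prophage_history(host, 3.0, 1.0, seed=4)
        assert all(jumps.values())
        for h, p in assoc.links:
            assert origin[p] != h

    def test_realized_jump_fraction_within_binomial_ci(self):
        host = sim.simulate_host_tree(10, 1.0, seed=11)
        p_jump = 0.1
        total = jumped = 0
        for s in range(50):
            _, assoc, jumps, _ = sim.simulate_prophage_history(host, 3.0, p_jump, seed=s)
            total += len(assoc)
            jumped += sum(jumps.values())
        se = np.sqrt(p_jump * (1 - p_jump) / total)
        assert abs(jumped / total - p_jump) <= 2.58 * se  # 99% CI

    def test_phage_tree_mirrors_host_tree_distances(self):
        host = sim.simulate_host_tree(6, 1.0, seed=21)
        phage_tree, assoc, _, origin = sim.simulate_prophage_history(
            host, 2.0, 0.0, seed=2, tip_branch_length=0.02
        )
        host_d = phylo.patristic_matrix(host)
        phage_d = phylo.patristic_matrix(phage_tree)
        for i, (h1, p1) in enumerate(assoc.links):
            for h2, p2 in assoc.links[i + 1 :]:
                if h1 == h2:
                    continue
                expected = host_d.value(h1, h2) + 2 * 0.02
                assert phage_d.value(p1, p2) == pytest.approx(expected, abs=1e-9)


class TestSequenceEvolution:
    def test_zero_length_branches_give_identical_sequences(self):
        tree = iof.read_newick("((A:0,B:0):0,C:0);")
        records, identity = sim.evolve_sequences(tree, 500, 0.1, seed=1)
        assert len({r.sequence for r in records}) == 1
        assert np.allclose(identity.values, 100.0)

    def test_recorded_identity_is_exact_hamming_identity(self):
        tree = iof.read_newick("((A:0.05,B:0.05):0.02,C:0.07);")
        records, identity = sim.evolve_sequences(tree, 1000, 0.5, seed=8)
        seqs = {r.id: np.array(list(r.sequence)) for r in records}
        for i, a in enumerate(identity.labels):
            for b in identity.labels[i + 1 :]:
                hamming = (seqs[a] != seqs[b]).sum()
                assert identity.value(a, b) == pytest.approx(
                    100.0 * (1000 - hamming) / 1000
                )

    def test_oracle_agrees_with_recorded_identity(self):
        tree = iof.read_newick("(A:0.03,B:0.03);")
        records, identity = sim.evolve_sequences(tree, 800, 0.5, seed=5)
        oracle = ani.nw_identity_oracle(records[0].sequence, records[1].sequence)
        assert oracle == pytest.approx(identity.value("A", "B"), abs=0.5)


class TestMetadata:
    def _species(self, n_species=20, members=100):
        return {
            f"p{i}": f"sp{i % n_species}" for i in range(n_species * members)
        }

    def test_strength_one_determines_category_from_species(self):
        labels, analytic = sim.simulate_metadata(
            self._species(), ["c1", "c2", "c3"], 1.0, seed=2
        )
        from prophagepop.diversity import uncertainty_coefficient

        species = self._species()
        res = uncertainty_coefficient(
            [labels[p] for p in sorted(species)], [species[p] for p in sorted(species)]
        )
        assert res.U_x_given_y == pytest.approx(1.0)
        assert analytic["U_category_given_species"] == pytest.approx(1.0)

    def test_strength_zero_estimates_near_zero(self):
        species = self._species()
        labels, analytic = sim.simulate_metadata(species, ["c1", "c2", "c3", "c4"], 0.0, seed=3)
        from prophagepop.diversity import uncertainty_coefficient

        ids = sorted(species)
        res = uncertainty_coefficient([species[p] for p in ids], [labels[p] for p in ids])
        assert analytic["U_species_given_category"] == pytest.approx(0.0, abs=1e-12)
        assert res.U_x_given_y <= 0.05

    def test_estimated_u_tracks_analytic_u(self):
        species = self._species()
        labels, analytic = sim.simulate_metadata(species, ["c1", "c2", "c3", "c4"], 0.7, seed=4)
        from prophagepop.diversity import uncertainty_coefficient

        ids = sorted(species)
        res = uncertainty_coefficient([species[p] for p in ids], [labels[p] for p in ids])
        assert res.U_x_given_y == pytest.approx(analytic["U_species_given_category"], abs=0.05)
        res_rev = uncertainty_coefficient([labels[p] for p in ids], [species[p] for p in ids])
        assert res_rev.U_x_given_y == pytest.approx(
            analytic["U_category_given_species"], abs=0.05
        )


class TestBuildDataset:
    def test_written_files_load_through_io(self, tmp_path):
        cfg = sim.SimulationConfig(seed=6)
        truth = sim.build_dataset(cfg, tmp_path)
        records = iof.read_fasta(tmp_path / "phages.fasta")
        assert [r.id for r in records] == [r.id for r in truth.records]
        meta = iof.read_metadata_tsv(tmp_path / "metadata.tsv")
        assert set(meta.index) == set(truth.species_label)
        host = iof.load_newick(tmp_path / "host_tree.nwk")
        assert len(list(host.leaf_node_iter())) == cfg.n_hosts
        assoc = iof.read_associations_tsv(tmp_path / "associations.tsv")
        assert assoc.links == truth.associations.links
        payload = json.loads((tmp_path / "truth.json").read_text())
        assert payload["species_label"] == truth.species_label

    def test_same_seed_reproduces_files_byte_identically(self, tmp_path):
        cfg = sim.SimulationConfig(seed=12)
        sim.build_dataset(cfg, tmp_path / "a")
        sim.build_dataset(cfg, tmp_path / "b")
        for name in (
            "phages.fasta",
            "metadata.tsv",
            "host_tree.nwk",
            "phage_tree.nwk",
            "associations.tsv",
            "true_identity.tsv",
            "truth.json",
        ):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_true_identities_separate_species_with_margin(self):
        truth = sim.build_dataset(sim.SimulationConfig(seed=3))
        ti, sp = truth.true_identity, truth.species_label
        for i, a in enumerate(ti.labels):
            for b in ti.labels[i + 1 :]:
                if sp[a] == sp[b]:
                    assert ti.value(a, b) >= 95.0 + 1.0
                else:
                    assert ti.value(a, b) <= 95.0 - 10.0

    def test_estimated_taxonomy_recovers_planted_species(self):
        truth = sim.build_dataset(sim.SimulationConfig(seed=3))
        matrix = ani.tani_matrix(truth.records)
        part = taxonomy.assign_taxa(matrix)
        ids = part.phage_ids
        ari = adjusted_rand_score(
            [truth.species_label[i] for i in ids],
            [part.species_label[i] for i in ids],
        )
        assert ari == 1.0

    def test_doubling_hosts_roughly_doubles_phage_count(self):
        counts = {}
        for n_hosts in (10, 20):
            total = 0
            for s in range(10):
                truth = sim.build_dataset(
                    sim.SimulationConfig(
                        n_hosts=n_hosts, root_sequence_length=400, seed=900 + s
                    )
                )
                total += len(truth.records)
            counts[n_hosts] = total
        # each arm is Poisson with mean 10 * n_hosts * 3
        ratio = counts[20] / counts[10]
        assert 1.6 <= ratio <= 2.4
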