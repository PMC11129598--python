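"""Simulator checks against closed forms and an independent coalescent oracle."""

import numpy as np
import pytest
from scipy import stats

import ghostintro as gi
from ghostintro.simulate import LocusAlignment, _SubstitutionKernel
from ghostintro.trees import GeneTree, Node


def _freqs(topo, k=3):
    return np.bincount(topo, minlength=k) / len(topo)


class TestGeneTreeLaw:
    def test_msc_limit_matches_closed_form(self):
        # gamma = 0, C_T = 1.5: P(ab|c) = 1 - (2/3) e^{-1.5} = 0.8512
        m = gi.from_coalescent_grid("ghost", 0.3, 1.5, 0.0)
        topo, _, _ = gi.simulate_trio_arrays(m, 100_000, np.random.default_rng(1))
        expected = 1 - 2 / 3 * np.exp(-1.5)
        se = np.sqrt(expected * (1 - expected) / len(topo))
        assert _freqs(topo)[0] == pytest.approx(expected, abs=3 * se)

    def test_ghost_full_introgression_delays_ab_to_the_ghost_join(self):
        m = gi.from_coalescent_grid("ghost", 0.3, 1.5, 1.0)
        topo, t1, t2 = gi.simulate_trio_arrays(m, 5_000, np.random.default_rng(2))
        t_ab = gi.pair_ages_from_arrays("ab", topo, t1, t2)
        assert t_ab.min() >= m.tau_G

    def test_object_and_vectorized_paths_agree(self, study_models):
        m = study_models["inflow"]
        trees = gi.simulate_gene_trees(m, gi.SimConfig(n_loci=4_000, seed=5))
        topo_o, t1_o, _ = gi.trees_to_arrays(trees, outgroup="o")
        topo_v, t1_v, _ = gi.simulate_trio_arrays(m, 40_000, np.random.default_rng(5))
        table = np.stack([np.bincount(topo_o, minlength=3),
                          np.bincount(topo_v, minlength=3)])
        assert stats.chi2_contingency(table).pvalue > 0.001
        assert stats.ks_2samp(t1_o, t1_v).pvalue > 0.001

    def test_inflow_outflow_matched_topology_distributions_coincide(self, matched_models):
        """The core non-identifiability: matched (C_T, C_S, gamma) inflow and
        outflow give the same topology frequencies."""
        n = 60_000
        t_in, _, _ = gi.simulate_trio_arrays(matched_models["inflow"], n,
                                             np.random.default_rng(7))
        t_out, _, _ = gi.simulate_trio_arrays(matched_models["outflow"], n,
                                              np.random.default_rng(8))
        table = np.stack([np.bincount(t_in, minlength=3), np.bincount(t_out, minlength=3)])
        assert stats.chi2_contingency(table).pvalue > 0.001

    def test_determinism_and_per_locus_substreams(self, study_models):
        m = study_models["ghost"]
        trees_a = gi.simulate_gene_trees(m, gi.SimConfig(n_loci=5, seed=123))
        trees_b = gi.simulate_gene_trees(m, gi.SimConfig(n_loci=5, seed=123))
        assert [t.to_newick() for t in trees_a] == [t.to_newick() for t in trees_b]
        # locus substreams are index-keyed: a shorter run reproduces a prefix
        trees_c = gi.simulate_gene_trees(m, gi.SimConfig(n_loci=3, seed=123))
        assert [t.to_newick() for t in trees_c] == [t.to_newick() for t in trees_a[:3]]

    def test_multiple_sequences_per_species(self, study_models):
        trees = gi.simulate_gene_trees(
            study_models["outflow"], gi.SimConfig(n_loci=3, seqs_per_species=2, seed=9))
        labels = sorted(trees[0].tip_labels())
        assert labels == ["a1", "a2", "b1", "b2", "c1", "c2", "o1", "o2"]


class TestIndependentOracle:
    def test_ghost_scenario_against_msprime(self):
        """Topology frequencies and t_ab distribution from an independent
        coalescent simulator match our simulator's law and analytic density."""
        msprime = pytest.importorskip("msprime")
        m = gi.from_coalescent_grid("ghost", 0.3, 1.5, 0.3)
        theta = m.common_theta
        demography = msprime.Demography()
        for name in ("A", "B", "C", "O", "G"):
            demography.add_population(name=name, initial_size=theta / 2)
        demography.add_mass_migration(time=m.tau_H, source="A", dest="G",
                                      proportion=m.gamma)
        demography.add_mass_migration(time=m.tau_T, source="B", dest="A", proportion=1)
        demography.add_mass_migration(time=m.tau_R, source="C", dest="A", proportion=1)
        demography.add_mass_migration(time=m.tau_G, source="G", dest="A", proportion=1)
        demography.add_mass_migration(time=m.tau_O, source="O", dest="A", proportion=1)
        reps = msprime.sim_ancestry(
            samples=[msprime.SampleSet(1, population=p, ploidy=1)
                     for p in ("A", "B", "C")],
            demography=demography, ploidy=1, num_replicates=30_000, random_seed=11,
        )
        t_ab, topos = [], []
        for ts in reps:
            tree = ts.first()
            ages = {
                0: tree.time(tree.mrca(0, 1)),
                1: tree.time(tree.mrca(1, 2)),
                2: tree.time(tree.mrca(0, 2)),
            }
            topos.append(min(ages, key=ages.get))
            t_ab.append(ages[0])
        topos = np.asarray(topos)
        expected = gi.topology_probs(0.3, *gi.coalescent_units(m)).as_array()
        se = np.sqrt(expected * (1 - expected) / len(topos))
        np.testing.assert_allclose(_freqs(topos), expected, atol=float((4 * se).max()))
        mix = gi.pairwise_density(m, "ab")
        ks = stats.kstest(np.asarray(t_ab),
                          lambda x: np.asarray(mix.cdf(x), dtype=float))
        assert ks.pvalue > 0.001


class TestSequences:
    def test_zero_height_tree_gives_identical_sequences(self):
        root = Node(age=1e-12, children=(Node(0.0, "a"), Node(0.0, "b")))
        aln = gi.simulate_alignments([GeneTree(root)],
                                     gi.SimConfig(n_loci=1, sites_per_locus=500, seed=3))[0]
        assert aln.sequence("a") == aln.sequence("b")

    def test_jc_pairwise_divergence_closed_form(self):
        # two tips at total path 2h: P(diff) = (3/4)(1 - e^{-8h/3})
        h = 0.05
        root = Node(age=h, children=(Node(0.0, "a"), Node(0.0, "b")))
        cfg = gi.SimConfig(n_loci=1, sites_per_locus=40_000, subst_model="JC69", seed=4)
        aln = gi.simulate_alignments([GeneTree(root)], cfg)[0]
        p_obs = np.mean(aln.data[0] != aln.data[1])
        p_exp = 0.75 * (1 - np.exp(-8 * h / 3))
        se = np.sqrt(p_exp * (1 - p_exp) / cfg.sites_per_locus)
        assert p_obs == pytest.approx(p_exp, abs=4 * se)

    def test_hky_kappa_one_equal_freqs_reduces_to_jc(self):
        kernel = _SubstitutionKernel(1.0, (0.25,) * 4)
        t = 0.07
        P = kernel.transition_matrix(t)
        off = 0.25 * (1 - np.exp(-4 * t / 3))
        expected = np.full((4, 4), off)
        np.fill_diagonal(expected, 1 - 3 * off)
        np.testing.assert_allclose(P, expected, atol=1e-12)

    def test_hky_matrix_matches_expm(self):
        from scipy.linalg import expm
        from ghostintro.simulate import _hky_rate_matrix
        freqs = np.array([0.1, 0.2, 0.3, 0.4])
        kernel = _SubstitutionKernel(2.5, freqs)
        Q = _hky_rate_matrix(2.5, freqs)
        np.testing.assert_allclose(kernel.transition_matrix(0.3), expm(Q * 0.3),
                                   atol=1e-12)

    def test_negative_branch_rejected(self):
        bad = GeneTree(Node(age=0.01, children=(Node(0.02, "a"), Node(0.0, "b"))))
        with pytest.raises(ValueError, match="negative branch"):
            gi.simulate_alignments([bad], gi.SimConfig(n_loci=1, sites_per_locus=10, seed=1))

    def test_alignment_validation(self):
        with pytest.raises(ValueError, match="equal length"):
            LocusAlignment.from_strings({"a": "ACGT", "b": "ACG"})
        with pytest.raises(ValueError, match="unknown characters"):
            LocusAlignment.from_strings({"a": "ACGN", "b": "ACGT"})


class TestDatasetIO:
    @pytest.mark.parametrize("fmt", ["fasta", "phylip"])
    def test_round_trip(self, tmp_path, study_models, fmt):
        m = study_models["ghost"]
        cfg = gi.SimConfig(n_loci=4, sites_per_locus=60, seed=21)
        trees = gi.simulate_gene_trees(m, cfg)
        alns = gi.simulate_alignments(trees, cfg)
        out = tmp_path / "ds"
        gi.write_dataset(trees, alns, out, model=m, config=cfg, fmt=fmt)
        trees2, alns2, manifest, model2 = gi.read_dataset(out)
        assert model2 == m
        assert manifest["seed"] == "21"
        assert len(trees2) == len(trees) and len(alns2) == len(alns)
        for t_old, t_new in zip(trees, trees2):
            for pair, age in t_old.pair_mrca_ages().items():
                assert t_new.pair_mrca_ages()[pair] == pytest.approx(age, abs=1e-12)
        for a_old, a_new in zip(alns, alns2):
            assert a_old.to_dict() == a_new.to_dict()

    def test_manifest_seed_reruns_bit_identical(self, tmp_path, study_models):
        m = study_models["inflow"]
        cfg = gi.SimConfig(n_loci=3, sites_per_locus=20, seed=77)
        trees = gi.simulate_gene_trees(m, cfg)
        gi.write_dataset(trees, None, tmp_path / "ds", model=m, config=cfg)
        _, _, manifest, model2 = gi.read_dataset(tmp_path / "ds")
        rerun = gi.simulate_gene_trees(
            model2, gi.SimConfig(n_loci=int(manifest["n_loci"]),
                                 seed=int(manifest["seed"])))
        assert [t.to_newick() for t in rerun] == [t.to_newick() for t in trees]

    def test_empty_dataset(self, tmp_path):
        out = gi.write_dataset([], None, tmp_path / "empty")
        trees, alns, manifest, model = gi.read_dataset(out)
        assert trees == [] and alns == [] and model is None
        assert manifest["n_loci"] == "0"
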