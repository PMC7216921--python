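"""Marginal ancestral reconstruction: pruning correctness against exhaustive
enumeration, point ancestors, Bayesian sampling, and parsimony gap flags."""

import itertools

import numpy as np
import pytest

from nitromet import (AncestralReconstruction, ASRConfig, LabeledAlignment,
                      infer_gaps, jtt)
from nitromet.substitution import AA_INDEX, AMINO_ACIDS


def enumerate_posteriors(newick, alignment, model):
    """Independent oracle: exact marginal posteriors by vectorised exhaustive
    enumeration over all joint internal-state assignments."""
    import dendropy
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    internal = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    names = []
    for i, n in enumerate(internal):
        names.append(n.label or f"int{i}")
        n.label = names[-1]
    k = len(internal)
    node_pos = {n.label: i for i, n in enumerate(internal)}
    assign = np.indices((20,) * k).reshape(k, -1)  # (k, 20^k)
    L = alignment.n_columns
    post = {name: np.zeros((L, 20)) for name in names}
    loglik = 0.0
    for site in range(L):
        prob = model.equilibrium_freqs[assign[node_pos[tree.seed_node.label]]]
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            P = model.transition_matrix(node.edge.length or 0.0)
            parent_states = assign[node_pos[node.parent_node.label]]
            if node.is_leaf():
                ch = alignment.row(node.taxon.label)[site]
                if ch in AA_INDEX:
                    prob = prob * P[parent_states, AA_INDEX[ch]]
            else:
                prob = prob * P[parent_states, assign[node_pos[node.label]]]
        tot = prob.sum()
        loglik += np.log(tot)
        for name in names:
            post[name][site] = np.bincount(assign[node_pos[name]],
                                           weights=prob, minlength=20) / tot
    return post, loglik


def random_tree(rng, n_leaves):
    """Random rooted bifurcating topology with U(0.02, 1.2) branch lengths."""
    nodes = [f"L{i}" for i in range(n_leaves)]
    counter = itertools.count()
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), 2, replace=False)
        a, b = nodes[i], nodes[j]
        merged = (f"({a}:{rng.uniform(0.02, 1.2):.4f},"
                  f"{b}:{rng.uniform(0.02, 1.2):.4f})I{next(counter)}")
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(merged)
    return nodes[0] + ";"


class TestPruningOracle:
    def test_star_tree_zero_branches_point_mass(self, model):
        nwk = "(A:0.0,B:0.0,C:0.0)root;"
        aln = LabeledAlignment(["A", "B", "C"], ["K", "K", "K"],
                               ["unknown"] * 3)
        res = AncestralReconstruction(nwk, aln, model).fit()
        expected = np.zeros(20)
        expected[AA_INDEX["K"]] = 1.0
        assert np.allclose(res.posteriors["root"][0], expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_on_random_trees(self, model, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        nwk = random_tree(rng, n)
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), 2)) for _ in range(n)]
        aln = LabeledAlignment([f"L{i}" for i in range(n)], seqs,
                               ["unknown"] * n)
        res = AncestralReconstruction(nwk, aln, model).fit()
        oracle, loglik = enumerate_posteriors(nwk, aln, model)
        for node, expected in oracle.items():
            assert np.abs(res.posteriors[node] - expected).max() < 1e-10
        assert res.log_likelihood == pytest.approx(loglik, abs=1e-9)

    def test_long_branches_reach_equilibrium(self, model):
        nwk = "(A:400.0,B:400.0)root;"
        aln = LabeledAlignment(["A", "B"], ["W", "C"], ["unknown"] * 2)
        res = AncestralReconstruction(nwk, aln, model).fit()
        assert np.abs(res.posteriors["root"][0]
                      - model.equilibrium_freqs).max() < 1e-4

    def test_likelihood_invariant_to_rerooting(self, model, rng):
        """Under a reversible model the total likelihood does not depend on
        the root position along any branch."""
        import dendropy
        nwk = random_tree(rng, 6)
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), 5)) for _ in range(6)]
        aln = LabeledAlignment([f"L{i}" for i in range(6)], seqs,
                               ["unknown"] * 6)
        base = AncestralReconstruction(nwk, aln, model).fit().log_likelihood
        tree = dendropy.Tree.get(data=nwk, schema="newick",
                                 preserve_underscores=True)
        edge = [e for e in tree.preorder_edge_iter()
                if e.head_node is not tree.seed_node][2]
        tree.reroot_at_edge(edge, length1=edge.length / 2,
                            length2=edge.length / 2)
        rerooted = tree.as_string(schema="newick")
        other = AncestralReconstruction(rerooted, aln, model).fit()
        assert other.log_likelihood == pytest.approx(base, abs=1e-9)

    def test_leaf_alignment_mismatch_names_taxa(self, model):
        aln = LabeledAlignment(["A", "X"], ["K", "K"], ["unknown"] * 2)
        with pytest.raises(ValueError, match="X"):
            AncestralReconstruction("(A:0.1,B:0.1)r;", aln, model)


class TestPointAncestors:
    def test_argmax_residue(self, family_asr):
        node = family_asr.internal_nodes[0]
        seq = family_asr.ml_ancestor(node)
        post = family_asr.posteriors[node]
        for site in (0, 5, 100):
            assert seq[site] == AMINO_ACIDS[post[site].argmax()]

    def test_tie_broken_alphabetically(self, model):
        # two leaves with different residues on equal branches tie exactly
        nwk = "(A:0.3,B:0.3)root;"
        aln = LabeledAlignment(["A", "B"], ["I", "L"], ["unknown"] * 2)
        res = AncestralReconstruction(nwk, aln, model).fit()
        post = res.posteriors["root"][0].copy()
        # force an exact two-way tie, then argmax must pick alphabetical first
        i, l = AA_INDEX["I"], AA_INDEX["L"]
        post[[i, l]] = post[[i, l]].mean()
        res.posteriors["root"][0] = post
        assert res.ml_ancestor("root")[0] == "I"

    def test_unknown_node_rejected(self, family_asr):
        with pytest.raises(KeyError, match="nonexistent"):
            family_asr.ml_ancestor("nonexistent")

    def test_vnf_anf_ancestor_recovers_carbonate_loop(self, family,
                                                      family_asr):
        """The V/Fe common ancestor reconstructs the V-form TGGPRL loop at
        reference positions 355-360, matching the planted truth."""
        _, truth, _ = family
        ml = family_asr.ml_ancestor(truth.vnf_anf_ancestor)
        true_anc = truth.ancestral_sequences[truth.vnf_anf_ancestor]
        assert ml[354:360] == true_anc[354:360]
        assert ml[354] == "T" and ml[357] == "P" and ml[359] == "L"


class TestBayesianSampling:
    def test_point_mass_posteriors_reproduce_ml(self, model):
        nwk = "(A:0.0,B:0.0)root;"
        aln = LabeledAlignment(["A", "B"], ["KR", "KR"], ["unknown"] * 2)
        res = AncestralReconstruction(nwk, aln, model).fit()
        samples = res.sample_ancestors("root", ASRConfig(n_samples=20, seed=3))
        assert set(samples) == {res.ml_ancestor("root")}

    def test_deterministic_under_seed(self, family_asr):
        cfg = ASRConfig(n_samples=100, seed=11)
        node = family_asr.internal_nodes[-1]
        a = family_asr.sample_ancestors(node, cfg)
        b = family_asr.sample_ancestors(node, cfg)
        assert a == b
        assert len(a) == 100

    def test_sampling_frequency_tracks_posterior(self, family_asr):
        """A site with a (p, 1-p) posterior is sampled at frequency p within
        binomial error (10,000 draws)."""
        node = "anc_vnf_anf"
        post = family_asr.posteriors[node]
        # pick the least certain site to make the check informative
        site = int(post.max(axis=1).argmin())
        p = float(post[site].max())
        top = AMINO_ACIDS[post[site].argmax()]
        draws = family_asr.sample_ancestors(
            node, ASRConfig(n_samples=10_000, seed=7))
        freq = sum(s[site] == top for s in draws) / 10_000
        assert freq == pytest.approx(p, abs=0.015)


class TestGapParsimony:
    def _aln(self, cols):
        names = [f"L{i}" for i in range(len(cols[0]))]
        seqs = ["".join(c[i] for c in cols) for i in range(len(names))]
        return LabeledAlignment(names, seqs, ["unknown"] * len(names))

    def test_no_gaps_all_present(self):
        nwk = "((L0:0.1,L1:0.1)a:0.1,(L2:0.1,L3:0.1)b:0.1)root;"
        flags = infer_gaps(nwk, self._aln(["AAAA"]))
        assert not any(f.any() for f in flags.values())

    def test_single_gapped_leaf_keeps_internals_present(self):
        """Fitch oracle: one gapped leaf costs one change on its terminal
        branch; every internal node stays residue-present."""
        nwk = "((L0:0.1,L1:0.1)a:0.1,(L2:0.1,L3:0.1)b:0.1)root;"
        flags = infer_gaps(nwk, self._aln(["A-AA"]))
        assert not any(f[0] for f in flags.values())

    def test_fully_gapped_clade_ancestor_gapped(self):
        nwk = "((L0:0.1,L1:0.1)a:0.1,(L2:0.1,L3:0.1)b:0.1)root;"
        flags = infer_gaps(nwk, self._aln(["--AA"]))
        assert flags["a"][0]
        assert not flags["b"][0]
        assert not flags["root"][0]  # ambiguity resolved toward presence

    def test_ml_ancestor_marks_gap_sites(self, model):
        nwk = "((L0:0.1,L1:0.1)a:0.1,(L2:0.1,L3:0.1)b:0.1)root;"
        aln = self._aln(["--AA", "KKKK"])
        res = AncestralReconstruction(nwk, aln, model).fit()
        assert res.ml_ancestor("a")[0] == "-"
        assert res.ml_ancestor("a")[1] == "K"


class TestSupportSummary:
    def test_point_masses_give_one(self, model):
        nwk = "(A:0.0,B:0.0)root;"
        aln = LabeledAlignment(["A", "B"], ["KR", "KR"], ["unknown"] * 2)
        res = AncestralReconstruction(nwk, aln, model).fit()
        assert res.support_summary("root") == (1.0, 0.0)

    def test_population_sd_arithmetic(self, family_asr):
        node = family_asr.internal_nodes[0]
        post = family_asr.posteriors[node].copy()
        post[0] = 0.0
        post[0, 0] = 1.0  # max 1.0
        post[1] = 0.0
        post[1, 0], post[1, 1] = 0.8, 0.2  # max 0.8
        family_asr.posteriors["_tmp"] = post
        family_asr.gap_flags["_tmp"] = np.zeros(post.shape[0], dtype=bool)
        mean, sd = family_asr.support_summary("_tmp", [0, 1])
        assert (mean, sd) == pytest.approx((0.9, 0.1))

    def test_active_site_support_exceeds_background(self, family, family_asr):
        """Active-site residues evolve under stronger constraint, so their
        mean maximum posterior exceeds the whole-sequence mean at every
        reconstructed backbone ancestor."""
        _, truth, _ = family
        for node in (truth.vnf_anf_ancestor, *truth.deep_ancestors[:2]):
            full_mean, _ = family_asr.support_summary(node)
            site_mean, _ = family_asr.support_summary(node,
                                                      truth.site_columns)
            assert site_mean >= full_mean - 0.05

    def test_gapped_site_subset_rejected(self, model):
        nwk = "((L0:0.1,L1:0.1)a:0.1,(L2:0.1,L3:0.1)b:0.1)root;"
        aln = LabeledAlignment([f"L{i}" for i in range(4)],
                               ["-A", "-A", "AA", "AA"], ["unknown"] * 4)
        res = AncestralReconstruction(nwk, aln, model).fit()
        with pytest.raises(ValueError, match="gapped"):
            res.support_summary("a", [0])
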