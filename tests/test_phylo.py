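"""Phylogenetic covariance, signal, ANOVA, ancestral states, UPGMA."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from phylomorph.phylo import (
    AncestralStates,
    Phylogeny,
    ReconciliationError,
    TreeError,
    ancestral_states,
    discordant_pairs,
    kmult,
    pgls_anova,
    phylo_covariance,
    phylomorphospace,
    species_means,
    upgma,
)
from phylomorph.stats import procrustes_anova, shape_pca

THREE_TIP = "((A:1,B:1):1,C:2);"

# independently computed with phytools (phylosig / fastAnc) on this fixture
PHYTOOLS_TREE = "((A:0.3,B:0.3):0.7,((C:0.5,D:0.5):0.2,E:0.7):0.3);"
PHYTOOLS_X = {"A": 1.2, "B": 0.9, "C": -0.4, "D": -0.1, "E": 0.6}
PHYTOOLS_K = 1.449672046044
PHYTOOLS_ANC = {"root": 0.472519083969466, "AB": 0.948091603053435,
                "CDE": 0.268702290076336, "CD": 0.038167938931298}


def star_tree(labels, depth=1.0):
    return Phylogeny.from_newick(
        "(" + ",".join(f"{l}:{depth}" for l in labels) + ");"
    )


class TestPhylogeny:
    def test_covariance_hand_cases(self):
        two = Phylogeny.from_newick("(A:1,B:1);")
        np.testing.assert_array_equal(two.covariance(["A", "B"]), np.eye(2))
        three = Phylogeny.from_newick(THREE_TIP)
        np.testing.assert_array_equal(
            three.covariance(["A", "B", "C"]),
            [[2, 1, 0], [1, 2, 0], [0, 0, 2]],
        )

    def test_covariance_matches_path_enumeration(self, small_bundle):
        """C_ij equals the brute-force length of the shared root path."""
        _, tree, *_ = small_bundle
        c = tree.covariance()
        labels = tree.tip_labels

        def root_path(tip):
            node = tree.node_for_tip(tip)
            edges = []
            while node.parent_node is not None:
                edges.append(node)
                node = node.parent_node
            return set(id(e) for e in edges), {
                id(e): e.edge.length for e in edges
            }

        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                pa, la = root_path(a)
                pb, lb = root_path(b)
                shared = sum(la[k] for k in pa & pb)
                assert c[i, j] == pytest.approx(shared, abs=1e-12)

    def test_negative_branch_rejected(self):
        with pytest.raises(TreeError):
            Phylogeny.from_newick("((A:1,B:-1):1,C:2);")

    def test_tip_reconciliation_error_lists_offenders(self):
        tree = Phylogeny.from_newick(THREE_TIP)
        with pytest.raises(ReconciliationError) as err:
            tree.covariance(["A", "B", "X"])
        assert "X" in str(err.value)


class TestSpeciesMeans:
    def test_matches_brute_force_group_average(self, small_bundle):
        spec, tree, means, configs, meta = small_bundle
        from phylomorph.geometry import symmetric_gpa

        aligned = symmetric_gpa(configs, spec.symmetry_map)
        sm = species_means(aligned, meta["species"].to_numpy(), tree)
        assert list(sm.index) == tree.tip_labels
        flat = aligned.flat()
        sp = meta["species"].to_numpy()
        for label in tree.tip_labels:
            np.testing.assert_allclose(
                sm.loc[label].to_numpy(), flat[sp == label].mean(axis=0), atol=1e-12
            )

    def test_single_specimen_identity(self):
        from phylomorph.geometry import AlignedDataset

        shapes = np.random.default_rng(0).normal(size=(3, 4, 3))
        ds = AlignedDataset(shapes, np.ones(3), shapes.mean(0), ["a", "b", "c"])
        sm = species_means(ds, np.array(["s1", "s2", "s3"]))
        np.testing.assert_array_equal(
            sm.loc["s2"].to_numpy(), shapes[1].ravel()
        )


class TestKmult:
    def test_star_phylogeny_gives_exactly_one(self, rng):
        tree = star_tree([f"t{i}" for i in range(8)], depth=0.7)
        y = pd.DataFrame(rng.normal(size=(8, 12)), index=[f"t{i}" for i in range(8)])
        res = kmult(y, tree, n_perm=10, seed=0)
        assert res.k_statistic == pytest.approx(1.0, abs=1e-9)

    def test_univariate_matches_phytools(self):
        tree = Phylogeny.from_newick(PHYTOOLS_TREE)
        y = pd.DataFrame({"x": PHYTOOLS_X}).loc[list("ABCDE")]
        res = kmult(y, tree, n_perm=10, seed=0)
        assert res.k_statistic == pytest.approx(PHYTOOLS_K, abs=1e-9)

    def test_scalar_formula_on_three_tip_tree(self):
        """Hand-evaluated K on ((A:1,B:1):1,C:2) with x = (1, 2, 4)."""
        tree = Phylogeny.from_newick(THREE_TIP)
        y = pd.DataFrame({"x": [1.0, 2.0, 4.0]}, index=["A", "B", "C"])
        c = np.array([[2.0, 1, 0], [1, 2, 0], [0, 0, 2]])
        ci = np.linalg.inv(c)
        one = np.ones(3)
        x = np.array([1.0, 2.0, 4.0])
        a = (one @ ci @ x) / (one @ ci @ one)
        r = x - a
        expected_k = ((r @ r) / (r @ ci @ r)) / (
            (np.trace(c) - 3 / (one @ ci @ one)) / 2
        )
        res = kmult(y, tree, n_perm=10, seed=0)
        assert res.k_statistic == pytest.approx(expected_k, abs=1e-12)

    def test_p_value_counting_rule(self, rng):
        tree = star_tree(list("abcdefgh"))
        y = pd.DataFrame(rng.normal(size=(8, 4)), index=list("abcdefgh"))
        res = kmult(y, tree, n_perm=99, seed=1)
        count = int((res.perm_distribution >= res.k_statistic - 1e-14).sum())
        assert res.p_value == pytest.approx(count / 100)


class TestPglsAnova:
    def test_identity_covariance_reduces_to_ordinary_anova(self, rng):
        labels = np.array(["a"] * 5 + ["b"] * 5)
        y = pd.DataFrame(rng.normal(size=(10, 9)), index=[f"t{i}" for i in range(10)])
        tree = star_tree(y.index)
        r_pgls = pgls_anova(y, tree, {"g": labels}, n_perm=99, seed=7)
        r_ols = procrustes_anova(y.to_numpy(), {"g": labels}, n_perm=99, seed=7)
        assert r_pgls.terms[0].ss == pytest.approx(r_ols.terms[0].ss, abs=1e-9)
        assert r_pgls.terms[0].f == pytest.approx(r_ols.terms[0].f, abs=1e-9)
        assert r_pgls.terms[0].p_value == r_ols.terms[0].p_value
        np.testing.assert_allclose(
            r_pgls.terms[0].perm_distribution, r_ols.terms[0].perm_distribution,
            atol=1e-9,
        )

    def test_detects_phylogeny_independent_effect(self, small_bundle):
        """Habitat assigned at random with a large shape offset: the
        phylogenetic ANOVA should reject for most assignments."""
        from phylomorph.convergence import simulate_bm_tips
        from phylomorph.simulate import SimulationSpec, simulate_tree

        tree = simulate_tree(SimulationSpec(n_tips=16, seed=5))
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 20
        for _ in range(n_rep):
            y = simulate_bm_tips(tree, np.eye(6), 1, rng)[0]
            labels = rng.permutation(np.repeat(["w", "m"], 8))
            y[labels == "m"] += 3.0  # strong effect, orthogonal to phylogeny
            res = pgls_anova(
                pd.DataFrame(y, index=tree.tip_labels), tree,
                {"h": labels}, n_perm=99, seed=rng,
            )
            rejections += res.terms[0].p_value <= 0.05
        assert rejections >= 0.8 * n_rep


class TestAncestralStates:
    def test_two_tips_root_is_midpoint(self):
        tree = Phylogeny.from_newick("(A:1,B:1);")
        anc = ancestral_states(pd.DataFrame({"x": [0.0, 4.0]}, index=["A", "B"]), tree)
        assert anc.root[0] == pytest.approx(2.0)

    def test_closed_form_on_three_tip_tree(self):
        """GLS closed form: root = weighted mean with weights from C^{-1}."""
        tree = Phylogeny.from_newick(THREE_TIP)
        x = np.array([1.0, 2.0, 4.0])
        anc = ancestral_states(pd.DataFrame({"x": x}, index=["A", "B", "C"]), tree)
        c = np.array([[2.0, 1, 0], [1, 2, 0], [0, 0, 2]])
        ci = np.linalg.inv(c)
        one = np.ones(3)
        root_gls = (one @ ci @ x) / (one @ ci @ one)
        assert anc.root[0] == pytest.approx(root_gls, abs=1e-12)

    def test_matches_phytools_fast_anc(self):
        tree = Phylogeny.from_newick(PHYTOOLS_TREE)
        y = pd.DataFrame({"x": PHYTOOLS_X}).loc[list("ABCDE")]
        anc = ancestral_states(y, tree)
        assert anc.root[0] == pytest.approx(PHYTOOLS_ANC["root"], abs=1e-9)
        assert anc.states[tree.mrca("A", "B").index][0] == pytest.approx(
            PHYTOOLS_ANC["AB"], abs=1e-9
        )
        assert anc.states[tree.mrca("C", "E").index][0] == pytest.approx(
            PHYTOOLS_ANC["CDE"], abs=1e-9
        )
        assert anc.states[tree.mrca("C", "D").index][0] == pytest.approx(
            PHYTOOLS_ANC["CD"], abs=1e-9
        )

    def test_objective_matches_numerical_optimizer(self, small_bundle):
        from scipy.optimize import minimize

        _, tree, means, *_ = small_bundle
        y = means.iloc[:, :4]
        anc = ancestral_states(y, tree)
        internal = [n.index for n in tree.nodes if not n.is_leaf()]
        x0 = np.zeros(len(internal) * 4)

        yv = y.loc[tree.tip_labels].to_numpy()
        tipmap = {tree.node_for_tip(l).index: yv[i] for i, l in enumerate(tree.tip_labels)}

        def objective(flat):
            vals = dict(zip(internal, flat.reshape(len(internal), 4)))

            def state(idx):
                return vals[idx] if idx in vals else tipmap[idx]

            return sum(
                ((state(p) - state(c)) ** 2).sum() / ln for p, c, ln in tree.edges()
            )

        res = minimize(objective, x0, method="L-BFGS-B",
                       options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 5000})
        assert anc.objective() == pytest.approx(res.fun, abs=1e-8)


class TestPhylomorphospace:
    def test_tips_reproduce_pca_scores(self, small_bundle):
        _, tree, means, *_ = small_bundle
        pca = shape_pca(means.to_numpy())
        anc = ancestral_states(means, tree)
        nodes, edges = phylomorphospace(pca, anc, tree)
        for i, label in enumerate(tree.tip_labels):
            row = nodes[nodes["label"] == label]
            assert row["PC1"].iloc[0] == pytest.approx(pca.scores[i, 0], abs=1e-9)
            assert row["PC2"].iloc[0] == pytest.approx(pca.scores[i, 1], abs=1e-9)
        assert len(edges) == len(tree.nodes) - 1

    def test_root_projection_composes(self, small_bundle):
        _, tree, means, *_ = small_bundle
        pca = shape_pca(means.to_numpy())
        anc = ancestral_states(means, tree)
        nodes, _ = phylomorphospace(pca, anc, tree)
        expected = pca.project(anc.root)[0]
        root_row = nodes.loc[0]
        assert root_row["PC1"] == pytest.approx(expected[0], abs=1e-9)


class TestUpgma:
    def test_hand_agglomeration(self):
        d = pd.DataFrame(
            [[0, 2, 6], [2, 0, 6], [6, 6, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = upgma(d)
        pdm = tree.path_distance_matrix(["A", "B", "C"])
        np.testing.assert_allclose(pdm, d.to_numpy(), atol=1e-12)
        ab = tree.mrca("A", "B")
        assert tree.depths.max() - tree.depths[ab.index] == pytest.approx(1.0)

    def test_ultrametric_input_reproduced(self, small_bundle):
        _, tree, *_ = small_bundle
        pdm = tree.path_distance_matrix()
        rebuilt = upgma(pd.DataFrame(pdm, index=tree.tip_labels, columns=tree.tip_labels))
        np.testing.assert_allclose(
            rebuilt.path_distance_matrix(tree.tip_labels), pdm, atol=1e-9
        )

    def test_matches_scipy_average_linkage(self, rng):
        """Cross-check cophenetic distances against scipy's average linkage
        on a tie-free random distance matrix."""
        pts = rng.normal(size=(9, 4))
        d = squareform(np.linalg.norm(pts[:, None] - pts[None, :], axis=-1), checks=False)
        labels = [f"t{i}" for i in range(9)]
        ours = upgma(
            pd.DataFrame(squareform(d), index=labels, columns=labels)
        )
        coph = cophenet(average(d))
        np.testing.assert_allclose(
            squareform(ours.path_distance_matrix(labels), checks=False),
            coph, atol=1e-9,
        )

    def test_label_order_invariance(self, rng):
        pts = rng.normal(size=(7, 3))
        dm = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = [f"t{i}" for i in range(7)]
        a = upgma(pd.DataFrame(dm, index=labels, columns=labels))
        perm = rng.permutation(7)
        b = upgma(pd.DataFrame(dm[np.ix_(perm, perm)],
                               index=[labels[i] for i in perm],
                               columns=[labels[i] for i in perm]))
        np.testing.assert_allclose(
            a.path_distance_matrix(labels), b.path_distance_matrix(labels), atol=1e-9
        )

    def test_negative_distance_rejected(self):
        d = np.array([[0.0, -1], [-1, 0]])
        with pytest.raises(ValueError, match="negative"):
            upgma(pd.DataFrame(d, index=["A", "B"], columns=["A", "B"]))


class TestDiscordantPairs:
    def test_identical_topology_gives_empty(self, small_bundle):
        _, tree, *_ = small_bundle
        out = discordant_pairs(tree, tree)
        assert len(out) == 0

    def test_swapped_tips_rank_first(self):
        tree = Phylogeny.from_newick(
            "(((A:1,B:1):1,C:2):2,((D:1,E:1):1,F:2):2);"
        )
        # phenogram pairs A with D: tips from opposite deep clades
        phen = Phylogeny.from_newick(
            "(((A:1,D:1):1,C:2):2,((B:1,E:1):1,F:2):2);"
        )
        out = discordant_pairs(tree, phen, quantile=0.25)
        assert len(out) >= 1
        assert {out.iloc[0]["tip_a"], out.iloc[0]["tip_b"]} in ({"A", "D"}, {"B", "E"})

    def test_star_phenogram_gives_empty(self, small_bundle):
        _, tree, *_ = small_bundle
        phen = star_tree(tree.tip_labels)
        assert len(discordant_pairs(tree, phen)) == 0

    def test_tip_mismatch_rejected(self):
        a = Phylogeny.from_newick("(A:1,B:1);")
        b = Phylogeny.from_newick("(A:1,C:1);")
        with pytest.raises(ReconciliationError):
            discordant_pairs(a, b)


def test_phylo_covariance_wrapper(small_bundle):
    _, tree, *_ = small_bundle
    np.testing.assert_array_equal(phylo_covariance(tree), tree.covariance())
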