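"""Alignment building, NJ bootstrap, pruning likelihood and clock LRT."""

import itertools

import numpy as np
import pytest

from plastidkit import phylo
from plastidkit.gtrmodel import GtrParams
from plastidkit.io import tree_from_string
from plastidkit.phylo import (
    SnvAlignment,
    alignment_from_sequences,
    clock_lrt,
    concat_variable_sites,
    fit_gtr,
    gtr_lnl,
    nj_bootstrap_tree,
    p_distance_matrix,
)


def brute_force_lnl(tree, aln, params):
    """Exhaustive summation over all internal-state assignments."""
    tt = tree.clone(depth=1)
    tt.resolve_polytomies()
    nodes = list(tt.postorder_node_iter())
    internals = [nd for nd in nodes if not nd.is_leaf()]
    pmat = {
        id(nd): params.transition_matrix(nd.edge.length or 0.0)
        for nd in nodes
        if nd.parent_node is not None
    }
    total = 0.0
    for site in range(aln.n_sites):
        states = {s: aln.row(s)[site] for s in aln.samples}
        site_l = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            amap = dict(zip([id(n) for n in internals], assign))
            pr = params.pi[amap[id(nodes[-1])]]
            for nd in nodes:
                if nd.parent_node is None:
                    continue
                par = amap[id(nd.parent_node)]
                if nd.is_leaf():
                    st = states[nd.taxon.label]
                    if st != phylo.MISSING_STATE:
                        pr *= pmat[id(nd)][par, st]
                else:
                    pr *= pmat[id(nd)][par, amap[id(nd)]]
            site_l += pr
        total += np.log(site_l)
    return total


class TestAlignment:
    def test_variable_snv_sites_concatenated(self, toy8_dataset, toy8_matrix):
        aln = concat_variable_sites(toy8_matrix)
        assert aln.n_sites == len(
            [p for p in toy8_matrix.snv_positions()]
        ) - self._n_invariant(toy8_matrix)
        assert set(aln.samples) == set(toy8_matrix.samples)

    @staticmethod
    def _n_invariant(matrix):
        n = 0
        for pos in matrix.snv_positions():
            states = {matrix.calls.at[pos, s] for s in matrix.samples}
            states.discard(None)
            if len(states) < 2:
                n += 1
        return n

    def test_every_column_variable(self, toy8_matrix):
        aln = concat_variable_sites(toy8_matrix)
        for j in range(aln.n_sites):
            col = aln.matrix[:, j]
            assert len(set(col[col >= 0])) >= 2

    def test_too_few_samples_rejected(self, toy8_matrix):
        small = type(toy8_matrix)(
            positions=toy8_matrix.positions,
            samples=toy8_matrix.samples[:2],
            calls=toy8_matrix.calls[toy8_matrix.samples[:2]],
            meta=toy8_matrix.meta,
        )
        with pytest.raises(ValueError, match="3 samples"):
            concat_variable_sites(small)


class TestNeighborJoining:
    def test_additive_distances_recovered_exactly(self):
        # additive 4-taxon matrix from known branch lengths
        lengths = {"A": 0.10, "B": 0.15, "C": 0.20, "D": 0.05, "int": 0.08}
        labels = ["A", "B", "C", "D"]
        d = np.zeros((4, 4))
        pairs = {
            ("A", "B"): lengths["A"] + lengths["B"],
            ("C", "D"): lengths["C"] + lengths["D"],
            ("A", "C"): lengths["A"] + lengths["int"] + lengths["C"],
            ("A", "D"): lengths["A"] + lengths["int"] + lengths["D"],
            ("B", "C"): lengths["B"] + lengths["int"] + lengths["C"],
            ("B", "D"): lengths["B"] + lengths["int"] + lengths["D"],
        }
        for (x, y), v in pairs.items():
            i, j = labels.index(x), labels.index(y)
            d[i, j] = d[j, i] = v
        tree = phylo._nj_from_distances(d, labels)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for (x, y), v in pairs.items():
            assert pdm.patristic_distance(taxa[x], taxa[y]) == pytest.approx(v, abs=1e-9)

    def test_identical_sequences_form_zero_length_cherry(self):
        seqs = {"A": "ACGTACGTAC", "B": "ACGTACGTAC", "C": "GGGGACGTAC", "D": "GGGGTTTTAC"}
        aln = alignment_from_sequences(seqs)
        tree = nj_bootstrap_tree(aln, n_boot=10, seed=1)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.patristic_distance(taxa["A"], taxa["B"]) == pytest.approx(0.0, abs=1e-9)

    def test_clean_signal_gives_full_support(self, toy8_dataset, toy8_matrix):
        aln = concat_variable_sites(toy8_matrix)
        tree = nj_bootstrap_tree(aln, n_boot=100, seed=3)
        supports = [
            int(nd.label)
            for nd in tree.preorder_internal_node_iter()
            if nd.label is not None
        ]
        assert supports and np.mean([s >= 95 for s in supports]) >= 0.8

    def test_disjoint_missing_patterns_rejected(self):
        aln = SnvAlignment(
            samples=["A", "B", "C"],
            positions=[0, 1],
            matrix=np.array([[0, -1], [-1, 1], [0, 1]], dtype=np.int8),
        )
        with pytest.raises(ValueError, match="no non-missing"):
            p_distance_matrix(aln)


class TestLikelihood:
    def test_pruning_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for rep in range(12):
            n_taxa = int(rng.integers(3, 5))
            n_sites = int(rng.integers(3, 21))
            labels = [chr(65 + i) for i in range(n_taxa)]
            if n_taxa == 3:
                newick = f"({labels[0]}:{rng.uniform(0.02,0.4):.3f},{labels[1]}:{rng.uniform(0.02,0.4):.3f},{labels[2]}:{rng.uniform(0.02,0.4):.3f});"
            else:
                bl = rng.uniform(0.02, 0.4, size=6)
                newick = (
                    f"(({labels[0]}:{bl[0]:.3f},{labels[1]}:{bl[1]:.3f}):{bl[4]:.3f},"
                    f"({labels[2]}:{bl[2]:.3f},{labels[3]}:{bl[3]:.3f}):{bl[5]:.3f});"
                )
            tree = tree_from_string(newick)
            seqs = {}
            for lab in labels:
                chars = rng.choice(list("ACGT"), size=n_sites)
                # sprinkle missing data
                miss = rng.random(n_sites) < 0.1
                seqs[lab] = "".join("N" if m else c for c, m in zip(chars, miss))
            aln = alignment_from_sequences(seqs)
            pi = rng.dirichlet([5, 5, 5, 5])
            exch = rng.uniform(0.5, 3.0, size=6)
            params = GtrParams(pi=pi, exch=exch)
            assert gtr_lnl(tree, aln, params) == pytest.approx(
                brute_force_lnl(tree, aln, params), abs=1e-8
            )

    def test_likelihood_invariant_to_leaf_order(self):
        rng = np.random.default_rng(5)
        seqs = {lab: "".join(rng.choice(list("ACGT"), 15)) for lab in "ABCD"}
        aln = alignment_from_sequences(seqs)
        params = GtrParams()
        t1 = tree_from_string("((A:0.1,B:0.2):0.05,(C:0.1,D:0.3):0.07);")
        t2 = tree_from_string("((D:0.3,C:0.1):0.07,(B:0.2,A:0.1):0.05);")
        assert gtr_lnl(t1, aln, params) == pytest.approx(gtr_lnl(t2, aln, params), abs=1e-9)

    def test_identical_pair_optimum_is_zero_branch(self):
        seqs = {"A": "ACGTACGTGG", "B": "ACGTACGTGG", "C": "ACGTTTTTGG"}
        aln = alignment_from_sequences(seqs)
        tree = tree_from_string("(A:0.05,B:0.05,C:0.1);")
        lnl, fitted, params = fit_gtr(tree, aln)
        pdm = fitted.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in fitted.taxon_namespace}
        assert pdm.patristic_distance(taxa["A"], taxa["B"]) < 1e-4
        # closed form for fully identical columns: sum log pi
        seqs2 = {"A": "AACC", "B": "AACC", "C": "AACC"}
        aln2 = alignment_from_sequences(seqs2)
        lnl2, _, params2 = fit_gtr(tree_from_string("(A:0.1,B:0.1,C:0.1);"), aln2)
        expected = 2 * np.log(params2.pi[0]) + 2 * np.log(params2.pi[1])
        assert lnl2 == pytest.approx(expected, abs=1e-4)

    def test_clock_fit_never_beats_unconstrained(self):
        rng = np.random.default_rng(9)
        for rep in range(3):
            seqs = {lab: "".join(rng.choice(list("ACGT"), 40)) for lab in "ABCDE"}
            aln = alignment_from_sequences(seqs)
            tree = tree_from_string("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")
            lnl_u, _, _ = fit_gtr(tree, aln, clock=False)
            lnl_c, _, _ = fit_gtr(tree, aln, clock=True)
            assert lnl_c <= lnl_u + 1e-6

    def test_clock_constrained_tree_is_ultrametric(self):
        rng = np.random.default_rng(11)
        seqs = {lab: "".join(rng.choice(list("ACGT"), 30)) for lab in "ABCD"}
        aln = alignment_from_sequences(seqs)
        tree = tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")
        _, fitted, _ = fit_gtr(tree, aln, clock=True)
        depths = []
        for leaf in fitted.leaf_node_iter():
            depth, nd = 0.0, leaf
            while nd.parent_node is not None:
                depth += nd.edge.length or 0.0
                nd = nd.parent_node
            depths.append(depth)
        assert max(depths) - min(depths) < 1e-8


class TestClockLrt:
    def test_worked_example(self):
        chi2, df, p = clock_lrt(9717.403, 11250.99, 34)
        assert chi2 == pytest.approx(3067.174, abs=1e-9)
        assert df == 32
        assert p < 1e-10

    def test_equal_likelihoods_give_p_one(self):
        chi2, df, p = clock_lrt(100.0, 100.0, 10)
        assert chi2 == 0.0
        assert p == 1.0

    def test_simple_arithmetic(self):
        chi2, df, _ = clock_lrt(100.0, 110.0, 10)
        assert chi2 == pytest.approx(20.0)
        assert df == 8

    def test_swapped_inputs_rejected(self):
        with pytest.raises(ValueError, match="swapped"):
            clock_lrt(110.0, 100.0, 10)
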