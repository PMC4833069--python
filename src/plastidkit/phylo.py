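"""SNV phylogeny: variable-site alignment, NJ bootstrap tree, GTR likelihood
with and without a molecular clock, and the clocklikeness LRT.

The variable-site alignment concatenates the biallelic and triallelic SNV
columns of the variant matrix, one sequence per sample, with MISSING states
kept.  Tree inference is neighbor joining on p-distances (pairwise deletion
of MISSING); branch support comes from site-resampled bootstrap replicates.
Likelihoods are computed by the pruning recursion under GTR over unique site
patterns, with MISSING marginalized.  The clock test compares the
unconstrained fit against a height-parameterized (ultrametric) fit with a
chi-square LRT on N-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import optimize, stats

from .gtrmodel import BASES, GtrParams, transition_matrices

MISSING_STATE = -1


@dataclass
class SnvAlignment:
    samples: list[str]
    positions: list[int]
    matrix: np.ndarray  # (n_samples, n_sites) int8; -1 = MISSING

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def row(self, sample: str) -> np.ndarray:
        return self.matrix[self.samples.index(sample)]


def concat_variable_sites(matrix) -> SnvAlignment:
    """Concatenate variable SNV columns of a VariantMatrix into an alignment.

    Indel rows are excluded; columns with fewer than two distinct non-missing
    states (invariant after calls) are dropped.
    """
    samples = matrix.samples
    if len(samples) < 3:
        raise ValueError("need at least 3 samples for phylogenetic analysis")
    cols = []
    keep_pos = []
    for pos in matrix.snv_positions():
        states = []
        for s in samples:
            call = matrix.calls.at[pos, s]
            states.append(BASES.index(call) if call in BASES else MISSING_STATE)
        distinct = {x for x in states if x != MISSING_STATE}
        if len(distinct) >= 2:
            cols.append(states)
            keep_pos.append(pos)
    if not cols:
        raise ValueError("no variable SNV sites among the samples")
    mat = np.array(cols, dtype=np.int8).T
    return SnvAlignment(samples=list(samples), positions=keep_pos, matrix=mat)


def alignment_from_sequences(seqs: dict[str, str]) -> SnvAlignment:
    """Build an alignment directly from equal-length sequences (N/-/? = MISSING)."""
    samples = sorted(seqs)
    L = len(next(iter(seqs.values())))
    mat = np.full((len(samples), L), MISSING_STATE, dtype=np.int8)
    for i, s in enumerate(samples):
        for j, ch in enumerate(seqs[s].upper()):
            if ch in BASES:
                mat[i, j] = BASES.index(ch)
    return SnvAlignment(samples=samples, positions=list(range(L)), matrix=mat)


# ---------------------------------------------------------------------------
# distances and NJ


def p_distance_matrix(aln: SnvAlignment) -> np.ndarray:
    """Pairwise p-distances with pairwise deletion of MISSING."""
    m = aln.matrix
    n = len(aln.samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (m[i] != MISSING_STATE) & (m[j] != MISSING_STATE)
            shared = int(ok.sum())
            if shared == 0:
                raise ValueError(
                    f"samples {aln.samples[i]} and {aln.samples[j]} share no non-missing sites"
                )
            d[i, j] = d[j, i] = float((m[i][ok] != m[j][ok]).sum()) / shared
    return d


def _nj_from_distances(d: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic (lexicographic) tie-breaks.

    Ties in the Q criterion are resolved toward the smallest index pair so
    results are bit-identical across runs; negative branch lengths are
    clamped to zero.
    """
    n = len(labels)
    d = d.astype(float).copy()
    active = list(range(n))
    newicks = {i: lab for i, lab in enumerate(labels)}

    def join_str(a, b, la, lb):
        return f"({newicks[a]}:{max(la, 0.0):.10g},{newicks[b]}:{max(lb, 0.0):.10g})"

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        best = np.unravel_index(np.argmin(q), q.shape)  # first minimum: row-major
        i, j = sorted((best[0], best[1]))
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = dij - li
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (d[ai, active] + d[aj, active] - dij)
        newicks[ai] = join_str(ai, aj, li, lj)
        d[ai, active] = new_row
        d[np.asarray(active), ai] = new_row
        d[ai, ai] = 0.0
        active.pop(j)
    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
        lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
        lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
        text = (
            f"({newicks[a]}:{max(la, 0.0):.10g},{newicks[b]}:{max(lb, 0.0):.10g},"
            f"{newicks[c]}:{max(lc, 0.0):.10g});"
        )
    else:
        a, b = active
        half = max(d[a, b] / 2, 0.0)
        text = f"({newicks[a]}:{half:.10g},{newicks[b]}:{half:.10g});"
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    return tree


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_internal_node_iter():
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(all_taxa):
            out.add(min(side, all_taxa - side, key=lambda s: (len(s), sorted(s))))
    return out


def nj_bootstrap_tree(aln: SnvAlignment, n_boot: int = 100, seed: int = 0) -> dendropy.Tree:
    """NJ tree on p-distances with site-resampled bootstrap supports (%)."""
    if len(aln.samples) < 3:
        raise ValueError("need at least 3 samples")
    d = p_distance_matrix(aln)
    tree = _nj_from_distances(d, aln.samples)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_boot):
        idx = rng.integers(0, aln.n_sites, size=aln.n_sites)
        sub = SnvAlignment(aln.samples, [aln.positions[i] for i in idx], aln.matrix[:, idx])
        try:
            bd = p_distance_matrix(sub)
        except ValueError:
            continue
        for bp in _bipartitions(_nj_from_distances(bd, aln.samples)):
            counts[bp] = counts.get(bp, 0) + 1
    all_taxa = frozenset(aln.samples)
    for node in tree.preorder_internal_node_iter():
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(all_taxa):
            key = min(side, all_taxa - side, key=lambda s: (len(s), sorted(s)))
            node.label = str(round(100.0 * counts.get(key, 0) / n_boot))
    return tree


# ---------------------------------------------------------------------------
# GTR likelihood by pruning


def _compress_patterns(aln: SnvAlignment, order: list[str]):
    m = np.stack([aln.row(s) for s in order])
    patterns, inverse, counts = np.unique(m, axis=1, return_inverse=True, return_counts=True)
    return patterns, counts


def _partials_for_state(state: int) -> np.ndarray:
    if state == MISSING_STATE:
        return np.ones(4)
    v = np.zeros(4)
    v[state] = 1.0
    return v


def _prepare_tree(tree: dendropy.Tree):
    """Postorder node list with integer ids; resolve polytomies with zero branches."""
    tree = tree.clone(depth=1)
    tree.resolve_polytomies()
    nodes = list(tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    return tree, nodes, index


def _pruning_lnl(
    nodes, index, patterns, counts, params: GtrParams, lengths: dict[int, float]
) -> float:
    n_pat = patterns.shape[1]
    partials = {}
    lens = []
    branch_nodes = [nd for nd in nodes if nd.parent_node is not None]
    lens = np.array([max(lengths[index[id(nd)]], 0.0) for nd in branch_nodes])
    pmats = transition_matrices(params, lens)
    pmat_of = {id(nd): pmats[i] for i, nd in enumerate(branch_nodes)}
    leaf_rank = {}
    r = 0
    for nd in nodes:
        if nd.is_leaf():
            leaf_rank[id(nd)] = r
            r += 1
    scale_log = np.zeros(n_pat)
    for nd in nodes:
        if nd.is_leaf():
            states = patterns[leaf_rank[id(nd)]]
            p = np.zeros((n_pat, 4))
            known = states != MISSING_STATE
            p[known, states[known]] = 1.0
            p[~known] = 1.0
            partials[id(nd)] = p
        else:
            p = np.ones((n_pat, 4))
            for ch in nd.child_nodes():
                p = p * (partials[id(ch)] @ pmat_of[id(ch)].T)
            mx = p.max(axis=1)
            mx[mx == 0] = 1.0
            scale_log += np.log(mx)
            partials[id(nd)] = p / mx[:, None]
    root = nodes[-1]
    site_l = partials[id(root)] @ params.pi
    site_l = np.clip(site_l, 1e-300, None)
    return float(np.dot(counts, np.log(site_l) + scale_log))


def gtr_lnl(tree: dendropy.Tree, aln: SnvAlignment, params: GtrParams | None = None) -> float:
    """Log-likelihood of the alignment on the tree (branch lengths as given)."""
    params = params or empirical_gtr(aln)
    t, nodes, index = _prepare_tree(tree)
    order = [nd.taxon.label for nd in nodes if nd.is_leaf()]
    patterns, counts = _compress_patterns(aln, order)
    lengths = {index[id(nd)]: (nd.edge.length or 0.0) for nd in nodes if nd.parent_node is not None}
    return _pruning_lnl(nodes, index, patterns, counts, params, lengths)


def empirical_gtr(aln: SnvAlignment) -> GtrParams:
    """GTR with empirical base frequencies and unit exchangeabilities."""
    m = aln.matrix
    freqs = np.array([(m == b).sum() for b in range(4)], dtype=float)
    freqs = np.maximum(freqs, 1.0)
    return GtrParams(pi=freqs / freqs.sum(), exch=np.ones(6))


def fit_gtr(
    tree: dendropy.Tree,
    aln: SnvAlignment,
    clock: bool = False,
    estimate_exchangeabilities: bool = False,
    tol: float = 1e-6,
):
    """Optimize branch lengths (or node heights under a clock) by ML.

    Returns ``(lnL, fitted_tree, GtrParams)``.  Base frequencies are
    empirical; exchangeabilities are optionally optimized jointly.  In clock
    mode node heights are parameterized so every root-to-leaf path is equal
    (ultrametric), which is the nested null of the clock LRT.
    """
    work, nodes, index = _prepare_tree(tree)
    leaf_labels = {nd.taxon.label for nd in nodes if nd.is_leaf()}
    if leaf_labels != set(aln.samples):
        raise ValueError("tree leaves do not match alignment samples")
    order = [nd.taxon.label for nd in nodes if nd.is_leaf()]
    patterns, counts = _compress_patterns(aln, order)
    params0 = empirical_gtr(aln)
    branch_nodes = [nd for nd in nodes if nd.parent_node is not None]

    n_exch = 5 if estimate_exchangeabilities else 0

    if not clock:
        init_lens = np.array(
            [max(nd.edge.length if nd.edge.length else 0.01, 1e-6) for nd in branch_nodes]
        )
        x0 = np.concatenate([np.log(init_lens), np.zeros(n_exch)])

        def unpack(x):
            lens = np.exp(x[: len(branch_nodes)])
            if n_exch:
                exch = np.concatenate([np.exp(x[len(branch_nodes) :]), [1.0]])
                params = GtrParams(pi=params0.pi, exch=exch)
            else:
                params = params0
            lengths = {index[id(nd)]: l for nd, l in zip(branch_nodes, lens)}
            return lengths, params

    else:
        internal = [nd for nd in nodes if not nd.is_leaf()]
        root = nodes[-1]
        non_root_internal = [nd for nd in internal if nd is not root]
        x0 = np.concatenate([[np.log(0.05)], np.zeros(len(non_root_internal)), np.zeros(n_exch)])

        def unpack(x):
            h_root = np.exp(x[0])
            props = 1.0 / (1.0 + np.exp(-x[1 : 1 + len(non_root_internal)]))
            if n_exch:
                exch = np.concatenate([np.exp(x[1 + len(non_root_internal) :]), [1.0]])
                params = GtrParams(pi=params0.pi, exch=exch)
            else:
                params = params0
            heights = {id(root): h_root}
            pi = 0
            for nd in [n for n in reversed(nodes) if not n.is_leaf() and n is not root]:
                heights[id(nd)] = heights[id(nd.parent_node)] * props[pi]
                pi += 1
            lengths = {}
            for nd in branch_nodes:
                h_child = 0.0 if nd.is_leaf() else heights[id(nd)]
                lengths[index[id(nd)]] = max(heights[id(nd.parent_node)] - h_child, 0.0)
            return lengths, params

    def neg(x):
        lengths, params = unpack(x)
        return -_pruning_lnl(nodes, index, patterns, counts, params, lengths)

    res = optimize.minimize(neg, x0, method="L-BFGS-B", options={"ftol": tol, "maxiter": 2000})
    lengths, params = unpack(res.x)
    for nd in branch_nodes:
        nd.edge.length = lengths[index[id(nd)]]
    return -res.fun, work, params


def clock_lrt(neg_lnl_unconstrained: float, neg_lnl_clock: float, n_taxa: int):
    """Likelihood-ratio test of clocklike behavior.

    Inputs are -lnL values (clock >= unconstrained).  Returns
    ``(chi2, df, p)`` with ``chi2 = 2 * (neg_lnl_clock - neg_lnl_unconstrained)``
    and ``df = n_taxa - 2``.
    """
    chi2 = 2.0 * (neg_lnl_clock - neg_lnl_unconstrained)
    if chi2 < 0:
        raise ValueError("clock -lnL must be >= unconstrained -lnL (inputs swapped?)")
    df = n_taxa - 2
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p
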