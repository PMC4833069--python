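"""Branch-omega positive-selection scan from parsimony substitution counts.

Per-gene codon alignments are screened with a counting-based branch model:
ancestral codons are reconstructed by Fitch parsimony, each branch's codon
differences are decomposed into synonymous and nonsynonymous substitutions by
Nei-Gojobori (1986) pathway averaging, and the branch substitution counts are
modeled binomially: of the n_b + s_b substitutions on branch b, the
nonsynonymous number is Binomial with success probability
p(omega) = omega*N / (omega*N + S), where N and S are the NG86 nonsynonymous
and synonymous site totals of the gene.  Three nested models are compared by
likelihood ratio: omega fixed at 1 everywhere; a single free omega; and a
two-ratio model with separate foreground and background omegas.  A gene is
called under positive (negative) selection on a clade when the foreground
omega exceeds (falls below) 1 and the two-ratio model beats the
foreground-neutral null at level alpha; genes with too few substitutions are
filtered out.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"


def translate(codon: str) -> str:
    return "*" if codon in _STOPS else _TABLE.forward_table[codon]


@dataclass
class CodonAlignment:
    gene: str
    sequences: dict[str, str]  # sample -> in-frame codon sequence

    def __post_init__(self) -> None:
        drop = []
        for name, seq in self.sequences.items():
            if len(seq) % 3 != 0:
                raise ValueError(f"{name}: length not a multiple of 3")
            codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
            if any(c in _STOPS for c in codons[:-1]):
                drop.append(name)
        for name in drop:
            warnings.warn(f"{name}: internal stop codon; sequence dropped from {self.gene}")
            del self.sequences[name]

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3

    def codons(self, sample: str) -> list[str]:
        s = self.sequences[sample]
        return [s[i : i + 3] for i in range(0, len(s), 3)]


@dataclass
class SubstCounts:
    gene: str
    per_branch: dict[frozenset, tuple[float, float]]  # branch -> (n, s)
    n_sites: float
    s_sites: float

    @property
    def total(self) -> float:
        return sum(n + s for n, s in self.per_branch.values())


@dataclass
class SelTestResult:
    gene: str
    foreground: frozenset
    omega_global: float
    omega_foreground: float
    omega_background: float
    lnl_neutral: float
    lnl_global: float
    lnl_two_ratio: float
    lrt: float
    p_value: float
    verdict: str  # positive / negative / neutral / filtered


# ---------------------------------------------------------------------------
# NG86 site and pathway counting

_COMP = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one codon.

    Each of the nine single-base changes contributes 1/3 of a site; changes
    creating a stop codon are counted as nonsynonymous.  N + S = 3.
    """
    if codon in _STOPS:
        return (3.0, 0.0)
    aa = translate(codon)
    syn = 0.0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if mut not in _STOPS and translate(mut) == aa:
                syn += 1.0 / 3.0
    return (3.0 - syn, syn)


@lru_cache(maxsize=None)
def pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) changes between two codons.

    All orderings of the differing positions are enumerated; paths passing
    through a stop codon are excluded unless every path does.  Each step is
    synonymous iff the amino acid is unchanged (stop transitions count as
    nonsynonymous).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return (0.0, 0.0)
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        n = s = 0.0
        through_stop = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if nxt in _STOPS and nxt != c2:
                through_stop = True
            if cur in _STOPS or nxt in _STOPS:
                n += 1.0
            elif translate(cur) == translate(nxt):
                s += 1.0
            else:
                n += 1.0
            cur = nxt
        paths.append((through_stop, n, s))
    valid = [(n, s) for through, n, s in paths if not through]
    if not valid:
        valid = [(n, s) for _, n, s in paths]
    n_avg = float(np.mean([n for n, _ in valid]))
    s_avg = float(np.mean([s for _, s in valid]))
    return (n_avg, s_avg)


# ---------------------------------------------------------------------------
# codon alignment extraction


def extract_codon_alignment(
    genomes: dict,
    genes: pd.DataFrame,
    gene_id: str,
    ir_intervals: list[tuple[int, int]] | None = None,
) -> CodonAlignment:
    """Build the per-sample in-frame codon alignment of one gene.

    ``genomes`` maps sample -> GenomeState (reference-frame representation).
    Exons are concatenated in genomic order and reverse-complemented for
    negative-strand genes.  Any codon column touched by an indel in any
    sample (deleted positions or an anchored insertion) is removed across all
    rows, keeping the alignment in frame.
    """
    rows = genes[genes["gene"] == gene_id].sort_values("start")
    if rows.empty:
        raise KeyError(f"unknown gene {gene_id}")
    strand = rows.iloc[0]["strand"]
    span = [(int(r["start"]), int(r["end"])) for _, r in rows.iterrows()]
    if ir_intervals:
        for s, e in span:
            if any(s < ie and is_ < e for is_, ie in ir_intervals):
                raise ValueError(f"gene {gene_id} overlaps an inverted repeat")
    positions = [p for s, e in span for p in range(s, e)]
    if strand == "-":
        positions = positions[::-1]
    n_codons = len(positions) // 3
    codon_pos = [positions[3 * i : 3 * i + 3] for i in range(n_codons)]

    bad_codons = set()
    for state in genomes.values():
        for ci, triple in enumerate(codon_pos):
            for p in triple:
                if state.deleted[p] or p in state.insertions:
                    bad_codons.add(ci)
                    break
    seqs = {}
    for name, state in genomes.items():
        chars = []
        for ci, triple in enumerate(codon_pos):
            if ci in bad_codons:
                continue
            for p in triple:
                base = "ACGT"[state.bases[p]]
                chars.append(base if strand == "+" else base.translate(_COMP))
        seqs[name] = "".join(chars)
    return CodonAlignment(gene=gene_id, sequences=seqs)


# ---------------------------------------------------------------------------
# parsimony counting along the tree


def count_substitutions(tree, aln: CodonAlignment) -> SubstCounts:
    """Per-branch synonymous/nonsynonymous counts by Fitch parsimony + NG86.

    Ancestral codons per column are reconstructed with Fitch's set method over
    the observed codon states; ambiguities resolve toward fewer nonsynonymous
    changes, then lexicographically.  Per-branch codon differences are
    decomposed by pathway averaging; N and S site totals are NG86 counts
    averaged over the leaf sequences.
    """
    if aln.n_codons == 0:
        raise ValueError("empty codon alignment")
    leaves = {nd.taxon.label: nd for nd in tree.leaf_node_iter()}
    missing = set(leaves) - set(aln.sequences)
    if missing:
        raise ValueError(f"no sequence for tree leaves: {sorted(missing)}")
    clade = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            clade[id(nd)] = frozenset([nd.taxon.label])
        else:
            clade[id(nd)] = frozenset().union(*(clade[id(c)] for c in nd.child_nodes()))

    per_branch: dict[frozenset, list[float]] = {
        clade[id(nd)]: [0.0, 0.0] for nd in tree.preorder_node_iter() if nd.parent_node is not None
    }
    codons_by_leaf = {name: aln.codons(name) for name in aln.sequences}

    for col in range(aln.n_codons):
        # Fitch bottom-up
        sets: dict[int, frozenset] = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                sets[id(nd)] = frozenset([codons_by_leaf[nd.taxon.label][col]])
            else:
                children = [sets[id(c)] for c in nd.child_nodes()]
                inter = frozenset.intersection(*children)
                sets[id(nd)] = inter if inter else frozenset.union(*children)
        # top-down assignment
        assign: dict[int, str] = {}
        for nd in tree.preorder_node_iter():
            options = sorted(sets[id(nd)])
            if nd.parent_node is None:
                assign[id(nd)] = options[0]
            else:
                parent = assign[id(nd.parent_node)]
                if parent in sets[id(nd)]:
                    assign[id(nd)] = parent
                else:
                    assign[id(nd)] = min(options, key=lambda c: (pathway_counts(parent, c)[0], c))
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            n, s = pathway_counts(assign[id(nd.parent_node)], assign[id(nd)])
            acc = per_branch[clade[id(nd)]]
            acc[0] += n
            acc[1] += s

    site_counts = []
    for name in aln.sequences:
        tot_n = tot_s = 0.0
        for c in codons_by_leaf[name]:
            n, s = ng86_sites(c)
            tot_n += n
            tot_s += s
        site_counts.append((tot_n, tot_s))
    n_sites = float(np.mean([n for n, _ in site_counts]))
    s_sites = float(np.mean([s for _, s in site_counts]))
    return SubstCounts(
        gene=aln.gene,
        per_branch={k: (v[0], v[1]) for k, v in per_branch.items()},
        n_sites=n_sites,
        s_sites=s_sites,
    )


# ---------------------------------------------------------------------------
# binomial branch-omega models and LRT


def _p_of_omega(omega: float, N: float, S: float) -> float:
    return omega * N / (omega * N + S)


def _binom_ll(n: float, s: float, p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return n * np.log(p) + s * np.log(1 - p)


def _mle_omega(n: float, s: float, N: float, S: float) -> float:
    """Closed-form MLE: omega = (n/N) / (s/S); capped for zero counts."""
    if n == 0 and s == 0:
        return 1.0
    if s == 0:
        return 999.0
    if n == 0:
        return 1e-6
    return (n / N) / (s / S)


def omega_lrt(
    counts: SubstCounts,
    foreground: set[frozenset],
    alpha: float = 0.05,
    min_subs: float = 5.0,
) -> SelTestResult:
    """Three-model branch-omega comparison on one gene and one foreground clade.

    The two-ratio model (separate foreground/background omegas) is tested
    against the foreground-neutral null (foreground omega fixed at 1,
    background free) with a 1-df chi-square LRT.
    """
    N, S = counts.n_sites, counts.s_sites
    if N <= 0 or S <= 0:
        raise ValueError("N and S site counts must be positive")
    branches = list(counts.per_branch)
    unknown = set(foreground) - set(branches)
    if unknown:
        raise KeyError(f"foreground branches not in tree: {sorted(map(sorted, unknown))}")
    fg = [b for b in branches if b in foreground]
    bg = [b for b in branches if b not in foreground]
    n_fg = sum(counts.per_branch[b][0] for b in fg)
    s_fg = sum(counts.per_branch[b][1] for b in fg)
    n_bg = sum(counts.per_branch[b][0] for b in bg)
    s_bg = sum(counts.per_branch[b][1] for b in bg)
    n_all, s_all = n_fg + n_bg, s_fg + s_bg

    p1 = _p_of_omega(1.0, N, S)
    lnl_neutral = _binom_ll(n_all, s_all, p1)
    omega_g = _mle_omega(n_all, s_all, N, S)
    lnl_global = _binom_ll(n_all, s_all, _p_of_omega(omega_g, N, S))
    omega_f = _mle_omega(n_fg, s_fg, N, S)
    omega_b = _mle_omega(n_bg, s_bg, N, S)
    lnl_two = _binom_ll(n_fg, s_fg, _p_of_omega(omega_f, N, S)) + _binom_ll(
        n_bg, s_bg, _p_of_omega(omega_b, N, S)
    )
    # null for the clade test: foreground neutral, background free
    lnl_null = _binom_ll(n_fg, s_fg, p1) + _binom_ll(n_bg, s_bg, _p_of_omega(omega_b, N, S))
    lrt = max(2.0 * (lnl_two - lnl_null), 0.0)
    p = float(stats.chi2.sf(lrt, df=1))

    if counts.total < min_subs:
        verdict = "filtered"
    elif p < alpha and omega_f > 1.0:
        verdict = "positive"
    elif p < alpha and omega_f < 1.0:
        verdict = "negative"
    else:
        verdict = "neutral"
    fg_key = frozenset().union(*foreground) if foreground else frozenset()
    return SelTestResult(
        gene=counts.gene,
        foreground=fg_key,
        omega_global=omega_g,
        omega_foreground=omega_f,
        omega_background=omega_b,
        lnl_neutral=lnl_neutral,
        lnl_global=lnl_global,
        lnl_two_ratio=lnl_two,
        lrt=lrt,
        p_value=p,
        verdict=verdict,
    )


def selection_scan(
    genomes: dict,
    genes: pd.DataFrame,
    tree,
    ir_intervals: list[tuple[int, int]] | None = None,
    alpha: float = 0.05,
    min_subs: float = 5.0,
) -> pd.DataFrame:
    """Scan every gene x internal clade; BH-corrected q-values across tests."""
    results = []
    clades = []
    for nd in tree.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        clades.append(frozenset(lf.taxon.label for lf in nd.leaf_iter()))
    for gene_id in genes["gene"].unique():
        try:
            aln = extract_codon_alignment(genomes, genes, gene_id, ir_intervals)
        except ValueError:
            continue
        leaf_labels = {nd.taxon.label for nd in tree.leaf_node_iter()}
        retained = leaf_labels & set(aln.sequences)
        if len(retained) < 3:
            continue
        if retained != leaf_labels:
            # rows dropped (e.g. internal stops): test on the induced subtree
            gene_tree = tree.extract_tree_with_taxa_labels(retained)
        else:
            gene_tree = tree
        cnt = count_substitutions(gene_tree, aln)
        branch_keys = set(cnt.per_branch)
        for clade in clades:
            fg = {b for b in branch_keys if b <= clade}
            if not fg:
                continue
            results.append(omega_lrt(cnt, fg, alpha=alpha, min_subs=min_subs))
    if not results:
        return pd.DataFrame()
    df = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "clade": "|".join(sorted(r.foreground)),
                "omega_fg": r.omega_foreground,
                "omega_bg": r.omega_background,
                "omega_global": r.omega_global,
                "lrt": r.lrt,
                "p": r.p_value,
                "verdict": r.verdict,
            }
            for r in results
        ]
    )
    tested = df["verdict"] != "filtered"
    pvals = df.loc[tested, "p"].to_numpy()
    if len(pvals):
        order = np.argsort(pvals)
        q = np.empty_like(pvals)
        m = len(pvals)
        prev = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            prev = min(prev, pvals[i] * m / (rank + 1))
            q[i] = prev
        df.loc[tested, "q"] = q
    return df
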