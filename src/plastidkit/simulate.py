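"""Synthetic chloroplast genome evolution and deep-pileup simulator.

The simulator emulates the structure of a plant chloroplast: a circular
genome of roughly 160 kb with two large inverted repeats (IRa/IRb) separating
the large and small single-copy regions, plus tracts with homology to the
nuclear genome.  Leaf genomes are evolved along a user-supplied timed tree
under a GTR substitution model with indels; hybridization events leave a small
fraction of a paternal donor's plastomes in a recipient (heteroplasmy), and
large deletions can be planted between short homologous flanking motifs.

Coordinates are reported linearly on ``[0, L)``; circularity is not crossed by
any simulated event.  Leaf genomes are kept in the reference coordinate frame
(substituted base array + deleted flags + anchored insertions), which is what
read mapping against the single reference would produce, so multi-sample
pileups are consistent by construction.

Every random stage draws from a stream derived from the master seed, so a
configuration is fully reproducible.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gtrmodel import BASES, GtrParams
from . import io as pkio

MISSING = None


def default_indel_length_probs() -> np.ndarray:
    """Length distribution over 1..36 bp.

    Calibrated so single-base events dominate, 2-5 bp events make up ~14%,
    ~90% of events are shorter than 13 bp, and longer events are sporadic.
    """
    p = np.zeros(36)
    p[0] = 0.55
    p[1:5] = 0.14 / 4
    p[5:12] = 0.21 / 7
    p[12:] = 0.10 / 24
    return p / p.sum()


@dataclass
class LargeDeletion:
    """A planted large deletion flanked by a short homologous motif.

    The motif is written at ``[start-len, start)`` and ``[end-len, end)`` of
    the reference so the deletion joins the two copies leaving one, mimicking
    a crossover between the homologous tracks.  ``residual`` is the fraction
    of plastomes in the carrier that still hold the reference allele
    (heteroplasmic deletion).
    """

    motif: str
    start: int
    end: int
    leaf: str
    residual: float = 0.0


@dataclass
class HybridEvent:
    recipient: str
    donor: str
    leakage: float

    def __post_init__(self) -> None:
        if not 0.0 < self.leakage < 0.5:
            raise ValueError("leakage must lie in (0, 0.5)")


@dataclass
class SimulationConfig:
    genome_length: int = 160_129
    ir_intervals: tuple[tuple[int, int], tuple[int, int]] = ((88_000, 114_000), (133_000, 160_000))
    homolog_tracts: list[tuple[int, int]] = field(default_factory=list)
    tree: str = ""
    subst_rate: float = 5e-4  # substitutions / site / My
    gtr: GtrParams = field(default_factory=GtrParams)
    indel_rate: float = 1e-4  # events / site / My
    indel_length_probs: np.ndarray = field(default_factory=default_indel_length_probs)
    insertion_fraction: float = 0.59
    large_deletions: list[LargeDeletion] = field(default_factory=list)
    hybrid_events: list[HybridEvent] = field(default_factory=list)
    coverage: float = 2000.0
    error_rate: float = 0.001
    seed: int = 0
    n_genes: int = 12
    gene_length: int = 300

    def __post_init__(self) -> None:
        L = self.genome_length
        for s, e in list(self.ir_intervals) + list(self.homolog_tracts):
            if not (0 <= s < e <= L):
                raise ValueError(f"interval [{s},{e}) out of genome bounds [0,{L})")
        (a0, a1), (b0, b1) = self.ir_intervals
        if not (a1 <= b0 or b1 <= a0):
            raise ValueError("inverted repeat intervals must be disjoint")
        if not 0.0 <= self.insertion_fraction <= 1.0:
            raise ValueError("insertion_fraction must be in [0,1]")

    def stream(self, name: str) -> np.random.Generator:
        """Named RNG stream derived from the master seed (stable across runs)."""
        tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence((self.seed, tag)))


@dataclass
class GenomeState:
    """A genome in the reference coordinate frame."""

    bases: np.ndarray  # int8, 0..3
    deleted: np.ndarray  # bool
    insertions: dict[int, str] = field(default_factory=dict)
    # large-deletion intervals carried by this genome, with residual fractions
    large_dels: list[tuple[int, int, float]] = field(default_factory=list)

    def copy(self) -> "GenomeState":
        return GenomeState(
            self.bases.copy(), self.deleted.copy(), dict(self.insertions), list(self.large_dels)
        )

    def sequence(self) -> str:
        """Realize the linear sequence (drop deleted bases, splice insertions)."""
        out = []
        for i in range(len(self.bases)):
            if not self.deleted[i]:
                out.append(BASES[self.bases[i]])
            ins = self.insertions.get(i)
            if ins:
                out.append(ins)
        return "".join(out)


@dataclass
class TruthSet:
    """Ground truth emitted alongside the synthetic data."""

    true_variants: dict[str, list[tuple]] = field(default_factory=dict)
    true_shp: dict[str, list[tuple]] = field(default_factory=dict)
    true_donor: dict[str, str] = field(default_factory=dict)
    true_sv: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    true_ages: dict[frozenset, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reference generation

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES if a + b + c not in _STOPS]


def generate_reference(cfg: SimulationConfig):
    """Build a reference sequence, gene model and region mask.

    Returns ``(sequence, genes, mask_intervals)``.  The mask is the union of
    the inverted repeats and the nuclear-homologous tracts.  Genes are placed
    in the single-copy region upstream of the first IR, alternating strands,
    each a single in-frame exon (ATG ... stop with no internal stop codons).
    """
    if cfg.genome_length < 10_000:
        raise ValueError("genome_length must be at least 10 kb")
    rng = cfg.stream("reference")
    seq = rng.choice(list(BASES), size=cfg.genome_length, p=cfg.gtr.pi)

    # IRb mirrors IRa (reverse complement) over the shorter of the two spans
    (a0, a1), (b0, b1) = cfg.ir_intervals
    span = min(a1 - a0, b1 - b0)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    ira = seq[a0 : a0 + span]
    seq[b0 : b0 + span] = [comp[b] for b in ira[::-1]]

    # plant large-deletion flanking motifs
    for ld in cfg.large_deletions:
        m = list(ld.motif)
        if ld.start - len(m) < 0 or ld.end > cfg.genome_length:
            raise ValueError("large deletion interval out of bounds")
        seq[ld.start - len(m) : ld.start] = m
        seq[ld.end - len(m) : ld.end] = m

    genes = _place_genes(seq, cfg, rng)
    mask = pkio.merge_intervals(list(cfg.ir_intervals) + list(cfg.homolog_tracts))
    return "".join(seq), genes, mask


def _place_genes(seq: list, cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    first_ir = min(s for s, _ in cfg.ir_intervals)
    forbidden = pkio.merge_intervals(
        list(cfg.homolog_tracts)
        + [(ld.start - len(ld.motif) - 5, ld.end + 5) for ld in cfg.large_deletions]
    )
    rows = []
    pos = 200
    gap = max(200, (first_ir - 400) // max(cfg.n_genes, 1) - cfg.gene_length)
    for g in range(cfg.n_genes):
        start = pos
        end = start + cfg.gene_length
        if end + 200 > first_ir:
            break
        if any(s < end and start < e for s, e in forbidden):
            pos = end + gap
            continue
        strand = "+" if g % 2 == 0 else "-"
        cds = "ATG" + "".join(rng.choice(_NONSTOP_CODONS, size=cfg.gene_length // 3 - 2)) + "TAA"
        if strand == "+":
            seq[start:end] = list(cds)
        else:
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            seq[start:end] = [comp[b] for b in cds[::-1]]
        rows.append({"gene": f"gene{g + 1:02d}", "strand": strand, "start": start, "end": end, "exon": 0})
        pos = end + gap
    return pd.DataFrame(rows, columns=pkio.GENE_COLUMNS)


# ---------------------------------------------------------------------------
# evolution along the tree


def node_ages(tree) -> dict:
    """Node ages (My before present): deepest leaf distance below each node.

    Equals edge-length ages on an ultrametric tree; on a slightly
    non-ultrametric one it degrades gracefully to the max-depth convention.
    """
    ages: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            ages[nd] = 0.0
        else:
            ages[nd] = max(ages[c] + (c.edge.length or 0.0) for c in nd.child_nodes())
    return ages


def evolve_genomes(tree, reference: str, cfg: SimulationConfig):
    """Evolve genomes down the tree; returns (leaf states, TruthSet).

    Substitution and indel event counts on a branch are Poisson with mean
    rate x active (non-IR, non-deleted) sites x branch duration.  Large
    deletions are applied on the terminal branch of their target leaf, only if
    the flanking motif is present on both sides (otherwise skipped with a
    warning).
    """
    rng = cfg.stream("evolve")
    L = cfg.genome_length
    ref_bases = np.fromiter((("ACGT").index(b) for b in reference), dtype=np.int8, count=L)
    ir_mask = pkio.interval_mask(cfg.ir_intervals, L)
    # planted large-deletion flank motifs are part of the study design and
    # must survive to the carrier leaf, so they are excluded from mutation
    motif_mask = pkio.interval_mask(
        [
            iv
            for ld in cfg.large_deletions
            for iv in ((ld.start - len(ld.motif), ld.start), (ld.end - len(ld.motif), ld.end))
        ],
        L,
    )
    mutable = np.flatnonzero(~ir_mask & ~motif_mask)

    q = cfg.gtr.rate_matrix()
    jump = q.copy()
    np.fill_diagonal(jump, 0.0)
    jump = jump / jump.sum(axis=1, keepdims=True)

    root = tree.seed_node
    states: dict = {root: GenomeState(ref_bases.copy(), np.zeros(L, dtype=bool))}
    ld_by_leaf: dict[str, list[LargeDeletion]] = {}
    for ld in cfg.large_deletions:
        ld_by_leaf.setdefault(ld.leaf, []).append(ld)

    truth = TruthSet()
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_state = states[node.parent_node]
        state = parent_state.copy()
        t = node.edge.length or 0.0
        if t > 0:
            active = mutable[~state.deleted[mutable]]
            n_sub = rng.poisson(cfg.subst_rate * len(active) * t)
            if n_sub:
                pos = rng.choice(active, size=n_sub, replace=False)
                for p in pos:
                    state.bases[p] = rng.choice(4, p=jump[state.bases[p]])
            n_indel = rng.poisson(cfg.indel_rate * len(active) * t)
            for _ in range(n_indel):
                length = int(rng.choice(36, p=cfg.indel_length_probs)) + 1
                p = int(rng.choice(active))
                if rng.random() < cfg.insertion_fraction:
                    ins = "".join(rng.choice(list(BASES), size=length))
                    state.insertions[p] = state.insertions.get(p, "") + ins
                else:
                    state.deleted[p : p + length] = True
        if node.is_leaf():
            leaf = node.taxon.label
            for ld in ld_by_leaf.get(leaf, ()):
                m = len(ld.motif)
                left = "".join(BASES[b] for b in state.bases[ld.start - m : ld.start])
                right = "".join(BASES[b] for b in state.bases[ld.end - m : ld.end])
                if left != ld.motif or right != ld.motif:
                    warnings.warn(
                        f"flank motif {ld.motif} absent at [{ld.start},{ld.end}) in {leaf}; "
                        "deletion skipped"
                    )
                    continue
                state.deleted[ld.start : ld.end] = True
                state.large_dels.append((ld.start, ld.end, ld.residual))
            states[leaf] = state
            truth.true_variants[leaf] = _diff_truth(ref_bases, reference, state)
            truth.true_sv[leaf] = [(s, e) for s, e, _ in state.large_dels]
        else:
            states[node] = state

    ages = node_ages(tree)
    for nd, age in ages.items():
        leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        truth.true_ages[leaves] = age
    return {k: v for k, v in states.items() if isinstance(k, str)}, truth


def _diff_truth(ref_bases: np.ndarray, reference: str, state: GenomeState) -> list[tuple]:
    out = []
    subs = np.flatnonzero((state.bases != ref_bases) & ~state.deleted)
    for p in subs:
        out.append((int(p), reference[p], BASES[state.bases[p]], "SNV"))
    large = pkio.interval_mask([(s, e) for s, e, _ in state.large_dels], len(ref_bases))
    small_del = state.deleted & ~large
    if small_del.any():
        idx = np.flatnonzero(small_del)
        run_start = idx[0]
        prev = idx[0]
        for p in list(idx[1:]) + [None]:
            if p is None or p != prev + 1:
                out.append((int(run_start), reference[run_start : prev + 1], "-", "indel"))
                run_start = p
            prev = p if p is not None else prev
    for p, ins in sorted(state.insertions.items()):
        out.append((int(p), "", ins, "indel"))
    return out


# ---------------------------------------------------------------------------
# hybridization and pileups


def apply_hybridization(recipient: GenomeState, donor: GenomeState, leakage: float) -> list[tuple]:
    """True single-heteroplasmic positions created by paternal leakage.

    At every position where the donor and recipient genomes differ (both
    present), the donor base becomes the minor allele at expected fraction
    ``leakage``.
    """
    if not 0.0 < leakage < 0.5:
        raise ValueError("leakage must lie in (0, 0.5): the donor allele must stay minor")
    both = ~recipient.deleted & ~donor.deleted
    diff = np.flatnonzero(both & (recipient.bases != donor.bases))
    return [(int(p), BASES[donor.bases[p]], leakage) for p in diff]


def simulate_pileup(
    state: GenomeState,
    sample: str,
    cfg: SimulationConfig,
    true_shp: Sequence[tuple] = (),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a deep pileup for one sample over the reference frame.

    Depth is Poisson(coverage) per position.  Each read reports the sample's
    allele, or the heteroplasmic minor allele with probability equal to the
    SHP fraction, and is mutated to a uniform different base with probability
    ``error_rate``.  Positions inside a carried large deletion collapse to
    Poisson(coverage x residual) depth of reference-allele reads; small
    deletions are reported as a deletion allele at full depth.
    """
    if cfg.coverage < 1:
        raise ValueError("coverage must be >= 1")
    if rng is None:
        rng = cfg.stream(f"pileup:{sample}")
    L = cfg.genome_length
    depth = rng.poisson(cfg.coverage, size=L)
    large = pkio.interval_mask([(s, e) for s, e, _ in state.large_dels], L)
    for s, e, residual in state.large_dels:
        depth[s:e] = rng.poisson(cfg.coverage * residual, size=e - s)

    counts = np.zeros((L, 5), dtype=np.int64)  # A C G T del
    shown = state.bases.copy()
    small_del = state.deleted & ~large
    # within large deletions the only mapped reads carry the reference allele
    # (state.bases already equals the pre-deletion base there)

    shp_pos = np.array([p for p, _, _ in true_shp], dtype=int)
    shp_minor = np.array([("ACGT").index(a) for _, a, _ in true_shp], dtype=np.int8)
    shp_frac = np.array([f for _, _, f in true_shp], dtype=float)

    minor_counts = np.zeros(L, dtype=np.int64)
    if len(shp_pos):
        minor_counts[shp_pos] = rng.binomial(depth[shp_pos], shp_frac)

    major_counts = depth - minor_counts
    # sequencing errors on base-reporting reads
    err_major = rng.binomial(major_counts, cfg.error_rate)
    correct_major = major_counts - err_major
    counts[np.arange(L), shown] += correct_major
    _scatter_errors(counts, shown, err_major, rng)
    if len(shp_pos):
        err_minor = rng.binomial(minor_counts[shp_pos], cfg.error_rate)
        ok_minor = minor_counts[shp_pos] - err_minor
        np.add.at(counts, (shp_pos, shp_minor), ok_minor)
        sub = np.zeros(L, dtype=np.int64)
        sub[shp_pos] = err_minor
        shown_minor = shown.copy()
        shown_minor[shp_pos] = shp_minor
        _scatter_errors(counts, shown_minor, sub, rng)

    # small deletions: all reads show the deletion allele instead of a base
    if small_del.any():
        idx = np.flatnonzero(small_del)
        counts[idx, :4] = 0
        counts[idx, 4] = depth[idx]

    ins_col = np.empty(L, dtype=object)
    ins_col[:] = ""
    for p, seq_ins in state.insertions.items():
        ins_col[p] = f"{seq_ins}:{depth[p]}"

    df = pd.DataFrame(
        {
            "sample": sample,
            "pos": np.arange(L),
            "A": counts[:, 0],
            "C": counts[:, 1],
            "G": counts[:, 2],
            "T": counts[:, 3],
            "del": counts[:, 4],
            "ins": ins_col,
            "depth": counts.sum(axis=1),
        }
    )
    return df


def _scatter_errors(counts, shown, n_err, rng) -> None:
    """Distribute per-position error reads uniformly over the 3 other bases."""
    total = int(n_err.sum())
    if total == 0:
        return
    pos = np.flatnonzero(n_err)
    for p in pos:
        others = [b for b in range(4) if b != shown[p]]
        alloc = rng.multinomial(n_err[p], [1 / 3] * 3)
        for b, k in zip(others, alloc):
            counts[p, b] += k


# ---------------------------------------------------------------------------
# whole-dataset driver


@dataclass
class SimulatedDataset:
    reference: str
    genes: pd.DataFrame
    mask: list[tuple[int, int]]
    tree: object
    genomes: dict[str, GenomeState]
    pileups: pd.DataFrame
    truth: TruthSet


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: reference, genomes, hybridization, pileups."""
    reference, genes, mask = generate_reference(cfg)
    tree = pkio.tree_from_string(cfg.tree)
    genomes, truth = evolve_genomes(tree, reference, cfg)
    shp_by_sample: dict[str, list[tuple]] = {leaf: [] for leaf in genomes}
    for ev in cfg.hybrid_events:
        shp = apply_hybridization(genomes[ev.recipient], genomes[ev.donor], ev.leakage)
        shp_by_sample[ev.recipient].extend(shp)
        truth.true_shp[ev.recipient] = shp
        truth.true_donor[ev.recipient] = ev.donor
    frames = [
        simulate_pileup(genomes[leaf], leaf, cfg, shp_by_sample[leaf]) for leaf in sorted(genomes)
    ]
    return SimulatedDataset(reference, genes, mask, tree, genomes, pd.concat(frames, ignore_index=True), truth)


def write_dataset(ds: SimulatedDataset, cfg: SimulationConfig, outdir: str | Path) -> None:
    """Write the dataset and its truth tables as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pkio.write_fasta({"reference": ds.reference}, outdir / "reference.fasta")
    pkio.write_fasta({k: v.sequence() for k, v in ds.genomes.items()}, outdir / "leaves.fasta")
    pkio.write_bed(ds.mask, outdir / "mask.bed", name="mask")
    pkio.write_gene_model(ds.genes, outdir / "genes.tsv")
    pkio.write_pileup(ds.pileups, outdir / "pileups.tsv")
    ds.tree.write(path=str(outdir / "true_tree.nwk"), schema="newick")
    rows = [
        {"sample": s, "pos": p, "ref": r, "alt": a, "type": t}
        for s, vs in ds.truth.true_variants.items()
        for p, r, a, t in vs
    ]
    pd.DataFrame(rows, columns=["sample", "pos", "ref", "alt", "type"]).to_csv(
        outdir / "truth_variants.tsv", sep="\t", index=False
    )
    rows = [
        {"sample": s, "pos": p, "minor": m, "fraction": f}
        for s, shps in ds.truth.true_shp.items()
        for p, m, f in shps
    ]
    pd.DataFrame(rows, columns=["sample", "pos", "minor", "fraction"]).to_csv(
        outdir / "truth_shp.tsv", sep="\t", index=False
    )
    rows = [
        {"sample": s, "start": a, "end": b}
        for s, svs in ds.truth.true_sv.items()
        for a, b in svs
    ]
    pd.DataFrame(rows, columns=["sample", "start", "end"]).to_csv(
        outdir / "truth_sv.tsv", sep="\t", index=False
    )
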