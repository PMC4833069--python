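"""Masked multi-sample haploid variant matrix from deep allele-count tables.

The chloroplast is haploid, so a sample's genotype at a position is simply the
majority allele — but only when that allele is supported by at least 90% of
the covering reads; anything less is imputed as MISSING (the deep-coverage
analogue of a low-confidence call).  Positions inside regions homologous to
the nuclear genome, or inside the inverted repeats, are masked out before the
matrix is built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as pkio

MISSING = None
NO_COVERAGE = "no_coverage"
DEL = "-"

_BASE_COLS = ["A", "C", "G", "T", "del"]
_ALLELE_OF_COL = {"A": "A", "C": "C", "G": "G", "T": "T", "del": DEL}


@dataclass
class ThresholdConfig:
    """Calling and masking thresholds.

    ``mapq_min`` is metadata only: reads are assumed pre-filtered upstream and
    the value is recorded for provenance, never acted on.
    """

    genotype_support_min: float = 0.90
    review_support_max: float = 0.95  # calls in [support_min, review_max) get a review flag
    homolog_evalue_max: float = 1e-4
    homolog_len_min: int = 101
    homolog_identity_min: float = 0.90
    mapq_min: int = 29

    def __post_init__(self) -> None:
        if not 0.0 < self.genotype_support_min <= 1.0:
            raise ValueError("genotype_support_min must be in (0,1]")


@dataclass
class Call:
    allele: str | None
    flag: str | None = None  # None, "review", "no_coverage"


def call_genotype(counts: dict, thresholds: ThresholdConfig | None = None) -> Call:
    """Haploid majority call with the 90%-support rule.

    ``counts`` maps alleles (bases, ``-`` for deletion, ``I:<seq>`` for
    insertions) to read counts.  Returns the majority allele iff its support
    fraction is >= ``genotype_support_min`` (inclusive); MISSING otherwise.
    Zero depth yields MISSING with a distinct no-coverage flag.
    """
    thresholds = thresholds or ThresholdConfig()
    depth = sum(counts.values())
    if depth == 0:
        return Call(MISSING, NO_COVERAGE)
    allele, best = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    support = best / depth
    if support >= thresholds.genotype_support_min:
        flag = "review" if support < thresholds.review_support_max else None
        return Call(allele, flag)
    return Call(MISSING)


@dataclass
class VariantMatrix:
    """Positions x samples called-allele matrix with per-position metadata."""

    positions: list[int]
    samples: list[str]
    calls: pd.DataFrame  # index positions, columns samples; values allele str or None
    meta: pd.DataFrame  # index positions; columns ref, type, n_alleles, masked
    reference_discrepancies: pd.DataFrame = field(default_factory=pd.DataFrame)

    def records(self):
        for pos in self.positions:
            row = self.meta.loc[pos]
            calls = {s: self.calls.at[pos, s] for s in self.samples}
            alts = sorted({c for c in calls.values() if c is not None and c != row["ref"]})
            yield {
                "pos": pos,
                "ref": row["ref"],
                "type": row["type"],
                "n_alleles": row["n_alleles"],
                "calls": calls,
                "alts": alts,
            }

    def snv_positions(self) -> list[int]:
        return [p for p in self.positions if self.meta.at[p, "type"] == "SNV"]


def _calls_from_pileup(pileup: pd.DataFrame, thresholds: ThresholdConfig) -> pd.DataFrame:
    """Vectorized per-sample haploid calls; returns long frame (sample,pos,call)."""
    df = pileup
    counts = df[_BASE_COLS].to_numpy()
    depth = counts.sum(axis=1)
    best_idx = counts.argmax(axis=1)
    best = counts[np.arange(len(df)), best_idx]
    support = np.divide(best, depth, out=np.zeros(len(df)), where=depth > 0)
    call = np.array([_ALLELE_OF_COL[_BASE_COLS[i]] for i in best_idx], dtype=object)
    call[support < thresholds.genotype_support_min] = None
    call[depth == 0] = None

    # insertion alleles: all supporting reads listed as seq:count
    has_ins = df["ins"].astype(str) != ""
    ins_call = np.full(len(df), None, dtype=object)
    for i in np.flatnonzero(has_ins.to_numpy()):
        seq, _, cnt = df["ins"].iloc[i].partition(":")
        if depth[i] > 0 and int(cnt) / depth[i] >= thresholds.genotype_support_min:
            ins_call[i] = f"I:{seq}"
    out = pd.DataFrame(
        {"sample": df["sample"].to_numpy(), "pos": df["pos"].to_numpy(), "call": call, "ins_call": ins_call}
    )
    return out


def build_variant_matrix(
    pileups: pd.DataFrame,
    reference: str,
    mask: list[tuple[int, int]],
    thresholds: ThresholdConfig | None = None,
) -> VariantMatrix:
    """Build the masked multi-sample variant matrix.

    A position enters the matrix iff it is outside the mask and at least one
    sample's call differs from the reference allele.  Positions where every
    sample disagrees with the reference in the same way are reported
    separately as reference discrepancies (likely reference errors) and also
    kept in the matrix.
    """
    thresholds = thresholds or ThresholdConfig()
    L = len(reference)
    samples = sorted(pileups["sample"].unique())
    pmin, pmax = pileups["pos"].min(), pileups["pos"].max()
    if pmin < 0 or pmax >= L:
        raise ValueError("pileup positions outside the reference coordinate frame")
    calls_long = _calls_from_pileup(pileups, thresholds)
    wide = calls_long.pivot(index="pos", columns="sample", values="call")
    ins_wide = calls_long.pivot(index="pos", columns="sample", values="ins_call")
    masked = pkio.interval_mask(mask, L)

    ref_arr = np.array(list(reference), dtype=object)
    positions: list[int] = []
    meta_rows = []
    call_rows = {}
    disc_rows = []
    arr = wide.to_numpy()
    ins_arr = ins_wide.to_numpy() if ins_wide.size else None
    pos_index = wide.index.to_numpy()
    # vectorized prefilter: only positions with a non-reference call or an insertion
    ref_col = ref_arr[pos_index]
    not_none = arr != None  # noqa: E711  (elementwise on object array)
    candidate = ((arr != ref_col[:, None]) & not_none).any(axis=1)
    if ins_arr is not None:
        candidate |= (ins_arr != None).any(axis=1)  # noqa: E711
    candidate_idx = np.flatnonzero(candidate)
    for i in candidate_idx:
        pos = pos_index[i]
        ref = ref_arr[pos]
        row = arr[i]
        ins_row = ins_arr[i] if ins_arr is not None else [None] * len(samples)
        non_missing = [c for c in row if c is not None]
        variant_base = any(c != ref for c in non_missing)
        has_ins = any(c is not None for c in ins_row)
        if masked[pos] or (not variant_base and not has_ins):
            continue
        if variant_base:
            alleles = sorted(set(non_missing) | {ref})
            typ = "SNV" if all(a in "ACGT" for a in alleles) else "indel"
            positions.append(int(pos))
            meta_rows.append(
                {"pos": int(pos), "ref": ref, "type": typ, "n_alleles": len(alleles), "masked": False}
            )
            call_rows[int(pos)] = dict(zip(samples, row))
            if non_missing and len(non_missing) == len(samples) and len(set(non_missing)) == 1 and non_missing[0] != ref:
                disc_rows.append({"pos": int(pos), "ref": ref, "observed": non_missing[0]})
        if has_ins:
            ins_alleles = sorted({c for c in ins_row if c is not None})
            if not variant_base:
                positions.append(int(pos))
                meta_rows.append(
                    {
                        "pos": int(pos),
                        "ref": ref,
                        "type": "indel",
                        "n_alleles": len(ins_alleles) + 1,
                        "masked": False,
                    }
                )
                call_rows[int(pos)] = {
                    s: (ic if ic is not None else (ref if c is not None else None))
                    for s, c, ic in zip(samples, row, ins_row)
                }
    meta = pd.DataFrame(meta_rows).set_index("pos") if meta_rows else pd.DataFrame(
        columns=["ref", "type", "n_alleles", "masked"]
    )
    calls = pd.DataFrame.from_dict(call_rows, orient="index")
    if not calls.empty:
        calls = calls.reindex(columns=samples).sort_index()
    positions = sorted(positions)
    return VariantMatrix(
        positions=positions,
        samples=samples,
        calls=calls,
        meta=meta,
        reference_discrepancies=pd.DataFrame(disc_rows, columns=["pos", "ref", "observed"]),
    )


# ---------------------------------------------------------------------------
# nuclear-homologous region detection (seed-and-extend, ungapped)

# Karlin-Altschul constants for +1/-2 match/mismatch scoring (ungapped).
_KA_LAMBDA = 1.33
_KA_K = 0.621
_SEED_K = 12


def find_homologous_regions(
    chloroplast: str,
    decoys: dict[str, str] | list[str],
    thresholds: ThresholdConfig | None = None,
) -> list[tuple[int, int]]:
    """Chloroplast intervals with local ungapped homology to decoy sequences.

    Exact 12-mer seeds are extended in both directions without gaps under a
    +1 match / -2 mismatch score with an X-drop of 20.  A segment is reported
    when its length exceeds ``homolog_len_min - 1``, identity exceeds
    ``homolog_identity_min`` and its Karlin-Altschul e-value
    ``K * m * n * exp(-lambda * S)`` is below ``homolog_evalue_max``.
    Overlapping intervals are merged.
    """
    thresholds = thresholds or ThresholdConfig()
    if isinstance(decoys, dict):
        decoy_seqs = list(decoys.values())
    else:
        decoy_seqs = list(decoys)
    if not chloroplast or not decoy_seqs:
        raise ValueError("sequences must be non-empty")
    m = len(chloroplast)
    hits: list[tuple[int, int]] = []
    for decoy in decoy_seqs:
        n = len(decoy)
        seeds: dict[str, list[int]] = {}
        for j in range(n - _SEED_K + 1):
            seeds.setdefault(decoy[j : j + _SEED_K], []).append(j)
        seen: set[tuple[int, int]] = set()
        for i in range(m - _SEED_K + 1):
            for j in seeds.get(chloroplast[i : i + _SEED_K], ()):
                s0, e0, score, ident = _extend(chloroplast, decoy, i, j, _SEED_K)
                length = e0 - s0
                key = (s0, i - j)  # one extension per (segment start, diagonal)
                if key in seen:
                    continue
                seen.add(key)
                if (
                    length >= thresholds.homolog_len_min
                    and ident >= thresholds.homolog_identity_min
                    and _KA_K * m * n * math.exp(-_KA_LAMBDA * score) < thresholds.homolog_evalue_max
                ):
                    hits.append((s0, e0))
    return pkio.merge_intervals(hits)


def _extend(a: str, b: str, i: int, j: int, k: int, xdrop: int = 20):
    """Ungapped X-drop extension of a seed; returns (start, end, score, identity) on ``a``."""
    score = k
    best = score
    # right
    ai, bj = i + k, j + k
    best_right = 0
    cur = score
    step = 0
    while ai + step < len(a) and bj + step < len(b):
        cur += 1 if a[ai + step] == b[bj + step] else -2
        step += 1
        if cur > best:
            best = cur
            best_right = step
        if best - cur > xdrop:
            break
    # left
    best_left = 0
    cur = best
    step = 0
    while i - step - 1 >= 0 and j - step - 1 >= 0:
        cur += 1 if a[i - step - 1] == b[j - step - 1] else -2
        step += 1
        if cur > best:
            best = cur
            best_left = step
        if best - cur > xdrop:
            break
    s0, e0 = i - best_left, i + k + best_right
    matches = sum(1 for x, y in zip(a[s0:e0], b[j - best_left : j - best_left + (e0 - s0)]) if x == y)
    identity = matches / (e0 - s0)
    return s0, e0, best, identity


# ---------------------------------------------------------------------------
# annotation and density


def classify_variants(matrix: VariantMatrix, genes: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Annotate each matrix row against the gene model.

    Region is exon / intron / intergenic.  Exonic indels are frameshift iff
    the net length change is not a multiple of 3; insertions identical to the
    adjacent reference tract are flagged as duplications.
    """
    L = len(reference)
    exon_of = {}
    gene_intervals: dict[str, tuple[int, int, str]] = {}
    for _, g in genes.iterrows():
        gene_intervals.setdefault(g["gene"], (g["start"], g["end"], g["strand"]))
        s, e, strand = gene_intervals[g["gene"]]
        gene_intervals[g["gene"]] = (min(s, g["start"]), max(e, g["end"]), strand)
        for p in range(g["start"], g["end"]):
            exon_of[p] = g["gene"]
    rows = []
    for rec in matrix.records():
        pos = rec["pos"]
        if not 0 <= pos < L:
            raise ValueError(f"variant position {pos} outside reference bounds")
        region, gene = "intergenic", ""
        if pos in exon_of:
            region, gene = "exon", exon_of[pos]
        else:
            for gname, (s, e, _) in gene_intervals.items():
                if s <= pos < e:
                    region, gene = "intron", gname
                    break
        effect = ""
        if rec["type"] == "indel" and region == "exon":
            net = 0
            dup = False
            for alt in rec["alts"]:
                if alt == DEL:
                    net = -1  # per-position deletion allele: one base removed
                elif alt.startswith("I:"):
                    ins = alt[2:]
                    net = len(ins)
                    right = reference[pos + 1 : pos + 1 + len(ins)]
                    left = reference[max(pos + 1 - len(ins), 0) : pos + 1]
                    dup = ins == right or ins == left
            effect = "frameshift" if net % 3 != 0 else ("duplication" if dup else "in-frame")
        rows.append(
            {
                "pos": pos,
                "type": rec["type"],
                "region": region,
                "gene": gene,
                "effect": effect,
                "n_alleles": rec["n_alleles"],
            }
        )
    return pd.DataFrame(rows, columns=["pos", "type", "region", "gene", "effect", "n_alleles"])


def variant_density(
    positions: list[int],
    windows: list[tuple[int, int]],
    mask: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-window variant counts and densities per unmasked kb."""
    mask = mask or []
    for s, e in windows:
        if e <= s:
            raise ValueError(f"zero-length window [{s},{e})")
    sorted_w = sorted(windows)
    for (s1, e1), (s2, e2) in zip(sorted_w, sorted_w[1:]):
        if s2 < e1:
            raise ValueError("windows must be non-overlapping")
    pos_arr = np.asarray(sorted(positions))
    rows = []
    for s, e in windows:
        count = int(((pos_arr >= s) & (pos_arr < e)).sum()) if len(pos_arr) else 0
        masked_bp = sum(max(0, min(e, me) - max(s, ms)) for ms, me in mask)
        eff = (e - s) - masked_bp
        density = count / (eff / 1000.0) if eff > 0 else float("nan")
        rows.append({"start": s, "end": e, "count": count, "effective_bp": eff, "per_kb": density})
    return pd.DataFrame(rows)


def summarize_variants(matrix: VariantMatrix, annotations: pd.DataFrame) -> dict:
    """Overall accounting: totals by type and intergenic fractions.

    Percentages are integer-rounded, matching how such tallies are usually
    reported (e.g. "296 of 323 indels intergenic -> 92%").
    """
    n_snv = int((annotations["type"] == "SNV").sum())
    n_indel = int((annotations["type"] == "indel").sum())
    indels = annotations[annotations["type"] == "indel"]
    n_indel_intergenic = int((indels["region"] == "intergenic").sum())
    out = {
        "n_snv": n_snv,
        "n_indel": n_indel,
        "n_nonredundant": n_snv + n_indel,
        "n_indel_intergenic": n_indel_intergenic,
        "pct_indel_intergenic": round(100 * n_indel_intergenic / n_indel) if n_indel else float("nan"),
        "n_triallelic": int((annotations["n_alleles"] >= 3).sum()),
    }
    return out
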