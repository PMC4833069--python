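"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinates are 0-based half-open everywhere internally; the VCF-like writer
converts to 1-based on output.  Pileup tables are TSV with one row per
(sample, position): base counts, a deletion-allele count, observed insertion
alleles as ``seq:count`` pairs, and total depth.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PILEUP_COLUMNS = ["sample", "pos", "A", "C", "G", "T", "del", "ins", "depth"]

GENE_COLUMNS = ["gene", "strand", "start", "end", "exon"]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_pileup(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "ins": str})
    df["ins"] = df["ins"].fillna("")
    return df


def write_pileup(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=PILEUP_COLUMNS)


def read_bed(path: str | Path) -> list[tuple[int, int]]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            intervals.append((int(parts[1]), int(parts[2])))
    return intervals


def write_bed(intervals: Iterable[tuple[int, int]], path: str | Path, name: str = "region") -> None:
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(intervals):
            fh.write(f"chloroplast\t{s}\t{e}\t{name}{i}\n")


def read_gene_model(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene model missing columns: {sorted(missing)}")
    return df


def write_gene_model(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False, columns=GENE_COLUMNS)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and merged."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def interval_mask(intervals: Iterable[tuple[int, int]], length: int):
    import numpy as np

    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(s, 0) : min(e, length)] = True
    return mask


def write_vcf_like(matrix, reference: str, path: str | Path) -> None:
    """Write a haploid VCF-like file (1-based positions, anchor-free SNVs)."""
    samples = matrix.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2-like\n")
        fh.write("##source=plastidkit\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for row in matrix.records():
            pos0 = row["pos"]
            ref_allele = row["ref"]
            alts = row["alts"]
            alt_field = ",".join(alts) if alts else "."
            gts = []
            for s in samples:
                call = row["calls"][s]
                if call is None:
                    gts.append(".")
                elif call == ref_allele:
                    gts.append("0")
                else:
                    gts.append(str(alts.index(call) + 1))
            info = f"TYPE={row['type']};NALLELES={row['n_alleles']}"
            fh.write(
                f"chloroplast\t{pos0 + 1}\t.\t{ref_allele}\t{alt_field}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def pileup_from_frames(frames: Iterable[pd.DataFrame]) -> pd.DataFrame:
    return pd.concat(list(frames), ignore_index=True)


def read_newick(path_or_text: str | Path):
    import dendropy

    text = str(path_or_text)
    if "(" in text and ";" in text:
        src = {"data": text, "schema": "newick"}
    else:
        src = {"path": str(path_or_text), "schema": "newick"}
    return dendropy.Tree.get(**src, preserve_underscores=True)


def tree_from_string(newick: str):
    import dendropy

    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
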