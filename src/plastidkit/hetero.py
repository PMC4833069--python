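"""Single heteroplasmic positions (SHPs) and biparental-inheritance testing.

A position is heteroplasmic in a sample when the minor allele is supported by
at least 5 reads out of a minimum depth of 1,000.  SHPs are only searched at
the nonredundant SNV positions of the multi-sample variant matrix, which
controls for sequencing error: a genuine paternal-leakage allele must match a
base segregating in the collection.

The paternity (compatibility) test asks, for each candidate paternal parent,
at how many of a hybrid's SHPs the candidate's called allele equals the
hybrid's minor allele.  Known hybrids are never used as candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_MINOR_READS = 5
MIN_DEPTH = 1000

_BASES = ["A", "C", "G", "T"]


@dataclass
class ShpRecord:
    sample: str
    pos: int
    major: str
    minor: str
    minor_count: int
    depth: int
    ambiguous: bool = False

    @property
    def minor_fraction(self) -> float:
        return self.minor_count / self.depth


@dataclass
class ClusterSpec:
    """A clade of samples over which heteroplasmy sharing is computed.

    ``min_sharing`` (k) is the number of members a position must be
    heteroplasmic in to count as shared; by default all members.
    """

    name: str
    members: list[str]
    min_sharing: int | None = None

    def __post_init__(self) -> None:
        k = self.min_sharing if self.min_sharing is not None else len(self.members)
        if not 2 <= k <= len(self.members):
            raise ValueError("min_sharing must satisfy 2 <= k <= member count")
        self.min_sharing = k


@dataclass
class PaternityResult:
    hybrid: str
    candidate: str
    n_compatible: int
    n_incompatible: int

    @property
    def ratio(self) -> float:
        total = self.n_compatible + self.n_incompatible
        return self.n_compatible / total if total else float("nan")

    @property
    def reported(self) -> bool:
        return self.n_compatible > 70


def call_shp(
    pileup: pd.DataFrame,
    snv_positions: list[int],
    min_minor: int = MIN_MINOR_READS,
    min_depth: int = MIN_DEPTH,
) -> list[ShpRecord]:
    """Call SHPs for every sample in ``pileup`` at the candidate SNV positions.

    The minor allele must be a single consistent base; when two bases tie with
    >= ``min_minor`` reads the position is emitted once per allele, flagged
    ambiguous.  Ties within the rule are broken toward the highest count, then
    alphabetically.
    """
    cand = pileup[pileup["pos"].isin(set(snv_positions))]
    records: list[ShpRecord] = []
    counts = cand[_BASES].to_numpy()
    depth = counts.sum(axis=1)
    order = np.argsort(-counts, axis=1, kind="stable")
    samples = cand["sample"].to_numpy()
    positions = cand["pos"].to_numpy()
    for i in range(len(cand)):
        if depth[i] < min_depth:
            continue
        top = order[i, 0]
        second = order[i, 1]
        c_top, c_second = counts[i, top], counts[i, second]
        if c_second < min_minor:
            continue
        major = _BASES[top]
        # any other bases tied with the runner-up?
        tied = [j for j in order[i, 1:] if counts[i, j] == c_second]
        ambiguous = len(tied) > 1
        for j in sorted(tied, key=lambda j: _BASES[j]):
            records.append(
                ShpRecord(
                    sample=str(samples[i]),
                    pos=int(positions[i]),
                    major=major,
                    minor=_BASES[j],
                    minor_count=int(counts[i, j]),
                    depth=int(depth[i]),
                    ambiguous=ambiguous,
                )
            )
            if not ambiguous:
                break
    return records


def shp_sets(records: list[ShpRecord]) -> dict[str, set[int]]:
    out: dict[str, set[int]] = {}
    for r in records:
        out.setdefault(r.sample, set()).add(r.pos)
    return out


def sharing_stats(sets_by_sample: dict[str, set[int]], cluster: ClusterSpec) -> dict:
    """Cluster-level sharing: total, shared count and integer percentage.

    ``total`` is the mean per-sample SHP count for clusters of four or more
    members, and the minimum per-sample count otherwise.  ``shared`` counts
    positions heteroplasmic in at least ``min_sharing`` members.
    """
    members = cluster.members
    missing = [m for m in members if m not in sets_by_sample]
    if missing:
        raise KeyError(f"no SHP set for cluster members: {missing}")
    per_sample = [len(sets_by_sample[m]) for m in members]
    if len(members) >= 4:
        total = float(np.mean(per_sample))
    else:
        total = float(min(per_sample))
    from collections import Counter

    tally = Counter(p for m in members for p in sets_by_sample[m])
    shared = sum(1 for _, c in tally.items() if c >= cluster.min_sharing)
    pct = round(100 * shared / total) if total > 0 else None
    return {"cluster": cluster.name, "total": total, "shared": shared, "percentage": pct}


def paternity_test(
    hybrid: str,
    hybrid_shps: list[ShpRecord],
    candidate_calls: pd.DataFrame,
    known_hybrids: set[str] | None = None,
) -> list[PaternityResult]:
    """Rank candidate paternal parents by SHP compatibility ratio.

    ``candidate_calls`` is a positions x samples frame of haploid calls (None
    for MISSING).  For each candidate, compatible = SHPs where the candidate's
    call equals the hybrid's minor allele; incompatible = SHPs with a
    different non-missing call.  MISSING positions are excluded from both
    counts.  Known hybrids and the hybrid itself are excluded from the pool.
    An ambiguous SHP (tied minors) is compatible if either allele matches.
    """
    known_hybrids = set(known_hybrids or ())
    if not hybrid_shps:
        return []
    minors_by_pos: dict[int, set[str]] = {}
    for r in hybrid_shps:
        minors_by_pos.setdefault(r.pos, set()).add(r.minor)
    candidates = [c for c in candidate_calls.columns if c != hybrid and c not in known_hybrids]
    results = []
    for cand in candidates:
        comp = incomp = 0
        for pos, minors in minors_by_pos.items():
            if pos not in candidate_calls.index:
                continue
            call = candidate_calls.at[pos, cand]
            if call is None or (isinstance(call, float) and np.isnan(call)):
                continue
            if call in minors:
                comp += 1
            else:
                incomp += 1
        results.append(PaternityResult(hybrid, cand, comp, incomp))
    results.sort(key=lambda r: (-(r.ratio if r.ratio == r.ratio else -1), r.candidate))
    return results


def paternity_table(results: list[PaternityResult]) -> pd.DataFrame:
    """Table-style output with ratios rounded to 2 decimal places."""
    return pd.DataFrame(
        [
            {
                "hybrid": r.hybrid,
                "candidate": r.candidate,
                "compatible": r.n_compatible,
                "incompatible": r.n_incompatible,
                "ratio": round(r.ratio, 2) if r.ratio == r.ratio else float("nan"),
                "reported": r.reported,
            }
            for r in results
        ]
    )


def ancestral_origin_map(tree, presence: dict[int, set[str]]) -> dict[frozenset, int]:
    """Assign each SHP position to its origin node (MRCA of carriers).

    A single hybridization event introduces heteroplasmy once, so a Dollo-like
    single-origin assignment at the most recent common ancestor of the
    carrying leaves is used.  Returns event counts keyed by the origin node's
    descendant leaf set.
    """
    tree.is_rooted = True
    taxa = {t.label: t for t in tree.taxon_namespace}
    counts: dict[frozenset, int] = {}
    for pos, samples in presence.items():
        missing = samples - taxa.keys()
        if missing:
            raise KeyError(f"samples not in tree: {sorted(missing)}")
        if len(samples) == 1:
            key = frozenset(samples)
        else:
            mrca = tree.mrca(taxa=[taxa[s] for s in samples])
            key = frozenset(lf.taxon.label for lf in mrca.leaf_iter())
        counts[key] = counts.get(key, 0) + 1
    return counts
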