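"""Coverage-based deletion calling and breakpoint microhomology.

Large deletions leave a sharp drop in mapped-read depth; heteroplasmic
deletions (a minority of plastomes still carrying the reference allele) leave
a residual depth floor instead of zero.  Calls are maximal runs of positions
whose depth falls below ``drop_ratio`` times the flanking median; the
residual reference fraction is the interior median over the flanking median.
Breakpoints under flanking homology are ambiguous by up to the homology
length and are reported left-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MIN_SV_LEN = 50
DEFAULT_DROP_RATIO = 0.2
HETEROPLASMIC_RESIDUAL = 0.005


@dataclass
class Microhomology:
    seq: str
    unit: str = ""
    left_run: int = 0
    right_run: int = 0

    @property
    def is_homopolymer(self) -> bool:
        return bool(self.unit)


@dataclass
class SvCall:
    sample: str
    start: int
    end: int
    interior_depth: float
    flank_depth: float
    residual_fraction: float
    heteroplasmic: bool
    microhomology: Microhomology | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def left_align(reference: str, start: int, end: int) -> tuple[int, int]:
    """Leftmost equivalent representation of deleting ``[start, end)``."""
    while start > 0 and reference[start - 1] == reference[end - 1]:
        start -= 1
        end -= 1
    return start, end


def detect_deletions(
    pileup: pd.DataFrame,
    sample: str | None = None,
    min_sv_len: int = DEFAULT_MIN_SV_LEN,
    drop_ratio: float = DEFAULT_DROP_RATIO,
    reference: str | None = None,
    flank_bp: int = 300,
) -> list[SvCall]:
    """Call large deletions from one sample's coverage profile.

    ``pileup`` may hold several samples; pass ``sample`` to select one.
    Runs never touch the profile boundary; if a reference sequence is given,
    breakpoints are left-aligned.
    """
    df = pileup if sample is None else pileup[pileup["sample"] == sample]
    if sample is None:
        uniq = df["sample"].unique()
        if len(uniq) != 1:
            raise ValueError("pileup holds multiple samples; pass sample=")
        sample = str(uniq[0])
    df = df.sort_values("pos")
    depth = df["depth"].to_numpy(dtype=float)
    pos = df["pos"].to_numpy()
    L = len(depth)
    if L < 2 * min_sv_len:
        raise ValueError("coverage profile shorter than twice min_sv_len")
    baseline = float(np.median(depth))
    low = depth < drop_ratio * baseline
    calls: list[SvCall] = []
    i = 0
    while i < L:
        if not low[i]:
            i += 1
            continue
        j = i
        while j < L and low[j]:
            j += 1
        run_len = j - i
        if run_len >= min_sv_len and i > 0 and j < L:
            flank = np.concatenate(
                [depth[max(i - flank_bp, 0) : i], depth[j : min(j + flank_bp, L)]]
            )
            flank_med = float(np.median(flank))
            interior_med = float(np.median(depth[i:j]))
            if flank_med > 0 and interior_med < flank_med:
                start, end = int(pos[i]), int(pos[j - 1]) + 1
                if reference is not None:
                    start, end = left_align(reference, start, end)
                residual = interior_med / flank_med
                calls.append(
                    SvCall(
                        sample=sample,
                        start=start,
                        end=end,
                        interior_depth=interior_med,
                        flank_depth=flank_med,
                        residual_fraction=residual,
                        heteroplasmic=residual >= HETEROPLASMIC_RESIDUAL,
                    )
                )
        i = j
    return calls


def annotate_breakpoint_homology(
    reference: str, call: SvCall, max_probe: int = 25
) -> Microhomology:
    """Longest homologous context shared by the two breakpoints.

    Looks for the longest string (up to ``max_probe``) that both ends at the
    left breakpoint and ends at the right breakpoint (equivalently, flanks
    both junction sides), in either orientation of the junction.  Homopolymer
    homology additionally reports the unit and the run lengths on each side.
    """
    s, e = call.start, call.end
    if not (0 <= s < e <= len(reference)):
        raise ValueError("call interval outside reference")
    best = ""
    for m in range(1, max_probe + 1):
        if s - m >= 0 and reference[s - m : s] == reference[e - m : e]:
            best = reference[s - m : s]
    if not best:
        for m in range(1, max_probe + 1):
            if e + m <= len(reference) and reference[s : s + m] == reference[e : e + m]:
                best = reference[s : s + m]
    mh = Microhomology(seq=best)
    # homopolymer annotation: both breakpoints border a run (>= 4) of the same
    # base, as in poly(dA)-flanked deletions; runs may end at the breakpoints
    # (right-aligned representation) or start at them (left-aligned)
    def run_ending_at(pos: int, base: str) -> int:
        n = 0
        while pos - n - 1 >= 0 and reference[pos - n - 1] == base:
            n += 1
        return n

    def run_starting_at(pos: int, base: str) -> int:
        n = 0
        while pos + n < len(reference) and reference[pos + n] == base:
            n += 1
        return n

    candidates = []
    if s > 0 and reference[s - 1] == reference[e - 1]:
        b = reference[s - 1]
        candidates.append((b, run_ending_at(s, b), run_ending_at(e, b)))
    if e < len(reference) and reference[s] == reference[e]:
        b = reference[s]
        candidates.append((b, run_starting_at(s, b), run_starting_at(e, b)))
    if candidates:
        b, run_l, run_r = max(candidates, key=lambda c: min(c[1], c[2]))
        if min(run_l, run_r) >= 4:
            mh.unit = b
            mh.left_run = run_l
            mh.right_run = run_r
    call.microhomology = mh
    return mh


@dataclass
class SvEvent:
    start: int
    end: int
    carriers: frozenset
    origin: frozenset  # leaf set of the origin node


def assign_origins(calls: list[SvCall], tree) -> list[SvEvent]:
    """Group calls by exact breakpoints; each group is one event at the MRCA.

    Overlapping deletions with distinct breakpoints remain separate events
    (independent origins).
    """
    tree.is_rooted = True
    taxa = {t.label: t for t in tree.taxon_namespace}
    groups: dict[tuple[int, int], set[str]] = {}
    for c in calls:
        if c.sample not in taxa:
            raise KeyError(f"sample {c.sample} not in tree")
        groups.setdefault((c.start, c.end), set()).add(c.sample)
    events = []
    for (s, e), carriers in sorted(groups.items()):
        if len(carriers) == 1:
            origin = frozenset(carriers)
        else:
            mrca = tree.mrca(taxa=[taxa[x] for x in carriers])
            origin = frozenset(lf.taxon.label for lf in mrca.leaf_iter())
        events.append(SvEvent(start=s, end=e, carriers=frozenset(carriers), origin=origin))
    return events


def consensus_filter(
    primary: list[SvCall], external: list[tuple[int, int]], min_reciprocal_overlap: float = 0.9
) -> list[SvCall]:
    """Keep primary calls confirmed by an external call set.

    Confirmation requires reciprocal overlap of at least
    ``min_reciprocal_overlap`` with some external interval (a hook for
    consensus with independently produced call sets).
    """
    kept = []
    for c in primary:
        for s, e in external:
            ov = max(0, min(c.end, e) - max(c.start, s))
            if ov / c.length >= min_reciprocal_overlap and ov / max(e - s, 1) >= min_reciprocal_overlap:
                kept.append(c)
                break
    return kept
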