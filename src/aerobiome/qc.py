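"""Initial read processing: replicate removal and masking filters.

Three per-sample filters, applied in order: (1) artificial-replicate removal
— near-identical reads sharing a start, a pyrosequencing artifact; (2) a
low-complexity filter dropping reads more than half covered by
low-complexity sequence; (3) a repeat filter dropping reads more than half
covered by known repeat-family matches (masks consumed from a BED file or
from the built-in library screen).  Both ">50%" rules are strict, evaluated
on the union length of the mask intervals.

The replicate definition mirrors the standard 454-replicate rule: two reads
are replicates when their first three bases agree, the shorter read aligns
to the prefix of the longer at >= 90% global identity, and the length
difference is at most 10% of the longer read.  Groups are transitive
closures; the longest read of a group (ties broken by lexicographically
smallest id) is kept.

The low-complexity masker is a windowed symmetric-DUST variant (triplet
counting, window 64, level 20): a window is masked when ten times its
triplet score ``sum(c*(c-1)/2) / (ntriplets-1)`` exceeds the level.  The
repeat screen is a declared stand-in for an external masking tool: exact
15-mer seeds with ungapped extension, keeping matches >= 50 bases at >= 80%
identity.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import edlib

from .align import SubjectIndex, find_hits
from .core import (MaskInterval, PipelineConfig, Read, masked_fraction,
                   merge_intervals)


@dataclass(frozen=True)
class QCOutcome:
    read_id: str
    verdict: str  # kept | dropped_replicate | dropped_lowcomplexity | dropped_repeat
    masked_fraction_lowcomp: float = 0.0
    masked_fraction_repeat: float = 0.0


class _UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _is_replicate_pair(a: Read, b: Read, min_identity: float,
                       max_len_diff_pct: float) -> bool:
    longer, shorter = (a, b) if a.length >= b.length else (b, a)
    if longer.length - shorter.length > max_len_diff_pct / 100.0 * longer.length:
        return False
    res = edlib.align(shorter.seq, longer.seq[:shorter.length], mode="NW")
    identity = 1.0 - res["editDistance"] / shorter.length
    return identity * 100.0 >= min_identity


def flag_artificial_replicates(reads: list[Read],
                               config: PipelineConfig | None = None,
                               ) -> tuple[list[list[str]], dict[str, str]]:
    """Group artificial replicates; pick one representative per group.

    Returns (groups as lists of read ids, read_id → representative id map
    covering every read in a multi-member group).  Grouping is symmetric and
    independent of input order.
    """
    cfg = config or PipelineConfig()
    k = cfg.replicate_prefix
    buckets: dict[str, list[Read]] = defaultdict(list)
    for r in reads:
        buckets[r.seq[:k]].append(r)
    uf = _UnionFind()
    for prefix, members in buckets.items():
        if len(prefix) < k or len(members) < 2:
            continue
        members = sorted(members, key=lambda r: r.id)
        for i in range(len(members)):
            uf.find(members[i].id)
            for j in range(i + 1, len(members)):
                if _is_replicate_pair(members[i], members[j],
                                      cfg.replicate_min_identity,
                                      cfg.replicate_max_len_diff):
                    uf.union(members[i].id, members[j].id)
    by_root: dict[str, list[Read]] = defaultdict(list)
    by_id = {r.id: r for r in reads}
    for rid in uf.parent:
        by_root[uf.find(rid)].append(by_id[rid])
    groups, representative = [], {}
    for members in by_root.values():
        if len(members) < 2:
            continue
        members.sort(key=lambda r: (-r.length, r.id))
        ids = [m.id for m in members]
        groups.append(sorted(ids))
        for rid in ids:
            representative[rid] = members[0].id
    groups.sort()
    return groups, representative


def low_complexity_mask(read: Read, window: int = 64,
                        level: int = 20) -> list[MaskInterval]:
    """Windowed symmetric-DUST masking (triplet counting).

    Every window whose triplet score exceeds the level is masked whole;
    overlapping masked windows are merged.
    """
    seq = read.seq
    L = len(seq)
    if L < 3:
        return []
    intervals = []
    n_windows = max(1, L - window + 1)
    for i in range(n_windows):
        w = seq[i:i + window]
        counts: dict[str, int] = defaultdict(int)
        ntrip = 0
        for t in range(len(w) - 2):
            trip = w[t:t + 3]
            if "N" not in trip:
                counts[trip] += 1
                ntrip += 1
        if ntrip < 2:
            continue
        score = sum(c * (c - 1) // 2 for c in counts.values())
        if 10.0 * score / (ntrip - 1) > level:
            intervals.append(MaskInterval(read.id, i, min(i + window, L)))
    return merge_intervals(intervals)


def screen_repeat_library(read: Read, library: dict[str, str],
                          config: PipelineConfig | None = None,
                          index: SubjectIndex | None = None,
                          ) -> list[MaskInterval]:
    """Mask read regions matching a repeat library (built-in screen).

    Exact 15-mer seeds with ungapped extension; matches of >= 50 bases at
    >= 80% identity become mask intervals.  Pass a prebuilt
    :class:`SubjectIndex` when screening many reads against one library.
    """
    if not library:
        raise ValueError("repeat library is empty")
    cfg = config or PipelineConfig()
    if index is None:
        index = SubjectIndex(library, k=cfg.repeat_seed_k)
    hits = find_hits(read, index, min_len=cfg.repeat_min_len,
                     min_identity=cfg.repeat_min_identity,
                     exclude_self=False)
    return merge_intervals(
        [MaskInterval(read.id, h.q_start - 1, h.q_end) for h in hits])


def apply_fraction_filter(read: Read, masks: list[MaskInterval],
                          which: str,
                          drop_fraction_pct: float = 50.0) -> QCOutcome:
    """Drop the read iff the union mask covers strictly more than half of it.

    ``which`` selects the verdict family ("lowcomplexity" or "repeat").
    """
    if which not in ("lowcomplexity", "repeat"):
        raise ValueError(f"unknown filter {which!r}")
    frac = masked_fraction(read.length, masks)
    dropped = frac > drop_fraction_pct / 100.0
    if which == "lowcomplexity":
        verdict = "dropped_lowcomplexity" if dropped else "kept"
        return QCOutcome(read.id, verdict, masked_fraction_lowcomp=frac)
    verdict = "dropped_repeat" if dropped else "kept"
    return QCOutcome(read.id, verdict, masked_fraction_repeat=frac)


def run_qc_stage(reads: list[Read], config: PipelineConfig | None = None,
                 repeat_masks: list[MaskInterval] | None = None,
                 repeat_library: dict[str, str] | None = None,
                 ) -> tuple[list[Read], list[QCOutcome]]:
    """Replicates → low-complexity → repeats, in that order.

    Precomputed repeat masks (BED) take precedence over the built-in
    library screen when both are supplied; with neither, the repeat filter
    is a no-op.
    """
    cfg = config or PipelineConfig()
    outcomes: list[QCOutcome] = []
    _, representative = flag_artificial_replicates(reads, cfg)
    kept: list[Read] = []
    for r in reads:
        if representative.get(r.id, r.id) != r.id:
            outcomes.append(QCOutcome(r.id, "dropped_replicate"))
        else:
            kept.append(r)
    masks_by_read: dict[str, list[MaskInterval]] = defaultdict(list)
    if repeat_masks is not None:
        for m in repeat_masks:
            masks_by_read[m.read_id].append(m)
    lib_index = (SubjectIndex(repeat_library, k=cfg.repeat_seed_k)
                 if repeat_masks is None and repeat_library else None)
    survivors: list[Read] = []
    for r in kept:
        lc = low_complexity_mask(r, cfg.dust_window, cfg.dust_level)
        out = apply_fraction_filter(r, lc, "lowcomplexity",
                                    cfg.mask_drop_fraction)
        if out.verdict != "kept":
            outcomes.append(out)
            continue
        if lib_index is not None:
            rep = screen_repeat_library(r, repeat_library, cfg, lib_index)
        else:
            rep = masks_by_read.get(r.id, [])
        out2 = apply_fraction_filter(r, rep, "repeat", cfg.mask_drop_fraction)
        outcomes.append(QCOutcome(r.id, out2.verdict,
                                  masked_fraction_lowcomp=out.masked_fraction_lowcomp,
                                  masked_fraction_repeat=out2.masked_fraction_repeat))
        if out2.verdict == "kept":
            survivors.append(r)
    return survivors, outcomes
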