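"""Detection of amplification (MDA) chimeras in shotgun reads.

phi29 multiple displacement amplification of low-input DNA creates chimeric
molecules by branch migration; the sequenced artifacts come in two
rearrangement classes, inverted sequences and transposed direct sequences.
Detection is rule-based, applied in order:

1. flag any read containing an exact repeat of at least 25 bases, in either
   the forward or the reverse direction ("reverse" read as reverse
   complement — the product branch migration creates — with plain reversal
   available behind a config switch);
2. flag any read with a >90%-identity match covering >95% of its length to
   a read flagged in step 1 (single pass, no transitive chaining);
3. classify every pair of reads sharing local-alignment hits into a pair
   pattern — inverted, transposed-direct, collinear or ambiguous;
4. flag any remaining read with strictly more chimeric-pattern neighbors
   than non-pattern neighbors.

Step 4 assumes chimeras are a small fraction of all reads; a runtime
warning is emitted when more than 30% of reads end up flagged.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

from .core import HitRecord, PipelineConfig, Read, revcomp

logger = logging.getLogger("aerobiome")


@dataclass(frozen=True)
class RepeatEvidence:
    orientation: str  # forward | reverse
    length: int
    pos_a: int        # 0-based start of the first copy
    pos_b: int        # 0-based start of the second copy / reverse partner


@dataclass(frozen=True)
class ChimeraVerdict:
    read_id: str
    status: str  # clean | flagged_repeat | flagged_propagated | flagged_vote
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PairPattern:
    a: str
    b: str
    pattern: str  # inverted | transposed_direct | collinear | ambiguous
    hits: tuple = ()


def _extend_forward(seq: str, i: int, j: int, k: int) -> tuple[int, int, int]:
    """Maximal exact forward repeat around seed copies at i and j (i < j)."""
    left = 0
    while i - left - 1 >= 0 and seq[i - left - 1] == seq[j - left - 1]:
        left += 1
    right = 0
    while (j + k + right < len(seq)
           and seq[i + k + right] == seq[j + k + right]):
        right += 1
    return i - left, j - left, k + left + right


def _extend_reverse(seq: str, i: int, j: int, k: int,
                    comp: dict) -> tuple[int, int, int]:
    """Maximal block X at i whose reverse complement sits at j."""
    # grow on X's right / partner's left
    right = 0
    while (i + k + right < len(seq) and j - right - 1 >= 0
           and seq[j - right - 1] == comp.get(seq[i + k + right], "?")):
        right += 1
    left = 0
    while (i - left - 1 >= 0 and j + k + left < len(seq)
           and seq[j + k + left] == comp.get(seq[i - left - 1], "?")):
        left += 1
    return i - left, j - right, k + left + right


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def find_internal_repeats(read: Read, min_len: int = 25,
                          reverse_is_revcomp: bool = True,
                          ) -> RepeatEvidence | None:
    """Exact internal repeat of at least ``min_len`` bases, either direction.

    A read is flagged when some substring of length >= ``min_len`` occurs at
    two distinct start positions (forward), or when such a substring equals
    the reverse complement (or plain reversal, per the switch) of another
    substring of the same read (reverse direction).  Returns evidence for
    the maximal block found, or None.
    """
    seq = read.seq
    k = min_len
    if len(seq) < k:
        return None
    positions: dict[str, int] = {}
    best: RepeatEvidence | None = None
    # forward: first repeated k-mer, maximally extended
    for j in range(len(seq) - k + 1):
        w = seq[j:j + k]
        if "N" in w:
            continue
        if w in positions:
            i0, j0, length = _extend_forward(seq, positions[w], j, k)
            ev = RepeatEvidence("forward", length, i0, j0)
            if best is None or ev.length > best.length:
                best = ev
        else:
            positions[w] = j
    # reverse direction
    for j in range(len(seq) - k + 1):
        w = seq[j:j + k]
        if "N" in w:
            continue
        partner = revcomp(w) if reverse_is_revcomp else w[::-1]
        i = positions.get(partner)
        if i is None:
            continue
        if reverse_is_revcomp:
            i0, j0, length = _extend_reverse(seq, i, j, k, _COMP)
        else:
            i0, j0, length = i, j, k
        ev = RepeatEvidence("reverse", length, i0, j0)
        if best is None or ev.length > best.length:
            best = ev
    return best


def propagate_similarity_flags(reads: list[Read], seed_flagged: set[str],
                               hits: list[HitRecord],
                               config: PipelineConfig | None = None,
                               ) -> dict[str, dict]:
    """Single-pass extension of repeat flags over strong similarity.

    A read is flagged when some hit links it (as query) to a seed-flagged
    read with identity strictly above 90% covering strictly more than 95%
    of the query's length.  Returns read_id → evidence.
    """
    cfg = config or PipelineConfig()
    length_of = {r.id: r.length for r in reads}
    out: dict[str, dict] = {}
    for h in hits:
        if h.subject_id not in seed_flagged or h.query_id in seed_flagged:
            continue
        qlen = length_of.get(h.query_id)
        if qlen is None:
            continue
        cov = 100.0 * h.q_span / qlen
        if (h.pct_identity > cfg.propagate_min_identity
                and cov > cfg.propagate_min_cov):
            prev = out.get(h.query_id)
            if prev is None or h.pct_identity > prev["identity"]:
                out[h.query_id] = {"seed": h.subject_id,
                                   "identity": h.pct_identity,
                                   "coverage": cov}
    return out


def _filter_pattern_hits(hits, cfg: PipelineConfig):
    return [h for h in hits
            if h.aln_length >= cfg.pattern_min_hit_len
            and h.evalue <= cfg.pattern_evalue_cutoff]


def classify_pair_pattern(a: str, b: str, hits: list[HitRecord],
                          config: PipelineConfig | None = None) -> PairPattern:
    """Classify the match geometry between two reads.

    ``hits`` are the alignments between the pair, expressed with ``a`` as
    the query.  The two highest-bitscore hits that do not overlap on the
    query decide the pattern: transposed-direct when both are plus strand
    and the query-interval order is the reverse of the subject-interval
    order; inverted when the strands differ and the subject intervals
    overlap or lie within the configured tolerance of each other; collinear
    when order and strand are consistent (a single hit is collinear);
    ambiguous otherwise.
    """
    cfg = config or PipelineConfig()
    cand = sorted(_filter_pattern_hits(hits, cfg), key=lambda h: -h.bitscore)
    if not cand:
        return PairPattern(a, b, "ambiguous")
    h1 = cand[0]
    h2 = None
    for h in cand[1:]:
        if h.q_end < h1.q_start or h.q_start > h1.q_end:
            h2 = h
            break
    if h2 is None:
        return PairPattern(a, b, "collinear", (h1,))
    ha, hb = (h1, h2) if h1.q_start <= h2.q_start else (h2, h1)
    if ha.strand == hb.strand == "plus":
        if ha.s_start > hb.s_start:
            return PairPattern(a, b, "transposed_direct", (ha, hb))
        if ha.s_start < hb.s_start:
            return PairPattern(a, b, "collinear", (ha, hb))
        return PairPattern(a, b, "ambiguous", (ha, hb))
    if ha.strand != hb.strand:
        gap = max(ha.s_start, hb.s_start) - min(ha.s_end, hb.s_end)
        if gap <= cfg.inverted_overlap_tolerance:
            return PairPattern(a, b, "inverted", (ha, hb))
        return PairPattern(a, b, "ambiguous", (ha, hb))
    # both minus: consistent collinear order is descending subject intervals
    if ha.s_start > hb.s_start:
        return PairPattern(a, b, "collinear", (ha, hb))
    return PairPattern(a, b, "ambiguous", (ha, hb))


def build_pair_patterns(hits: list[HitRecord],
                        config: PipelineConfig | None = None,
                        ) -> list[PairPattern]:
    """Classify every unordered read pair sharing at least one filtered hit.

    Hits are canonicalized into the frame of the lexicographically smaller
    read id (query/subject intervals swapped where needed) so each pair is
    classified exactly once.
    """
    cfg = config or PipelineConfig()
    by_pair: dict[tuple[str, str], list[HitRecord]] = defaultdict(list)
    for h in _filter_pattern_hits(hits, cfg):
        if h.query_id == h.subject_id:
            continue
        a, b = sorted((h.query_id, h.subject_id))
        if h.query_id == a:
            by_pair[(a, b)].append(h)
        else:
            by_pair[(a, b)].append(HitRecord(
                a, b, h.pct_identity, h.aln_length, h.mismatches,
                h.gap_opens, h.s_start, h.s_end, h.q_start, h.q_end,
                h.evalue, h.bitscore, h.strand))
    return [classify_pair_pattern(a, b, pair_hits, cfg)
            for (a, b), pair_hits in sorted(by_pair.items())]


def vote_chimeras(read_ids: list[str], patterns: list[PairPattern],
                  already_flagged: set[str]) -> dict[str, dict]:
    """Strict-majority neighbor vote over pair patterns.

    A not-yet-flagged read is flagged when strictly more of its neighbors
    (reads sharing at least one filtered hit) show a chimeric pair pattern
    than show a non-chimeric one.  Already-flagged reads still count inside
    other reads' neighbor censuses.
    """
    chim: dict[str, int] = defaultdict(int)
    plain: dict[str, int] = defaultdict(int)
    for p in patterns:
        tgt = chim if p.pattern in ("inverted", "transposed_direct") else plain
        tgt[p.a] += 1
        tgt[p.b] += 1
    out = {}
    for rid in read_ids:
        if rid in already_flagged:
            continue
        c, n = chim.get(rid, 0), plain.get(rid, 0)
        if c > n:
            out[rid] = {"pattern_neighbors": c, "plain_neighbors": n}
    return out


def run_chimera_stage(reads: list[Read], hits: list[HitRecord] | None,
                      config: PipelineConfig | None = None,
                      ) -> tuple[list[Read], list[ChimeraVerdict]]:
    """Apply the four rules in order and remove flagged reads.

    ``hits`` must be an all-vs-all hit table over the reads (an empty list
    is accepted and limits detection to the internal-repeat rule); ``None``
    raises with a pointer to the built-in matcher.
    """
    if hits is None:
        raise ValueError(
            "chimera stage needs an all-vs-all hit table; generate one with "
            "aerobiome.align.all_vs_all(reads) or supply a twelve-column "
            "file via read_hit_table")
    cfg = config or PipelineConfig()
    verdicts: dict[str, ChimeraVerdict] = {}
    for r in reads:
        ev = find_internal_repeats(r, cfg.min_repeat_len,
                                   cfg.reverse_repeat_is_revcomp)
        if ev is not None:
            verdicts[r.id] = ChimeraVerdict(
                r.id, "flagged_repeat",
                {"orientation": ev.orientation, "length": ev.length})
    seed_ids = set(verdicts)
    for rid, ev in propagate_similarity_flags(reads, seed_ids, hits,
                                              cfg).items():
        verdicts[rid] = ChimeraVerdict(rid, "flagged_propagated", ev)
    patterns = build_pair_patterns(hits, cfg)
    for rid, ev in vote_chimeras([r.id for r in reads], patterns,
                                 set(verdicts)).items():
        verdicts[rid] = ChimeraVerdict(rid, "flagged_vote", ev)
    out_verdicts = []
    kept = []
    for r in reads:
        v = verdicts.get(r.id, ChimeraVerdict(r.id, "clean"))
        out_verdicts.append(v)
        if v.status == "clean":
            kept.append(r)
    frac = 1.0 - len(kept) / len(reads) if reads else 0.0
    if frac > 0.30:
        warnings.warn(
            f"{100 * frac:.1f}% of reads flagged as chimeric; the method "
            "assumes chimeras are a small fraction of the reads",
            RuntimeWarning, stacklevel=2)
    logger.info("chimera stage: %d/%d flagged", len(reads) - len(kept),
                len(reads))
    return kept, out_verdicts
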