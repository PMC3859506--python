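"""Built-in k-mer seed / ungapped-extension matcher.

A small local aligner so that the all-vs-all similarity steps (chimera
pattern search, repeat-library screening) run without an external search
binary.  It is a declared stand-in for a full local-alignment search, not a
claim of equivalence: seeds are exact k-mers, extension is ungapped along
the seed diagonal (best-scoring segment per diagonal run, match +1 /
mismatch -2), and the e-value is a simple search-space estimate
``qlen * slen * 2**(-bitscore)`` with ``bitscore = 2*matches - 3*mismatches``.
Exact or near-exact matches — the regime the pipeline's rules operate in —
score essentially as a rigorous search would.
"""

from __future__ import annotations

from collections import defaultdict

from .core import HitRecord, Read, revcomp


class SubjectIndex:
    """Exact k-mer index over a set of subject sequences (forward strand).

    Minus-strand matches are found by searching the reverse complement of
    the query against this index and mapping coordinates back.
    """

    def __init__(self, subjects: dict[str, str], k: int = 15):
        self.k = k
        self.subjects = subjects
        self._idx: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for sid, seq in subjects.items():
            for i in range(len(seq) - k + 1):
                w = seq[i:i + k]
                if "N" not in w:
                    self._idx[w].append((sid, i))

    def seed_diagonals(self, q: str) -> dict[str, set[int]]:
        """Per subject, the set of diagonals (qpos - spos) holding a seed."""
        diags: dict[str, set[int]] = defaultdict(set)
        k = self.k
        get = self._idx.get
        for i in range(len(q) - k + 1):
            for sid, j in get(q[i:i + k], ()):
                diags[sid].add(i - j)
        return diags


def _positive_segments(q: str, s: str, d: int, match: int = 1,
                       mismatch: int = -2):
    """Maximal positive-scoring ungapped segments on diagonal qpos = spos + d.

    Yields (q0, q1, n_match, n_mismatch), query coords 0-based half-open,
    one best segment per zero-resetting run of the cumulative score.
    """
    q0 = max(0, d)
    s0 = q0 - d
    n = min(len(q) - q0, len(s) - s0)
    cur = 0
    seg_start = 0
    best = (-1, 0, 0)
    out = []
    for t in range(n + 1):
        sc = 0
        if t < n:
            sc = match if q[q0 + t] == s[s0 + t] else mismatch
        if t == n or cur + sc < 0:
            if best[0] > 0:
                a, b = best[1], best[2]
                while a < b and q[q0 + a] != s[s0 + a]:
                    a += 1
                while b > a and q[q0 + b - 1] != s[s0 + b - 1]:
                    b -= 1
                if b > a:
                    m = sum(1 for u in range(a, b) if q[q0 + u] == s[s0 + u])
                    out.append((q0 + a, q0 + b, m, (b - a) - m))
            cur = 0
            seg_start = t + 1
            best = (-1, 0, 0)
        else:
            cur += sc
            if cur > best[0]:
                best = (cur, seg_start, t + 1)
    return out


def find_hits(query: Read, index: SubjectIndex, min_len: int = 25,
              min_identity: float = 0.0,
              exclude_self: bool = True) -> list[HitRecord]:
    """All seed-and-extend hits of one query against an indexed subject set.

    Both strands are searched; a minus-strand hit means the query matches
    the subject's reverse complement, with subject coordinates normalized
    to the forward strand.
    """
    out = []
    qlen = query.length
    for strand, q in (("plus", query.seq), ("minus", revcomp(query.seq))):
        for sid, diags in index.seed_diagonals(q).items():
            if exclude_self and sid == query.id:
                continue
            s = index.subjects[sid]
            for d in diags:
                for a, b, m, x in _positive_segments(q, s, d):
                    length = b - a
                    if length < min_len:
                        continue
                    ident = 100.0 * m / length
                    if ident < min_identity:
                        continue
                    sa, sb = a - d, b - d  # 0-based half-open on subject
                    if strand == "plus":
                        qs, qe = a + 1, b
                    else:
                        qs, qe = qlen - b + 1, qlen - a
                    bitscore = max(2.0 * m - 3.0 * x, 0.0)
                    evalue = qlen * len(s) * 2.0 ** (-bitscore)
                    out.append(HitRecord(query.id, sid, round(ident, 2),
                                         length, x, 0, qs, qe, sa + 1, sb,
                                         evalue, bitscore, strand))
    # dedupe (a plus and minus pass can rediscover palindromic segments)
    seen = set()
    uniq = []
    for h in sorted(out, key=lambda h: (-h.bitscore, h.subject_id, h.q_start)):
        key = (h.subject_id, h.q_start, h.q_end, h.s_start, h.s_end, h.strand)
        if key not in seen:
            seen.add(key)
            uniq.append(h)
    return uniq


def all_vs_all(reads: list[Read], k: int = 15, min_len: int = 25,
               min_identity: float = 0.0) -> list[HitRecord]:
    """All-vs-all hits among a read set (self-hits excluded)."""
    index = SubjectIndex({r.id: r.seq for r in reads}, k=k)
    hits = []
    for r in reads:
        hits.extend(find_hits(r, index, min_len=min_len,
                              min_identity=min_identity))
    return hits
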