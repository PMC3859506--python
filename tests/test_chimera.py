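"""Four-rule chimera detection against brute-force oracles."""

import numpy as np
import pytest

from aerobiome import align, synthetic as syn
from aerobiome.chimera import (ChimeraVerdict, build_pair_patterns,
                               classify_pair_pattern, find_internal_repeats,
                               propagate_similarity_flags, run_chimera_stage,
                               vote_chimeras)
from aerobiome.core import HitRecord, PipelineConfig, Read, revcomp


def _rand(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))


def brute_force_repeat(seq, k=25):
    """O(n^2) all-substring-pair comparison: the independent oracle."""
    n = len(seq)
    fwd = any(seq[i:i + k] == seq[j:j + k]
              for i in range(n - k + 1) for j in range(i + 1, n - k + 1))
    rev = any(seq[i:i + k] == revcomp(seq[j:j + k])
              for i in range(n - k + 1) for j in range(n - k + 1) if i != j)
    return fwd or rev


class TestInternalRepeats:
    def test_forward_block_at_boundary(self):
        a, b, c = _rand(60, 1), _rand(40, 2), _rand(30, 3)
        block25 = _rand(25, 4)
        ev = find_internal_repeats(Read("r", a + block25 + b + block25 + c))
        assert ev is not None and ev.orientation == "forward"
        assert ev.length >= 25
        # distinct flanking bases so the 24-base block cannot extend to 25
        block24 = _rand(24, 5)
        seq = a + "A" + block24 + "C" + b + "G" + block24 + "T" + c
        assert find_internal_repeats(Read("r", seq)) is None

    def test_reverse_direction_block(self):
        a, b = _rand(60, 6), _rand(40, 7)
        block = _rand(25, 8)
        ev = find_internal_repeats(Read("r", a + block + b + revcomp(block)))
        assert ev is not None and ev.orientation == "reverse"

    def test_random_reads_agree_with_brute_force(self):
        for seed in range(8):
            seq = _rand(300, 100 + seed)
            got = find_internal_repeats(Read("r", seq)) is not None
            assert got == brute_force_repeat(seq)

    def test_constructed_repeats_agree_with_brute_force(self):
        for seed in range(4):
            block = _rand(30, 200 + seed)
            seq = _rand(100, 300 + seed) + block + _rand(50, 400 + seed) + block
            assert (find_internal_repeats(Read("r", seq)) is not None) \
                == brute_force_repeat(seq) is True

    def test_plain_reversal_switch(self):
        a = _rand(60, 9)
        block = _rand(25, 10)
        seq = a + block + _rand(40, 11) + block[::-1]
        assert find_internal_repeats(Read("r", seq),
                                     reverse_is_revcomp=True) is None
        ev = find_internal_repeats(Read("r", seq), reverse_is_revcomp=False)
        assert ev is not None and ev.orientation == "reverse"

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_monotone_under_added_reads(self):
        block = _rand(25, 12)
        chimeric = Read("c", _rand(80, 13) + block + _rand(40, 14) + block)
        others = [Read(f"o{i}", _rand(300, 20 + i)) for i in range(5)]
        _, v1 = run_chimera_stage([chimeric], [])
        _, v2 = run_chimera_stage([chimeric] + others, [])
        assert v1[0].status == "flagged_repeat"
        assert v2[0].status == "flagged_repeat"


class TestPropagation:
    def _hit(self, q, s, ident, qlen, cov_pct):
        span = int(round(cov_pct / 100 * qlen))
        return HitRecord(q, s, ident, span, 0, 0, 1, span, 1, span,
                         1e-40, 2.0 * span)

    def test_strict_inequalities(self):
        reads = [Read("seed", "A" * 100), Read("x", _rand(100, 1)),
                 Read("y", _rand(100, 2)), Read("z", _rand(100, 3))]
        hits = [self._hit("x", "seed", 92.0, 100, 96),   # both strict: in
                self._hit("y", "seed", 90.0, 100, 96),   # identity == 90: out
                self._hit("z", "seed", 92.0, 100, 95)]   # coverage == 95: out
        out = propagate_similarity_flags(reads, {"seed"}, hits)
        assert set(out) == {"x"}

    def test_no_seeds_no_propagation(self):
        reads = [Read("x", _rand(100, 1))]
        hits = [self._hit("x", "seed", 99.0, 100, 99)]
        assert propagate_similarity_flags(reads, set(), hits) == {}

    def test_single_pass_no_chaining(self):
        reads = [Read("seed", "A" * 100), Read("x", _rand(100, 1)),
                 Read("y", _rand(100, 2))]
        hits = [self._hit("x", "seed", 95.0, 100, 99),
                self._hit("y", "x", 95.0, 100, 99)]  # y linked to x, not seed
        out = propagate_similarity_flags(reads, {"seed"}, hits)
        assert set(out) == {"x"}


def _pair_hit(qs, qe, ss, se, strand="plus", bits=200.0):
    return HitRecord("a", "b", 99.0, qe - qs + 1, 0, 0, qs, qe, ss, se,
                     1e-40, bits, strand)


class TestPairPatterns:
    def test_transposed_direct_order_inversion(self):
        hits = [_pair_hit(1, 100, 201, 300), _pair_hit(151, 250, 1, 100)]
        assert classify_pair_pattern("a", "b", hits).pattern == \
            "transposed_direct"

    def test_inverted_opposite_strands_overlapping_subject(self):
        hits = [_pair_hit(1, 100, 1, 100),
                _pair_hit(151, 250, 40, 139, strand="minus")]
        assert classify_pair_pattern("a", "b", hits).pattern == "inverted"

    def test_single_hit_collinear(self):
        assert classify_pair_pattern(
            "a", "b", [_pair_hit(1, 200, 1, 200)]).pattern == "collinear"

    def test_consistent_two_hit_collinear(self):
        hits = [_pair_hit(1, 100, 1, 100), _pair_hit(151, 250, 160, 259)]
        assert classify_pair_pattern("a", "b", hits).pattern == "collinear"

    def test_opposite_strands_far_apart_ambiguous(self):
        hits = [_pair_hit(1, 100, 1, 100),
                _pair_hit(151, 250, 500, 599, strand="minus")]
        assert classify_pair_pattern("a", "b", hits).pattern == "ambiguous"

    def test_short_or_weak_hits_ignored(self):
        hits = [_pair_hit(1, 20, 201, 220),   # below min length
                _pair_hit(151, 250, 1, 100)]
        assert classify_pair_pattern("a", "b", hits).pattern == "collinear"


class TestVote:
    def test_strict_majority(self):
        from aerobiome.chimera import PairPattern
        pats = [PairPattern("r", f"c{i}", "inverted") for i in range(3)]
        pats += [PairPattern("r", f"p{i}", "collinear") for i in range(2)]
        assert "r" in vote_chimeras(["r"], pats, set())

    def test_tie_not_flagged(self):
        from aerobiome.chimera import PairPattern
        pats = [PairPattern("r", "c0", "transposed_direct"),
                PairPattern("r", "c1", "inverted"),
                PairPattern("r", "p0", "collinear"),
                PairPattern("r", "p1", "ambiguous")]
        assert vote_chimeras(["r"], pats, set()) == {}

    def test_isolated_read_not_flagged(self):
        assert vote_chimeras(["lonely"], [], set()) == {}


def _brute_force_stage(reads, hits, cfg):
    """Independent straight-line reimplementation of the four rules."""
    flagged = {}
    for r in reads:
        if brute_force_repeat(r.seq, cfg.min_repeat_len):
            flagged[r.id] = "flagged_repeat"
    lengths = {r.id: r.length for r in reads}
    seeds = set(flagged)
    for h in hits:
        if (h.subject_id in seeds and h.query_id not in seeds
                and h.pct_identity > cfg.propagate_min_identity
                and 100.0 * h.q_span / lengths[h.query_id]
                > cfg.propagate_min_cov):
            flagged.setdefault(h.query_id, "flagged_propagated")
    patterns = build_pair_patterns(hits, cfg)
    chim, plain = {}, {}
    for p in patterns:
        d = chim if p.pattern in ("inverted", "transposed_direct") else plain
        for rid in (p.a, p.b):
            d[rid] = d.get(rid, 0) + 1
    for r in reads:
        if r.id not in flagged and chim.get(r.id, 0) > plain.get(r.id, 0):
            flagged[r.id] = "flagged_vote"
    return flagged


class TestStage:
    def test_clean_synthetic_set_yields_no_flags(self, community, genomes):
        reads, _ = syn.simulate_reads(community, genomes, 150, 55)
        hits = align.all_vs_all(reads)
        kept, verdicts = run_chimera_stage(reads, hits)
        assert len(kept) == len(reads)

    def test_injected_big_block_chimeras_all_flagged_at_step_one(
            self, community, genomes):
        reads, truth = syn.simulate_reads(community, genomes, 150, 56)
        reads2, t2 = syn.inject_artifacts(reads, truth, genomes, 57,
                                          chimera_rate=0.15)
        chim_ids = set(t2.loc[t2["is_chimera"], "read_id"])
        assert chim_ids
        for r in reads2:
            ev = find_internal_repeats(r)
            if r.id in chim_ids:
                assert ev is not None

    def test_stage_matches_brute_force_oracle(self, community, genomes):
        cfg = PipelineConfig()
        reads, truth = syn.simulate_reads(
            community, genomes, 180, 58, length_model=(220.0, 30.0))
        reads2, _ = syn.inject_artifacts(reads, truth, genomes, 59,
                                         chimera_rate=0.1,
                                         sub25_block_fraction=0.5)
        hits = align.all_vs_all(reads2)
        _, verdicts = run_chimera_stage(reads2, hits, cfg)
        got = {v.read_id: v.status for v in verdicts if v.status != "clean"}
        expected = _brute_force_stage(reads2, hits, cfg)
        assert got == expected

    def test_missing_hit_table_raises_with_remedy(self):
        with pytest.raises(ValueError, match="all_vs_all"):
            run_chimera_stage([Read("r", "ACGT" * 30)], None)

    def test_high_flag_fraction_warns(self):
        block = _rand(30, 60)
        reads = [Read(f"c{i}", _rand(60, 70 + i) + block + block)
                 for i in range(5)]
        with pytest.warns(RuntimeWarning, match="small fraction"):
            run_chimera_stage(reads, [])
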