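"""Synthetic communities, reads and artifacts with truth labels.

Every downstream stage of the pipeline is testable without external data:
this module generates multi-genome communities with controllable GC content
and kingdom labels, pyrosequencing-style single-end reads, the three
artifact classes the pipeline removes (artificial replicates, low-complexity
stretches, amplification chimeras of the inverted and transposed-direct
rearrangement classes), two-component GC mixtures with a known mixing
proportion, and hit/annotation tables consistent with the truth.

All generators are pure functions of (spec, seed).  Chimera geometry follows
the branch-migration model of phi29 amplification: junctions are
intra-genome and local, and the junction region is duplicated — in reverse
complement for the inverted class, forward for the transposed-direct class —
with a configurable duplicated-block length (>= 25 bases for detectable
cases, smaller for hard cases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import HitRecord, Read, revcomp

TRUTH_COLUMNS = ["read_id", "sample", "genome", "kingdom", "genus",
                 "start", "end", "is_replicate", "replicate_group",
                 "is_chimera", "chimera_class", "is_lowcomp"]

#: Default GC-mixture components: a low-GC eukaryote-like component and a
#: higher-GC prokaryote/virus-like component, well separated (means 0.38 and
#: 0.60, sd ~0.05 each) as in a community whose kingdoms differ in GC.
DEFAULT_E_DIST = stats.beta(35, 57)
DEFAULT_PV_DIST = stats.beta(60, 40)


@dataclass(frozen=True)
class GenomeSpec:
    label: str
    kingdom: str
    genus: str
    length: int
    gc: float
    abundance: float


@dataclass
class CommunitySpec:
    """A community of source genomes with relative abundances summing to 1."""

    genomes: list[GenomeSpec]

    def __post_init__(self):
        total = sum(g.abundance for g in self.genomes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, not 1")
        for g in self.genomes:
            if g.length < 1000:
                raise ValueError(f"genome {g.label}: length {g.length} < 1000")
            if not 0.0 < g.gc < 1.0:
                raise ValueError(f"genome {g.label}: GC target {g.gc} "
                                 "outside (0,1)")
            if g.abundance < 0:
                raise ValueError(f"genome {g.label}: negative abundance")


def default_community() -> CommunitySpec:
    """A small mixed-kingdom community used as the stock test condition."""
    return CommunitySpec([
        GenomeSpec("euk1", "Eukaryota", "Aspergillus", 60000, 0.38, 0.35),
        GenomeSpec("bac1", "Bacteria", "Pseudomonas", 60000, 0.62, 0.30),
        GenomeSpec("bac2", "Bacteria", "Sphingomonas", 40000, 0.55, 0.20),
        GenomeSpec("arc1", "Archaea", "Halobacterium", 30000, 0.60, 0.10),
        GenomeSpec("vir1", "Viruses", "Caudovirales", 20000, 0.45, 0.05),
    ])


def generate_genomes(spec: CommunitySpec, seed: int) -> dict[str, str]:
    """iid-base genomes whose per-base GC probability equals the target.

    Deterministic given the seed; the realized GC fraction concentrates
    within about two binomial standard deviations of the target.
    """
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genomes = {}
    for g in spec.genomes:
        is_gc = rng.random(g.length) < g.gc
        coin = rng.random(g.length) < 0.5
        # A/T when not GC, G/C when GC, coin picks within each pair
        codes = np.where(is_gc, np.where(coin, 2, 1), np.where(coin, 0, 3))
        genomes[g.label] = bases[codes].tobytes().decode()
    return genomes


def simulate_reads(spec: CommunitySpec, genomes: dict[str, str],
                   n_reads: int, seed: int,
                   length_model: tuple[float, float] = (350.0, 80.0),
                   min_len: int = 50, sample: str = "S1",
                   ) -> tuple[list[Read], pd.DataFrame]:
    """Uniform shotgun reads from abundance-weighted genomes, plus truth.

    Lengths follow a truncated normal (minimum ``min_len`` bases); start
    positions are uniform on the chosen genome.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    mean, sd = length_model
    for g in spec.genomes:
        if g.length < min_len:
            raise ValueError(f"genome {g.label} shorter than min read length")
    rng = np.random.default_rng(seed)
    labels = [g.label for g in spec.genomes]
    probs = np.array([g.abundance for g in spec.genomes])
    probs = probs / probs.sum()
    by_label = {g.label: g for g in spec.genomes}
    choices = rng.choice(len(labels), size=n_reads, p=probs)
    lengths = rng.normal(mean, sd, size=n_reads)
    lengths = np.maximum(lengths, min_len).astype(int)
    reads, rows = [], []
    for i in range(n_reads):
        glab = labels[choices[i]]
        gseq = genomes[glab]
        L = min(int(lengths[i]), len(gseq))
        start = int(rng.integers(0, len(gseq) - L + 1))
        rid = f"{sample}_r{i:06d}"
        reads.append(Read(rid, gseq[start:start + L], sample))
        gs = by_label[glab]
        rows.append((rid, sample, glab, gs.kingdom, gs.genus, start,
                     start + L, False, "", False, "none", False))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return reads, truth


def _make_inverted(gseq: str, rng, target_len: int, block: int):
    """prefix segment + reverse complement of an overlapping segment."""
    T = max(target_len, 2 * block + 20)
    L1 = max(block + 10, T // 2)
    L2 = T - L1
    a = int(rng.integers(0, len(gseq) - T))
    c = a + L1 - block
    seg1 = gseq[a:a + L1]
    seg2 = gseq[c:c + L2]
    return seg1 + revcomp(seg2), a, c + L2


def _make_transposed(gseq: str, rng, target_len: int, block: int):
    """two same-strand overlapping segments emitted in swapped order."""
    T = max(target_len, 2 * block + 20)
    L1 = max(block + 10, T // 2)
    L2 = T - L1
    a = int(rng.integers(0, len(gseq) - T))
    seg1 = gseq[a:a + L1]
    seg2 = gseq[a + L1 - block:a + L1 - block + L2]
    return seg2 + seg1, a, a + L1 - block + L2


_LOWCOMP_MOTIFS = ("AC", "AG", "AT", "CG", "CT", "GT", "A", "T")


def inject_artifacts(reads: list[Read], truth: pd.DataFrame,
                     genomes: dict[str, str], seed: int,
                     replicate_rate: float = 0.0, chimera_rate: float = 0.0,
                     lowcomp_rate: float = 0.0,
                     sub25_block_fraction: float = 0.0,
                     block_range: tuple[int, int] = (25, 60),
                     lowcomp_span: float = 0.6,
                     ) -> tuple[list[Read], pd.DataFrame]:
    """Inject replicates, chimeras and low-complexity stretches, with truth.

    Each input read independently becomes a chimera (probability
    ``chimera_rate``, class inverted or transposed-direct with equal odds)
    or gains a low-complexity stretch (``lowcomp_rate``); afterwards each
    read independently spawns an artificial replicate (``replicate_rate``) —
    a copy sharing the original's start, truncated by up to 10%.  A fraction
    ``sub25_block_fraction`` of chimeras get a duplicated junction block
    below 25 bases (hard cases invisible to the exact-repeat rule).

    Read count out = read count in + number of injected replicates.
    """
    for r, name in ((replicate_rate, "replicate_rate"),
                    (chimera_rate, "chimera_rate"),
                    (lowcomp_rate, "lowcomp_rate")):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [0,1]")
    rng = np.random.default_rng(seed)
    truth = truth.set_index("read_id", drop=False)
    out_reads: list[Read] = []
    rows = []
    u = rng.random(len(reads))
    for i, read in enumerate(reads):
        row = truth.loc[read.id].copy()
        gseq = genomes[row["genome"]]
        if u[i] < chimera_rate:
            if rng.random() < sub25_block_fraction:
                block = int(rng.integers(10, 25))
            else:
                block = int(rng.integers(block_range[0], block_range[1] + 1))
            cls = "inverted" if rng.random() < 0.5 else "transposed_direct"
            maker = _make_inverted if cls == "inverted" else _make_transposed
            seq, a, b = maker(gseq, rng, read.length, block)
            read = Read(read.id, seq, read.sample)
            row["start"], row["end"] = a, b
            row["is_chimera"], row["chimera_class"] = True, cls
        elif u[i] < chimera_rate + lowcomp_rate:
            span = max(2, int(lowcomp_span * read.length))
            motif = _LOWCOMP_MOTIFS[int(rng.integers(0, len(_LOWCOMP_MOTIFS)))]
            stretch = (motif * (span // len(motif) + 1))[:span]
            pos = int(rng.integers(0, read.length - span + 1))
            seq = read.seq[:pos] + stretch + read.seq[pos + span:]
            read = Read(read.id, seq, read.sample)
            row["is_lowcomp"] = True
        out_reads.append(read)
        rows.append(row)
    n0 = len(out_reads)
    v = rng.random(n0)
    for i in range(n0):
        if v[i] < replicate_rate:
            src = out_reads[i]
            keep = src.length - int(rng.integers(0, src.length // 10 + 1))
            rep = Read(f"{src.id}_rep", src.seq[:keep], src.sample)
            out_reads.append(rep)
            rrow = rows[i].copy()
            rrow["read_id"] = rep.id
            rrow["is_replicate"] = True
            rrow["replicate_group"] = src.id
            rows[i]["replicate_group"] = src.id
            rows.append(rrow)
    new_truth = pd.DataFrame(rows).reset_index(drop=True)
    return out_reads, new_truth


def sample_gc_mixture(p: float, n: int, seed: int, dist_e=None, dist_pv=None,
                      ) -> pd.DataFrame:
    """Draw n GC fractions from ``p * E + (1-p) * PV`` with component labels.

    Returns a DataFrame with columns ``gc`` and ``component`` ("E"/"PV").
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0,1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    dist_e = DEFAULT_E_DIST if dist_e is None else dist_e
    dist_pv = DEFAULT_PV_DIST if dist_pv is None else dist_pv
    rng = np.random.default_rng(seed)
    from_e = rng.random(n) < p
    vals = np.where(from_e,
                    dist_e.rvs(size=n, random_state=rng),
                    dist_pv.rvs(size=n, random_state=rng))
    return pd.DataFrame({"gc": vals,
                         "component": np.where(from_e, "E", "PV")})


_KO_POOL = [f"K{q:05d}" for q in (0, 1, 2, 1130, 1467, 2314, 2315, 8151,
                                  3043, 2358)]
_COG_POOL = [f"COG{q:04d}" for q in (1, 2, 3, 12, 305, 550)]

ANNOTATION_COLUMNS = ["peptide_id", "read_id", "sample", "kingdom", "genus",
                      "ko", "cog", "pep_len_aa", "gene_len_aa",
                      "pct_identity", "pct_coverage"]


def fabricate_hit_tables(reads: list[Read], truth: pd.DataFrame, seed: int,
                         hit_fraction: float = 0.9,
                         noise_fraction: float = 0.0,
                         ) -> tuple[list[HitRecord], pd.DataFrame,
                                    dict[str, dict]]:
    """Nucleotide hits + peptide annotations consistent with the truth.

    A ``hit_fraction`` of reads receive nucleotide hits to reference
    subjects of their true kingdom and (for non-eukaryotic reads) peptide
    annotations carrying the true kingdom/genus and a KO/COG label; a
    ``noise_fraction`` of those reads instead get one extra hit/peptide from
    a conflicting kingdom.  Remaining reads get nothing (Unclassified).

    Returns (nucleotide hits, annotation table, subject→taxonomy map).
    """
    rng = np.random.default_rng(seed)
    truth = truth.set_index("read_id", drop=False)
    kingdoms = ("Archaea", "Bacteria", "Eukaryota", "Viruses")
    taxon_map: dict[str, dict] = {}

    def subject_for(kingdom: str, genus: str) -> str:
        sid = f"{kingdom.lower()}_ref_{genus}"
        taxon_map[sid] = {"kingdom": kingdom, "phylum": "", "genus": genus}
        return sid

    nt_hits: list[HitRecord] = []
    ann_rows = []
    u = rng.random(len(reads))
    w = rng.random(len(reads))
    for i, read in enumerate(reads):
        if u[i] >= hit_fraction:
            continue
        row = truth.loc[read.id]
        kingdom, genus = row["kingdom"], row["genus"]
        noisy = w[i] < noise_fraction
        L = read.length
        sid = subject_for(kingdom, genus)
        nt_hits.append(HitRecord(read.id, sid, 98.0, L, 2, 0, 1, L,
                                 1000, 1000 + L - 1, 1e-30, 2.0 * L))
        if noisy:
            other = kingdoms[(kingdoms.index(kingdom) + 1) % 4]
            sid2 = subject_for(other, "noise")
            nt_hits.append(HitRecord(read.id, sid2, 95.0, L, 5, 0, 1, L,
                                     2000, 2000 + L - 1, 1e-20, 1.8 * L))
        if kingdom == "Eukaryota" and not noisy:
            continue  # resolved by the nucleotide prescreen
        pep_len = max(60, L // 3 - 10)
        n_pep = 1 + int(rng.random() < 0.5)
        pep_kingdoms = [kingdom] * n_pep
        if noisy:
            pep_kingdoms[-1] = kingdoms[(kingdoms.index(kingdom) + 1) % 4]
        for j, pk in enumerate(pep_kingdoms):
            ann_rows.append((f"{read.id}_p{j}", read.id, read.sample, pk,
                             genus if pk == kingdom else "noise",
                             _KO_POOL[int(rng.integers(0, len(_KO_POOL)))],
                             _COG_POOL[int(rng.integers(0, len(_COG_POOL)))],
                             pep_len,
                             int(rng.integers(150, 600)),
                             round(90 + 10 * rng.random(), 1),
                             round(90 + 10 * rng.random(), 1)))
    annotations = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    return nt_hits, annotations, taxon_map
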