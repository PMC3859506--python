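"""Two-tier read taxonomy and the seven-category tabulation.

Reads are first prescreened at the nucleotide level: among the top ten hits
below e-value 1e-5, a read whose matching subjects are all eukaryotic is
classified Eukaryota outright (this captures human and other large-genome
material that rarely codes for proteins over a read's span).  All other
reads go through the peptide path: predicted peptides carry the kingdom of
their best protein hit, and peptide kingdoms are transferred onto the read —
a single consistent kingdom (unclassified peptides do not break consistency)
transfers, conflicting kingdoms yield Mixed, no classified peptide yields
Unclassified.  The seven resulting categories are Archaea, Bacteria,
Eukaryota, Viruses, Mixed, Other (unidentifiable/synthetic subjects) and
Unclassified.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd

from .core import CATEGORIES, HitRecord, PipelineConfig, Read, revcomp

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class PeptideRecord:
    peptide_id: str
    read_id: str
    kingdom: str  # one of KINGDOMS, "Other", or "Unclassified"
    genus: str = ""
    ko: tuple[str, ...] = ()
    cog: str = ""
    pep_len_aa: int = 0


class UnknownSubjectError(KeyError):
    def __init__(self, subjects):
        self.subjects = sorted(subjects)
        super().__init__(
            "subjects missing from the taxon map: " + ", ".join(self.subjects))


def _kingdoms_for(hits, taxon_map):
    missing = {h.subject_id for h in hits if h.subject_id not in taxon_map}
    if missing:
        raise UnknownSubjectError(missing)


def nucleotide_prescreen(read_id: str, hits: list[HitRecord],
                         taxon_map: dict[str, dict],
                         config: PipelineConfig | None = None) -> str:
    """"Eukaryota" iff every retained nucleotide hit is eukaryotic.

    Retained = top hits by bitscore (at most ten) with e-value strictly
    below 1e-5.  Anything else — no retained hit, or any non-eukaryotic
    subject — returns "undetermined" and the read falls through to the
    peptide path.
    """
    cfg = config or PipelineConfig()
    mine = [h for h in hits
            if h.query_id == read_id and h.evalue < cfg.nt_evalue_cutoff]
    mine.sort(key=lambda h: (-h.bitscore, h.subject_id))
    retained = mine[:cfg.max_nt_hits]
    if not retained:
        return "undetermined"
    _kingdoms_for(retained, taxon_map)
    if all(taxon_map[h.subject_id]["kingdom"] == "Eukaryota"
           for h in retained):
        return "Eukaryota"
    return "undetermined"


def _translate(seq: str) -> str:
    return "".join(_CODON_TABLE.get(seq[i:i + 3], "X")
                   for i in range(0, len(seq) - 2, 3))


def predict_peptides_standin(read: Read, min_len_aa: int = 60,
                             ) -> list[tuple[str, str]]:
    """Six-frame ORF caller: longest stop-free stretch >= 60 aa per frame.

    A declared stand-in for a frameshift-aware gene caller; deterministic,
    symmetric under reverse complementation.  Returns (frame label, peptide)
    pairs, frames labelled +1..+3 / -1..-3.
    """
    out = []
    for strand, seq in (("+", read.seq), ("-", revcomp(read.seq))):
        for offset in range(3):
            aa = _translate(seq[offset:])
            best = ""
            for fragment in aa.split("*"):
                if len(fragment) > len(best):
                    best = fragment
            if len(best) >= min_len_aa:
                out.append((f"{strand}{offset + 1}", best))
    return out


def assign_peptide_taxonomy(peptide_id: str, hits: list[HitRecord],
                            taxon_map: dict[str, dict],
                            config: PipelineConfig | None = None,
                            ) -> tuple[str, str]:
    """(kingdom, genus) of the best-bitscore protein hit below e-value 1e-5.

    Ties on bitscore break deterministically to the lexicographically
    smallest subject id, so the result is invariant to input order.
    Returns ("Unclassified", "") when no hit qualifies.
    """
    cfg = config or PipelineConfig()
    mine = [h for h in hits
            if h.query_id == peptide_id and h.evalue < cfg.nt_evalue_cutoff]
    if not mine:
        return "Unclassified", ""
    _kingdoms_for(mine, taxon_map)
    best = min(mine, key=lambda h: (-h.bitscore, h.subject_id))
    entry = taxon_map[best.subject_id]
    return entry["kingdom"], entry.get("genus", "")


def transfer_to_read(peptide_kingdoms: list[str]) -> str:
    """Transfer peptide kingdoms onto the read.

    All classified peptides agreeing on one kingdom transfer it (extra
    unclassified peptides do not interfere); two or more distinct kingdoms
    yield Mixed; no classified peptide yields Unclassified.  "Other" acts
    as a kingdom in the conflict test.
    """
    classified = {k for k in peptide_kingdoms if k != "Unclassified"}
    if not classified:
        return "Unclassified"
    if len(classified) == 1:
        return classified.pop()
    return "Mixed"


def categorize_reads(reads: list[Read], nt_hits: list[HitRecord],
                     annotations: pd.DataFrame, taxon_map: dict[str, dict],
                     config: PipelineConfig | None = None,
                     ) -> pd.DataFrame:
    """Per-read category via prescreen then peptide transfer.

    ``annotations`` is the peptide annotation table (columns peptide_id,
    read_id, kingdom, genus, ...); reads classified Eukaryota by the
    prescreen never consult it.  Returns a DataFrame (read_id, sample,
    category, genus).
    """
    cfg = config or PipelineConfig()
    hits_by_read: dict[str, list[HitRecord]] = defaultdict(list)
    for h in nt_hits:
        hits_by_read[h.query_id].append(h)
    peps_by_read: dict[str, list] = defaultdict(list)
    if len(annotations):
        for row in annotations.itertuples(index=False):
            peps_by_read[row.read_id].append(row)
    rows = []
    for r in reads:
        verdict = nucleotide_prescreen(r.id, hits_by_read.get(r.id, []),
                                       taxon_map, cfg)
        genus = ""
        if verdict == "Eukaryota":
            category = "Eukaryota"
        else:
            peps = peps_by_read.get(r.id, [])
            category = transfer_to_read([p.kingdom for p in peps])
            if category not in ("Mixed", "Unclassified"):
                genera = [p.genus for p in peps
                          if p.kingdom == category and p.genus]
                genus = genera[0] if genera else ""
        rows.append((r.id, r.sample, category, genus))
    return pd.DataFrame(rows, columns=["read_id", "sample", "category",
                                       "genus"])


def tabulate_kingdoms(categories: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate per-read categories into the per-sample count table.

    Rows are samples; columns are the seven categories plus Total.  Total
    equals the number of reads in the sample by construction.
    """
    table = (categories.groupby(["sample", "category"]).size()
             .unstack(fill_value=0)
             .reindex(columns=list(CATEGORIES), fill_value=0))
    table["Total"] = table.sum(axis=1)
    table.columns.name = None
    return table


def genus_profile(categories: pd.DataFrame, sample: str,
                  config: PipelineConfig | None = None,
                  ) -> tuple[pd.Series, float]:
    """Bacterial genus relative abundances and the long-tail share.

    The denominator is the genus-labelled bacterial reads of the sample
    (reads without genus resolution are excluded); the tail share is the
    summed abundance of genera individually below the 2% cutoff (strict).
    """
    cfg = config or PipelineConfig()
    sub = categories[(categories["sample"] == sample)
                     & (categories["category"] == "Bacteria")
                     & (categories["genus"] != "")]
    if not len(sub):
        return pd.Series(dtype=float), 0.0
    abundance = (sub["genus"].value_counts() / len(sub)).sort_values(
        ascending=False)
    tail = float(abundance[abundance < cfg.genus_tail_cutoff / 100.0].sum())
    return abundance, tail
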