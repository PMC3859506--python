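"""Readers and writers for the pipeline's external formats.

FASTA/FASTQ go through Biopython; the twelve-column tabular alignment
dialect, 3-column BED masks and the small TSV annotation tables are parsed
by hand because their error contracts (line-numbered parse errors) matter to
the pipeline.

Normalization on sequence ingest: lowercase bases are upper-cased, U becomes
T, and any ambiguity symbol other than N becomes N; each is logged once per
file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from Bio import SeqIO

from .core import HitRecord, MaskInterval, ParseError, PipelineConfig, Read

logger = logging.getLogger("aerobiome")

_VALID = set("ACGTN")


def _normalize_seq(seq: str, stats: dict) -> str:
    s = seq.upper()
    if s != seq:
        stats["lowercased"] += 1
    s = s.replace("U", "T")
    if set(s) - _VALID:
        cleaned = [c if c in _VALID else "N" for c in s]
        stats["ambiguous"] += sum(1 for a, b in zip(s, cleaned) if a != b)
        s = "".join(cleaned)
    return s


def read_sequences(path, format: str = "fasta", sample: str = "") -> list[Read]:
    """Read a FASTA or FASTQ file into a list of :class:`Read`.

    Record ids are kept verbatim up to the first whitespace and input order
    is preserved.  An empty file yields an empty list; a malformed record
    raises :class:`ParseError` naming the file.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    stats = {"lowercased": 0, "ambiguous": 0}
    reads = []
    try:
        for rec in SeqIO.parse(str(path), format):
            seq = _normalize_seq(str(rec.seq), stats)
            reads.append(Read(rec.id, seq, sample))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if stats["lowercased"]:
        logger.info("%s: upper-cased %d records", path, stats["lowercased"])
    if stats["ambiguous"]:
        logger.info("%s: replaced %d non-N ambiguity bases with N",
                    path, stats["ambiguous"])
    return reads


def write_sequences(reads, path) -> None:
    """Write reads as single-line-sequence FASTA (round-trip stable)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.seq}\n")


def read_hit_table(path) -> list[HitRecord]:
    """Parse a twelve-column tab-separated local-alignment table.

    Columns: query, subject, %identity, alignment length, mismatches, gap
    opens, q_start, q_end, s_start, s_end, e-value, bitscore.  A subject
    interval with start > end encodes a minus-strand match; it is normalized
    to start <= end with ``strand="minus"``.

    Raises :class:`ParseError` naming the line on a wrong column count or a
    non-numeric numeric field.  An empty file yields an empty list.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
            try:
                q, s = fields[0], fields[1]
                ident = float(fields[2])
                alen = int(fields[3])
                mism = int(fields[4])
                gaps = int(fields[5])
                qs, qe = int(fields[6]), int(fields[7])
                ss, se = int(fields[8]), int(fields[9])
                ev = float(fields[10])
                bs = float(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            strand = "plus"
            if ss > se:
                ss, se = se, ss
                strand = "minus"
            try:
                hits.append(HitRecord(q, s, ident, alen, mism, gaps,
                                      qs, qe, ss, se, ev, bs, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hit_table(hits, path) -> None:
    """Serialize hits back to the twelve-column dialect.

    Minus-strand matches are written with swapped subject coordinates, the
    dialect's own convention, so read → write → read is the identity.
    """
    with open(path, "w") as fh:
        for h in hits:
            ss, se = (h.s_end, h.s_start) if h.strand == "minus" else (h.s_start, h.s_end)
            fh.write("\t".join(map(str, (
                h.query_id, h.subject_id, h.pct_identity, h.aln_length,
                h.mismatches, h.gap_opens, h.q_start, h.q_end, ss, se,
                h.evalue, h.bitscore))) + "\n")


def read_bed_masks(path) -> list[MaskInterval]:
    """Read 3-column BED (0-based half-open) mask intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                out.append(MaskInterval(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_taxon_map(path) -> dict[str, dict]:
    """Read a subject→taxonomy TSV (subject_id, kingdom, phylum, genus).

    The kingdom column accepts the four kingdom names plus the explicit
    ``Other`` token for unidentifiable/synthetic subjects.  Header row
    optional (detected by a ``subject_id`` first field).
    """
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "subject_id":
                continue
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns")
            out[fields[0]] = {
                "kingdom": fields[1],
                "phylum": fields[2] if len(fields) > 2 else "",
                "genus": fields[3] if len(fields) > 3 else "",
            }
    return out


def load_config(path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a JSON or YAML file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        data = yaml.safe_load(text) or {}
    else:
        data = json.loads(text)
    return PipelineConfig.from_dict(data)
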