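"""Pipeline driver and the summary arithmetic over kingdom count tables.

"Assigned" means Total − Unclassified: Mixed and Other rows count as
assigned, since those reads did match reference sequences.  Percentages are
rendered by half-up rounding at the printed precision; raw unrounded values
are always kept alongside.  The mean assignment percentage is the
unweighted mean of the per-sample percentages, not a pooled ratio.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .core import CATEGORIES, PipelineConfig, gc_fraction
from . import align, chimera, gcmix, qc, synthetic, taxonomy
from .io import write_hit_table, write_sequences

logger = logging.getLogger("aerobiome")

KINGDOM_COLS = [c for c in CATEGORIES if c != "Unclassified"]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero at the given decimal precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AssignmentSummary:
    per_sample: pd.DataFrame      # raw values
    mean_assigned_pct: float      # unweighted over samples, raw
    grand_total: int

    def rendered(self, ndigits: int = 0) -> pd.DataFrame:
        """Half-up-rounded copy of the percentage columns."""
        out = self.per_sample.copy()
        for col in out.columns:
            if col.endswith("_pct"):
                out[col] = out[col].map(lambda v: round_half_up(v, ndigits))
        return out


def assignment_summary(table: pd.DataFrame) -> AssignmentSummary:
    """Per-sample assignment percentages from a kingdom count table.

    ``table`` has samples as rows and the seven category columns plus
    Total.  assigned = Total − Unclassified; each kingdom's percentage is
    taken of the assigned reads.
    """
    if (table["Total"] == 0).any():
        bad = table.index[table["Total"] == 0].tolist()
        raise ValueError(f"samples with zero reads: {bad}")
    per = pd.DataFrame(index=table.index)
    per["total"] = table["Total"]
    per["assigned"] = table["Total"] - table["Unclassified"]
    per["assigned_pct"] = 100.0 * per["assigned"] / per["total"]
    for k in KINGDOM_COLS:
        per[f"{k}_pct"] = 100.0 * table[k] / per["assigned"]
    return AssignmentSummary(per, float(per["assigned_pct"].mean()),
                             int(table["Total"].sum()))


def grand_total(tables: list[pd.DataFrame]) -> int:
    """Total reads across samples (sum of the per-table totals)."""
    return int(sum(int(t["Total"].sum()) for t in tables))


def chimera_percent(flagged: int, total: int) -> float:
    """Flagged fraction as a percentage, one decimal, half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= flagged <= total:
        raise ValueError("flagged must lie in [0, total]")
    return round_half_up(100.0 * flagged / total, 1)


def run_pipeline(config: dict, outdir) -> dict:
    """Synthetic-mode end-to-end run: simulate → qc → chimera → taxonomy →
    gcmix → functional → report.

    ``config`` keys: seed; n_reads; rates (replicate/chimera/lowcomp);
    hit_fraction and noise_fraction for the fabricated annotation tables;
    optional thresholds overriding :class:`PipelineConfig` defaults.
    Outputs (FASTA, TSV, JSON) land in ``outdir``; the returned manifest
    records the seed, thresholds and the per-stage read-count ledger, which
    telescopes from raw input to the final table total.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig.from_dict(config)
    seed = int(config.get("seed", 0))
    n_reads = int(config.get("n_reads", 2000))
    sample = config.get("sample", "S1")

    spec = config.get("community") or synthetic.default_community()
    genomes = synthetic.generate_genomes(spec, seed)
    reads, truth = synthetic.simulate_reads(spec, genomes, n_reads, seed + 1,
                                            sample=sample)
    reads, truth = synthetic.inject_artifacts(
        reads, truth, genomes, seed + 2,
        replicate_rate=float(config.get("replicate_rate", 0.0)),
        chimera_rate=float(config.get("chimera_rate", 0.0)),
        lowcomp_rate=float(config.get("lowcomp_rate", 0.0)))
    write_sequences(reads, outdir / "reads.fasta")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    ledger = {"raw": len(reads)}

    kept, qc_outcomes = qc.run_qc_stage(reads, cfg)
    pd.DataFrame([vars(o) for o in qc_outcomes]).to_csv(
        outdir / "qc_outcomes.tsv", sep="\t", index=False)
    ledger["after_qc"] = len(kept)

    hits = align.all_vs_all(kept, min_len=cfg.pattern_min_hit_len)
    write_hit_table(hits, outdir / "all_vs_all.tsv")
    kept, verdicts = chimera.run_chimera_stage(kept, hits, cfg)
    pd.DataFrame([{"read_id": v.read_id, "status": v.status,
                   **{f"ev_{k}": val for k, val in v.evidence.items()}}
                  for v in verdicts]).to_csv(
        outdir / "chimera_verdicts.tsv", sep="\t", index=False)
    ledger["after_chimera"] = len(kept)
    write_sequences(kept, outdir / "clean_reads.fasta")

    nt_hits, annotations, taxon_map = synthetic.fabricate_hit_tables(
        kept, truth, seed + 3,
        hit_fraction=float(config.get("hit_fraction", 0.9)),
        noise_fraction=float(config.get("noise_fraction", 0.0)))
    write_hit_table(nt_hits, outdir / "nt_hits.tsv")
    annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    categories = taxonomy.categorize_reads(kept, nt_hits, annotations,
                                           taxon_map, cfg)
    categories.to_csv(outdir / "read_categories.tsv", sep="\t", index=False)
    table = taxonomy.tabulate_kingdoms(categories)
    table.to_csv(outdir / "kingdom_counts.tsv", sep="\t")
    ledger["final_table_total"] = int(table["Total"].sum())

    # GC mixture of the unclassified reads against the classified groups
    gc_by_read = {r.id: gc_fraction(r.seq) for r in kept}
    cat_of = dict(zip(categories["read_id"], categories["category"]))
    groups = {"U": [], "E": [], "PV": []}
    for rid, g in gc_by_read.items():
        cat = cat_of[rid]
        if cat == "Unclassified":
            groups["U"].append(g)
        elif cat == "Eukaryota":
            groups["E"].append(g)
        elif cat in ("Archaea", "Bacteria", "Viruses"):
            groups["PV"].append(g)
    mixture = None
    if all(len(v) for v in groups.values()):
        res = gcmix.GCMixtureModel(groups["U"], groups["E"],
                                   groups["PV"]).fit()
        res.curve.to_csv(outdir / "gcmix_curve.tsv", sep="\t", index=False)
        mixture = {"p": res.p, "kl": res.kl_at_p,
                   "n": {k: len(v) for k, v in groups.items()}}
        (outdir / "gcmix.json").write_text(
            json.dumps(mixture, indent=2, sort_keys=True))

    from . import functional
    bact = annotations[annotations["kingdom"] == "Bacteria"]
    mean_len = {sample: float(pd.Series([r.length for r in kept]).mean())}
    functional_summary = {}
    if len(bact):
        for mode in ("raw", "length_normalized"):
            mat = functional.ko_abundance(bact, mean_len, mode=mode)
            mat.to_csv(outdir / f"ko_abundance_{mode}.tsv", sep="\t")
        functional_summary["n_ko_peptides"] = int(bact["ko"].astype(bool).sum())

    summary = assignment_summary(table)
    summary.per_sample.to_csv(outdir / "assignment_summary.tsv", sep="\t")
    manifest = {
        "seed": seed,
        "config": cfg.to_dict(),
        "ledger": ledger,
        "mean_assigned_pct": summary.mean_assigned_pct,
        "grand_total": summary.grand_total,
        "gc_mixture": mixture,
        "functional": functional_summary,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
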