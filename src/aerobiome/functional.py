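"""Functional (KO/COG) profiling of the bacterial peptides.

Per-sample abundances of KEGG Orthologs are computed two ways: ``raw``
(peptide counts) and ``length_normalized``, where each KO-assigned peptide
contributes weight 1 / (L_gene + L̄_read − 1), with L_gene the subject
gene's length in nucleotides (3 × its amino-acid length) and L̄_read the
sample's mean read length in bases — the number of read start positions
that can overlap the gene.  This removes the bias whereby longer genes, and
samples with longer reads, collect more peptide hits.  Weighted sums are
divided by the sample's total weight, so a normalized profile is a relative
abundance vector summing to 1.

KO abundances roll up into KEGG functional categories (a KO may belong to
several; it contributes to each), sample profiles are compared by Pearson
correlation, and samples are ordinated by column-centered PCA on the KO
profiles with top-loading KOs extracted per axis.  COGs reuse the same code
path with a COG→functional-class map.  Resistance/virulence matches pass a
stringent inclusive filter: >= 90% identity over >= 90% of the peptide
length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger("aerobiome")


def ko_abundance(annotations: pd.DataFrame,
                 mean_read_length: dict[str, float],
                 mode: str = "length_normalized",
                 feature: str = "ko") -> pd.DataFrame:
    """Per-sample KO (or COG) abundance matrix (rows samples, columns ids).

    ``annotations`` needs columns sample, ``feature`` and, in normalized
    mode, gene_len_aa; ``mean_read_length`` maps each sample to its mean
    read length in bases.  Raw mode returns plain peptide counts; normalized
    mode returns relative abundances (rows sum to 1).  Samples with no
    assigned peptide are excluded (logged).
    """
    if mode not in ("raw", "length_normalized"):
        raise ValueError(f"unknown mode {mode!r}")
    ann = annotations[annotations[feature].astype(bool)].copy()
    if mode == "length_normalized":
        missing = ann[~(ann["gene_len_aa"] > 0)]
        if len(missing):
            raise ValueError(
                "missing subject gene lengths for: "
                + ", ".join(sorted(set(missing["peptide_id"].astype(str)))[:20]))
        lbar = ann["sample"].map(mean_read_length)
        ann["weight"] = 1.0 / (3.0 * ann["gene_len_aa"] + lbar - 1.0)
    else:
        ann["weight"] = 1.0
    mat = (ann.groupby(["sample", feature])["weight"].sum()
           .unstack(fill_value=0.0))
    empty = mat.index[mat.sum(axis=1) == 0]
    if len(empty):
        logger.warning("samples with no %s-assigned peptides excluded: %s",
                       feature, list(empty))
        mat = mat.drop(index=empty)
    if mode == "length_normalized":
        mat = mat.div(mat.sum(axis=1), axis=0)
    mat.columns.name = None
    mat.index.name = "sample"
    return mat


def category_rollup(matrix: pd.DataFrame,
                    ko_to_categories: dict[str, list[str]]) -> pd.DataFrame:
    """Sum KO abundances into category abundances, renormalized per row.

    A KO mapping to several categories contributes once to each; KOs absent
    from the map accumulate under ``unmapped`` (logged).
    """
    cols: dict[str, np.ndarray] = {}
    unmapped = np.zeros(len(matrix))
    n_unmapped = 0
    for ko in matrix.columns:
        cats = ko_to_categories.get(ko)
        if not cats:
            unmapped += matrix[ko].to_numpy()
            n_unmapped += 1
            continue
        for cat in cats:
            cols[cat] = cols.get(cat, np.zeros(len(matrix))) + matrix[ko].to_numpy()
    if n_unmapped:
        logger.info("category rollup: %d KOs not in the map -> 'unmapped'",
                    n_unmapped)
        cols["unmapped"] = unmapped
    out = pd.DataFrame(cols, index=matrix.index)
    out = out.div(out.sum(axis=1), axis=0)
    return out


def profile_correlation(matrix: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Pearson correlations between sample profiles and their pairwise mean.

    Constant profiles have undefined correlations; such pairs are excluded
    from the mean (logged).  Requires at least two samples.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 samples")
    X = matrix.to_numpy(dtype=float)
    stds = X.std(axis=1)
    with np.errstate(invalid="ignore"):  # constant rows yield NaN, handled
        corr = pd.DataFrame(np.corrcoef(X), index=matrix.index,
                            columns=matrix.index)
    vals = []
    samples = list(matrix.index)
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            if stds[i] == 0 or stds[j] == 0:
                logger.warning("constant profile pair (%s, %s) excluded",
                               samples[i], samples[j])
                continue
            vals.append(corr.iloc[i, j])
    mean = float(np.mean(vals)) if vals else float("nan")
    return corr, mean


@dataclass(frozen=True)
class OrdinationResult:
    scores: pd.DataFrame             # samples x PCs
    variance_fractions: np.ndarray   # per PC, non-increasing
    top_loadings: list[pd.Series]    # per PC, top-|loading| features


def pca_ordination(matrix: pd.DataFrame, n_top: int = 10,
                   ) -> OrdinationResult:
    """Column-centered (unscaled) PCA of the abundance matrix.

    Loadings follow a deterministic sign convention (the largest-|loading|
    entry of each component is positive) so top-loading lists are stable.
    Requires at least three samples.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 samples for ordination")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 features")
    pca = PCA(n_components=min(len(matrix) - 1, matrix.shape[1]))
    scores = pca.fit_transform(matrix.to_numpy(dtype=float))
    components = pca.components_
    for c in range(components.shape[0]):
        k = int(np.argmax(np.abs(components[c])))
        if components[c, k] < 0:
            components[c] = -components[c]
            scores[:, c] = -scores[:, c]
    pcs = [f"PC{i + 1}" for i in range(components.shape[0])]
    tops = []
    for c in range(components.shape[0]):
        load = pd.Series(components[c], index=matrix.columns, name=pcs[c])
        tops.append(load.reindex(load.abs().sort_values(ascending=False)
                                 .index[:n_top]))
    return OrdinationResult(
        pd.DataFrame(scores, index=matrix.index, columns=pcs),
        pca.explained_variance_ratio_.copy(), tops)


def stringent_match_filter(hits: pd.DataFrame,
                           min_identity: float = 90.0,
                           min_coverage: float = 90.0) -> pd.DataFrame:
    """Keep resistance/virulence matches at >=90% identity over >=90% of the
    peptide length (both inclusive).

    ``hits`` needs columns pct_identity and pct_coverage (percent of the
    peptide length covered by the match).
    """
    if not len(hits):
        return hits
    keep = (hits["pct_identity"] >= min_identity) & \
           (hits["pct_coverage"] >= min_coverage)
    return hits[keep]
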