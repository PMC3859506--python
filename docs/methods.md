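# Methods

This note documents the models and procedures the package implements, the
parameter choices behind them, what the synthetic data do and do not
emulate, and the numerical decisions a maintainer would want explained.

## Read quality control

**Artificial replicates.** Pyrosequencing of amplified low-input DNA
produces near-identical reads sharing a start position, which inflate
abundances if kept.  The published method names replicate removal without an
algorithmic definition, so the package uses the standard 454-replicate rule:
two reads are replicates when (i) their first 3 bases agree, (ii) the
shorter read aligns globally to the prefix of the longer at ≥ 90% identity
(edlib edit distance), and (iii) the length difference is ≤ 10% of the
longer read.  Groups are transitive closures of the pair relation; the
longest member (ties: lexicographically smallest id) represents the group.
All three parameters are configurable (`replicate_prefix`,
`replicate_min_identity`, `replicate_max_len_diff`).

**Low-complexity masking.** The triplet-counting masker is a windowed
symmetric-DUST variant: every window of 64 bases is scored
`10 · Σ_t c_t(c_t−1)/2 / (l−1)` over its triplet counts `c_t` (`l` triplets
counted, N-containing triplets skipped) and masked whole when the score
exceeds the level (default 20, the widespread default); masked windows are
merged.  This is a deliberate simplification of the perfect-interval
algorithm: it can overmask flanks by up to one window around a short
low-complexity core, which is conservative with respect to the downstream
>50% drop rule.  A pure dinucleotide repeat scores ≈ 150 (masked); a
uniform random window scores ≈ 5 (not masked), so the decision margin is
wide.

**Repeat masking.** Repeat masks are consumed as BED intervals from any
external masker; when only a repeat-library FASTA is available, a built-in
screen (exact 15-mer seeds, ungapped extension, matches ≥ 50 bases at ≥ 80%
identity) produces the intervals.  The screen is a declared stand-in, not a
claim of equivalence to a full repeat-masking tool.

**Drop rule.** A read is dropped when the union length of its mask
intervals strictly exceeds 50% of the read length.  Union (not summed
overlapping lengths) is used; the boundary is strict, so a read masked
exactly half survives.

## Chimera detection

phi29 multiple displacement amplification of picogram DNA inputs creates
chimeric molecules via branch migration; the sequenced rearrangements come
as inverted sequences and transposed direct sequences, and in both cases the
junction region is duplicated — in reverse complement for the inverted
class.  Four rules run in order, each read keeping the first status that
fires (repeat → propagated → vote):

1. **Internal repeats.** A read containing an exact repeat of ≥ 25 bases —
   a substring occurring at two distinct positions, or one whose reverse
   complement occurs elsewhere in the read — is flagged.  The scan is
   k-mer-exact (a repeated block of length ≥ 25 exists iff a repeated 25-mer
   exists), with greedy extension to report the maximal block; a brute-force
   all-substring-pair comparator is kept as the test oracle.  "Reverse
   direction" means reverse complement by default (the branch-migration
   product); plain reversal is available behind
   `reverse_repeat_is_revcomp=False`.
2. **Propagation.** Any read with a > 90%-identity hit covering > 95% of
   *its own* (query) length to a rule-1 read is flagged.  Both inequalities
   are strict, and the pass is single — the published wording describes one
   extension step, not a fixpoint iteration.
3. **Pair patterns.** For every read pair sharing filtered hits
   (alignment ≥ 25 bases, e-value ≤ 1e-5), the two highest-bitscore hits
   that do not overlap on the query decide a pattern: *transposed-direct*
   when both hits are plus-strand and the query-interval order reverses the
   subject-interval order; *inverted* when strands differ and the subject
   intervals overlap or lie within 100 bases; *collinear* when order and
   strand are consistent (a single hit is collinear); *ambiguous* otherwise.
   The geometry constants (25, 1e-5, 100) are not part of the published
   description; they are configurable and logged.
4. **Neighbor vote.** A remaining read is flagged when strictly more of its
   hit-sharing neighbors show a chimeric pattern than a non-chimeric one
   (ties are not flagged).  Already-flagged reads still count in other
   reads' neighbor censuses.  The vote presumes chimeras are a minority of
   reads; a RuntimeWarning fires when more than 30% of reads end up
   flagged.

The all-vs-all hit table can come from any producer of the twelve-column
dialect; the built-in seed-and-extend matcher (15-mer seeds, ungapped
Kadane-style extension per diagonal, bitscore `2·matches − 3·mismatches`,
e-value `qlen·slen·2^(−bitscore)`) exists so the pipeline and its tests run
without an external search binary.  It is exact-match-oriented and not a
substitute for a rigorous local aligner on diverged sequences — but the
chimera rules operate on near-identical intra-sample matches, where the two
agree.

## Taxonomy

The prescreen retains at most ten nucleotide hits per read, ranked by
bitscore, with e-value strictly below 1e-5; a read whose retained subjects
are all eukaryotic is Eukaryota outright and never reaches the peptide
path.  Bitscore ranking (rather than e-value) is a choice; the two orders
rarely differ and the cutoff dominates.  Peptides from the remaining reads
carry the kingdom of their best-bitscore protein hit (best-hit, not
lowest-common-ancestor — the simplest reading of annotation transfer), with
bitscore ties broken by lexicographic subject id so results are
input-order-invariant.  Kingdom transfer onto reads: one consistent kingdom
transfers (unclassified peptides do not interfere); conflicting kingdoms
give Mixed, with the `Other` token (unidentifiable/synthetic subjects)
acting as a kingdom in the conflict test; no classified peptide gives
Unclassified.

The built-in peptide caller is a declared stand-in (six-frame longest
stop-free ORFs ≥ 60 aa, deterministic, strand-symmetric), not a
frameshift-aware gene finder; real annotation tables can be supplied
instead via the peptide-annotation TSV.

Genus profiles use genus-labelled bacterial reads as the denominator (reads
without genus resolution are excluded, recorded in output metadata); the
long-tail share sums the relative abundances of genera individually below
2% (strict).

## GC mixture model

U, E and PV are %(G+C) histograms on 101 integer-percent bins (bin *i*
covers [i, i+1)%, bin 100 is the point 100%).  GC fractions count G+C over
A+C+G+T only; N and other ambiguity codes are excluded from numerator and
denominator, and all-N reads are dropped from the histograms (the published
method is silent on ambiguity handling; this choice is recorded in output
metadata).  The mixture X = p·E + (1−p)·PV is fitted by exhaustive grid
search over p ∈ {0, 0.001, …, 1} minimizing the symmetric Kullback–Leibler
distance Σᵢ (pᵢ−qᵢ)·ln(pᵢ/qᵢ), with natural logarithms (the argmin is
base-independent), a pseudocount of 1e-9 per bin followed by
renormalization (keeps the objective finite on empty bins), and ties
resolving to the smallest p.  The 0.001 grid makes two-decimal estimates
stable; the full objective curve is returned for audit.  When
D(E, PV) < 0.05 the components are effectively identical and a warning
marks p as unidentifiable.

On well-separated components (the default beta components have means 0.38
and 0.60, sd ≈ 0.05) the tests require recovery within ±0.02 at n = 50 000
across the 0.1–0.9 range, with exact recovery at the boundaries p = 0 and
p = 1.  Real E/PV distributions are closer and multimodal, so real-data
estimates carry more uncertainty than the synthetic recovery suggests.

## Functional profiling

In length-normalized mode each KO-assigned peptide contributes weight
1 / (L_gene + L̄_read − 1), with L_gene = 3 × the subject gene length in
amino acids (nucleotides) and L̄_read the sample's mean read length in
bases: the count of start positions at which a read can overlap a gene,
which is the quantity raw counts are proportional to.  Dividing by it
removes both the gene-length bias within a sample and the read-length bias
between samples; weighted sums are then divided by the sample total, so
rows are relative abundances summing to 1.  Raw counts are emitted
alongside, since both variants are legitimate summaries.  Category rollups
sum member-KO abundances (a KO in several categories contributes to each;
unmapped KOs pool under `unmapped`) and renormalize.

Ordination is column-centered, variance-unscaled PCA (scikit-learn) on the
KO matrix, with an eigendecomposition of the feature covariance kept as an
independent test oracle (agreement to 1e-8).  Loadings follow a
deterministic sign convention — the largest-|loading| entry of each
component is positive — so top-loading lists are reproducible.  The
resistance/virulence filter is inclusive on both thresholds (≥ 90%
identity, ≥ 90% peptide coverage), in contrast to the strict inequalities
of the chimera propagation rule; the tests pin both boundary semantics.

## Report arithmetic

"Assigned" is Total − Unclassified: Mixed and Other count as assigned since
those reads did match references.  Kingdom shares are percentages of
assigned reads; the mean assignment percentage is the unweighted mean of
per-sample percentages (not a pooled ratio).  Percentages render by half-up
rounding at the printed precision, with raw values always stored alongside.
Note the source tables this arithmetic was validated against contain two
internal rounding inconsistencies (a bacterial share computing to 81.7% but
printed as 81%, and an amplicon chimera rate computing to 2.294% but
printed as 2.2%); the package keeps consistent half-up rendering rather
than reproducing either printed figure.

## Synthetic data: what it emulates, and what it does not

The generator produces iid-base genomes whose per-base GC probability
equals the target (realized GC concentrates within ±0.02), truncated-normal
read lengths (mean 350, sd 80, minimum 50 bases — the 454 FLX/Titanium
regime), uniform read starts weighted by community abundance, exact-or-
truncated replicate copies, both chimera classes with intra-genome local
junctions (duplicated junction block configurable, ≥ 25 bases by default
with a `sub25_block_fraction` for hard cases; the transposed-direct class
also duplicates its junction by default, mirroring the branch-migration
mechanism), injected dinucleotide low-complexity stretches, two-component
beta GC mixtures with labels, and hit/annotation tables consistent with
truth plus a controllable conflicting-kingdom noise fraction.

It does **not** emulate homopolymer/flowgram sequencing errors, real
genomic repeat structure or taxonomic marker genes, GC-skewed
amplification bias, or inter-genome homology.  Consequently the tests
demonstrate correctness of the *rules* (boundary semantics, truth recovery
under the generator's assumptions) — they do not certify field performance
on real airborne metagenomes, where eukaryotic repeats make the
internal-repeat rule deliberately conservative and where real E/PV GC
distributions overlap more than the synthetic components.

Sequencing error is off by default because none of the implemented filters
is error-driven; the replicate rule tolerates 10% divergence regardless.

## Problem sizes and determinism

Every generator is a pure function of (spec, seed); one seeded NumPy
generator per operation, derived from the run seed, makes pipeline reruns
byte-identical.  The test suite exercises the chimera detector at 5 000
reads (≈ 8× coverage of a 210 kb community), the rule-equivalence oracle at
200 reads, and mixture recovery at n = 50 000 over 180 seeded runs; the
acceptance script uses 3 000 reads and 45 mixture runs.  These sizes make
the binomial checks well-powered while keeping a full run in tens of
seconds.

## Known limitations

- The built-in matcher, ORF caller, DUST variant and repeat screen are
  stand-ins with documented simplifications; external tools can replace
  each through the file interfaces (twelve-column hit tables, BED masks,
  annotation TSVs).
- Propagation uses the query's length for the >95% coverage test; the
  published wording is ambiguous about which sequence's length is meant.
- The internal-repeat rule flags genuine biological repeats (acknowledged
  as conservative); no attempt is made to rescue them.
- Mixture decomposition is strictly two-component and binned; per-taxon
  GC deconvolution and EM on unbinned values are out of scope.
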