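# Methods

## Redundancy clustering

Mature miRNA reference sets aggregate many species' orthologs of the same
family; before homology search the set is collapsed by greedy incremental
clustering in the style of CD-HIT. Sequences are processed sorted by
(length descending, id ascending); each joins the first existing cluster
whose representative it matches at identity ≥ the threshold (default 0.90),
otherwise it seeds a new cluster. Because of the processing order the
representative is always the longest member (ties: lexicographically
smallest id), and re-clustering the representatives yields only singletons.

**Identity definition.** Identity follows the CD-HIT convention — identical
alignment columns divided by the length of the shorter sequence — under a
semi-global alignment of the shorter onto the longer: end gaps on the longer
are free, matches score 1, mismatches 0, and each internal gap column costs
0.5. Among maximum-score alignments the one with fewest gap columns defines
the result; the match count is then fully determined as M = S + G/2 (score
S, gap columns G), which makes the metric symmetric and independent of
traceback order. The gap penalty is chosen so that a substitution is never
"re-aligned around" with an insertion/deletion pair (which would otherwise
inflate the identity of any two sequences differing by substitutions only).
No k-mer pre-filter is applied: at the scale this package targets
(10³–10⁴ short sequences) full pairwise comparison against cluster
representatives is fast, and a screen could only be added if it provably
left the partition unchanged.

## Homology search

The search is exact rather than heuristic. For the default parameters —
no gaps, full query coverage — every placement of the miRNA on the gene
(both strands) is scored by Hamming distance via a vectorized sliding
window, which is the exact optimum of that restricted alignment problem.
When gaps are allowed, a hand-written Smith–Waterman with affine gaps
(match +1, mismatch −1, gap open −2, extend −1) is used, with a
deterministic traceback (optimal end cell with the smallest subject
coordinate; diagonal preferred over gaps on ties). One best hit per
(miRNA, gene) pair is kept; the default thresholds — ≤ 4 mismatches, 0
gaps, 100 % query coverage — reflect standard homology-based plant miRNA
prediction practice and are all configurable.

E-values use the ungapped Karlin–Altschul formula E = K·m·n·e^(−λS) with m
the query length and n the total searched length (both strands). λ is
solved numerically from Σᵢⱼ pᵢpⱼ e^(λ·sᵢⱼ) = 1 at uniform base composition
(for +1/−1 scoring the root is exactly ln 3); K defaults to 0.1 and is
configurable, since K only shifts E-values by a constant factor and the
pipeline's decisions are mismatch-count based.

## Coding filter

Putative precursor loci must be non-coding. Each candidate window is
translated in all six frames (standard genetic code); internal stop codons
split the translation into segments (≥ 8 aa) that are aligned independently
against the protein reference with a local BLOSUM62 alignment (gap open 11,
extend 1, via Biopython's PairwiseAligner). The best raw score is converted
with the gapped BLOSUM62 parameters (λ = 0.267, K = 0.041); a candidate
with any translated hit at E ≤ 1e−10 is discarded. With no protein
reference supplied the filter is skipped and all candidates are retained,
flagged accordingly.

## Precursor extraction and folding

Windows are cut around each hit at several flank sizes (default 60, 100,
150, 250 nt) in three modes — upstream-only, downstream-only, symmetric —
so the mature sequence can land on either hairpin arm. Windows clipped at
a gene boundary are kept and flagged. Minus-strand hits are reverse
complemented with the mature span re-expressed in precursor coordinates.

The internal folding model is a deliberately simple, fully specified
dynamic program: maximize pairing stability over nested structures with
Watson–Crick and GU wobble pairs, per-pair energies GC −3, AU −2,
GU −1 kcal/mol, a minimum hairpin loop of 3 nt, and no loop terms. It is
deterministic (ties: position left unpaired, then smallest pairing
partner) and is verified against exhaustive enumeration of all structures
for sequences up to 12 nt. Its energies are **not** comparable to
Turner-model folders (MFOLD, RNAfold); when thermodynamic realism matters,
externally computed folds can be supplied as Vienna dot-bracket files (or
CT files) and are used instead. All derived statistics (AMFE, MFEI) are
pure arithmetic on whatever energy is attached, so published MFE values
can be fed straight through the same code path.

## Hairpin screening

Eight criteria gate a folded candidate: (1) precursor length ≥ 60 nt;
(2) a stem-loop fold exists (an apical loop reachable from the mature
span); (3) the mature sits entirely in one arm — at or before the apical
loop midpoint is 5p, after it is 3p, and straddling fails; (4) at most 6
mature positions are mismatched in the miRNA/miRNA\* duplex, counting
positions unpaired or paired into their own arm (bulges on the star arm do
not count); (5) no multibranch loop between the duplex's outermost pair
and the apical loop — internal loops and bulges are allowed, they are what
criterion 4 counts; (6) A+U content within 30–70 %; (7) negative MFE; and
(8) an MFEI floor (default 0.85). The floor is advisory by default
(`criteria-mode report-only`) because the literature calls only for "high"
MFEI without a universal cutoff, and because published screens have
retained candidates that failed individual criteria; `--criteria-mode
strict` folds it into the pass/fail gate.

**Helix topology filter.** For the topology-dependent criteria (apical
loop, arm, branching) helices shorter than 3 stacked pairs are ignored: the
simplified maximum-pairing model happily decorates a structure with 1–2
pair micro-stems that no thermodynamic folder would keep (they cost more
entropy than they gain), and counting them as branches or loops would make
the screen reject essentially every real hairpin embedded in genomic
context. The full pair table is still used for the duplex mismatch count,
where an unstacked pair simply fails to protect its position.

**Rounding.** All table statistics are rounded half-up to 2 decimals, the
presentation convention of the field's summary tables. Single-base
percentages are count/length × 100; A/U and G/C ratios are ratios of the
rounded percentages; the combined (A+U)% and (G+C)% are computed from raw
counts and then rounded. Undefined ratios (zero U or C count) and an
undefined MFEI (zero GC) are reported as NA, never as infinities.

## Expression (2^−ΔΔCt)

Within each condition, ΔCt = Ct(gene) − Ct(reference gene) per replicate;
ΔΔCt = mean ΔCt(condition) − mean ΔCt(control); fold = 2^−ΔΔCt, which is 1
exactly in the control condition by construction. The SD is reported on
the fold scale from per-replicate folds (replicate ΔCt against the control
mean), with the log-scale SD alongside. Significance is a two-sided
two-sample t-test on replicate ΔCt values, Welch by default (a robust
default when condition variances differ; `--equal-var` restores the pooled
version), at p ≤ 0.05. When both groups have zero variance the p-value is
1 for equal means and 0 otherwise. Technical replicates, when annotated,
are averaged into biological units before testing (a helper is provided;
the default table format treats each row as one replicate). The
inverse-pattern report labels a miRNA/target pair per condition "inverse"
when both members are significant with opposite directions, "concordant"
when both significant in the same direction, and "ns" otherwise.

## Synthetic data

The generators emit inputs with the statistical structure each stage
assumes, plus machine-readable ground truth:

- **miRNA reference**: 10 families × 3 members by default, lengths
  20–24 nt, members within 90 % identity of their family seed and seeds
  mutually below 70 % — so clustering at 0.90 provably recovers the
  families. Member ids sort after the seed id, making the seed the
  representative.
- **gene family**: 8 genes × 600 nt of uniform-composition background with
  planted homologs (0–6 substitutions, either strand) at recorded
  positions. With `hairpin_context` the mature copy is planted together
  with a star strand and a short non-pairing loop (star–loop–mature), so
  extracted windows can fold into a screening-grade hairpin; the star
  carries one GU-wobble substitution, which keeps the duplex fully paired
  under the folding model while leaving the mature copy the strictly best
  search hit.
- **hairpins**: a symmetric stem with an exact A+U budget, the mature span
  placed on the requested arm, and exactly k planted duplex mismatches
  (star positions replaced by a same-class non-pairing base, preserving
  composition).
- **Ct tables**: gene Cts shifted by −log₂(fold) from a fixed baseline,
  Gaussian noise (default σ = 0.1) on every well including the reference
  gene, ≥ 2 replicates. With zero noise the ΔΔCt estimator returns the
  planted folds exactly; at σ = 0.1 and 3 replicates the mean recovered
  fold is within 10 % of truth over 100 simulations.

One integer seed drives a separate fixed-offset stream per generator, so
adding a generator never perturbs another's output and identical seeds give
byte-identical files.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: realistic genome composition, repeats and gene
structure; Turner-model folding energies; amplification-efficiency
variation or technical-replicate correlation structure in qPCR; and
database-scale reference sets (the generators run at desk scale: tens of
miRNAs, a handful of genes). Published dataset-scale counts depend on
database snapshots and are not reproduction targets.

## Problem sizes and known limitations

The bundled end-to-end runs use the generator defaults above with flank
steps 45/60/100/150 (bracketing typical plant pre-miRNA lengths of
~60–300 nt). The simplified folding model is the main known limitation:
on windows with long random flanks its maximum-pairing optimum can braid
flank sequence into the duplex region, so an occasional planted candidate
fails the structural criteria even though a thermodynamic folder would
recover it; the screen's external-fold ingestion is the intended remedy on
real data. Internal folding is O(n³) and comfortable up to a few hundred
nt per window. The search stage is exact and quadratic per
(miRNA, gene) pair, appropriate for gene-family scale, not genome scale.
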