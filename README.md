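# mirdir

Homology-based prediction of miRNAs targeting a gene family, with hairpin
screening and qPCR validation — built around the workflow used to find
miRNAs regulating the dirigent (DIR) genes of *Oryza sativa* Indica, but
applicable to any mature-miRNA reference set and gene-family FASTA.

## What it does

Conserved plant miRNAs can be discovered in a new species by homology: a
reference set of known mature miRNAs is searched against candidate gene
sequences, and each match is accepted only if its genomic context folds into
a credible pre-miRNA hairpin. The pipeline stages are:

1. **Redundancy clustering** — greedy longest-first clustering of the mature
   miRNA set at 90 % identity (CD-HIT style); one representative per cluster.
2. **Homology search** — each representative is aligned against every gene on
   both strands (exact Smith–Waterman / sliding-window scan at desk scale);
   hits with ≤ 4 mismatches, no gaps and full query coverage survive.
   E-values follow Karlin–Altschul statistics, E = K·m·n·e^(−λS).
3. **Coding filter** — candidate loci are translated in all six frames and
   aligned (BLOSUM62) against a protein reference; anything with a translated
   hit at E ≤ 1e−10 is discarded as protein-coding.
4. **Hairpin screen** — windows around each hit are folded and checked
   against the eight standard criteria: precursor ≥ 60 nt; stem-loop fold;
   mature entirely in one arm; ≤ 6 mismatches in the miRNA/miRNA\* duplex;
   no multibranch loop between the duplex and the apical loop; A+U content
   in 30–70 %; negative MFE; and a (configurable, advisory) MFEI floor.
   The screen reports, per candidate:

   - **AMFE** = |ΔG| / L × 100 — folding energy per 100 nt,
   - **MFEI** = AMFE / (G+C)% — the index separating miRNA precursors from
     other RNAs,

   plus base composition, A/U and G/C ratios, arm, and per-criterion flags.
5. **Expression validation** — relative expression from qPCR threshold
   cycles by the comparative Ct method, fold = 2^−ΔΔCt, normalized to a
   reference gene (e.g. rice actin 1) and a control condition, with Welch
   t-tests on replicate ΔCt values; miRNA/target pairs are then labeled
   `inverse`, `concordant`, or `ns` per condition.

A first-class synthetic-data module generates every input with known ground
truth (clustered miRNA families, genes with planted homologs in a stem-loop
context, hairpins with chosen duplex mismatches and A+U content, Ct tables
with planted fold changes), so the whole pipeline is testable offline.

## Worked example

Generate a synthetic bundle and run the full pipeline:

```
mirdir synth bundle --out bundle --seed 42
cat > run.cfg <<'CFG'
mirnas = bundle/mirnas.fasta
genes = bundle/genes.fasta
ct_table = bundle/ct_table.csv
reference_gene = actin1
control_condition = control
out_dir = run
flank_steps = 45,60,100,150
seed = 42
CFG
mirdir run --config run.cfg
```

The stage log shows the candidate funnel — 30 reference miRNAs collapse to
10 clusters, 3 homology hits survive, 36 precursor windows are cut and
folded, 26 pass the screen:

```
INFO mirdir.pipeline: stage=cluster in=30 out=10 identity=0.9
INFO mirdir.pipeline: stage=search in=10 out=3 max_mismatches=4
INFO mirdir.pipeline: stage=extract in=3 out=36 flanks=(45, 60, 100, 150)
INFO mirdir.pipeline: stage=screen in=36 out=26 mode=report-only
26 candidates pass; outputs in run
```

`run/summary.tsv` carries one row per screened window with the hairpin
statistics (LP = precursor length, LM = mature length, NM = duplex
mismatches):

```
id                             Loc  LP  LM  NM  GC_pct  MFE   AMFE   MFEI
gene000|fam000_a000|+|f45up    3p   68  23  1   51.47   65.0  95.59  1.86
gene000|fam000_a000|+|f45down  5p   68  23  6   52.94   63.0  92.65  1.75
```

and `run/inverse_report.tsv` labels each surviving miRNA/target pair per
condition — here the generator planted miRNA fold 0.25 against target fold
4.0, and every pair comes back `inverse`:

```
   mirna_id gene_id condition  mirna_fold  target_fold pattern
fam000_a000 gene000   drought        0.24         4.40 inverse
fam000_a000 gene000      salt        0.25         3.95 inverse
fam001_a000 gene003   drought        0.24         3.84 inverse
```

Every stage is also available on its own (`mirdir cluster`, `search`,
`codingfilter`, `extract`, `fold`, `screen`, `express`, `report`) and as
library functions (`mirdir.greedy_cluster`, `mirdir.search_mirna_homologs`,
`mirdir.evaluate_criteria`, `mirdir.ddct`, ...).

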