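"""End-to-end orchestration: cluster → search → coding filter → extract →
fold → screen → target assignment → expression → inverse-pattern report.

The run is a pure function of (inputs, config, seed): re-running with the
same configuration produces byte-identical outputs.  Every stage logs one
structured line (parameters, input count, output count) so the candidate
funnel is auditable, and each stage's table is written into the run
directory as TSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import clustering, expression, formats_io, hairpin, homology

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage thresholds plus input/output paths; key = value on disk."""

    mirnas: Optional[str] = None
    genes: Optional[str] = None
    proteins: Optional[str] = None
    folds: Optional[str] = None
    ct_table: Optional[str] = None
    reference_gene: Optional[str] = None
    control_condition: Optional[str] = None
    out_dir: str = "run"
    identity: float = 0.90
    max_mismatches: int = 4
    max_gaps: int = 0
    min_coverage: float = 1.0
    evalue_max: float = 1e-10
    flank_steps: Tuple[int, ...] = (60, 100, 150, 250)
    min_lp: int = 60
    max_nm: int = 6
    au_min: float = 30.0
    au_max: float = 70.0
    mfei_floor: float = 0.85
    criteria_mode: str = "report-only"  # "strict" enforces the MFEI floor
    equal_var: bool = False
    seed: int = 0

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                value = getattr(self, f.name)
                if isinstance(value, tuple):
                    value = ",".join(str(v) for v in value)
                fh.write(f"{f.name} = {value}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        values: Dict[str, str] = {}
        for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{line_no}: expected 'key = value'")
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in values:
                continue
            raw = values.pop(f.name)
            if raw == "None":
                kwargs[f.name] = None
            elif f.name == "flank_steps":
                kwargs[f.name] = tuple(int(x) for x in raw.split(","))
            elif f.type in ("float", float):
                kwargs[f.name] = float(raw)
            elif f.type in ("int", int):
                kwargs[f.name] = int(raw)
            elif f.type in ("bool", bool):
                kwargs[f.name] = raw.lower() in ("1", "true", "yes")
            else:
                kwargs[f.name] = raw
        if values:
            raise ValueError(f"{path}: unknown config keys {sorted(values)}")
        return cls(**kwargs)


@dataclass
class PipelineResult:
    clusters: List[clustering.Cluster]
    hits: List[homology.HomologyHit]
    coding: List[homology.CodingFilterResult]
    evaluations: List[hairpin.HairpinEvaluation]
    assignments: List[expression.TargetAssignment]
    expression_records: List[expression.ExpressionRecord]
    inverse_report: Optional[pd.DataFrame]
    summary: pd.DataFrame


def _stage(name: str, n_in: int, n_out: int, **params) -> None:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    logger.info("stage=%s in=%d out=%d %s", name, n_in, n_out, kv)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "run.cfg")

    # --- cluster ---------------------------------------------------------
    if config.mirnas is None:
        raise ValueError("pipeline requires a miRNA reference FASTA")
    try:
        mirna_recs = formats_io.read_fasta(config.mirnas, moltype="rna")
    except formats_io.ParseError as exc:
        if "no FASTA records" not in str(exc):
            raise
        mirna_recs = []
    mirnas = [clustering.MatureMiRNA.from_record(r) for r in mirna_recs]
    clusters = clustering.greedy_cluster(mirnas, config.identity) if mirnas else []
    reps = clustering.representatives(clusters)
    _stage("cluster", len(mirnas), len(clusters), identity=config.identity)
    pd.DataFrame(clustering.clusters_to_rows(clusters),
                 columns=["cluster_id", "representative_id", "member_id", "identity"]
                 ).to_csv(out / "clusters.tsv", sep="\t", index=False)

    # --- search ----------------------------------------------------------
    genes = formats_io.read_fasta(config.genes, moltype="dna") if config.genes else []
    hits = homology.search_mirna_homologs(
        reps, genes, max_mismatches=config.max_mismatches,
        max_gaps=config.max_gaps, min_coverage=config.min_coverage,
    ) if reps and genes else []
    _stage("search", len(reps), len(hits), max_mismatches=config.max_mismatches)
    hits_frame(hits).to_csv(out / "hits.tsv", sep="\t", index=False)

    # --- precursor extraction -------------------------------------------
    gene_by_id = {g.id: g for g in genes}
    candidates: List[hairpin.PrecursorCandidate] = []
    for hit in hits:
        candidates.extend(hairpin.extract_precursor(
            gene_by_id[hit.gene_id].sequence, hit, config.flank_steps))
    _stage("extract", len(hits), len(candidates), flanks=config.flank_steps)

    # --- coding filter (on extracted candidate regions) ------------------
    proteins = (formats_io.read_fasta(config.proteins, moltype="protein")
                if config.proteins else None)
    cand_records = [
        formats_io.SequenceRecord(c.id, c.id, c.sequence.replace("U", "T"), "dna")
        for c in candidates
    ]
    coding = homology.coding_filter(cand_records, proteins, config.evalue_max)
    coding_ids = {r.query_id for r in coding if r.is_coding}
    candidates = [c for c in candidates if c.id not in coding_ids]
    _stage("codingfilter", len(cand_records), len(candidates),
           evalue_max=config.evalue_max,
           skipped=proteins is None)

    # --- fold ------------------------------------------------------------
    external = {}
    if config.folds:
        external = {f.id: f for f in formats_io.read_fold(config.folds)}
    folded: List[hairpin.PrecursorCandidate] = []
    for cand in candidates:
        ext = external.get(cand.id)
        if ext is not None:
            cand.structure, cand.mfe_kcal_mol = ext.structure, ext.mfe_kcal_mol
            cand.fold_source = "external"
        else:
            fold = hairpin.fold_internal(cand.sequence)
            cand.structure, cand.mfe_kcal_mol = fold.structure, fold.mfe_kcal_mol
            cand.fold_source = "internal"
        folded.append(cand)
    _stage("fold", len(candidates), len(folded), external=len(external))

    # --- screen ----------------------------------------------------------
    evaluations = [
        hairpin.evaluate_criteria(
            cand, min_lp=config.min_lp, max_nm=config.max_nm,
            au_range=(config.au_min, config.au_max),
            mfei_floor=config.mfei_floor,
            enforce_mfei=config.criteria_mode == "strict",
        )
        for cand in folded
    ]
    passing = [e for e in evaluations if e.passes_all]
    _stage("screen", len(folded), len(passing), mode=config.criteria_mode)
    table4, table5 = render_tables(evaluations)
    table4.to_csv(out / "screen_summary.tsv", sep="\t", index=False)
    table5.to_csv(out / "screen_composition.tsv", sep="\t", index=False)

    # --- targets: best passing candidate per (miRNA, gene) pair ----------
    passing_pairs = {(c.mirna_id, c.gene_id)
                     for c, e in zip(folded, evaluations) if e.passes_all}
    assignments = [
        expression.TargetAssignment(h.mirna_id, h.gene_id, h)
        for h in hits if (h.mirna_id, h.gene_id) in passing_pairs
    ]
    _stage("targets", len(hits), len(assignments))
    pd.DataFrame([{"mirna_id": a.mirna_id, "gene_id": a.gene_id}
                  for a in assignments]).to_csv(out / "targets.tsv", sep="\t",
                                                index=False)

    # --- expression ------------------------------------------------------
    expression_records: List[expression.ExpressionRecord] = []
    inverse = None
    if config.ct_table:
        table = formats_io.read_ct_table(
            config.ct_table, reference_gene=config.reference_gene,
            control_condition=config.control_condition)
        expression_records = expression.ddct(table, equal_var=config.equal_var)
        expression.expression_to_frame(expression_records).to_csv(
            out / "expression.tsv", sep="\t", index=False)
        by_name = {r.gene for r in expression_records}
        mir_records = [r for r in expression_records
                       if any(r.gene == a.mirna_id for a in assignments)]
        tgt_records = [r for r in expression_records
                       if any(r.gene == a.gene_id for a in assignments)]
        if assignments and mir_records and tgt_records:
            inverse = expression.inverse_pattern_report(
                mir_records, tgt_records, assignments,
                control_condition=config.control_condition)
            inverse.to_csv(out / "inverse_report.tsv", sep="\t", index=False)
        _stage("express", len(table.df), len(expression_records))

    summary = table4.assign(passes_all=[e.passes_all for e in evaluations])
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    (Path(out) / "summary.sha256").write_text(
        hashlib.sha256(summary.to_csv(index=False).encode()).hexdigest() + "\n")
    return PipelineResult(clusters, hits, coding, evaluations, assignments,
                          expression_records, inverse, summary)


def hits_frame(hits: Sequence[homology.HomologyHit]) -> pd.DataFrame:
    """Hits as a 12-column table mirroring tabular BLAST (outfmt 6) semantics."""
    rows = []
    for h in hits:
        length = h.gene_end - h.gene_start
        matches = length - h.mismatches - h.gaps
        rows.append({
            "qseqid": h.mirna_id, "sseqid": h.gene_id,
            "pident": round(100.0 * matches / max(length, 1), 2),
            "length": length, "mismatch": h.mismatches, "gapopen": h.gaps,
            "qstart": h.query_start + 1, "qend": h.query_end,
            "sstart": h.gene_start + 1 if h.strand == "+" else h.gene_end,
            "send": h.gene_end if h.strand == "+" else h.gene_start + 1,
            "evalue": h.evalue, "bitscore": h.score,
        })
    return pd.DataFrame(rows, columns=[
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore"])


def _na(value) -> object:
    return "NA" if value is None else value


def render_tables(evaluations: Sequence[hairpin.HairpinEvaluation]
                  ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Screening summary and composition tables (2-decimal presentation).

    The first table carries the hairpin statistics (strand, arm, LP, LM, NM,
    (G+C)%, MFE magnitude, AMFE, MFEI) plus the per-criterion flags; the
    second carries the composition percentages and A/U, G/C ratios.
    Undefined ratios/indices render as "NA".
    """
    rows4, rows5 = [], []
    for e in evaluations:
        row4 = {
            "id": e.id, "mature_seq": e.mature_seq, "ST": e.strand,
            "Loc": _na(e.arm), "LP": e.lp, "LM": e.lm, "NM": e.nm_duplex,
            "GC_pct": e.gc_content_pct, "MFE": e.mfe_magnitude,
            "AMFE": _na(e.amfe), "MFEI": _na(e.mfei),
        }
        for i, name in enumerate(hairpin.CRITERIA_NAMES, start=1):
            row4[f"criterion_{i}_{name}"] = e.criteria[name]
        rows4.append(row4)
        rows5.append({
            "id": e.id, "A_pct": e.a_pct, "U_pct": e.u_pct,
            "G_pct": e.g_pct, "C_pct": e.c_pct,
            "AU_ratio": _na(e.au_ratio), "GC_ratio": _na(e.gc_ratio),
            "AU_content_pct": e.au_content_pct,
        })
    return pd.DataFrame(rows4), pd.DataFrame(rows5)
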