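"""Homology search of mature miRNAs inside target-family gene sequences.

The non-redundant miRNA reference set is searched against the gene family
on both strands.  At desk scale this is done exactly: a hand-written
Smith–Waterman with affine gaps (``local_align``) for general local
alignment, and — for the default gap-free, full-coverage miRNA search — an
exhaustive sliding-window scan that scores every placement of the miRNA on
the gene.  E-values follow Karlin–Altschul statistics, E = K·m·n·e^(−λS).

Candidate regions are then passed through a coding-potential filter:
six-frame translation, local protein alignment (BLOSUM62) against a protein
reference, and rejection of any candidate with a translated hit at
E ≤ 1e−10 — homology-based miRNA prediction keeps only non-coding loci.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from scipy.optimize import brentq

from .formats_io import SequenceRecord, normalize_sequence

logger = logging.getLogger(__name__)

DEFAULT_SCORING = {"match": 1.0, "mismatch": -1.0, "gap_open": -2.0, "gap_extend": -1.0}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass
class LocalAlignment:
    """Result of a local alignment: score plus column accounting."""

    score: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    matches: int
    mismatches: int
    gaps: int  # gap columns
    n_columns: int


@dataclass
class HomologyHit:
    """Best placement of a miRNA on a gene (0-based half-open, gene frame)."""

    mirna_id: str
    gene_id: str
    gene_start: int
    gene_end: int
    strand: str  # "+" | "-"
    mismatches: int
    gaps: int
    score: float
    evalue: float
    query_start: int = 0
    query_end: int = 0

    def __post_init__(self) -> None:
        if self.gene_end <= self.gene_start:
            raise ValueError("gene_end must exceed gene_start")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


def _as_dna(seq: str) -> str:
    return normalize_sequence(seq, "dna")


def local_align(query: str, subject: str, scoring: Optional[Dict[str, float]] = None
                ) -> LocalAlignment:
    """Optimal Smith–Waterman local alignment with affine gaps.

    U and T are treated as equivalent.  Traceback is deterministic: the
    optimal end cell with the smallest subject coordinate is chosen, and on
    equal-score moves the diagonal is preferred over gaps (so ties resolve
    to fewer gap columns, then to the smaller subject start).
    """
    sc = dict(DEFAULT_SCORING, **(scoring or {}))
    if not (sc["match"] > 0 > sc["mismatch"]):
        raise ValueError("scoring must satisfy match > 0 > mismatch")
    q = _as_dna(query)
    s = _as_dna(subject)
    if not q or not s:
        raise ValueError("local_align: empty sequence")
    m, n = len(q), len(s)
    go, ge = sc["gap_open"], sc["gap_extend"]
    NEG = float("-inf")
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)  # gap in query (move along subject)
    F = np.full((m + 1, n + 1), NEG)  # gap in subject (move along query)
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] + go, E[i, j - 1] + ge)
            F[i, j] = max(H[i - 1, j] + go, F[i - 1, j] + ge)
            diag = H[i - 1, j - 1] + (sc["match"] if qi == s[j - 1] else sc["mismatch"])
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
    best = float(H.max())
    if best <= 0:
        return LocalAlignment(0.0, 0, 0, 0, 0, 0, 0, 0, 0)
    # end cell: smallest subject end, then smallest query end
    js, iis = np.nonzero(H.T == best)
    j, i = int(js[0]), int(iis[0])
    matches = mismatches = gaps = cols = 0
    qe, se = i, j
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + (sc["match"] if q[i - 1] == s[j - 1] else sc["mismatch"])
            if H[i, j] == diag:
                cols += 1
                if q[i - 1] == s[j - 1]:
                    matches += 1
                else:
                    mismatches += 1
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols += 1
            gaps += 1
            if E[i, j] == H[i, j - 1] + go:
                state = "H"
            j -= 1
        else:  # F
            cols += 1
            gaps += 1
            if F[i, j] == H[i - 1, j] + go:
                state = "H"
            i -= 1
    return LocalAlignment(best, i, qe, j, se, matches, mismatches, gaps, cols)


def _window_scan(query_dna: str, subject: str) -> Tuple[int, int]:
    """Best gap-free full-coverage placement: (mismatches, subject_start).

    Exhaustive over all placements; ties resolve to the smallest start.
    """
    m = len(query_dna)
    if len(subject) < m:
        return (m + 1, -1)
    q = np.frombuffer(query_dna.encode(), dtype=np.uint8)
    s = np.frombuffer(subject.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mm = (windows != q).sum(axis=1)
    start = int(mm.argmin())
    return int(mm[start]), start


def nucleotide_lambda(match: float = 1.0, mismatch: float = -1.0,
                      gc: float = 0.5) -> float:
    """Ungapped Karlin–Altschul lambda for a match/mismatch scoring scheme.

    Solves sum_ij p_i p_j exp(lambda * s_ij) = 1 for a composition with the
    given GC fraction (uniform by default).
    """
    freqs = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]  # A, T, G, C
    p_match = sum(p * p for p in freqs)
    p_mismatch = 1 - p_match

    def f(lam: float) -> float:
        return p_match * math.exp(lam * match) + p_mismatch * math.exp(lam * mismatch) - 1

    return brentq(f, 1e-6, 10.0)


def karlin_altschul_evalue(score: float, m: int, n: int,
                           K: float = 0.1, lam: Optional[float] = None) -> float:
    """Expected chance alignments at >= score: E = K·m·n·exp(−λS)."""
    if m <= 0 or n <= 0:
        raise ValueError("m and n must be positive")
    if K <= 0:
        raise ValueError("K must be positive")
    if lam is None:
        lam = nucleotide_lambda()
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return K * m * n * math.exp(-lam * score)


def search_mirna_homologs(
    mirnas: Sequence,
    genes: Sequence[SequenceRecord],
    max_mismatches: int = 4,
    max_gaps: int = 0,
    min_coverage: float = 1.0,
    scoring: Optional[Dict[str, float]] = None,
    K: float = 0.1,
) -> List[HomologyHit]:
    """Search every miRNA against every gene on both strands.

    ``mirnas`` may be MatureMiRNA or SequenceRecord objects (anything with
    ``id`` and ``sequence``).  One best hit per (miRNA, gene) pair is kept;
    hits with more than ``max_mismatches`` mismatches, more than ``max_gaps``
    gap columns, or query coverage below ``min_coverage`` are discarded.
    Output is sorted by (mirna_id, evalue).
    """
    if max_mismatches < 0 or max_gaps < 0 or min_coverage < 0:
        raise ValueError("thresholds must be non-negative")
    if not genes:
        warnings.warn("search_mirna_homologs: empty gene set", stacklevel=2)
        return []
    sc = dict(DEFAULT_SCORING, **(scoring or {}))
    lam = nucleotide_lambda(sc["match"], sc["mismatch"])
    total_n = 2 * sum(len(g.sequence) for g in genes)
    gap_free = max_gaps == 0 and min_coverage >= 1.0
    hits: List[HomologyHit] = []
    for mir in mirnas:
        q_dna = _as_dna(mir.sequence)
        m = len(q_dna)
        for gene in genes:
            best: Optional[HomologyHit] = None
            for strand in "+-":
                subject = gene.sequence if strand == "+" else reverse_complement(gene.sequence)
                if gap_free:
                    mm, start = _window_scan(q_dna, subject)
                    if start < 0 or mm > max_mismatches:
                        continue
                    score = (m - mm) * sc["match"] + mm * sc["mismatch"]
                    sub_s, sub_e = start, start + m
                    gaps, q_s, q_e = 0, 0, m
                else:
                    aln = local_align(q_dna, subject, sc)
                    if aln.n_columns == 0:
                        continue
                    coverage = (aln.query_end - aln.query_start) / m
                    if (aln.mismatches > max_mismatches or aln.gaps > max_gaps
                            or coverage < min_coverage):
                        continue
                    score, mm, gaps = aln.score, aln.mismatches, aln.gaps
                    sub_s, sub_e = aln.subject_start, aln.subject_end
                    q_s, q_e = aln.query_start, aln.query_end
                L = len(gene.sequence)
                if strand == "-":
                    sub_s, sub_e = L - sub_e, L - sub_s
                hit = HomologyHit(
                    mirna_id=mir.id, gene_id=gene.id,
                    gene_start=sub_s, gene_end=sub_e, strand=strand,
                    mismatches=mm, gaps=gaps, score=score,
                    evalue=karlin_altschul_evalue(score, m, total_n, K=K, lam=lam),
                    query_start=q_s, query_end=q_e,
                )
                if best is None or (hit.score, -hit.gene_start) > (best.score, -best.gene_start):
                    best = hit
            if best is not None:
                hits.append(best)
    hits.sort(key=lambda h: (h.mirna_id, h.evalue, h.gene_id))
    return hits


# ---------------------------------------------------------------------------
# Coding-potential filter
# ---------------------------------------------------------------------------

@dataclass
class CodingFilterResult:
    query_id: str
    best_evalue: Optional[float]
    is_coding: bool


# Gapped BLOSUM62 statistics (open 11, extend 1), as used by protein BLAST.
BLOSUM62_LAMBDA = 0.267
BLOSUM62_K = 0.041


def six_frame_orfs(dna: str, min_aa: int = 8) -> List[str]:
    """Stop-free translated segments from all six reading frames."""
    dna = _as_dna(dna).replace("N", "A")
    segments: List[str] = []
    for strand_seq in (dna, reverse_complement(dna)):
        for frame in range(3):
            sub = strand_seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) < 3:
                continue
            aa = str(Seq(sub).translate())
            segments.extend(seg for seg in aa.split("*") if len(seg) >= min_aa)
    return segments


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def coding_filter(
    candidates: Sequence[SequenceRecord],
    proteins: Optional[Sequence[SequenceRecord]],
    evalue_max: float = 1e-10,
) -> List[CodingFilterResult]:
    """Flag candidates with significant translated similarity to a protein set.

    Each candidate is translated in all six frames; internal stops break the
    translation into segments that are aligned independently against every
    reference protein (local alignment, BLOSUM62, gap open 11 / extend 1).
    The best raw score is converted to an E-value with gapped BLOSUM62
    Karlin–Altschul parameters; ``is_coding`` is true iff E <= ``evalue_max``.
    The pipeline keeps only non-coding candidates.
    """
    results: List[CodingFilterResult] = []
    if not proteins:
        logger.info("coding filter skipped: no protein reference supplied")
        return [CodingFilterResult(c.id, None, False) for c in candidates]
    aligner = _protein_aligner()
    total_n = sum(len(p.sequence) for p in proteins)
    for cand in candidates:
        if len(cand.sequence) < 3:
            warnings.warn(f"candidate {cand.id!r} shorter than one codon", stacklevel=2)
            results.append(CodingFilterResult(cand.id, None, False))
            continue
        segments = six_frame_orfs(cand.sequence)
        best_e: Optional[float] = None
        for seg in segments:
            m = len(seg)
            for prot in proteins:
                score = aligner.score(seg, prot.sequence)
                if score <= 0:
                    continue
                e = BLOSUM62_K * m * total_n * math.exp(-BLOSUM62_LAMBDA * score)
                if best_e is None or e < best_e:
                    best_e = e
        results.append(CodingFilterResult(cand.id, best_e,
                                          best_e is not None and best_e <= evalue_max))
    return results
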