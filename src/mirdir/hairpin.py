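"""Pre-miRNA hairpin extraction, folding and the eight-criterion screen.

Around every surviving homology hit, candidate precursor windows are cut
from the gene (upstream-only, downstream-only and symmetric, at several
flank sizes, so the mature sequence can end up on either arm).  Each window
is folded — either with the built-in simplified folding model or with an
externally supplied structure — and screened against the standard criteria
used in homology-based plant miRNA prediction:

1. precursor length >= 60 nt;
2. folds into a stem-loop hairpin;
3. the mature miRNA sits entirely in one arm;
4. at most 6 mismatched mature positions in the miRNA/miRNA* duplex;
5. no multibranch loop between the mature arm and its star arm;
6. A+U content within 30–70 %;
7. negative minimal folding free energy (MFE);
8. high minimal folding free energy index (MFEI) — advisory by default.

with the derived statistics AMFE = |MFE| / L × 100 (energy per 100 nt) and
MFEI = AMFE / (G+C)%, the index that separates miRNA precursors from other
non-coding and coding RNAs.

The internal folding model is deliberately simple and fully specified: a
Nussinov-style dynamic program over Watson–Crick plus GU wobble pairs with
per-pair stabilities GC −3, AU −2, GU −1 kcal/mol, a minimum hairpin loop
of 3 nt and no loop terms.  Its energies are NOT comparable to Turner-model
folders such as MFOLD/RNAfold; for thermodynamic realism external folds can
be ingested and screened instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

from .formats_io import FoldRecord, pair_table, validate_dot_bracket
from .homology import HomologyHit, reverse_complement

logger = logging.getLogger(__name__)

PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
MIN_LOOP = 3  # minimum unpaired nucleotides enclosed by a pair

CRITERIA_NAMES = (
    "min_length",          # 1
    "stem_loop",           # 2
    "mature_in_one_arm",   # 3
    "duplex_mismatches",   # 4
    "no_multibranch",      # 5
    "au_content",          # 6
    "negative_mfe",        # 7
    "mfei_floor",          # 8 (advisory unless enforced)
)


def round2(x: float) -> float:
    """Round half-up to 2 decimals (table presentation convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class PrecursorCandidate:
    """A putative pre-miRNA window with its mature-arm annotation."""

    id: str
    sequence: str  # RNA alphabet
    mature_start: int  # 0-based half-open, precursor frame
    mature_end: int
    structure: Optional[str] = None
    mfe_kcal_mol: Optional[float] = None
    fold_source: str = "internal"
    mirna_id: Optional[str] = None
    gene_id: Optional[str] = None
    strand: str = "+"
    clipped: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.mature_start < self.mature_end <= len(self.sequence)):
            raise ValueError(
                f"candidate {self.id!r}: mature span [{self.mature_start}, "
                f"{self.mature_end}) outside precursor of length {len(self.sequence)}"
            )
        if self.structure is not None and len(self.structure) != len(self.sequence):
            raise ValueError(f"candidate {self.id!r}: structure/sequence length mismatch")

    @property
    def mature_sequence(self) -> str:
        return self.sequence[self.mature_start : self.mature_end]


@dataclass
class HairpinEvaluation:
    """One screened candidate: the full report row plus per-criterion flags."""

    id: str
    mature_seq: str
    strand: str
    arm: Optional[str]           # "5p" | "3p" | None
    lp: int                      # precursor length
    lm: int                      # mature length
    nm_duplex: int               # mismatched mature positions in the duplex
    a_pct: float
    u_pct: float
    g_pct: float
    c_pct: float
    au_ratio: Optional[float]
    gc_ratio: Optional[float]
    au_content_pct: float
    gc_content_pct: float
    mfe_magnitude: float
    amfe: Optional[float]
    mfei: Optional[float]
    criteria: Dict[str, bool]
    passes_all: bool


def extract_precursor(
    gene: str,
    hit: HomologyHit,
    flank_steps: Sequence[int] = (60, 100, 150, 250),
) -> List[PrecursorCandidate]:
    """Cut candidate precursor windows around a homology hit.

    For each flank size three windows are produced — upstream-only,
    downstream-only and symmetric (gene coordinates) — so the mature region
    can end up on the 5' or 3' arm of whatever hairpin the window folds
    into.  Minus-strand hits yield the reverse complement, with the mature
    span re-expressed in the precursor frame.  Windows clipped at the gene
    boundary are still emitted, flagged ``clipped``.
    """
    L = len(gene)
    if not (0 <= hit.gene_start < hit.gene_end <= L):
        raise ValueError("hit coordinates outside gene")
    out: List[PrecursorCandidate] = []
    for flank in flank_steps:
        windows = {
            "up": (hit.gene_start - flank, hit.gene_end),
            "down": (hit.gene_start, hit.gene_end + flank),
            "sym": (hit.gene_start - flank, hit.gene_end + flank),
        }
        for mode, (a, b) in windows.items():
            ca, cb = max(0, a), min(L, b)
            clipped = (ca, cb) != (a, b)
            window = gene[ca:cb]
            if hit.strand == "+":
                seq = window.replace("T", "U")
                ms, me = hit.gene_start - ca, hit.gene_end - ca
            else:
                seq = reverse_complement(window).replace("T", "U")
                ms, me = cb - hit.gene_end, cb - hit.gene_start
            out.append(
                PrecursorCandidate(
                    id=f"{hit.gene_id}|{hit.mirna_id}|{hit.strand}|f{flank}{mode}",
                    sequence=seq,
                    mature_start=ms,
                    mature_end=me,
                    mirna_id=hit.mirna_id,
                    gene_id=hit.gene_id,
                    strand=hit.strand,
                    clipped=clipped,
                )
            )
    return out


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIR_ENERGY


def fold_internal(sequence: str) -> FoldRecord:
    """Fold with the simplified per-pair energy model (see module docstring).

    Deterministic: on energy ties the unpaired option is preferred, then the
    smallest pairing partner, so identical sequences always give identical
    structures.  Returned energy is the (non-positive) sum of pair energies.
    """
    seq = sequence.upper().replace("T", "U")
    if len(seq) < 10:
        raise ValueError("fold_internal: sequence shorter than 10 nt")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"fold_internal: non-RNA characters {sorted(bad)}")
    n = len(seq)
    best = _nussinov_fill(seq, n)
    structure = ["."] * n
    # traceback from stored optima; prefer "j unpaired", then smallest k
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < MIN_LOOP + 1:
            continue
        if best[i][j] == best[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - MIN_LOOP):
            if not _can_pair(seq[k], seq[j]):
                continue
            left = best[i][k - 1] if k > i else 0.0
            inner = best[k + 1][j - 1] if k + 1 <= j - 1 else 0.0
            if best[i][j] == left + inner + PAIR_ENERGY[(seq[k], seq[j])]:
                structure[k], structure[j] = "(", ")"
                if k > i:
                    stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                break
    energy = best[0][n - 1]
    return FoldRecord(id="internal", sequence=seq, structure="".join(structure),
                      mfe_kcal_mol=float(energy))


def _nussinov_fill(seq: str, n: int):
    import numpy as np

    idx = np.fromiter(("ACGU".index(c) for c in seq), dtype=np.intp, count=n)
    table = np.full((4, 4), np.inf)
    for (a, b), e in PAIR_ENERGY.items():
        table["ACGU".index(a), "ACGU".index(b)] = e
    emat = table[idx[:, None], idx[None, :]]
    best = np.zeros((n, n))
    left = np.empty(n)
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            hi = j - MIN_LOOP  # candidate pairing partners k in [i, hi)
            w = hi - i
            left[0] = 0.0
            if w > 1:
                left[1:w] = best[i, i : hi - 1]
            cand = left[:w] + best[i + 1 : hi + 1, j - 1] + emat[i:hi, j]
            b = cand.min()
            unpaired = best[i, j - 1]
            best[i, j] = unpaired if unpaired <= b else b
    return best


MIN_HELIX = 3  # stacked pairs required for a run to count as a helix


def _topology_pairs(structure: str, min_helix: int = MIN_HELIX) -> List[int]:
    """Pair table for topology analysis, with sub-helical runs removed.

    Runs of fewer than ``min_helix`` contiguously stacked pairs are too
    unstable to define a helix (thermodynamic folders suppress lonely pairs
    for the same reason); they are dropped before locating the apical loop,
    the arm, or branching.  The full pair table is still used for duplex
    mismatch counting, where an unstacked pair simply fails to protect its
    position.
    """
    partner = pair_table(structure)
    n = len(partner)
    seen = [False] * n
    for i in range(n):
        j = partner[i]
        if j <= i or seen[i]:
            continue
        run = [(i, j)]
        while (run[-1][0] + 1 < n and partner[run[-1][0] + 1] == run[-1][1] - 1
               and run[-1][1] - 1 > run[-1][0] + 1):
            run.append((run[-1][0] + 1, run[-1][1] - 1))
        for a, b in run:
            seen[a] = seen[b] = True
        if len(run) < min_helix:
            for a, b in run:
                partner[a] = partner[b] = -1
    return partner


def _hairpin_loops(partner: Sequence[int]) -> List[Tuple[int, int]]:
    """Innermost pairs (i, j): no paired position strictly inside (i, j)."""
    loops = []
    for i, j in ((i, p) for i, p in enumerate(partner) if p > i):
        if all(partner[k] == -1 for k in range(i + 1, j)):
            loops.append((i, j))
    return loops


def _apical_loop(candidate: PrecursorCandidate) -> Optional[Tuple[int, int]]:
    """The hairpin loop nearest the mature span (its enclosing innermost pair)."""
    partner = _topology_pairs(candidate.structure)
    loops = _hairpin_loops(partner)
    if not loops:
        return None

    def distance(loop: Tuple[int, int]) -> Tuple[int, int]:
        i, j = loop
        lo, hi = candidate.mature_start, candidate.mature_end - 1
        if hi < i:
            return (i - hi, i)
        if lo > j:
            return (lo - j, i)
        return (0, i)

    return min(loops, key=distance)


def locate_arm(candidate: PrecursorCandidate) -> Optional[str]:
    """Which hairpin arm carries the mature sequence.

    ``5p`` if the mature span lies entirely at or before the apical-loop
    midpoint, ``3p`` if entirely after; straddling the loop (or a structure
    with no pairs) returns None and fails the in-one-arm criterion.
    """
    if candidate.structure is None:
        raise ValueError("locate_arm: candidate has no structure")
    loop = _apical_loop(candidate)
    if loop is None:
        return None
    midpoint = (loop[0] + loop[1]) / 2
    if candidate.mature_end - 1 <= midpoint:
        return "5p"
    if candidate.mature_start > midpoint:
        return "3p"
    return None


def duplex_mismatches(candidate: PrecursorCandidate) -> int:
    """Mismatched mature positions in the miRNA/miRNA* duplex.

    A mature position counts as mismatched when it is unpaired or paired to
    a position on its own side of the apical loop; bulged nucleotides on the
    star arm do not add to the count.
    """
    if candidate.structure is None:
        raise ValueError("duplex_mismatches: candidate has no structure")
    partner = pair_table(candidate.structure)
    loop = _apical_loop(candidate)
    if loop is None:
        return candidate.mature_end - candidate.mature_start
    midpoint = (loop[0] + loop[1]) / 2

    def side(pos: int) -> int:
        return 0 if pos <= midpoint else 1

    nm = 0
    for p in range(candidate.mature_start, candidate.mature_end):
        q = partner[p]
        if q == -1 or side(q) == side(p):
            nm += 1
    return nm


def composition_stats(sequence: str) -> Dict[str, Optional[float]]:
    """Base composition percentages and ratios, table-rounded.

    Percentages are count/length × 100 rounded half-up to 2 decimals; A/U
    and G/C ratios are ratios of the rounded percentages; the combined
    (A+U)% and (G+C)% contents are computed from the raw counts and then
    rounded (so they agree with the sum of the single-base percentages to
    within rounding).  A zero U or C count makes the corresponding ratio
    undefined (None), not infinite.
    """
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    if n == 0:
        raise ValueError("composition_stats: empty sequence")
    counts = {b: seq.count(b) for b in "AUGC"}
    pct = {b: round2(counts[b] / n * 100) for b in "AUGC"}
    au_ratio = round2(pct["A"] / pct["U"]) if counts["U"] else None
    gc_ratio = round2(pct["G"] / pct["C"]) if counts["C"] else None
    return {
        "a_pct": pct["A"], "u_pct": pct["U"], "g_pct": pct["G"], "c_pct": pct["C"],
        "au_ratio": au_ratio, "gc_ratio": gc_ratio,
        "au_content_pct": round2((counts["A"] + counts["U"]) / n * 100),
        "gc_content_pct": round2((counts["G"] + counts["C"]) / n * 100),
    }


def compute_amfe(mfe_magnitude: float, lp: int) -> float:
    """Adjusted MFE: |ΔG| per 100 nt of precursor, rounded to 2 decimals."""
    if lp <= 0:
        raise ValueError("precursor length must be positive")
    return round2(mfe_magnitude / lp * 100)


def compute_mfei(amfe: float, gc_content_pct: float) -> Optional[float]:
    """MFE index: AMFE / (G+C)%; undefined (None) when GC is zero."""
    if gc_content_pct <= 0:
        return None
    return round2(amfe / gc_content_pct)


def evaluate_criteria(
    candidate: PrecursorCandidate,
    min_lp: int = 60,
    max_nm: int = 6,
    au_range: Tuple[float, float] = (30.0, 70.0),
    mfei_floor: float = 0.85,
    enforce_mfei: bool = False,
) -> HairpinEvaluation:
    """Apply the eight-criterion screen to a folded candidate.

    ``passes_all`` is the conjunction of criteria 1–7, plus the MFEI floor
    when ``enforce_mfei`` is set (the literature states "high MFEI" without
    a universal cutoff, so the floor is advisory by default).
    The evaluation is pure: the same candidate always yields the same row.
    """
    if candidate.structure is None or candidate.mfe_kcal_mol is None:
        raise ValueError(f"candidate {candidate.id!r} must be folded before screening")
    validate_dot_bracket(candidate.structure, name=candidate.id)
    lp = len(candidate.sequence)
    lm = candidate.mature_end - candidate.mature_start
    comp = composition_stats(candidate.sequence)
    mfe_mag = abs(candidate.mfe_kcal_mol)
    amfe = compute_amfe(mfe_mag, lp)
    mfei = compute_mfei(amfe, comp["gc_content_pct"])
    arm = locate_arm(candidate)
    nm = duplex_mismatches(candidate)
    apical = _apical_loop(candidate)

    criteria = {
        "min_length": lp >= min_lp,
        "stem_loop": apical is not None,
        "mature_in_one_arm": arm is not None,
        "duplex_mismatches": nm <= max_nm,
        "no_multibranch": _no_multibranch_on_path(candidate, apical),
        "au_content": au_range[0] <= comp["au_content_pct"] <= au_range[1],
        "negative_mfe": candidate.mfe_kcal_mol < 0,
        "mfei_floor": mfei is not None and mfei >= mfei_floor,
    }
    gating = list(CRITERIA_NAMES[:7]) + (["mfei_floor"] if enforce_mfei else [])
    passes_all = all(criteria[name] for name in gating)
    return HairpinEvaluation(
        id=candidate.id,
        mature_seq=candidate.mature_sequence,
        strand=candidate.strand,
        arm=arm,
        lp=lp,
        lm=lm,
        nm_duplex=nm,
        a_pct=comp["a_pct"], u_pct=comp["u_pct"],
        g_pct=comp["g_pct"], c_pct=comp["c_pct"],
        au_ratio=comp["au_ratio"], gc_ratio=comp["gc_ratio"],
        au_content_pct=comp["au_content_pct"],
        gc_content_pct=comp["gc_content_pct"],
        mfe_magnitude=round2(mfe_mag),
        amfe=amfe,
        mfei=mfei,
        criteria=criteria,
        passes_all=passes_all,
    )


def _no_multibranch_on_path(candidate: PrecursorCandidate,
                            apical: Optional[Tuple[int, int]]) -> bool:
    """True if the nested-pair path from the outermost miRNA/miRNA* duplex
    pair down to the apical loop never branches (no multibranch loop inside
    the duplex-spanning region).  Internal loops and bulges are allowed;
    they are accounted for by the duplex mismatch count instead.  Helices
    outside the duplex span (e.g. in the flanking window) are ignored."""
    if apical is None or candidate.structure is None:
        return False
    partner = _topology_pairs(candidate.structure)
    ai, aj = apical
    duplex_pos = [p for p in range(candidate.mature_start, candidate.mature_end)
                  if partner[p] != -1]
    if not duplex_pos:
        return False
    span = [x for p in duplex_pos for x in (p, partner[p])]
    lo, hi = min(span), max(span)
    # nested pairs between the duplex's outermost pair and the apical loop
    enclosing = [(i, partner[i]) for i in range(lo, ai + 1)
                 if partner[i] > i and aj <= partner[i] <= hi]
    for i, j in enclosing:
        # children: maximal pairs directly nested inside (i, j)
        children = 0
        k = i + 1
        while k < j:
            if partner[k] > k:
                children += 1
                k = partner[k] + 1
            else:
                k += 1
        if children > 1:
            return False
    return True
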