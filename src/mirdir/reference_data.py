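"""Published reference values for three rice DIR-targeting miRNA candidates.

These are the mature sequences, precursor statistics and base-composition
percentages reported for ath-miRf10317-akr, cre-miR910 and
osa-miRf10761-akr — the three miRNAs predicted to target dirigent (DIR)
genes in *Oryza sativa* Indica (targets BGIOSGA034397, BGIOSGA024969 and
BGIOSGA036979 respectively).  They serve as regression fixtures: the
derived columns (AMFE, MFEI, A+U ratios and contents) must recompute from
the primary ones under this package's arithmetic and rounding.

``mfe_magnitude`` is |ΔG| in kcal/mol as printed; ``lp``/``lm`` are
precursor/mature lengths in nt; percentages are of precursor composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple


@dataclass(frozen=True)
class ReportedCandidate:
    mirna_id: str
    mature_sequence: str      # RNA
    target_gene: str
    strand: str
    arm: str                  # location of the mature sequence
    lp: int                   # precursor length (nt)
    lm: int                   # mature length (nt)
    nm: int                   # duplex mismatches
    gc_content_pct: float     # (G+C)% of the precursor
    mfe_magnitude: float      # |ΔG| kcal/mol
    amfe: float               # reported, recomputable as |ΔG|/LP*100
    mfei: float               # reported, recomputable as AMFE/(G+C)%
    a_pct: float
    u_pct: float
    g_pct: float
    c_pct: float
    au_ratio: float
    gc_ratio: float
    au_content_pct: float


REPORTED_CANDIDATES: Dict[str, ReportedCandidate] = {
    "ath-miRf10317-akr": ReportedCandidate(
        mirna_id="ath-miRf10317-akr",
        mature_sequence="GAGAACGCGUCGUCGACGAGU",
        target_gene="BGIOSGA034397",
        strand="+", arm="3p",
        lp=147, lm=21, nm=1,
        gc_content_pct=48.98, mfe_magnitude=39.6, amfe=26.94, mfei=0.55,
        a_pct=27.21, u_pct=23.81, g_pct=29.25, c_pct=19.73,
        au_ratio=1.14, gc_ratio=1.48, au_content_pct=51.02,
    ),
    "cre-miR910": ReportedCandidate(
        mirna_id="cre-miR910",
        mature_sequence="AGCAGCGUCGGGCUCGACCGC",
        target_gene="BGIOSGA024969",
        strand="+", arm="3p",
        lp=227, lm=21, nm=1,
        gc_content_pct=75.33, mfe_magnitude=187.1, amfe=82.42, mfei=1.09,
        a_pct=11.89, u_pct=12.77, g_pct=37.44, c_pct=37.89,
        au_ratio=0.93, gc_ratio=0.99, au_content_pct=24.67,
    ),
    "osa-miRf10761-akr": ReportedCandidate(
        mirna_id="osa-miRf10761-akr",
        mature_sequence="AAUGUGGGCAAUGCUAGAAAGUCUUAU",
        target_gene="BGIOSGA036979",
        strand="+", arm="3p",
        lp=129, lm=27, nm=1,
        gc_content_pct=27.91, mfe_magnitude=56.4, amfe=43.72, mfei=1.57,
        a_pct=34.88, u_pct=37.21, g_pct=14.73, c_pct=13.18,
        au_ratio=0.94, gc_ratio=1.12, au_content_pct=72.09,
    ),
}
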