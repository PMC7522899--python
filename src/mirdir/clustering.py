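"""Greedy incremental redundancy clustering of mature miRNA reference sets.

Public miRNA databases are highly redundant: orthologous mature sequences
recur across species with near-identical sequence.  Before homology search
the reference set is collapsed by greedy longest-first clustering at an
identity threshold (0.90 by default), in the style of CD-HIT: sequences are
processed longest first, each joins the first existing cluster whose
representative it matches at or above the threshold, otherwise it seeds a
new cluster.

Identity follows the CD-HIT convention: identical alignment columns divided
by the length of the shorter sequence, under the best semi-global alignment
of the shorter onto the longer (free end gaps on the longer sequence only).
Internal gap columns are penalized so that an insertion/deletion pair can
never be used to manufacture an extra match.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

from .formats_io import SequenceRecord, normalize_sequence

logger = logging.getLogger(__name__)

_MATCH = 1.0
_GAP = -0.5  # per gap column; 2 * |_GAP| >= _MATCH blocks indel-pair tricks


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA reference entry (RNA alphabet)."""

    id: str
    sequence: str
    family: Optional[str] = None
    species_prefix: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"miRNA {self.id!r}: empty sequence")
        bad = set(self.sequence) - set("ACGU")
        if bad:
            raise ValueError(f"miRNA {self.id!r}: non-RNA characters {sorted(bad)}")
        if not 15 <= len(self.sequence) <= 30:
            warnings.warn(
                f"miRNA {self.id!r}: length {len(self.sequence)} outside the "
                "typical mature range 15-30 nt",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_record(cls, rec: SequenceRecord) -> "MatureMiRNA":
        prefix = rec.id.split("-")[0] if "-" in rec.id else None
        return cls(id=rec.id, sequence=normalize_sequence(rec.sequence, "rna"),
                   species_prefix=prefix)


@dataclass
class Cluster:
    """A redundancy cluster: representative plus all members (incl. itself)."""

    representative: MatureMiRNA
    members: List[MatureMiRNA]
    threshold: float


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns over the shorter sequence length.

    Semi-global alignment: the shorter sequence is aligned end to end onto
    the longer one (leading/trailing gaps on the longer are free; internal
    gap columns cost 0.5 each, matches score 1, mismatches 0).  Among
    maximum-score alignments the one with fewest gap columns defines the
    result, so substitutions are counted as mismatched columns rather than
    re-aligned around; the match count is then fully determined by
    M = S + G/2 (score S, gap columns G).
    """
    if not a or not b:
        raise ValueError("pairwise_identity: empty sequence")
    a = normalize_sequence(a, "rna")
    b = normalize_sequence(b, "rna")
    # canonical order for exact symmetry
    s, t = sorted((a, b), key=lambda x: (len(x), x))
    m, n = len(s), len(t)
    # dp over (score, -gap_columns), lexicographic; scores are multiples of
    # 0.5 so float comparisons are exact
    score = [[0.0] * (n + 1) for _ in range(m + 1)]
    gaps = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        score[i][0] = i * _GAP
        gaps[i][0] = i
    for i in range(1, m + 1):
        si = s[i - 1]
        last_row = i == m  # trailing gaps on t are free
        for j in range(1, n + 1):
            hit = _MATCH if si == t[j - 1] else 0.0
            best = (score[i - 1][j - 1] + hit, -gaps[i - 1][j - 1])
            up = (score[i - 1][j] + _GAP, -(gaps[i - 1][j] + 1))
            if up > best:
                best = up
            if last_row:
                left = (score[i][j - 1], -gaps[i][j - 1])
            else:
                left = (score[i][j - 1] + _GAP, -(gaps[i][j - 1] + 1))
            if left > best:
                best = left
            score[i][j], gaps[i][j] = best[0], -best[1]
    matches = score[m][n] + 0.5 * gaps[m][n]
    return matches / m


def greedy_cluster(mirnas: Sequence[MatureMiRNA], threshold: float = 0.90) -> List[Cluster]:
    """CD-HIT-style greedy clustering.

    Input is processed sorted by (length desc, id asc).  Each sequence joins
    the first cluster (creation order) whose representative it matches at
    identity >= ``threshold``, else it seeds a new cluster.  Because of the
    processing order, every representative is the longest member of its
    cluster (ties broken by lexicographically smallest id).
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside (0.5, 1.0]")
    ids = [m.id for m in mirnas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate miRNA ids in input")
    ordered = sorted(mirnas, key=lambda m: (-len(m.sequence), m.id))
    clusters: List[Cluster] = []
    for mirna in ordered:
        placed = False
        for cluster in clusters:
            if pairwise_identity(mirna.sequence, cluster.representative.sequence) >= threshold:
                cluster.members.append(mirna)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=mirna, members=[mirna],
                                    threshold=threshold))
    logger.info("greedy_cluster: %d sequences -> %d clusters at identity %.2f",
                len(ordered), len(clusters), threshold)
    return clusters


def representatives(clusters: Sequence[Cluster]) -> List[MatureMiRNA]:
    """One representative per cluster, in cluster-creation order."""
    return [c.representative for c in clusters]


def clusters_to_rows(clusters: Sequence[Cluster]) -> List[Tuple[int, str, str, float]]:
    """Flatten clusters into (cluster_id, representative_id, member_id, identity) rows."""
    rows = []
    for idx, cluster in enumerate(clusters):
        for member in cluster.members:
            ident = pairwise_identity(member.sequence, cluster.representative.sequence)
            rows.append((idx, cluster.representative.id, member.id, round(ident, 4)))
    return rows
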