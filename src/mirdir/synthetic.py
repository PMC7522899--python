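"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs to this pipeline come from public databases (a mature-miRNA
reference set, a gene-family nucleotide set, qPCR plates).  The generators
here emit files with the same statistical structure — clustered redundant
miRNA families, genes with planted near-exact miRNA homologs, stem-loop
precursors with a known mature arm and duplex mismatch count, and Ct tables
with planted fold changes under reference-gene normalization — together
with a machine-readable truth record, so recovery can be asserted exactly.

Determinism: one integer seed drives a separate named child stream per
generator (``numpy.random.default_rng(seed + offset)`` with fixed offsets),
so adding a generator never perturbs the output of another; identical seeds
give byte-identical files.

Background base composition is uniform (25% each) unless an A+U target is
requested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .clustering import MatureMiRNA, pairwise_identity
from .formats_io import SequenceRecord
from .hairpin import PrecursorCandidate, PAIR_ENERGY
from .homology import reverse_complement

RNA = "ACGU"
DNA = "ACGT"

# fixed stream offsets per generator (documented stream splitting)
_STREAMS = {"mirna": 11, "gene": 23, "hairpin": 37, "ct": 53}


@dataclass
class SyntheticTruth:
    """Ground truth for one generated bundle."""

    rng_seed: int
    planted_clusters: Dict[str, List[str]] = field(default_factory=dict)
    planted_homologs: List[dict] = field(default_factory=list)
    planted_hairpins: List[dict] = field(default_factory=list)
    planted_folds: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(int(seed) + _STREAMS[stream])


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = RNA) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def gen_mirna_reference(
    n_families: int = 10,
    members_per_family: int = 3,
    within_identity: float = 0.90,
    between_identity: float = 0.70,
    length_range: Tuple[int, int] = (20, 24),
    seed: int = 0,
) -> Tuple[List[MatureMiRNA], SyntheticTruth]:
    """A redundant mature-miRNA reference set with planted families.

    Each family is a seed sequence plus substitution variants kept within
    ``within_identity`` of the seed; seeds are re-drawn until all pairwise
    seed identities are at most ``between_identity``.  Clustering at the
    within-identity threshold therefore recovers exactly ``n_families``
    clusters.  Member ids sort after their seed so the seed is always the
    cluster representative.
    """
    if within_identity <= between_identity:
        raise ValueError("identity bands must not overlap")
    rng = _rng(seed, "mirna")
    min_len = length_range[0]
    if int((1 - within_identity) * min_len) < 1 and members_per_family > 1:
        raise ValueError(
            f"identity band {within_identity} leaves no substitution budget "
            f"at length {min_len}"
        )
    seeds: List[str] = []
    lengths: List[int] = []
    attempts = 0
    while len(seeds) < n_families:
        attempts += 1
        if attempts > 200 * n_families:
            raise ValueError("could not draw family seeds inside the identity band")
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        cand = _random_seq(rng, L)
        if all(pairwise_identity(cand, s) <= between_identity for s in seeds):
            seeds.append(cand)
            lengths.append(L)

    mirnas: List[MatureMiRNA] = []
    truth = SyntheticTruth(rng_seed=seed)
    for f, seq in enumerate(seeds):
        fam = f"fam{f:03d}"
        seed_id = f"{fam}_a000"  # sorts before every member id
        mirnas.append(MatureMiRNA(id=seed_id, sequence=seq, family=fam))
        members = [seed_id]
        budget = int((1 - within_identity) * len(seq))
        for m in range(1, members_per_family):
            while True:
                k = int(rng.integers(0, budget + 1)) if budget else 0
                positions = rng.choice(len(seq), size=k, replace=False)
                variant = list(seq)
                for p in positions:
                    variant[p] = rng.choice([b for b in RNA if b != seq[p]])
                vseq = "".join(variant)
                if (pairwise_identity(vseq, seq) >= within_identity and
                        all(pairwise_identity(vseq, s) < within_identity
                            for s in seeds if s != seq)):
                    break
            member_id = f"{fam}_m{m:03d}"
            mirnas.append(MatureMiRNA(id=member_id, sequence=vseq, family=fam))
            members.append(member_id)
        truth.planted_clusters[seed_id] = members
    return mirnas, truth


_DNA_COMPL = {"A": "T", "T": "A", "G": "C", "C": "G"}


def gen_gene_family(
    n_genes: int = 8,
    gene_length: int = 600,
    planted: Sequence[Tuple[str, int, str]] = (),
    seed: int = 0,
    hairpin_context: bool = False,
    loop_len: int = 8,
) -> Tuple[List[SequenceRecord], SyntheticTruth]:
    """Random uniform-composition genes with planted miRNA homologs.

    ``planted`` entries are (mirna_sequence_or_MatureMiRNA, n_mismatches,
    strand); each is substituted at ``n_mismatches`` positions, reverse
    complemented for minus-strand plants, and written once into a randomly
    chosen gene at a recorded position (plants never overlap).  With
    ``hairpin_context`` the mature copy is planted together with a star
    strand (the reverse complement of the unmutated mature) and a short
    loop — star, loop, mature in 5'→3' order — so that windows extracted
    around the homolog can fold into a screening-grade stem-loop with the
    mature on the 3' arm; the recorded position is that of the mature copy.
    """
    rng = _rng(seed, "gene")
    genes = [list(_random_seq(rng, gene_length, DNA)) for _ in range(n_genes)]
    occupied: Dict[int, List[Tuple[int, int]]] = {i: [] for i in range(n_genes)}
    truth = SyntheticTruth(rng_seed=seed)
    for item in planted:
        mir, n_mismatches, strand = item
        if n_mismatches > 6:
            raise ValueError("n_mismatches above the screening ceiling of 6")
        mirna_id = getattr(mir, "id", None) or f"planted{len(truth.planted_homologs)}"
        mir_seq = getattr(mir, "sequence", mir)
        insert = mir_seq.upper().replace("U", "T")
        L = len(insert)
        positions = rng.choice(L, size=n_mismatches, replace=False) if n_mismatches else []
        mutated = list(insert)
        for p in positions:
            mutated[p] = rng.choice([b for b in DNA if b != insert[p]])
        mature_copy = "".join(mutated)
        if hairpin_context:
            # Star = perfect complement of the planted mature copy except one
            # GU-wobble substitution: the duplex stays fully paired under the
            # folding model, while the extra sequence difference makes the
            # mature copy the strictly better search hit on its own strand.
            star = list(reverse_complement(mature_copy))
            mutated_set = {L - 1 - int(p) for p in positions}  # star frame
            wobble = [q for q in range(L)
                      if q not in mutated_set and star[q] in "AC"]
            if wobble:
                q = int(rng.choice(wobble))
                star[q] = "G" if star[q] == "A" else "T"  # U-G / G-U wobble
            else:  # no wobble-capable position: open one duplex pair instead
                q = int(rng.choice([q for q in range(L) if q not in mutated_set]))
                star[q] = _DNA_COMPL[star[q]]
            star = "".join(star)
            loop = "".join(rng.choice(["A", "C"], size=loop_len))  # non-pairing
            payload = star + loop + mature_copy
            mature_offset = len(star) + loop_len
        else:
            payload = mature_copy
            mature_offset = 0
        if strand == "-":
            payload = reverse_complement(payload)
            # mature lands at the start of the reversed payload
            mature_offset = len(payload) - mature_offset - L
        P = len(payload)
        if gene_length < P + 2:
            raise ValueError("gene too short for planted insert")
        for _ in range(200):
            g = int(rng.integers(0, n_genes))
            start = int(rng.integers(0, gene_length - P + 1))
            span = (start, start + P)
            if all(span[1] <= a or span[0] >= b for a, b in occupied[g]):
                break
        else:
            raise ValueError("could not place planted homolog without overlap")
        occupied[g].append(span)
        genes[g][start : start + P] = payload
        truth.planted_homologs.append({
            "mirna_id": mirna_id, "gene_id": f"gene{g:03d}",
            "position": start + mature_offset, "n_mismatches": int(n_mismatches),
            "strand": strand,
        })
    records = [
        SequenceRecord(id=f"gene{i:03d}", description=f"gene{i:03d} synthetic",
                       sequence="".join(g), moltype="dna")
        for i, g in enumerate(genes)
    ]
    return records, truth


def _class_preserving_mismatch(base: str) -> str:
    """A non-pairing replacement for the star position opposite ``base``.

    Using the base itself guarantees no Watson–Crick or GU wobble pair while
    keeping A+U / G+C composition unchanged (A-A, U-U, G-G, C-C never pair).
    """
    return base


_COMPL = {"A": "U", "U": "A", "G": "C", "C": "G"}


def gen_hairpin(
    lp: int = 80,
    mature_len: int = 21,
    arm: str = "3p",
    duplex_mismatches: int = 0,
    au_target_pct: float = 50.0,
    seed: int = 0,
    loop_len: Optional[int] = None,
    ident: str = "hairpin0",
) -> Tuple[PrecursorCandidate, SyntheticTruth]:
    """A single stem-loop precursor with planted screen properties.

    Construction: a 5' stem strand, an apical loop, and the 3' strand as the
    reverse complement of the 5' strand (so composition classes are
    symmetric).  ``duplex_mismatches`` mature positions are then unpaired by
    replacing the star nucleotide with a same-class non-pairing base and
    opening the pair in the emitted structure.  The A+U fraction is set
    exactly at construction (within ±2% of ``au_target_pct`` after integer
    rounding).  The emitted structure is the ground-truth fold, marked
    ``fold_source="external"``.
    """
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be '5p' or '3p'")
    if duplex_mismatches >= mature_len:
        raise ValueError("duplex_mismatches must be below the mature length")
    if loop_len is None:
        loop_len = 4 + (lp % 2)  # smallest comfortable loop with matching parity
    if (lp - loop_len) % 2:
        loop_len += 1
    stem = (lp - loop_len) // 2
    if stem < mature_len:
        raise ValueError(
            f"lp={lp} with loop {loop_len} leaves stem {stem} < mature {mature_len}"
        )
    rng = _rng(seed, "hairpin")

    n_au = round(au_target_pct / 100 * lp)
    # 3' strand mirrors 5' composition classes; distribute AU budget
    a5 = min(stem, n_au // 2)
    al = n_au - 2 * a5
    if al > loop_len:
        raise ValueError("A+U target infeasible for this stem/loop split")

    def draw(n_total: int, n_au_here: int) -> str:
        kinds = ["AU"] * n_au_here + ["GC"] * (n_total - n_au_here)
        rng.shuffle(kinds)
        return "".join(rng.choice(list(kind)) for kind in kinds)

    strand5 = draw(stem, a5)
    loop = draw(loop_len, al)
    strand3 = "".join(_COMPL[b] for b in reversed(strand5))
    seq = list(strand5 + loop + strand3)
    structure = ["("] * stem + ["."] * loop_len + [")"] * stem

    if arm == "5p":
        offset = int(rng.integers(0, stem - mature_len + 1))
        mature_start = offset
    else:
        offset = int(rng.integers(0, stem - mature_len + 1))
        mature_start = stem + loop_len + offset
    mature_end = mature_start + mature_len

    mm_positions = rng.choice(
        np.arange(mature_start, mature_end), size=duplex_mismatches, replace=False
    ) if duplex_mismatches else []
    for p in sorted(int(x) for x in mm_positions):
        # partner index in a perfect symmetric stem: i pairs with lp-1-i
        q = lp - 1 - p
        seq[q] = _class_preserving_mismatch(seq[p])
        structure[p] = "."
        structure[q] = "."

    energy = 0.0
    for i in range(stem):
        if structure[i] == "(":
            energy += PAIR_ENERGY[(seq[i], seq[lp - 1 - i])]

    candidate = PrecursorCandidate(
        id=ident,
        sequence="".join(seq),
        mature_start=mature_start,
        mature_end=mature_end,
        structure="".join(structure),
        mfe_kcal_mol=energy,
        fold_source="external",
    )
    truth = SyntheticTruth(rng_seed=seed)
    truth.planted_hairpins.append({
        "precursor_id": ident,
        "mature_start": mature_start, "mature_end": mature_end,
        "arm": arm, "duplex_mismatches": int(duplex_mismatches),
        "au_content_pct": 100.0 * sum(b in "AU" for b in seq) / lp,
    })
    return candidate, truth


def gen_ct_table(
    genes: Sequence[str],
    conditions: Sequence[str],
    true_folds: Dict[str, Dict[str, float]],
    reference_gene: str = "actin1",
    control_condition: str = "control",
    ct_noise_sd: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
    baseline_ct: float = 25.0,
    reference_ct: float = 18.0,
):
    """A long-format Ct table with planted fold changes.

    ``true_folds[gene][condition]`` is the planted 2^−ΔΔCt value relative to
    the control condition; the gene's Ct in that condition is shifted by
    −log2(fold).  Gaussian noise of SD ``ct_noise_sd`` is added to every
    well, including the reference gene.  With zero noise the ΔΔCt estimator
    returns the planted folds exactly.
    """
    from .expression import CtTable

    if replicates < 2:
        raise ValueError("at least 2 replicates are required")
    for g, conds in true_folds.items():
        for c, f in conds.items():
            if f <= 0:
                raise ValueError(f"true fold for {g}/{c} must be positive")
    rng = _rng(seed, "ct")
    rows = []
    all_genes = [reference_gene] + [g for g in genes if g != reference_gene]
    all_conditions = list(conditions)
    if control_condition not in all_conditions:
        all_conditions = [control_condition] + all_conditions
    for gene in all_genes:
        for cond in all_conditions:
            if gene == reference_gene:
                mean_ct = reference_ct
            else:
                fold = 1.0 if cond == control_condition else (
                    true_folds.get(gene, {}).get(cond, 1.0))
                mean_ct = baseline_ct - np.log2(fold) + (reference_ct - 18.0)
            for rep in range(1, replicates + 1):
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append({"gene": gene, "condition": cond,
                             "replicate": rep, "ct": mean_ct + noise})
    df = pd.DataFrame(rows)
    truth = SyntheticTruth(rng_seed=seed, planted_folds={
        g: dict(conds) for g, conds in true_folds.items()})
    return CtTable(df=df, reference_gene=reference_gene,
                   control_condition=control_condition), truth
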