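"""Relative expression from qPCR threshold cycles and miRNA/target reports.

Expression of each gene (or miRNA assay) is quantified by the comparative
threshold-cycle method: within each condition, ΔCt = Ct(gene) − Ct(reference
gene) per replicate; ΔΔCt = mean ΔCt(condition) − mean ΔCt(control); and
the relative fold change is 2^−ΔΔCt.  A reference gene with stable
expression (e.g. rice actin 1) normalizes loading; the control condition
anchors fold change at exactly 1.

Significance is assessed per condition with a two-sided two-sample t-test
on the replicate ΔCt values (Welch by default, pooled-variance optional),
at p <= 0.05.  The inverse-pattern report cross-tabulates each
miRNA/target pair per condition: "inverse" when both are significant with
opposite directions — the signature of miRNA-guided repression —
"concordant" when directions agree, "ns" otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .homology import HomologyHit

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class TargetAssignment:
    """A surviving miRNA→gene pair from the homology/screening stages."""

    mirna_id: str
    gene_id: str
    hit: Optional[HomologyHit] = None


@dataclass
class CtTable:
    """Long-format Ct measurements plus normalization metadata."""

    df: pd.DataFrame  # columns: gene, condition, replicate, ct
    reference_gene: Optional[str] = None
    control_condition: Optional[str] = None

    def check_reference(self) -> None:
        if self.reference_gene is None:
            raise ValueError("no reference gene set")
        conditions = set(self.df["condition"])
        have = set(self.df.loc[self.df["gene"] == self.reference_gene, "condition"])
        missing = conditions - have
        if missing:
            raise ValueError(
                f"reference gene {self.reference_gene!r} missing in "
                f"condition(s) {sorted(missing)}"
            )

    def conditions(self) -> List[str]:
        return sorted(set(self.df["condition"]))

    def genes(self) -> List[str]:
        return sorted(set(self.df["gene"]))


@dataclass
class ExpressionRecord:
    gene: str
    condition: str
    fold_change: float   # 2^-ddCt
    log2_fold: float
    sd: float            # SD of per-replicate fold changes
    log2_sd: float
    p_value: Optional[float]
    significant: bool
    direction: str       # "up" | "down" | "ns"
    n_replicates: int


def ttest_two_sample(a: Sequence[float], b: Sequence[float],
                     equal_var: bool = False) -> float:
    """Two-sided two-sample t-test p-value (Welch unless ``equal_var``).

    Degenerate zero-variance groups: p = 1 when the means are equal (no
    evidence of difference), 0 when both variances are zero but the means
    differ (the statistic diverges).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def ddct(table: CtTable, reference_gene: Optional[str] = None,
         control_condition: Optional[str] = None,
         equal_var: bool = False) -> List[ExpressionRecord]:
    """Relative expression (2^−ΔΔCt) per gene and condition.

    Per replicate, ΔCt = Ct(gene) − Ct(reference) within the same condition
    and replicate; ΔΔCt = mean ΔCt(condition) − mean ΔCt(control);
    fold = 2^−ΔΔCt.  Per-replicate folds (replicate ΔCt against the control
    mean) give the SD; a two-sample t-test of treated vs control ΔCt
    replicates gives p (None when a side has fewer than 2 replicates).
    """
    ref = reference_gene or table.reference_gene
    ctrl = control_condition or table.control_condition
    if ref is None or ctrl is None:
        raise ValueError("reference gene and control condition are required")
    df = table.df
    if ctrl not in set(df["condition"]):
        raise ValueError(f"control condition {ctrl!r} not in table")
    CtTable(df, ref, ctrl).check_reference()

    ref_ct = (df[df["gene"] == ref]
              .set_index(["condition", "replicate"])["ct"])
    records: List[ExpressionRecord] = []
    for gene, gdf in df[df["gene"] != ref].groupby("gene", sort=True):
        dct: Dict[str, np.ndarray] = {}
        for cond, cdf in gdf.groupby("condition", sort=True):
            keyed = cdf.set_index("replicate")["ct"]
            vals = []
            for rep, ct in keyed.items():
                try:
                    vals.append(ct - ref_ct.loc[(cond, rep)])
                except KeyError:
                    raise ValueError(
                        f"reference {ref!r} has no replicate {rep} in "
                        f"condition {cond!r}"
                    )
            dct[cond] = np.asarray(vals, dtype=float)
        if ctrl not in dct:
            raise ValueError(f"gene {gene!r} missing control condition {ctrl!r}")
        ctrl_mean = dct[ctrl].mean()
        for cond in sorted(dct):
            delta = dct[cond]
            ddct_val = delta.mean() - ctrl_mean if cond != ctrl else 0.0
            fold = 2.0 ** (-ddct_val)
            rep_folds = 2.0 ** (-(delta - ctrl_mean))
            sd = float(rep_folds.std(ddof=1)) if len(rep_folds) > 1 else 0.0
            log2_sd = float((-(delta - ctrl_mean)).std(ddof=1)) if len(delta) > 1 else 0.0
            if cond == ctrl:
                p: Optional[float] = None if len(delta) < 2 else 1.0
            elif len(delta) < 2 or len(dct[ctrl]) < 2:
                p = None
            else:
                p = ttest_two_sample(delta, dct[ctrl], equal_var=equal_var)
            significant = p is not None and p <= ALPHA and cond != ctrl
            if not significant:
                direction = "ns"
            else:
                direction = "up" if fold > 1 else "down"
            records.append(ExpressionRecord(
                gene=gene, condition=cond,
                fold_change=float(fold), log2_fold=float(-ddct_val),
                sd=sd, log2_sd=log2_sd,
                p_value=p, significant=significant, direction=direction,
                n_replicates=len(delta),
            ))
    return records


def average_technical_replicates(df: pd.DataFrame,
                                 bio_col: str = "biological",
                                 ) -> pd.DataFrame:
    """Collapse technical replicates into biological units.

    Expects an extra column naming the biological replicate; technical Cts
    within each (gene, condition, biological) cell are averaged and the
    biological id becomes the replicate.
    """
    if bio_col not in df.columns:
        raise ValueError(f"column {bio_col!r} not present")
    out = (df.groupby(["gene", "condition", bio_col], as_index=False)["ct"]
           .mean().rename(columns={bio_col: "replicate"}))
    return out[["gene", "condition", "replicate", "ct"]]


def inverse_pattern_report(
    mirna_records: Sequence[ExpressionRecord],
    target_records: Sequence[ExpressionRecord],
    pairs: Sequence[TargetAssignment],
    control_condition: Optional[str] = None,
) -> pd.DataFrame:
    """Label each miRNA/target pair per condition.

    "inverse" when both members are significant with opposite directions,
    "concordant" when both significant with the same direction, "ns" when
    either is non-significant.  The control condition (fold 1 by
    construction) is excluded.
    """
    def index(records: Sequence[ExpressionRecord]) -> Dict:
        return {(r.gene, r.condition): r for r in records}

    mi = index(mirna_records)
    ti = index(target_records)
    mir_conditions = {c for (_, c) in mi}
    tgt_conditions = {c for (_, c) in ti}
    if mir_conditions != tgt_conditions:
        missing = mir_conditions.symmetric_difference(tgt_conditions)
        raise ValueError(f"condition mismatch between record sets: {sorted(missing)}")
    conditions = sorted(c for c in mir_conditions if c != control_condition)
    rows = []
    for pair in pairs:
        for cond in conditions:
            mrec = mi.get((pair.mirna_id, cond))
            trec = ti.get((pair.gene_id, cond))
            if mrec is None or trec is None:
                continue
            if not (mrec.significant and trec.significant):
                label = "ns"
            elif mrec.direction != trec.direction:
                label = "inverse"
            else:
                label = "concordant"
            rows.append({
                "mirna_id": pair.mirna_id, "gene_id": pair.gene_id,
                "condition": cond,
                "mirna_fold": mrec.fold_change, "mirna_p": mrec.p_value,
                "mirna_direction": mrec.direction,
                "target_fold": trec.fold_change, "target_p": trec.p_value,
                "target_direction": trec.direction,
                "pattern": label,
            })
    return pd.DataFrame(rows)


def expression_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
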