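"""Expression rules of the survey.

Expressed/not-expressed thresholding on condition means (FPKM/RPKM below 1
counts as not expressed), log10(x+1) scaling, fold-change differential
expression calls (|log10 FC| >= log10 2, i.e. a two-fold change on
pseudocounted condition means), and 2^-delta-delta-Ct qPCR quantification
with Welch t-tests on replicate delta-Ct values.

The fold-change criterion deliberately applies no replicate-level test and
no multiple-testing correction: DE status is a property of condition means
alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LOG10_2 = math.log10(2.0)


@dataclass
class ExpressionMatrix:
    """Genes x samples of non-negative FPKM/RPKM values plus a sample →
    (condition, replicate) map."""

    values: pd.DataFrame
    condition_of_sample: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.condition_of_sample)
        if missing:
            raise ValueError(f"samples without a condition: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.condition_of_sample[s][0]
            if c not in seen:
                seen.append(c)
        return seen

    def condition_means(self) -> pd.DataFrame:
        """Genes x conditions mean over replicates."""
        groups: dict[str, list[str]] = {}
        for s in self.values.columns:
            groups.setdefault(self.condition_of_sample[s][0], []).append(s)
        return pd.DataFrame(
            {c: self.values[cols].mean(axis=1) for c, cols in groups.items()}
        )


@dataclass
class DECall:
    gene_id: str
    contrast: tuple[str, str]      # (treatment, control)
    log10_ratio: float
    direction: str                 # up | down | none


@dataclass
class QpcrResult:
    gene_id: str
    timepoint: str
    delta_delta_ct: float
    relative_quantity: float
    p_value: Optional[float]
    significance: str              # ns | * | **


def call_expressed(matrix: ExpressionMatrix, threshold: float = 1.0) -> pd.DataFrame:
    """Boolean genes x conditions table; a condition mean strictly below
    ``threshold`` means not expressed."""
    return matrix.condition_means() >= threshold


def tissue_specificity(
    matrix: ExpressionMatrix, min_expr: float = 1.0, fold: float = 2.0
) -> pd.DataFrame:
    """Per-gene top tissue and a specificity flag.

    Specific when the top condition mean is at least ``min_expr`` and at
    least ``fold`` times the second-highest mean.  Ties go to the
    lexicographically first condition and are flagged.
    """
    means = matrix.condition_means()
    if means.shape[1] < 2:
        raise ValueError("tissue specificity needs at least two conditions")
    means = means[sorted(means.columns)]
    rows = []
    for gene, row in means.iterrows():
        order = row.sort_values(ascending=False, kind="stable")
        top, second = order.iloc[0], order.iloc[1]
        tie = bool(np.isclose(top, second) and order.index[0] != order.index[1])
        rows.append(
            {
                "gene_id": gene,
                "top_tissue": order.index[0],
                "specific": bool(top >= min_expr and top >= fold * second),
                "tie": tie,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    if (matrix.values.values < 0).any():
        raise ValueError("negative expression values")
    return ExpressionMatrix(
        values=np.log10(matrix.values + pseudocount),
        condition_of_sample=dict(matrix.condition_of_sample),
    )


def call_de(
    matrix: ExpressionMatrix,
    treatment: str,
    control: str,
    pseudocount: float = 1.0,
    fold: float = 2.0,
) -> list[DECall]:
    """Fold-change DE calls on pseudocounted condition means."""
    means = matrix.condition_means()
    for c in (treatment, control):
        if c not in means.columns:
            raise KeyError(f"condition {c!r} absent from matrix")
    cutoff = math.log10(fold)
    calls = []
    for gene in means.index:
        ratio = math.log10(
            (means.at[gene, treatment] + pseudocount)
            / (means.at[gene, control] + pseudocount)
        )
        if ratio >= cutoff:
            direction = "up"
        elif ratio <= -cutoff:
            direction = "down"
        else:
            direction = "none"
        calls.append(DECall(gene, (treatment, control), ratio, direction))
    return calls


def de_summary(calls: Sequence[DECall]) -> dict[str, int]:
    up = sum(1 for c in calls if c.direction == "up")
    down = sum(1 for c in calls if c.direction == "down")
    return {"up": up, "down": down, "total_de": up + down}


# ---------------------------------------------------------------------------
# qPCR

def _stars(p: Optional[float]) -> str:
    if p is None:
        return "ns"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ddct(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_condition: str,
    welch: bool = True,
) -> list[QpcrResult]:
    """Relative quantification by 2^-ddCt.

    ``ct_table`` has columns gene, condition, replicate, ct.  Per replicate
    dCt = Ct_target - Ct_reference; ddCt = mean dCt(condition) - mean
    dCt(control); RQ = 2^-ddCt.  The p-value is a two-sided t-test (Welch by
    default) on replicate dCt values against the control condition.
    """
    required = {"gene", "condition", "replicate", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")

    def dct_values(condition: str) -> np.ndarray:
        sub = ct_table[ct_table["condition"] == condition]
        tgt = sub[sub["gene"] == target_gene].set_index("replicate")["ct"]
        ref = sub[sub["gene"] == reference_gene].set_index("replicate")["ct"]
        if ref.empty:
            raise ValueError(f"reference gene {reference_gene!r} missing in {condition!r}")
        if tgt.empty:
            raise ValueError(f"target gene {target_gene!r} missing in {condition!r}")
        common = tgt.index.intersection(ref.index)
        if common.empty:
            raise ValueError(f"no shared replicates for {condition!r}")
        return (tgt.loc[common] - ref.loc[common]).to_numpy(dtype=float)

    control = dct_values(control_condition)
    results = []
    for condition in dict.fromkeys(ct_table["condition"]):
        vals = dct_values(condition)
        ddct_value = float(vals.mean() - control.mean())
        rq = 2.0 ** (-ddct_value)
        if condition == control_condition:
            p = 1.0 if len(vals) > 1 else None
        elif len(vals) > 1 and len(control) > 1:
            p = float(stats.ttest_ind(vals, control, equal_var=not welch).pvalue)
        else:
            p = None
        results.append(
            QpcrResult(
                gene_id=target_gene,
                timepoint=condition,
                delta_delta_ct=ddct_value,
                relative_quantity=rq,
                p_value=p,
                significance=_stars(p),
            )
        )
    return results


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return df


def read_expression_matrix(values_path, sample_map_path) -> ExpressionMatrix:
    """TSV of genes x samples plus a sample→condition map TSV
    (columns sample, condition, replicate)."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    smap = pd.read_csv(sample_map_path, sep="\t")
    mapping = {
        str(r["sample"]): (str(r["condition"]), int(r["replicate"]))
        for _, r in smap.iterrows()
    }
    return ExpressionMatrix(values=values, condition_of_sample=mapping)
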