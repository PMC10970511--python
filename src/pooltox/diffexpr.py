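"""Per-lot differential expression on log2 expression matrices.

Fold change is the difference of arm means on the log2 scale (treated minus
control). Significance uses a per-gene Welch unequal-variance t-test followed
by Benjamini–Hochberg FDR control; genes with q <= q_max (default 0.1,
boundary inclusive) are called differentially expressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionStudy

DEFAULT_Q_MAX = 0.1


@dataclass
class FoldChangeTable:
    """Per-lot DE results: one row per measured gene.

    ``table`` columns: gene (index), log2_fc, p_raw, q_value, significant.
    """

    lot_id: str
    table: pd.DataFrame
    treated: str = "high"
    control: str = "control"
    q_max: float = DEFAULT_Q_MAX

    @property
    def fc(self) -> pd.Series:
        return self.table["log2_fc"]

    def significant_genes(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


def _arms(study: ExpressionStudy, lot: str, treated: str, control: str):
    a = study.arm(lot, treated)
    b = study.arm(lot, control)
    for name, arm in ((treated, a), (control, b)):
        if arm.shape[1] < 2:
            raise ValueError(
                f"lot {lot!r} arm {name!r} has {arm.shape[1]} replicate(s); need >= 2"
            )
    return a.to_numpy(dtype=float), b.to_numpy(dtype=float)


def compute_fold_changes(
    study: ExpressionStudy, lot: str, treated: str = "high", control: str = "control"
) -> pd.Series:
    """log2 FC per gene: mean treated log2 expression minus mean control."""
    t, c = _arms(study, lot, treated, control)
    return pd.Series(t.mean(axis=1) - c.mean(axis=1), index=study.expression.index,
                     name="log2_fc")


def welch_test(
    study: ExpressionStudy, lot: str, treated: str = "high", control: str = "control"
) -> pd.Series:
    """Two-sided Welch t-test p-value per gene on log2 values.

    Genes with zero variance in both arms get p = 1 when the arm means are
    equal (no evidence of change) and p = 0 when they differ (infinite t).
    """
    t, c = _arms(study, lot, treated, control)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(t, c, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    v1 = t.var(axis=1, ddof=1)
    v2 = c.var(axis=1, ddof=1)
    degenerate = (v1 == 0) & (v2 == 0)
    equal_means = t.mean(axis=1) == c.mean(axis=1)
    p[degenerate & equal_means] = 1.0
    p[degenerate & ~equal_means] = 0.0
    return pd.Series(p, index=study.expression.index, name="p_raw")


def bh_adjust(p_values: pd.Series) -> pd.Series:
    """Benjamini–Hochberg step-up q-values (capped at 1, order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return pd.Series(p, index=p_values.index, name="q_value")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return pd.Series(q, index=p_values.index, name="q_value")


def call_significant(fc_table: FoldChangeTable, q_max: float = DEFAULT_Q_MAX) -> set[str]:
    """Genes with q <= q_max (inclusive boundary)."""
    return set(fc_table.table.index[fc_table.table["q_value"] <= q_max])


def differential_expression(
    study: ExpressionStudy,
    lot: str,
    treated: str = "high",
    control: str = "control",
    q_max: float = DEFAULT_Q_MAX,
) -> FoldChangeTable:
    """Full per-lot DE pass: fold change, Welch p, BH q, significance flag."""
    fc = compute_fold_changes(study, lot, treated, control)
    p = welch_test(study, lot, treated, control)
    q = bh_adjust(p)
    table = pd.DataFrame({"log2_fc": fc, "p_raw": p, "q_value": q})
    table["significant"] = table["q_value"] <= q_max
    table.index.name = "gene"
    return FoldChangeTable(lot_id=lot, table=table, treated=treated,
                           control=control, q_max=q_max)


def de_all_lots(
    study: ExpressionStudy,
    treated: str = "high",
    control: str = "control",
    q_max: float = DEFAULT_Q_MAX,
) -> dict[str, FoldChangeTable]:
    """Run :func:`differential_expression` for every lot, keyed by lot id."""
    return {
        lot: differential_expression(study, lot, treated, control, q_max)
        for lot in study.lots
    }
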