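"""Lot-to-lot agreement analytics.

Quantifies how reproducible the treatment response is across lots of pooled
hepatocytes: pairwise DE-gene overlaps, the genes significant in every lot,
the merged (lot-averaged) fold-change profile, Pearson correlation matrices
including the merged column, per-gene cross-lot SD profiles with
fraction-below-threshold summaries, ranked top-k gene tables, and
sign-consistency flags for user-specified gene panels (e.g. transporters and
cytochrome P450 enzymes).

Conventions: sample SD uses the n-1 denominator everywhere; "fraction below
a threshold" is strictly below; report tables round half-away-from-zero at
2 decimals while full-precision values are always also emitted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import FoldChangeTable

logger = logging.getLogger(__name__)

MERGED = "merged"

CONSISTENT_UP = "consistent_up"
CONSISTENT_DOWN = "consistent_down"
MIXED = "mixed"


def round_half_away(x, decimals: int = 2):
    """Round half away from zero (the convention of printed report tables)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return out if out.ndim else float(out)


def _fc_map(tables: Mapping) -> dict[str, pd.Series]:
    out = {}
    for lot, t in tables.items():
        out[lot] = t.fc if isinstance(t, FoldChangeTable) else pd.Series(t, dtype=float)
    return out


def overlap_matrix(de_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Pairwise |DE_i ∩ DE_j| counts; the diagonal holds per-lot DE counts."""
    lots = list(de_sets)
    if not lots:
        raise ValueError("need at least one lot")
    mat = pd.DataFrame(0, index=lots, columns=lots, dtype=int)
    for i in lots:
        for j in lots:
            mat.loc[i, j] = len(set(de_sets[i]) & set(de_sets[j]))
    return mat


def common_genes(de_sets: Mapping[str, set[str]]) -> set[str]:
    """Genes called significant in every lot (the k-way intersection)."""
    if len(de_sets) < 2:
        raise ValueError("need at least two lots")
    sets = [set(s) for s in de_sets.values()]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def merged_fold_change(fc_tables: Mapping) -> pd.Series:
    """Unweighted per-gene mean FC across lots, on the shared gene universe."""
    fcs = _fc_map(fc_tables)
    lots = list(fcs)
    shared = fcs[lots[0]].index
    for lot in lots[1:]:
        shared = shared.intersection(fcs[lot].index)
    if len(shared) == 0:
        raise ValueError("no genes shared across all lots")
    dropped = sum(len(fcs[lot]) - len(shared) for lot in lots)
    if dropped:
        logger.warning("merged_fold_change: dropped %d gene rows absent from some lot",
                       dropped)
    stacked = pd.DataFrame({lot: fcs[lot].loc[shared] for lot in lots})
    merged = stacked.mean(axis=1)
    merged.name = MERGED
    return merged


def correlation_matrix(
    fc_tables: Mapping,
    merged: pd.Series | None = None,
    gene_subset: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Pearson r between per-lot FC vectors (plus the merged column).

    Vectors are restricted to *gene_subset* when given (the common-gene
    subset reproduces the tighter correlation regime; the default shared
    universe the looser all-gene one). The merged profile participates even
    though it is a function of the lots, mirroring lot-vs-consensus displays.
    Zero-variance vectors yield NA cells rather than an exception.
    """
    fcs = _fc_map(fc_tables)
    if merged is None:
        merged = merged_fold_change(fc_tables)
    cols = dict(fcs)
    cols[MERGED] = merged
    idx = None
    for s in cols.values():
        idx = s.index if idx is None else idx.intersection(s.index)
    if gene_subset is not None:
        idx = idx.intersection(pd.Index(list(gene_subset)))
    if len(idx) < 2:
        raise ValueError("need >= 2 shared genes to correlate")
    frame = pd.DataFrame({k: v.loc[idx] for k, v in cols.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = frame.corr(method="pearson")
    sds = frame.std(ddof=0)
    for name in frame.columns[sds == 0]:
        corr.loc[name, :] = np.nan
        corr.loc[:, name] = np.nan
    return corr


def sd_profile(
    fc_tables: Mapping,
    thresholds: Sequence[float] = (0.5, 1.0),
) -> tuple[pd.Series, dict[float, float]]:
    """Per-gene sample SD of FC across lots and fraction strictly below each
    threshold.

    Works equally for per-pathway z-score tables (rows = pathways).
    """
    fcs = _fc_map(fc_tables)
    if len(fcs) < 2:
        raise ValueError("need at least two lots")
    lots = list(fcs)
    shared = fcs[lots[0]].index
    for lot in lots[1:]:
        shared = shared.intersection(fcs[lot].index)
    frame = pd.DataFrame({lot: fcs[lot].loc[shared] for lot in lots})
    sd = frame.std(axis=1, ddof=1)
    sd.name = "sd"
    fractions = {float(t): float((sd < t).mean()) for t in thresholds}
    return sd, fractions


def cross_lot_stats(values: Sequence[float]) -> tuple[float, float]:
    """Cross-lot (mean, sample SD) of per-lot values — the Avg./SD columns
    of the report tables."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two per-lot values")
    return float(arr.mean()), float(arr.std(ddof=1))


def top_k_genes(
    merged_fc: pd.Series,
    k: int,
    sd: pd.Series,
    restrict_to: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ranked top-k up- and down-regulated gene tables by merged FC.

    Each row carries the merged (mean) FC and the cross-lot SD. Ties are
    broken by gene symbol ascending; k beyond the available gene count is
    truncated with a warning. Returns ``(up, down)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    fc = merged_fc
    if restrict_to is not None:
        fc = fc.loc[fc.index.intersection(pd.Index(list(restrict_to)))]
    if k > len(fc):
        logger.warning("top_k_genes: k=%d exceeds %d genes; truncated", k, len(fc))
        k = len(fc)
    df = pd.DataFrame({"avg_fc": fc, "sd": sd.reindex(fc.index)})
    df.index.name = "gene"
    df = df.reset_index()
    up = df.sort_values(["avg_fc", "gene"], ascending=[False, True]).head(k)
    down = df.sort_values(["avg_fc", "gene"], ascending=[True, True]).head(k)
    return up.reset_index(drop=True), down.reset_index(drop=True)


def sign_consistency(
    per_lot_fc: Sequence[float],
    significance_flags: Sequence[bool] | None = None,
) -> tuple[str, bool]:
    """Direction agreement across lots plus the "consistent but nowhere
    significant" star annotation.

    Returns ``(flag, starred)`` where flag is ``consistent_up`` when every
    lot FC > 0, ``consistent_down`` when every lot FC < 0, else ``mixed``
    (an exact 0 breaks consistency); ``starred`` is True when the direction
    is consistent yet no lot called the gene significant.
    """
    arr = np.asarray(list(per_lot_fc), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two lots")
    if (arr > 0).all():
        flag = CONSISTENT_UP
    elif (arr < 0).all():
        flag = CONSISTENT_DOWN
    else:
        flag = MIXED
    starred = False
    if significance_flags is not None and flag != MIXED:
        starred = not any(bool(s) for s in significance_flags)
    return flag, starred


def panel_table(
    fc_tables: Mapping,
    genes: Sequence[str],
    de_sets: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Report table for a user-specified gene panel (e.g. transporters/CYPs).

    One row per panel gene: per-lot FC, cross-lot mean and sample SD,
    sign-consistency flag, and the star for consistent-but-nowhere-significant
    genes. Panel genes missing from any lot are skipped with a warning.
    """
    fcs = _fc_map(fc_tables)
    lots = list(fcs)
    rows = []
    for g in genes:
        if any(g not in fcs[lot].index for lot in lots):
            logger.warning("panel gene %r not measured in every lot; skipped", g)
            continue
        vals = [float(fcs[lot].loc[g]) for lot in lots]
        mean, sd = cross_lot_stats(vals)
        sig = None
        if de_sets is not None:
            sig = [g in de_sets[lot] for lot in lots]
        flag, starred = sign_consistency(vals, sig)
        row = {"gene": g, **{lot: v for lot, v in zip(lots, vals)},
               "avg": mean, "sd": sd, "pattern": flag, "starred": starred}
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ConsistencyReport:
    """Bundle of every lot-agreement analytic for one study contrast."""

    overlap: pd.DataFrame
    common_genes: set[str]
    merged_fc: pd.Series
    correlation_all: pd.DataFrame
    correlation_common: pd.DataFrame | None
    sd_all: pd.Series
    sd_fraction_all: dict[float, float]
    sd_common: pd.Series | None
    sd_fraction_common: dict[float, float] | None
    top_up: pd.DataFrame
    top_down: pd.DataFrame
    panel: pd.DataFrame | None = None


def build_consistency_report(
    fc_tables: Mapping[str, FoldChangeTable],
    sd_thresholds: Sequence[float] = (0.5, 1.0),
    top_k: int = 10,
    panel_genes: Sequence[str] | None = None,
) -> ConsistencyReport:
    """Run the full consistency stage from per-lot DE tables."""
    de_sets = {lot: t.significant_genes() for lot, t in fc_tables.items()}
    overlap = overlap_matrix(de_sets)
    multi_lot = len(fc_tables) >= 2
    common = common_genes(de_sets) if multi_lot else set(de_sets[next(iter(de_sets))])
    merged = merged_fold_change(fc_tables)
    corr_all = correlation_matrix(fc_tables, merged) if multi_lot else None
    corr_common = None
    if multi_lot and len(common) >= 2:
        corr_common = correlation_matrix(fc_tables, merged, gene_subset=common)
    if multi_lot:
        sd_all, frac_all = sd_profile(fc_tables, sd_thresholds)
    else:
        sd_all = pd.Series(0.0, index=merged.index, name="sd")
        frac_all = {float(t): 1.0 for t in sd_thresholds}
    sd_common = frac_common = None
    if multi_lot and common:
        common_tables = {
            lot: t.fc.loc[t.fc.index.intersection(pd.Index(sorted(common)))]
            for lot, t in fc_tables.items()
        }
        sd_common, frac_common = sd_profile(common_tables, sd_thresholds)
    rank_universe = common if common else set(merged.index)
    up, down = top_k_genes(merged, top_k, sd_all, restrict_to=rank_universe)
    panel = None
    if panel_genes:
        panel = panel_table(fc_tables, panel_genes, de_sets)
    if corr_all is None:
        corr_all = pd.DataFrame([[1.0]], index=[MERGED], columns=[MERGED])
    return ConsistencyReport(
        overlap=overlap,
        common_genes=common,
        merged_fc=merged,
        correlation_all=corr_all,
        correlation_common=corr_common,
        sd_all=sd_all,
        sd_fraction_all=frac_all,
        sd_common=sd_common,
        sd_fraction_common=frac_common,
        top_up=up,
        top_down=down,
        panel=panel,
    )
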