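"""Gene-set scoring against per-lot fold-change profiles.

Two aggregate scores are defined over a set's measured members:

* AAFC (aggregated absolute fold change): mean of |log2 FC| — a
  direction-blind injury-module score;
* AFC (aggregated fold change): mean of signed log2 FC — carries the up/down
  direction, which matters for pathway display.

Significance is assessed against a permutation null built by drawing
equally sized random gene subsets (without replacement) from the measured
universe of the same fold-change profile, 10,000 draws by default:

    z = (raw - null_mean) / null_sd
    p = (1 + #{null >= raw}) / (n_perm + 1)        (add-one rule)

A set is called *activated* when z >= z_activation (default 2), read as a
significant injury-phenotype signal. Feature-set toxicity scores (e.g. PTGS
and TMG liver-toxicity panels) are plain AAFC scores per lot, summarised by
the cross-lot mean and n-1 SD. A generic one-sided hypergeometric
over-representation test is provided as plumbing for enrichment tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import FoldChangeTable, bh_adjust
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

METHODS = ("AAFC", "AFC")
DEFAULT_N_PERM = 10_000
DEFAULT_Z_ACTIVATION = 2.0
DEFAULT_MIN_GENES = 3

# sampling chunk: bounded scratch memory regardless of universe size
_CHUNK_CELLS = 4_000_000


@dataclass
class PermutationNull:
    """Null distribution of set scores for one (universe, set size, method)."""

    set_size: int
    n_perm: int
    seed: int
    null_scores: np.ndarray
    method: str = "AAFC"

    @property
    def null_mean(self) -> float:
        return float(self.null_scores.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null_scores.std(ddof=1))

    @property
    def degenerate(self) -> bool:
        # tolerance absorbs float summation-order jitter across draws
        return self.null_sd <= 1e-12 * max(1.0, abs(self.null_mean))


@dataclass
class ModuleScore:
    set_id: str
    lot_id: str
    method: str
    n_members_measured: int
    raw_score: float
    z_score: float
    p_perm: float
    activated: bool
    z_signed: float = field(default=np.nan)


def _fc_series(fc) -> pd.Series:
    if isinstance(fc, FoldChangeTable):
        return fc.fc
    return pd.Series(fc, dtype=float)


def _set_score(values: np.ndarray, method: str) -> float:
    if method == "AAFC":
        return float(np.abs(values).mean())
    if method == "AFC":
        return float(values.mean())
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def _measured_members(fc: pd.Series, members: Iterable[str]) -> pd.Series:
    present = fc.index.intersection(list(members))
    return fc.loc[present]


def aafc_score(fc, members: Iterable[str], min_genes: int = DEFAULT_MIN_GENES):
    """Mean |log2 FC| over measured members; ``(score, n_measured)``.

    Members absent from the fold-change map are ignored (but reflected in
    ``n_measured``); fewer than *min_genes* measured members is an error.
    """
    return _aggregate(fc, members, "AAFC", min_genes)


def afc_score(fc, members: Iterable[str], min_genes: int = DEFAULT_MIN_GENES):
    """Mean signed log2 FC over measured members; ``(score, n_measured)``."""
    return _aggregate(fc, members, "AFC", min_genes)


def _aggregate(fc, members, method: str, min_genes: int):
    series = _fc_series(fc)
    if series.empty:
        raise ValueError("empty fold-change map")
    measured = _measured_members(series, members)
    if len(measured) < min_genes:
        raise ValueError(
            f"only {len(measured)} measured member(s); need >= {min_genes}"
        )
    return _set_score(measured.to_numpy(), method), len(measured)


def permutation_null(
    fc,
    set_size: int,
    method: str = "AAFC",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.SeedSequence = 0,
) -> PermutationNull:
    """Score *n_perm* random subsets of *set_size* measured genes.

    Subsets are drawn uniformly without replacement from the full measured
    universe of *fc*; the draw stream is reproducible under *seed*.
    """
    series = _fc_series(fc)
    n = len(series)
    if set_size > n:
        raise ValueError(f"set_size {set_size} exceeds universe of {n} genes")
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    values = series.to_numpy(dtype=float)
    if method == "AAFC":
        values = np.abs(values)
    out = np.empty(n_perm, dtype=float)
    chunk = max(1, _CHUNK_CELLS // n)
    for start in range(0, n_perm, chunk):
        m = min(chunk, n_perm - start)
        # partial Fisher–Yates via random-key partial sort: each row is a
        # uniform subset of size set_size without replacement
        keys = rng.random((m, n))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        out[start : start + m] = values[idx].mean(axis=1)
    null = PermutationNull(
        set_size=set_size,
        n_perm=n_perm,
        seed=seed if isinstance(seed, int) else -1,
        null_scores=out,
        method=method,
    )
    if null.degenerate:
        logger.warning("degenerate permutation null (all scores identical)")
    return null


def score_set(
    fc,
    members: Iterable[str],
    set_id: str = "",
    lot_id: str = "",
    method: str = "AAFC",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.SeedSequence = 0,
    z_activation: float = DEFAULT_Z_ACTIVATION,
    min_genes: int = DEFAULT_MIN_GENES,
    null: PermutationNull | None = None,
) -> ModuleScore:
    """Score one gene set and attach its permutation z, p and activation call.

    A precomputed *null* for the same universe/method/set size may be passed
    to share nulls across sets of equal size.
    """
    raw, n_measured = _aggregate(fc, members, method, min_genes)
    if null is None:
        null = permutation_null(fc, n_measured, method, n_perm, seed)
    elif null.set_size != n_measured or null.method != method:
        raise ValueError("supplied null does not match set size/method")
    # ties at float precision count as >= (conservative)
    tie_tol = 1e-12 * max(1.0, abs(raw))
    p_perm = (1 + int((null.null_scores >= raw - tie_tol).sum())) / (null.n_perm + 1)
    if null.degenerate:
        logger.warning("set %r: degenerate null, z set to 0", set_id)
        z = 0.0
    else:
        z = (raw - null.null_mean) / null.null_sd
    z_signed = np.nan
    if method == "AFC":
        z_signed = float(np.sign(raw) * abs(z)) if raw != 0 else 0.0
    return ModuleScore(
        set_id=set_id,
        lot_id=lot_id,
        method=method,
        n_members_measured=n_measured,
        raw_score=raw,
        z_score=float(z),
        p_perm=float(p_perm),
        activated=bool(z >= z_activation),
        z_signed=z_signed,
    )


def score_collection(
    fc_tables: Mapping[str, FoldChangeTable | pd.Series],
    sets: GeneSetCollection,
    method: str = "AAFC",
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    z_activation: float = DEFAULT_Z_ACTIVATION,
    min_genes: int = DEFAULT_MIN_GENES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every (set, lot) pair and build the set x (lots + merged) z matrix.

    The merged z per set is the unweighted mean of the per-lot z-scores
    (the consensus column of the heat-map displays). Sets with fewer than
    *min_genes* measured members in a lot are reported as NA for that lot.
    Returns ``(long_table, z_matrix)``.
    """
    if not fc_tables:
        raise ValueError("need at least one lot")
    lots = list(fc_tables)
    rows: list[dict] = []
    z = pd.DataFrame(index=sets.ids(), columns=lots, dtype=float)
    root = np.random.SeedSequence(seed)
    null_cache: dict[tuple[str, str, int], PermutationNull] = {}
    for i_lot, lot in enumerate(lots):
        fc = _fc_series(fc_tables[lot])
        for gs in sets:
            measured = _measured_members(fc, gs.members)
            if len(measured) < min_genes:
                logger.warning(
                    "set %r has %d measured member(s) in lot %s; reported NA",
                    gs.set_id, len(measured), lot,
                )
                rows.append(
                    dict(set_id=gs.set_id, category=gs.category, lot=lot,
                         method=method, n_measured=len(measured),
                         raw_score=np.nan, z_score=np.nan, p_perm=np.nan,
                         activated=False)
                )
                continue
            key = (lot, method, len(measured))
            if key not in null_cache:
                child = np.random.SeedSequence(
                    seed, spawn_key=(i_lot, len(measured), METHODS.index(method))
                )
                null_cache[key] = permutation_null(
                    fc, len(measured), method, n_perm, child
                )
            ms = score_set(
                fc, gs.members, gs.set_id, lot, method,
                n_perm, seed, z_activation, min_genes, null=null_cache[key],
            )
            z.loc[gs.set_id, lot] = ms.z_score
            rows.append(
                dict(set_id=ms.set_id, category=gs.category, lot=lot,
                     method=method, n_measured=ms.n_members_measured,
                     raw_score=ms.raw_score, z_score=ms.z_score,
                     p_perm=ms.p_perm, activated=ms.activated)
            )
    z["merged"] = z[lots].mean(axis=1)
    long = pd.DataFrame(rows)
    return long, z


def feature_set_scores(
    fc_tables: Mapping[str, FoldChangeTable | pd.Series],
    feature_sets: GeneSetCollection,
    min_genes: int = DEFAULT_MIN_GENES,
) -> pd.DataFrame:
    """Toxicity feature-set scores: AAFC per (set, lot) plus cross-lot mean/SD.

    One row per set with one column per lot, then ``mean`` and ``sd``
    (sample SD, n-1 denominator) across lots.
    """
    lots = list(fc_tables)
    records = {}
    for gs in feature_sets:
        per_lot = {}
        for lot in lots:
            score, _ = aafc_score(fc_tables[lot], gs.members, min_genes)
            per_lot[lot] = score
        records[gs.set_id] = per_lot
    df = pd.DataFrame.from_dict(records, orient="index")[lots]
    df["mean"] = df[lots].mean(axis=1)
    df["sd"] = df[lots].std(axis=1, ddof=1)
    df.index.name = "set_id"
    return df


def ora_enrichment(
    de_genes: set[str],
    universe: set[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per set, BH-adjusted.

    P(X >= k) where k is the overlap of *de_genes* with the set's members
    restricted to *universe*. Generic plumbing for enrichment-style tables.
    """
    de_genes = set(de_genes)
    universe = set(universe)
    if not de_genes <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    M, N = len(universe), len(de_genes)
    rows = []
    for gs in sets:
        members = gs.members & universe
        k = len(members & de_genes)
        n = len(members)
        # survival function at k-1 gives P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append(dict(set_id=gs.set_id, n_members=n, overlap=k, p=min(p, 1.0)))
    df = pd.DataFrame(rows).set_index("set_id")
    df["q"] = bh_adjust(df["p"]).to_numpy()
    return df
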