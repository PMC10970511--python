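"""Synthetic multi-lot expression studies with known ground truth.

Emulates the pooled-hepatocyte study design — 5 lots x 3 treatment arms
(control, low, high) x 5 replicates = 75 samples over ~15,000 genes — on the
log2 scale with Gaussian replicate noise. The treatment response decomposes
into:

* a shared core of truly differentially expressed genes whose signed log2
  effects are drawn once and perturbed per lot by multiplicative jitter
  (lot heterogeneity);
* disjoint lot-specific DE genes, private to each lot;
* signal injected into designated gene sets so set-level scoring has a
  known positive control; auto-generated null sets provide the negative
  control.

Low-dose effects are the high-dose effects scaled by a fixed factor. All
randomness flows from one seed through a per-purpose seed sequence
(baseline, effects, membership, noise), so identical configs give
byte-identical studies.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    ExpressionStudy,
    GeneSet,
    GeneSetCollection,
    dump_config_file,
    write_expression_study,
    write_frame,
    write_gene_sets,
)


@dataclass
class SyntheticConfig:
    """Knobs of the study emulator (defaults mirror the emulated design)."""

    n_lots: int = 5
    n_replicates: int = 5
    n_genes: int = 15_000
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    residual_sd: float = 0.25
    n_core_de: int = 800
    effect_mean: float = 1.0          # mean |log2 FC| of true effects
    effect_sd: float = 0.5
    effect_min: float = 0.2           # magnitude floor (clip)
    n_lot_specific_de: int = 1500
    lot_effect_sd: float = 0.3        # multiplicative jitter on shared effects
    low_dose_scale: float = 0.15
    injected_sets: list[tuple[str, float]] = field(default_factory=list)
    injected_effect_sd: float = 0.2
    set_size: int = 20
    n_null_sets: int = 5
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_lots=self.n_lots, n_replicates=self.n_replicates,
                      n_genes=self.n_genes, set_size=self.set_size)
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        for name, v in dict(n_core_de=self.n_core_de,
                            n_lot_specific_de=self.n_lot_specific_de,
                            n_null_sets=self.n_null_sets).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.n_core_de + self.n_lot_specific_de > self.n_genes:
            raise ValueError("n_core_de + n_lot_specific_de exceeds n_genes")
        needed = (self.n_core_de
                  + self.n_lots * self.n_lot_specific_de
                  + len(self.injected_sets) * self.set_size)
        if needed > self.n_genes:
            raise ValueError(
                f"design needs {needed} distinct DE genes but only "
                f"{self.n_genes} genes are simulated"
            )


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream oracles.

    ``true_fc``: genes x lots true high-dose log2 FC; genes that are neither
    core, lot-specific nor injected have true FC exactly 0 in every lot.
    """

    true_fc: pd.DataFrame
    is_core: pd.Series
    lot_specific: dict[str, set[str]]
    gene_sets: GeneSetCollection
    injected_effect: dict[str, float]   # set_id -> planted mean |effect| (0 for null sets)

    def true_de_genes(self, lot: str) -> set[str]:
        """Genes with nonzero true FC in *lot*."""
        col = self.true_fc[lot]
        return set(col.index[col != 0.0])


def _lot_ids(n: int) -> list[str]:
    letters = string.ascii_uppercase
    if n <= len(letters):
        return list(letters[:n])
    return [f"L{i+1:02d}" for i in range(n)]


def _magnitudes(rng, n, mean, sd, floor):
    return np.clip(rng.normal(mean, sd, size=n), floor, None)


def generate_study(
    config: SyntheticConfig,
    sets: GeneSetCollection | None = None,
) -> tuple[ExpressionStudy, GroundTruth]:
    """Simulate one multi-lot study; returns the study and its ground truth.

    When *sets* is given, ``config.injected_sets`` ids must name sets in it
    and signal is injected into those members (unmeasured members ignored);
    otherwise the generator builds its own collection of injected plus null
    sets from non-DE genes.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_baseline, rng_effects, rng_members, rng_noise = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    gene_index = pd.Index(genes, name="gene")
    lots = _lot_ids(config.n_lots)

    if sets is not None:
        known = set(sets.ids())
        for set_id, _ in config.injected_sets:
            if set_id not in known:
                raise ValueError(f"injected set {set_id!r} not in supplied collection")

    baseline = rng_baseline.normal(config.baseline_mean, config.baseline_sd,
                                   size=config.n_genes)

    # --- assign disjoint roles: core, per-lot private, injected-set members
    pool = rng_members.permutation(config.n_genes)
    cursor = 0
    core_idx = pool[cursor : cursor + config.n_core_de]
    cursor += config.n_core_de
    lot_specific_idx: dict[str, np.ndarray] = {}
    for lot in lots:
        lot_specific_idx[lot] = pool[cursor : cursor + config.n_lot_specific_de]
        cursor += config.n_lot_specific_de

    injected_members: dict[str, np.ndarray] = {}
    injected_effect: dict[str, float] = {}
    collection = sets
    if sets is None:
        collection = GeneSetCollection()
        for set_id, eff in config.injected_sets:
            members = pool[cursor : cursor + config.set_size]
            cursor += config.set_size
            injected_members[set_id] = members
            injected_effect[set_id] = float(eff)
            collection.add(GeneSet(set_id, f"synthetic injected set (|effect| {eff})",
                                   frozenset(gene_index[members]), "injury_module"))
        for j in range(config.n_null_sets):
            members = rng_members.choice(config.n_genes, size=config.set_size,
                                         replace=False)
            set_id = f"null_{j:02d}"
            injected_effect[set_id] = 0.0
            collection.add(GeneSet(set_id, "synthetic null set",
                                   frozenset(gene_index[members]), "injury_module"))
    else:
        name_to_pos = {g: i for i, g in enumerate(genes)}
        for set_id, eff in config.injected_sets:
            idx = np.array([name_to_pos[m] for m in sets[set_id].members
                            if m in name_to_pos], dtype=int)
            injected_members[set_id] = idx
            injected_effect[set_id] = float(eff)
        for set_id in collection.ids():
            injected_effect.setdefault(set_id, 0.0)

    # --- shared signed effects, jittered per lot
    true_fc = np.zeros((config.n_genes, config.n_lots))
    shared = np.zeros(config.n_genes)
    if len(core_idx):
        mags = _magnitudes(rng_effects, len(core_idx), config.effect_mean,
                           config.effect_sd, config.effect_min)
        signs = rng_effects.choice([-1.0, 1.0], size=len(core_idx))
        shared[core_idx] = mags * signs
    for set_id, eff in config.injected_sets:
        idx = injected_members[set_id]
        mags = np.clip(rng_effects.normal(eff, config.injected_effect_sd,
                                          size=len(idx)), 0.05, None)
        signs = rng_effects.choice([-1.0, 1.0], size=len(idx))
        shared[idx] = mags * signs

    shared_mask = shared != 0
    for k, lot in enumerate(lots):
        jitter = 1.0 + rng_effects.normal(0.0, config.lot_effect_sd,
                                          size=int(shared_mask.sum()))
        true_fc[shared_mask, k] = shared[shared_mask] * jitter
        idx = lot_specific_idx[lot]
        if len(idx):
            mags = _magnitudes(rng_effects, len(idx), config.effect_mean,
                               config.effect_sd, config.effect_min)
            signs = rng_effects.choice([-1.0, 1.0], size=len(idx))
            true_fc[idx, k] += mags * signs

    # --- assemble replicate-level matrix
    sample_ids, lot_col, cond_col, rep_col = [], [], [], []
    columns = []
    for k, lot in enumerate(lots):
        for cond, scale in (("control", 0.0), ("low", config.low_dose_scale),
                            ("high", 1.0)):
            mean_profile = baseline + scale * true_fc[:, k]
            for rep in range(1, config.n_replicates + 1):
                noise = rng_noise.normal(0.0, config.residual_sd,
                                         size=config.n_genes)
                columns.append(mean_profile + noise)
                sample_ids.append(f"{lot}_{cond}_{rep}")
                lot_col.append(lot)
                cond_col.append(cond)
                rep_col.append(rep)

    expr = pd.DataFrame(np.column_stack(columns), index=gene_index,
                        columns=sample_ids)
    sheet = pd.DataFrame(
        {"lot": lot_col, "condition": cond_col, "replicate": rep_col},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    study = ExpressionStudy(expression=expr, samples=sheet)

    is_core = pd.Series(False, index=gene_index, name="core")
    is_core.iloc[core_idx] = True
    truth = GroundTruth(
        true_fc=pd.DataFrame(true_fc, index=gene_index, columns=lots),
        is_core=is_core,
        lot_specific={lot: set(gene_index[idx]) for lot, idx in lot_specific_idx.items()},
        gene_sets=collection,
        injected_effect=injected_effect,
    )
    return study, truth


def write_fixture_bundle(config: SyntheticConfig, out_dir) -> None:
    """Simulate a study and write the full fixture bundle.

    Layout: ``expression.tsv``, ``samples.tsv``, ``sets.gmt``, ``truth.tsv``,
    ``truth_sets.tsv``, ``config.yaml`` — all readable by :mod:`pooltox.io`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study, truth = generate_study(config)
    write_expression_study(study, out / "expression.tsv", out / "samples.tsv")
    write_gene_sets(truth.gene_sets, out / "sets.gmt")
    truth_df = truth.true_fc.copy()
    truth_df.insert(0, "core", truth.is_core.astype(int))
    truth_df.index.name = "gene"
    truth_df.reset_index().to_csv(out / "truth.tsv", sep="\t", index=False)
    set_rows = pd.DataFrame(
        [{"set_id": sid, "injected": int(eff > 0), "mean_effect": eff}
         for sid, eff in truth.injected_effect.items()]
    )
    write_frame(set_rows, out / "truth_sets.tsv")
    cfg = asdict(config)
    cfg["injected_sets"] = [[sid, eff] for sid, eff in config.injected_sets]
    dump_config_file(cfg, out / "config.yaml")
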