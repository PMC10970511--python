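"""Pipeline orchestration: simulate -> de -> score -> consistency -> report.

Files are the contract between stages; every stage is deterministic given
the config and seed, and a run manifest records the config echo, input
hashes, package version and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .consistency import MERGED, build_consistency_report, round_half_away
from .diffexpr import de_all_lots
from .genesets import feature_set_scores, score_collection
from .io import (
    ExpressionStudy,
    GeneSetCollection,
    ValidationError,
    load_config_file,
    read_expression_study,
    read_gene_sets,
    write_frame,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, overridable from a YAML/JSON file."""

    q_max: float = 0.1
    z_activation: float = 2.0
    n_perm: int = 10_000
    seed: int = 0
    sd_thresholds: list[float] = field(default_factory=lambda: [0.5, 1.0])
    top_k: int = 10
    min_genes: int = 3
    heatmap_clip: float = 0.6
    treated: str = "high"
    control: str = "control"

    def validate(self) -> None:
        for name in ("q_max", "z_activation", "top_k", "min_genes", "heatmap_clip"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if any(t <= 0 for t in self.sd_thresholds):
            raise ValueError("sd_thresholds must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        data = load_config_file(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def export_heatmap_matrix(matrix: pd.DataFrame, clip: float, out_prefix) -> None:
    """Emit a numeric matrix plus its display-band annotation.

    Values are never mutated: ``<prefix>.tsv`` holds the raw matrix and
    ``<prefix>.bands.tsv`` classifies each cell as ``neutral`` (|v| <= clip),
    ``up`` or ``down`` — the banded colour scheme of the heat-map displays.
    """
    out_prefix = Path(out_prefix)
    write_frame(matrix.reset_index(), f"{out_prefix}.tsv")
    vals = matrix.to_numpy(dtype=float)
    bands = np.where(np.abs(vals) <= clip, "neutral",
                     np.where(vals > 0, "up", "down"))
    bands_df = pd.DataFrame(bands, index=matrix.index, columns=matrix.columns)
    bands_df.reset_index().to_csv(f"{out_prefix}.bands.tsv", sep="\t", index=False)


def run_pipeline(
    config: PipelineConfig,
    matrix_path,
    sample_sheet_path,
    gene_sets: Mapping[str, object] | None = None,
    feature_sets_path=None,
    panel_genes: Sequence[str] | None = None,
    out_dir="results",
) -> Path:
    """Run the whole analysis and write every result table under *out_dir*.

    *gene_sets* maps a category (injury_module | pathway) to a GMT path or a
    loaded :class:`GeneSetCollection`; injury modules are scored with AAFC,
    pathways with AFC. Returns the output directory path.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "inputs": {},
        "version": __version__,
        "stages": {},
    }

    # ---- load ------------------------------------------------------------
    try:
        for label, p in (("matrix", matrix_path), ("samples", sample_sheet_path)):
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input file: {p}")
            manifest["inputs"][label] = _sha256(p)
        study = read_expression_study(matrix_path, sample_sheet_path)
    except Exception as e:  # noqa: BLE001 - stage labeling
        raise StageError("load", str(e)) from e
    manifest["stages"]["load"] = {"genes": study.n_genes, "samples": study.n_samples}

    collections: dict[str, GeneSetCollection] = {}
    try:
        for category, src in (gene_sets or {}).items():
            if isinstance(src, GeneSetCollection):
                collections[category] = src
            else:
                if not Path(src).exists():
                    raise FileNotFoundError(f"missing gene-set file: {src}")
                manifest["inputs"][f"sets:{category}"] = _sha256(src)
                collections[category] = read_gene_sets(src, category)
        feature_coll = None
        if feature_sets_path is not None:
            if not Path(feature_sets_path).exists():
                raise FileNotFoundError(f"missing gene-set file: {feature_sets_path}")
            manifest["inputs"]["sets:feature_set"] = _sha256(feature_sets_path)
            feature_coll = read_gene_sets(feature_sets_path, "feature_set")
    except Exception as e:
        raise StageError("gene_sets", str(e)) from e

    # ---- differential expression ----------------------------------------
    try:
        fc_tables = de_all_lots(study, config.treated, config.control, config.q_max)
        for lot, t in fc_tables.items():
            df = t.table.reset_index()
            write_frame(df, out / f"de_{lot}.tsv", float_decimals=6)
        manifest["stages"]["de"] = {
            lot: int(t.table["significant"].sum()) for lot, t in fc_tables.items()
        }
    except Exception as e:
        raise StageError("de", str(e)) from e

    # ---- gene-set scoring ------------------------------------------------
    try:
        method_for = {"injury_module": "AAFC", "pathway": "AFC"}
        all_scores = []
        for category, coll in collections.items():
            method = method_for.get(category, "AAFC")
            long, z = score_collection(
                fc_tables, coll, method=method, n_perm=config.n_perm,
                seed=config.seed, z_activation=config.z_activation,
                min_genes=config.min_genes,
            )
            all_scores.append(long)
            z_out = z.copy()
            z_out.index.name = "set_id"
            export_heatmap_matrix(z_out, config.heatmap_clip,
                                  out / f"z_matrix_{category}")
        if all_scores:
            scores = pd.concat(all_scores, ignore_index=True)
            write_frame(scores, out / "module_scores.tsv", float_decimals=6)
            manifest["stages"]["score"] = {"rows": int(len(scores))}
        if feature_coll is not None:
            feats = feature_set_scores(fc_tables, feature_coll, config.min_genes)
            write_frame(feats.reset_index(), out / "feature_scores.tsv")
            manifest["stages"]["feature_sets"] = {"rows": int(len(feats))}
    except Exception as e:
        raise StageError("score", str(e)) from e

    # ---- consistency ------------------------------------------------------
    try:
        report = build_consistency_report(
            fc_tables, sd_thresholds=config.sd_thresholds,
            top_k=config.top_k, panel_genes=panel_genes,
        )
        report.overlap.rename_axis("lot").reset_index().to_csv(
            out / "overlap.tsv", sep="\t", index=False)
        (out / "common_genes.txt").write_text(
            "\n".join(sorted(report.common_genes)) + "\n")
        merged = report.merged_fc.rename("avg_fc").rename_axis("gene").reset_index()
        write_frame(merged, out / "merged_fc.tsv", float_decimals=6)
        export_heatmap_matrix(
            pd.DataFrame({**{l: t.fc for l, t in fc_tables.items()},
                          MERGED: report.merged_fc}).rename_axis("gene"),
            config.heatmap_clip, out / "fc_matrix")
        write_frame(report.correlation_all.rename_axis("lot").reset_index(),
                    out / "correlations_all.tsv")
        if report.correlation_common is not None:
            write_frame(report.correlation_common.rename_axis("lot").reset_index(),
                        out / "correlations_common.tsv")
        sd_df = report.sd_all.rename_axis("gene").reset_index()
        write_frame(sd_df, out / "sd_profile.tsv", float_decimals=6)
        top = pd.concat(
            [report.top_up.assign(direction="up"),
             report.top_down.assign(direction="down")],
            ignore_index=True,
        )
        top["avg_fc_2dp"] = round_half_away(top["avg_fc"], 2)
        top["sd_2dp"] = round_half_away(top["sd"], 2)
        write_frame(top, out / "top_genes.tsv", float_decimals=6)
        if report.panel is not None:
            panel = report.panel.copy()
            panel["avg_2dp"] = round_half_away(panel["avg"], 2)
            panel["sd_2dp"] = round_half_away(panel["sd"], 2)
            write_frame(panel, out / "panel.tsv", float_decimals=6)
        manifest["stages"]["consistency"] = {
            "common_genes": len(report.common_genes),
            "sd_fraction_below": {str(k): v for k, v in report.sd_fraction_all.items()},
        }
    except Exception as e:
        raise StageError("consistency", str(e)) from e

    manifest_text = json.dumps(manifest, indent=2, sort_keys=True)
    (out / "manifest.json").write_text(manifest_text + "\n")
    logger.info("pipeline complete: %s", out)
    return out
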