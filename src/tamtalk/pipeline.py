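"""Pipeline orchestration: configuration, staged execution, report emission.

Stages run in the study's order — replicate-detection filter of the
conditioned-media proteomics, secretome restriction, receptor-gated
database join with polarization classification, and single-cell ligand
prioritization — and emit ``summary.tsv``, ``venn.json``,
``interactions.tsv``, ``priorities.tsv`` and a consolidated
``report.json``. Identical configuration and inputs produce byte-
identical outputs; the analysis stages are seed-free and deterministic.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

from pydantic import BaseModel, Field, ValidationError, field_validator

from . import __version__
from . import crosstalk as tx
from . import io as tio
from . import prioritize as tpri
from . import proteomics as tprot
from .errors import ConfigError, StageError, TamtalkError

logger = logging.getLogger(__name__)

STAGES = ("proteomics", "crosstalk", "prioritize")


class PipelineConfig(BaseModel):
    """Every path and threshold of one pipeline run.

    Thresholds default to the study constants: 2-of-3 replicate
    detection, receptor gate 1, fold-change class bounds 2 and 0.5, DEG
    filter |log2FC| >= 1 with adjusted p < 0.05, and BMD-vs-microglia
    adjusted p < 1e-3.
    """

    intensity_table: Path
    secretome: Path
    rl_database: Path
    expression_table: Path
    gate_sample: str
    out_dir: Path
    marker_table: Path | None = None
    cluster_annotation: Path | None = None
    bmd_deg_table: Path | None = None

    dialect: str = "tsv"
    zero_is_missing: bool = True
    aliases: dict[str, str] = Field(default_factory=dict)

    min_detected: int = 2
    receptor_gate: float = 1.0
    fc_high: float = 2.0
    fc_low: float = 0.5
    deg_lfc_min: float = 1.0
    deg_padj_max: float = 0.05
    bmd_padj_max: float = 1e-3
    top_k: int = 3
    ontogeny_ratio: float = 1.5
    pct2_mode: str = "unweighted"

    seed: int = 0
    log_level: str = "INFO"

    @field_validator("dialect")
    @classmethod
    def _dialect(cls, v: str) -> str:
        if v not in ("tsv", "csv"):
            raise ValueError("dialect must be 'tsv' or 'csv'")
        return v

    @field_validator("pct2_mode")
    @classmethod
    def _pct2(cls, v: str) -> str:
        if v not in ("unweighted", "pooled"):
            raise ValueError("pct2_mode must be 'unweighted' or 'pooled'")
        return v

    def problems(self) -> list[str]:
        """Cross-field and filesystem checks, all reported at once."""
        errs: list[str] = []
        if not (0 < self.fc_low < self.fc_high):
            errs.append("fc_low < fc_high required (both positive)")
        if self.min_detected < 1:
            errs.append("min_detected must be >= 1")
        if self.receptor_gate < 0:
            errs.append("receptor_gate must be >= 0")
        if self.ontogeny_ratio < 1:
            errs.append("ontogeny_ratio must be >= 1")
        if self.top_k < 1:
            errs.append("top_k must be >= 1")
        if not (0 < self.deg_padj_max <= 1) or not (0 < self.bmd_padj_max <= 1):
            errs.append("adjusted-p thresholds must be in (0, 1]")
        for name in ("intensity_table", "secretome", "rl_database", "expression_table",
                     "marker_table", "cluster_annotation", "bmd_deg_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                errs.append(f"{name}: no such file {p}")
        if self.marker_table is not None and self.cluster_annotation is None:
            errs.append("cluster_annotation required when marker_table is given")
        return errs


def validate_config(path: str | Path, overrides: Mapping[str, object] | None = None) -> PipelineConfig:
    """Load and validate a TOML (or YAML) config, reporting all errors at once."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    if path.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(path.read_text()) or {}
    else:
        import tomllib

        try:
            raw = tomllib.loads(path.read_text())
        except tomllib.TOMLDecodeError as e:
            raise ConfigError(f"config not parseable: {e}") from e
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    try:
        cfg = PipelineConfig(**raw)
    except ValidationError as e:
        raise ConfigError(
            [f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in e.errors()]
        ) from e
    problems = cfg.problems()
    if problems:
        raise ConfigError(problems)
    return cfg


def _config_echo(cfg: PipelineConfig) -> dict:
    echo = cfg.model_dump(mode="json")
    return {k: echo[k] for k in sorted(echo)}


def _check_report(report: dict) -> None:
    v = report["venn"]
    assert v["m1_only"] + v["m2_only"] + v["both"] == v["total"]
    if "interactions" in report:
        i = report["interactions"]
        assert i["M1_specific"] + i["M2_specific"] + i["pan"] == i["total"]


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stage prefix and write outputs.

    Returns the report dict (also written as ``report.json``). Any stage
    error aborts with a stage-tagged exception and removes partial
    outputs.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError([f"unknown stage {s!r}" for s in sorted(unknown)])
    problems = cfg.problems()
    if problems:
        raise ConfigError(problems)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": _config_echo(cfg),
        "stages": {},
    }

    def emit(name: str, writer) -> Path:
        p = out / name
        writer(p)
        written.append(p)
        return p

    aliases = tio.validate_alias_map({**tio.DEFAULT_ALIASES, **cfg.aliases})
    stage = "proteomics"
    try:
        table = tio.read_intensity_table(
            cfg.intensity_table, cfg.dialect,
            zero_is_missing=cfg.zero_is_missing, aliases=aliases,
        )
        filtered = tprot.filter_by_replicates(table, cfg.min_detected)
        set_m1, set_m2 = tprot.detection_sets(filtered, cfg.min_detected)
        venn = tprot.venn_counts(set_m1, set_m2)
        summary = tprot.summarize(filtered, cfg.min_detected)
        secretome = tio.read_secretome(cfg.secretome, cfg.dialect, aliases)
        detected_secreted = tprot.filter_secreted(set_m1 | set_m2, secretome)
        report["stages"]["proteomics"] = {
            "n_input_proteins": len(table),
            "n_after_replicate_filter": len(filtered),
            "n_detected_secreted": len(detected_secreted),
        }
        report["venn"] = venn.as_dict()
        emit("summary.tsv", lambda p: tprot.write_summary(summary, secretome, p, cfg.dialect))
        emit("venn.json", lambda p: p.write_text(
            json.dumps(venn.as_dict(), sort_keys=True, indent=2) + "\n"
        ))
        logger.info(
            "proteomics: %d proteins in, %d after replicate filter, %d secreted+detected",
            len(table), len(filtered), len(detected_secreted),
        )

        records: list[tx.InteractionRecord] = []
        if "crosstalk" in stages:
            stage = "crosstalk"
            expr = tio.read_expression_table(cfg.expression_table, cfg.dialect, aliases)
            db = tio.read_rl_database(cfg.rl_database, cfg.dialect, aliases)
            xcfg = tx.CrosstalkConfig(
                gate_sample=cfg.gate_sample,
                receptor_gate=cfg.receptor_gate,
                fc_high=cfg.fc_high,
                fc_low=cfg.fc_low,
            )
            gated = tx.gate_receptors(expr, cfg.gate_sample, cfg.receptor_gate)
            records = tx.build_interactions(
                detected_secreted,
                summary["fc"].to_dict(),
                gated,
                expr.data[cfg.gate_sample].to_dict(),
                db,
                xcfg,
            )
            report["stages"]["crosstalk"] = {
                "n_db_pairs": len(db),
                "n_gated_receptors": len(gated),
                "n_interactions": len(records),
            }
            report["interactions"] = tx.summary_dict(records)
            emit("interactions.tsv", lambda p: tx.write_interactions(records, p, cfg.dialect))
            logger.info(
                "crosstalk: %d of %d DB pairs survive the gate+detection join",
                len(records), len(db),
            )

        if "prioritize" in stages and cfg.marker_table is not None:
            stage = "prioritize"
            markers = tio.read_marker_table(cfg.marker_table, cfg.dialect, aliases)
            annotation = tio.read_cluster_annotation(cfg.cluster_annotation, cfg.dialect)
            candidates = sorted(
                {r.ligand_id for r in records if r.polarization_class == "M2_specific"}
            )
            priorities = tpri.prioritize_ligands(
                candidates, markers, annotation, cfg.ontogeny_ratio
            )
            prio_stage = {
                "n_candidates": len(candidates),
                "n_tam_predominant": int(priorities["tam_predominant"].sum()),
                "n_bmd": int((priorities["ontogeny_call"] == "BMD").sum()),
            }
            report["priorities"] = {
                "tam_predominant": priorities[priorities["tam_predominant"]]["ligand"].tolist(),
                "bmd": priorities[priorities["ontogeny_call"] == "BMD"]["ligand"].tolist(),
            }
            if cfg.bmd_deg_table is not None:
                degs = tio.read_deg_table(cfg.bmd_deg_table, cfg.dialect, aliases)
                top = tpri.rank_bmd_degs(degs, cfg.bmd_padj_max, cfg.top_k)
                report["priorities"]["top_bmd_degs"] = top
                prio_stage["n_bmd_deg_rows"] = len(degs)
            report["stages"]["prioritize"] = prio_stage
            emit("priorities.tsv", lambda p: priorities.to_csv(
                p, sep="\t" if cfg.dialect == "tsv" else ",", index=False
            ))
            logger.info(
                "prioritize: %d candidates, %d TAM-predominant",
                prio_stage["n_candidates"], prio_stage["n_tam_predominant"],
            )

        _check_report(report)
        emit("report.json", lambda p: p.write_text(
            json.dumps(report, sort_keys=True, indent=2) + "\n"
        ))
        return report
    except ConfigError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as e:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(e, StageError):
            raise
        raise StageError(stage, e) from e


def run_from_config_file(
    path: str | Path,
    stages: tuple[str, ...] = STAGES,
    overrides: Mapping[str, object] | None = None,
) -> dict:
    return run_pipeline(validate_config(path, overrides), stages)
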