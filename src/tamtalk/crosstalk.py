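"""Receptor-gated ligand–receptor pair construction and polarization classes.

Candidate paracrine interactions run macrophage → tumor cell: the ligand
must be a conventionally secreted protein detected in macrophage
conditioned media (after the replicate filter), and the receptor must be
expressed by the tumor cells — base-mean expression at or above the gate
(default 1) in the designated bulk RNA-seq sample. Each surviving
database pair is then classified by the ligand's M2/M1 conditioned-media
fold change:

* FC >= 2   → M2-specific (both boundaries inclusive),
* FC <= 0.5 → M1-specific,
* otherwise → pan-macrophage.

The classes partition the records exhaustively; the +inf/0 fold changes
of condition-exclusive ligands fall into the M2-/M1-specific classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import ConfigError, DataValidationError
from .io import ExpressionTable, ReceptorLigandDB

POLARIZATION_CLASSES = ("M1_specific", "M2_specific", "pan")


@dataclass(frozen=True)
class CrosstalkConfig:
    """Thresholds of the interaction stage.

    receptor_gate: minimum base-mean expression for a receptor (inclusive).
    fc_high / fc_low: fold-change bounds of the M2-/M1-specific classes
    (both inclusive); 0 < fc_low < fc_high required.
    gate_sample: name of the expression sample used for gating.
    """

    gate_sample: str
    receptor_gate: float = 1.0
    fc_high: float = 2.0
    fc_low: float = 0.5

    def __post_init__(self) -> None:
        errors = []
        if self.receptor_gate < 0:
            errors.append("receptor_gate must be >= 0")
        if not (0 < self.fc_low < self.fc_high):
            errors.append("fc_low < fc_high required (both positive)")
        if errors:
            raise ConfigError(errors)


@dataclass(frozen=True)
class InteractionRecord:
    """One gated ligand–receptor pair with its polarization class."""

    ligand_id: str
    receptor_id: str
    ligand_fc: float
    receptor_base_mean: float
    polarization_class: str


def gate_receptors(expr: ExpressionTable, sample: str, threshold: float = 1.0) -> set[str]:
    """Genes whose base mean in ``sample`` is at or above the gate."""
    if sample not in expr.data.columns:
        raise DataValidationError(
            f"unknown sample {sample!r}; available: {list(expr.data.columns)}"
        )
    col = expr.data[sample]
    return set(col.index[col >= threshold])


def classify_polarization(fc: float, cfg: CrosstalkConfig) -> str:
    """Polarization-specificity class of a ligand fold change (total function)."""
    if math.isnan(fc) or fc < 0:
        raise DataValidationError(f"fold change must be a non-negative number, got {fc}")
    if fc >= cfg.fc_high:
        return "M2_specific"
    if fc <= cfg.fc_low:
        return "M1_specific"
    return "pan"


def build_interactions(
    detected_secreted_ligands: set[str],
    ligand_fc: Mapping[str, float],
    gated_receptors: set[str],
    receptor_base_mean: Mapping[str, float],
    db: ReceptorLigandDB,
    cfg: CrosstalkConfig,
) -> list[InteractionRecord]:
    """Join the pair database against detected ligands and gated receptors.

    One record per database pair whose ligand is in the detected-secreted
    set and whose receptor passed the gate, carrying the ligand's M2/M1
    fold change and the receptor's base mean, classified and ordered
    (ligand, receptor) lexicographically.
    """
    records = []
    for lig, rec in db.pairs:
        if lig not in detected_secreted_ligands or rec not in gated_receptors:
            continue
        if lig not in ligand_fc:
            raise DataValidationError(f"detected ligand {lig!r} has no abundance summary")
        fc = float(ligand_fc[lig])
        records.append(
            InteractionRecord(
                ligand_id=lig,
                receptor_id=rec,
                ligand_fc=fc,
                receptor_base_mean=float(receptor_base_mean[rec]),
                polarization_class=classify_polarization(fc, cfg),
            )
        )
    records.sort(key=lambda r: (r.ligand_id, r.receptor_id))
    return records


def partition_counts(records: Iterable[InteractionRecord]) -> tuple[int, int, int]:
    """(n_M1_specific, n_M2_specific, n_pan); sums to the record count."""
    n = {c: 0 for c in POLARIZATION_CLASSES}
    for r in records:
        n[r.polarization_class] += 1
    return n["M1_specific"], n["M2_specific"], n["pan"]


def unique_members(
    records: Iterable[InteractionRecord], class_filter: str | None = None
) -> tuple[int, int]:
    """(n_unique_receptors, n_unique_ligands) over records, optionally one class."""
    recs = [r for r in records if class_filter is None or r.polarization_class == class_filter]
    return (
        len({r.receptor_id for r in recs}),
        len({r.ligand_id for r in recs}),
    )


def write_interactions(records: Iterable[InteractionRecord], path, dialect: str = "tsv") -> None:
    import pandas as pd

    sep = "\t" if dialect == "tsv" else ","
    pd.DataFrame(
        [
            {
                "ligand": r.ligand_id,
                "receptor": r.receptor_id,
                "ligand_fc": r.ligand_fc,
                "receptor_base_mean": r.receptor_base_mean,
                "class": r.polarization_class,
            }
            for r in records
        ],
        columns=["ligand", "receptor", "ligand_fc", "receptor_base_mean", "class"],
    ).to_csv(path, sep=sep, index=False)


def summary_dict(records: list[InteractionRecord]) -> dict[str, int]:
    """JSON-ready summary: totals, class partition, unique members of the M2 class."""
    n_m1, n_m2, n_pan = partition_counts(records)
    u_rec, u_lig = unique_members(records, "M2_specific")
    return {
        "total": len(records),
        "M1_specific": n_m1,
        "M2_specific": n_m2,
        "pan": n_pan,
        "unique_receptors_M2": u_rec,
        "unique_ligands_M2": u_lig,
    }
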