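"""Differential abundance of conditioned-media proteomics.

The procedure mirrors label-free detection analysis of macrophage
conditioned media collected under M1 (proinflammatory) and M2
(anti-inflammatory) polarization, in biological triplicate:

1. replicate-detection filter — a protein detected in fewer than
   ``min_detected`` replicates of a condition is treated as not detected
   in that condition at all; proteins detected in neither condition are
   dropped;
2. detection sets and their two-set (Venn) decomposition into
   M1-only / M2-only / both;
3. condition means over detected replicates and the fold change
   FC = mean(M2) / mean(M1);
4. restriction to conventionally secreted proteins via a
   predicted-secreted annotation.

Non-detection is never zero-imputed: condition means average detected
replicates only, and one-sided detection maps to the extended fold
changes FC = +inf (M2-only) and FC = 0 (M1-only), so that
condition-exclusive proteins land in the matching specificity class
downstream. No abundance p-values are computed; the method is detection
plus ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataValidationError, InputError
from .io import CONDITIONS, ProteinIntensityTable, SecretomeAnnotation


@dataclass(frozen=True)
class VennCounts:
    """Two-set decomposition of the detection sets."""

    m1_only: int
    m2_only: int
    both: int
    total: int

    def __post_init__(self) -> None:
        if self.m1_only + self.m2_only + self.both != self.total:
            raise DataValidationError("venn counts do not sum to total")

    def as_dict(self) -> dict[str, int]:
        return {
            "m1_only": self.m1_only,
            "m2_only": self.m2_only,
            "both": self.both,
            "total": self.total,
        }


def filter_by_replicates(
    table: ProteinIntensityTable, min_detected: int = 2
) -> ProteinIntensityTable:
    """Apply the replicate-detection filter.

    For each protein and condition, detection in fewer than
    ``min_detected`` replicates (but more than zero) is voided — those
    intensities become missing. Proteins left with no detection in either
    condition are dropped. Idempotent.
    """
    R = table.n_replicates
    if not (1 <= min_detected <= R):
        raise ConfigError(f"min_detected must be in [1, {R}], got {min_detected}")
    data = table.data.copy()
    for cond in CONDITIONS:
        counts = data[cond].notna().sum(axis=1)
        void = (counts > 0) & (counts < min_detected)
        if void.any():
            data.loc[void, cond] = np.nan
    keep = data.notna().any(axis=1)
    return ProteinIntensityTable(data.loc[keep])


def detection_sets(
    table: ProteinIntensityTable, min_detected: int = 2
) -> tuple[set[str], set[str]]:
    """Proteins detected (>= min_detected replicates) per condition: (M1, M2)."""
    out = []
    for cond in CONDITIONS:
        counts = table.data[cond].notna().sum(axis=1)
        out.append(set(table.data.index[counts >= min_detected]))
    return out[0], out[1]


def venn_counts(set_m1: set[str], set_m2: set[str]) -> VennCounts:
    both = len(set_m1 & set_m2)
    return VennCounts(
        m1_only=len(set_m1 - set_m2),
        m2_only=len(set_m2 - set_m1),
        both=both,
        total=len(set_m1 | set_m2),
    )


def condition_mean(table: ProteinIntensityTable, protein: str, condition: str) -> float:
    """Arithmetic mean over detected replicates; NaN when none are detected."""
    if condition not in CONDITIONS:
        raise InputError(f"unknown condition {condition!r}")
    if protein not in table.data.index:
        raise DataValidationError(f"unknown protein {protein!r}")
    vals = table.data.loc[protein, condition].dropna()
    return float(vals.mean()) if len(vals) else math.nan


def fold_change(mean_m2: float, mean_m1: float) -> float:
    """M2/M1 abundance ratio on the extended non-negative reals.

    Undefined (NaN) or zero mean on one side maps to the exclusive-
    detection conventions: +inf when the M1 mean is absent/zero, 0.0 when
    the M2 mean is absent/zero. Both sides absent is a contract violation
    (it cannot occur after the replicate filter).
    """
    m2_absent = math.isnan(mean_m2) or mean_m2 == 0
    m1_absent = math.isnan(mean_m1) or mean_m1 == 0
    if m2_absent and m1_absent:
        raise DataValidationError("fold change undefined: no detection in either condition")
    if m1_absent:
        return math.inf
    if m2_absent:
        return 0.0
    return mean_m2 / mean_m1


def _detection_class(n_m1: int, n_m2: int, min_detected: int) -> str:
    d1, d2 = n_m1 >= min_detected, n_m2 >= min_detected
    if d1 and d2:
        return "both"
    if d1:
        return "M1_only"
    if d2:
        return "M2_only"
    raise DataValidationError("protein with no detection reached summarize")


def summarize(table: ProteinIntensityTable, min_detected: int = 2) -> pd.DataFrame:
    """Per-protein condition summary of a replicate-filtered table.

    Columns: n_detected_M1, n_detected_M2, mean_M1, mean_M2, fc,
    detection_class. Means are NaN for undetected conditions; fc follows
    the +inf/0 conventions of :func:`fold_change`.
    """
    rows = []
    for protein in table.data.index:
        n1 = int(table.data.loc[protein, "M1"].notna().sum())
        n2 = int(table.data.loc[protein, "M2"].notna().sum())
        m1 = condition_mean(table, protein, "M1")
        m2 = condition_mean(table, protein, "M2")
        rows.append(
            {
                "protein_id": protein,
                "n_detected_M1": n1,
                "n_detected_M2": n2,
                "mean_M1": m1,
                "mean_M2": m2,
                "fc": fold_change(m2, m1),
                "detection_class": _detection_class(n1, n2, min_detected),
            }
        )
    cols = [
        "protein_id", "n_detected_M1", "n_detected_M2",
        "mean_M1", "mean_M2", "fc", "detection_class",
    ]
    return pd.DataFrame(rows, columns=cols).set_index("protein_id")


def filter_secreted(proteins: set[str], annotation: SecretomeAnnotation) -> set[str]:
    """Restrict to conventionally secreted proteins (set intersection)."""
    return set(proteins) & set(annotation.secreted_ids)


def write_summary(
    summary: pd.DataFrame,
    annotation: SecretomeAnnotation,
    path,
    dialect: str = "tsv",
) -> None:
    """Write the per-protein summary TSV with a secreted flag column."""
    out = summary.copy()
    out["secreted"] = [p in annotation for p in out.index]
    sep = "\t" if dialect == "tsv" else ","
    out.to_csv(path, sep=sep, index_label="protein_id")
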