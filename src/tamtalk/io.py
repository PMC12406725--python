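"""Domain tables, their on-disk forms, and gene-identifier harmonization.

Every table the pipeline touches is read and written here: the
conditioned-media protein intensity table (M1/M2 macrophage conditions in
replicate), the predicted-secreted annotation, the receptor–ligand pair
database, the bulk expression (base-mean) table, single-cell cluster marker
statistics with their cluster annotation, and differential-expression rows.

All cross-table joins downstream operate on *canonical* gene identifiers:
uppercased, whitespace-stripped, and routed through an alias map so that
synonymous symbols for the same gene (e.g. TGFBI and BIGH3, two names for
the same secreted extracellular-matrix protein) collapse to one identifier
before any join. :func:`harmonize_id` is applied by every reader.

On-disk convention is TSV (UTF-8, header row); CSV is accepted via
``dialect="csv"``. Missing intensity cells may be written as empty or
``NA``; a literal ``0`` intensity is treated as not-detected by default,
the common encoding of label-free non-detection.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataValidationError, InputError

logger = logging.getLogger(__name__)

#: The two macrophage polarization conditions of the conditioned-media design.
CONDITIONS = ("M1", "M2")

#: Cell types a cluster may be annotated with.
CELL_TYPES = ("malignant", "TAM", "T_cell", "other")

#: TAM ontogeny labels (bone-marrow-derived vs brain-resident microglia).
ONTOGENIES = ("microglia", "BMD")

#: Built-in gene-symbol aliases, user-extensible. The study's validated
#: ligand is referred to by both names; BIGH3 is kept canonical to match
#: single-cell marker tables.
DEFAULT_ALIASES: dict[str, str] = {"TGFBI": "BIGH3"}

MISSING = math.nan

_HEADER_RE = re.compile(r"^(?P<cond>[A-Za-z][A-Za-z0-9]*)_(?P<rep>\d+)$")


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise InputError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")


# ---------------------------------------------------------------------------
# identifier harmonization
# ---------------------------------------------------------------------------

def validate_alias_map(aliases: Mapping[str, str]) -> dict[str, str]:
    """Normalize and validate an alias→canonical map.

    Keys and values are uppercased/stripped. The map must be acyclic and
    canonical identifiers must be fixed points: no value may itself be an
    alias of something else, which also makes :func:`harmonize_id`
    idempotent.
    """
    out: dict[str, str] = {}
    for k, v in aliases.items():
        ku, vu = k.strip().upper(), v.strip().upper()
        if not ku or not vu:
            raise InputError("empty identifier in alias map")
        out[ku] = vu
    for alias, canon in out.items():
        if canon in out and out[canon] != canon:
            raise DataValidationError(
                f"alias map is not canonical: {alias!r} -> {canon!r} -> {out[canon]!r}"
            )
    return out


def harmonize_id(raw: str, aliases: Mapping[str, str] | None = None) -> str:
    """Canonicalize one gene identifier.

    Uppercases and strips whitespace, then applies the alias map (default:
    the built-in :data:`DEFAULT_ALIASES`). Idempotent for any validated
    alias map. Applied identically before every cross-table join.
    """
    if raw is None or not str(raw).strip():
        raise InputError("empty gene identifier")
    s = str(raw).strip().upper()
    amap = DEFAULT_ALIASES if aliases is None else aliases
    return amap.get(s, s)


def _harmonize_series(ids: Iterable[str], aliases: Mapping[str, str] | None) -> list[str]:
    return [harmonize_id(i, aliases) for i in ids]


def _check_unique(ids: list[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups: set[str] = set()
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
        if seen[i] > 1:
            dups.add(i)
    if dups:
        raise DataValidationError(
            f"duplicate {what} after harmonization: {sorted(dups)}"
        )


# ---------------------------------------------------------------------------
# protein intensity table
# ---------------------------------------------------------------------------

@dataclass
class ProteinIntensityTable:
    """Per-protein normalized intensities by (condition, replicate).

    ``data`` is indexed by canonical protein identifier with a two-level
    column index ``(condition, replicate)``; NaN encodes not-detected.
    Both conditions carry the same replicate count.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data.columns, pd.MultiIndex):
            raise DataValidationError("intensity columns must be (condition, replicate)")
        conds = tuple(sorted(set(self.data.columns.get_level_values(0))))
        if conds != tuple(sorted(CONDITIONS)):
            raise DataValidationError(f"conditions must be {CONDITIONS}, got {conds}")
        reps = {
            c: sorted(self.data[c].columns) for c in CONDITIONS
        }
        if reps["M1"] != reps["M2"]:
            raise DataValidationError("conditions carry different replicate sets")
        if not self.data.index.is_unique:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise DataValidationError(f"duplicate protein identifiers: {sorted(set(dups))}")
        if (self.data.to_numpy() < 0).any():
            raise DataValidationError("negative intensity")

    @property
    def n_replicates(self) -> int:
        return self.data["M1"].shape[1]

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


def read_intensity_table(
    path: str | Path,
    dialect: str = "tsv",
    *,
    zero_is_missing: bool = True,
    aliases: Mapping[str, str] | None = None,
) -> ProteinIntensityTable:
    """Read a protein intensity table.

    The first column holds protein identifiers; remaining headers encode
    condition and replicate as ``<condition>_<replicate>`` (``M1_1`` ...
    ``M2_3``). Empty cells and ``NA`` are not-detected; a literal 0 is
    treated likewise unless ``zero_is_missing`` is False.
    """
    df = pd.read_csv(path, sep=_sep(dialect))
    if df.shape[1] < 2:
        raise DataValidationError(f"{path}: no intensity columns")
    id_col = df.columns[0]
    cols: dict[tuple[str, int], str] = {}
    for c in df.columns[1:]:
        m = _HEADER_RE.match(str(c))
        if not m:
            raise DataValidationError(f"{path}: unparseable intensity header {c!r}")
        cols[(m["cond"].upper(), int(m["rep"]))] = c
    conds = {c for c, _ in cols}
    if conds != set(CONDITIONS):
        raise DataValidationError(
            f"{path}: expected conditions {set(CONDITIONS)}, found {conds}"
        )
    ids = _harmonize_series(df[id_col].astype(str), aliases)
    _check_unique(ids, "protein identifiers")
    wide = pd.DataFrame(
        {key: pd.to_numeric(df[src], errors="coerce") for key, src in sorted(cols.items())}
    )
    wide.columns = pd.MultiIndex.from_tuples(sorted(cols), names=["condition", "replicate"])
    wide.index = pd.Index(ids, name="protein_id")
    if zero_is_missing:
        wide = wide.mask(wide == 0)
    return ProteinIntensityTable(wide)


def write_intensity_table(table: ProteinIntensityTable, path: str | Path, dialect: str = "tsv") -> None:
    flat = table.data.copy()
    flat.columns = [f"{c}_{r}" for c, r in flat.columns]
    flat.to_csv(path, sep=_sep(dialect), index_label="protein_id", na_rep="")


# ---------------------------------------------------------------------------
# secretome annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SecretomeAnnotation:
    """Set of genes predicted to be conventionally secreted."""

    secreted_ids: frozenset[str]

    def __contains__(self, gene: str) -> bool:
        return gene in self.secreted_ids

    def __len__(self) -> int:
        return len(self.secreted_ids)


def read_secretome(
    path: str | Path, dialect: str = "tsv", aliases: Mapping[str, str] | None = None
) -> SecretomeAnnotation:
    """Read a one-column list of predicted-secreted gene identifiers."""
    df = pd.read_csv(path, sep=_sep(dialect))
    ids = _harmonize_series(df.iloc[:, 0].dropna().astype(str), aliases)
    return SecretomeAnnotation(frozenset(ids))


def write_secretome(ann: SecretomeAnnotation, path: str | Path, dialect: str = "tsv") -> None:
    pd.DataFrame({"gene_id": sorted(ann.secreted_ids)}).to_csv(
        path, sep=_sep(dialect), index=False
    )


# ---------------------------------------------------------------------------
# receptor-ligand database
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReceptorLigandDB:
    """Curated ligand→receptor interaction records.

    Self-pairs are permitted; duplicate records are not (readers drop them
    with a logged count). A pair listed with swapped roles is a distinct
    record and is never auto-symmetrized.
    """

    pairs: tuple[tuple[str, str], ...]
    source_tag: str = ""

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise DataValidationError("duplicate (ligand, receptor) records")

    def __len__(self) -> int:
        return len(self.pairs)


def read_rl_database(
    path: str | Path,
    dialect: str = "tsv",
    aliases: Mapping[str, str] | None = None,
    source_tag: str = "",
) -> ReceptorLigandDB:
    df = pd.read_csv(path, sep=_sep(dialect))
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise DataValidationError(f"{path}: required column {col!r} missing")
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for lig, rec in zip(df["ligand"].astype(str), df["receptor"].astype(str)):
        p = (harmonize_id(lig, aliases), harmonize_id(rec, aliases))
        if p in seen:
            n_dup += 1
            continue
        seen.add(p)
        pairs.append(p)
    if n_dup:
        logger.info("dropped %d duplicate receptor-ligand records from %s", n_dup, path)
    return ReceptorLigandDB(tuple(pairs), source_tag=source_tag or str(path))


def write_rl_database(db: ReceptorLigandDB, path: str | Path, dialect: str = "tsv") -> None:
    pd.DataFrame(db.pairs, columns=["ligand", "receptor"]).to_csv(
        path, sep=_sep(dialect), index=False
    )


# ---------------------------------------------------------------------------
# bulk expression (base mean) table
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """Per-gene normalized base-mean expression, one column per sample."""

    data: pd.DataFrame  # index gene_id, columns sample names

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise DataValidationError("duplicate gene identifiers in expression table")
        if not self.data.columns.is_unique:
            raise DataValidationError("duplicate sample names in expression table")
        if (self.data.to_numpy() < 0).any():
            raise DataValidationError("negative base_mean in expression table")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def base_mean(self, gene: str, sample: str) -> float:
        return float(self.data.at[gene, sample])


def read_expression_table(
    path: str | Path, dialect: str = "tsv", aliases: Mapping[str, str] | None = None
) -> ExpressionTable:
    df = pd.read_csv(path, sep=_sep(dialect))
    if df.shape[1] < 2:
        raise DataValidationError(f"{path}: expression table needs at least one sample column")
    ids = _harmonize_series(df.iloc[:, 0].astype(str), aliases)
    _check_unique(ids, "gene identifiers")
    vals = df.iloc[:, 1:].apply(pd.to_numeric)
    vals.index = pd.Index(ids, name="gene_id")
    return ExpressionTable(vals)


def write_expression_table(expr: ExpressionTable, path: str | Path, dialect: str = "tsv") -> None:
    expr.data.to_csv(path, sep=_sep(dialect), index_label="gene_id")


# ---------------------------------------------------------------------------
# single-cell cluster marker table + cluster annotation
# ---------------------------------------------------------------------------

#: internal column names of the marker table; on-disk pct columns use the
#: conventional dotted names pct.1 / pct.2 and avg_log2FC.
MARKER_COLUMNS = ("gene", "cluster", "pct1", "pct2", "log2_fc", "p_adj")
_MARKER_DISK = {
    "gene": "gene",
    "cluster": "cluster",
    "pct1": "pct.1",
    "pct2": "pct.2",
    "log2_fc": "avg_log2FC",
    "p_adj": "p_adj",
}


def validate_marker_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in MARKER_COLUMNS:
        if col not in df.columns:
            raise DataValidationError(f"marker table column {col!r} missing")
    for col in ("pct1", "pct2"):
        bad = df[(df[col] < 0) | (df[col] > 1)]
        if len(bad):
            raise DataValidationError(f"{col} outside [0,1] for {bad['gene'].tolist()}")
    bad = df[(df["p_adj"] < 0) | (df["p_adj"] > 1)]
    if len(bad):
        raise DataValidationError(f"p_adj outside [0,1] for {bad['gene'].tolist()}")
    return df


def read_marker_table(
    path: str | Path, dialect: str = "tsv", aliases: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read per-(gene, cluster) marker statistics.

    Required columns: gene, cluster, pct.1, pct.2, avg_log2FC, p_adj.
    Returns a frame with internal names ``gene, cluster, pct1, pct2,
    log2_fc, p_adj``; identifiers harmonized.
    """
    df = pd.read_csv(path, sep=_sep(dialect))
    for internal, disk in _MARKER_DISK.items():
        if disk not in df.columns:
            raise DataValidationError(f"{path}: required column {disk!r} missing")
    out = df.rename(columns={v: k for k, v in _MARKER_DISK.items()})[list(MARKER_COLUMNS)].copy()
    out["gene"] = _harmonize_series(out["gene"].astype(str), aliases)
    out["cluster"] = out["cluster"].astype(int)
    return validate_marker_table(out)


def write_marker_table(df: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    validate_marker_table(df)
    df[list(MARKER_COLUMNS)].rename(columns=_MARKER_DISK).to_csv(
        path, sep=_sep(dialect), index=False
    )


@dataclass(frozen=True)
class ClusterAnnotation:
    """Cluster → cell-type map, with TAM ontogeny where known.

    ``ontogeny`` distinguishes bone-marrow-derived (BMD) from resident
    microglial TAM clusters and may only annotate TAM clusters.
    """

    cell_type: Mapping[int, str]
    ontogeny: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, ct in self.cell_type.items():
            if ct not in CELL_TYPES:
                raise DataValidationError(f"cluster {cid}: unknown cell type {ct!r}")
        for cid, ont in self.ontogeny.items():
            if self.cell_type.get(cid) != "TAM":
                raise DataValidationError(
                    f"ontogeny annotated for non-TAM cluster {cid}"
                )
            if ont not in ONTOGENIES:
                raise DataValidationError(f"cluster {cid}: unknown ontogeny {ont!r}")

    @property
    def tam_clusters(self) -> list[int]:
        return sorted(c for c, t in self.cell_type.items() if t == "TAM")

    def clusters_of(self, ontogeny: str) -> list[int]:
        return sorted(c for c, o in self.ontogeny.items() if o == ontogeny)

    def covers(self, clusters: Iterable[int]) -> None:
        missing = sorted(set(clusters) - set(self.cell_type))
        if missing:
            raise DataValidationError(f"clusters without annotation: {missing}")


def read_cluster_annotation(path: str | Path, dialect: str = "tsv") -> ClusterAnnotation:
    df = pd.read_csv(path, sep=_sep(dialect))
    for col in ("cluster", "cell_type"):
        if col not in df.columns:
            raise DataValidationError(f"{path}: required column {col!r} missing")
    cell_type = dict(zip(df["cluster"].astype(int), df["cell_type"].astype(str)))
    ontogeny: dict[int, str] = {}
    if "ontogeny" in df.columns:
        for cid, ont in zip(df["cluster"].astype(int), df["ontogeny"]):
            if isinstance(ont, str) and ont.strip():
                ontogeny[cid] = ont.strip()
    return ClusterAnnotation(cell_type, ontogeny)


def write_cluster_annotation(ann: ClusterAnnotation, path: str | Path, dialect: str = "tsv") -> None:
    rows = [
        {
            "cluster": cid,
            "cell_type": ct,
            "ontogeny": ann.ontogeny.get(cid, ""),
        }
        for cid, ct in sorted(ann.cell_type.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep(dialect), index=False)


# ---------------------------------------------------------------------------
# differential-expression rows
# ---------------------------------------------------------------------------

def validate_deg_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("gene", "log2_fc", "p_adj"):
        if col not in df.columns:
            raise DataValidationError(f"DEG table column {col!r} missing")
    bad = df[(df["p_adj"] < 0) | (df["p_adj"] > 1)]
    if len(bad):
        raise DataValidationError(f"p_adj outside [0,1] for {bad['gene'].tolist()}")
    return df


def read_deg_table(
    path: str | Path, dialect: str = "tsv", aliases: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read DEG rows (gene, log2_fc, p_adj); sign convention is the caller's."""
    df = pd.read_csv(path, sep=_sep(dialect))
    validate_deg_table(df)
    out = df[["gene", "log2_fc", "p_adj"]].copy()
    out["gene"] = _harmonize_series(out["gene"].astype(str), aliases)
    return out


def write_deg_table(df: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    validate_deg_table(df)
    df[["gene", "log2_fc", "p_adj"]].to_csv(path, sep=_sep(dialect), index=False)
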