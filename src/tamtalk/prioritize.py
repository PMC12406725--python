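"""Single-cell prioritization of candidate ligands.

Candidate ligands from the crosstalk stage are ranked against published
single-cell cluster statistics from tumor specimens. Each (gene, cluster)
row carries pct.1 (fraction of cells in the cluster detecting the gene)
and pct.2 (average detection fraction across all other clusters); their
ratio is the enrichment score. A ligand is TAM-predominant when the
cluster maximizing its enrichment is annotated as a tumor-associated
macrophage cluster; TAM-predominant ligands are further called BMD
(bone-marrow-derived), microglia, or mixed by comparing maximal
enrichment across the two ontogeny groups. Finally, differential
expression between BMD and microglial TAMs ranks the top candidates.

An optional boolean cell x gene :class:`DetectionMatrix` serves as the
primitive substrate: marker-table pct statistics can be recomputed from
it by direct per-cell counting, which keeps the published-table path
checkable against an exact oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError, InputError
from .io import ClusterAnnotation, validate_marker_table

logger = logging.getLogger(__name__)

ONTOGENY_CALLS = ("BMD", "microglia", "mixed", "NA")


def enrichment_score(pct1: float, pct2: float) -> float:
    """pct.1 / pct.2 on the extended non-negative reals.

    A gene detected nowhere else (pct2 = 0 < pct1) scores +inf and sorts
    above every finite score; a gene absent from the cluster (pct1 = 0,
    including 0/0) scores 0 — absence is never enrichment.
    """
    for name, v in (("pct1", pct1), ("pct2", pct2)):
        if math.isnan(v) or not (0 <= v <= 1):
            raise DataValidationError(f"{name} must be in [0,1], got {v}")
    if pct1 == 0:
        return 0.0
    if pct2 == 0:
        return math.inf
    return pct1 / pct2


@dataclass
class DetectionMatrix:
    """Boolean cell x gene detection with per-cell cluster labels."""

    detected: np.ndarray  # (n_cells, n_genes) bool
    genes: list[str]
    clusters: np.ndarray  # (n_cells,) int

    def __post_init__(self) -> None:
        self.detected = np.asarray(self.detected, dtype=bool)
        self.clusters = np.asarray(self.clusters, dtype=int)
        if self.detected.shape != (len(self.clusters), len(self.genes)):
            raise DataValidationError("detection matrix shape mismatch")
        if len(np.unique(self.clusters)) < 2:
            raise DataValidationError("at least 2 clusters required")

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(np.unique(self.clusters).tolist())

    @classmethod
    def from_mtx(
        cls,
        matrix_path: str | Path,
        features_path: str | Path,
        clusters_path: str | Path,
    ) -> "DetectionMatrix":
        """Load from a MatrixMarket count matrix (genes x cells, 10x layout)
        plus one-column feature and per-cell cluster-label TSVs; any
        positive count is a detection."""
        from scipy.io import mmread

        counts = mmread(str(matrix_path)).tocsr()
        genes = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str).tolist()
        clusters = pd.read_csv(clusters_path, sep="\t", header=None)[0].to_numpy(dtype=int)
        if counts.shape[0] != len(genes):
            raise DataValidationError("feature count does not match matrix rows")
        return cls((counts.T > 0).toarray(), genes, clusters)


def compute_pcts(
    matrix: DetectionMatrix, gene: str, cluster: int, pct2_mode: str = "unweighted"
) -> tuple[float, float]:
    """Detection fractions (pct1, pct2) for one gene and cluster.

    pct1 is the detected fraction within the cluster. pct2 is, by
    default, the unweighted mean of the other clusters' per-cluster
    detection fractions ("on average in all the other clusters");
    ``pct2_mode="pooled"`` instead pools all other cells.
    """
    if gene not in matrix.genes:
        raise DataValidationError(f"gene {gene!r} not in matrix")
    if cluster not in matrix.cluster_ids:
        raise DataValidationError(f"cluster {cluster} not in matrix")
    if pct2_mode not in ("unweighted", "pooled"):
        raise InputError(f"unknown pct2_mode {pct2_mode!r}")
    g = matrix.genes.index(gene)
    col = matrix.detected[:, g]
    in_c = matrix.clusters == cluster
    pct1 = int(col[in_c].sum()) / int(in_c.sum())
    others = [c for c in matrix.cluster_ids if c != cluster]
    if pct2_mode == "pooled":
        out = ~in_c
        pct2 = int(col[out].sum()) / int(out.sum())
    else:
        # exact rational mean so the result is independent of cluster order
        from fractions import Fraction

        fracs = []
        for c in others:
            m = matrix.clusters == c
            fracs.append(Fraction(int(col[m].sum()), int(m.sum())))
        pct2 = float(sum(fracs) / len(fracs))
    return pct1, pct2


def marker_table_from_matrix(
    matrix: DetectionMatrix, pct2_mode: str = "unweighted"
) -> pd.DataFrame:
    """Full gene x cluster marker table computed from a detection matrix.

    pct columns come from :func:`compute_pcts`; log2_fc is the detection
    odds-ratio log and p_adj a BH-adjusted Fisher exact p-value of the
    in-cluster vs out-of-cluster detection contrast.
    """
    from scipy.stats import false_discovery_control, fisher_exact

    rows = []
    pvals = []
    for cluster in matrix.cluster_ids:
        in_c = matrix.clusters == cluster
        n_in, n_out = int(in_c.sum()), int((~in_c).sum())
        for g, gene in enumerate(matrix.genes):
            pct1, pct2 = compute_pcts(matrix, gene, cluster, pct2_mode)
            col = matrix.detected[:, g]
            a = int(col[in_c].sum())
            b = int(col[~in_c].sum())
            _, p = fisher_exact([[a, n_in - a], [b, n_out - b]], alternative="two-sided")
            eps = 1e-9
            rows.append(
                {
                    "gene": gene,
                    "cluster": cluster,
                    "pct1": pct1,
                    "pct2": pct2,
                    "log2_fc": math.log2((pct1 + eps) / (pct2 + eps)),
                }
            )
            pvals.append(p)
    df = pd.DataFrame(rows)
    df["p_adj"] = false_discovery_control(np.asarray(pvals), method="bh")
    return validate_marker_table(df)


def _enrichment_column(markers: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [enrichment_score(r.pct1, r.pct2) for r in markers.itertuples()],
        index=markers.index,
    )


def annotate_clusters_by_markers(
    markers: pd.DataFrame,
    marker_sets: Mapping[str, set[str]],
    overrides: Mapping[int, str] | None = None,
    ontogeny: Mapping[int, str] | None = None,
) -> ClusterAnnotation:
    """Assign each cluster the cell type whose markers are most enriched.

    The score of a cell type in a cluster is the mean enrichment of its
    marker genes present in that cluster's rows; ties break by mean pct1,
    then lexicographic cell-type name. Clusters where no marker gene of
    any set appears are assigned "other" with a warning. Explicit
    ``overrides`` (cluster id → cell type, as published annotations give
    them) win over marker scoring.
    """
    if not marker_sets or any(not s for s in marker_sets.values()):
        raise InputError("marker sets must be non-empty")
    sets = list(marker_sets.items())
    for i, (t1, s1) in enumerate(sets):
        for t2, s2 in sets[i + 1:]:
            if s1 & s2:
                raise InputError(f"marker sets {t1!r} and {t2!r} overlap: {sorted(s1 & s2)}")

    markers = markers.copy()
    markers["enrichment"] = _enrichment_column(markers)
    cell_type: dict[int, str] = {}
    for cluster, sub in markers.groupby("cluster"):
        best: tuple | None = None
        for ct, genes in sorted(marker_sets.items()):
            hit = sub[sub["gene"].isin(genes)]
            if not len(hit):
                continue
            score = (float(hit["enrichment"].mean()), float(hit["pct1"].mean()))
            # ties: higher mean enrichment, then higher mean pct1, then
            # lexicographically smaller cell-type name (iteration order)
            if best is None or score > best[0]:
                best = (score, ct)
        if best is None:
            logger.warning("cluster %s: no marker gene present; assigned 'other'", cluster)
            cell_type[int(cluster)] = "other"
        else:
            cell_type[int(cluster)] = best[1]
    if overrides:
        for cid, ct in overrides.items():
            cell_type[int(cid)] = ct
    ont = dict(ontogeny) if ontogeny else {}
    ont = {c: o for c, o in ont.items() if cell_type.get(c) == "TAM"}
    return ClusterAnnotation(cell_type, ont)


def tam_predominant(
    ligand: str, markers: pd.DataFrame, annotation: ClusterAnnotation
) -> tuple[bool, int | None]:
    """Whether the ligand's most-enriched cluster is a TAM cluster.

    Returns (flag, best_cluster). The best cluster maximizes the
    enrichment score; ties break by higher pct1 then lower cluster id.
    A ligand absent from the marker table returns (False, None).
    """
    sub = markers[markers["gene"] == ligand]
    if not len(sub):
        logger.info("ligand %s absent from marker table", ligand)
        return False, None
    annotation.covers(sub["cluster"])
    scored = sorted(
        (
            (-enrichment_score(r.pct1, r.pct2), -r.pct1, int(r.cluster))
            for r in sub.itertuples()
        ),
    )
    best_cluster = scored[0][2]
    return annotation.cell_type[best_cluster] == "TAM", best_cluster


def ontogeny_call(
    ligand: str,
    markers: pd.DataFrame,
    annotation: ClusterAnnotation,
    ontogeny_ratio: float = 1.5,
) -> str:
    """BMD vs microglia preference of a TAM-predominant ligand.

    Compares the ligand's maximal enrichment among BMD-annotated TAM
    clusters with that among microglial ones; the larger side is called
    when it exceeds the other by ``ontogeny_ratio`` (default 1.5), else
    "mixed". A side with no rows scores 0.
    """
    bmd = set(annotation.clusters_of("BMD"))
    mic = set(annotation.clusters_of("microglia"))
    if not bmd and not mic:
        raise DataValidationError("annotation carries no TAM ontogeny")
    sub = markers[markers["gene"] == ligand]

    def side_max(clusters: set[int]) -> float:
        rows = sub[sub["cluster"].isin(clusters)]
        if not len(rows):
            return 0.0
        return max(enrichment_score(r.pct1, r.pct2) for r in rows.itertuples())

    mb, mm = side_max(bmd), side_max(mic)
    if mb == mm == 0:
        return "mixed"
    if mb >= ontogeny_ratio * mm:
        return "BMD"
    if mm >= ontogeny_ratio * mb:
        return "microglia"
    return "mixed"


def prioritize_ligands(
    ligands: Iterable[str],
    markers: pd.DataFrame,
    annotation: ClusterAnnotation,
    ontogeny_ratio: float = 1.5,
) -> pd.DataFrame:
    """Rank candidate ligands by TAM predominance and enrichment.

    Returns one row per ligand: tam_predominant, best_cluster,
    best_enrichment, ontogeny_call (NA unless TAM-predominant and
    ontogeny annotation is available), ordered TAM-predominant first,
    then by descending best enrichment, then pct1, then name.
    """
    has_ontogeny = bool(annotation.ontogeny)
    rows = []
    for lig in sorted(set(ligands)):
        flag, best = tam_predominant(lig, markers, annotation)
        sub = markers[(markers["gene"] == lig) & (markers["cluster"] == best)]
        if best is not None and len(sub):
            r = sub.iloc[0]
            enr = enrichment_score(float(r["pct1"]), float(r["pct2"]))
            pct1 = float(r["pct1"])
        else:
            enr, pct1 = 0.0, 0.0
        call = "NA"
        if flag and has_ontogeny:
            call = ontogeny_call(lig, markers, annotation, ontogeny_ratio)
        rows.append(
            {
                "ligand": lig,
                "tam_predominant": flag,
                "best_cluster": -1 if best is None else best,
                "best_enrichment": enr,
                "best_pct1": pct1,
                "ontogeny_call": call,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "ligand", "tam_predominant", "best_cluster",
            "best_enrichment", "best_pct1", "ontogeny_call",
        ],
    )
    if len(df):
        df = df.sort_values(
            by=["tam_predominant", "best_enrichment", "best_pct1", "ligand"],
            ascending=[False, False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def filter_degs(
    degs: pd.DataFrame, lfc_min: float = 1.0, padj_max: float = 0.05
) -> pd.DataFrame:
    """Keep rows with |log2FC| >= lfc_min (inclusive) and p_adj < padj_max (strict)."""
    keep = (degs["log2_fc"].abs() >= lfc_min) & (degs["p_adj"] < padj_max)
    return degs[keep].reset_index(drop=True)


def rank_bmd_degs(
    degs: pd.DataFrame, padj_max: float = 1e-3, k: int = 3
) -> list[str]:
    """Top-k genes upregulated in BMD TAMs vs microglia.

    ``degs`` uses the sign convention positive = up in BMD. Rows with
    p_adj < padj_max and log2_fc > 0 are ordered by descending log2_fc,
    ties by ascending p_adj then gene name; the first k genes are
    returned (all of them, with a note, when fewer survive).
    """
    surv = degs[(degs["p_adj"] < padj_max) & (degs["log2_fc"] > 0)]
    ordered = surv.sort_values(
        by=["log2_fc", "p_adj", "gene"],
        ascending=[False, True, True],
        kind="mergesort",
    )["gene"].tolist()
    if len(ordered) < k:
        logger.info("only %d of requested %d upregulated BMD genes survive", len(ordered), k)
    return ordered[:k]
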