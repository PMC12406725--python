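"""Seeded generators for every pipeline input, with planted ground truth.

The generators emulate the statistical structure of the study design so
the whole pipeline is testable end to end without any external data:

* conditioned-media proteomics — log-normal protein intensities in
  triplicate per polarization condition, a multiplicative M2/M1 effect
  per planted specificity class, planted condition-exclusive proteins
  (the other condition fully missing), and i.i.d. per-replicate
  detection dropout (an intensity-dependent logistic option exists,
  since low-abundance dropout is the realistic regime);
* a secreted / non-secreted partition of the proteins;
* receptor base-mean expression placed a safe margin above or below the
  gate, so the planted gated set is identifiable;
* a ligand–receptor pair database mixing planted cognate pairs
  (detected secreted ligand x gated receptor) with decoys that each
  violate at least one eligibility condition;
* cluster-structured single-cell detection with genes planted in TAM
  clusters of known ontogeny, plus canonical cell-type marker genes, and
  a BMD-vs-microglia differential-expression table.

Every generator is a pure function of (params, seed): per-stage random
streams are derived from the scenario seed, so the same parameters give
bit-identical outputs. :func:`expected_counts` computes the downstream
pair counts, class partition, and unique members by brute-force
enumeration over the planted design, independent of the pipeline code
path — it is the oracle the pipeline is checked against.

The default :class:`ScenarioParams` mirror the study's scale: 1,093
proteins of which 207 are M1-exclusive and 63 M2-exclusive, three
replicates per condition, a 3,631-pair interaction database, and a gate
threshold of 1.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from . import io as tio
from . import prioritize as tpri

#: canonical cell-type marker genes used to annotate synthetic clusters
CELL_TYPE_MARKERS: dict[str, set[str]] = {
    "TAM": {"C1QA", "C1QB", "C1QC", "TYROBP", "CD68"},
    "malignant": {"GAP43", "GPM6B", "SEC61G", "PTN"},
    "T_cell": {"CD3G", "GZMH", "IL2RB"},
}


@dataclass
class ScenarioParams:
    """Parameters of one synthetic study scenario.

    Counts follow the planted design: ``n_m1_exclusive`` / ``n_m2_exclusive``
    proteins are detected in one condition only, and the remaining
    proteins are detected in both with a multiplicative M2/M1 effect of
    ``effect_fc_m2`` (planted M2-specific), ``effect_fc_m1`` (M1-specific)
    or ``effect_fc_pan``. Intensities are log-normal: ``protein_log_sd``
    is the between-protein abundance spread and ``intensity_log_sd`` the
    replicate-level noise, both on the natural-log scale.
    """

    seed: int
    # --- proteomics ---
    n_proteins: int = 1093
    n_m1_exclusive: int = 207
    n_m2_exclusive: int = 63
    n_m2_specific: int = 80
    n_m1_specific: int = 80
    n_pan: int = 663
    effect_fc_m2: float = 4.0
    effect_fc_m1: float = 0.25
    effect_fc_pan: float = 1.0
    dropout: float = 0.1
    dropout_model: str = "iid"  # "iid" | "intensity"
    R: int = 3
    intensity_log_mean: float = math.log(1e6)
    intensity_log_sd: float = 0.2
    protein_log_sd: float = 1.5
    frac_secreted: float = 0.25
    # --- receptor expression ---
    n_receptors: int = 400
    frac_gated: float = 0.6
    receptor_gate: float = 1.0
    gate_margin: float = 0.5
    gate_sample: str = "GSC20_M2CM"
    # --- pair database ---
    n_db_pairs: int = 3631
    frac_cognate: float = 0.08
    # --- single cell ---
    n_cells: int = 1000
    n_clusters: int = 8
    tam_cluster_ids: tuple[int, ...] = (2, 3, 6, 7)
    bmd_cluster_ids: tuple[int, ...] = (2, 3)
    t_cell_cluster_ids: tuple[int, ...] = (5,)
    n_planted_tam_genes: int = 10
    n_background_genes: int = 30
    planted_pct1: float = 0.8
    background_pct: float = 0.1

    def __post_init__(self) -> None:
        errs = []
        planted = (
            self.n_m1_exclusive + self.n_m2_exclusive
            + self.n_m2_specific + self.n_m1_specific + self.n_pan
        )
        if planted != self.n_proteins:
            errs.append(
                f"planted class counts sum to {planted}, n_proteins is {self.n_proteins}"
            )
        for name in ("frac_secreted", "frac_gated", "frac_cognate",
                     "planted_pct1", "background_pct"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                errs.append(f"{name} must be in [0,1], got {v}")
        if not (0 <= self.dropout < 1):
            errs.append(f"dropout must be in [0,1), got {self.dropout}")
        if self.dropout_model not in ("iid", "intensity"):
            errs.append(f"unknown dropout_model {self.dropout_model!r}")
        if self.R < 1:
            errs.append("R must be >= 1")
        if not (0 < self.effect_fc_m1 < self.effect_fc_pan < self.effect_fc_m2):
            errs.append("effect fold changes must satisfy m1 < pan < m2")
        if self.gate_margin < 0 or self.gate_margin > self.receptor_gate:
            errs.append("gate_margin must be in [0, receptor_gate]")
        tam = set(self.tam_cluster_ids)
        if not tam <= set(range(self.n_clusters)):
            errs.append("tam_cluster_ids outside cluster range")
        if not set(self.bmd_cluster_ids) <= tam:
            errs.append("bmd_cluster_ids must be TAM clusters")
        if set(self.t_cell_cluster_ids) & tam:
            errs.append("t_cell_cluster_ids overlap TAM clusters")
        if self.n_clusters < 2 or self.n_cells < self.n_clusters:
            errs.append("need >= 2 clusters and >= 1 cell per cluster")
        if errs:
            raise ConfigError(errs)

    @property
    def n_both(self) -> int:
        return self.n_m2_specific + self.n_m1_specific + self.n_pan


def load_params(path: str | Path) -> ScenarioParams:
    """Load scenario parameters from TOML (or YAML by suffix)."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(path.read_text())
    else:
        import tomllib

        raw = tomllib.loads(path.read_text())
    known = {f.name for f in dataclasses.fields(ScenarioParams)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError([f"unknown scenario parameter {k!r}" for k in sorted(unknown)])
    for key in ("tam_cluster_ids", "bmd_cluster_ids", "t_cell_cluster_ids"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "seed" not in raw:
        raise ConfigError("scenario seed is mandatory")
    return ScenarioParams(**raw)


@dataclass
class SyntheticTruth:
    """Planted labels the pipeline output is scored against."""

    secreted: frozenset[str]
    pol_class: dict[str, str]          # protein -> planted polarization label
    detection_design: dict[str, str]   # protein -> M1_only | M2_only | both
    receptors: tuple[str, ...]
    gated_receptors: frozenset[str]
    db_pairs: tuple[tuple[str, str], ...] = ()
    cognate_pairs: frozenset[tuple[str, str]] = frozenset()
    planted_cluster: dict[str, int] = field(default_factory=dict)
    planted_ontogeny: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        obj = {
            "secreted": sorted(self.secreted),
            "pol_class": dict(sorted(self.pol_class.items())),
            "detection_design": dict(sorted(self.detection_design.items())),
            "receptors": list(self.receptors),
            "gated_receptors": sorted(self.gated_receptors),
            "db_pairs": [list(p) for p in self.db_pairs],
            "cognate_pairs": sorted([list(p) for p in self.cognate_pairs]),
            "planted_cluster": dict(sorted(self.planted_cluster.items())),
            "planted_ontogeny": dict(sorted(self.planted_ontogeny.items())),
        }
        return json.dumps(obj, sort_keys=True, indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        obj = json.loads(text)
        return cls(
            secreted=frozenset(obj["secreted"]),
            pol_class=obj["pol_class"],
            detection_design=obj["detection_design"],
            receptors=tuple(obj["receptors"]),
            gated_receptors=frozenset(obj["gated_receptors"]),
            db_pairs=tuple(tuple(p) for p in obj["db_pairs"]),
            cognate_pairs=frozenset(tuple(p) for p in obj["cognate_pairs"]),
            planted_cluster={k: int(v) for k, v in obj["planted_cluster"].items()},
            planted_ontogeny=obj["planted_ontogeny"],
        )


def _rng(params: ScenarioParams, stream: int) -> np.random.Generator:
    # one independent stream per generator so each op is pure in (params, seed)
    return np.random.default_rng([params.seed, stream])


def _protein_design(params: ScenarioParams) -> tuple[list[str], dict[str, str], dict[str, str], dict[str, float]]:
    """Protein ids with planted detection design, class label, and effect."""
    ids = [f"P{i:04d}" for i in range(params.n_proteins)]
    design: dict[str, str] = {}
    label: dict[str, str] = {}
    effect: dict[str, float] = {}
    blocks = [
        (params.n_m1_exclusive, "M1_only", "M1_specific", params.effect_fc_m1),
        (params.n_m2_exclusive, "M2_only", "M2_specific", params.effect_fc_m2),
        (params.n_m2_specific, "both", "M2_specific", params.effect_fc_m2),
        (params.n_m1_specific, "both", "M1_specific", params.effect_fc_m1),
        (params.n_pan, "both", "pan", params.effect_fc_pan),
    ]
    i = 0
    for n, des, lab, eff in blocks:
        for p in ids[i:i + n]:
            design[p] = des
            label[p] = lab
            effect[p] = eff
        i += n
    return ids, design, label, effect


def generate_proteomics(params: ScenarioParams) -> tuple[tio.ProteinIntensityTable, SyntheticTruth]:
    """Synthesize the conditioned-media intensity table.

    Each protein draws a log-normal base abundance; M2 replicates carry
    the planted multiplicative effect, and each present cell is then
    masked with the dropout probability. Condition-exclusive proteins
    have the other condition fully missing by design. The returned truth
    carries the planted secreted set, detection design, and class labels
    (receptor/database fields are filled by the other generators).
    """
    rng = _rng(params, 1)
    ids, design, label, effect = _protein_design(params)
    n, R = params.n_proteins, params.R
    base = np.exp(rng.normal(params.intensity_log_mean, params.protein_log_sd, size=n))
    noise = np.exp(rng.normal(0.0, params.intensity_log_sd, size=(n, 2 * R)))
    eff = np.array([effect[p] for p in ids])
    vals = base[:, None] * noise
    vals[:, R:] *= eff[:, None]  # M2 block
    # planted exclusivity: void the whole other condition
    des = np.array([design[p] for p in ids])
    vals[des == "M2_only", :R] = np.nan
    vals[des == "M1_only", R:] = np.nan
    # detection dropout on present cells
    if params.dropout > 0:
        if params.dropout_model == "iid":
            p_drop = np.full_like(vals, params.dropout)
        else:
            # logistic in log intensity: low-abundance proteins drop more,
            # centered at the abundance mean with the between-protein width
            z = (params.intensity_log_mean - np.log(np.where(np.isnan(vals), 1.0, vals)))
            p_drop = np.clip(
                2 * params.dropout / (1 + np.exp(-z / params.protein_log_sd)), 0, 0.95
            )
        vals = np.where(rng.random(vals.shape) < p_drop, np.nan, vals)
    cols = pd.MultiIndex.from_tuples(
        [("M1", r + 1) for r in range(R)] + [("M2", r + 1) for r in range(R)],
        names=["condition", "replicate"],
    )
    data = pd.DataFrame(vals, index=pd.Index(ids, name="protein_id"), columns=cols)
    n_secreted = round(params.frac_secreted * n)
    secreted = frozenset(rng.choice(ids, size=n_secreted, replace=False).tolist())
    truth = SyntheticTruth(
        secreted=secreted,
        pol_class=label,
        detection_design=design,
        receptors=(),
        gated_receptors=frozenset(),
    )
    return tio.ProteinIntensityTable(data), truth


def generate_expression(params: ScenarioParams) -> tuple[tio.ExpressionTable, frozenset[str]]:
    """Receptor base-mean expression with a margin around the gate.

    Gated receptors draw base means at or above gate + margin, non-gated
    strictly below gate - margin, so :func:`tamtalk.crosstalk.gate_receptors`
    recovers the planted gated set exactly whenever margin > 0.
    """
    rng = _rng(params, 2)
    receptors = [f"R{i:04d}" for i in range(params.n_receptors)]
    n_gated = round(params.frac_gated * params.n_receptors)
    gated = frozenset(rng.choice(receptors, size=n_gated, replace=False).tolist())
    lo = max(params.receptor_gate - params.gate_margin, 0.0)
    vals = np.where(
        np.isin(receptors, sorted(gated)),
        params.receptor_gate + params.gate_margin + rng.exponential(2.0, params.n_receptors),
        rng.uniform(0.0, lo, params.n_receptors) if lo > 0 else 0.0,
    )
    expr = tio.ExpressionTable(
        pd.DataFrame({params.gate_sample: vals}, index=pd.Index(receptors, name="gene_id"))
    )
    return expr, gated


def generate_rl_db(params: ScenarioParams, truth: SyntheticTruth) -> tuple[tio.ReceptorLigandDB, frozenset[tuple[str, str]]]:
    """Pair database of planted cognate pairs plus decoys.

    A cognate pair joins a secreted (planted-detected) protein to a gated
    receptor. Each decoy violates at least one eligibility condition:
    an undetected ligand, a non-secreted ligand, or an ungated receptor.
    """
    if not truth.receptors:
        raise InputError("generate_rl_db needs a truth with receptors (run generate_expression)")
    rng = _rng(params, 3)
    proteins = sorted(truth.detection_design)
    secreted = sorted(truth.secreted)
    non_secreted = sorted(set(proteins) - truth.secreted)
    gated = sorted(truth.gated_receptors)
    ungated = sorted(set(truth.receptors) - truth.gated_receptors)
    undetected = [f"X{i:04d}" for i in range(max(params.n_db_pairs // 4, 1))]

    n_cognate = round(params.frac_cognate * params.n_db_pairs)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()

    def add_from(ligs: Sequence[str], recs: Sequence[str], n: int) -> None:
        attempts = 100 * n + 1000  # bail out if the product space is exhausted
        while n > 0 and ligs and recs and attempts > 0:
            attempts -= 1
            p = (str(rng.choice(ligs)), str(rng.choice(recs)))
            if p in seen:
                continue
            seen.add(p)
            pairs.append(p)
            n -= 1

    add_from(secreted, gated, n_cognate)
    cognate = frozenset(pairs)
    n_decoy = params.n_db_pairs - len(pairs)
    kinds = rng.integers(0, 3, size=n_decoy)
    for k in kinds:
        if k == 0:
            add_from(undetected, gated + ungated, 1)
        elif k == 1 and non_secreted:
            add_from(non_secreted, gated + ungated, 1)
        elif ungated:
            add_from(secreted, ungated, 1)
        else:
            add_from(undetected, gated, 1)
    order = rng.permutation(len(pairs))
    db = tio.ReceptorLigandDB(tuple(pairs[i] for i in order), source_tag="synthetic")
    return db, cognate


def _cluster_labels(params: ScenarioParams, rng: np.random.Generator) -> np.ndarray:
    sizes = np.full(params.n_clusters, params.n_cells // params.n_clusters)
    sizes[: params.n_cells % params.n_clusters] += 1
    return np.repeat(np.arange(params.n_clusters), sizes)


def planted_annotation(params: ScenarioParams) -> tio.ClusterAnnotation:
    """The designed cluster annotation (cell type + TAM ontogeny)."""
    tam = set(params.tam_cluster_ids)
    tcell = set(params.t_cell_cluster_ids)
    cell_type = {
        c: ("TAM" if c in tam else "T_cell" if c in tcell else "malignant")
        for c in range(params.n_clusters)
    }
    ontogeny = {
        c: ("BMD" if c in set(params.bmd_cluster_ids) else "microglia") for c in tam
    }
    return tio.ClusterAnnotation(cell_type, ontogeny)


def generate_sc_markers(
    params: ScenarioParams, planted_genes: Sequence[str] | None = None
) -> tuple[tpri.DetectionMatrix, pd.DataFrame, tio.ClusterAnnotation, dict[str, int]]:
    """Cluster-structured single-cell detection and its marker table.

    Planted TAM genes are detected with probability ``planted_pct1`` in
    their planted TAM cluster (cycling over the TAM cluster ids) and
    ``background_pct`` elsewhere; canonical cell-type markers are planted
    across their cell-type's clusters so marker-based annotation works;
    background genes detect uniformly. The marker table is computed from
    the matrix via :func:`tamtalk.prioritize.compute_pcts`, so table and
    per-cell oracle agree by construction.
    """
    rng = _rng(params, 4)
    if planted_genes is None:
        planted_genes = [f"TAMG{i:02d}" for i in range(params.n_planted_tam_genes)]
    planted_genes = list(planted_genes)[: params.n_planted_tam_genes]
    while len(planted_genes) < params.n_planted_tam_genes:
        planted_genes.append(f"TAMG{len(planted_genes):02d}")

    annotation = planted_annotation(params)
    clusters = _cluster_labels(params, rng)
    planted_cluster = {
        g: params.tam_cluster_ids[i % len(params.tam_cluster_ids)]
        for i, g in enumerate(planted_genes)
    }
    marker_genes = [g for ct in sorted(CELL_TYPE_MARKERS) for g in sorted(CELL_TYPE_MARKERS[ct])]
    background = [f"BG{i:03d}" for i in range(params.n_background_genes)]
    genes = planted_genes + marker_genes + background

    probs = np.full((params.n_cells, len(genes)), params.background_pct)
    for j, g in enumerate(planted_genes):
        probs[clusters == planted_cluster[g], j] = params.planted_pct1
    type_clusters = {
        ct: [c for c, t in annotation.cell_type.items() if t == ct]
        for ct in CELL_TYPE_MARKERS
    }
    for ct, gset in CELL_TYPE_MARKERS.items():
        mask = np.isin(clusters, type_clusters[ct])
        for g in gset:
            probs[mask, genes.index(g)] = 0.9
    detected = rng.random(probs.shape) < probs
    matrix = tpri.DetectionMatrix(detected, genes, clusters)
    markers = tpri.marker_table_from_matrix(matrix)
    return matrix, markers, annotation, planted_cluster


def generate_bmd_degs(params: ScenarioParams, planted_ontogeny: dict[str, str]) -> pd.DataFrame:
    """BMD-vs-microglia DEG table (positive log2FC = up in BMD).

    Planted BMD genes receive strong positive fold changes with tiny
    adjusted p-values, microglial genes the mirror image, and background
    genes null effects with uniform p-values.
    """
    rng = _rng(params, 5)
    rows = []
    for g, ont in sorted(planted_ontogeny.items()):
        lfc = float(rng.uniform(2.0, 5.0))
        rows.append(
            {
                "gene": g,
                "log2_fc": lfc if ont == "BMD" else -lfc,
                "p_adj": float(rng.uniform(1e-12, 1e-6)),
            }
        )
    for i in range(params.n_background_genes):
        rows.append(
            {
                "gene": f"BG{i:03d}",
                "log2_fc": float(rng.normal(0.0, 0.3)),
                "p_adj": float(rng.uniform(0.05, 1.0)),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "log2_fc", "p_adj"])


def generate_scenario(params: ScenarioParams) -> dict:
    """Run every generator and assemble a complete input bundle in memory.

    Single-cell TAM genes are planted on the scenario's own candidate
    ligands — the secreted M2-specific ligands of cognate pairs — so the
    prioritization stage has planted positives to recover.
    """
    table, truth = generate_proteomics(params)
    expr, gated = generate_expression(params)
    truth = dataclasses.replace(
        truth, receptors=tuple(expr.data.index), gated_receptors=gated
    )
    db, cognate = generate_rl_db(params, truth)
    truth = dataclasses.replace(truth, db_pairs=db.pairs, cognate_pairs=cognate)
    m2_ligands = sorted(
        {
            lig
            for lig, _ in cognate
            if truth.pol_class[lig] == "M2_specific"
        }
    )
    matrix, markers, annotation, planted_cluster = generate_sc_markers(params, m2_ligands)
    planted_ontogeny = {
        g: annotation.ontogeny[c] for g, c in planted_cluster.items()
    }
    truth = dataclasses.replace(
        truth, planted_cluster=planted_cluster, planted_ontogeny=planted_ontogeny
    )
    degs = generate_bmd_degs(params, planted_ontogeny)
    return {
        "params": params,
        "intensity": table,
        "secretome": tio.SecretomeAnnotation(truth.secreted),
        "expression": expr,
        "db": db,
        "matrix": matrix,
        "markers": markers,
        "annotation": annotation,
        "bmd_degs": degs,
        "truth": truth,
    }


def write_bundle(scenario: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write a scenario to disk as the pipeline's input bundle.

    Produces intensity.tsv, secretome.tsv, rl_db.tsv, expression.tsv,
    markers.tsv, clusters.tsv, bmd_degs.tsv, truth.json and a ready
    config.toml pointing at them.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params: ScenarioParams = scenario["params"]
    paths = {k: out / f"{k}.tsv" for k in (
        "intensity", "secretome", "rl_db", "expression", "markers", "clusters", "bmd_degs"
    )}
    tio.write_intensity_table(scenario["intensity"], paths["intensity"])
    tio.write_secretome(scenario["secretome"], paths["secretome"])
    tio.write_rl_database(scenario["db"], paths["rl_db"])
    tio.write_expression_table(scenario["expression"], paths["expression"])
    tio.write_marker_table(scenario["markers"], paths["markers"])
    tio.write_cluster_annotation(scenario["annotation"], paths["clusters"])
    tio.write_deg_table(scenario["bmd_degs"], paths["bmd_degs"])
    (out / "truth.json").write_text(scenario["truth"].to_json())
    config = "\n".join(
        [
            f'intensity_table = "{paths["intensity"]}"',
            f'secretome = "{paths["secretome"]}"',
            f'rl_database = "{paths["rl_db"]}"',
            f'expression_table = "{paths["expression"]}"',
            f'marker_table = "{paths["markers"]}"',
            f'cluster_annotation = "{paths["clusters"]}"',
            f'bmd_deg_table = "{paths["bmd_degs"]}"',
            f'gate_sample = "{params.gate_sample}"',
            f"receptor_gate = {params.receptor_gate}",
            f'out_dir = "{out / "results"}"',
            f"seed = {params.seed}",
            "",
        ]
    )
    (out / "config.toml").write_text(config)
    paths["truth"] = out / "truth.json"
    paths["config"] = out / "config.toml"
    return paths


def expected_counts(truth: SyntheticTruth) -> dict:
    """Downstream counts derived from the planted design alone.

    Brute-force enumeration, independent of the pipeline code path: a
    pair contributes iff its ligand is planted-detected and secreted and
    its receptor is planted-gated; classes come from the planted labels.
    """
    design = truth.detection_design
    venn = {
        "m1_only": sum(1 for d in design.values() if d == "M1_only"),
        "m2_only": sum(1 for d in design.values() if d == "M2_only"),
        "both": sum(1 for d in design.values() if d == "both"),
    }
    venn["total"] = venn["m1_only"] + venn["m2_only"] + venn["both"]
    eligible = {p for p in design if p in truth.secreted}
    pairs = [
        (lig, rec)
        for lig, rec in truth.db_pairs
        if lig in eligible and rec in truth.gated_receptors
    ]
    partition = {"M1_specific": 0, "M2_specific": 0, "pan": 0}
    for lig, _ in pairs:
        partition[truth.pol_class[lig]] += 1
    m2_pairs = [p for p in pairs if truth.pol_class[p[0]] == "M2_specific"]
    return {
        "venn": venn,
        "n_pairs": len(pairs),
        "partition": partition,
        "unique_receptors_M2": len({r for _, r in m2_pairs}),
        "unique_ligands_M2": len({l for l, _ in m2_pairs}),
    }
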