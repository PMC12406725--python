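# Methods

## Problem and model

Glioblastoma stem cells (GSCs) invade more aggressively when exposed to
conditioned media (CM) from anti-inflammatory (M2-polarized) macrophages
than from proinflammatory (M1) ones, implicating secreted
macrophage-derived ligands acting on GSC receptors. `tamtalk` implements
the computational chain that nominates such ligands from four inputs:
label-free CM proteomics of M1/M2 macrophages in replicate, a
predicted-secreted gene annotation, a curated ligand–receptor pair
database, bulk RNA-seq of the receiving GSCs, and published single-cell
cluster statistics from patient tumors.

The chain is deliberately simple — detection, ratios, set joins, and
argmax rules — because that is what the underlying experimental design
supports. No abundance p-values are computed: label-free CM intensities
in biological triplicate carry detection information and a fold-change
ratio, not a usable per-protein variance model.

### Stage 1 — differential abundance of CM proteomics

A protein's intensity is observed per condition `c ∈ {M1, M2}` and
replicate `r ∈ 1..R` (default R = 3), with missingness meaning
non-detection. The stages are:

1. **Replicate-detection filter.** Detection in fewer than
   `min_detected` (default 2) replicates of a condition is voided for
   that condition; proteins with no surviving detection are dropped.
   "Per sample" is read as "per condition": the two CM preparations are
   the samples, each in triplicate — the only reading under which
   "detected only in M1 CM" is well defined.
2. **Detection sets and Venn decomposition** into M1-only / M2-only /
   both, with the conservation invariant
   `m1_only + m2_only + both = total`.
3. **Fold change** `FC = mean(M2) / mean(M1)` over *detected* replicates
   only (no zero-imputation; a zero-imputation mode is available for
   sensitivity analysis via `zero_is_missing=False` at read time).
   One-sided detection maps to the extended values `FC = +∞` (M2-only)
   and `FC = 0` (M1-only), chosen so condition-exclusive proteins fall
   into the matching specificity class in stage 2.
4. **Secretome restriction**: intersection with the predicted
   conventionally-secreted annotation (the experimental motivation: the
   proinvasive activity is in the EV-free soluble fraction).

### Stage 2 — receptor-gated interaction records

A database pair (ligand, receptor) becomes an interaction record iff the
ligand is detected (post-filter, either condition) *and* secreted, and
the receptor's base-mean expression in the designated GSC sample is at
or above the gate (default 1, boundary inclusive). Records are
classified by ligand FC:

* `FC ≥ fc_high` (default 2) → **M2-specific**;
* `FC ≤ fc_low` (default 0.5) → **M1-specific**;
* otherwise → **pan-macrophage**.

Both boundaries are inclusive; the classes are mutually exclusive,
exhaustive, and monotone in FC. Duplicate database rows are dropped on
read (counted in the log); role-swapped pairs are distinct records and
never symmetrized. Output ordering is (ligand, receptor) lexicographic
so reports diff cleanly.

### Stage 3 — single-cell prioritization

Published marker tables carry, per (gene, cluster), `pct.1` (fraction of
cells in the cluster detecting the gene) and `pct.2` (average detection
fraction across all other clusters). The enrichment score is
`pct.1 / pct.2` with `0/anything = 0` (absence is not enrichment) and
`pct2 = 0 < pct1 → +∞` (sorted above all finite scores).

* **pct.2 semantics**: the unweighted mean of the other clusters'
  per-cluster fractions, matching the "on average in all the other
  clusters" phrasing; a pooled-cells mode is available
  (`pct2_mode="pooled"`). The unweighted mean is computed in exact
  rational arithmetic so its value is independent of cluster order.
* **TAM predominance** is operationalized as: the cluster maximizing
  the ligand's enrichment (ties → higher pct.1, then lower cluster id)
  is annotated as a TAM cluster. The source analyses present dot plots
  without a stated rule; argmax is this package's choice, and it
  recovers planted calls on synthetic reconstructions — that is not a
  guarantee of matching visual judgement on real data.
* **Ontogeny call** (BMD vs microglia): the side (among
  ontogeny-annotated TAM clusters) with the larger maximal enrichment is
  called if it exceeds the other by `ontogeny_ratio` (default 1.5, our
  parameter, exposed in config); otherwise "mixed".
* **Cluster annotation** can be given explicitly (cluster-id lists, as
  published annotations are) or derived from canonical marker sets
  (malignant: GAP43, GPM6B, SEC61G, PTN; TAM: C1QA, C1QB, C1QC, TYROBP,
  CD68; T cells: CD3G, GZMH, IL2RB) by highest mean marker enrichment,
  ties broken by mean pct.1 then cell-type name; explicit annotations
  override scoring.
* **DEG handling**: generic DEG tables are filtered at |log2FC| ≥ 1
  (inclusive) and adjusted p < 0.05 (strict). BMD-vs-microglia ranking
  keeps adjusted p < 1e-3 and log2FC > 0 and orders by effect size
  (descending log2FC, ties by ascending p then gene name) — the "top
  DEGs" ordering is not stated in the source, and effect-size-first is
  this package's choice.

### Identifier harmonization

All tables pass through one canonicalization before any join: uppercase,
strip, then an alias map whose values are fixed points (validated), so
harmonization is idempotent. A built-in alias maps TGFBI → BIGH3 (two
names for the same secreted ECM protein, both in circulation); the map
is user-extensible via the `aliases` config table. Which mapping the
original proteomics software applied is not recoverable; the alias
mechanism is this package's device for making joins well defined.

## Synthetic data generator

The generator produces every pipeline input with planted truth; its
defaults are the study-scale conditions, fixed once:

| parameter | default | rationale |
|---|---|---|
| n_proteins | 1,093 | total detected proteins at study scale |
| n_m1_exclusive / n_m2_exclusive | 207 / 63 | planted condition-exclusive proteins |
| n_m2_specific / n_m1_specific / n_pan | 80 / 80 / 663 | both-detected split (unstated in the source; chosen as a realistic minority of polarization-responsive proteins) |
| effect_fc_m2 / m1 / pan | 4.0 / 0.25 / 1.0 | planted multiplicative M2/M1 effects, ≥2× beyond the class boundaries |
| R / dropout | 3 / 0.1 | triplicate design; ~10% per-replicate non-detection, a mild label-free regime |
| intensity_log_mean / protein_log_sd / intensity_log_sd | ln 1e6 / 1.5 / 0.2 | log-normal abundance: wide between-protein spread, ~20% CV replicate noise |
| n_db_pairs / frac_cognate | 3,631 / 0.08 | database at study scale; cognate pairs a small planted minority |
| n_receptors / frac_gated / gate_margin | 400 / 0.6 / 0.5 | receptor base means placed a margin away from the gate of 1 |
| n_cells / n_clusters / tam clusters | 1,000 / 8 / {2,3,6,7} (BMD {2,3}) | scaled-down cluster structure with a T-cell cluster (5) and malignant remainder |
| planted_pct1 / background_pct | 0.8 / 0.1 | planted TAM-gene detection vs background |

Model choices: intensities are log-normal with a multiplicative
condition effect — the natural model for a ratio-based analysis;
dropout is i.i.d. per replicate by default, with an
intensity-dependent logistic option (`dropout_model="intensity"`) since
low-abundance dropout is the realistic regime. Single-cell TAM genes
are planted on the scenario's own M2-specific cognate ligands so the
prioritization stage has true positives to find; the marker table is
computed from the simulated detection matrix by the same integer
counting the oracle uses, so table and matrix agree by construction.
The BMD-vs-microglia DEG table gives planted genes strong effects with
tiny p-values and background genes null effects.

`expected_counts` is the independent oracle: it derives the Venn
decomposition, pair count, class partition, and unique-member counts by
brute-force enumeration over the *planted* design, never touching the
pipeline code path. With dropout 0 and a positive gate margin the
pipeline must reproduce it exactly (verified over 50 randomized
parameter draws with fixed seeds).

What the generator does **not** emulate: correlated replicate noise,
intensity-dependent normalization artifacts, shared peptides /
protein-inference ambiguity, doublets or ambient RNA in the single-cell
matrix, and real gene-gene correlation. Passing tests therefore
demonstrate correctness of the *procedure* under its stated model, not
robustness to every artifact of real data.

## Numerical and degenerate-case choices

* Missing encoding on read: empty, `NA`, and (by default) literal 0 are
  non-detection; configurable because label-free exporters differ.
* `fold_change` with both sides absent is a contract violation (cannot
  occur after the replicate filter) and raises.
* `enrichment_score(0, 0) = 0`; `pct2` uses exact rational arithmetic
  (`fractions.Fraction`) before the final float conversion, making the
  value order-independent and exactly reproducible by integer counting.
* All ordering rules (interaction records, priorities, DEG ranks) have
  total deterministic tie-breaks, so identical config + inputs give
  byte-identical outputs; report JSON is written with sorted keys.
* Random streams: every generator derives an independent
  `numpy.random.default_rng([seed, stream])`, so each generator is a
  pure function of (params, seed) and generators can be called alone or
  composed without perturbing each other.

## Problem sizes used in the tests and acceptance script

Unit and property tests run at desk scale (60–500 proteins, 30–90
receptors, 60–250 database pairs, 80–1,000 cells), sizes chosen so the
whole suite exercises every stage end to end in well under a minute
while the planted-recovery statistics remain tight (20 seeds × 500
proteins gives a standard error of ~0.2 percentage points on the
recovery rate). The acceptance script runs the full default
study-scale scenario once plus the 20-seed recovery experiment.

## Known limitations

* The 255/100/97/58 pair accounting and the 1,093-protein Venn counts
  of the original study are recomputable only with its deposited
  proteomics, pair database, and RNA-seq files; this package reproduces
  the *procedure* and validates it against planted synthetic truth at
  the same scale.
* TAM predominance and the ontogeny ratio are operationalizations of
  qualitative statements; both are exposed as config parameters.
* The pipeline treats the pair database as ground truth and performs no
  direction inference, communication-probability modeling, or network
  analysis.
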