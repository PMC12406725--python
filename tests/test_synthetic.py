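"""Generator determinism, planted-truth identifiability, and calibration."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from tamtalk import crosstalk as tx
from tamtalk import prioritize as tpri
from tamtalk import proteomics as tprot
from tamtalk import synthetic as ts
from tamtalk.errors import ConfigError

from conftest import small_params


class TestParams:
    def test_invalid_params_rejected_before_generation(self):
        with pytest.raises(ConfigError):
            ts.ScenarioParams(seed=1, n_proteins=10)  # default class counts mismatch
        with pytest.raises(ConfigError):
            small_params(1, dropout=1.0)
        with pytest.raises(ConfigError):
            small_params(1, tam_cluster_ids=(99,))

    def test_defaults_are_paper_scale(self):
        p = ts.ScenarioParams(seed=0)
        assert p.n_proteins == 1093
        assert (p.n_m1_exclusive, p.n_m2_exclusive) == (207, 63)
        assert p.R == 3 and p.n_db_pairs == 3631 and p.receptor_gate == 1.0


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = ts.generate_proteomics(small_params(5))[0]
        b = ts.generate_proteomics(small_params(5))[0]
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_different_seed_differs(self):
        a = ts.generate_proteomics(small_params(5))[0]
        b = ts.generate_proteomics(small_params(6))[0]
        assert not a.data.equals(b.data)

    def test_scenario_truth_deterministic(self):
        t1 = ts.generate_scenario(small_params(9))["truth"]
        t2 = ts.generate_scenario(small_params(9))["truth"]
        assert t1.to_json() == t2.to_json()


class TestZeroDropout:
    def test_detection_matches_planted_design(self):
        params = small_params(3, dropout=0.0)
        table, truth = ts.generate_proteomics(params)
        filtered = tprot.filter_by_replicates(table)
        s1, s2 = tprot.detection_sets(filtered)
        v = tprot.venn_counts(s1, s2)
        exp = ts.expected_counts(truth)["venn"]
        assert v.as_dict() == exp

    def test_expression_margin_makes_gate_exact(self):
        params = small_params(4, gate_margin=0.5)
        expr, gated = ts.generate_expression(params)
        recovered = tx.gate_receptors(expr, params.gate_sample, params.receptor_gate)
        assert recovered == set(gated)

    def test_decoy_only_db_yields_no_pairs(self):
        params = small_params(7, frac_cognate=0.0)
        sc = ts.generate_scenario(params)
        assert ts.expected_counts(sc["truth"])["n_pairs"] == 0

    def test_oracle_is_pure(self):
        truth = ts.generate_scenario(small_params(8))["truth"]
        assert ts.expected_counts(truth) == ts.expected_counts(truth)


class TestCalibration:
    def test_effect_fc_4_gives_fc_above_2_without_dropout(self):
        """With a 4-fold planted effect, replicate noise sd 0.2 and no
        dropout, the empirical M2/M1 ratio clears the class boundary of 2
        for at least 99% of planted M2-specific proteins (n=500)."""
        params = ts.ScenarioParams(
            seed=21, n_proteins=500, n_m1_exclusive=0, n_m2_exclusive=0,
            n_m2_specific=250, n_m1_specific=250, n_pan=0,
            effect_fc_pan=1.0, dropout=0.0, intensity_log_sd=0.2,
        )
        table, truth = ts.generate_proteomics(params)
        summary = tprot.summarize(tprot.filter_by_replicates(table))
        m2 = [p for p, c in truth.pol_class.items() if c == "M2_specific"]
        hits = sum(summary.loc[p, "fc"] >= 2 for p in m2)
        assert hits / len(m2) >= 0.99

    def test_planted_pct1_concentrates(self):
        """Binomial concentration: with detection probability 0.8 in the
        planted cluster and 250 cells per cluster, the observed pct1 lies
        within +-0.05 of 0.8."""
        params = small_params(
            13, n_cells=1000, n_clusters=4, planted_pct1=0.8, background_pct=0.2
        )
        matrix, markers, _, planted = ts.generate_sc_markers(params)
        for g, c in planted.items():
            p1, _ = tpri.compute_pcts(matrix, g, c)
            assert abs(p1 - 0.8) <= 0.05

    def test_exclusive_detection_gives_inf_enrichment(self):
        params = small_params(14, planted_pct1=1.0, background_pct=0.0)
        matrix, markers, _, planted = ts.generate_sc_markers(params)
        g, c = next(iter(planted.items()))
        p1, p2 = tpri.compute_pcts(matrix, g, c)
        assert tpri.enrichment_score(p1, p2) == math.inf


class TestNoiseDegradation:
    def test_recovery_monotone_in_dropout(self):
        """Planted-class recovery does not improve as dropout rises."""

        def recovery(dropout: float, seed: int) -> float:
            params = small_params(seed, dropout=dropout)
            table, truth = ts.generate_proteomics(params)
            filtered = tprot.filter_by_replicates(table)
            summary = tprot.summarize(filtered)
            cfg = tx.CrosstalkConfig(gate_sample="S")
            ok = 0
            for p, label in truth.pol_class.items():
                if p in summary.index and tx.classify_polarization(
                    summary.loc[p, "fc"], cfg
                ) == label:
                    ok += 1
            return ok / len(truth.pol_class)

        seeds = range(100, 120)
        rates = [np.mean([recovery(d, s) for s in seeds]) for d in (0.0, 0.1, 0.3)]
        assert rates[0] >= rates[1] >= rates[2]
        assert rates[0] == 1.0


class TestSingleCellTruth:
    def test_planted_genes_called_in_their_cluster(self):
        params = small_params(31, planted_pct1=0.8, background_pct=0.1)
        matrix, markers, annotation, planted = ts.generate_sc_markers(params)
        for g, c in planted.items():
            flag, best = tpri.tam_predominant(g, markers, annotation)
            assert flag and best == c

    def test_marker_annotation_recovers_design(self):
        params = small_params(32)
        _, markers, annotation, _ = ts.generate_sc_markers(params)
        called = tpri.annotate_clusters_by_markers(
            markers, ts.CELL_TYPE_MARKERS, ontogeny=annotation.ontogeny
        )
        assert called.cell_type == dict(annotation.cell_type)

    def test_bmd_degs_rank_planted_bmd_genes_first(self):
        params = small_params(33)
        sc = ts.generate_scenario(params)
        top = tpri.rank_bmd_degs(sc["bmd_degs"], k=3)
        assert all(sc["truth"].planted_ontogeny[g] == "BMD" for g in top)
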