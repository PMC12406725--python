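"""Enrichment scores, pct statistics, TAM predominance and DEG ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tamtalk import prioritize as tp
from tamtalk.errors import DataValidationError
from tamtalk.io import ClusterAnnotation


class TestEnrichment:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (0.8, 0.2, 4.0),
            (0.5, 0.5, 1.0),
            (0.3, 0.0, math.inf),
            (0.0, 0.0, 0.0),
            (0.0, 0.4, 0.0),
        ],
    )
    def test_conventions(self, p1, p2, expected):
        assert tp.enrichment_score(p1, p2) == expected

    def test_out_of_range(self):
        with pytest.raises(DataValidationError):
            tp.enrichment_score(1.2, 0.5)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.floats(min_value=0.01, max_value=1.0),
        st.floats(min_value=0.01, max_value=1.0),
        st.floats(min_value=0.01, max_value=1.0),
    )
    def test_scale_invariant(self, p1, p2, f):
        a = tp.enrichment_score(p1, p2)
        b = tp.enrichment_score(p1 * f, p2 * f)
        assert b == pytest.approx(a)


def _matrix(fracs_by_cluster: dict[int, float], per_cluster: int = 10) -> tp.DetectionMatrix:
    """One-gene matrix with an exact per-cluster detection fraction."""
    clusters, detected = [], []
    for cid, frac in fracs_by_cluster.items():
        k = round(frac * per_cluster)
        clusters += [cid] * per_cluster
        detected += [True] * k + [False] * (per_cluster - k)
    return tp.DetectionMatrix(
        np.array(detected, dtype=bool)[:, None], ["G"], np.array(clusters)
    )


class TestComputePcts:
    def test_exclusive_detection(self):
        m = _matrix({1: 1.0, 2: 0.0}, per_cluster=2)
        assert tp.compute_pcts(m, "G", 1) == (1.0, 0.0)

    def test_everywhere(self):
        m = _matrix({1: 1.0, 2: 1.0, 3: 1.0})
        for c in (1, 2, 3):
            assert tp.compute_pcts(m, "G", c) == (1.0, 1.0)

    def test_unweighted_mean_of_other_clusters(self):
        # per-cluster fractions (0.5, 0.2, 0.8): pct2 for cluster 1 = mean(0.2, 0.8)
        m = _matrix({1: 0.5, 2: 0.2, 3: 0.8})
        p1, p2 = tp.compute_pcts(m, "G", 1)
        assert p1 == 0.5
        assert p2 == pytest.approx(0.5)

    def test_pooled_mode_weights_by_cells(self):
        m = _matrix({1: 0.5, 2: 0.2, 3: 0.8})
        _, p2 = tp.compute_pcts(m, "G", 1, pct2_mode="pooled")
        assert p2 == pytest.approx(0.5)  # equal cluster sizes: same value
        m2 = tp.DetectionMatrix(
            np.array([True] * 2 + [False] * 2 + [True] * 6, dtype=bool)[:, None],
            ["G"],
            np.array([0, 0, 1, 1, 2, 2, 2, 2, 2, 2]),
        )
        assert tp.compute_pcts(m2, "G", 0, pct2_mode="pooled")[1] == 6 / 8
        assert tp.compute_pcts(m2, "G", 0)[1] == pytest.approx((0.0 + 1.0) / 2)

    def test_matches_per_cell_oracle(self):
        from fractions import Fraction

        rng = np.random.default_rng(11)
        n_cells, genes = 120, [f"G{i}" for i in range(6)]
        clusters = rng.integers(0, 4, n_cells)
        detected = rng.random((n_cells, len(genes))) < 0.3
        m = tp.DetectionMatrix(detected, genes, clusters)
        for g in genes:
            gi = genes.index(g)
            for c in sorted(set(clusters.tolist())):
                p1, p2 = tp.compute_pcts(m, g, c)
                fracs = {}
                for cell in range(n_cells):
                    cc = int(clusters[cell])
                    fracs.setdefault(cc, [0, 0])
                    fracs[cc][0] += int(detected[cell, gi])
                    fracs[cc][1] += 1
                assert p1 == fracs[c][0] / fracs[c][1]
                others = [k for k in fracs if k != c]
                exact = sum(Fraction(*fracs[k]) for k in others) / len(others)
                assert p2 == float(exact)


ANN = ClusterAnnotation(
    {0: "malignant", 1: "TAM", 2: "TAM", 3: "T_cell"},
    {1: "BMD", 2: "microglia"},
)


def _markers(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["gene", "cluster", "pct1", "pct2"])
    df["log2_fc"] = 0.0
    df["p_adj"] = 0.01
    return df


class TestAnnotateByMarkers:
    SETS = {"TAM": {"C1QA", "C1QB"}, "malignant": {"GAP43"}}

    def test_argmax_assignment(self):
        markers = _markers(
            [
                ("C1QA", 1, 0.9, 0.1), ("C1QB", 1, 0.8, 0.1), ("GAP43", 1, 0.1, 0.5),
                ("C1QA", 0, 0.1, 0.6), ("GAP43", 0, 0.9, 0.1),
            ]
        )
        ann = tp.annotate_clusters_by_markers(markers, self.SETS)
        assert ann.cell_type[1] == "TAM"
        assert ann.cell_type[0] == "malignant"

    def test_explicit_override_wins(self):
        markers = _markers([("C1QA", 17, 0.9, 0.1)])
        ann = tp.annotate_clusters_by_markers(markers, self.SETS, overrides={17: "T_cell"})
        assert ann.cell_type[17] == "T_cell"

    def test_no_marker_present_gives_other(self):
        markers = _markers([("XYZ", 5, 0.9, 0.1)])
        ann = tp.annotate_clusters_by_markers(markers, self.SETS)
        assert ann.cell_type[5] == "other"

    def test_tie_breaks_lexicographically(self):
        markers = _markers([("C1QA", 0, 0.5, 0.5), ("GAP43", 0, 0.5, 0.5)])
        ann = tp.annotate_clusters_by_markers(markers, self.SETS)
        assert ann.cell_type[0] == "TAM"  # "TAM" < "malignant" lexicographically

    def test_overlapping_sets_rejected(self):
        with pytest.raises(Exception):
            tp.annotate_clusters_by_markers(
                _markers([("A", 0, 0.5, 0.5)]), {"TAM": {"A"}, "malignant": {"A"}}
            )


class TestTamPredominant:
    def test_argmax_in_tam_cluster(self):
        markers = _markers([("L", 1, 0.6, 0.1), ("L", 0, 0.6, 0.5)])
        flag, best = tp.tam_predominant("L", markers, ANN)
        assert flag and best == 1

    def test_malignant_best_cluster(self):
        markers = _markers([("L", 0, 0.9, 0.1)])
        assert tp.tam_predominant("L", markers, ANN) == (False, 0)

    def test_absent_ligand(self):
        assert tp.tam_predominant("NOPE", _markers([("L", 0, 0.5, 0.5)]), ANN) == (False, None)

    def test_invariant_to_row_order(self):
        rows = [("L", 1, 0.6, 0.1), ("L", 0, 0.6, 0.5), ("L", 2, 0.3, 0.3)]
        a = tp.tam_predominant("L", _markers(rows), ANN)
        b = tp.tam_predominant("L", _markers(rows[::-1]), ANN)
        assert a == b

    def test_tie_breaks_by_pct1_then_lower_cluster(self):
        rows = [("L", 2, 0.4, 0.2), ("L", 1, 0.4, 0.2)]
        _, best = tp.tam_predominant("L", _markers(rows), ANN)
        assert best == 1


class TestOntogeny:
    def test_bmd_preference(self):
        markers = _markers([("L", 1, 0.6, 0.1), ("L", 2, 0.1, 0.1)])  # BMD 6 vs mic 1
        assert tp.ontogeny_call("L", markers, ANN) == "BMD"

    def test_tie_is_mixed(self):
        markers = _markers([("L", 1, 0.4, 0.2), ("L", 2, 0.4, 0.2)])
        assert tp.ontogeny_call("L", markers, ANN) == "mixed"

    def test_missing_ontogeny_annotation(self):
        ann = ClusterAnnotation({1: "TAM"})
        with pytest.raises(DataValidationError):
            tp.ontogeny_call("L", _markers([("L", 1, 0.5, 0.1)]), ann)


class TestDegs:
    def test_filter_boundaries(self):
        df = pd.DataFrame(
            {
                "gene": ["A", "B", "C", "D"],
                "log2_fc": [1.0, 0.99, -1.2, 2.0],
                "p_adj": [0.049, 0.001, 0.01, 0.05],
            }
        )
        kept = tp.filter_degs(df)["gene"].tolist()
        # lfc boundary inclusive, padj strict
        assert kept == ["A", "C"]

    def test_empty(self):
        df = pd.DataFrame({"gene": [], "log2_fc": [], "p_adj": []})
        assert len(tp.filter_degs(df)) == 0

    def test_rank_ordering(self):
        df = pd.DataFrame(
            {
                "gene": ["A", "B", "C"],
                "log2_fc": [3.0, 2.0, 0.5],
                "p_adj": [1e-5, 1e-5, 1e-9],
            }
        )
        assert tp.rank_bmd_degs(df, k=2) == ["A", "B"]

    def test_rank_excludes_downregulated(self):
        df = pd.DataFrame(
            {"gene": ["A", "B"], "log2_fc": [-3.0, -2.0], "p_adj": [1e-9, 1e-9]}
        )
        assert tp.rank_bmd_degs(df) == []

    def test_fewer_than_k_returns_all(self):
        df = pd.DataFrame({"gene": ["A"], "log2_fc": [2.0], "p_adj": [1e-9]})
        assert tp.rank_bmd_degs(df, k=3) == ["A"]

    def test_tie_break_by_padj_then_gene(self):
        df = pd.DataFrame(
            {
                "gene": ["B", "A", "C"],
                "log2_fc": [2.0, 2.0, 2.0],
                "p_adj": [1e-5, 1e-5, 1e-7],
            }
        )
        assert tp.rank_bmd_degs(df, k=3) == ["C", "A", "B"]
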