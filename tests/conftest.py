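import numpy as np
import pandas as pd
import pytest

from tamtalk.io import ProteinIntensityTable
from tamtalk.synthetic import ScenarioParams


def make_intensity(rows: dict[str, list[float]], R: int = 3) -> ProteinIntensityTable:
    """Build a tiny intensity table from {protein: [M1_1..M1_R, M2_1..M2_R]};
    None encodes not-detected."""
    cols = pd.MultiIndex.from_tuples(
        [("M1", r + 1) for r in range(R)] + [("M2", r + 1) for r in range(R)],
        names=["condition", "replicate"],
    )
    data = pd.DataFrame(
        [[np.nan if v is None else float(v) for v in vals] for vals in rows.values()],
        index=pd.Index(list(rows), name="protein_id"),
        columns=cols,
    )
    return ProteinIntensityTable(data)


def small_params(seed: int, **kw) -> ScenarioParams:
    """Desk-scale scenario defaults for fast tests."""
    base = dict(
        n_proteins=120,
        n_m1_exclusive=20,
        n_m2_exclusive=10,
        n_m2_specific=20,
        n_m1_specific=20,
        n_pan=50,
        dropout=0.0,
        n_receptors=60,
        frac_gated=0.6,
        n_db_pairs=200,
        frac_cognate=0.2,
        n_cells=160,
        n_clusters=4,
        tam_cluster_ids=(1, 2),
        bmd_cluster_ids=(1,),
        t_cell_cluster_ids=(3,),
        n_planted_tam_genes=4,
        n_background_genes=5,
    )
    base.update(kw)
    return ScenarioParams(seed=seed, **base)


@pytest.fixture
def intensity_table() -> ProteinIntensityTable:
    return make_intensity(
        {
            "A": [2.0, 4.0, None, 3.0, 3.0, 3.0],   # both
            "B": [5.0, None, None, None, None, None],  # 1/3 M1 only -> dropped
            "C": [1.0, 2.0, None, 8.0, None, None],  # M1 kept, M2 voided
            "D": [None, None, None, 6.0, 6.0, 6.0],  # M2 only
        }
    )
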