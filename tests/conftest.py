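import numpy as np
import pandas as pd
import pytest

from seropanel import (
    ArrayLayout,
    CohortSpec,
    EngineParams,
    IntensityMatrix,
    SpotRecord,
    SpotTable,
    generate_cohort,
    preprocess_cohort,
)

# ---------------------------------------------------------------------------
# tiny hand-built layout / tables for gpr_io tests
# ---------------------------------------------------------------------------


@pytest.fixture
def tiny_layout() -> ArrayLayout:
    spot_map = {
        "NM_002870.1": [(1, 1, 1), (1, 1, 2)],
        "NM_003764.2": [(1, 2, 1), (1, 2, 2)],
    }
    return ArrayLayout(
        feature_ids=list(spot_map),
        spot_map=spot_map,
        names={k: k.split(".")[0] for k in spot_map},
        lot_id="LOT-A",
    )


def make_table(layout: ArrayLayout, sample_id: str, group: str, base: float) -> SpotTable:
    records = []
    for i, fid in enumerate(layout.feature_ids):
        for rep, (b, r, c) in enumerate(layout.spot_map[fid]):
            records.append(
                SpotRecord(
                    block=b, column=c, row=r, name=layout.names[fid], id=fid,
                    fg_median=base + 100.0 * i + 10.0 * rep, bg_median=50.0, flag=0,
                )
            )
    return SpotTable(sample_id=sample_id, records=records, group=group)


@pytest.fixture
def tiny_tables(tiny_layout):
    return [
        make_table(tiny_layout, "ALS_1", "ALS", 1000.0),
        make_table(tiny_layout, "ALS_2", "ALS", 1100.0),
        make_table(tiny_layout, "NDC_1", "NDC", 900.0),
        make_table(tiny_layout, "NDC_2", "NDC", 950.0),
    ]


# ---------------------------------------------------------------------------
# small synthetic cohort for engine-level tests
# ---------------------------------------------------------------------------

SMALL_SPEC = CohortSpec(
    n_cases=10, n_controls=10, n_features=300, n_planted=8,
    delta=1.2, sigma_subject=0.25, sigma_tech=0.15, seed=7,
)

FAST_PARAMS = EngineParams(
    k_preselect=60, n_trees_init=60, n_trees_iter=30, n_test_per_group=3
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_matrix(small_cohort) -> IntensityMatrix:
    _, matrix = preprocess_cohort(small_cohort[0])
    return matrix


@pytest.fixture(scope="session")
def small_truth(small_cohort):
    return small_cohort[1]


def make_matrix(values: np.ndarray, groups: list[str], feature_ids=None) -> IntensityMatrix:
    """Helper: wrap a plain array into an IntensityMatrix."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    fids = feature_ids or [f"F{i:03d}" for i in range(m)]
    sids = [f"S{j:02d}" for j in range(n)]
    return IntensityMatrix(
        values=pd.DataFrame(values, index=fids, columns=sids),
        groups=pd.Series(groups, index=sids),
        log_scale=True,
    )
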