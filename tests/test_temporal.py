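"""Week mapping, scan aggregation and time-point table assembly."""

import numpy as np
import pandas as pd
import pytest

from rwradiomics.catalogue import FEATURE_CODES
from rwradiomics.io import CohortRecord, ValidationError
from rwradiomics.temporal import (
    aggregate_scan,
    assemble_design,
    build_week_table,
    fraction_to_week,
    tidy_table,
    time_points_for_regimen,
    weeks_for_regimen,
)


class TestWeekMap:
    @pytest.mark.parametrize(
        "fraction,regimen,week",
        [
            (1, "74Gy_37F", 1), (5, "74Gy_37F", 1), (6, "74Gy_37F", 2),
            (30, "74Gy_37F", 6), (31, "74Gy_37F", 7), (37, "74Gy_37F", 7),
            (1, "60Gy_20F", 1), (16, "60Gy_20F", 4), (20, "60Gy_20F", 4),
        ],
    )
    def test_printed_week_boundaries(self, fraction, regimen, week):
        assert fraction_to_week(fraction, regimen) == week

    @pytest.mark.parametrize(
        "regimen,n_fractions,n_weeks",
        [("74Gy_37F", 37, 7), ("60Gy_20F", 20, 4)],
    )
    def test_weeks_partition_fractions(self, regimen, n_fractions, n_weeks):
        assert weeks_for_regimen(regimen) == list(range(1, n_weeks + 1))
        seen = [fraction_to_week(f, regimen) for f in range(1, n_fractions + 1)]
        assert set(seen) == set(range(1, n_weeks + 1))
        # each fraction maps to exactly one week, weeks are contiguous blocks
        assert seen == sorted(seen)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValidationError):
            fraction_to_week(0, "74Gy_37F")
        with pytest.raises(ValidationError):
            fraction_to_week(21, "60Gy_20F")
        with pytest.raises(ValidationError):
            fraction_to_week(1, "80Gy_40F")

    def test_time_points_include_planning_ct(self):
        assert time_points_for_regimen("74Gy_37F") == [
            "CT", "W1", "W2", "W3", "W4", "W5", "W6", "W7"
        ]
        assert time_points_for_regimen("60Gy_20F") == ["CT", "W1", "W2", "W3", "W4"]


class TestAggregateScan:
    def test_mean_identities(self):
        v = np.arange(118.0)
        np.testing.assert_array_equal(aggregate_scan([v]), v)
        np.testing.assert_allclose(aggregate_scan([v, 3 * v]), 2 * v)

    def test_matches_naive_sum_oracle(self, rng):
        vecs = [rng.normal(size=118) for _ in range(100)]
        got = aggregate_scan(vecs)
        naive = sum(vecs) / len(vecs)
        np.testing.assert_allclose(got, naive, rtol=1e-12)

    def test_permutation_invariance(self, rng):
        vecs = [rng.normal(size=118) for _ in range(10)]
        a = aggregate_scan(vecs)
        b = aggregate_scan(list(reversed(vecs)))
        np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-14)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_scan([])


def _scan_features_frame(rng, pid, regimen, fractions):
    rows = []
    base = {"patient_id": pid, "modality": "planning_ct",
            "fraction_index": np.nan}
    base.update(dict(zip(FEATURE_CODES, rng.normal(size=118))))
    rows.append(base)
    for f in fractions:
        row = {"patient_id": pid, "modality": "mvct", "fraction_index": f}
        row.update(dict(zip(FEATURE_CODES, rng.normal(size=118))))
        rows.append(row)
    return pd.DataFrame(rows)


class TestWeekTable:
    def test_full_74gy_series_populates_all_columns(self, rng):
        rec = CohortRecord("P1", "74Gy_37F", 1)
        sf = _scan_features_frame(rng, "P1", "74Gy_37F", range(1, 38))
        table = build_week_table([rec], sf)
        tps = {c.split(":")[0] for c in table.columns}
        assert tps == {"CT", "W1", "W2", "W3", "W4", "W5", "W6", "W7"}
        assert table.shape == (1, 8 * 118)
        assert not table.isna().any().any()

    def test_week_mean_of_available_fractions(self, rng):
        rec = CohortRecord("P1", "60Gy_20F", 0)
        sf = _scan_features_frame(rng, "P1", "60Gy_20F", range(1, 21))
        table = build_week_table([rec], sf)
        w1 = sf[sf["fraction_index"].isin([1, 2, 3, 4, 5])][FEATURE_CODES]
        np.testing.assert_allclose(
            table.loc["P1", [f"W1:{f}" for f in FEATURE_CODES]].to_numpy(),
            w1.mean(axis=0).to_numpy(),
        )

    def test_missing_fraction_uses_remaining_four(self, rng, caplog):
        rec = CohortRecord("P1", "60Gy_20F", 0)
        sf = _scan_features_frame(rng, "P1", "60Gy_20F", [1, 2, 4, 5])
        with caplog.at_level("INFO"):
            table = build_week_table([rec], sf)
        w1 = sf[sf["modality"] == "mvct"][FEATURE_CODES]
        np.testing.assert_allclose(
            table.loc["P1", [f"W1:{f}" for f in FEATURE_CODES]].to_numpy(),
            w1.mean(axis=0).to_numpy(),
        )
        # weeks 2-4 entirely absent for the whole cohort -> no columns
        assert not any(c.startswith("W2:") for c in table.columns)

    def test_tidy_round_trip_shape(self, rng):
        rec = CohortRecord("P1", "60Gy_20F", 0)
        sf = _scan_features_frame(rng, "P1", "60Gy_20F", range(1, 21))
        table = build_week_table([rec], sf)
        long = tidy_table(table)
        assert set(long.columns) == {
            "patient_id", "time_point", "feature_name", "value"
        }
        assert len(long) == table.size


class TestAssembleDesign:
    @pytest.fixture
    def table(self, rng):
        recs = [CohortRecord(f"P{k}", "60Gy_20F", k % 2) for k in range(4)]
        sf = pd.concat(
            [_scan_features_frame(rng, f"P{k}", "60Gy_20F", range(1, 21))
             for k in range(4)]
        )
        return build_week_table(recs, sf)

    def test_separate_mode_returns_full_block(self, table):
        d = assemble_design(table, "W1", mode="separate")
        assert d.shape == (4, 118)
        assert all(c.startswith("W1:") for c in d.columns)

    def test_cumulative_base_case_is_ct_selection(self, table):
        sel = {"CT": ["CT:FOS1", "CT:GLCM3"]}
        d = assemble_design(table, "CT", mode="cumulative", selections=sel)
        assert list(d.columns) == ["CT:FOS1", "CT:GLCM3"]

    def test_cumulative_columns_monotone_in_week(self, table):
        sel = {
            "CT": ["CT:FOS1"], "W1": ["W1:GLSZM3"], "W2": ["W2:FOS2"],
            "W3": [], "W4": ["W4:NGTDM1"],
        }
        prev: set = set()
        for tp in ["CT", "W1", "W2", "W3", "W4"]:
            cols = set(
                assemble_design(table, tp, mode="cumulative",
                                selections=sel).columns
            )
            assert prev <= cols
            prev = cols

    def test_cumulative_without_selections_is_sequencing_error(self, table):
        with pytest.raises(ValidationError):
            assemble_design(table, "W2", mode="cumulative")
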