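"""Quantile normalization, group-minimum imputation and the preprocess
chain: hand-computed references, invariants and property tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import epiconnect as ec
from epiconnect.matrix import InputError, IntensityMatrix, SampleDesign
from epiconnect.preprocess import (
    PipelineError,
    impute_missing_group_min,
    preprocess,
    quantile_normalize_within_groups,
)


def _matrix(data: dict, scale="raw") -> IntensityMatrix:
    return IntensityMatrix(pd.DataFrame(data), scale=scale)


def _design(samples_by_condition: dict) -> SampleDesign:
    records = [
        (s, cond, i + 1)
        for cond, samples in samples_by_condition.items()
        for i, s in enumerate(samples)
    ]
    return SampleDesign.from_records(records)


TWO_GROUP = _design({"A": ["a1", "a2"], "B": ["b1", "b2"]})


class TestQuantileNormalize:
    def test_hand_computed_two_column_group(self):
        """Columns (1,2,3) and (4,5,6) both become the rank means
        (2.5, 3.5, 4.5)."""
        m = _matrix({"a1": [1.0, 2.0, 3.0], "a2": [4.0, 5.0, 6.0]})
        d = _design({"A": ["a1", "a2"]})
        out = quantile_normalize_within_groups(m, d)
        expected = [2.5, 3.5, 4.5]
        assert out.values["a1"].tolist() == pytest.approx(expected)
        assert out.values["a2"].tolist() == pytest.approx(expected)

    def test_identical_columns_unchanged(self):
        m = _matrix({"a1": [1.0, 5.0, 9.0], "a2": [1.0, 5.0, 9.0]})
        d = _design({"A": ["a1", "a2"]})
        out = quantile_normalize_within_groups(m, d)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_idempotent(self):
        m = _matrix(
            {"a1": [3.0, 1.0, 7.0, 2.0], "a2": [8.0, 2.0, 5.0, 1.0],
             "b1": [1.0, 2.0, 3.0, 4.0], "b2": [4.0, 3.0, 2.0, 1.0]}
        )
        once = quantile_normalize_within_groups(m, TWO_GROUP)
        twice = quantile_normalize_within_groups(once, TWO_GROUP)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_conditions_not_pooled(self):
        """Scaling one condition's columns must not leak into the other."""
        m = _matrix(
            {"a1": [1.0, 2.0, 3.0], "a2": [2.0, 3.0, 4.0],
             "b1": [100.0, 200.0, 300.0], "b2": [200.0, 300.0, 400.0]}
        )
        out = quantile_normalize_within_groups(m, TWO_GROUP)
        assert out.values[["a1", "a2"]].to_numpy().max() < 10
        assert out.values[["b1", "b2"]].to_numpy().min() > 10

    def test_missing_cells_stay_missing(self):
        m = _matrix({"a1": [1.0, np.nan, 3.0], "a2": [4.0, 5.0, 6.0]})
        d = _design({"A": ["a1", "a2"]})
        out = quantile_normalize_within_groups(m, d)
        assert np.isnan(out.values.loc[1, "a1"])
        assert out.values.notna().sum().sum() == 5

    def test_singleton_group_returned_unchanged(self, caplog):
        m = _matrix({"a1": [1.0, 2.0], "b1": [5.0, 6.0], "b2": [7.0, 8.0]})
        d = _design({"A": ["a1"], "B": ["b1", "b2"]})
        with caplog.at_level("WARNING"):
            out = quantile_normalize_within_groups(m, d)
        assert out.values["a1"].tolist() == [1.0, 2.0]
        assert "single replicate" in caplog.text

    def test_unknown_sample_rejected(self):
        m = _matrix({"a1": [1.0], "zz": [2.0]})
        d = _design({"A": ["a1"]})
        with pytest.raises(InputError, match="zz"):
            quantile_normalize_within_groups(m, d)

    def test_complete_group_columns_quantile_identical(self, small_config):
        """After normalization the multiset of values is identical across a
        complete group's columns."""
        cfg = ec.SimConfig(
            n_proteins=200, mnar_strength=0.0, mcar_rate=0.0,
            n_terms=5, term_size_range=(3, 10), seed=9,
        )
        m, truth = ec.simulate_intensities(cfg)
        out = quantile_normalize_within_groups(m, truth.design)
        for _cond, samples in truth.design.groups().items():
            cols = [np.sort(out.values[s].to_numpy()) for s in samples]
            for c in cols[1:]:
                np.testing.assert_allclose(c, cols[0], rtol=1e-12)

    @given(
        st.lists(
            st.floats(min_value=0.1, max_value=1e6, allow_nan=False),
            min_size=3,
            max_size=12,
        ),
        st.lists(
            st.floats(min_value=0.1, max_value=1e6, allow_nan=False),
            min_size=3,
            max_size=12,
        ),
    )
    def test_per_column_monotone(self, col1, col2):
        """Normalization never reverses the order of observed values within
        a column (ties may collapse)."""
        n = min(len(col1), len(col2))
        m = _matrix({"a1": col1[:n], "a2": col2[:n]})
        d = _design({"A": ["a1", "a2"]})
        out = quantile_normalize_within_groups(m, d)
        for col in ("a1", "a2"):
            raw = m.values[col].to_numpy()
            norm = out.values[col].to_numpy()
            order = np.argsort(raw, kind="stable")
            assert (np.diff(norm[order]) >= -1e-9).all()


class TestImputation:
    def test_missing_filled_with_protein_group_minimum(self):
        m = _matrix({"a1": [np.nan], "a2": [5.0], "a3": [7.0]})
        d = _design({"A": ["a1", "a2", "a3"]})
        out = impute_missing_group_min(m, m, d)
        assert out.values.loc[0, "a1"] == 5.0

    def test_no_missing_is_identity(self):
        m = _matrix({"a1": [1.0, 2.0], "a2": [3.0, 4.0]})
        d = _design({"A": ["a1", "a2"]})
        out = impute_missing_group_min(m, m, d)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_all_missing_group_falls_back_to_global_minimum(self, caplog):
        m = _matrix(
            {"a1": [np.nan, 2.0], "a2": [np.nan, 9.0], "a3": [np.nan, 4.0]}
        )
        d = _design({"A": ["a1", "a2", "a3"]})
        with caplog.at_level("WARNING"):
            out = impute_missing_group_min(m, m, d)
        assert out.values.loc[0].tolist() == [2.0, 2.0, 2.0]
        assert "fell back" in caplog.text

    def test_imputation_reads_raw_not_normalized(self):
        """The fill value comes from the raw matrix even when the working
        matrix has been normalized to different values."""
        raw = _matrix({"a1": [np.nan, 10.0], "a2": [4.0, 20.0]})
        norm = IntensityMatrix(
            pd.DataFrame({"a1": [np.nan, 11.0], "a2": [5.0, 19.0]}),
            scale="normalized",
        )
        d = _design({"A": ["a1", "a2"]})
        out = impute_missing_group_min(norm, raw, d)
        assert out.values.loc[0, "a1"] == 4.0

    def test_shape_mismatch_rejected(self):
        m = _matrix({"a1": [1.0, 2.0]})
        raw = _matrix({"a1": [1.0]})
        d = _design({"A": ["a1"]})
        with pytest.raises(InputError, match="mismatch"):
            impute_missing_group_min(m, raw, d)

    def test_imputed_never_exceeds_observed_raw_minimum(self):
        cfg = ec.SimConfig(
            n_proteins=150, n_terms=5, term_size_range=(3, 10), seed=21,
        )
        m, truth = ec.simulate_intensities(cfg)
        out = impute_missing_group_min(m, m, truth.design)
        for _cond, samples in truth.design.groups().items():
            raw_block = m.values[samples]
            filled_block = out.values[samples]
            row_min = raw_block.min(axis=1)
            has_observed = raw_block.notna().any(axis=1)
            imputed = filled_block.where(raw_block.isna())
            ok = imputed.le(row_min, axis=0) | imputed.isna()
            # rows with no observed value use the group-global fallback and
            # have no per-protein raw minimum to compare against
            assert ok[has_observed].all().all()


class TestPreprocessChain:
    def test_constant_matrix_gives_exact_log10(self):
        m = _matrix({c: [100.0, 100.0] for c in ["a1", "a2", "b1", "b2"]})
        out = preprocess(m, TWO_GROUP)
        assert out.scale == "log10"
        assert (out.values.to_numpy() == 2.0).all()

    def test_output_finite_and_complete_over_seeded_simulations(self):
        for seed in range(20):
            cfg = ec.SimConfig(
                n_proteins=60, n_replicates=3, n_chaperome=2, n_terms=5,
                term_size_range=(3, 10), hub_degree=10, seed=seed,
            )
            m, truth = ec.simulate_intensities(cfg)
            out = preprocess(m, truth.design)
            vals = out.values.to_numpy()
            assert np.isfinite(vals).all()

    def test_rank_order_preserved_for_observed_cells(self):
        cfg = ec.SimConfig(
            n_proteins=100, n_terms=5, term_size_range=(3, 10), hub_degree=10,
            seed=13,
        )
        m, truth = ec.simulate_intensities(cfg)
        out = preprocess(m, truth.design)
        for col in m.sample_ids:
            raw = m.values[col]
            obs = raw.notna()
            raw_ranks = raw[obs].rank(method="average")
            out_ranks = out.values.loc[obs, col].rank(method="average")
            # monotone chain: observed raw order survives to log10 output
            assert (
                raw_ranks.sort_values().index == out_ranks.sort_values().index
            ).all()

    def test_zero_reaching_log10_is_an_error(self):
        # zeros at matched ranks survive normalization, so the log10 guard
        # must fire: zeros are supposed to be declared missing at read time
        m = _matrix({"a1": [0.0, 1.0], "a2": [0.0, 3.0]})
        d = _design({"A": ["a1", "a2"]})
        with pytest.raises(PipelineError, match="log10"):
            preprocess(m, d)
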