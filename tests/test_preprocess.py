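import numpy as np
import pandas as pd
import pytest

from sensomet.preprocess import (
    PreprocessError,
    apply_filters,
    filter_early_rt,
    filter_low_intensity,
    filter_missing,
    normalize,
    preprocess,
)

from conftest import make_metadata, make_table


class TestLowIntensityFilter:
    def test_strictly_below_threshold_removed(self):
        # means 100, 0.05, 50; threshold = 0.001 * 100 = 0.1
        table = make_table([[100, 100], [0.05, 0.05], [50, 50]])
        out = filter_low_intensity(table, frac=0.001)
        assert list(out.feature_ids) == ["f1", "f3"]

    def test_boundary_is_strict(self):
        # mean exactly frac * max stays ("less than" is strict)
        table = make_table([[100, 100], [0.1, 0.1]])
        out = filter_low_intensity(table, frac=0.001)
        assert list(out.feature_ids) == ["f1", "f2"]

    def test_single_feature_always_kept(self):
        table = make_table([[3.0, 4.0]])
        assert filter_low_intensity(table).n_features == 1

    def test_means_ignore_missing(self):
        # observed mean of f2 is 50 (missing cell skipped), above threshold
        table = make_table([[100, 100], [np.nan, 50]])
        assert filter_low_intensity(table, frac=0.4).n_features == 2


class TestMissingFilter:
    @pytest.mark.parametrize(
        "n_missing,kept", [(4, False), (3, True), (0, True)]
    )
    def test_30_percent_boundary_strict(self, n_missing, kept):
        row = [1.0] * 10
        for j in range(n_missing):
            row[j] = np.nan
        table = make_table([row, [2.0] * 10])
        out = filter_missing(table, max_missing=0.30)
        assert ("f1" in out.feature_ids) is kept


class TestEarlyRTFilter:
    @pytest.mark.parametrize(
        "rt,kept", [(0.44, False), (0.45, True), (10.0, True), (0.0, False)]
    )
    def test_boundary(self, rt, kept):
        table = make_table([[1, 1], [1, 1]], rt=[rt, 5.0])
        out = filter_early_rt(table, min_rt=0.45)
        assert ("f1" in out.feature_ids) is kept

    def test_no_early_features_is_identity(self):
        table = make_table([[1, 1], [2, 2]], rt=[1.0, 2.0])
        out = filter_early_rt(table)
        assert list(out.feature_ids) == ["f1", "f2"]


@pytest.mark.parametrize(
    "filt,kwargs",
    [
        (filter_low_intensity, {"frac": 0.001}),
        (filter_missing, {"max_missing": 0.30}),
        (filter_early_rt, {"min_rt": 0.45}),
    ],
)
def test_filters_idempotent(filt, kwargs):
    rng = np.random.default_rng(1)
    vals = rng.lognormal(2, 2, size=(30, 8))
    vals[rng.random(vals.shape) < 0.4] = np.nan
    table = make_table(vals, rt=rng.uniform(0, 2, 30))
    once = filt(table, **kwargs)
    twice = filt(once, **kwargs)
    assert list(once.feature_ids) == list(twice.feature_ids)


def test_report_counts_additive():
    rng = np.random.default_rng(2)
    vals = rng.lognormal(3, 1, size=(40, 10))
    vals[0, :] = 1e-9  # low intensity
    vals[1, :4] = np.nan  # 40% missing
    rt = rng.uniform(1, 10, 40)
    rt[2] = 0.1
    table = make_table(vals, rt=rt)
    out, rep = apply_filters(table)
    assert rep.n_input_features == 40
    assert rep.n_input_features == rep.n_output_features + (
        rep.n_removed_low_intensity + rep.n_removed_missing + rep.n_removed_early_rt
    )
    assert rep.removed_low_intensity == ["f1"]
    assert rep.removed_missing == ["f2"]
    assert rep.removed_early_rt == ["f3"]


def test_all_features_removed_is_error():
    table = make_table([[1, 1]], rt=[0.1])
    with pytest.raises(PreprocessError):
        filter_early_rt(table)


class TestNormalize:
    def test_sample_median_step(self):
        from sensomet.preprocess import normalize_samples

        table = make_table([[2.0], [4.0], [8.0]])
        meta = make_metadata(["s1"])
        out = normalize_samples(table, meta)
        np.testing.assert_allclose(
            out.intensities["s1"].to_numpy(), [0.5, 1.0, 2.0]
        )

    def test_batch_step_single_batch(self):
        # one feature across 3 samples of one batch: divide by median 2
        table = make_table([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        meta = make_metadata(["s1", "s2", "s3"])
        out, _ = normalize(table, meta)
        # after sample-median step each column has median 1; batch medians then 1
        batch_median = out.intensities.median(axis=1)
        np.testing.assert_allclose(batch_median, 1.0)

    def test_two_identical_batches_equal_global_median(self):
        vals = np.array([[1.0, 3.0, 1.0, 3.0], [5.0, 2.0, 5.0, 2.0]])
        t1 = make_table(vals)
        m_batched = make_metadata(["s1", "s2", "s3", "s4"], batches=["B1", "B1", "B2", "B2"])
        m_global = make_metadata(["s1", "s2", "s3", "s4"])
        out_b, _ = normalize(t1, m_batched)
        out_g, _ = normalize(make_table(vals), m_global)
        pd.testing.assert_frame_equal(out_b.intensities, out_g.intensities)

    def test_volume_division(self):
        table = make_table([[2.0, 2.0], [4.0, 4.0]])
        meta = make_metadata(["s1", "s2"], volumes=[1.0, 2.0])
        out, rep = normalize(table, meta)
        # volume scaling cancels in the median steps; medians still 1
        assert "injection_volume" in rep.normalization_steps
        np.testing.assert_allclose(out.intensities.median(axis=0), 1.0)

    def test_all_missing_sample_errors(self):
        table = make_table([[np.nan, 1.0], [np.nan, 2.0]])
        meta = make_metadata(["s1", "s2"])
        with pytest.raises(PreprocessError, match="s1"):
            normalize(table, meta)

    def test_missing_stays_missing(self):
        table = make_table([[1.0, np.nan], [2.0, 3.0], [4.0, 5.0]])
        meta = make_metadata(["s1", "s2"])
        out, _ = normalize(table, meta)
        assert np.isnan(out.intensities.loc["f1", "s2"])
        assert out.intensities.notna().sum().sum() == 5


def test_full_chain_median_identities(default_dataset):
    """After the sample-median step every sample median is 1; after the
    batch step every within-batch feature median is 1."""
    from sensomet.preprocess import normalize_batches, normalize_samples

    table, meta, *_ = default_dataset
    filtered, rep = apply_filters(table)
    mid = normalize_samples(filtered, meta)
    np.testing.assert_allclose(
        mid.intensities.median(axis=0, skipna=True).to_numpy(), 1.0, atol=1e-9
    )
    out = normalize_batches(mid, meta)
    am = meta.aligned_to(out)
    X = out.intensities
    for batch, sids in X.columns.groupby(am["batch"]).items():
        med = X[list(sids)].median(axis=1, skipna=True)
        np.testing.assert_allclose(med.to_numpy(), 1.0, atol=1e-9)
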