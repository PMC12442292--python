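"""TF-IDF flavors, diagnostics, quantile normalization, mock-null test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from picmix.datatypes import CountMatrix
from picmix.normalize import (
    cptt,
    depth_diagnostics,
    full_quantile_normalize,
    gc_bias_curve,
    idf,
    lsi,
    mock_null_test,
    smooth_gcfq,
    term_frequency,
    tfidf_transform,
)


def cm(values, **kw):
    values = np.asarray(values)
    return CountMatrix(
        values,
        [f"r{i}" for i in range(values.shape[0])],
        [f"c{i}" for i in range(values.shape[1])],
        **kw,
    )


count_matrices = arrays(
    np.int64,
    st.tuples(st.integers(2, 6), st.integers(2, 6)),
    elements=st.integers(0, 8),
)


class TestTermFrequency:
    def test_cell_proportions(self):
        m = cm(np.array([[1], [1], [0], [2]]))
        tf = term_frequency(m)
        assert tf.values[:, 0].tolist() == [0.25, 0.25, 0.0, 0.5]

    def test_uniform_cell(self):
        m = cm(np.full((5, 2), 3))
        assert np.allclose(term_frequency(m).values, 0.2)

    def test_zero_total_cell_lists_barcodes(self):
        m = cm(np.array([[1, 0], [2, 0]]))
        with pytest.raises(ValueError, match="c1"):
            term_frequency(m)

    @settings(derandomize=True, max_examples=30)
    @given(count_matrices)
    def test_columns_sum_to_one_and_cptt_scaling(self, values):
        values = values + 1  # avoid zero-total cells
        m = cm(values)
        tf = term_frequency(m)
        assert np.allclose(tf.values.sum(axis=0), 1.0)
        assert np.allclose(cptt(m).values, 1e4 * tf.values)


class TestIdf:
    def test_values_and_flagging(self):
        m = cm(np.array([[1, 1, 0, 2], [1, 1, 0, 0], [0, 0, 0, 0]]))
        w = idf(m)
        assert w["r0"] == pytest.approx(1.0)  # N=4, total=4
        assert w["r1"] == pytest.approx(2.0)  # N=4, total=2
        assert np.isnan(w["r2"])  # zero-total region flagged

    @settings(derandomize=True, max_examples=30)
    @given(count_matrices)
    def test_idf_times_mean_is_one(self, values):
        m = cm(values)
        w = idf(m).to_numpy()
        mu = values.mean(axis=1)
        kept = ~np.isnan(w)
        assert np.allclose(w[kept] * mu[kept], 1.0)

    def test_variance_scaling_identity(self, rng):
        """Scaling a region by IDF divides its variance by mu^2 exactly."""
        x = rng.poisson(2.0, size=(10, 40)) + 1
        m = cm(x)
        w = idf(m).to_numpy()
        scaled_var = np.var(w[:, None] * x, axis=1, ddof=1)
        mu = x.mean(axis=1)
        assert np.allclose(scaled_var, np.var(x, axis=1, ddof=1) / mu**2)


class TestTfidfFlavors:
    def test_signac_matches_hand_computation(self):
        x = np.array([[1, 0], [1, 2]])
        m = cm(x)
        tf = x / x.sum(axis=0)
        w = 2 / x.sum(axis=1)
        expected = np.log(tf * 1e4 * w[:, None] + 1.0)
        out = tfidf_transform(m, "signac", binarize=False)
        assert np.allclose(out.values, expected)
        assert not out.binarized

    def test_binarize_makes_counts_saturate(self, rng):
        x = rng.poisson(2.0, size=(6, 5)) + 1
        x2 = x.copy()
        x2[x2 > 1] = 1 + rng.integers(1, 5, size=(x2 > 1).sum())  # different >1 values
        a = tfidf_transform(cm(x), "archr", binarize=True).values
        b = tfidf_transform(cm(x2), "archr", binarize=True).values
        assert np.allclose(a, b)

    def test_cellranger_constant_within_region(self, rng):
        x = rng.poisson(1.0, size=(5, 8)) + 1
        out = tfidf_transform(cm(x), "cellranger").values
        assert np.allclose(out, out[:, :1])  # no TF term: constant per region

    def test_default_binarization_follows_flavor(self):
        x = np.array([[1, 2], [3, 1]])
        assert tfidf_transform(cm(x), "archr").binarized
        assert not tfidf_transform(cm(x), "signac").binarized

    def test_unknown_flavor(self):
        with pytest.raises(ValueError, match="unknown flavor"):
            tfidf_transform(cm(np.ones((2, 2), dtype=int)), "seurat")


class TestDepthDiagnostics:
    def test_nonzero_mean(self):
        cells, regions = depth_diagnostics(cm(np.array([[0], [0], [3], [1]])))
        assert cells.loc[0, "total"] == 4
        assert cells.loc[0, "nonzero_mean"] == 2.0

    def test_all_zero_cell_flagged(self):
        cells, _ = depth_diagnostics(cm(np.array([[0, 1], [0, 2]])))
        assert cells.loc[0, "all_zero"]
        assert cells.loc[0, "nonzero_mean"] == 0.0

    def test_idf_variance_column(self, rng):
        x = rng.poisson(3.0, size=(7, 30)) + 1
        _, regions = depth_diagnostics(cm(x))
        mu = x.mean(axis=1)
        assert np.allclose(regions["var_idf"], regions["var_raw"] / mu**2)


class TestLsi:
    def test_rank_one_matrix(self):
        x = np.outer([1, 2, 3], [1, 1, 2, 2]).astype(int)
        e = lsi(cm(x), n_components=2, binarize=False)
        assert e.variance_fraction[0] > 0.95

    def test_two_block_structure_separated(self):
        x = np.zeros((10, 8), dtype=int)
        x[:5, :4] = 5
        x[5:, 4:] = 5
        e = lsi(cm(x), n_components=3, binarize=False)
        side = e.coordinates[:4, 0].mean(), e.coordinates[4:, 0].mean()
        # one of the top components splits the two cell blocks
        split = False
        for c in range(e.n_components):
            a, b = e.coordinates[:4, c], e.coordinates[4:, c]
            if np.sign(a.mean()) != np.sign(b.mean()) and abs(a.mean() - b.mean()) > 1e-6:
                split = True
        assert split

    def test_drop_first_removes_component(self, rng):
        x = rng.poisson(2.0, size=(20, 12)) + 1
        full = lsi(cm(x), n_components=5)
        dropped = lsi(cm(x), n_components=5, drop_first=True)
        assert dropped.n_components == full.n_components - 1
        assert np.allclose(dropped.coordinates, full.coordinates[:, 1:])


class TestFullQuantile:
    def test_per_rank_medians(self):
        x = np.array([[1, 10], [2, 20], [3, 30]], dtype=float)
        out = full_quantile_normalize(x)
        assert np.allclose(out, [[5.5, 5.5], [11, 11], [16.5, 16.5]])

    def test_identical_columns_unchanged(self):
        x = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 4))
        assert np.allclose(full_quantile_normalize(x), x)

    def test_rank_equivariance(self, rng):
        x = rng.normal(size=(15, 3))
        out = full_quantile_normalize(x)
        perm = rng.permutation(15)
        x2 = x.copy()
        x2[:, 1] = x[perm, 1]
        out2 = full_quantile_normalize(x2)
        assert np.allclose(out2[:, 1], out[perm, 1])

    @settings(derandomize=True, max_examples=25)
    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(2, 10), st.integers(2, 5)),
            elements=st.floats(-50, 50, allow_nan=False),
        )
    )
    def test_columns_share_sorted_values(self, x):
        out = full_quantile_normalize(x, ties="positional")
        ref = np.sort(out[:, 0])
        for c in range(1, x.shape[1]):
            assert np.allclose(np.sort(out[:, c]), ref)

    def test_tie_averaging_mode_shares_one_value(self):
        # all zeros of a column are indistinguishable: averaged reference
        x = np.array([[0, 5], [0, 1], [0, 0], [3, 0]], dtype=float)
        out = full_quantile_normalize(x, ties="average")
        assert len(set(out[:3, 0])) == 1

    def test_tie_modes_agree_without_ties(self, rng):
        x = rng.normal(size=(20, 4))
        assert np.allclose(
            full_quantile_normalize(x, ties="average"),
            full_quantile_normalize(x, ties="positional"),
        )


class TestSmoothGcfq:
    def test_single_bin_reduces_to_fq(self, rng):
        x = rng.poisson(5.0, size=(30, 4)).astype(float)
        gc = rng.uniform(0.3, 0.7, 30)
        assert np.allclose(smooth_gcfq(x, gc, n_bins=1), full_quantile_normalize(x))

    def test_gc_independent_data_close_to_fq(self, rng):
        x = rng.poisson(20.0, size=(400, 6)).astype(float)
        gc = rng.uniform(0.2, 0.8, 400)
        fq = full_quantile_normalize(x)
        sm = smooth_gcfq(x, gc, n_bins=5)
        # same distributional target: medians of the column-value distributions agree
        assert abs(np.median(sm) - np.median(fq)) < 1.0
        assert np.corrcoef(sm.ravel(), fq.ravel())[0, 1] > 0.95


class TestGcBiasCurve:
    def test_flat_when_independent(self, rng):
        x = rng.poisson(2.0, size=(300, 50))
        gc = rng.uniform(0.2, 0.8, 300)
        curves = gc_bias_curve(cm(x), gc)
        fitted = curves["all"]["fitted"]
        assert fitted.max() - fitted.min() < 0.15

    def test_monotone_when_rate_depends_on_gc(self, rng):
        gc = rng.uniform(0.2, 0.8, 300)
        x = rng.poisson(0.3 * np.exp(2 * gc)[:, None], size=(300, 50))
        curves = gc_bias_curve(cm(x), gc)
        fitted = curves["all"]["fitted"].to_numpy()
        assert fitted[-1] > fitted[0] + 0.3

    def test_groups_with_different_slopes_differ(self, rng):
        gc = rng.uniform(0.2, 0.8, 300)
        flat = rng.poisson(1.0, size=(300, 40))
        sloped = rng.poisson(0.3 * np.exp(2 * gc)[:, None], size=(300, 40))
        m = cm(np.hstack([flat, sloped]))
        labels = ["flat"] * 40 + ["sloped"] * 40
        curves = gc_bias_curve(m, gc, groups=labels)
        d_flat = np.ptp(curves["flat"]["fitted"])
        d_slope = np.ptp(curves["sloped"]["fitted"])
        assert d_slope > d_flat + 0.3

    def test_too_few_regions(self):
        with pytest.raises(ValueError, match="10 regions"):
            gc_bias_curve(cm(np.ones((5, 4), dtype=int)), np.full(5, 0.5))


class TestMockNull:
    @staticmethod
    def _fixture(rng, n_regions=300, n_donors=6, cells_per_donor=30):
        gc = rng.uniform(0.2, 0.8, n_regions)
        base = np.exp(rng.normal(np.log(0.3), 0.4, n_regions))
        donors = np.repeat([f"d{i}" for i in range(n_donors)], cells_per_donor)
        p = rng.beta(2, 4, len(donors)) * 0.9 + 0.05
        x = rng.poisson(base[:, None] * p[None, :])
        return cm(x), donors, gc

    def test_seeded_reproducibility(self, rng):
        m, donors, gc = self._fixture(rng)
        kw = dict(donors=donors, cell_types=["ct"] * len(donors), gc=gc, seed=42)
        a = mock_null_test(m, **kw)["ct"]
        b = mock_null_test(m, **kw)["ct"]
        assert a.treatment_donors == b.treatment_donors
        assert np.allclose(a.table["lfc"], b.table["lfc"])

    def test_balanced_identical_groups_give_zero_lfc(self):
        # two donors with byte-identical cells: equal group means, equal
        # pseudocounts, so the log fold change vanishes identically
        block = np.arange(12).reshape(4, 3) % 3
        x = np.hstack([block, block])
        donors = ["d1"] * 3 + ["d2"] * 3
        res = mock_null_test(
            cm(x), donors, ["ct"] * 6, np.full(4, 0.5), seed=0, n_bins=2
        )["ct"]
        assert np.allclose(res.table["lfc"], 0.0)

    def test_single_donor_cell_type_skipped(self, rng):
        m, donors, gc = self._fixture(rng, n_donors=2, cells_per_donor=10)
        cell_types = ["lonely"] * 10 + ["ok"] * 10
        donors = ["dA"] * 10 + list(donors[10:20])
        res = mock_null_test(m, donors, cell_types, gc, seed=0)
        assert "lonely" not in res

    def test_wilcoxon_detects_true_shift(self, rng):
        # two donors -> the mock split is exactly donor vs donor, so a
        # donor-level shift in region 0 must be detected while region 1 is null
        x = np.vstack(
            [
                np.concatenate([rng.poisson(0.2, 30), rng.poisson(3.0, 30)]),
                rng.poisson(1.0, 60),
            ]
        )
        donors = ["d1"] * 30 + ["d2"] * 30
        res = mock_null_test(
            cm(x), donors, ["ct"] * 60, np.array([0.4, 0.6]), seed=3, n_bins=2
        )["ct"]
        shifted_p = res.table.loc[0, "wilcoxon_p"]
        flat_p = res.table.loc[1, "wilcoxon_p"]
        assert shifted_p < 0.01 < flat_p


class TestGroupAwareGcfq:
    def test_group_shrinkage_preserves_group_quantile_differences(self, rng):
        # two sample groups with systematically different scales: the
        # group-aware variant keeps them apart, the plain one merges them
        x = np.vstack([
            np.hstack([rng.poisson(5.0, (200, 6)), rng.poisson(20.0, (200, 6))])
        ]).astype(float)
        gc = rng.uniform(0.2, 0.8, 200)
        groups = ["a"] * 6 + ["b"] * 6
        plain = smooth_gcfq(x, gc, n_bins=4)
        aware = smooth_gcfq(x, gc, n_bins=4, groups=groups)
        gap_plain = plain[:, 6:].mean() - plain[:, :6].mean()
        gap_aware = aware[:, 6:].mean() - aware[:, :6].mean()
        assert abs(gap_plain) < 1.0
        assert gap_aware > 5.0

    def test_groups_length_validated(self, rng):
        x = rng.poisson(2.0, (20, 4)).astype(float)
        with pytest.raises(ValueError, match="groups"):
            smooth_gcfq(x, rng.uniform(0, 1, 20), groups=["a", "b"])
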