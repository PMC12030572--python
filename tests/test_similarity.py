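import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from leafspot import (
    SpectrumSet,
    boxplot_outliers,
    cosine_similarity,
    leaf_mean_spectrum,
    preprocess,
    repeatability_report,
    similarity_table,
)
from leafspot.synthetic import SyntheticConfig, generate_dataset
from conftest import make_meta

finite_vec = st.lists(
    st.floats(-1e3, 1e3, allow_nan=False, allow_infinity=False),
    min_size=2,
    max_size=16,
)


class TestCosineSimilarity:
    def test_identical_vectors_give_one(self):
        v = np.array([2.0, 3.0, 5.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_half_overlap(self):
        assert cosine_similarity([1, 0, 1], [1, 1, 0]) == pytest.approx(0.5)

    @pytest.mark.parametrize("a,b", [([0, 0], [1, 1]), ([1, 1], [0, 0])])
    def test_zero_norm_rejected(self, a, b):
        with pytest.raises(ValueError):
            cosine_similarity(a, b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([1, 2], [1, 2, 3])

    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(v=finite_vec, w=st.data(), c=st.floats(1e-3, 1e3))
    def test_scale_invariance_and_symmetry(self, v, w, c):
        a = np.array(v)
        b = np.array(w.draw(st.lists(st.floats(-1e3, 1e3), min_size=len(v), max_size=len(v))))
        if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
            return
        s = cosine_similarity(a, b)
        assert cosine_similarity(c * a, b) == pytest.approx(s, abs=1e-9)
        assert cosine_similarity(b, a) == pytest.approx(s, abs=1e-12)
        assert -1 - 1e-12 <= s <= 1 + 1e-12


class TestLeafMean:
    def test_single_spectrum_leaf_is_its_own_reference(self, tiny_set):
        single = tiny_set.select(np.array([0]))
        ref = leaf_mean_spectrum(single, "L1")
        np.testing.assert_array_equal(ref, single.intensities[0])
        table = similarity_table(single)
        assert table["similarity"].iloc[0] == pytest.approx(1.0)

    def test_hand_mean(self):
        spectra = SpectrumSet(
            wavenumbers=np.array([1.0, 2.0]),
            intensities=np.array([[1.0, 3.0], [3.0, 1.0]]),
            meta=make_meta(2),
        )
        np.testing.assert_array_equal(leaf_mean_spectrum(spectra, "L1"), [2.0, 2.0])

    def test_unknown_leaf_rejected(self, tiny_set):
        with pytest.raises(KeyError):
            leaf_mean_spectrum(tiny_set, "nope")


class TestSimilarityTable:
    def test_identical_spectra_all_one(self):
        spectra = SpectrumSet(
            wavenumbers=np.arange(5, dtype=float),
            intensities=np.tile([1.0, 2.0, 3.0, 2.0, 1.0], (4, 1)),
            meta=make_meta(4),
        )
        table = similarity_table(spectra)
        assert len(table) == spectra.n_spectra
        np.testing.assert_allclose(table["similarity"], 1.0)

    def test_injected_anomaly_is_leaf_minimum(self):
        """A single strongly perturbed position scores strictly lowest."""
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 5, 32)
        rows = np.tile(base, (10, 1)) * (1 + rng.normal(0, 0.01, (10, 32)))
        rows[3, :16] *= 0.3  # anomalous composition at one position
        spectra = SpectrumSet(
            wavenumbers=np.arange(32, dtype=float), intensities=rows, meta=make_meta(10)
        )
        table = similarity_table(spectra)
        assert table["similarity"].idxmin() == 3
        assert (table["similarity"].drop(3) > table["similarity"][3]).all()


def brute_force_flags(values, q=0.25):
    """Sort-based oracle for quartile and whisker thresholds."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)

    def quantile(p):
        h = (n - 1) * p
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    whisker = q1 - 1.5 * (q3 - q1)
    return q1, whisker


class TestBoxplotOutliers:
    def test_all_equal_no_outliers(self):
        sims = make_meta(6).assign(similarity=0.99)
        flagged, summary = boxplot_outliers(sims)
        assert not flagged["is_outlier"].any()
        assert not flagged["below_q1"].any()
        assert summary["n_outliers"] == 0

    def test_single_low_value_flagged(self):
        sims = make_meta(20).assign(similarity=[0.99] * 19 + [0.5])
        flagged, _ = boxplot_outliers(sims)
        assert flagged["is_outlier"].tolist() == [False] * 19 + [True]

    def test_outlier_implies_below_q1(self):
        rng = np.random.default_rng(7)
        sims = make_meta(200).assign(similarity=rng.beta(20, 1, 200))
        flagged, _ = boxplot_outliers(sims)
        assert (flagged["is_outlier"] <= flagged["below_q1"]).all()

    @pytest.mark.parametrize("n", [4, 17, 100, 1000])
    def test_agrees_with_sort_oracle(self, n):
        rng = np.random.default_rng(n)
        values = rng.uniform(0.8, 1.0, n)
        sims = make_meta(n).assign(similarity=values)
        flagged, summary = boxplot_outliers(sims)
        q1, whisker = brute_force_flags(values)
        np.testing.assert_array_equal(flagged["below_q1"], values < q1)
        np.testing.assert_array_equal(flagged["is_outlier"], values < whisker)
        assert summary["q1"] == pytest.approx(q1)

    def test_per_leaf_population(self, two_leaf_set):
        rng = np.random.default_rng(0)
        sims = two_leaf_set.meta.assign(similarity=rng.uniform(0.9, 1.0, 8))
        flagged, _ = boxplot_outliers(sims, population="per_leaf")
        for _, sub in flagged.groupby("leaf_id"):
            q1, whisker = brute_force_flags(sub["similarity"].to_numpy())
            np.testing.assert_array_equal(sub["below_q1"], sub["similarity"] < q1)

    def test_too_small_population_rejected(self):
        sims = make_meta(3).assign(similarity=[0.9, 0.95, 1.0])
        with pytest.raises(ValueError):
            boxplot_outliers(sims)


class TestRepeatability:
    def test_prefix_minima_and_their_means(self):
        """Streams constructed to dip at known acquisitions reproduce their
        per-position minima and the cross-position means exactly."""
        dips = {
            "P1": [0.99211, 0.99139, 0.99135],
            "P2": [0.99191, 0.99153, 0.99134],
            "P3": [0.99273, 0.99215, 0.99203],
        }
        streams = {}
        for pos, (d10, d20, d30) in dips.items():
            s = np.ones(30)
            s[9], s[19], s[29] = d10, d20, d30  # new minimum in each decade
            streams[pos] = s
        report = repeatability_report(streams)
        for pos, vals in dips.items():
            np.testing.assert_allclose(report.minima.loc[pos], vals)
        np.testing.assert_allclose(
            np.round(report.means, 5), [0.99225, 0.99169, 0.99157]
        )

    def test_identical_replicates_all_one(self):
        stream = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (30, 1))
        report = repeatability_report({"P1": stream})
        np.testing.assert_allclose(report.minima.to_numpy(), 1.0)
        assert report.passes_floor

    def test_minima_non_increasing_in_count(self):
        rng = np.random.default_rng(11)
        base = rng.uniform(1, 5, 64)
        stream = base + rng.normal(0, 0.05, (30, 64))
        report = repeatability_report({"P1": stream})
        m = report.minima.iloc[0]
        assert m[10] >= m[20] >= m[30]

    def test_short_stream_warns_and_restricts(self):
        stream = np.tile(np.array([1.0, 2.0]), (12, 1))
        with pytest.warns(UserWarning):
            report = repeatability_report({"P1": stream})
        assert list(report.minima.columns) == [10]
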