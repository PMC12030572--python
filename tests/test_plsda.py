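import numpy as np
import pandas as pd
import pytest

from leafspot import (
    SpectrumSet,
    before_after_comparison,
    evaluate,
    fit_plsda,
    interleaved_split,
    select_lvs,
    train_and_evaluate,
)
from leafspot.plsda import confusion_matrix, macro_metrics
from conftest import make_meta


def _labelled_set(n_per_class, n_chan=24, sep=5.0, noise=0.5, seed=0,
                  groups=("CK", "ND", "PD", "KD"), duration_h=24):
    """Well-separated classes: each group shifts its own channel by `sep`."""
    rng = np.random.default_rng(seed)
    rows, metas = [], []
    for gi, g in enumerate(groups):
        mu = np.ones(n_chan)
        mu[gi] += sep
        rows.append(mu + rng.normal(0, noise, (n_per_class, n_chan)))
        m = make_meta(n_per_class, leaf_id=f"L{gi}", group=g, duration_h=duration_h,
                      start=gi * n_per_class)
        metas.append(m)
    return SpectrumSet(
        wavenumbers=np.arange(n_chan, dtype=float),
        intensities=np.vstack(rows),
        meta=pd.concat(metas, ignore_index=True),
    )


class TestInterleavedSplit:
    def test_even_count_splits_in_half(self):
        spectra = _labelled_set(10, groups=("CK",))
        train, test = interleaved_split(spectra)
        assert (train.n_spectra, test.n_spectra) == (5, 5)

    def test_odd_count_gives_train_the_extra(self):
        spectra = _labelled_set(11, groups=("CK",))
        train, test = interleaved_split(spectra)
        assert (train.n_spectra, test.n_spectra) == (6, 5)

    def test_stratified_within_group(self):
        spectra = _labelled_set(7)
        train, test = interleaved_split(spectra)
        assert (train.meta.groupby("group").size() == 4).all()
        assert (test.meta.groupby("group").size() == 3).all()

    def test_alternation_follows_row_order(self):
        spectra = _labelled_set(4, groups=("CK",))
        train, test = interleaved_split(spectra)
        assert train.meta["spectrum_id"].tolist() == ["L0_s0", "L0_s2"]
        assert test.meta["spectrum_id"].tolist() == ["L0_s1", "L0_s3"]


class TestFitPredict:
    def test_separable_classes_fit_perfectly(self):
        spectra = _labelled_set(12, sep=8.0, noise=0.3)
        model = fit_plsda(spectra.intensities, spectra.meta["group"], n_lv=3)
        report = evaluate(model, spectra.intensities, spectra.meta["group"])
        assert report.macro_F1 == pytest.approx(100.0)
        assert report.mds == 0

    def test_confusion_total_is_sample_count(self):
        spectra = _labelled_set(9, noise=3.0)
        model = fit_plsda(spectra.intensities, spectra.meta["group"], n_lv=3)
        report = evaluate(model, spectra.intensities, spectra.meta["group"])
        assert report.confusion.sum() == spectra.n_spectra
        assert report.mds == report.confusion.sum() - np.trace(report.confusion)

    def test_prediction_deterministic(self):
        spectra = _labelled_set(8, noise=2.0)
        X, y = spectra.intensities, spectra.meta["group"]
        p1 = fit_plsda(X, y, 3).predict(X)
        p2 = fit_plsda(X, y, 3).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        spectra = _labelled_set(8, groups=("CK",))
        with pytest.raises(ValueError):
            fit_plsda(spectra.intensities, spectra.meta["group"], 1)

    def test_bad_lv_rejected(self):
        spectra = _labelled_set(4)
        with pytest.raises(ValueError):
            fit_plsda(spectra.intensities, spectra.meta["group"], 0)

    def test_univariate_threshold_oracle(self):
        """On a 2-class problem with one informative channel, 1-LV PLS-DA
        matches a univariate threshold classifier on >=95% of test points."""
        agreement = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 60
            X = rng.normal(0, 0.2, (2 * n, 10))
            y = np.array(["CK"] * n + ["ND"] * n)
            X[:n, 0] += 1.0
            X[n:, 0] -= 1.0
            Xt = rng.normal(0, 0.2, (40, 10))
            yt = np.array(["CK"] * 20 + ["ND"] * 20)
            Xt[:20, 0] += 1.0
            Xt[20:, 0] -= 1.0
            model = fit_plsda(X, y, 1)
            pls_labels = model.predict(Xt)
            thr = (X[:n, 0].mean() + X[n:, 0].mean()) / 2
            oracle = np.where(Xt[:, 0] > thr, "CK", "ND")
            agreement.append((pls_labels == oracle).mean())
        assert np.mean(agreement) >= 0.95


class TestMetrics:
    def test_perfect_predictions(self):
        cm = np.diag([5, 5, 5, 5])
        m = macro_metrics(cm)
        assert m == {"macro_P": 100.0, "macro_R": 100.0, "macro_F1": 100.0}

    def test_two_class_hand_arithmetic(self):
        cm = np.array([[5, 5], [0, 10]])
        m = macro_metrics(cm)
        assert m["macro_P"] == pytest.approx((100 + 100 * 10 / 15) / 2)
        assert m["macro_R"] == pytest.approx((50 + 100) / 2)

    def test_invariant_under_label_permutation(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(list("ABCD"), 100)
        y_pred = rng.choice(list("ABCD"), 100)
        m1 = macro_metrics(confusion_matrix(y_true, y_pred, list("ABCD")))
        perm = {"A": "C", "B": "D", "C": "A", "D": "B"}
        yt = np.array([perm[v] for v in y_true])
        yp = np.array([perm[v] for v in y_pred])
        m2 = macro_metrics(confusion_matrix(yt, yp, list("ABCD")))
        for k in m1:
            assert m1[k] == pytest.approx(m2[k])

    def test_never_predicted_class_warns_zero_precision(self):
        cm = np.array([[3, 0], [2, 0]])  # second class never predicted
        with pytest.warns(UserWarning):
            m = macro_metrics(cm)
        assert m["macro_P"] == pytest.approx((3 / 5 * 100 + 0) / 2)

    def test_empty_test_set_rejected(self):
        spectra = _labelled_set(6)
        model = fit_plsda(spectra.intensities, spectra.meta["group"], 2)
        with pytest.raises(ValueError):
            evaluate(model, np.empty((0, 24)), np.array([]))


class TestSelectLVs:
    def test_one_lv_suffices_on_trivial_data(self):
        spectra = _labelled_set(20, groups=("CK", "ND"), sep=10.0, noise=0.2)
        best, report = select_lvs(
            spectra.intensities, spectra.meta["group"], k=4, lv_max=6, seed=0
        )
        assert best == 1
        assert report.loc[best, "macro_F1"] >= report["macro_F1"].max() - 0.5

    def test_best_within_tau_of_grid_max(self):
        spectra = _labelled_set(15, noise=2.5, seed=3)
        best, report = select_lvs(
            spectra.intensities, spectra.meta["group"], k=3, lv_max=8, seed=1
        )
        assert 1 <= best <= 8
        assert report.loc[best, "macro_F1"] >= report["macro_F1"].max() - 0.5

    def test_too_small_class_rejected(self):
        spectra = _labelled_set(3)
        with pytest.raises(ValueError):
            select_lvs(spectra.intensities, spectra.meta["group"], k=5)


class TestBeforeAfter:
    def test_identical_sets_give_zero_deltas(self):
        spectra = _labelled_set(16, noise=1.0)
        table = before_after_comparison(spectra, spectra, k=3, lv_max=4,
                                        durations=(24,), seed=0)
        cleaned = table[table["Condition"] == "cleaned"]
        assert (cleaned["dLVs"] == 0).all()
        assert (cleaned["dMDs"] == 0).all()
        assert (cleaned["dTest_Macro_F1"] == 0).all()

    def test_duration_rows_paired(self):
        sets = []
        for d in (24, 72):
            s = _labelled_set(12, duration_h=d, seed=d)
            sets.append(s)
        spectra = SpectrumSet(
            wavenumbers=sets[0].wavenumbers,
            intensities=np.vstack([s.intensities for s in sets]),
            meta=pd.concat([s.meta for s in sets], ignore_index=True).assign(
                spectrum_id=lambda df: df["spectrum_id"] + "_" + df["duration_h"].astype(str),
                leaf_id=lambda df: df["leaf_id"] + "_" + df["duration_h"].astype(str),
            ),
        )
        table = before_after_comparison(spectra, spectra, k=3, lv_max=3,
                                        durations=(24, 72), seed=0)
        assert len(table) == 4
        assert table["Group"].tolist() == ["24 h", "24 h-cleaned", "72 h", "72 h-cleaned"]

    def test_missing_duration_rejected(self):
        spectra = _labelled_set(8)
        with pytest.raises(ValueError):
            before_after_comparison(spectra, spectra, durations=(72,))
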