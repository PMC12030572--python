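"""PLS-DA nutrient-deficiency classifier and its evaluation.

The classifier is partial least squares regression of the spectra onto a
one-hot class matrix over {CK, ND, PD, KD}; a sample is assigned the class
with the largest continuous score (ties broken by class order). The number
of latent variables (LVs) is chosen by stratified K-fold cross-validation
as the smallest count whose mean CV macro-F1 comes within a plateau
tolerance of the best over the grid — more LVs fit better but overfit.

Evaluation reports the 4x4 confusion matrix, the misdiagnosis count (MDs,
off-diagonal total) and macro-averaged precision/recall/F1 in percent, for
cross-validation and for an interleaved held-out test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .containers import DURATIONS_H, GROUPS, SpectrumSet

CLASS_ORDER = list(GROUPS)  # CK < ND < PD < KD; also the tie-break order


def interleaved_split(spectra: SpectrumSet) -> tuple[SpectrumSet, SpectrumSet]:
    """Alternate spectra between train and test in collection order.

    Within each group x duration stratum (row order = collection sequence),
    even-indexed spectra go to the training set and odd-indexed to the test
    set, so both halves contain every class and the training half gets the
    extra sample when a stratum is odd-sized.
    """
    meta = spectra.meta
    train_mask = np.zeros(spectra.n_spectra, dtype=bool)
    for _, sub in meta.groupby(["group", "duration_h"], sort=False):
        pos = sub.index.to_numpy()
        train_mask[pos[::2]] = True
    return spectra.select(train_mask), spectra.select(~train_mask)


@dataclass
class PLSDAModel:
    """A fitted PLS-DA model: PLS regression onto one-hot labels + argmax."""

    pls: PLSRegression
    classes: list[str]
    n_lv: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.pls.predict(np.asarray(X, dtype=float))
        # ties broken by class order because argmax returns the first max
        return np.asarray(self.classes, dtype=object)[np.argmax(scores, axis=1)]


def _one_hot(y: np.ndarray, classes: list[str]) -> np.ndarray:
    Y = np.zeros((len(y), len(classes)))
    for j, c in enumerate(classes):
        Y[np.asarray(y) == c, j] = 1.0
    return Y


def fit_plsda(
    X: np.ndarray, y: np.ndarray, n_lv: int, classes: list[str] | None = None
) -> PLSDAModel:
    """Fit PLS-DA with ``n_lv`` latent variables on labelled spectra."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if classes is None:
        classes = [c for c in CLASS_ORDER if c in set(y)] or sorted(set(map(str, y)))
    if len(set(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    max_lv = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_lv <= max_lv:
        raise ValueError(f"n_lv must be in [1, {max_lv}], got {n_lv}")
    pls = PLSRegression(n_components=n_lv, scale=False)
    pls.fit(X, _one_hot(y, classes))
    return PLSDAModel(pls=pls, classes=list(classes), n_lv=n_lv)


# -- metrics -------------------------------------------------------------


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, classes: list[str]) -> np.ndarray:
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    idx = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return cm


def macro_metrics(cm: np.ndarray) -> dict[str, float]:
    """Unweighted class-mean precision/recall/F1 in percent from a confusion
    matrix (rows = true, columns = predicted).

    A class never predicted gets precision 0 (with a warning); a class
    absent from the truth gets recall 0 likewise; F1 per class is
    2PR/(P+R), 0 when both are 0.
    """
    tp = np.diag(cm).astype(float)
    pred_tot = cm.sum(axis=0).astype(float)
    true_tot = cm.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        recall = np.where(true_tot > 0, tp / true_tot, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    if np.any(pred_tot == 0):
        warnings.warn("class(es) never predicted: precision reported as 0")
    return {
        "macro_P": float(precision.mean() * 100),
        "macro_R": float(recall.mean() * 100),
        "macro_F1": float(f1.mean() * 100),
    }


@dataclass
class ModelReport:
    """Evaluation bundle for one fitted model on one data split."""

    n_samples: int
    n_lv: int
    confusion: np.ndarray
    mds: int
    macro_P: float
    macro_R: float
    macro_F1: float
    cv_macro_P: float | None = None
    cv_macro_R: float | None = None
    cv_macro_F1: float | None = None

    def to_row(self) -> dict:
        return {
            "SampleSize": self.n_samples,
            "LVs": self.n_lv,
            "MDs": self.mds,
            "CV_Macro_P": self.cv_macro_P,
            "CV_Macro_R": self.cv_macro_R,
            "CV_Macro_F1": self.cv_macro_F1,
            "Test_Macro_P": self.macro_P,
            "Test_Macro_R": self.macro_R,
            "Test_Macro_F1": self.macro_F1,
        }


def evaluate(model: PLSDAModel, X: np.ndarray, y: np.ndarray) -> ModelReport:
    """Confusion matrix, MDs and macro metrics of a model on labelled data."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    cm = confusion_matrix(y, model.predict(X), model.classes)
    m = macro_metrics(cm)
    return ModelReport(
        n_samples=int(cm.sum()),
        n_lv=model.n_lv,
        confusion=cm,
        mds=int(cm.sum() - np.trace(cm)),
        **m,
    )


def select_lvs(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    lv_max: int = 15,
    tau: float = 0.5,
    seed: int = 0,
    classes: list[str] | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the LV count by stratified K-fold cross-validation.

    Scans n_lv = 1..lv_max; the chosen count is the smallest whose mean CV
    macro-F1 is within ``tau`` F1 percentage points of the best over the
    grid (the "stable performance" plateau rule). Returns the choice and a
    per-LV table of CV macro metrics. Warns if the profile is still rising
    at ``lv_max``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} samples; cannot form {k} stratified folds"
        )
    if classes is None:
        classes = [c for c in CLASS_ORDER if c in set(y)] or sorted(set(map(str, y)))
    lv_cap = min(lv_max, min(len(y) - int(np.ceil(len(y) / k)) - 1, X.shape[1]))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    records = []
    for n_lv in range(1, lv_cap + 1):
        cms = np.zeros((len(classes), len(classes)), dtype=int)
        for tr, va in folds:
            model = fit_plsda(X[tr], y[tr], n_lv, classes=classes)
            cms += confusion_matrix(y[va], model.predict(X[va]), classes)
        with warnings.catch_warnings():
            # low LV counts legitimately miss classes during the grid scan
            warnings.simplefilter("ignore", UserWarning)
            m = macro_metrics(cms)
        records.append({"n_lv": n_lv, **m})
    report = pd.DataFrame(records).set_index("n_lv")
    best_score = report["macro_F1"].max()
    plateau = report.index[report["macro_F1"] >= best_score - tau]
    best_lv = int(plateau.min())
    if report["macro_F1"].idxmax() == lv_cap and best_lv == lv_cap:
        warnings.warn("CV macro-F1 still rising at lv_max: no plateau reached")
    return best_lv, report


@dataclass
class TrainResult:
    model: PLSDAModel
    report: ModelReport
    cv_report: pd.DataFrame


def train_and_evaluate(
    spectra: SpectrumSet,
    k: int = 5,
    lv_max: int = 15,
    tau: float = 0.5,
    seed: int = 0,
) -> TrainResult:
    """Interleaved split, CV-based LV choice, final fit and test evaluation."""
    train, test = interleaved_split(spectra)
    Xtr, ytr = train.intensities, train.meta["group"].to_numpy()
    Xte, yte = test.intensities, test.meta["group"].to_numpy()
    best_lv, cv_report = select_lvs(Xtr, ytr, k=k, lv_max=lv_max, tau=tau, seed=seed)
    model = fit_plsda(Xtr, ytr, best_lv)
    report = evaluate(model, Xte, yte)
    cv_row = cv_report.loc[best_lv]
    report.cv_macro_P = float(cv_row["macro_P"])
    report.cv_macro_R = float(cv_row["macro_R"])
    report.cv_macro_F1 = float(cv_row["macro_F1"])
    return TrainResult(model=model, report=report, cv_report=cv_report)


def before_after_comparison(
    raw: SpectrumSet,
    cleaned: SpectrumSet,
    k: int = 5,
    lv_max: int = 15,
    tau: float = 0.5,
    seed: int = 0,
    durations: tuple[int, ...] = DURATIONS_H,
    pooled: bool = False,
) -> pd.DataFrame:
    """Evaluate the classifier per stress duration before vs. after cleansing.

    Both sets must share preprocessing and the interleaved split policy.
    Returns one row per duration and condition ("raw" / "cleaned"), in the
    before/after pairing layout, plus delta columns on the cleaned rows
    (ΔLVs, ΔMDs, ΔF1 for CV and test). With ``pooled=True`` an extra pair of
    rows over all durations combined is appended.
    """
    rows = []
    subsets: list[tuple[str, SpectrumSet, SpectrumSet]] = [
        (f"{d} h", _by_duration(raw, d), _by_duration(cleaned, d)) for d in durations
    ]
    if pooled:
        subsets.append(("pooled", raw, cleaned))
    for label, raw_sub, cleaned_sub in subsets:
        res_raw = train_and_evaluate(raw_sub, k=k, lv_max=lv_max, tau=tau, seed=seed)
        res_cln = train_and_evaluate(cleaned_sub, k=k, lv_max=lv_max, tau=tau, seed=seed)
        r, c = res_raw.report, res_cln.report
        # SampleSize reports the whole subset; the confusion matrix itself
        # only covers the held-out half
        rows.append(
            {"Group": label, "Condition": "raw", **r.to_row(), "SampleSize": raw_sub.n_spectra}
        )
        rows.append(
            {
                "Group": f"{label}-cleaned",
                "Condition": "cleaned",
                **c.to_row(),
                "SampleSize": cleaned_sub.n_spectra,
                "dLVs": c.n_lv - r.n_lv,
                "dMDs": c.mds - r.mds,
                "dCV_Macro_F1": c.cv_macro_F1 - r.cv_macro_F1,
                "dTest_Macro_F1": c.macro_F1 - r.macro_F1,
            }
        )
    return pd.DataFrame(rows)


def _by_duration(spectra: SpectrumSet, duration_h: int) -> SpectrumSet:
    mask = (spectra.meta["duration_h"] == duration_h).to_numpy()
    if not mask.any():
        raise ValueError(f"no spectra at duration {duration_h} h")
    return spectra.select(mask)
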