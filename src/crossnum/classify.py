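"""Network-level classification of NRS patterns.

A linear support vector machine with stratified k-fold cross-validation
distinguishes groups from ROI-mean NRS features (one session) or from
tutoring-induced change scores (post - pre per ROI).  Significance comes
from a label-permutation test: the full cross-validation is re-run for
each permuted labeling and p = (1 + #{perm acc >= observed}) /
(n_perm + 1), so p is never exactly zero.

Conventions: C = 1, stratified folds with seeded shuffling, per-fold
feature standardization fit on the training folds only (no leakage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .group import roi_means


def build_features(
    nrs_maps: dict,
    roi_labels: np.ndarray,
    subjects: list[str],
    mode: str = "session",
    session: str = "pre",
) -> pd.DataFrame:
    """ROI-mean NRS feature matrix, rows = subjects, manifest-ordered columns.

    ``nrs_maps`` is keyed by (subject_id, session).  ``mode="session"``
    takes per-ROI means at one session; ``mode="delta"`` takes post minus
    pre.  A missing session or an all-NaN ROI raises.
    """
    roi_ids = sorted(int(v) for v in np.unique(roi_labels) if v != 0)
    cols = [f"roi_{r}" for r in roi_ids]
    rows = []
    for sid in subjects:
        if mode == "session":
            if (sid, session) not in nrs_maps:
                raise ValueError(f"subject {sid} missing session {session}")
            m = roi_means(nrs_maps[(sid, session)], roi_labels, roi_ids)
            rows.append([m[r] for r in roi_ids])
        elif mode == "delta":
            for s in ("pre", "post"):
                if (sid, s) not in nrs_maps:
                    raise ValueError(f"subject {sid} missing session {s}")
            m0 = roi_means(nrs_maps[(sid, "pre")], roi_labels, roi_ids)
            m1 = roi_means(nrs_maps[(sid, "post")], roi_labels, roi_ids)
            rows.append([m1[r] - m0[r] for r in roi_ids])
        else:
            raise ValueError("mode must be 'session' or 'delta'")
    X = pd.DataFrame(rows, index=pd.Index(subjects, name="subject_id"), columns=cols)
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing entries")
    return X


@dataclass
class ClassificationResult:
    """Cross-validated accuracy with its permutation p-value."""

    accuracy: float
    p: float
    n_permutations: int
    k_folds: int
    seed: int

    def __post_init__(self):
        if self.n_permutations > 0 and self.p < 1.0 / (self.n_permutations + 1) - 1e-12:
            raise ValueError("p below the permutation floor")


def _cv_accuracy(X: np.ndarray, y: np.ndarray, folds, C: float) -> float:
    accs = []
    for tr, te in folds:
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=C)
        clf.fit((X[tr] - mu) / sd, y[tr])
        accs.append(float(np.mean(clf.predict((X[te] - mu) / sd) == y[te])))
    return float(np.mean(accs))


def _folds(y: np.ndarray, k_folds: int, seed: int):
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros((len(y), 1)), y))


def _encode(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    return np.searchsorted(classes, y)


def svm_cv_accuracy(
    X, y, k_folds: int = 10, seed: int = 0, C: float = 1.0
) -> float:
    """Mean fold accuracy of a linear SVM under stratified k-fold CV."""
    Xa = np.asarray(X, float)
    ya = _encode(y)
    return _cv_accuracy(Xa, ya, _folds(ya, k_folds, seed), C)


def permutation_p(
    X,
    y,
    observed_accuracy: float | None = None,
    n_perm: int = 5000,
    k_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> ClassificationResult:
    """Permutation test of classification accuracy.

    Labels are permuted ``n_perm`` times and the full cross-validation is
    re-run each time with the same fold scheme.  When
    ``observed_accuracy`` is None it is computed from the unpermuted
    labels first.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Xa = np.asarray(X, float)
    ya = _encode(y)
    if observed_accuracy is None:
        observed_accuracy = _cv_accuracy(Xa, ya, _folds(ya, k_folds, seed), C)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        yp = rng.permutation(ya)
        acc = _cv_accuracy(Xa, yp, _folds(yp, k_folds, seed), C)
        if acc >= observed_accuracy - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return ClassificationResult(
        accuracy=float(observed_accuracy),
        p=float(p),
        n_permutations=n_perm,
        k_folds=k_folds,
        seed=seed,
    )
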