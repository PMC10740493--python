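"""Statistical evaluation of synthetic signals.

Four procedures:

* **Mantel test** — Pearson correlation between the upper triangles of two
  symmetric feature-correlation matrices (real vs. generated), with a
  permutation null built by jointly permuting rows and columns of the second
  matrix.  Answers: are inter-feature relationships preserved?
* **Classification** — held-out accuracy of a standard classifier (AdaBoost,
  bagging, SVM or logistic regression, features standardised on the training
  split only) on a labelled feature matrix.
* **Augmentation sweep** — classifier accuracy as synthetic windows are mixed
  into the training data in 25% increments of the real set, over the full
  window-length x increment grid, with class-balanced additions and a test
  split mirroring the mixed composition.
* **Classifier two-sample test (C2ST)** — a binary classifier's held-out
  accuracy on pooled real/generated features; 50% means the two samples are
  statistically indistinguishable.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureSpec, feature_array, feature_columns, feature_matrix
from .protocol_sim import Session
from .sigproc import WindowGrid, segment_windows

#: Correlation-strength reporting bands (edges are configurable).
STRENGTH_BANDS = (
    (0.2, "very weak"),
    (0.4, "weak"),
    (0.6, "medium"),
    (0.8, "strong"),
    (np.inf, "very strong"),
)


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


@dataclasses.dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    permutations: int
    seed: int | None


@dataclasses.dataclass(frozen=True)
class C2STResult:
    accuracy: float
    n_train: int
    n_test: int
    seed: int


def correlation_strength(r: float,
                         bands=STRENGTH_BANDS) -> str:
    """Qualitative label for the magnitude of a correlation coefficient."""
    a = abs(r)
    for edge, name in bands:
        if a < edge:
            return name
    return bands[-1][1]


def feature_correlation(fm) -> pd.DataFrame:
    """Pearson correlation matrix across the feature columns of a matrix.

    Zero-variance columns are dropped (with a warning) since Pearson r is
    undefined for them.
    """
    if isinstance(fm, pd.DataFrame):
        X = feature_array(fm)
        names = feature_columns(fm)
    else:
        X = np.asarray(fm, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with >= 3 rows")
    std = X.std(axis=0)
    keep = std > 0
    if not np.all(keep):
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping zero-variance feature columns: {dropped}")
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    if X.shape[1] < 3:
        raise ValueError("need >= 3 non-degenerate feature columns")
    corr = np.corrcoef(X, rowvar=False)
    return pd.DataFrame(corr, index=names, columns=names)


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std(ddof=1)
    if s == 0:
        raise UndefinedStatisticError("zero variance in upper triangle")
    return (v - v.mean()) / s


def mantel_test(dx, dy, permutations: int = 1000,
                seed: int | None = None) -> MantelResult:
    """Mantel permutation test between two symmetric matrices.

    The statistic is r_M = sum(stand(DX_ij) * stand(DY_ij)) / (d - 1) over
    the upper triangle (d = n(n-1)/2 entries), i.e. the Pearson correlation
    of the vectorised triangles.  The null distribution jointly permutes the
    rows and columns of DY; the one-sided (greater) p-value uses the +1
    convention, so the smallest attainable p is 1/(permutations + 1).
    Identity permutations are rejected during sampling so that bound is
    attained for DY = DX.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if dx.shape != dy.shape or dx.ndim != 2 or dx.shape[0] != dx.shape[1]:
        raise ValueError("matrices must be square with matching dimensions")
    n = dx.shape[0]
    if n < 4:
        raise ValueError("need n >= 4 for a meaningful permutation null")
    if not (np.allclose(dx, dx.T) and np.allclose(dy, dy.T)):
        raise ValueError("matrices must be symmetric")
    x = _standardize(_upper(dx))
    d = x.size
    y_raw = _upper(dy)
    y = _standardize(y_raw)
    r = float(np.dot(x, y) / (d - 1))

    rng = np.random.default_rng(seed)
    count = 0
    identity = np.arange(n)
    iu = np.triu_indices(n, k=1)
    for _ in range(permutations):
        perm = rng.permutation(n)
        while np.array_equal(perm, identity):
            perm = rng.permutation(n)
        yp = dy[np.ix_(perm, perm)][iu]
        sp = yp.std(ddof=1)
        if sp == 0:
            continue
        rp = float(np.dot(x, (yp - yp.mean()) / sp) / (d - 1))
        if rp >= r:
            count += 1
    p = (1 + count) / (1 + permutations)
    return MantelResult(r=r, p_value=p, permutations=permutations, seed=seed)


# ---------------------------------------------------------------------------
# classifiers


def _make_classifier(name: str, seed: int):
    registry: dict[str, Callable] = {
        "adaboost": lambda: AdaBoostClassifier(random_state=seed),
        "bagging": lambda: BaggingClassifier(random_state=seed),
        "svm": lambda: SVC(kernel="rbf", random_state=seed),
        "logistic": lambda: LogisticRegression(max_iter=2000, random_state=seed),
    }
    if name not in registry:
        raise ValueError(f"unknown classifier {name!r}; choose from {sorted(registry)}")
    return registry[name]()


def _evaluate_split(X: np.ndarray, y: np.ndarray, strata: np.ndarray | None,
                    classifier: str, seed: int, test_size: float = 0.2) -> float:
    # stratification needs >= 2 members per stratum and test/train splits at
    # least as large as the stratum count; degrade composite -> class -> none
    n_test = int(np.ceil(len(y) * test_size))
    n_train = len(y) - n_test

    def _usable(s):
        if s is None:
            return True
        vals, counts = np.unique(s, return_counts=True)
        return counts.min() >= 2 and len(vals) <= min(n_test, n_train)

    for candidate in (strata, y, None):
        if _usable(candidate):
            strata = candidate
            break
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, random_state=seed, shuffle=True,
        stratify=strata,
    )
    pipe = make_pipeline(StandardScaler(), _make_classifier(classifier, seed))
    pipe.fit(X_tr, y_tr)
    return float(pipe.score(X_te, y_te))


def classify(features, labels=None, classifier: str = "adaboost",
             test_size: float = 0.2, seed: int = 0) -> float:
    """Held-out accuracy of one classifier on a labelled feature matrix.

    Features are standardised to zero mean / unit variance using training-
    split statistics only; the split is stratified 80/20 by class.
    """
    if isinstance(features, pd.DataFrame):
        X = feature_array(features)
        if labels is None:
            labels = features["label"].to_numpy()
    else:
        X = np.asarray(features, dtype=float)
        if labels is None:
            raise ValueError("labels required for array input")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("classification needs >= 2 classes")
    return _evaluate_split(X, y, strata=y, classifier=classifier, seed=seed,
                           test_size=test_size)


def c2st(real_features, generated_features, classifier: str = "logistic",
         test_size: float = 0.2, seed: int = 0) -> C2STResult:
    """Classifier two-sample test between real and generated feature samples.

    The pooled set labels real rows 1 and generated rows 0, is shuffled and
    split 80/20; the returned accuracy on the held-out fraction is the test
    statistic (0.5 = indistinguishable).  The margin classifier defaults to
    logistic regression.
    """
    R = feature_array(real_features) if isinstance(real_features, pd.DataFrame) \
        else np.asarray(real_features, dtype=float)
    G = feature_array(generated_features) \
        if isinstance(generated_features, pd.DataFrame) \
        else np.asarray(generated_features, dtype=float)
    if R.size == 0 or G.size == 0:
        raise ValueError("both samples must be non-empty")
    X = np.vstack([R, G])
    y = np.concatenate([np.ones(len(R)), np.zeros(len(G))])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, random_state=seed, shuffle=True,
    )
    pipe = make_pipeline(StandardScaler(), _make_classifier(classifier, seed))
    pipe.fit(X_tr, y_tr)
    acc = float(pipe.score(X_te, y_te))
    return C2STResult(accuracy=acc, n_train=len(X_tr), n_test=len(X_te), seed=seed)


# ---------------------------------------------------------------------------
# augmentation sweep


def _balanced_pick(rng: np.random.Generator, labels: np.ndarray,
                   per_class: dict[int, int]) -> np.ndarray:
    """Seeded per-class row selection (counts per gesture equal within +-1)."""
    chosen = []
    for cls, k in per_class.items():
        idx = np.flatnonzero(labels == cls)
        if k > len(idx):
            raise ValueError(
                f"synthetic pool has only {len(idx)} windows for class {cls}, "
                f"need {k}"
            )
        chosen.append(rng.choice(idx, size=k, replace=False))
    return np.sort(np.concatenate(chosen)) if chosen else np.empty(0, dtype=int)


def augmentation_sweep(
    real: Session,
    synthetic: Session,
    grid: WindowGrid | None = None,
    fractions: Sequence[float] = (0.0, 0.25, 0.50, 0.75, 1.00),
    classifier: str = "svm",
    seed: int = 0,
    feature_spec: FeatureSpec | None = None,
    max_windows_per_cell: int | None = None,
) -> pd.DataFrame:
    """Accuracy grid over (window length, increment fraction, synthetic fraction).

    For each grid cell, real and synthetic sessions are windowed and
    featurised identically; for each synthetic fraction f, floor(f * n_c)
    synthetic rows are added per gesture class c (balanced against the real
    per-class counts), and the 80/20 split is stratified by (class, origin)
    so the test set mirrors the mixed-train composition.  The f = 0 cell is
    identical to :func:`classify` on the real data under a shared seed.
    """
    grid = grid or WindowGrid()
    fspec = feature_spec or FeatureSpec()
    rows = []
    for length, frac in grid.cells():
        fm_r = feature_matrix(segment_windows(real, length, frac), fspec)
        fm_s = feature_matrix(segment_windows(synthetic, length, frac), fspec)
        Xr, yr = feature_array(fm_r), fm_r["label"].to_numpy()
        Xs, ys = feature_array(fm_s), fm_s["label"].to_numpy()
        cell_rng = np.random.default_rng([seed, length, int(frac * 100)])
        if max_windows_per_cell is not None and len(yr) > max_windows_per_cell:
            keep = _balanced_pick(
                cell_rng, yr,
                {c: max_windows_per_cell // len(np.unique(yr))
                 for c in np.unique(yr)},
            )
            Xr, yr = Xr[keep], yr[keep]
        real_counts = {int(c): int(np.sum(yr == c)) for c in np.unique(yr)}
        for f in fractions:
            if f == 0.0:
                acc = _evaluate_split(Xr, yr, strata=yr, classifier=classifier,
                                      seed=seed)
            else:
                per_class = {c: int(np.floor(f * k))
                             for c, k in real_counts.items()}
                pick = _balanced_pick(cell_rng, ys, per_class)
                X = np.vstack([Xr, Xs[pick]])
                y = np.concatenate([yr, ys[pick]])
                origin = np.concatenate([np.zeros(len(yr)), np.ones(len(pick))])
                strata = y * 2 + origin
                acc = _evaluate_split(X, y, strata=strata, classifier=classifier,
                                      seed=seed)
            rows.append({
                "window_length": length,
                "increment_fraction": frac,
                "synthetic_fraction": f,
                "accuracy": acc,
            })
    out = pd.DataFrame(rows)
    out.attrs["classifier"] = classifier
    out.attrs["seed"] = seed
    out.attrs["grid"] = grid.to_dict()
    return out
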