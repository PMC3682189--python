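"""Multiclass pattern decoding: searchlight selection + ECOC linear SVM + LOTO CV.

The classifier answers, per region of interest, "which of the three
memories was being recalled on this trial?". The procedure for each ROI:

* build one spherical *searchlight* (radius 3 voxels, lattice distance)
  centred on every ROI voxel, truncated at the ROI border;
* under leave-one-trial-out (LOTO) cross-validation, select -- using the
  training trials only -- the searchlight whose voxels carry the most
  decoding information, then train a multiclass classifier on those
  voxels and predict the held-out trial;
* multiclass prediction uses Error-Correcting Output Codes: each class
  gets a binary codeword over several two-class dichotomies, one linear
  soft-margin SVM (C = 1) is trained per dichotomy, and the class whose
  codeword is nearest in Hamming distance to the vector of binary
  predictions wins.

Feature selection is performed inside each fold on the training trials
alone, so the held-out trial never influences which voxels are used --
the "no double-dipping" guarantee that the test suite asserts exactly.

Searchlight scoring defaults to a *nested* LOTO cross-validation within
the training set (``scoring="nested"``); plain training accuracy is
available as ``scoring="train"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import RoiMask, TrialPatternSet

__all__ = [
    "Searchlight",
    "EcocCodebook",
    "LinearClassifier",
    "DecodingResult",
    "build_searchlights",
    "exhaustive_codebook",
    "train_binary",
    "ecoc_train",
    "ecoc_predict",
    "score_searchlight",
    "select_features",
    "loto_crossval",
    "SearchlightDecoder",
]

# -- fast LIBSVM access ------------------------------------------------------
# sklearn's SVC wrapper spends >90% of its time in input validation, which
# matters here because nested searchlight scoring performs ~10^4-10^6 fits.
# We call the LIBSVM binding directly and fall back to SVC if the private
# module ever moves. Empirically the raw libsvm decision value for a binary
# problem is the negative of the "positive value => +1 label" convention
# (verified against SVC across random problems in the test suite), hence
# the sign flip below.
try:
    from sklearn.svm import _libsvm as _raw_libsvm

    _raw_libsvm.set_verbosity_wrap(0)
except Exception:  # pragma: no cover - fallback path
    _raw_libsvm = None


@dataclass
class LinearClassifier:
    """A trained linear soft-margin binary classifier (w . x + b)."""

    weights: np.ndarray
    bias: float
    c_param: float = 1.0

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(X) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Sign predictions in {-1, +1}; a decision value of 0 maps to +1."""
        return np.where(self.decision_values(X) >= 0, 1, -1)


def _fit_wb(
    X: np.ndarray, y: np.ndarray, c_param: float, tol: float = 1e-3
) -> tuple[np.ndarray, float]:
    """Unvalidated linear-SVM fit returning (w, b); hot-loop workhorse."""
    if _raw_libsvm is not None:
        out = _raw_libsvm.fit(
            X, y, svm_type=0, kernel="linear", C=float(c_param), tol=float(tol)
        )
        sv, sv_coef, intercept = out[1], out[3], out[4]
        return -(sv_coef.ravel() @ sv), -float(intercept[0])
    from sklearn.svm import SVC  # pragma: no cover

    clf = SVC(kernel="linear", C=float(c_param)).fit(X, y)  # pragma: no cover
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])  # pragma: no cover


def train_binary(
    X: np.ndarray, y: np.ndarray, c_param: float = 1.0, tol: float = 1e-3
) -> LinearClassifier:
    """Train a linear SVM (LIBSVM, fixed C) on +/-1 labels.

    Minimises ``0.5 ||w||^2 + C * sum(hinge)``; both classes must be
    present. ``tol`` is the LIBSVM stopping tolerance.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2D")
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("labels must be -1/+1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    if c_param <= 0:
        raise ValueError("c_param must be positive")
    w, b = _fit_wb(X, y, c_param, tol)
    return LinearClassifier(weights=w, bias=b, c_param=float(c_param))


# ---------------------------------------------------------------------------
# ECOC
# ---------------------------------------------------------------------------

@dataclass
class EcocCodebook:
    """Classes x dichotomies +/-1 code matrix.

    Rows are pairwise distinct and no column is constant, so every
    dichotomy genuinely splits the classes.
    """

    classes: np.ndarray
    code: np.ndarray

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        self.code = np.asarray(self.code, dtype=int)
        k, L = self.code.shape
        if len(self.classes) != k:
            raise ValueError("one code row per class required")
        if set(np.unique(self.code)) - {-1, 1}:
            raise ValueError("code entries must be +/-1")
        for j in range(L):
            if len(set(self.code[:, j])) < 2:
                raise ValueError(f"code column {j} is constant")
        for i in range(k):
            for j in range(i + 1, k):
                if np.array_equal(self.code[i], self.code[j]):
                    raise ValueError("code rows must be pairwise distinct")

    @property
    def n_dichotomies(self) -> int:
        return self.code.shape[1]


def exhaustive_codebook(classes) -> EcocCodebook:
    """The exhaustive code: all 2^(k-1) - 1 bipartitions of k classes.

    For three classes this is equivalent to one-vs-rest (3 dichotomies).
    Classes are sorted ascending so tie-breaks favour the lowest label.
    """
    classes = np.sort(np.unique(np.asarray(classes)))
    k = len(classes)
    if k < 2:
        raise ValueError("need at least 2 classes")
    cols = []
    for s in range(2 ** (k - 1) - 1):
        col = [1] + [1 if (s >> j) & 1 else -1 for j in range(k - 1)]
        cols.append(col)
    code = np.array(cols).T  # (k, L)
    return EcocCodebook(classes=classes, code=code)


def ecoc_train(
    X: np.ndarray,
    y: np.ndarray,
    codebook: EcocCodebook,
    c_param: float = 1.0,
    allow_partial: bool = False,
) -> list[LinearClassifier | None]:
    """One binary classifier per codebook column, on relabelled data.

    A column whose +1 or -1 side has no training trials cannot be
    trained: with ``allow_partial`` it yields ``None`` (skipped at
    prediction time, used by the nested scoring of degenerate folds);
    otherwise it is an error naming the column.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classifiers: list[LinearClassifier | None] = []
    for j in range(codebook.n_dichotomies):
        col = codebook.code[:, j]
        relabel = {c: col[i] for i, c in enumerate(codebook.classes)}
        yj = np.array([relabel[v] for v in y], dtype=float)
        if len(np.unique(yj)) < 2:
            if allow_partial:
                classifiers.append(None)
                continue
            raise ValueError(f"dichotomy column {j} has an empty side in training data")
        classifiers.append(train_binary(X, yj, c_param))
    if all(c is None for c in classifiers):
        raise ValueError("no trainable dichotomy column")
    return classifiers


def ecoc_predict(
    classifiers: list[LinearClassifier | None],
    codebook: EcocCodebook,
    X: np.ndarray,
):
    """Nearest-codeword (Hamming) decoding of the binary predictions.

    Ties go to the lowest class label. Accepts one feature vector or a
    matrix of rows; returns a scalar label or an array accordingly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    usable = [j for j, c in enumerate(classifiers) if c is not None]
    if not usable:
        raise ValueError("no usable classifiers")
    bits = np.stack(
        [np.where(classifiers[j].decision_values(X) >= 0, 1, -1) for j in usable],
        axis=1,
    )  # (n, L_usable)
    code = codebook.code[:, usable]  # (k, L_usable)
    # Hamming distance = (L - <bits, codeword>) / 2
    dist = (len(usable) - bits @ code.T) / 2  # (n, k)
    idx = np.argmin(dist, axis=1)  # argmin -> first (lowest) label on ties
    labels = codebook.classes[idx]
    return labels[0] if labels.shape[0] == 1 and X.shape[0] == 1 else labels


# ---------------------------------------------------------------------------
# searchlights
# ---------------------------------------------------------------------------

@dataclass
class Searchlight:
    """A border-truncated sphere of ROI voxels around one centre voxel."""

    centre: tuple[int, int, int]
    members: np.ndarray  # column indices into the ROI's voxel ordering
    radius_voxels: float = 3.0
    centre_index: int = 0  # column index of the centre voxel


def _sphere_offsets(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    pts = []
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dz in range(-r, r + 1):
                if dx * dx + dy * dy + dz * dz <= radius * radius:
                    pts.append((dx, dy, dz))
    return np.array(pts, dtype=int)


def build_searchlights(mask, radius_voxels: float = 3.0) -> list[Searchlight]:
    """One searchlight per ROI voxel, truncated at the ROI border.

    ``mask`` is a :class:`RoiMask` or an (n, 3) array of voxel
    coordinates. Members are the ROI voxels at squared lattice distance
    <= radius^2 from the centre; an interior voxel at radius 3 has 123
    members. The list is ordered by the centre's C-order (linear) index,
    which is the tie-break order used during feature selection.
    """
    if isinstance(mask, RoiMask):
        coords = mask.voxel_coords()
    else:
        coords = np.asarray(mask, dtype=int)
    if coords.size == 0:
        raise ValueError("empty ROI")
    if radius_voxels <= 0:
        raise ValueError("radius_voxels must be positive")
    index = {tuple(c): i for i, c in enumerate(coords)}
    offsets = _sphere_offsets(radius_voxels)
    lights = []
    for i, c in enumerate(coords):
        neighbours = c[None, :] + offsets
        members = sorted(
            index[t] for t in map(tuple, neighbours) if t in index
        )
        lights.append(
            Searchlight(
                centre=tuple(int(v) for v in c),
                members=np.asarray(members, dtype=int),
                radius_voxels=radius_voxels,
                centre_index=i,
            )
        )
    return lights


# ---------------------------------------------------------------------------
# scoring and selection
# ---------------------------------------------------------------------------

def score_searchlight(
    X: np.ndarray,
    y: np.ndarray,
    codebook: EcocCodebook,
    c_param: float = 1.0,
    scoring: str = "nested",
) -> float:
    """Decoding score of one voxel set, computed within the given trials.

    ``scoring="nested"``: leave-one-trial-out cross-validated accuracy
    over the supplied (training) trials, using the same ECOC/SVM
    machinery as the outer classification. A nested fold that leaves a
    dichotomy untrainable drops that column; a fold with no trainable
    column is skipped.

    ``scoring="train"``: plain training accuracy (fit once, score the
    fitting data).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes present to score")
    missing = set(codebook.classes.tolist()) - set(np.unique(y).tolist())
    if missing:
        raise ValueError(f"classes absent from patterns: {sorted(missing)}")
    n = X.shape[0]
    if scoring == "train":
        clfs = ecoc_train(X, y, codebook, c_param)
        pred = ecoc_predict(clfs, codebook, X)
        return float(np.mean(np.atleast_1d(pred) == y))
    if scoring != "nested":
        raise ValueError(f"unknown scoring mode {scoring!r}")
    # Hot path: relabel every dichotomy once, then loop the nested folds
    # with the lean fitter. Semantics identical to ecoc_train/ecoc_predict
    # with allow_partial (asserted in the test suite).
    X = np.ascontiguousarray(X)
    L = codebook.n_dichotomies
    class_pos = {c: i for i, c in enumerate(codebook.classes)}
    Ycols = codebook.code[np.array([class_pos[v] for v in y])].astype(float)  # (n, L)
    code = codebook.code  # (k, L)
    correct = 0
    counted = 0
    idx = np.arange(n)
    for t in range(n):
        tr = idx != t
        Xtr = np.ascontiguousarray(X[tr])
        bits = np.zeros(L)
        usable = np.zeros(L, dtype=bool)
        for j in range(L):
            yj = Ycols[tr, j]
            if yj[0] == yj[-1] and np.all(yj == yj[0]):
                continue  # empty side: column untrainable in this fold
            w, b = _fit_wb(Xtr, yj, c_param)
            bits[j] = 1.0 if X[t] @ w + b >= 0 else -1.0
            usable[j] = True
        if not usable.any():
            continue  # degenerate fold skipped entirely
        dist = (usable.sum() - code[:, usable] @ bits[usable]) / 2
        pred = codebook.classes[int(np.argmin(dist))]
        counted += 1
        if pred == y[t]:
            correct += 1
    return correct / counted if counted else 0.0


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    searchlights: list[Searchlight],
    codebook: EcocCodebook,
    c_param: float = 1.0,
    scoring: str = "nested",
    _cache: dict | None = None,
) -> Searchlight:
    """The searchlight scoring highest on the training trials.

    Ties are broken toward the earliest searchlight in the list, i.e. the
    lowest centre linear index as produced by :func:`build_searchlights`.
    ``_cache`` memoises scores by member set within one call context
    (searchlights with identical members necessarily score identically).
    """
    if not searchlights:
        raise ValueError("searchlights must be non-empty")
    cache = _cache if _cache is not None else {}
    best: Searchlight | None = None
    best_score = -np.inf
    for sl in searchlights:
        key = sl.members.tobytes()
        score = cache.get(key)
        if score is None:
            score = score_searchlight(X[:, sl.members], y, codebook, c_param, scoring)
            cache[key] = score
        if score > best_score:
            best, best_score = sl, score
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# leave-one-trial-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldRecord:
    test_trial: int
    true_label: int
    predicted_label: int
    searchlight_centre: tuple[int, int, int]
    n_members: int


@dataclass
class DecodingResult:
    """Per-fold predictions and overall accuracy for one ROI.

    ``accuracy`` is the proportion of correct guesses over all folds;
    ``n_folds`` equals the number of included trials.
    """

    roi_label: str
    hemisphere: str
    accuracy: float
    n_folds: int
    folds: list[FoldRecord] = field(default_factory=list)
    chance: float = 1.0 / 3.0

    @property
    def key(self) -> str:
        return f"{self.roi_label}_{self.hemisphere}"

    def to_dict(self) -> dict:
        return {
            "roi_label": self.roi_label,
            "hemisphere": self.hemisphere,
            "accuracy": self.accuracy,
            "n_folds": self.n_folds,
            "chance": self.chance,
            "folds": [
                {
                    "test_trial": f.test_trial,
                    "true_label": f.true_label,
                    "predicted_label": f.predicted_label,
                    "searchlight_centre": list(f.searchlight_centre),
                    "n_members": f.n_members,
                }
                for f in self.folds
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = [
            f"Leave-one-trial-out decoding -- ROI {self.key}",
            f"  trials (folds): {self.n_folds}",
            f"  accuracy:       {self.accuracy:.4f} ({self.accuracy * 100:.2f}%)",
            f"  chance:         {self.chance:.4f} ({self.chance * 100:.2f}%)",
        ]
        return "\n".join(lines)


def _run_fold(
    X: np.ndarray,
    y: np.ndarray,
    t: int,
    searchlights: list[Searchlight],
    codebook: EcocCodebook,
    c_param: float = 1.0,
    scoring: str = "nested",
):
    """Feature selection + ECOC training on all trials except ``t``,
    then prediction of trial ``t``. Exposed for leakage auditing."""
    idx = np.arange(X.shape[0])
    tr = idx != t
    cache: dict = {}
    selected = select_features(
        X[tr], y[tr], searchlights, codebook, c_param, scoring, _cache=cache
    )
    clfs = ecoc_train(X[tr][:, selected.members], y[tr], codebook, c_param)
    pred = ecoc_predict(clfs, codebook, X[t, selected.members])
    return selected, clfs, pred


def loto_crossval(
    patterns: TrialPatternSet,
    searchlights: list[Searchlight] | None = None,
    codebook: EcocCodebook | None = None,
    c_param: float = 1.0,
    radius_voxels: float = 3.0,
    scoring: str = "nested",
) -> DecodingResult:
    """Leave-one-trial-out cross-validated decoding of one ROI.

    k folds with k = number of included trials; per fold the searchlight
    is selected and the ECOC/SVM ensemble trained on the other k-1 trials
    only. Every class needs >= 2 trials so no training set loses a class.
    """
    X, y = patterns.X, np.asarray(patterns.y)
    if X.shape[0] == 0:
        raise ValueError("no included trials to decode")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    thin = classes[counts < 2]
    if thin.size:
        raise ValueError(
            f"classes with fewer than 2 trials cannot be cross-validated: {thin.tolist()}"
        )
    if searchlights is None:
        searchlights = build_searchlights(patterns.voxel_coords, radius_voxels)
    if codebook is None:
        codebook = exhaustive_codebook(classes)
    folds = []
    n = X.shape[0]
    correct = 0
    for t in range(n):
        selected, _clfs, pred = _run_fold(
            X, y, t, searchlights, codebook, c_param, scoring
        )
        ok = pred == y[t]
        correct += int(ok)
        folds.append(
            FoldRecord(
                test_trial=int(patterns.trial_indices[t]),
                true_label=int(y[t]),
                predicted_label=int(pred),
                searchlight_centre=selected.centre,
                n_members=int(selected.members.size),
            )
        )
    return DecodingResult(
        roi_label=patterns.roi_label,
        hemisphere=patterns.hemisphere,
        accuracy=correct / n,
        n_folds=n,
        folds=folds,
        chance=1.0 / len(classes),
    )


class SearchlightDecoder:
    """Model object for one ROI's decoding analysis.

    Parameters
    ----------
    patterns : TrialPatternSet
        Included-trial patterns for one ROI (from :mod:`mtldecode.prep`).
    radius_voxels : float
        Searchlight radius in voxel (lattice) units.
    c_param : float
        SVM regularisation constant, fixed at 1 by convention.
    scoring : {"nested", "train"}
        How candidate searchlights are scored within the training set.

    ``fit()`` runs the leave-one-trial-out cross-validation and returns a
    :class:`DecodingResult`.
    """

    def __init__(
        self,
        patterns: TrialPatternSet,
        radius_voxels: float = 3.0,
        c_param: float = 1.0,
        scoring: str = "nested",
        codebook: EcocCodebook | None = None,
    ) -> None:
        self.patterns = patterns
        self.radius_voxels = radius_voxels
        self.c_param = c_param
        self.scoring = scoring
        self.codebook = codebook or exhaustive_codebook(np.unique(patterns.y))
        self.searchlights = build_searchlights(patterns.voxel_coords, radius_voxels)

    @classmethod
    def from_file(cls, path, **kwargs) -> "SearchlightDecoder":
        return cls(TrialPatternSet.load(path), **kwargs)

    def fit(self) -> DecodingResult:
        return loto_crossval(
            self.patterns,
            self.searchlights,
            self.codebook,
            c_param=self.c_param,
            scoring=self.scoring,
        )
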