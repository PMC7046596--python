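"""Case-level classification heads and radiology–pathology fusion strategies.

A *case* is one patient with two imaging modalities: a whole-slide pathology
image and a multi-sequence MRI study.  Upstream predictors (out of scope
here; any model satisfying the :class:`StochasticExtractor` contract) reduce
each modality to either a class-probability pair or a fixed-length feature
vector.  This module fuses the two modalities into one decision by three
strategies, mirroring the three winning approaches of the task:

1. **confidence voting** — trust whichever modality is more confident;
2. **dropout-sampled feature concatenation + SVM** — draw many stochastic
   feature vectors per case from each modality (test-time dropout), train a
   max-margin classifier on the concatenations;
3. **weighted averaging** — ``ŷ = α·f(Xp) + (1−α)·g(Xr)`` with α estimated
   on training data.

It also provides the radiomics head: PCA to 16 components followed by a
liblinear logistic regression, evaluated by stratified fivefold
cross-validation.

Class order is fixed as ``(oligodendroglioma, astrocytoma)`` — label 0 is
oligodendroglioma — and every tie rule resolves toward the earlier class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.svm import LinearSVC

CLASSES: tuple[str, str] = ("oligodendroglioma", "astrocytoma")
LABEL_OLIGO, LABEL_ASTRO = 0, 1


@dataclass(frozen=True)
class CaseProbabilities:
    """Per-case class-probability pair for one modality."""

    p_oligo: float
    p_astro: float
    modality: str = "pathology"

    def __post_init__(self) -> None:
        if self.p_oligo < 0 or self.p_astro < 0:
            raise ValueError("probabilities must be non-negative")
        if abs(self.p_oligo + self.p_astro - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.p_oligo, self.p_astro])

    @property
    def label(self) -> int:
        # tie resolves toward the earlier class (oligodendroglioma)
        return LABEL_OLIGO if self.p_oligo >= self.p_astro else LABEL_ASTRO

    @property
    def confidence(self) -> float:
        return max(self.p_oligo, self.p_astro)


@dataclass(frozen=True)
class FusionWeights:
    """The pathology weight α of the weighted-average fusion."""

    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@runtime_checkable
class StochasticExtractor(Protocol):
    """Contract for a pluggable per-case feature extractor.

    ``sample`` returns a fixed-length vector for a case; with ``stochastic``
    False repeated calls are identical, with it True calls under different
    seeds differ (e.g. a network with dropout left active at test time).
    """

    length: int
    stochastic: bool

    def sample(self, case_id, seed: int) -> np.ndarray: ...


# ---------------------------------------------------------------------------
# probability-level fusion
# ---------------------------------------------------------------------------


def confidence_vote(path: CaseProbabilities,
                    rad: CaseProbabilities) -> tuple[int, CaseProbabilities]:
    """Pick the class of whichever modality is more confident.

    On an exact tie of maximum probabilities the pathology modality wins
    (its patch-level evidence is the finer-grained of the two); within a
    modality an argmax tie resolves to oligodendroglioma.
    """
    chosen = path if path.confidence >= rad.confidence else rad
    fused = CaseProbabilities(chosen.p_oligo, chosen.p_astro, modality="fused")
    return fused.label, fused


def weighted_average(path: CaseProbabilities, rad: CaseProbabilities,
                     w: FusionWeights) -> CaseProbabilities:
    """Componentwise ``α·path + (1−α)·rad``; stays a distribution."""
    a = w.alpha
    return CaseProbabilities(
        a * path.p_oligo + (1 - a) * rad.p_oligo,
        a * path.p_astro + (1 - a) * rad.p_astro,
        modality="fused",
    )


def estimate_alpha(train_path: Sequence[CaseProbabilities],
                   train_rad: Sequence[CaseProbabilities],
                   labels: Sequence[int],
                   grid_step: float = 0.01) -> FusionWeights:
    """Grid-search α maximizing training accuracy of the fused argmax.

    Returns the *smallest* maximizing α so the result is deterministic and,
    all else equal, leans on the radiology model no more than needed.
    """
    if not (len(train_path) == len(train_rad) == len(labels)):
        raise ValueError("inputs must have equal lengths")
    if len(labels) < 2 or len(set(labels)) < 2:
        raise ValueError("need both classes present to estimate alpha")
    p = np.array([c.as_array for c in train_path])
    r = np.array([c.as_array for c in train_rad])
    y = np.asarray(labels)
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 12)
    best_alpha, best_acc = 0.0, -1.0
    for a in grid:
        fused = a * p + (1 - a) * r
        # argmax tie -> earlier class: >= favors column 0
        pred = np.where(fused[:, 0] >= fused[:, 1], LABEL_OLIGO, LABEL_ASTRO)
        acc = float((pred == y).mean())
        if acc > best_acc:
            best_alpha, best_acc = float(a), acc
    return FusionWeights(best_alpha)


# ---------------------------------------------------------------------------
# dropout-sampled feature ensemble
# ---------------------------------------------------------------------------


def _child_seed(seed: int, *keys: int) -> int:
    ss = np.random.SeedSequence([int(seed), *map(int, keys)])
    return int(ss.generate_state(1)[0] % (2**31))


def dropout_sample(ex_path: StochasticExtractor, ex_rad: StochasticExtractor,
                   case_ids: Sequence, k: int, seed: int,
                   ) -> list[tuple[object, np.ndarray]]:
    """Draw ``k`` concatenated pathology+radiology vectors per case.

    With both extractors stochastic this emulates test-time dropout
    sampling: every draw is a distinct but informative view of the case,
    inflating a small cohort into a training set large enough for an SVM.
    Deterministic for a fixed ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: list[tuple[object, np.ndarray]] = []
    for ci, case_id in enumerate(case_ids):
        for j in range(k):
            vp = np.asarray(ex_path.sample(case_id, _child_seed(seed, 0, ci, j)))
            vr = np.asarray(ex_rad.sample(case_id, _child_seed(seed, 1, ci, j)))
            if vp.shape != (ex_path.length,) or vr.shape != (ex_rad.length,):
                raise ValueError("extractor returned a vector of unexpected length")
            out.append((case_id, np.concatenate([vp, vr])))
    return out


@dataclass
class EnsembleSVM:
    """A trained max-margin classifier over concatenated feature samples."""

    clf: LinearSVC
    n_features: int

    def decision(self, X: np.ndarray) -> np.ndarray:
        """Signed margins; positive points toward astrocytoma (label 1)."""
        return self.clf.decision_function(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict(X)


def train_ensemble_svm(samples: Sequence[tuple[object, np.ndarray]],
                       labels: dict, C: float = 1.0,
                       seed: int = 0) -> EnsembleSVM:
    """Train a linear SVM on dropout-sampled vectors, one label per case.

    Every sampled vector inherits the label of its case.  ``C`` weighs the
    *mean* hinge loss (internally divided by the sample count), so the fit
    is invariant to duplicating the sample set or raising ``k``.  Requires
    at least two cases per class.
    """
    X = np.vstack([v for _, v in samples])
    y = np.array([labels[cid] for cid, _ in samples])
    case_labels = {cid: labels[cid] for cid, _ in samples}
    counts = np.bincount(np.array(list(case_labels.values())), minlength=2)
    if (counts < 2).any():
        raise ValueError("need at least two cases per class")
    clf = LinearSVC(C=C / len(y), dual=False, random_state=seed)
    clf.fit(X, y)
    return EnsembleSVM(clf, X.shape[1])


def predict_ensemble(model: EnsembleSVM, ex_path: StochasticExtractor,
                     ex_rad: StochasticExtractor, case_id, k: int, seed: int,
                     aggregate: str = "majority") -> CaseProbabilities:
    """Classify ``k`` sampled vectors for one case and aggregate.

    ``majority`` returns per-class vote fractions; ``mean_margin`` squashes
    the mean signed margin through a sigmoid.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    samples = dropout_sample(ex_path, ex_rad, [case_id], k, seed)
    X = np.vstack([v for _, v in samples])
    if aggregate == "majority":
        votes = model.predict(X)
        p_astro = float((votes == LABEL_ASTRO).mean())
    elif aggregate == "mean_margin":
        p_astro = float(1.0 / (1.0 + np.exp(-model.decision(X).mean())))
    else:
        raise ValueError(f"unknown aggregate mode: {aggregate!r}")
    return CaseProbabilities(1.0 - p_astro, p_astro, modality="fused")


# ---------------------------------------------------------------------------
# radiomics head: PCA(16) + liblinear logistic regression, fivefold CV
# ---------------------------------------------------------------------------


def pca_logreg_head(features: np.ndarray, labels: Sequence[int],
                    n_components: int = 16, folds: int = 5,
                    seed: int = 0) -> tuple[Pipeline, float]:
    """Reduce radiomic vectors by PCA and classify by logistic regression.

    The PCA is refit inside every cross-validation training fold so the
    reported accuracy is leakage-free; the returned pipeline is then fit on
    the full data, which is the deployable model.  Returns
    ``(fitted pipeline, mean CV accuracy)``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n = X.shape[0]
    if n < folds:
        raise ValueError("need at least as many cases as folds")
    max_train = n - int(np.ceil(n / folds))
    if n_components > min(max_train, X.shape[1]):
        raise ValueError("n_components too large for the fold size or feature length")
    pipe = Pipeline([
        ("pca", PCA(n_components=n_components, random_state=seed)),
        ("logreg", LogisticRegression(solver="liblinear", random_state=seed)),
    ])
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc = cross_val_score(pipe, X, y, cv=cv, scoring="accuracy")
    pipe.fit(X, y)
    return pipe, float(acc.mean())
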