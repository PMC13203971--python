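"""The 2-scheme x 3-feature-set grid of kernelized SVM classifiers with
greedy forward feature selection, and the cross-model consensus.

Six models: two classification schemes (respiratory vs non-respiratory;
nasal vs oral vs non-respiratory) crossed with three nested feature sets
(all vOTUs; nonspecific removed; rare and nonspecific removed).  Each
model reports test accuracy on its full feature set, then the ordered
list of up to ``n_select`` features chosen by greedy forward selection
(scored by stratified cross-validated accuracy on the training partition
only; the test set is quarantined), then test accuracy refitted on the
selected features.  vOTUs selected by at least ``min_votes`` models are
the consensus biomarker candidates.

Features are log10(x + eps) transformed and standardized per feature
with statistics fitted on the training partition: raw relative-abundance
fractions span orders of magnitude and would swamp any kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .exceptions import ValidationError
from .filtering import FeatureSets
from .io import AbundanceMatrix, SampleMetadata

SCHEMES = ("two_class", "three_class")

_TWO_CLASS = {
    "nasal": "respiratory", "buccal_mucosa": "respiratory",
    "saliva": "respiratory", "throat": "respiratory",
    "stool": "non_respiratory", "skin": "non_respiratory",
}
_THREE_CLASS = {
    "nasal": "nasal", "buccal_mucosa": "oral", "saliva": "oral",
    "throat": "oral", "stool": "non_respiratory", "skin": "non_respiratory",
}


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one grid cell."""

    scheme: str = "two_class"
    feature_set_label: str = "all"
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    seed: int = 0
    n_select: int = 10
    cv_folds: int = 5
    test_fraction: float = 0.25
    log_eps: float = 1e-8

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {self.scheme!r}")
        if self.n_select < 1:
            raise ValidationError("n_select must be >= 1")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValidationError("test_fraction must be in (0, 1)")

    def make_classifier(self) -> SVC:
        # one-vs-one multiclass decomposition (libsvm default)
        return SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)


@dataclass(frozen=True)
class ModelResult:
    """Fitted accuracies and the ordered feature selection of one model."""

    spec: ModelSpec
    accuracy_full: float
    selected_features: tuple
    accuracy_selected: float
    train_ids: tuple
    test_ids: tuple

    def to_dict(self) -> dict:
        return {
            "scheme": self.spec.scheme,
            "feature_set": self.spec.feature_set_label,
            "seed": self.spec.seed,
            "accuracy_full": self.accuracy_full,
            "selected_features": list(self.selected_features),
            "accuracy_selected": self.accuracy_selected,
            "n_train": len(self.train_ids),
            "n_test": len(self.test_ids),
        }


@dataclass(frozen=True)
class ConsensusResult:
    """Per-vOTU vote counts and the >= min_votes candidate set."""

    votes: dict
    min_votes: int
    candidates: tuple

    def to_dict(self) -> dict:
        return {"min_votes": self.min_votes,
                "votes": dict(self.votes),
                "candidates": list(self.candidates)}


def assign_labels(metadata: Sequence[SampleMetadata], scheme: str) -> np.ndarray:
    """Classification label per sample under the given scheme."""
    mapping = {"two_class": _TWO_CLASS, "three_class": _THREE_CLASS}.get(scheme)
    if mapping is None:
        raise ValidationError(f"unknown scheme {scheme!r}")
    labels = []
    for m in metadata:
        if m.body_site not in mapping:
            raise ValidationError(f"sample {m.sample_id!r}: unknown site "
                                  f"{m.body_site!r}")
        labels.append(mapping[m.body_site])
    return np.array(labels)


def split_train_test(metadata: Sequence[SampleMetadata],
                     labels: Sequence[str],
                     test_fraction: float = 0.25,
                     seed: int = 0):
    """Stratified, seeded train/test partition of sample ids."""
    labels = np.asarray(labels)
    ids = np.array([m.sample_id for m in metadata])
    classes, counts = np.unique(labels, return_counts=True)
    tiny = classes[counts < 2]
    if tiny.size:
        raise ValidationError(f"class(es) with < 2 samples: {list(tiny)}")
    # canonicalize on sorted ids so the partition (and hence every grid
    # accuracy) is invariant to the order samples arrive in
    order = np.argsort(ids, kind="stable")
    train_ids, test_ids = train_test_split(
        ids[order], test_size=test_fraction, stratify=labels[order],
        random_state=seed, shuffle=True,
    )
    train_set = set(train_ids)
    train_labels = labels[[sid in train_set for sid in ids]]
    _, train_counts = np.unique(train_labels, return_counts=True)
    if (train_counts < 2).any():
        raise ValidationError("a class has < 2 training samples; increase "
                              "cohort size or lower test_fraction")
    return tuple(train_ids), tuple(test_ids)


class _LogScaler:
    """log10(x + eps) then per-feature standardization, fitted on train."""

    def __init__(self, eps: float):
        self.eps = eps

    def fit(self, X: np.ndarray) -> "_LogScaler":
        logged = np.log10(X + self.eps)
        self.mean_ = logged.mean(axis=0)
        sd = logged.std(axis=0)
        self.sd_ = np.where(sd == 0, 1.0, sd)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.log10(X + self.eps) - self.mean_) / self.sd_


def fit_and_score(X_train: np.ndarray, y_train: np.ndarray,
                  X_test: np.ndarray, y_test: np.ndarray,
                  spec: ModelSpec) -> float:
    """Test accuracy of the kernelized classifier (inputs already
    preprocessed)."""
    if len(np.unique(y_train)) < 2:
        raise ValidationError("training data contains a single class")
    clf = spec.make_classifier()
    clf.fit(X_train, y_train)
    return float(np.mean(clf.predict(X_test) == y_test))


def forward_select(X_train: np.ndarray, y_train: np.ndarray,
                   feature_ids: Sequence[str], spec: ModelSpec) -> list[str]:
    """Greedy forward selection on the training partition.

    At each step every unselected feature is scored by the mean
    ``cv_folds``-fold stratified cross-validated accuracy of the
    classifier on (current U {feature}); the maximizer is added, ties
    broken by lexicographically smallest vOTU id.  Stops after
    ``n_select`` steps or when features are exhausted.  ``X_train`` must
    already be preprocessed.
    """
    feature_ids = list(feature_ids)
    if not feature_ids:
        raise ValidationError("empty feature set")
    if X_train.shape[1] != len(feature_ids):
        raise ValidationError("X_train columns do not match feature_ids")
    if len(np.unique(y_train)) < 2:
        raise ValidationError("training data contains a single class")

    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                          random_state=spec.seed)
    folds = [(tr, te) for tr, te in skf.split(X_train, y_train)]
    order = sorted(range(len(feature_ids)), key=lambda i: feature_ids[i])

    selected: list[int] = []
    remaining = list(order)                  # kept in lexicographic id order
    n_steps = min(spec.n_select, len(feature_ids))
    for _ in range(n_steps):
        best_idx, best_score = None, -np.inf
        for idx in remaining:
            cols = selected + [idx]
            Xc = X_train[:, cols]
            correct = 0
            total = 0
            for tr, te in folds:
                clf = spec.make_classifier()
                clf.fit(Xc[tr], y_train[tr])
                correct += int(np.sum(clf.predict(Xc[te]) == y_train[te]))
                total += len(te)
            score = correct / total
            if score > best_score:           # strict: first (smallest id) wins ties
                best_idx, best_score = idx, score
        selected.append(best_idx)
        remaining.remove(best_idx)
    return [feature_ids[i] for i in selected]


def run_grid(matrix: AbundanceMatrix,
             metadata: Sequence[SampleMetadata],
             feature_sets: FeatureSets,
             base_spec: ModelSpec = ModelSpec()) -> list[ModelResult]:
    """One ModelResult per (scheme, feature set): 6 under defaults."""
    sample_ids = [m.sample_id for m in metadata]
    if sample_ids != matrix.sample_ids:
        matrix = AbundanceMatrix(
            matrix.target_ids, sample_ids,
            matrix.values[:, matrix.sample_indices(sample_ids)])

    results = []
    for scheme in SCHEMES:
        labels = assign_labels(metadata, scheme)
        train_ids, test_ids = split_train_test(
            metadata, labels, base_spec.test_fraction, base_spec.seed)
        tr_idx = matrix.sample_indices(train_ids)
        te_idx = matrix.sample_indices(test_ids)
        label_of = dict(zip(sample_ids, labels))
        y_train = np.array([label_of[s] for s in train_ids])
        y_test = np.array([label_of[s] for s in test_ids])

        for fset in feature_sets:
            spec = replace(base_spec, scheme=scheme,
                           feature_set_label=fset.label)
            sub = matrix.subset_targets(fset.votu_ids)
            X = sub.values.T                         # samples x features
            scaler = _LogScaler(spec.log_eps).fit(X[tr_idx])
            X_train = scaler.transform(X[tr_idx])
            X_test = scaler.transform(X[te_idx])

            acc_full = fit_and_score(X_train, y_train, X_test, y_test, spec)
            chosen = forward_select(X_train, y_train, fset.votu_ids, spec)
            col = {t: i for i, t in enumerate(fset.votu_ids)}
            keep = [col[t] for t in chosen]
            acc_sel = fit_and_score(X_train[:, keep], y_train,
                                    X_test[:, keep], y_test, spec)
            results.append(ModelResult(
                spec=spec,
                accuracy_full=acc_full,
                selected_features=tuple(chosen),
                accuracy_selected=acc_sel,
                train_ids=tuple(train_ids),
                test_ids=tuple(test_ids),
            ))
    return results


def consensus_candidates(results: Iterable[ModelResult],
                         min_votes: int = 2) -> ConsensusResult:
    """vOTUs selected by >= min_votes models, ordered by votes then id."""
    results = list(results)
    if len(results) < 2:
        raise ValidationError("consensus needs >= 2 model results")
    votes: dict[str, int] = {}
    for r in results:
        for votu in r.selected_features:
            votes[votu] = votes.get(votu, 0) + 1
    candidates = tuple(sorted(
        (v for v, n in votes.items() if n >= min_votes),
        key=lambda v: (-votes[v], v)))
    return ConsensusResult(votes=votes, min_votes=min_votes,
                           candidates=candidates)
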