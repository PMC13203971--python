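"""Label schemes, stratified splitting, forward selection, the 6-model
grid and the consensus vote."""

import json

import numpy as np
import pytest

from conftest import make_matrix, make_metadata
from viromarker import simulate
from viromarker.exceptions import ValidationError
from viromarker.filtering import build_feature_sets
from viromarker.io import SampleMetadata
from viromarker.selection import (ModelSpec, assign_labels,
                                  consensus_candidates, fit_and_score,
                                  forward_select, run_grid, split_train_test)


# -- labels ----------------------------------------------------------------

@pytest.mark.parametrize("site,scheme,label", [
    ("throat", "two_class", "respiratory"),
    ("throat", "three_class", "oral"),
    ("nasal", "three_class", "nasal"),
    ("skin", "two_class", "non_respiratory"),
    ("skin", "three_class", "non_respiratory"),
    ("stool", "two_class", "non_respiratory"),
])
def test_assign_labels(site, scheme, label):
    meta = [SampleMetadata("s", site, 10**6)]
    assert assign_labels(meta, scheme)[0] == label


def test_assign_labels_unknown_scheme():
    with pytest.raises(ValidationError):
        assign_labels([SampleMetadata("s", "nasal", 1)], "four_class")


# -- splitting -------------------------------------------------------------

def test_split_sizes_and_determinism():
    meta = make_metadata({"nasal": 50, "stool": 50})
    labels = assign_labels(meta, "two_class")
    train, test = split_train_test(meta, labels, 0.25, seed=3)
    assert len(train) == 75 and len(test) == 25
    assert set(train).isdisjoint(test)
    assert set(train) | set(test) == {m.sample_id for m in meta}
    assert (train, test) == split_train_test(meta, labels, 0.25, seed=3)


def test_split_stratification_arithmetic():
    meta = make_metadata({"nasal": 60, "stool": 40})
    labels = assign_labels(meta, "two_class")
    train, test = split_train_test(meta, labels, 0.25, seed=0)
    site = lambda sid: sid.split("_")[0]
    assert sum(site(s) == "nasal" for s in test) == 15
    assert sum(site(s) == "stool" for s in test) == 10


def test_split_order_invariance():
    meta = make_metadata({"nasal": 20, "stool": 20})
    labels = assign_labels(meta, "two_class")
    perm = np.random.default_rng(0).permutation(len(meta))
    meta_p = [meta[i] for i in perm]
    labels_p = [labels[i] for i in perm]
    assert split_train_test(meta, labels, 0.25, 7) == \
        split_train_test(meta_p, labels_p, 0.25, 7)


def test_split_refuses_tiny_class():
    meta = make_metadata({"nasal": 30, "stool": 1})
    labels = assign_labels(meta, "two_class")
    with pytest.raises(ValidationError):
        split_train_test(meta, labels, 0.25, 0)


# -- fit and score ---------------------------------------------------------

def _separable(n_per_class=20, n_noise=3, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["a"] * n_per_class + ["b"] * n_per_class)
    signal = np.where(y == "a", -2.0, 2.0)[:, None]
    X = np.hstack([signal + rng.normal(0, 0.2, (2 * n_per_class, 1)),
                   rng.normal(0, 1, (2 * n_per_class, n_noise))])
    return X, y


def test_fit_and_score_separable_and_memorization():
    X, y = _separable()
    spec = ModelSpec()
    assert fit_and_score(X[::2], y[::2], X[1::2], y[1::2], spec) == 1.0
    assert fit_and_score(X, y, X, y, spec) == 1.0


def test_fit_and_score_single_class_errors():
    X, y = _separable()
    with pytest.raises(ValidationError):
        fit_and_score(X[y == "a"], y[y == "a"], X, y, ModelSpec())


# -- forward selection -----------------------------------------------------

def test_forward_select_finds_planted_feature():
    X, y = _separable(n_per_class=25, n_noise=6, seed=4)
    spec = ModelSpec(n_select=1, seed=4)
    ids = [f"v{i:02d}" for i in range(X.shape[1])]
    assert forward_select(X, y, ids, spec) == ["v00"]


def test_forward_select_exhaustion_returns_all():
    X, y = _separable(n_noise=2)
    ids = ["b", "a", "c"]
    chosen = forward_select(X, y, ids, ModelSpec(n_select=10))
    assert sorted(chosen) == ["a", "b", "c"] and len(chosen) == 3


def test_forward_select_tie_breaks_lexicographically():
    rng = np.random.default_rng(1)
    y = np.array(["a"] * 20 + ["b"] * 20)
    informative = np.where(y == "a", -2.0, 2.0) + rng.normal(0, 0.1, 40)
    X = np.column_stack([informative, informative])
    chosen = forward_select(X, y, ["zeta", "alpha"], ModelSpec(n_select=1))
    assert chosen == ["alpha"]


# -- the grid --------------------------------------------------------------

@pytest.fixture(scope="module")
def grid_results(small_cohort):
    _, meta, matrix, _ = small_cohort
    sets = build_feature_sets(matrix, meta)
    return run_grid(matrix, meta, sets, ModelSpec(seed=11)), sets


def test_grid_shape_and_feature_containment(grid_results):
    results, sets = grid_results
    assert len(results) == 6
    by_label = {fs.label: set(fs.votu_ids) for fs in sets}
    for r in results:
        assert len(r.selected_features) <= 10
        assert len(set(r.selected_features)) == len(r.selected_features)
        assert set(r.selected_features) <= by_label[r.spec.feature_set_label]
        assert 0.0 <= r.accuracy_full <= 1.0
        assert 0.0 <= r.accuracy_selected <= 1.0


def test_grid_deterministic_given_seed(small_cohort, grid_results):
    _, meta, matrix, _ = small_cohort
    results, sets = grid_results
    again = run_grid(matrix, meta, sets, ModelSpec(seed=11))
    a = json.dumps([r.to_dict() for r in results], sort_keys=True)
    b = json.dumps([r.to_dict() for r in again], sort_keys=True)
    assert a == b


def test_grid_accuracy_high_on_clean_markers():
    """Deterministically site-specific markers make every model accurate."""
    clean = {}
    for name, spec in simulate.default_class_specs().items():
        if name in ("rare_respiratory", "background"):
            clean[name] = spec        # leave non-marker noise untouched
        else:
            clean[name] = simulate.MarkerClassSpec(
                name,
                {s: (1.0 if p >= 0.5 else 0.0)
                 for s, p in spec.prevalence.items()},
                spec.log10_mean, spec.log10_sd)
    config = simulate.CohortConfig(
        n_samples={s: 15 for s in simulate.BODY_SITES},
        n_votus={"oral_marker": 3, "nasal_marker": 2, "nasal_oral_marker": 2,
                 "skin_assoc": 2, "stool_assoc": 2, "nonspecific": 2,
                 "rare_respiratory": 2, "background": 4},
        class_specs=clean, seed=0)
    for seed in range(10):
        meta, matrix, _ = simulate.generate_cohort(config.with_seed(seed))
        sets = build_feature_sets(matrix, meta)
        results = run_grid(matrix, meta, sets, ModelSpec(seed=seed, n_select=5))
        for r in results:
            assert r.accuracy_selected >= 0.9, (seed, r.spec)


# -- consensus -------------------------------------------------------------

def _fake_result(features, scheme="two_class", label="all"):
    from viromarker.selection import ModelResult
    return ModelResult(ModelSpec(scheme=scheme, feature_set_label=label),
                       1.0, tuple(features), 1.0, ("t",), ("u",))


def test_consensus_votes_and_ordering():
    results = ([_fake_result(["A", "B"])] * 2
               + [_fake_result(["A", "C"])]
               + [_fake_result(["A"])] * 2
               + [_fake_result(["B", "A"])])
    consensus = consensus_candidates(results)
    assert consensus.votes == {"A": 6, "B": 3, "C": 1}
    assert consensus.candidates == ("A", "B")


def test_consensus_empty_candidates_ok():
    consensus = consensus_candidates([_fake_result(["A"]),
                                      _fake_result(["B"])])
    assert consensus.candidates == ()


def test_consensus_matches_bruteforce_recount(grid_results):
    results, _ = grid_results
    consensus = consensus_candidates(results)
    for votu, votes in consensus.votes.items():
        recount = sum(votu in r.selected_features for r in results)
        assert votes == recount
    assert set(consensus.candidates) == {
        v for v, n in consensus.votes.items() if n >= 2}
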