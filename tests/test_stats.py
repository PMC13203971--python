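"""Normality gate, rank-sum test, BH correction, clustering."""

from io import StringIO

import numpy as np
import pytest
from Bio import Phylo
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_matrix, make_metadata
from viromarker.exceptions import ValidationError
from viromarker.io import NON_RESPIRATORY, RESPIRATORY
from viromarker.stats import (benjamini_hochberg, cluster_targets,
                              compare_groups, normality_gate,
                              wilcoxon_rank_sum)


# -- normality gate --------------------------------------------------------

def test_gate_lognormal_rejects_normal_accepts():
    rng = np.random.default_rng(42)
    heavy = 10 ** rng.normal(-4, 1.5, size=50)
    assert normality_gate(heavy) == "non_normal"
    gaussian = rng.normal(0, 1, size=50)
    assert normality_gate(gaussian) == "normal"


def test_gate_degenerate_inputs():
    with pytest.raises(ValidationError):
        normality_gate([1.0, 2.0])
    with pytest.raises(ValidationError):
        normality_gate([3.0] * 10)


# -- rank-sum --------------------------------------------------------------

def test_ranksum_exact_small_case():
    """{1,2} vs {3,4}: 6 equally likely rank splits, two-sided p = 1/3."""
    _, p = wilcoxon_rank_sum([1, 2], [3, 4])
    assert p == pytest.approx(1 / 3)


def test_ranksum_identical_groups_p_one():
    _, p = wilcoxon_rank_sum([1, 2, 3, 3], [3, 1, 3, 2])
    assert p == 1.0
    _, p = wilcoxon_rank_sum([5.0] * 4, [5.0] * 6)
    assert p == 1.0


def test_ranksum_large_shift_tiny_p():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 50)
    b = rng.normal(5, 1, 50)
    _, p = wilcoxon_rank_sum(a, b)
    assert p < 1e-6


def test_ranksum_empty_group_errors():
    with pytest.raises(ValidationError):
        wilcoxon_rank_sum([], [1.0])


def _exact_twosided_p(a_vals, all_vals):
    """Enumeration oracle: distribution of U over all equally likely
    group-A choices of the pooled (distinct) values."""
    from itertools import combinations
    k = len(a_vals)
    u_obs = sum(1 for x in a_vals for y in all_vals
                if y not in a_vals and x > y)
    us = []
    for combo in combinations(all_vals, k):
        rest = [v for v in all_vals if v not in combo]
        us.append(sum(1 for x in combo for y in rest if x > y))
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


@pytest.mark.parametrize("n,k", [(4, 2), (5, 2), (6, 3)])
def test_ranksum_matches_enumeration_spot(n, k):
    from itertools import combinations
    values = list(range(1, n + 1))
    for a in combinations(values, k):
        b = [v for v in values if v not in a]
        _, p = wilcoxon_rank_sum(list(a), b)
        assert p == pytest.approx(_exact_twosided_p(a, values), abs=1e-12)


# -- BH correction ---------------------------------------------------------

def test_bh_hand_computed_fixture():
    adjusted = benjamini_hochberg([0.005, 0.01, 0.03, 0.04])
    assert np.allclose(adjusted, [0.02, 0.02, 0.04, 0.04])


def test_bh_trivial_cases():
    assert benjamini_hochberg([0.07]).tolist() == [0.07]
    assert benjamini_hochberg([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]
    with pytest.raises(ValidationError):
        benjamini_hochberg([0.5, 1.5])


@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                min_size=1, max_size=12),
       st.randoms(use_true_random=False))
def test_bh_permutation_equivariance_and_monotonicity(ps, rnd):
    adjusted = benjamini_hochberg(ps)
    assert np.all((adjusted >= 0) & (adjusted <= 1))
    perm = list(range(len(ps)))
    rnd.shuffle(perm)
    permuted = benjamini_hochberg([ps[i] for i in perm])
    assert np.allclose(permuted, adjusted[perm])
    # raising one raw p never lowers any adjusted p
    if ps:
        bumped = list(ps)
        i = perm[0]
        bumped[i] = min(1.0, bumped[i] + 0.1)
        assert np.all(benjamini_hochberg(bumped) >= adjusted - 1e-12)


# -- compare_groups --------------------------------------------------------

def _planted_matrix(seed, effect=100.0):
    rng = np.random.default_rng(seed)
    meta = make_metadata({"buccal_mucosa": 25, "stool": 25})
    base = 10 ** rng.normal(-5, 0.4, size=(2, 50))
    base[0, :25] *= effect          # target 'hit' high in oral
    return make_matrix(["hit", "null"], meta, np.clip(base, 0, 1)), meta


@pytest.mark.parametrize("seed", range(10))
def test_compare_groups_detects_planted_effect(seed):
    matrix, meta = _planted_matrix(seed)
    results = compare_groups(matrix, meta, ["hit", "null"],
                             [(RESPIRATORY, NON_RESPIRATORY)])
    by_target = {r.target_id: r for r in results}
    assert by_target["hit"].p_adjusted < 0.05
    assert by_target["hit"].mean_a > by_target["hit"].mean_b


def test_compare_groups_identical_groups_p_one():
    meta = make_metadata({"nasal": 6, "stool": 6})
    row = [1e-4, 2e-4, 3e-4] * 4
    matrix = make_matrix(["v"], meta, [row])
    (result,) = compare_groups(matrix, meta, ["v"],
                               [(RESPIRATORY, NON_RESPIRATORY)])
    assert result.p_raw == 1.0 and result.p_adjusted == 1.0


def test_compare_groups_family_of_one_adjusted_equals_raw():
    matrix, meta = _planted_matrix(0)
    (result,) = compare_groups(matrix, meta, ["hit"],
                               [(RESPIRATORY, NON_RESPIRATORY)])
    assert result.p_adjusted == result.p_raw


def test_compare_groups_bh_recomputable_from_raw():
    matrix, meta = _planted_matrix(3, effect=5.0)
    results = compare_groups(matrix, meta, ["hit", "null"],
                             [(RESPIRATORY, NON_RESPIRATORY)])
    raw = [r.p_raw for r in results]
    assert np.allclose([r.p_adjusted for r in results],
                       benjamini_hochberg(raw))


# -- clustering ------------------------------------------------------------

def test_cluster_identical_profiles_merge_at_zero():
    meta = make_metadata({"nasal": 3})
    matrix = make_matrix(["a", "b", "c"],
                         meta, [[0.1, 0.2, 0.0],
                                [0.1, 0.2, 0.0],
                                [0.9, 0.9, 0.9]])
    result = cluster_targets(matrix)
    assert result.linkage[0, 2] == 0.0          # first merge at height 0
    assert set(result.leaf_order) == {"a", "b", "c"}


def test_cluster_outlier_joins_last():
    """3x2 fixture with hand-checkable distances: the outlier merges last."""
    meta = make_metadata({"nasal": 2})
    matrix = make_matrix(["near1", "near2", "outlier"],
                         meta, [[0.00, 0.01],
                                [0.01, 0.00],
                                [1.00, 1.00]])
    result = cluster_targets(matrix)
    # final merge height ~ distance from the outlier to the near pair
    assert result.linkage[-1, 2] > result.linkage[0, 2]
    assert result.leaf_order[0] == "outlier" or result.leaf_order[-1] == "outlier"


def test_cluster_invariant_to_sample_permutation():
    rng = np.random.default_rng(5)
    meta = make_metadata({"nasal": 6})
    vals = rng.random((4, 6)) * 1e-3
    matrix = make_matrix(["a", "b", "c", "d"], meta, vals)
    perm = [3, 0, 5, 1, 4, 2]
    permuted = make_matrix(["a", "b", "c", "d"],
                           [meta[i] for i in perm], vals[:, perm])
    z1 = cluster_targets(matrix).linkage
    z2 = cluster_targets(permuted).linkage
    assert np.allclose(z1[:, 2], z2[:, 2])


def test_cluster_newick_parses_with_all_leaves():
    meta = make_metadata({"nasal": 4})
    rng = np.random.default_rng(1)
    matrix = make_matrix(["a", "b", "c", "d", "e"], meta,
                         rng.random((5, 4)) * 1e-2)
    result = cluster_targets(matrix)
    tree = Phylo.read(StringIO(result.newick), "newick")
    assert {leaf.name for leaf in tree.get_terminals()} == {"a", "b", "c",
                                                            "d", "e"}


def test_cluster_needs_two_targets():
    meta = make_metadata({"nasal": 2})
    with pytest.raises(ValidationError):
        cluster_targets(make_matrix(["a"], meta, [[0.1, 0.2]]))
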