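"""Group statistics: normality gate, rank tests with Benjamini-Hochberg
correction, and hierarchical clustering of target abundance profiles.

Abundance distributions in metagenomes are heavily zero-inflated and
right-skewed, so the workflow tests normality (Shapiro-Wilk) and applies
the unpaired two-sided Wilcoxon rank-sum (Mann-Whitney) test to
non-normal data, correcting families of comparisons with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .io import AbundanceMatrix, SampleMetadata, SiteGroup
from .profiles import detection


def normality_gate(values: Sequence[float], alpha: float = 0.05) -> str:
    """Shapiro-Wilk gate: 'non_normal' iff p < alpha.

    Needs n >= 3 and a non-constant sample (the test statistic is
    undefined for constant data; refused rather than guessed)."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValidationError("normality gate needs at least 3 observations")
    if np.ptp(values) == 0:
        raise ValidationError("normality gate undefined for constant data")
    _, p = sps.shapiro(values)
    return "non_normal" if p < alpha else "normal"


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]):
    """Unpaired two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null enumeration when both groups are small and tie-free;
    otherwise the tie-corrected normal approximation (no continuity
    correction, so identical groups give exactly p = 1).  Returns
    (U statistic of the first group, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return float(a.size * b.size / 2), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 8) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.min(p) < 0 or np.max(p) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class TestResult:
    """One group comparison: target, groups, test and BH-adjusted p."""

    target_id: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    normality: str             # normal | non_normal | not_testable
    statistic: float
    p_raw: float
    p_adjusted: float


def compare_groups(matrix: AbundanceMatrix,
                   metadata: Sequence[SampleMetadata],
                   targets: Sequence[str],
                   group_pairs: Sequence[tuple],
                   present_only: bool = True,
                   alpha: float = 0.05) -> list[TestResult]:
    """Rank-sum comparisons of target abundance between site-group pairs,
    BH-corrected across exactly the family given in this call.

    ``present_only`` drops samples where the target is absent before
    comparing (mirroring abundance summaries over detected samples); set
    False to compare over all samples including zeros.
    """
    site_of = {m.sample_id: m.body_site for m in metadata}
    group_idx = {}
    for pair in group_pairs:
        for g in pair:
            if g.name not in group_idx:
                idx = [j for j, sid in enumerate(matrix.sample_ids)
                       if site_of[sid] in g]
                if not idx:
                    raise ValidationError(f"site group {g.name!r} has no samples")
                group_idx[g.name] = np.array(idx, dtype=int)

    partial = []
    for target in targets:
        row = matrix.target_row(target)
        for ga, gb in group_pairs:
            va = row[group_idx[ga.name]]
            vb = row[group_idx[gb.name]]
            if present_only:
                va = va[va > 0]
                vb = vb[vb > 0]
            if va.size == 0 or vb.size == 0:
                partial.append((target, ga.name, gb.name, va, vb,
                                "not_testable", np.nan, np.nan))
                continue
            try:
                gate = normality_gate(np.concatenate([va, vb]), alpha)
            except ValidationError:
                gate = "not_testable"
            stat, p = wilcoxon_rank_sum(va, vb)
            partial.append((target, ga.name, gb.name, va, vb, gate, stat, p))

    raw = [p for *_, p in partial]
    tested = [i for i, p in enumerate(raw) if not np.isnan(p)]
    adjusted = np.full(len(raw), np.nan)
    if tested:
        adjusted[tested] = benjamini_hochberg([raw[i] for i in tested])

    results = []
    for (target, ga, gb, va, vb, gate, stat, p), p_adj in zip(partial, adjusted):
        results.append(TestResult(
            target_id=target, group_a=ga, group_b=gb,
            n_a=int(va.size), n_b=int(vb.size),
            mean_a=float(va.mean()) if va.size else np.nan,
            mean_b=float(vb.mean()) if vb.size else np.nan,
            normality=gate, statistic=float(stat), p_raw=float(p),
            p_adjusted=float(p_adj),
        ))
    return results


@dataclass(frozen=True)
class ClusteringResult:
    """Hierarchical clustering of target abundance profiles."""

    leaf_order: tuple           # target ids in dendrogram leaf order
    linkage: np.ndarray         # scipy linkage matrix
    newick: str


def _to_newick(node, names) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _to_newick(node.get_left(), names)
    right = _to_newick(node.get_right(), names)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:g},{right}:{dr:g})"


def cluster_targets(matrix: AbundanceMatrix,
                    linkage_method: str = "average") -> ClusteringResult:
    """Agglomerative clustering of targets on Euclidean distances between
    their abundance profiles across samples; deterministic leaf order
    given input order."""
    if len(matrix.target_ids) < 2:
        raise ValidationError("clustering needs at least 2 targets")
    dists = pdist(matrix.values, metric="euclidean")
    Z = hierarchy.linkage(dists, method=linkage_method)
    order = hierarchy.leaves_list(Z)
    tree = hierarchy.to_tree(Z)
    newick = _to_newick(tree, matrix.target_ids) + ";"
    return ClusteringResult(
        leaf_order=tuple(matrix.target_ids[i] for i in order),
        linkage=Z,
        newick=newick,
    )
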