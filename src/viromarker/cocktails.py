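"""Exhaustive evaluation of 2- and 3-member biomarker cocktails.

A cocktail is detected in a sample iff ANY member is detected (union
semantics); its abundance in a sample is the sum of member abundances.
Cocktails are ranked by the difference between respiratory and
non-respiratory union prevalence (descending), with the full table and
the Pareto front under (maximize respiratory, minimize non-respiratory)
always reported so other criteria can be applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import NON_RESPIRATORY, RESPIRATORY, AbundanceMatrix, SampleMetadata, SiteGroup


@dataclass(frozen=True)
class Cocktail:
    """A 2- or 3-member marker set with per-group union-prevalence and
    mean summed-abundance summaries."""

    members: tuple
    prevalence: dict            # group name -> union prevalence fraction
    mean_abundance: dict        # group name -> mean summed abundance (detected samples)
    score: float
    pareto: bool = False


def enumerate_cocktails(candidates: Sequence[str],
                        sizes: Sequence[int] = (2, 3)) -> list[tuple]:
    """All size-k member tuples for each k, members sorted, list in
    lexicographic order.  Sizes larger than the candidate pool are
    skipped with a warning."""
    candidates = sorted(set(candidates))
    out: list[tuple] = []
    for k in sorted(sizes):
        if k > len(candidates):
            warnings.warn(f"only {len(candidates)} candidates; "
                          f"skipping size-{k} cocktails")
            continue
        out.extend(combinations(candidates, k))
    return out


def cocktail_detection(members: Sequence[str],
                       matrix: AbundanceMatrix,
                       threshold: float = 0.0) -> np.ndarray:
    """Binary vector over samples: 1 iff any member's abundance > threshold."""
    missing = [m for m in members if m not in matrix.target_ids]
    if missing:
        raise ValidationError(f"cocktail members not in matrix: {missing}")
    rows = np.stack([matrix.target_row(m) for m in members])
    return (rows > threshold).any(axis=0).astype(int)


def cocktail_abundance(members: Sequence[str],
                       matrix: AbundanceMatrix) -> np.ndarray:
    """Per-sample summed abundance over the cocktail members."""
    missing = [m for m in members if m not in matrix.target_ids]
    if missing:
        raise ValidationError(f"cocktail members not in matrix: {missing}")
    return np.stack([matrix.target_row(m) for m in members]).sum(axis=0)


def _pareto_front(points: list[tuple]) -> list[bool]:
    """Non-dominated flags under (maximize first, minimize second)."""
    flags = []
    for i, (ri, ni) in enumerate(points):
        dominated = any(
            (rj >= ri and nj <= ni and (rj > ri or nj < ni))
            for j, (rj, nj) in enumerate(points) if j != i)
        flags.append(not dominated)
    return flags


def rank_cocktails(matrix: AbundanceMatrix,
                   metadata: Sequence[SampleMetadata],
                   candidates: Sequence[str],
                   sizes: Sequence[int] = (2, 3),
                   groups: Sequence[SiteGroup] = (RESPIRATORY, NON_RESPIRATORY),
                   threshold: float = 0.0,
                   include_zeros: bool = False) -> list[Cocktail]:
    """Enumerate, summarise and rank every cocktail.

    Default objective: respiratory minus non-respiratory union
    prevalence, descending; ties by higher respiratory prevalence, then
    lexicographic members.  ``include_zeros`` switches the group
    abundance summary from mean over detected samples to mean over all
    samples in the group.
    """
    group_names = [g.name for g in groups]
    for needed in ("respiratory", "non_respiratory"):
        if needed not in group_names:
            raise ValidationError(f"rank_cocktails needs the {needed!r} group")
    site_of = {m.sample_id: m.body_site for m in metadata}
    group_idx = {
        g.name: np.array([j for j, sid in enumerate(matrix.sample_ids)
                          if site_of[sid] in g], dtype=int)
        for g in groups
    }
    for name, idx in group_idx.items():
        if idx.size == 0:
            raise ValidationError(f"site group {name!r} has no samples")

    cocktails = []
    for members in enumerate_cocktails(candidates, sizes):
        det = cocktail_detection(members, matrix, threshold)
        ab = cocktail_abundance(members, matrix)
        prev = {}
        mean_ab = {}
        for name, idx in group_idx.items():
            hits = det[idx]
            prev[name] = int(hits.sum()) / len(idx)
            if include_zeros:
                mean_ab[name] = float(ab[idx].mean())
            else:
                mean_ab[name] = (float(ab[idx][hits == 1].mean())
                                 if hits.any() else 0.0)
        score = prev["respiratory"] - prev["non_respiratory"]
        cocktails.append(Cocktail(members, prev, mean_ab, score))

    points = [(c.prevalence["respiratory"], c.prevalence["non_respiratory"])
              for c in cocktails]
    flags = _pareto_front(points)
    cocktails = [Cocktail(c.members, c.prevalence, c.mean_abundance, c.score, f)
                 for c, f in zip(cocktails, flags)]
    cocktails.sort(key=lambda c: (-c.score, -c.prevalence["respiratory"],
                                  c.members))
    return cocktails


def cocktail_table(cocktails: Sequence[Cocktail]) -> pd.DataFrame:
    """Flat ranked table (one row per cocktail) for writing to TSV."""
    rows = []
    for rank, c in enumerate(cocktails, start=1):
        row = {"rank": rank, "members": "+".join(c.members),
               "size": len(c.members), "score": c.score, "pareto": c.pareto}
        for g, p in c.prevalence.items():
            row[f"prevalence_{g}"] = p
        for g, a in c.mean_abundance.items():
            row[f"mean_abundance_{g}"] = a
        rows.append(row)
    return pd.DataFrame(rows)
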