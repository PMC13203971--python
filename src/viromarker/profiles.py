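"""Relative abundance, detection and group prevalence.

Relative abundance of a target in a sample is the ratio of basepairs
mapped to the target over total QC'd basepairs in the sample.  A target
counts as *present* in a sample iff its abundance is strictly greater
than the detection threshold (default 0, i.e. any mapped basepairs).
Prevalence of a target in a site group is the detected-sample count over
the group size, computed from integer counts so the final float is the
correctly rounded value of the exact rational.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import AbundanceMatrix, MappingStats, SampleMetadata, SiteGroup


def relative_abundance(mapped_basepairs: int, total_basepairs: int) -> float:
    """mapped/total as a fraction in [0, 1]."""
    if total_basepairs <= 0:
        raise ValidationError(
            "total_basepairs must be positive; a sample with no basepairs has "
            "undefined relative abundances"
        )
    if mapped_basepairs < 0:
        raise ValidationError("mapped_basepairs must be non-negative")
    if mapped_basepairs > total_basepairs:
        raise ValidationError(
            f"mapped_basepairs ({mapped_basepairs}) exceeds total_basepairs "
            f"({total_basepairs})"
        )
    return mapped_basepairs / total_basepairs


def build_matrix(stats: Iterable[MappingStats],
                 metadata: Sequence[SampleMetadata]) -> AbundanceMatrix:
    """Assemble an abundance matrix from mapped-basepair counts.

    Samples follow metadata order; targets follow first appearance in
    ``stats``.  Pairs absent from ``stats`` are exactly 0.  Duplicate
    (target, sample) pairs and sample ids missing from metadata are
    refused.
    """
    stats = list(stats)
    totals = {m.sample_id: m.total_basepairs for m in metadata}
    unknown = sorted({s.sample_id for s in stats} - set(totals))
    if unknown:
        raise ValidationError(f"sample ids not in metadata: {unknown}")

    targets: list[str] = []
    t_index: dict[str, int] = {}
    for s in stats:
        if s.target_id not in t_index:
            t_index[s.target_id] = len(targets)
            targets.append(s.target_id)
    sample_ids = [m.sample_id for m in metadata]
    s_index = {sid: j for j, sid in enumerate(sample_ids)}

    values = np.zeros((len(targets), len(sample_ids)))
    seen = set()
    for s in stats:
        key = (s.target_id, s.sample_id)
        if key in seen:
            raise ValidationError(f"duplicate mapping-stat row for {key}")
        seen.add(key)
        values[t_index[s.target_id], s_index[s.sample_id]] = relative_abundance(
            s.mapped_basepairs, totals[s.sample_id]
        )
    return AbundanceMatrix(targets, sample_ids, values)


def detection(matrix: AbundanceMatrix, threshold: float = 0.0) -> np.ndarray:
    """Binary presence matrix: 1 iff abundance strictly exceeds threshold."""
    return (matrix.values > threshold).astype(int)


class PrevalenceTable:
    """Per-target, per-site-group detection prevalence.

    Backed by integer detected-sample counts and group sizes, so each
    prevalence is the float of an exact rational count/n.
    """

    def __init__(self, counts: pd.DataFrame, group_sizes: dict[str, int]):
        self.counts = counts                # targets x groups, ints
        self.group_sizes = dict(group_sizes)

    @property
    def target_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def group_names(self) -> list[str]:
        return list(self.counts.columns)

    def prevalence(self, target_id: str, group: str) -> float:
        return int(self.counts.at[target_id, group]) / self.group_sizes[group]

    def n_samples(self, group: str) -> int:
        return self.group_sizes[group]

    def group_column(self, group: str) -> pd.Series:
        """Prevalence fractions for every target in one group."""
        return self.counts[group] / self.group_sizes[group]

    def to_frame(self) -> pd.DataFrame:
        """Wide table of prevalence fractions (targets x groups)."""
        return self.counts.div(pd.Series(self.group_sizes))

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: target_id, group, prevalence, n_samples."""
        rows = [
            (t, g, self.prevalence(t, g), self.group_sizes[g])
            for t in self.target_ids for g in self.group_names
        ]
        return pd.DataFrame(rows, columns=["target_id", "group", "prevalence",
                                           "n_samples"])


def group_prevalence(matrix: AbundanceMatrix,
                     metadata: Sequence[SampleMetadata],
                     groups: Sequence[SiteGroup],
                     threshold: float = 0.0) -> PrevalenceTable:
    """Detection prevalence of every target in every site group."""
    site_of = {m.sample_id: m.body_site for m in metadata}
    missing = sorted(set(matrix.sample_ids) - set(site_of))
    if missing:
        raise ValidationError(f"matrix samples not in metadata: {missing}")
    detected = detection(matrix, threshold)

    counts = {}
    sizes = {}
    for group in groups:
        members = [j for j, sid in enumerate(matrix.sample_ids)
                   if site_of[sid] in group]
        if not members:
            raise ValidationError(f"site group {group.name!r} has no samples")
        sizes[group.name] = len(members)
        counts[group.name] = detected[:, members].sum(axis=1)
    frame = pd.DataFrame(counts, index=matrix.target_ids).astype(int)
    return PrevalenceTable(frame, sizes)
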