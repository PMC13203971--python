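"""Logical exclusion filters producing the three nested feature sets.

A vOTU is *nonspecific* if it is present in strictly more than 80% of
stool samples or strictly more than 80% of skin samples; it is *rare*
if it is present in strictly less than 20% of respiratory samples
(pooled nasal + oral by default).  Feature set 1 is every vOTU, set 2
removes nonspecific vOTUs, set 3 additionally removes rare vOTUs, so
set3 is a subset of set2 is a subset of set1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .exceptions import ValidationError
from .io import (NASAL, NON_RESPIRATORY, ORAL, RESPIRATORY, SKIN, STOOL,
                 AbundanceMatrix, SampleMetadata)
from .profiles import PrevalenceTable, group_prevalence

NONSPECIFIC_THRESHOLD = 0.80
RARE_THRESHOLD = 0.20


def _require_groups(prevalence: PrevalenceTable, names: Sequence[str]) -> None:
    missing = [n for n in names if n not in prevalence.group_names]
    if missing:
        raise ValidationError(f"prevalence table lacks group(s) {missing}")


def flag_nonspecific(prevalence: PrevalenceTable,
                     threshold: float = NONSPECIFIC_THRESHOLD) -> set[str]:
    """vOTUs present in > threshold of stool samples OR > threshold of
    skin samples (strict inequality: exactly 80% is kept)."""
    _require_groups(prevalence, ("stool", "skin"))
    stool = prevalence.group_column("stool")
    skin = prevalence.group_column("skin")
    return set(stool.index[(stool > threshold) | (skin > threshold)])


def flag_rare(prevalence: PrevalenceTable,
              threshold: float = RARE_THRESHOLD,
              scope: str = "pooled") -> set[str]:
    """vOTUs present in < threshold of respiratory samples.

    ``scope='pooled'`` uses the pooled respiratory (nasal + oral) group;
    ``scope='either_site_group'`` requires the prevalence to be below the
    threshold in both the nasal and the oral group separately.
    """
    if scope == "pooled":
        _require_groups(prevalence, ("respiratory",))
        resp = prevalence.group_column("respiratory")
        return set(resp.index[resp < threshold])
    if scope == "either_site_group":
        _require_groups(prevalence, ("nasal", "oral"))
        nasal = prevalence.group_column("nasal")
        oral = prevalence.group_column("oral")
        return set(nasal.index[(nasal < threshold) & (oral < threshold)])
    raise ValidationError(f"unknown rare_scope {scope!r}")


@dataclass(frozen=True)
class FeatureSet:
    """One of the three nested vOTU feature sets, with removal bookkeeping."""

    label: str                     # all | nonspecific_removed | rare_nonspecific_removed
    votu_ids: tuple
    provenance: dict

    def __len__(self):
        return len(self.votu_ids)

    def __contains__(self, votu_id: str) -> bool:
        return votu_id in set(self.votu_ids)


class FeatureSets(NamedTuple):
    all: FeatureSet
    nonspecific_removed: FeatureSet
    rare_nonspecific_removed: FeatureSet

    def __iter__(self):
        return iter((self.all, self.nonspecific_removed,
                     self.rare_nonspecific_removed))


def build_feature_sets(matrix: AbundanceMatrix,
                       metadata: Sequence[SampleMetadata],
                       nonspecific_threshold: float = NONSPECIFIC_THRESHOLD,
                       rare_threshold: float = RARE_THRESHOLD,
                       rare_scope: str = "pooled",
                       detection_threshold: float = 0.0) -> FeatureSets:
    """The three nested feature sets, preserving matrix target order."""
    groups = [STOOL, SKIN, RESPIRATORY, NASAL, ORAL, NON_RESPIRATORY]
    prevalence = group_prevalence(matrix, metadata, groups, detection_threshold)
    nonspecific = flag_nonspecific(prevalence, nonspecific_threshold)
    rare = flag_rare(prevalence, rare_threshold, rare_scope)

    all_ids = tuple(matrix.target_ids)
    set2 = tuple(t for t in all_ids if t not in nonspecific)
    set3 = tuple(t for t in set2 if t not in rare)

    prov1 = {"n_total": len(all_ids), "n_removed": 0}
    prov2 = {"n_total": len(all_ids), "n_removed_nonspecific": len(nonspecific),
             "n_kept": len(set2)}
    removed3 = nonspecific | (rare & set(all_ids))
    prov3 = {"n_total": len(all_ids), "n_removed_nonspecific": len(nonspecific),
             "n_removed_rare_or_nonspecific": len(removed3), "n_kept": len(set3)}

    return FeatureSets(
        FeatureSet("all", all_ids, prov1),
        FeatureSet("nonspecific_removed", set2, prov2),
        FeatureSet("rare_nonspecific_removed", set3, prov3),
    )
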