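"""Validation-side computations: qPCR detection calls and prevalence,
coding-density scoring, and the OVB/NVB/NOVB naming convention.

Detection semantics: a target is present in a sample iff its mean
replicate Ct is strictly lower than the mean no-template-control (NTC)
Ct for that target, i.e. it amplified earlier than the negative control.
The alternative literal reading (present iff mean Ct strictly greater
than the NTC) is available as ``rule="literal_methods"`` but inverts
ordinary qPCR semantics and is not the default.

Coding density of a vOTU is the fraction of its total contig length
covered by ORFs, with overlapping intervals merged so the density never
exceeds 1.  Multi-contig vOTUs aggregate covered and total basepairs
over their contigs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import AbundanceMatrix, CtRecord, GeneAnnotation, SampleMetadata
from .profiles import PrevalenceTable

DETECTION_RULES = ("earlier_than_ntc", "literal_methods")


def mean_ct(record: CtRecord) -> float:
    """Arithmetic mean of replicate Cts (45-sentinels included as 45)."""
    if not record.replicate_cts:
        raise ValidationError("empty replicate list")
    return float(np.mean(record.replicate_cts))


def detection_call(mean_ct_value: float, ntc_mean: float,
                   rule: str = "earlier_than_ntc") -> bool:
    """Present iff the sample amplified strictly earlier than the NTC
    (mean Ct < mean NTC); equal means count as absent."""
    for v in (mean_ct_value, ntc_mean):
        if not np.isfinite(v) or v > 45:
            raise ValidationError(f"Ct value {v} must be finite and <= 45")
    if rule == "earlier_than_ntc":
        return mean_ct_value < ntc_mean
    if rule == "literal_methods":
        return mean_ct_value > ntc_mean
    raise ValidationError(f"unknown detection rule {rule!r}")


@dataclass(frozen=True)
class DetectionCall:
    sample_id: str
    sample_type: str
    target_id: str
    mean_ct: float
    ntc_mean_ct: float
    present: bool


def _ntc_means(records: Sequence[CtRecord],
               ntc: Mapping[str, float] | None) -> dict[str, float]:
    if ntc is not None:
        return dict(ntc)
    means: dict[str, list] = {}
    for r in records:
        if r.is_ntc:
            means.setdefault(r.target_id, []).extend(r.replicate_cts)
    return {t: float(np.mean(v)) for t, v in means.items()}


def detection_calls(records: Sequence[CtRecord],
                    ntc: Mapping[str, float] | None = None,
                    rule: str = "earlier_than_ntc") -> list[DetectionCall]:
    """Per-(sample, target) detection calls; NTC means are taken from
    ``ntc`` or pooled from the NTC-flagged records."""
    ntc_mean = _ntc_means(records, ntc)
    calls = []
    for r in records:
        if r.is_ntc:
            continue
        if r.target_id not in ntc_mean:
            raise ValidationError(f"no NTC available for target {r.target_id!r}")
        m = mean_ct(r)
        calls.append(DetectionCall(
            sample_id=r.sample_id, sample_type=r.sample_type,
            target_id=r.target_id, mean_ct=m,
            ntc_mean_ct=ntc_mean[r.target_id],
            present=detection_call(m, ntc_mean[r.target_id], rule),
        ))
    return calls


def ct_prevalence(records: Sequence[CtRecord],
                  ntc: Mapping[str, float] | None = None,
                  rule: str = "earlier_than_ntc") -> pd.DataFrame:
    """Percent of samples present per target and sample type (0-100
    scale).  Sample types with zero samples are omitted with a warning."""
    calls = detection_calls(records, ntc, rule)
    if not calls:
        warnings.warn("no sample records; prevalence table is empty")
        return pd.DataFrame(columns=["target_id", "sample_type",
                                     "percent_present", "n_samples"])
    frame = pd.DataFrame([(c.target_id, c.sample_type, c.present)
                          for c in calls],
                         columns=["target_id", "sample_type", "present"])
    grouped = frame.groupby(["target_id", "sample_type"], sort=True)
    out = grouped.agg(
        percent_present=("present", lambda s: 100.0 * int(s.sum()) / len(s)),
        n_samples=("present", "size"),
    ).reset_index()
    return out


# --------------------------------------------------------------------------
# coding density

def merge_intervals(intervals: Iterable[tuple]) -> list[tuple]:
    """Merge overlapping or adjacent 1-based inclusive intervals."""
    ivals = sorted(intervals)
    merged: list[list] = []
    for start, end in ivals:
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(m) for m in merged]


def coding_density(annotations: Sequence[GeneAnnotation] | GeneAnnotation) -> float:
    """ORF-covered basepairs over total contig length, overlaps merged.

    A multi-contig vOTU passes all of its contigs; covered and total
    lengths are aggregated before dividing.
    """
    if isinstance(annotations, GeneAnnotation):
        annotations = [annotations]
    if not annotations:
        raise ValidationError("no annotations given")
    covered = 0
    total = 0
    for a in annotations:
        total += a.contig_length
        covered += sum(e - s + 1 for s, e in merge_intervals(a.orf_intervals))
    return covered / total


# --------------------------------------------------------------------------
# naming

@dataclass(frozen=True)
class BiomarkerName:
    """An OVB/NVB/NOVB-style name with a low-prevalence caveat flag."""

    name: str
    low_prevalence: bool = False

    def __str__(self):
        return self.name


def name_biomarker(oral_prevalence: float, nasal_prevalence: float,
                   rank: int, tau: float = 0.20) -> BiomarkerName:
    """Prefix by where prevalence clears tau: NOVB (both oral and nasal),
    OVB (oral only), NVB (nasal only); below tau everywhere the argmax
    site decides and the name is flagged low-prevalence."""
    oral_hit = oral_prevalence >= tau
    nasal_hit = nasal_prevalence >= tau
    if oral_hit and nasal_hit:
        prefix, flag = "NOVB", False
    elif oral_hit:
        prefix, flag = "OVB", False
    elif nasal_hit:
        prefix, flag = "NVB", False
    else:
        prefix = "OVB" if oral_prevalence >= nasal_prevalence else "NVB"
        flag = True
    return BiomarkerName(f"{prefix}_{rank}", flag)


def name_candidates(prevalence: PrevalenceTable,
                    matrix: AbundanceMatrix,
                    metadata: Sequence[SampleMetadata],
                    candidates: Sequence[str],
                    tau: float = 0.20) -> dict[str, BiomarkerName]:
    """Names for a candidate list, ranked by descending respiratory
    prevalence with mean respiratory abundance as the tie-breaker."""
    for needed in ("oral", "nasal", "respiratory"):
        if needed not in prevalence.group_names:
            raise ValidationError(f"prevalence table lacks group {needed!r}")
    resp_sites = {"nasal", "buccal_mucosa", "saliva", "throat"}
    site_of = {m.sample_id: m.body_site for m in metadata}
    resp_idx = [j for j, sid in enumerate(matrix.sample_ids)
                if site_of[sid] in resp_sites]

    def sort_key(votu):
        resp_prev = prevalence.prevalence(votu, "respiratory")
        mean_ab = float(matrix.target_row(votu)[resp_idx].mean())
        return (-resp_prev, -mean_ab, votu)

    # ranks count within each prefix family (OVB_1..,NVB_1..,NOVB_1..)
    names = {}
    counters: dict[str, int] = {}
    for votu in sorted(candidates, key=sort_key):
        provisional = name_biomarker(
            prevalence.prevalence(votu, "oral"),
            prevalence.prevalence(votu, "nasal"), 1, tau)
        prefix = provisional.name.rsplit("_", 1)[0]
        counters[prefix] = counters.get(prefix, 0) + 1
        names[votu] = BiomarkerName(f"{prefix}_{counters[prefix]}",
                                    provisional.low_prevalence)
    return names
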