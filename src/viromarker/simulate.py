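"""Synthetic multi-body-site cohorts with planted viral-marker structure.

The generator emulates the qualitative structure of body-site-resolved
vOTU abundance profiles: clusters of oral-specific, nasal-specific,
nasal+oral, skin-associated, stool-associated, broadly nonspecific and
rare-respiratory viruses on top of low-prevalence background, with
zero-inflated log-normal relative abundances.  Presence of a vOTU in a
sample is Bernoulli with a per-(class, site) probability; conditional on
presence the abundance is 10**Normal(mu, sd) truncated to (0, 1]; absent
entries are exactly 0.

Default marker classes are strong (prevalence 0.9 in their target sites,
0.05 elsewhere) over 30 samples per site, so the planted signal is
recoverable by the downstream filter -> model-grid -> consensus pipeline.
Default conditional abundances put marker means around 1e-5..1e-4
(fractions), the scale reported for respiratory viral biomarkers in
human metagenomes.

Randomness: a single global seed drives per-component substreams keyed
by fixed component labels, so draws for one component never depend on
the order in which other components are generated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ValidationError
from .io import (BODY_SITES, AbundanceMatrix, CtRecord, GeneAnnotation,
                 SampleMetadata)

MARKER_CLASSES = (
    "oral_marker", "nasal_marker", "nasal_oral_marker", "skin_assoc",
    "stool_assoc", "nonspecific", "rare_respiratory", "background",
)

#: classes planted as true respiratory markers (the recovery targets)
RESPIRATORY_MARKER_CLASSES = ("oral_marker", "nasal_marker", "nasal_oral_marker")

_ORAL_SITES = ("buccal_mucosa", "saliva", "throat")


@dataclass(frozen=True)
class MarkerClassSpec:
    """Per-site presence probabilities and a conditional log10-normal
    abundance model for one planted vOTU class."""

    class_name: str
    prevalence: Mapping[str, float]          # body_site -> probability
    log10_mean: float                        # of relative abundance | present
    log10_sd: float

    def __post_init__(self):
        for site, p in self.prevalence.items():
            if site not in BODY_SITES:
                raise ValidationError(f"{self.class_name}: unknown site {site!r}")
            if not (0.0 <= p <= 1.0):
                raise ValidationError(
                    f"{self.class_name}: prevalence {p} for {site} outside [0, 1]"
                )
        if self.log10_sd < 0:
            raise ValidationError(f"{self.class_name}: negative log10_sd")

    def site_prevalence(self, site: str) -> float:
        return float(self.prevalence.get(site, 0.0))


def _spread(target_sites: Mapping[str, float], elsewhere: float) -> dict[str, float]:
    return {site: target_sites.get(site, elsewhere) for site in BODY_SITES}


def default_class_specs() -> dict[str, MarkerClassSpec]:
    """The default planted-class catalogue.

    Marker classes are strongly site-specific (0.9 in target sites, 0.05
    elsewhere).  Skin- and stool-associated classes exceed the 80%
    nonspecific threshold in their site and leak moderately into nasal
    resp. oral samples, mirroring the skin~nasal and stool~oral community
    overlap seen in body-site surveys.  The broadly nonspecific class is
    highly prevalent in both stool and skin and common everywhere; the
    rare-respiratory class sits below the 20% rare threshold.
    """
    oral = {s: 0.9 for s in _ORAL_SITES}
    return {
        "oral_marker": MarkerClassSpec(
            "oral_marker", _spread(oral, 0.05), -4.3, 0.6),
        "nasal_marker": MarkerClassSpec(
            "nasal_marker", _spread({"nasal": 0.9}, 0.05), -4.0, 0.7),
        "nasal_oral_marker": MarkerClassSpec(
            "nasal_oral_marker", _spread({"nasal": 0.9, **oral}, 0.05), -4.2, 0.6),
        "skin_assoc": MarkerClassSpec(
            "skin_assoc", _spread({"skin": 0.9, "nasal": 0.3}, 0.05), -4.3, 0.7),
        "stool_assoc": MarkerClassSpec(
            "stool_assoc",
            _spread({"stool": 0.9, **{s: 0.3 for s in _ORAL_SITES}}, 0.05),
            -4.3, 0.7),
        "nonspecific": MarkerClassSpec(
            "nonspecific", _spread({"stool": 0.9, "skin": 0.9}, 0.6), -4.0, 0.8),
        "rare_respiratory": MarkerClassSpec(
            "rare_respiratory",
            _spread({"nasal": 0.12, **{s: 0.12 for s in _ORAL_SITES}}, 0.02),
            -5.0, 0.6),
        "background": MarkerClassSpec(
            "background", _spread({}, 0.3), -5.5, 0.8),
    }


DEFAULT_N_VOTUS = {
    "oral_marker": 5,
    "nasal_marker": 4,
    "nasal_oral_marker": 4,
    "skin_assoc": 5,
    "stool_assoc": 5,
    "nonspecific": 6,
    "rare_respiratory": 5,
    "background": 14,
}

DEFAULT_N_SAMPLES = {site: 30 for site in BODY_SITES}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort dimensions, class catalogue and the global seed."""

    n_samples: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_N_SAMPLES))
    n_votus: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_N_VOTUS))
    class_specs: Mapping[str, MarkerClassSpec] = field(default_factory=default_class_specs)
    seed: int = 0
    total_bp_log10_mean: float = 9.5         # ~3 Gbp QC'd per metagenome
    total_bp_log10_sd: float = 0.35
    subject_effect_sd: float = 0.0           # optional within-subject hook, off by default

    def __post_init__(self):
        for site in self.n_samples:
            if site not in BODY_SITES:
                raise ValidationError(f"unknown site {site!r} in n_samples")
        for cls in self.n_votus:
            if cls not in self.class_specs:
                raise ValidationError(f"class {cls!r} has no MarkerClassSpec")
        resp = {"nasal", *_ORAL_SITES}
        if not (any(self.n_samples.get(s, 0) >= 2 for s in resp)
                and any(self.n_samples.get(s, 0) >= 2 for s in ("stool", "skin"))):
            raise ValidationError(
                "need >= 2 samples in at least one respiratory and one "
                "non-respiratory site"
            )

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


def _component_rng(seed: int, label: str) -> np.random.Generator:
    """Substream keyed by (seed, stable hash of label): draws for one
    component are unaffected by which other components exist."""
    key = [ord(c) for c in label]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


def generate_cohort(config: CohortConfig):
    """Draw a cohort: (metadata list, AbundanceMatrix, truth table).

    The truth table maps each generated vOTU id to its planted class
    name.  Fully reproducible from ``config.seed``.
    """
    sites = [s for s in BODY_SITES if config.n_samples.get(s, 0) > 0]
    meta_rng = _component_rng(config.seed, "metadata")
    metadata: list[SampleMetadata] = []
    for site in sites:
        for j in range(config.n_samples[site]):
            total = int(round(10 ** meta_rng.normal(config.total_bp_log10_mean,
                                                    config.total_bp_log10_sd)))
            metadata.append(SampleMetadata(
                sample_id=f"{site}_{j + 1:03d}",
                body_site=site,
                total_basepairs=max(total, 1),
            ))
    site_of = np.array([m.body_site for m in metadata])
    n_samples = len(metadata)

    votu_ids: list[str] = []
    truth: dict[str, str] = {}
    blocks = []
    counter = 0
    for cls in config.n_votus:               # insertion order fixes vOTU ids
        spec = config.class_specs[cls]
        n = config.n_votus[cls]
        if n <= 0:
            continue
        if all(spec.site_prevalence(s) == 0.0 for s in sites):
            warnings.warn(f"class {cls!r} has zero prevalence at every "
                          "generated site; its vOTUs will be all-zero")
        rng = _component_rng(config.seed, f"class:{cls}")
        p_per_sample = np.array([spec.site_prevalence(s) for s in site_of])
        present = rng.random((n, n_samples)) < p_per_sample
        log10_ab = rng.normal(spec.log10_mean, spec.log10_sd, size=(n, n_samples))
        abundances = np.where(present, np.minimum(10.0 ** log10_ab, 1.0), 0.0)
        blocks.append(abundances)
        for _ in range(n):
            counter += 1
            vid = f"vOTU_{counter:04d}"
            votu_ids.append(vid)
            truth[vid] = cls

    values = np.vstack(blocks) if blocks else np.zeros((0, n_samples))
    matrix = AbundanceMatrix(votu_ids, [m.sample_id for m in metadata], values)
    return metadata, matrix, truth


def write_truth_table(truth: Mapping[str, str], path) -> None:
    import pandas as pd
    pd.DataFrame(sorted(truth.items()), columns=["votu_id", "class_name"]).to_csv(
        path, sep="\t", index=False)


# --------------------------------------------------------------------------
# qPCR dataset

def generate_ct_dataset(n_samples: Mapping[str, int],
                        targets: Sequence[str],
                        detection_prob: Mapping[str, Mapping[str, float]],
                        ct_mean: float = 30.0,
                        ct_sd: float = 2.0,
                        ntc_ct: float = 45.0,
                        n_replicates: int = 2,
                        seed: int = 0) -> list[CtRecord]:
    """Simulate replicate qPCR threshold cycles plus NTC records.

    ``n_samples`` maps sample_type (e.g. saliva, nasal_swab) to a count;
    ``detection_prob[target][sample_type]`` is the chance a sample carries
    the target.  Detected reactions draw replicate Cts from
    Normal(ct_mean, ct_sd) capped strictly below ``ntc_ct``; non-detected
    reactions record the 45-cycle no-amplification sentinel.  One NTC
    record per target is emitted with all replicates at ``ntc_ct``.
    """
    if ntc_ct > 45:
        raise ValidationError("ntc_ct cannot exceed the 45-cycle programme")
    records: list[CtRecord] = []
    for target in targets:
        records.append(CtRecord("NTC", "ntc", target,
                                tuple([float(ntc_ct)] * n_replicates), is_ntc=True))
    for sample_type in n_samples:
        rng = _component_rng(seed, f"ct:{sample_type}")
        for j in range(n_samples[sample_type]):
            sid = f"{sample_type}_{j + 1:03d}"
            for target in targets:
                p = float(detection_prob.get(target, {}).get(sample_type, 0.0))
                if rng.random() < p:
                    cts = np.minimum(rng.normal(ct_mean, ct_sd, n_replicates),
                                     ntc_ct - 1.0)
                    cts = np.maximum(cts, 1.0)
                else:
                    cts = np.full(n_replicates, 45.0)
                records.append(CtRecord(sid, sample_type, target,
                                        tuple(float(c) for c in cts)))
    return records


# --------------------------------------------------------------------------
# gene annotations

def generate_gene_annotations(contig_id: str,
                              contig_length: int,
                              target_density: float,
                              seed: int = 0,
                              mean_orf_length: int = 600) -> GeneAnnotation:
    """Non-overlapping ORF intervals whose total length is
    round(target_density * contig_length) within +/- 1 bp."""
    if not (0.0 <= target_density <= 1.0):
        raise ValidationError("target_density must be in [0, 1]")
    if contig_length <= 0:
        raise ValidationError("contig_length must be positive")
    total = int(round(target_density * contig_length))
    if total == 0:
        return GeneAnnotation(contig_id, contig_length, ())
    if total >= contig_length:
        return GeneAnnotation(contig_id, contig_length, ((1, contig_length),))

    rng = _component_rng(seed, f"genes:{contig_id}")
    k = max(1, int(round(total / mean_orf_length)))
    # split `total` coding bp into k pieces of >= 1 bp
    cuts = np.sort(rng.choice(np.arange(1, total), size=k - 1, replace=False)) \
        if k > 1 else np.array([], dtype=int)
    orf_lengths = np.diff(np.concatenate(([0], cuts, [total])))
    # split the remaining bp into k+1 gaps (first/last may be 0)
    slack = contig_length - total
    gap_cuts = np.sort(rng.integers(0, slack + 1, size=k))
    gaps = np.diff(np.concatenate(([0], gap_cuts, [slack])))

    intervals = []
    pos = 1 + int(gaps[0])
    for length, gap in zip(orf_lengths, gaps[1:]):
        start = pos
        end = start + int(length) - 1
        intervals.append((start, end))
        pos = end + 1 + int(gap)
    annotation = GeneAnnotation(contig_id, contig_length, tuple(intervals))
    covered = sum(e - s + 1 for s, e in intervals)
    if abs(covered - total) > 1:
        raise ValidationError("internal packing error")   # defensive; unreachable
    return annotation
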