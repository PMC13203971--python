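"""Shared domain types and readers/writers for the tabular and sequence
formats the pipeline touches.

Abundances are stored internally as *fractions* in [0, 1]; report layers
multiply by 100 when a percentage is wanted.  Body-site labels are drawn
from the six-site vocabulary of the healthy-human cohort (anterior nares,
buccal mucosa, saliva, throat, stool, retroauricular-crease skin) and are
normalised case-insensitively through an extensible alias map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .exceptions import FormatError, ValidationError

# --------------------------------------------------------------------------
# body sites and site groups

BODY_SITES = ("nasal", "buccal_mucosa", "saliva", "throat", "stool", "skin")

#: default, user-extensible alias map (keys lower-case, spaces/underscores folded)
SITE_ALIASES = {
    "anterior nares": "nasal",
    "anterior_nares": "nasal",
    "nares": "nasal",
    "nasal": "nasal",
    "buccal mucosa": "buccal_mucosa",
    "buccal_mucosa": "buccal_mucosa",
    "saliva": "saliva",
    "throat": "throat",
    "stool": "stool",
    "feces": "stool",
    "skin": "skin",
    "retroauricular crease": "skin",
    "retroauricular_crease": "skin",
}


def normalize_body_site(label: str, aliases: Mapping[str, str] | None = None) -> str:
    """Map a free-text body-site label onto the canonical six-site vocabulary.

    Matching is case-insensitive; extra aliases extend (and may override)
    the built-in map.
    """
    table = dict(SITE_ALIASES)
    if aliases:
        table.update({k.strip().lower(): v for k, v in aliases.items()})
    key = label.strip().lower()
    if key not in table:
        raise ValidationError(
            f"unknown body site {label!r}; known labels: {sorted(set(table))}"
        )
    site = table[key]
    if site not in BODY_SITES:
        raise ValidationError(f"alias {label!r} maps to unknown site {site!r}")
    return site


@dataclass(frozen=True)
class SiteGroup:
    """A named group of body sites (e.g. 'respiratory' = nasal + oral sites)."""

    name: str
    members: frozenset

    def __contains__(self, site: str) -> bool:
        return site in self.members


RESPIRATORY = SiteGroup("respiratory", frozenset({"nasal", "buccal_mucosa", "saliva", "throat"}))
ORAL = SiteGroup("oral", frozenset({"buccal_mucosa", "saliva", "throat"}))
NASAL = SiteGroup("nasal", frozenset({"nasal"}))
NON_RESPIRATORY = SiteGroup("non_respiratory", frozenset({"stool", "skin"}))
STOOL = SiteGroup("stool", frozenset({"stool"}))
SKIN = SiteGroup("skin", frozenset({"skin"}))

SITE_GROUPS = {g.name: g for g in (RESPIRATORY, ORAL, NASAL, NON_RESPIRATORY, STOOL, SKIN)}


# --------------------------------------------------------------------------
# records

@dataclass(frozen=True)
class SampleMetadata:
    """One metagenome sample: id, body site and total QC'd basepairs."""

    sample_id: str
    body_site: str
    total_basepairs: int
    subject_id: str | None = None

    def __post_init__(self):
        if self.body_site not in BODY_SITES:
            raise ValidationError(
                f"sample {self.sample_id!r}: body site {self.body_site!r} "
                f"not in {BODY_SITES}"
            )
        if self.total_basepairs < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative total_basepairs"
            )


@dataclass(frozen=True)
class MappingStats:
    """Basepairs mapped to one target in one sample (flagstat-style count)."""

    target_id: str
    sample_id: str
    mapped_basepairs: int

    def __post_init__(self):
        if self.mapped_basepairs < 0:
            raise ValidationError(
                f"({self.target_id}, {self.sample_id}): negative mapped_basepairs"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """ORF intervals (1-based, inclusive, strand-agnostic) on one contig."""

    contig_id: str
    contig_length: int
    orf_intervals: tuple = ()

    def __post_init__(self):
        if self.contig_length <= 0:
            raise ValidationError(f"contig {self.contig_id!r}: non-positive length")
        for start, end in self.orf_intervals:
            if not (1 <= start <= end <= self.contig_length):
                raise ValidationError(
                    f"contig {self.contig_id!r}: interval ({start}, {end}) outside "
                    f"[1, {self.contig_length}]"
                )


@dataclass(frozen=True)
class CtRecord:
    """Replicate qPCR threshold cycles for one (sample, target) pair.

    Ct = 45 is the no-amplification sentinel (the cycle count of the
    thermocycling programme); NTC reactions are flagged with ``is_ntc``.
    """

    sample_id: str
    sample_type: str
    target_id: str
    replicate_cts: tuple
    is_ntc: bool = False

    def __post_init__(self):
        if not self.replicate_cts:
            raise ValidationError(
                f"({self.sample_id}, {self.target_id}): empty replicate list"
            )
        for ct in self.replicate_cts:
            if not (0 < ct <= 45):
                raise ValidationError(
                    f"({self.sample_id}, {self.target_id}): Ct {ct} outside (0, 45]"
                )


class AbundanceMatrix:
    """A vOTU x sample matrix of relative-abundance fractions in [0, 1].

    A target is *detected* in a sample iff its value is strictly positive
    (optionally above a configurable threshold; see
    :func:`viromarker.profiles.detection`).
    """

    def __init__(self, target_ids: Sequence[str], sample_ids: Sequence[str],
                 values: np.ndarray):
        values = np.asarray(values, dtype=float)
        target_ids = list(target_ids)
        sample_ids = list(sample_ids)
        if values.shape != (len(target_ids), len(sample_ids)):
            raise ValidationError(
                f"value shape {values.shape} does not match "
                f"{len(target_ids)} targets x {len(sample_ids)} samples"
            )
        if len(set(target_ids)) != len(target_ids):
            raise ValidationError("duplicate target ids")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample ids")
        if values.size and (np.min(values) < 0 or np.max(values) > 1):
            raise ValidationError(
                "relative abundances must be fractions in [0, 1]; "
                "values > 1 suggest percent/fraction confusion"
            )
        self.target_ids = target_ids
        self.sample_ids = sample_ids
        self.values = values
        self._t_index = {t: i for i, t in enumerate(target_ids)}
        self._s_index = {s: i for i, s in enumerate(sample_ids)}

    @property
    def shape(self):
        return self.values.shape

    def target_row(self, target_id: str) -> np.ndarray:
        return self.values[self._t_index[target_id]]

    def sample_column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self._s_index[sample_id]]

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        return np.array([self._s_index[s] for s in sample_ids], dtype=int)

    def subset_targets(self, target_ids: Sequence[str]) -> "AbundanceMatrix":
        idx = [self._t_index[t] for t in target_ids]
        return AbundanceMatrix(list(target_ids), self.sample_ids, self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.target_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AbundanceMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def __eq__(self, other):
        return (isinstance(other, AbundanceMatrix)
                and self.target_ids == other.target_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.values, other.values))

    def __repr__(self):
        return (f"AbundanceMatrix({len(self.target_ids)} targets x "
                f"{len(self.sample_ids)} samples)")


# --------------------------------------------------------------------------
# readers / writers (tab-separated text, mandatory headers, UTF-8)

_NA_VALUES = {"", "."}


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def read_mapping_stats(path) -> list[MappingStats]:
    """Parse a TSV of per-(target, sample) mapped-basepair counts.

    Columns: target_id, sample_id, mapped_basepairs.  Malformed rows are
    reported with their 1-based file line number (header is line 1).
    """
    frame = _read_tsv(path)
    _require_columns(frame, ("target_id", "sample_id", "mapped_basepairs"), path)
    records = []
    for pos, row in enumerate(frame.itertuples(index=False)):
        line = pos + 2
        raw = row.mapped_basepairs
        try:
            count = int(raw)
        except ValueError:
            raise FormatError(
                f"{path}: line {line}: mapped_basepairs {raw!r} is not an integer"
            ) from None
        if count < 0:
            raise ValidationError(
                f"{path}: line {line}: negative mapped_basepairs {count}"
            )
        records.append(MappingStats(row.target_id, row.sample_id, count))
    return records


def write_mapping_stats(records: Iterable[MappingStats], path) -> None:
    frame = pd.DataFrame(
        [(r.target_id, r.sample_id, r.mapped_basepairs) for r in records],
        columns=["target_id", "sample_id", "mapped_basepairs"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_metadata(path, aliases: Mapping[str, str] | None = None) -> list[SampleMetadata]:
    """Parse a sample-metadata TSV: sample_id, body_site, total_basepairs
    [, subject_id].  Body sites are normalised through the alias map."""
    frame = _read_tsv(path)
    _require_columns(frame, ("sample_id", "body_site", "total_basepairs"), path)
    has_subject = "subject_id" in frame.columns
    records = []
    seen = set()
    for pos, row in enumerate(frame.itertuples(index=False)):
        line = pos + 2
        if row.sample_id in seen:
            raise ValidationError(f"{path}: line {line}: duplicate sample id "
                                  f"{row.sample_id!r}")
        seen.add(row.sample_id)
        try:
            total = int(row.total_basepairs)
        except ValueError:
            raise FormatError(
                f"{path}: line {line}: total_basepairs {row.total_basepairs!r} "
                "is not an integer"
            ) from None
        subject = getattr(row, "subject_id", None) if has_subject else None
        if subject in _NA_VALUES:
            subject = None
        records.append(SampleMetadata(
            sample_id=row.sample_id,
            body_site=normalize_body_site(row.body_site, aliases),
            total_basepairs=total,
            subject_id=subject,
        ))
    return records


def write_metadata(records: Iterable[SampleMetadata], path) -> None:
    frame = pd.DataFrame(
        [(r.sample_id, r.body_site, r.total_basepairs, r.subject_id or "")
         for r in records],
        columns=["sample_id", "body_site", "total_basepairs", "subject_id"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_abundance_matrix(path) -> AbundanceMatrix:
    """Parse a rectangular TSV: first column target ids, remaining columns
    sample ids, cells relative-abundance fractions in [0, 1]."""
    frame = _read_tsv(path)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: need a target-id column plus >= 1 sample column")
    target_col = frame.columns[0]
    targets = list(frame[target_col])
    samples = list(frame.columns[1:])
    cells = frame[samples].mask(frame[samples].isin(_NA_VALUES))
    try:
        values = cells.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric abundance cell ({exc})") from exc
    if np.isnan(values).any():
        t, s = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"{path}: missing/ragged value at target {targets[t]!r}, "
            f"sample {samples[s]!r}"
        )
    if values.size and np.max(values) > 1:
        t, s = np.argwhere(values > 1)[0]
        raise ValidationError(
            f"{path}: value {values[t, s]} at ({targets[t]}, {samples[s]}) "
            "exceeds 1; abundances must be fractions, not percentages"
        )
    return AbundanceMatrix(targets, samples, values)


def write_abundance_matrix(matrix: AbundanceMatrix, path) -> None:
    """Write a matrix TSV; floats use shortest round-trip repr so that
    read -> write -> read reproduces values exactly."""
    frame = matrix.to_frame()
    frame.index.name = "target_id"
    frame.to_csv(path, sep="\t")


def read_fasta_lengths(path) -> dict[str, int]:
    """Sequence lengths per record id from a FASTA file."""
    lengths: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in lengths:
            raise FormatError(f"{path}: duplicate FASTA header {record.id!r}")
        lengths[record.id] = len(record.seq)
    return lengths


def read_gene_annotations(path) -> list[GeneAnnotation]:
    """Parse a gene-interval TSV (contig_id, contig_length, start, end;
    1-based inclusive coordinates) into per-contig annotations."""
    frame = _read_tsv(path)
    _require_columns(frame, ("contig_id", "contig_length", "start", "end"), path)
    by_contig: dict[str, dict] = {}
    for pos, row in enumerate(frame.itertuples(index=False)):
        line = pos + 2
        try:
            length, start, end = int(row.contig_length), int(row.start), int(row.end)
        except ValueError:
            raise FormatError(f"{path}: line {line}: non-integer coordinate") from None
        entry = by_contig.setdefault(row.contig_id, {"length": length, "ivals": []})
        if entry["length"] != length:
            raise ValidationError(
                f"{path}: line {line}: conflicting lengths for contig {row.contig_id!r}"
            )
        entry["ivals"].append((start, end))
    return [
        GeneAnnotation(cid, entry["length"], tuple(entry["ivals"]))
        for cid, entry in by_contig.items()
    ]


def write_gene_annotations(annotations: Iterable[GeneAnnotation], path) -> None:
    rows = [
        (a.contig_id, a.contig_length, start, end)
        for a in annotations for (start, end) in a.orf_intervals
    ]
    frame = pd.DataFrame(rows, columns=["contig_id", "contig_length", "start", "end"])
    frame.to_csv(path, sep="\t", index=False)


def read_ct_table(path) -> list[CtRecord]:
    """Parse a qPCR Ct TSV: sample_id, sample_type, target_id, ct_values
    (comma-separated replicate Cts), is_ntc (0/1)."""
    frame = _read_tsv(path)
    _require_columns(frame, ("sample_id", "sample_type", "target_id", "ct_values"), path)
    has_ntc = "is_ntc" in frame.columns
    records = []
    for pos, row in enumerate(frame.itertuples(index=False)):
        line = pos + 2
        try:
            cts = tuple(float(x) for x in str(row.ct_values).split(",") if x.strip())
        except ValueError:
            raise FormatError(f"{path}: line {line}: bad ct_values "
                              f"{row.ct_values!r}") from None
        is_ntc = bool(int(row.is_ntc)) if has_ntc else False
        records.append(CtRecord(row.sample_id, row.sample_type, row.target_id,
                                cts, is_ntc))
    return records


def write_ct_table(records: Iterable[CtRecord], path) -> None:
    frame = pd.DataFrame(
        [(r.sample_id, r.sample_type, r.target_id,
          ",".join(repr(c) for c in r.replicate_cts), int(r.is_ntc))
         for r in records],
        columns=["sample_id", "sample_type", "target_id", "ct_values", "is_ntc"],
    )
    frame.to_csv(path, sep="\t", index=False)
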