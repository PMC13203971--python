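"""High-level model object for the biomarker-discovery pipeline.

``BiomarkerDiscovery`` wraps the full workflow — prevalence-based
exclusion filtering, the 2-scheme x 3-feature-set grid of kernelized SVM
classifiers with forward feature selection, and the cross-model
consensus — behind a fit()/results interface.  The returned
``DiscoveryResults`` carries the per-model accuracies and selections,
the consensus candidate set, and offers cocktail evaluation, group
statistics and biomarker naming on top of the fitted candidates.

    >>> from viromarker import BiomarkerDiscovery, simulate
    >>> meta, matrix, truth = simulate.generate_cohort(simulate.CohortConfig(seed=1))
    >>> res = BiomarkerDiscovery(matrix, meta).fit(seed=1)
    >>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from . import filtering, selection, stats, validation
from .cocktails import Cocktail, cocktail_table, rank_cocktails
from .io import (NASAL, NON_RESPIRATORY, ORAL, RESPIRATORY, SKIN, STOOL,
                 AbundanceMatrix, SampleMetadata, read_abundance_matrix,
                 read_metadata)
from .profiles import group_prevalence

_FILTERED_LABELS = ("nonspecific_removed", "rare_nonspecific_removed")


class BiomarkerDiscovery:
    """Biomarker-discovery model over an abundance matrix and metadata.

    Parameters mirror the pipeline stages: exclusion-filter thresholds
    (strictly >80% stool-or-skin prevalence marks a vOTU nonspecific,
    strictly <20% respiratory prevalence marks it rare), the SVM kernel,
    the number of features kept by forward selection, the CV folds used
    to score candidate features, the train/test fraction, and the
    minimum number of models that must select a vOTU for it to become a
    consensus candidate.
    """

    def __init__(self, matrix: AbundanceMatrix,
                 metadata: Sequence[SampleMetadata],
                 *,
                 nonspecific_threshold: float = filtering.NONSPECIFIC_THRESHOLD,
                 rare_threshold: float = filtering.RARE_THRESHOLD,
                 rare_scope: str = "pooled",
                 detection_threshold: float = 0.0,
                 kernel: str = "rbf",
                 C: float = 1.0,
                 gamma="scale",
                 n_select: int = 10,
                 cv_folds: int = 5,
                 test_fraction: float = 0.25,
                 min_votes: int = 2):
        self.matrix = matrix
        self.metadata = list(metadata)
        self.nonspecific_threshold = nonspecific_threshold
        self.rare_threshold = rare_threshold
        self.rare_scope = rare_scope
        self.detection_threshold = detection_threshold
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.n_select = n_select
        self.cv_folds = cv_folds
        self.test_fraction = test_fraction
        self.min_votes = min_votes

    @classmethod
    def from_tables(cls, abundance_path, metadata_path, **kwargs):
        """Build the model from an abundance TSV and a metadata TSV."""
        return cls(read_abundance_matrix(abundance_path),
                   read_metadata(metadata_path), **kwargs)

    def build_feature_sets(self) -> filtering.FeatureSets:
        return filtering.build_feature_sets(
            self.matrix, self.metadata,
            nonspecific_threshold=self.nonspecific_threshold,
            rare_threshold=self.rare_threshold,
            rare_scope=self.rare_scope,
            detection_threshold=self.detection_threshold)

    def fit(self, seed: int = 0) -> "DiscoveryResults":
        """Run filtering, the six-model grid and the consensus."""
        feature_sets = self.build_feature_sets()
        base_spec = selection.ModelSpec(
            kernel=self.kernel, C=self.C, gamma=self.gamma, seed=seed,
            n_select=self.n_select, cv_folds=self.cv_folds,
            test_fraction=self.test_fraction, log_eps=1e-8)
        results = selection.run_grid(self.matrix, self.metadata,
                                     feature_sets, base_spec)
        consensus = selection.consensus_candidates(results, self.min_votes)
        filtered = [r for r in results
                    if r.spec.feature_set_label in _FILTERED_LABELS]
        filtered_consensus = selection.consensus_candidates(filtered,
                                                            self.min_votes)
        return DiscoveryResults(self, seed, feature_sets, results,
                                consensus, filtered_consensus)


class DiscoveryResults:
    """Results of a fitted :class:`BiomarkerDiscovery`.

    Attributes
    ----------
    feature_sets : the three nested vOTU feature sets with provenance
    model_results : six :class:`~viromarker.selection.ModelResult`
    consensus : candidates voted by >= min_votes of all six models
    filtered_consensus : consensus restricted to the four models that
        used the exclusion-filtered feature sets
    """

    def __init__(self, model, seed, feature_sets, model_results,
                 consensus, filtered_consensus):
        self.model = model
        self.seed = seed
        self.feature_sets = feature_sets
        self.model_results = model_results
        self.consensus = consensus
        self.filtered_consensus = filtered_consensus

    # -- candidate views ---------------------------------------------------

    @property
    def candidate_ids(self) -> tuple:
        return self.consensus.candidates

    def prevalence(self):
        """Group prevalence of every target over the standard site groups."""
        return group_prevalence(
            self.model.matrix, self.model.metadata,
            [RESPIRATORY, ORAL, NASAL, NON_RESPIRATORY, STOOL, SKIN],
            self.model.detection_threshold)

    def grid_frame(self) -> pd.DataFrame:
        """The six grid cells as a tidy table."""
        return pd.DataFrame([r.to_dict() for r in self.model_results])

    # -- downstream evaluations -------------------------------------------

    def evaluate_cocktails(self, sizes=(2, 3), candidates=None,
                           include_zeros: bool = False) -> list[Cocktail]:
        """Rank all 2-/3-member cocktails of the consensus candidates."""
        if candidates is None:
            candidates = self.candidate_ids
        return rank_cocktails(self.model.matrix, self.model.metadata,
                              candidates, sizes=sizes,
                              threshold=self.model.detection_threshold,
                              include_zeros=include_zeros)

    def cocktail_frame(self, **kwargs) -> pd.DataFrame:
        return cocktail_table(self.evaluate_cocktails(**kwargs))

    def compare_candidate_abundance(self, candidates=None,
                                    present_only: bool = True):
        """Respiratory vs non-respiratory abundance comparisons for the
        candidates, BH-corrected as one family."""
        if candidates is None:
            candidates = self.candidate_ids
        return stats.compare_groups(
            self.model.matrix, self.model.metadata, list(candidates),
            [(RESPIRATORY, NON_RESPIRATORY)], present_only=present_only)

    def name_candidates(self, tau: float = 0.20, candidates=None):
        """OVB/NVB/NOVB names for the candidates."""
        if candidates is None:
            candidates = self.candidate_ids
        return validation.name_candidates(
            self.prevalence(), self.model.matrix, self.model.metadata,
            candidates, tau)

    # -- reporting ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "feature_set_sizes": {fs.label: len(fs) for fs in self.feature_sets},
            "models": [r.to_dict() for r in self.model_results],
            "consensus": self.consensus.to_dict(),
            "filtered_consensus": self.filtered_consensus.to_dict(),
        }

    def summary(self) -> str:
        """Plain-text summary: feature-set sizes, the six-model grid and
        the consensus candidates with vote counts."""
        lines = []
        lines.append("Viral biomarker discovery summary")
        lines.append("=" * 70)
        lines.append(f"samples: {len(self.model.metadata)}   "
                     f"vOTUs: {len(self.model.matrix.target_ids)}   "
                     f"seed: {self.seed}")
        sizes = " / ".join(f"{fs.label}={len(fs)}" for fs in self.feature_sets)
        lines.append(f"feature sets: {sizes}")
        lines.append("-" * 70)
        frame = self.grid_frame()[["scheme", "feature_set", "accuracy_full",
                                   "accuracy_selected"]]
        frame = frame.rename(columns={"accuracy_full": "acc(full)",
                                      "accuracy_selected": "acc(selected)"})
        lines.append(frame.to_string(index=False,
                                     float_format=lambda x: f"{x:.3f}"))
        lines.append("-" * 70)
        cands = self.consensus.candidates
        lines.append(f"consensus candidates (votes >= "
                     f"{self.consensus.min_votes}): {len(cands)}")
        for votu in cands:
            lines.append(f"  {votu}  votes={self.consensus.votes[votu]}")
        return "\n".join(lines)
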