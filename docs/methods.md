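# Methods

This note documents the models, defaults and numerical choices behind
`viromarker`, and what its synthetic cohorts do and do not emulate.

## Quantities

**Relative abundance.** For target *t* in sample *s*,
`a(t, s) = mapped_bp(t, s) / total_bp(s)`, a fraction in [0, 1]. Abundances
are stored as fractions throughout; report layers multiply by 100. This
avoids double-percent bugs, and the reader rejects matrix cells above 1 with
a hint about percent/fraction confusion.

**Detection.** `present(t, s) ⇔ a(t, s) > θ` with θ = 0 by default (any
mapped basepairs). No minimum-coverage floor is imposed, but θ is a
parameter for users who want one. All detection comparisons are strict.

**Prevalence.** For a site group *g*,
`prev(t, g) = #{s ∈ g : present(t, s)} / |g|`, computed from integer counts
so the float is the correctly rounded value of the exact rational. Site
groups: respiratory = {nasal, buccal mucosa, saliva, throat}; oral =
respiratory minus nasal; non-respiratory = {stool, skin}.

## Exclusion filtering

* **Nonspecific:** `prev(t, stool) > 0.80` **or** `prev(t, skin) > 0.80`.
  The OR is evaluated per site, not on the pooled non-respiratory group.
* **Rare:** `prev(t, respiratory) < 0.20` on the pooled respiratory group
  (`rare_scope="either_site_group"` instead requires < 0.20 in both the
  nasal and the oral group separately).
* Feature sets: set 1 = all vOTUs; set 2 = set 1 minus nonspecific;
  set 3 = set 2 minus rare. The subset chain set 3 ⊆ set 2 ⊆ set 1 is an
  invariant, and equality at the thresholds (exactly 0.80 / 0.20) keeps the
  vOTU — the inequalities are strict.

Both thresholds are parameters with these defaults.

## Classification grid and forward selection

Two schemes (two-class: respiratory vs non-respiratory; three-class: nasal
vs oral vs non-respiratory) × three feature sets = six models.

* **Classifier:** RBF-kernel SVM (`C = 1`, bandwidth `gamma="scale"`),
  one-vs-one for the three-class scheme. Kernel family and hyperparameters
  sit in `ModelSpec` and may be swapped.
* **Preprocessing:** `log10(x + ε)` with ε = 10⁻⁸ followed by per-feature
  standardization whose mean/sd are fitted on the training partition only.
  Raw fractions span 10⁻⁶–10⁻¹ and would otherwise dominate any kernel
  through a handful of large values. ε sits well below the smallest
  realistic single-read abundance, so zeros map to a distinct floor.
* **Split:** stratified 75 : 25 train : test, seeded. Sample ids are sorted
  before splitting so the partition — and every accuracy — is invariant to
  the order samples arrive in.
* **Forward selection:** greedy; each step scores every unselected feature
  by mean stratified 5-fold cross-validated accuracy *on the training
  partition* of the classifier on (current ∪ {feature}), adds the maximizer,
  and breaks exact ties by lexicographically smallest vOTU id. Ten steps by
  default. The test set is never touched until the final re-fit, which
  reports `accuracy_selected`.
* **Consensus:** a vOTU selected by ≥ 2 of the models is a candidate.
  `DiscoveryResults` also exposes the consensus restricted to the four
  models on filtered feature sets, which is the relevant set when the
  question is "markers that survive the exclusion rules".

Degenerate inputs: single-class training data and classes with fewer than
two samples are refused; constant features get unit variance in the scaler
rather than a division by zero.

## Cocktails

A cocktail (2 or 3 members by default; sizes are a parameter) is detected in
a sample iff any member is detected; its abundance is the member sum. The
ranking objective is `prev(respiratory) − prev(non_respiratory)`,
descending, ties broken by higher respiratory prevalence then lexicographic
members. Because the "best" cocktail criterion is genuinely open, the full
ranked table and the Pareto front under (maximize respiratory, minimize
non-respiratory) are always reported; group mean abundances are computed
over detected samples by default (`include_zeros=True` switches to all
samples).

## Statistics

* Shapiro–Wilk gates normality at α = 0.05; constant vectors and n < 3 are
  refused rather than guessed.
* Group comparisons use the unpaired two-sided Wilcoxon rank-sum
  (Mann–Whitney) test: exact enumeration when both groups are ≤ 8 and
  tie-free, otherwise the tie-corrected normal approximation *without*
  continuity correction — so identical groups give exactly p = 1, and a
  pooled constant sample short-circuits to p = 1.
* Benjamini–Hochberg step-up adjustment is applied across exactly the family
  of comparisons passed to one `compare_groups` call; adjusted values are
  recomputable from the returned raw p-values.
* Abundance comparisons drop absent samples by default (mirroring
  present-only abundance summaries); a flag includes zeros. Comparisons
  where a whole group is empty after dropping are reported as
  `not_testable` with NaN p-values rather than silently skipped.
* Target clustering is agglomerative on Euclidean distances between
  abundance profiles, average linkage by default (configurable: single,
  complete, average, ward), with a deterministic leaf order and a Newick
  serialization of the dendrogram.

## qPCR and genome checks

* Replicate threshold cycles are averaged per (sample, target); reactions
  that never amplify are recorded as Ct = 45 (the cycle count of the
  programme) so means stay defined.
* **Detection call:** present ⇔ mean Ct < mean NTC for that target; equality
  is absent. The inverse reading (present ⇔ mean Ct > NTC) exists behind
  `rule="literal_methods"` but contradicts ordinary qPCR semantics and is
  not the default.
* **Coding density** = ORF-covered basepairs / total length, with
  overlapping or adjacent intervals merged first (so density ≤ 1 always and
  the value is invariant to interval splitting and permutation). ORF
  coordinates are 1-based inclusive at the interface. Multi-contig vOTUs
  aggregate covered and total lengths before dividing.
* **Naming:** candidates are ranked by descending respiratory prevalence
  (mean respiratory abundance breaks ties) and prefixed by where prevalence
  clears τ = 0.20: NOVB (oral and nasal), OVB (oral only), NVB (nasal only);
  rank suffixes count within each prefix family. Below τ everywhere, the
  argmax site decides and the name carries a low-prevalence flag. τ is a
  parameter; 0.20 matches the rare-vOTU threshold.

## Synthetic cohorts

`generate_cohort` plants eight vOTU classes over the six body sites:
oral-specific, nasal-specific, nasal+oral, skin-associated,
stool-associated, broadly nonspecific, rare-respiratory, and background.
Presence is Bernoulli per (class, site); conditional on presence the
abundance is `10^Normal(μ, σ)` truncated to (0, 1]; absences are exactly 0
(zero-inflated log-normal — chosen because body-site virome profiles are
presence/absence-dominated with heavily right-skewed small abundances).

Defaults, chosen once as the package's study conditions:

* 30 samples per site (50 in the calibration tests); per-sample sequencing
  depth log-normal around 10^9.5 bp.
* Marker classes: prevalence 0.9 in their target sites, 0.05 elsewhere —
  strong, recoverable signal. Skin-associated vOTUs leak into nasal (0.3)
  and stool-associated into oral sites (0.3), mirroring the skin~nasal and
  stool~oral community overlaps seen in body-site surveys. The nonspecific
  class is at 0.9 in stool and skin and 0.6 everywhere else; the rare class
  sits at 0.12 in respiratory sites; background is 0.3 everywhere.
* Conditional abundance means 10⁻⁵–10⁻⁴ (fractions) for markers — the scale
  reported for respiratory viral biomarkers in human metagenomes — with
  nasal markers slightly hotter, background around 10⁻⁵·⁵.
* 48 vOTUs total (5 oral, 4 nasal, 4 dual-site, 5 skin, 5 stool,
  6 nonspecific, 5 rare, 14 background). This desk-scale catalogue keeps a
  full 10-seed pipeline run in the low minutes while leaving every filter
  and consensus stage a non-trivial decision.

Randomness: every component (metadata, each vOTU class, each qPCR sample
type, gene layout) draws from a substream keyed by the global seed plus a
fixed component label, so adding or reordering components never perturbs the
draws of another — and identical seeds give byte-identical cohorts.

What the generator does **not** emulate: within-subject correlation across
body sites (samples are independent; a subject-effect hook exists but
defaults to off), sequencing error or read-level noise, compositional
coupling between vOTUs, and phylogenetic relatedness. Passing the planted
recovery tests therefore demonstrates that the pipeline machinery is
correct and recovers site-structured signal of the stated strength — not
that the method would attain the same accuracy on real cohorts, where
signal is weaker and correlated.

`generate_gene_annotations` packs non-overlapping ORFs (mean length 600 bp)
to hit a target coding density within ±1 bp; `generate_ct_dataset` draws
duplicate replicate Cts from a truncated normal capped strictly below the
NTC for detected samples and emits 45-sentinels otherwise, plus one NTC
record per target.

## Known limitations

* Forward selection is O(steps × features × folds) SVM fits; pools beyond a
  few hundred features call for sub-sampling or a cheaper selection score.
* The rank-sum normal approximation without continuity correction is
  slightly anti-conservative for tiny tied samples; the exact branch covers
  the tie-free small-sample case.
* Union-prevalence ranking ignores assay interactions (primer competition
  in multiplexed cocktails) by construction.
* Accuracies from a single stratified split have seed-to-seed variance of a
  few percentage points at these cohort sizes; the multi-seed recovery
  metric, not any single accuracy, is the supported summary.
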