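# Methods

This note documents the models and procedures implemented in `foodreadout`,
the defaults chosen where the design was genuinely open, and what the
synthetic validation does and does not demonstrate.

## Problem setting

Untargeted LC-MS/MS of foods yields tens of thousands of ion features —
chromatographic (m/z, RT) entities with an MS1 peak area per sample and,
for most, an MS/MS fragmentation spectrum. Only a small fraction can be
annotated with a chemical structure. The package's premise is that
annotation is unnecessary for dietary readout: an ion feature that is
consistently and strongly enriched in one food category is a usable
biomarker of that category regardless of its identity, because its MS/MS
spectrum lets us recognize it again in feces, urine or plasma.

One molecule can produce several ion features (adducts, multimers,
in-source fragments), so the unit throughout is the *ion feature*, not the
compound.

## Learning the biomarker library

**Contrasts.** Foods live in a rooted ontology; samples are assigned to
leaves. For every non-root category at every level a one-vs-rest contrast
is formed. The default scope is *global* — positives are all samples in the
category's subtree, negatives every other provided sample — because the
enrichment that justifies a biomarker is enrichment against *all other
foods*. A *siblings* scope (negatives restricted to the same parent) is
kept as an option for users who want level-local discrimination. Contrasts
with fewer than `min_group_size` (default 3) samples on either side are
dropped and logged: a discriminant fit needs at least two samples per class
plus one for variance.

**Preprocessing.** The default chain is per-sample TIC normalization
(models are fit on relative abundances; total signal varies with injection
and matrix), log10(x+1) (LC-MS intensities span decades and the +1 keeps
true zeros at zero), then per-feature centering with unit-variance scaling.
Every stage is configurable (`PreprocessSpec`); Pareto scaling and raw
modes are available. Zero-variance features get scale 1 and a flag rather
than an error. The preprocessing actually used is recorded in the library's
parameters.

**OPLS-DA.** The single-response O-PLS algorithm: per orthogonal component
on the current deflated matrix X, compute the PLS weight w ∝ Xᵀy, loadings
p = Xᵀ(Xw)/‖Xw‖², split off the y-orthogonal part w_o ∝ p − (wᵀp)w, and
deflate X by the orthogonal component t_o·p_oᵀ; finish with one ordinary
PLS component. Because X is column-centered, every orthogonal score is
uncorrelated with the class vector by construction (checked to 1e-6 in the
tests). With `n_ortho=0` the model is exactly a one-component PLS, which
the tests verify against an independent NIPALS implementation. The default
`n_ortho=1` is the minimal O-PLS model; if orthogonal variation is
exhausted (perfectly predictive data) fitting stops early and flags the
model rather than failing. Classes are encoded ±1 without size reweighting
— imbalance is handled by the fold-change co-filter, matching classical
OPLS-DA practice. Weight-vector signs are fixed (largest-magnitude element
positive) so output is deterministic.

**VIP.** Variable importance in projection is computed over the predictive
component only: with a single predictive component, VIP_j = √p·|w_j| and
Σ VIP² = p exactly. Excluding orthogonal components is deliberate — a
"VIP > threshold" selection is only meaningful on the axis that separates
the classes.

**Filters.** A feature is selected for a category when VIP is strictly
above the VIP threshold (default 4.0) *and* the fold-change is at or above
the fold threshold (default 6) *and* the direction is enrichment.
Fold-changes are ratios of mean TIC-normalized, unlogged intensities — an
"n-fold enrichment" claim is about abundances, not log-abundances — with
pseudo-count ε defaulting to half the smallest nonzero normalized intensity
in the table, a scale-aware choice that keeps ratios finite when a feature
is entirely absent from the rest of the foods. A feature may be selected
for several categories and levels; hierarchical overlap (a berry marker is
also a fruit marker) is intentional and no deduplication is applied.

Note the thresholds' strictness conventions differ on purpose: VIP > 4.0
(strict) versus fold-change ≥ 6 (inclusive).

**Library.** Entries carry (feature, category, level, VIP, fold-change,
group means) plus a reference spectrum id; spectra are linked by feature
id. Features without an MS/MS spectrum stay in the library flagged
spectrum-less (usable only in feature-id matching). Serialization is JSON
plus a companion MGF; loading re-audits every entry against the recorded
thresholds.

## Spectral matching

Similarity is cosine on square-root-transformed intensities: candidate
peak pairs are those within the fragment tolerance (default 0.02 Da), and
the score is the maximum of Σ√(Iₐ·I_b) over one-to-one pairings, divided by
‖√Iₐ‖·‖√I_b‖. Square-root weighting damps base-peak dominance and is
standard library-search practice. The modified cosine additionally allows
pairs offset by the precursor mass difference, which recovers host- and
microbially modified derivatives (methylation, glucuronidation,
hydroxylation, deamination) of food compounds.

The pairing is solved by exact linear assignment when both spectra have at
most 12 peaks and by a greedy pass (descending pair product, ties broken by
smaller |Δm/z|, then by peak index) beyond that. The greedy path is an
approximation; the test suite measures its gap against exhaustive
enumeration on small spectra (zero in practice) and checks that it never
falls below the greedy pairing of an independent implementation (matchms).

Library search defaults — precursor tolerance 0.01 Da (cosine mode), analog
window 200 Da (modified-cosine mode), fragment tolerance 0.02 Da, minimum 4
matched peaks, minimum score 0.7 — are conventional repository-search
settings; all are recorded per run because results depend on them.

## Dietary scores

For sample *s* and category *c*, the score is the mean MS1 intensity of
*c*'s biomarkers in *s*. A biomarker is detected when a library match hits
its reference spectrum and the matching query spectrum links to a feature
of the query table (explicit `FEATURE_ID` links win; otherwise the nearest
feature within m/z and RT tolerances). When several query spectra match
the same biomarker, the top-scoring match supplies the intensity. The
default `fill="zeros"` averages over *all* of the category's biomarkers
(undetected → 0), rewarding breadth of detection and making scores
comparable across samples; `fill="detected_only"` averages over detected
biomarkers alone and suits very sparse matrices. Query tables are TIC
normalized before scoring by default, appropriate for fecal/urine data
where total signal varies strongly.

Scores are computed per ontology level and proportion normalization
(`normalize_scores`) is restricted to a single level: categories at
different levels mix granularities and must not be summed together. Scores
are *relative* readouts. Ionization efficiency, detector response and
matrix effects differ per compound, so no conversion to grams or calories
is attempted.

## Statistics

- **PCA** via SVD of the column-centered matrix, deterministic component
  signs, explained-variance ratios equal to the covariance eigenvalue
  shares.
- **PERMANOVA** with the classical sum-of-squares partition on a distance
  matrix; Euclidean distance on proportion-normalized scores is the
  default, Bray–Curtis is offered since scores are composition-like. The
  permutation p uses the (1 + more-extreme)/(1 + N) convention; when N
  reaches the number of distinct label arrangements the null is enumerated
  exactly (with multiset permutations, so ties in labels are handled).
  Only one-factor runs are provided; repeated-measures designs should be
  analyzed per factor, a documented limitation.
- **Pearson correlations** of every score column against numeric metadata,
  pairwise-complete, t-distribution p-values, Benjamini–Hochberg q over the
  whole category × variable grid. Zero-variance or n < 3 pairs are emitted
  flagged and excluded from the adjustment.

## Synthetic data: what it emulates, and what it does not

`simulate_reference` draws per-feature baselines from a lognormal (spread
σ = 1 around a base abundance of 1e5 counts, typical of LC-MS peak areas),
multiplies planted features by the enrichment fold in their home category,
applies multiplicative lognormal noise (mean-one, CV-parameterized —
LC-MS intensity error is multiplicative) and Bernoulli dropout after
mixing, mimicking per-run detection failure. Default conditions are 8 leaf
categories × 12 samples, 40 planted markers per category at 10-fold
enrichment, 400 background features, 30% CV, 10% dropout. Ontology depths
1 and 2 are supported (deeper chains are rejected); spectra are random
peak lists (8 uniform fragments, exponential intensities) — geometrically
but not chemically realistic, which is sufficient because the matching
layer only needs geometric structure.

Mixtures combine leaf-category *mean* profiles at known fractions;
cohorts perturb group weight profiles per subject with a lognormal
between-subject effect and renormalize.

What passing tests therefore show: the selection filters recover planted
enrichment structure, scores track known composition, and the statistics
are calibrated — under clean, independently noisy, adduct-free data. What
they do not show: robustness to chromatographic drift, correlated adduct
networks, retention-time misalignment, shared compounds between foods with
partial enrichment, or microbial biotransformation of biomarkers; real
spectra also have fragment structure (neutral losses) these synthetic peak
lists lack.

## Numerical choices and degenerate inputs

- VIP threshold at the synthetic validation scale: with p ≈ 720 features
  and 40 equally informative markers per category, each marker's VIP
  plateaus near √(p/40·share) ≈ 2–4, so the validation suite and the
  acceptance script select at VIP > 1.5 while the real-data default stays
  at 4.0 (a 57,000-feature table concentrates far higher VIP on its
  markers). Both values are configuration, recorded per run.
- All-zero samples survive TIC normalization as zeros with a warning;
  empty peak lists are rejected at write time and for any similarity
  computation; an all-zero score matrix is rejected by PCA.
- Fold-change ε > 0 is enforced; a table with no nonzero entries falls
  back to ε = 1e-12.
- Score comparisons in the permutation test use a 1e-12 tolerance so the
  identity arrangement always counts as at least as extreme as itself.
- JSON artifacts are written with sorted keys and MGF peak lines with
  fixed formats, so identical seeds give byte-identical files.

## Known limitations

- OPLS-DA component count is fixed by configuration; no cross-validated
  Q² selection.
- No multi-class single-model OPLS-DA; one model per contrast.
- Library search is brute-force over the library — appropriate for
  thousands of reference spectra, not for repository-scale indexing.
- Scores quantify relative, within-level dietary composition only.
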