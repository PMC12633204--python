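# foodreadout

Reference-based dietary readout from untargeted LC-MS/MS metabolomics.

Most molecular features detected in foods — and in the feces, urine and
plasma of the people who eat them — have no structural annotation. This
package implements a strategy that sidesteps annotation entirely: learn
which MS/MS ion features are *specific to food categories* from a reference
food dataset, then detect those features in biological samples by spectral
matching and read out relative dietary composition from their MS1
intensities. It is aimed at metabolomics researchers and nutritional
epidemiologists who want objective, survey-free estimates of dietary
patterns from existing untargeted data.

## The method

**Learning food biomarkers.** Foods are organized in a hierarchical
ontology (e.g. plant → fruit → blueberry). For every category *c* at every
level, a one-vs-rest orthogonal partial least squares discriminant analysis
(OPLS-DA) is fitted on the preprocessed feature table (TIC normalization,
log10(x+1), unit-variance scaling by default). A feature *j* becomes an
**MS/MS food biomarker** of *c* when

- its variable importance in projection exceeds the threshold,
  VIP_j > 4.0 (strict), where VIP_j = √p·|w_j| on the predictive component
  and Σ_j VIP_j² = p (the feature count), and
- it is enriched, FC_j = (x̄_j^c + ε)/(x̄_j^rest + ε) ≥ 6 (inclusive),
  computed on TIC-normalized, unlogged intensities with a scale-aware
  pseudo-count ε.

Selected features are stored with their reference MS/MS spectra as a
`BiomarkerLibrary`.

**Readout.** Query spectra are matched against the library by cosine
similarity on √-intensities (one-to-one peak pairing within a fragment
tolerance; exact assignment for small spectra), or by **modified cosine**
for analog search, which additionally pairs peaks offset by the precursor
mass difference and so captures host/microbially modified metabolites.
Matches are linked back to query features, and the **dietary score** of
sample *s* for category *c* is the mean MS1 intensity of *c*'s biomarkers
in *s* (undetected biomarkers count as zero by default). Scores are
relative readouts — never grams or calories — and can be
proportion-normalized within one ontology level.

**Statistics.** PCA, one-factor PERMANOVA
(pseudo-F = (SS_B/(g−1))/(SS_W/(n−g)), R² = SS_B/SS_T, permutation p with
exact enumeration on small designs) and Pearson correlation against
metadata with Benjamini–Hochberg control.

A synthetic-data module generates category-structured reference tables with
planted enriched features, known-fraction mixtures and diet-group cohorts,
so the whole pipeline is testable without any external download.

## Worked example

```python
import foodreadout as fr

table, ontology, spectra, truth = fr.simulate_reference(fr.SynthConfig(seed=42))
library = fr.learn_library(table, ontology, spectra,
                           fr.LibraryConfig(vip_threshold=1.5, fold_threshold=6.0))
```

Running `python examples/01_learn_biomarker_library.py` prints:

```
reference: 720 features x 96 samples, 8 leaf categories
contrasts run: 8  library entries: 319
recall 0.997  precision 1.000
example biomarker: feature F00001 -> food01 (VIP 3.94, 9.8-fold enriched)
```

i.e. 8 one-vs-rest discriminant analyses selected 319 (feature, category)
biomarkers, recovering 99.7% of the planted enriched features with no false
selections. `examples/02_mixture_readout.py` then mixes two reference foods
at known fractions and scores them:

```
fraction 0.00  mean food01 dietary score 0.00093
fraction 0.50  mean food01 dietary score 0.00508
fraction 1.00  mean food01 dietary score 0.00884
Pearson r(known fraction, dietary score) = 0.998
```

— the dietary score rises monotonically with the true ingredient fraction
(the intercept at fraction 0 reflects background features shared between
foods). `examples/03_cohort_statistics.py` separates two simulated diet
groups (PERMANOVA R²=0.93, p=0.001; PCA PC1 carries 93% of variance) and
recovers a planted diet–outcome correlation, and
`examples/04_analog_matching.py` shows the modified cosine retrieving a
+14.0157 Da methylated derivative that plain cosine search misses.

The same stages are available as a thin CLI:

```bash
foodreadout simulate --out-dir sim --seed 1
foodreadout learn --feature-table sim/feature_table.csv \
    --ontology sim/ontology.json --mgf sim/spectra.mgf --out-dir lib
foodreadout readout --query-table sim/feature_table.csv \
    --library lib/library.json --query-mgf sim/spectra.mgf --out scores.tsv
```

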