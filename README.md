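# lscpanel

Quantitative tissue-section biomarker screening by slide-based (laser
scanning) cytometry, for studies that ask: *which surface markers — alone or
in small panels — separate diseased from control tissue?*

The motivating setting is rheumatoid-arthritis (RA) synovium: candidate
surface antigens (CD11b, CD38, CD29, CD90, HLA-DR, CD64, CD304, CD4, CD271)
are stained on serial sections from RA patients — subgrouped into mild
(RA(+)) and high (RA(++)) current-activity synovitis — and trauma controls,
then scanned whole-section. `lscpanel` implements the full analysis chain
downstream of the scanner, plus a synthetic-cohort generator so the entire
pipeline runs and is tested without instrument data.

## Method

**Phantom quantification.** Instead of segmenting cells, the scan is tiled
into fixed-size square *phantoms*. Each phantom carries its integral
fluorescence, its brightest pixel (MaxPixel), and its brightest scatter
pixel; phantoms are gated to tissue on the scatter channel (fixed cutoff or
automatic two-class histogram split).

**Two section statistics**, both calibrated per patient and dye on a matched
negative-control (isotype) section:

- *corrected MFI* = median(integral) − median(integral on negative control);
- *affected area* = % of tissue phantoms with MaxPixel above the
  autofluorescence cutoff, where the cutoff is the smallest observed
  negative-control MaxPixel leaving **< 5 %** of calibration events above it.

**Statistics and classification.** Markers are screened with the
Mann-Whitney *U* test (control vs disease), Kruskal-Wallis across the three
cohorts with Bonferroni-adjusted post hocs (0.05/3 → *P* ≤ 0.017), and
profile banding against control mean + 1 SD / + 2 SD. Discrimination uses
Fisher's linear discriminant w ∝ (Σ_w + λI)⁻¹(μ₁ − μ₀) with pooled
within-class covariance, a small ridge λ, and equal priors, under 10-fold
stratified cross-validation with 10 repetitions; sensitivity, specificity
and LR⁺ = sens/(1 − spec) come from the pooled held-out confusion counts.
ROC analysis (trapezoid AUC ≡ the pairwise U-statistic, DeLong or bootstrap
95 % CI, sensitivity at 90 % specificity, AUC bands > 0.85 / < 0.55) runs on
the out-of-fold discriminant scores, and every marker subset of size 1–3 is
ranked by these cross-validated metrics per cohort contrast and per
parameter track (MFI and affected area are never mixed in one model).

## Worked example

```python
import lscpanel as lp
from lscpanel.panels import results_frame

design = lp.default_design(seed=1, phantoms_per_section=2000)   # 14 control, 12 RA(+), 5 RA(++), 9 markers
tables, metadata = lp.generate_study(design)
summaries = lp.summarize_study(tables, max_fpr=0.05)
dataset = lp.build_dataset(summaries, metadata, parameter="affected_area")

comparisons = lp.compare_cohorts(dataset)
print(comparisons.query("comparison == 'control vs disease' and significant")
      [["marker", "statistic", "p_value"]])

ranked = lp.search_panels(dataset, contrast="control-vs-ra", max_size=2, seed=1)
print(results_frame(ranked).head(5)
      [["panel", "auc", "ci_low", "ci_high", "sens_at_90_spec", "band"]].round(3))
```

prints

```
marker  statistic  p_value
 CD11b        7.0 0.000010
  CD29       40.0 0.001831
 CD304       59.0 0.018163
  CD64       18.0 0.000066
  CD90       13.0 0.000028
HLA-DR       43.5 0.002907
      panel   auc  ci_low  ci_high  sens_at_90_spec                  band
 CD11b+CD90 0.983   0.947      1.0            0.941 highly_discriminative
CD90+HLA-DR 0.962   0.904      1.0            0.906 highly_discriminative
  CD29+CD90 0.958   0.900      1.0            0.847 highly_discriminative
CD11b+CD271 0.954   0.881      1.0            0.941 highly_discriminative
      CD11b 0.950   0.858      1.0            0.941 highly_discriminative
```

The first table lists the markers whose affected area differs significantly
between control and RA cohorts (U statistic and two-sided *p*); the second
is the top of the cross-validated panel ranking — two-marker panels beat the
best single marker, and the AUC band labels each panel's discriminability.

The same analysis is available from the shell:

```sh
lscpanel simulate --seed 1 --out run/
lscpanel summarize --tables run/phantom_tables.csv --out run/summaries.csv
lscpanel compare   --summaries run/summaries.csv --metadata run/metadata.csv \
                   --parameter affected_area --out run/comparisons.csv
lscpanel panels    --summaries run/summaries.csv --metadata run/metadata.csv \
                   --max-size 2 --contrast control-vs-ra --out run/panels.csv
lscpanel run-all   --seed 1 --out run/     # everything + manifest with checksums
```

## Layout

- `lscpanel.synthetic` — cohort designs, phantom-table and scan generators
- `lscpanel.phantom` — grid tiling and scatter-based tissue gating
- `lscpanel.markers` — threshold calibration, corrected MFI, affected area
- `lscpanel.stats` — Mann-Whitney / Kruskal-Wallis / Bonferroni / Spearman / profile bands
- `lscpanel.discriminant` — `LinearDiscriminant` (scikit-learn estimator API) and repeated stratified CV
- `lscpanel.roc` — ROC curves, AUC CIs, sensitivity at fixed specificity, bands
- `lscpanel.panels` — exhaustive panel enumeration, evaluation, ranking
- `lscpanel.pipeline` / `lscpanel.cli` — configuration, orchestration, manifests, CLI

See `docs/methods.md` for the model, parameter defaults and limitations.
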