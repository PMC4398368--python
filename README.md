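# faniche

Fluctuating asymmetry, morphological disparity, and environmental
suitability: a reproducible geometric-morphometrics pipeline.

## The problem

Fluctuating asymmetry (FA) — small, non-directional deviations from perfect
bilateral symmetry — is a classic proxy for developmental instability:
individuals developing under environmental stress tend to be less
symmetric. Species-distribution models (SDMs) such as Maxent summarize, on
a 0–1 scale, how suitable each cell of a landscape is for a species. If
both signals are real, populations living in low-suitability habitat
should show elevated skull FA. `faniche` implements the full analysis
chain needed to test that prediction on landmark data from a bilaterally
symmetric structure (a rodent skull in the motivating use case), and a
synthetic-data generator that creates complete studies with known
FA–suitability coupling, so that every stage is verifiable without museum
specimens.

## What it computes

Given 2D landmark configurations (TPS files), a left/right landmark
pairing, a locality table and a suitability raster (ESRI ASCII grid):

1. **Generalized Procrustes analysis** — removes position, scale and
   orientation, yielding Procrustes shape coordinates and centroid sizes
   CS = √Σⱼ‖xⱼ − x̄‖².
2. **Object-symmetry FA scores** — each configuration and its
   reflected/relabeled copy enter one joint Procrustes fit; the FA score
   of a specimen is the Procrustes distance between its aligned original
   and its own symmetric consensus (the mean of the two copies). A
   directional-asymmetry-corrected score is also reported.
3. **Procrustes ANOVA** — on specimens digitized twice, a two-factor
   individuals × sides ANOVA over all landmark coordinates separates the
   FA signal (individual × side mean square) from digitizing error
   (error mean square), with object-symmetry degrees of freedom
   d_s = d_a = 2l + m − 2 for l landmark pairs and m midline landmarks.
4. **Population summaries** — mean FA, morphological disparity (within-
   population Procrustes variance Σdᵢ²/(n−1)), mean centroid size; a
   shape-on-size (allometry) regression for the whole sample.
5. **Suitability extraction** — local scale: the raster cell containing
   each locality; regional scale: the mean of the 3×3 cell block around
   it (edge-truncated).
6. **Moran's I screen** — global spatial autocorrelation of the response
   vectors with inverse great-circle-distance weights; the null
   expectation is −1/(n−1).
7. **Association battery** — eight OLS regressions: FA and disparity
   against suitability at both scales, against per-population sample
   size, and against mean centroid size, reported as
   F(1, n−2), P, R², b.

## Worked example

Simulate a survey-scale study (22 populations, 380 specimens, 40
landmarks, 50 specimens digitized twice) and run the full pipeline:

```bash
fa-niche simulate --seed 7 --out study/
fa-niche run --tps study/landmarks.tps --symmetry-map study/symmetry_map.csv \
    --localities study/localities.csv --raster study/suitability.asc \
    --specimens study/specimens.csv --out report/
```

which prints (abridged):

```
report written to report
  mean_fa ~ suitability_local: F_1,20 = 66.31; P = 8.853e-08; R2 = 0.768; b = -0.00388
  mean_fa ~ suitability_regional: F_1,20 = 65.59; P = 9.642e-08; R2 = 0.766; b = -0.00389
  disparity ~ suitability_local: F_1,20 = 3.30; P = 0.0843; R2 = 0.142; b = -0.00035
  disparity ~ suitability_regional: F_1,20 = 3.19; P = 0.08941; R2 = 0.137; b = -0.00034
  mean_fa ~ n: F_1,20 = 0.50; P = 0.4869; R2 = 0.024; b = 0.00045
  ...
```

Read: per-population mean FA falls by ≈0.0039 Procrustes-distance units
per unit of suitability (a strongly significant negative association at
both spatial scales — the generator injected a coupling of −0.004), while
disparity, which was generated without any suitability link, shows no
significant association. `report/` also contains the per-specimen FA
scores, the population summary, the Procrustes ANOVA table (here the FA
mean square is ≈3.6× the error mean square, so digitizing noise does not
masquerade as FA), the Moran's I screen, and scatter plots.

The same steps are available as library functions
(`faniche.gpa`, `faniche.fa_scores`, `faniche.procrustes_anova`,
`faniche.morans_i`, `faniche.run_association_suite`, ...) and as
stage-level subcommands (`fa-niche gpa|fa|anova-error|extract|moran|regress`).

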