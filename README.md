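# radiotme

Radio-genomics of the breast tumor microenvironment: linking DCE-MRI
radiomic phenotypes to the abundance of immune and stromal cell
populations.

## The problem

The cellular composition of a breast tumor's microenvironment — how
heavily it is infiltrated by T cells, NK cells, fibroblasts, endothelial
cells and other populations — is prognostically informative but normally
requires biopsy. Dynamic contrast-enhanced MRI (DCE-MRI) is acquired as
standard of care and carries quantitative phenotypes far beyond what
visual reading uses. `radiotme` implements, as a tested and reusable
pipeline, the analysis that connects the two:

1. **Radiomic extraction** — 199 features per lesion from a 4-phase study
   (one pre-contrast + three post-contrast volumes with a tumor mask):
   111 static features (shape, first-order, GLCM/GLRLM/GLSZM/GLDM/NGTDM
   texture families, with 8-bit rescale and binWidth-25 quantization) and
   88 kinetic features in three groups — aggregate (mean/SD of wash-in
   slope WIS, wash-out slope WOS, peak enhancement PE and time-to-peak
   TTP, plus MPE and the hot spot), heterogeneity (statistics on the
   3-label quick/intermediate/slow TTP characteristic map), and textural
   kinetic (co-occurrence + histogram descriptors of the kinetic
   parameter maps).
2. **Abundance scoring** — MCP-counter-style marker scores for 8 immune
   and 2 stromal cell populations from a bulk expression matrix, with
   median high/low stratification (score ≥ median → "high").
3. **Association scan** — per (feature, population) pair, linear
   regression with a two-sided slope test and Benjamini–Hochberg FDR
   control over all 199 × 10 = 1,990 pairs; the features × populations
   correlation matrix; Welch t-tests of tumor volume and mean PE between
   high/low groups.
4. **Classification** — per population, recursive feature elimination
   (random-forest importance, CV-accuracy size selection) feeding a
   binary logistic gradient-boosting classifier, evaluated by pooled
   leave-one-out cross-validation and on an external cohort, with a PCA
   silhouette diagnostic for inter-institution batch effects.
5. **Synthetic cohorts** — a first-class generator of paired imaging +
   expression cohorts with piecewise-linear enhancement phantoms,
   two institution profiles with differing geometry and intensity
   mapping, and planted feature–abundance couplings, so every stage has
   a recoverable ground truth.

See `docs/methods.md` for the model conventions and design decisions.

## Worked example

```python
import radiotme as rt

# a 60-lesion synthetic cohort with a planted correlation of 0.5 between
# mean peak enhancement and fibroblast abundance
cfg = rt.CohortConfig(
    n_lesions=60, seed=7,
    planted_assoc=[rt.PlantedAssociation("kin_mean_pe", "Fibroblasts", 0.5)],
)
studies, expr, truth = rt.gen_cohort(cfg)

features = rt.extract_features(studies)          # 60 x 199
abundance = rt.stratify_median(rt.score_abundance(expr))
scan = rt.univariate_scan(features, abundance)   # 1,990 rows

hit = scan[(scan.feature == "kin_mean_pe")
           & (scan.population == "Fibroblasts")].iloc[0]
print(f"kin_mean_pe ~ Fibroblasts: r={hit.r:.2f}, adjusted p={hit.p_adj:.2g}")
print(f"realized planted r: "
      f"{truth.realized_correlations[('kin_mean_pe', 'Fibroblasts')]:.2f}")
```

prints

```
kin_mean_pe ~ Fibroblasts: r=0.44, adjusted p=0.03
realized planted r: 0.43
```

i.e. the scan recovers the correlation actually realized by the planting
(r ≈ 0.5 up to sampling noise at n = 60) and the pair survives FDR
adjustment over all 1,990 tests. The `examples/` directory walks through each capability —
simulation, extraction, scoring, association, classification, and the
batch diagnostic — as short narrative scripts.

A thin CLI mirrors the stages
(`radiotme simulate | extract-static | extract-kinetic | score |
associate | classify | run-full`); see `radiotme --help`.

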