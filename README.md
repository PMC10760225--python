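# histopheno

Self-supervised histomorphological phenotype analysis for biopsy whole-slide
images, with survival and binary-outcome modelling on compositional patient
vectors.

## The problem

Risk stratification of primary cutaneous squamous cell carcinoma (cSCC) at
the time of initial biopsy is hard: most poor outcomes (local recurrence,
nodal or distant metastasis, disease-specific death) occur in tumors that
current staging systems call low risk. Supervised deep learning needs
expensive annotations and is hard to interpret. The alternative implemented
here learns a vocabulary of recurring tissue morphologies directly from
unlabeled image tiles, and only then asks which morphologies carry
prognostic signal — keeping every modelling step linear and inspectable.

The pipeline:

1. **Tessellation** — each slide is rescaled to ~0.5 µm/px, cut into
   non-overlapping 224×224 px tiles, tiles with >75% background rejected,
   and colors normalized with Reinhard mean/std transfer in lαβ space.
2. **Self-supervised encoding** — a Barlow-Twins encoder maps each tile to
   a 128-d vector *z*. For two augmented views of a batch with
   batch-normalized embeddings ẑ^A, ẑ^B, the loss is

   L = Σᵢ (1 − Cᵢᵢ)² + λ Σ_{i≠j} Cᵢⱼ²,  with Cᵢⱼ = (1/n) Σ_b ẑ^A_{b,i} ẑ^B_{b,j},

   pushing the cross-correlation C toward the identity (invariance on the
   diagonal, redundancy reduction off it). 40% of tiles per institution are
   used for training.
3. **Phenotype clustering** — Leiden community detection on a kNN graph of
   the embeddings. A first pass at high resolution (r = 7) over-clusters so
   artifact tiles (bubbles, blur, blank glass) concentrate in near-white
   clusters, which are removed; a second pass at a resolution chosen by
   patient/institution presence metrics defines the histomorphological
   phenotype clusters (HPCs).
4. **Compositional representation** — each patient is the fraction of their
   tiles in each HPC, pooled over slides, mapped through the centered
   log-ratio clr(x)ₖ = ln xₖ − (1/K) Σⱼ ln xⱼ (pseudocount of one tile).
5. **Outcome models** — 3-fold cross-validated elastic-net logistic
   regression (good vs poor outcome, α = 0.25) and elastic-net Cox
   regression on disease-free survival (α = 0.35, l1 ratio = 0.01), with
   folds constrained to matching train/test Kaplan-Meier profiles. Test
   patients are split at the median training hazard and compared by
   log-rank; discrimination is measured by AUROC and Harrell's/Uno's
   c-index.
6. **Interpretation** — exact linear SHAP, forest summaries (fold-averaged
   log hazard ratios with Fisher-combined Wald p-values), Spearman
   enrichment with Benjamini-Hochberg correction, and tile-adjacency
   interaction matrices describing which phenotypes neighbor each other on
   the slide.

Because the multi-institution clinical cohorts such a study uses are
private, the package ships a fully labelled synthetic cohort generator
(three institutions, unequal sizes and outcome mixes, one multi-slide
institution, planted phenotype textures including an artifact phenotype,
and survival drawn from a proportional-hazards model on the planted
compositions). The generator is first-class, tested code: it is the oracle
against which clustering recovery, artifact filtering and parameter
recovery are measured.

## Worked example

`examples/05_outcome_models.py` generates a 300-patient synthetic cohort,
builds CLR patient vectors from the planted phenotypes and cross-validates
both models:

```
fold KM gaps (train vs test): ['0.070', '0.136', '0.079']

Cox (disease-free survival):
      harrell_c_validation  uno_c_validation  harrell_c_test  uno_c_test
fold
0                    0.749             0.767           0.838       0.825
1                    0.805             0.799           0.841       0.845
2                    0.850             0.854           0.768       0.749
mean held-out Harrell c: 0.816

median-split risk stratification (per test fold):
  fold 0: high-risk n=46, log-rank p = 2.80e-05
  fold 1: high-risk n=52, log-rank p = 2.25e-08
  fold 2: high-risk n=64, log-rank p = 6.00e-03
```

The KM gaps show the fold constraint holding (≤ 0.15); the held-out
c-indices near 0.8 and the small log-rank p-values show the planted
phenotype-hazard link surviving the penalized Cox fit; the per-fold
coefficient printout in the example shows each planted log-hazard coming
back with the correct sign, shrunk toward zero by the penalty.

Other examples cover the generator (`01`), preprocessing (`02`), encoder
training (`03`), clustering with the artifact pass (`04`), interpretation
(`06`) and the one-command pipeline (`07`). The same stages are available
from a thin CLI: `histopheno demo|synthesize|validate|train-ssl|embed|
cluster|represent|fit-outcomes`.

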