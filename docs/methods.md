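# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of `histopheno`. Everything
quantitative stated here is computed by the test suite or
`scripts/acceptance.py`.

## Pipeline model

The package treats a whole-slide image as a bag of square tiles on a grid.
Tiles are embedded by a self-supervised encoder, clustered into
histomorphological phenotype clusters (HPCs), and each patient is reduced
to the composition of their tiles over HPCs. All downstream inference is
linear modelling on the centered log-ratio (CLR) of that composition. The
approach assumes that (i) prognostic information is carried by *which*
morphologies appear and in what proportions, not by their spatial layout
(spatial structure is summarized separately, descriptively, by the
adjacency interaction matrix), and (ii) tile morphology is exchangeable
within a cluster.

### Preprocessing

Slides are rescaled to a working resolution of 0.5 µm/px (area-averaging
resampling for downscales, bilinear for upscales), gridded into
non-overlapping `tile_px` squares (default 224) with half-open pixel
windows `[r·s, (r+1)·s)` in row-major order, and partial edge tiles
dropped. A pixel is background when, after a 3×3 mean filter, all three
channels are ≥ 220/255 — the standard white-glass detection; a tile is
rejected when background exceeds 75%. Deliberately out of scope here:
pen-mark/blur detection, which the artifact cluster pass handles.

Reinhard normalization works in the Ruderman lαβ decomposition
(RGB → LMS → log10 → fixed orthogonal transform): each channel is shifted
and scaled to a target mean/std, then mapped back and clipped to valid RGB.
The default target is the pooled statistic of the run's kept tiles,
overridable for cross-cohort parity. A source channel with zero spread is
only mean-shifted (scaling is undefined). The function returns float RGB
in [0, 1] so post-conditions on channel statistics can be checked below
8-bit quantization noise.

### Barlow-Twins encoder

The loss is built from the empirical cross-correlation of two views'
batch-normalized embeddings; it is zero exactly when that matrix is the
identity, grows as 4d for perfectly anti-correlated whitened views, and is
invariant to simultaneous permutation of both views' embedding columns.
λ (off-diagonal weight) defaults to 5·10⁻³, the original setting for this
loss family. Batch normalization uses biased variance with an ε = 10⁻⁶
guard inside the square root; the guard bounds the attainable exactness of
the algebraic identities at ~10⁻⁶ and is accounted for in the tests. A
zero-variance embedding column is a hard error in the public loss function
(it means a dead unit) but is tolerated inside the training loop, where the
guard keeps the gradient finite.

At desk scale the encoder is a fully connected network on tiles
down-sampled to 16×16×3: 768 → 512 → 128 (z) → 128 (projector head), ReLU
between layers, trained with Adam (lr 10⁻³, batch 64). Forward and
backward passes are written directly in numpy; the gradient of the loss
through the batch normalization is hand-derived and verified against
central finite differences to 10⁻⁴ on a 4×3 batch. Embeddings are the
z-layer output with augmentations disabled. The training subset is 40% of
kept tiles drawn per institution. Augmentations: random crop-resize (scale
≥ 0.6), horizontal/vertical flips, brightness/contrast/channel jitter, and
Gaussian blur; all strengths at zero reproduce the input exactly, which
pins the augmentation semantics in tests.

A bypass mode (`synthetic.sample_embeddings`) emits Gaussian-mixture
embeddings centered per planted phenotype, so clustering and statistics can
be tested without inheriting training stochasticity.

### Clustering

kNN graphs (default k = 50, cosine metric — embeddings are
direction-coded) feed Leiden with the RB-configuration objective; labels
are relabeled contiguously by decreasing cluster size. The artifact pass
over-clusters at r = 7; cluster-level mean tile luminance proposes artifact
candidates (threshold 215/255), standing in for the visual inspection that
identifies bubble/blur clusters in production use. The second pass re-runs
kNN on the retained tiles rather than sub-setting the old graph — the
removed tiles would otherwise still shape neighborhoods.

Resolution selection follows presence heuristics: for each resolution, the
average percentage of patients (institutions) with ≥ 1 tile — and with
≥ 1% of their own tiles — per cluster. Declines in these averages signal
patient- or institution-specific clusters; `select_resolution` takes the
largest resolution before the 1%-threshold patient presence falls more
than 2 percentage points below its running maximum. UMAP/PAGA layouts are
delegated to scanpy for visualization only.

### Compositions and CLR

Patient vectors pool tile counts across the patient's slides before
normalizing (a slide with three times the tiles carries three times the
weight), because the quantity modelled is the percentage of the patient's
tiles per cluster; slide-averaging is available but not default. Structural
zeros get an additive pseudocount of one tile before normalization
(multiplicative replacement behind a flag); CLR output rows sum to zero to
10⁻⁹ and are scale-invariant. CLR is applied after pooling.

### Outcome models

Elastic-net parameterization is explicit: `alpha` is the per-observation
penalty strength, `l1_ratio` the L1 share. The logistic model uses
α = 0.25 with a default `l1_ratio` of 0.5 (the L1 share for this model was
not part of the published settings; 0.5 is this package's documented
choice), mapped to scikit-learn's saga solver via C = 1/(α·n) so the fit
is invariant to duplicating observations. The Cox model uses coxnet with
α = 0.35, l1_ratio = 0.01 — almost ridge, so most coefficients stay active
but shrunk.

Folds: patients are permuted into three test thirds; the remaining
patients split 80/20 train/validation. Candidate splits are rejected until
the maximum vertical gap between each fold's train and test Kaplan-Meier
curves (evaluated at pooled event times) is ≤ `km_tolerance` (default
0.15); after 200 attempts the best split found is used with a warning.
CLR features are not re-standardized before the penalized fits (CLR
already centers per sample); a flag exists.

Wald tests on penalized fits are ill-defined, so p-values come from an
unpenalized refit restricted to the active set (|coef| > 10⁻⁸). Because
CLR columns sum to zero, an active set containing all K clusters is
exactly collinear; the refit greedily drops smallest-|coef| columns until
the design is full rank and reports NaN for dropped coefficients. Per-fold
p-values are combined with Fisher's method (−2Σ ln p ~ χ²(2m)).

Risk stratification thresholds test patients at the median (lower-median
convention for even n) of the *training* hazard predictions, so test
outcomes play no role in defining the groups and the log-rank test keeps
its nominal level. Uno's c truncates at the largest training event time by
default and is reported NaN for splits with no events before that horizon
(the IPCW sum is empty there). Concordance metrics with a constant score
vector are reported as 0.5 — a constant-risk model is chance-level.

## Synthetic study conditions

The generator emulates the structure of a three-institution cSCC biopsy
cohort: 38/85/40 patients per institution (163 total — the published
per-institution post-exclusion tally; the alternative 119 good/44 poor
overall split printed elsewhere in the same source is exposed as a second
preset without resolving the discrepancy), 1–5 slides per patient for one
institution and exactly one for the others, and 30–100 tiles per slide
(desk scale; the real cohorts run to thousands of tiles per slide).

Eight tissue phenotypes plus one artifact phenotype are planted. Patient
compositions are Dirichlet with concentration (3, 2, 1.5, 1, 1, 0.8, 0.5,
0.3) — cluster sizes vary considerably, as observed in practice — and each
institution multiplies the concentration of high-hazard phenotypes by a
tilt (0.7 / 1.0 / 1.6) to produce the unequal outcome mixes. Artifact
tiles replace tissue tiles at 5% (the production pipeline discarded ~3.4%
of tiles as artifact clusters). Survival: event times are exponential with
rate λ₀·exp(β·clr(composition)), β = (0.8, 0.5, 0, 0, −0.5, −0.8, 0, 0),
λ₀ = 4·10⁻⁴/month, independent exponential censoring at 10⁻²/month and
administrative censoring at 120 months. These rates were calibrated once
so the marginal event fraction (~27%) and the discrimination attainable by
the true model (oracle c-index ≈ 0.84) match the emulated cohort's regime;
the null-calibration experiments set β = 0 and raise λ₀ to 5·10⁻³ so the
event rate stays comparable. Outcome subtype is assigned by which planted
phenotype dominates (phenotype 0 → local recurrence; phenotype 1 →
metastasis, split nodal/distant/disease-specific death), and a whole-slide
diagnosis label is emitted only for the multi-slide institution.

Tile images are procedural textures — phenotype-specific palettes, blob
densities and radii on a pink-ish base; the artifact phenotype is
near-white with faint gray smudges covering ~⅓ of the tile, so its mean
luminance exceeds the white-glass threshold while fewer than 75% of its
pixels classify as background (real bubbles and blur also survive that
filter). The generator does **not** emulate: realistic histology, stain
variation between institutions, scanner noise, spatially correlated
phenotype layouts within a slide, or tile-level label noise. Passing tests
therefore show that the machinery is correct and recovers planted structure
under favorable separation — not that the encoder or the clustering would
achieve any particular performance on real stained tissue.

All randomness derives from a single integer seed via SHA-256-hashed named
sub-streams, so any entity's draw is independent of generation order and
every stage is reproducible bit-for-bit at fixed library versions.

## Problem sizes

Tests and the acceptance script run the cohort at its default 163 patients
(~15k tiles), clustering recovery on 4,000 tiles in 128-d, parameter
recovery on 20 replicates of 300-patient cohorts, null calibration on
40 cross-validated replicates plus 200 log-rank simulations, and encoder
training on 2,000 64-px tiles for 5 epochs — sizes chosen so the full
suite completes in a few minutes on one CPU while leaving the planted
effects comfortably detectable.

## Known limitations

- The encoder is a toy: a 16×16 down-sampled MLP cannot represent the
  texture detail a convolutional backbone learns at full scale; its role
  here is to realize the loss and training contract faithfully.
- Artifact identification is automated by luminance ranking only in the
  synthetic setting; on real slides it remains a visual review step.
- The presence-based resolution selection can under-split when rare planted
  phenotypes make presence decline for sparsity rather than overfitting
  reasons; the sweep table is written out so the choice is auditable.
- Fisher's combination treats fold p-values as independent; folds share
  80% of training patients pairwise, so combined p-values are
  anti-conservative and should be read as rankings, not calibrated error
  rates (the same caveat applies to the emulated workflow).
- The proportional-hazards generator draws event times from the same family
  the Cox model assumes; parameter-recovery results do not probe model
  misspecification.
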