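"""Interpretation outputs: SHAP, forest summary, enrichment, tile adjacency.

All interpretation is exact for the linear models used here: SHAP values
are w_k (x_k - background_k) and sum to the prediction; the forest table
combines per-fold Wald p-values with Fisher's method; Spearman enrichment
correlates cluster proportions with labels (BH-adjusted); and the adjacency
matrix summarizes which phenotypes neighbor each other on the slide grids.
"""

import numpy as np

from histopheno import composition, interpret, models, synthetic
from histopheno.clustering import HPCAssignment

cfg = synthetic.SyntheticConfig(
    seed=6, n_patients_per_institution={"NYU": 50, "UCSF": 100, "BWH": 50}
)
manifest, _, truth = synthetic.generate_cohort(cfg, tiles="none")
tp = truth.tile_phenotype[~truth.tile_phenotype["is_artifact"]]
assignment = HPCAssignment(tp["tile_id"].to_numpy(object), tp["phenotype"].to_numpy(), 0.0)
counts = composition.composition_matrix(assignment, tp, "patient_id",
                                        n_clusters=cfg.n_phenotypes, as_counts=True)
clr = composition.clr_matrix(counts)
patients = manifest.drop_duplicates("patient_id").reset_index(drop=True)
folds = models.make_folds(patients, seed=6)
cox = models.cross_validate(clr.loc[patients["patient_id"]], patients, folds, "cox")

# forest summary: mean log hazard ratio, Fisher-combined p, patient presence
forest = interpret.forest_summary(cox, counts)
print("forest summary:")
print(forest.round(4).to_string(index=False))

# SHAP on the locked fold's test set
fit = cox.fold_fits[0]
test_ids = folds.patients(0, "test")
background = clr.loc[folds.patients(0, "train")].mean(axis=0).to_numpy()
shap = interpret.linear_shap(fit.coef, 0.0, clr.loc[test_ids], background)
pred = clr.loc[test_ids].to_numpy() @ fit.coef
print(f"\nSHAP additivity holds exactly: {shap.check_additivity(pred, tol=1e-9)}")
top = shap.values.abs().mean(axis=0).sort_values(ascending=False).head(3)
print("clusters with largest mean |SHAP|:", ", ".join(top.index))

# enrichment of cluster proportions in LR vs overall metastasis (NM + DM)
subtype = patients.set_index("patient_id")["outcome_subtype"]
target = subtype[subtype.isin(["LR", "NM", "DM"])].map({"LR": 0, "NM": 1, "DM": 1})
props = counts.div(counts.sum(axis=1), axis=0)
enrich = interpret.spearman_enrichment(props.loc[target.index], target)
print("\nSpearman enrichment, local recurrence (rho<0) vs metastasis (rho>0):")
print(enrich.round(4).to_string(index=False))

# adjacency interactions on one slide's grid
tiles = assignment.to_frame().merge(tp, on="tile_id")
m = interpret.adjacency_interactions(tiles, n_clusters=cfg.n_phenotypes)
print("\nadjacency interaction matrix (columns sum to 1):")
print(m.round(2).to_string())
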