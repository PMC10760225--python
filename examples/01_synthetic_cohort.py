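"""Generate the synthetic multi-institution biopsy cohort and inspect it.

The generator emulates a three-institution cutaneous SCC cohort: unequal
institution sizes and outcome mixes, one institution with several slides per
patient, per-slide tile grids with planted phenotypes (plus a near-white
artifact phenotype), and disease-free survival drawn from a proportional-
hazards model on each patient's true phenotype composition.
"""

from histopheno import synthetic

cfg = synthetic.SyntheticConfig(seed=1)
manifest, _, truth = synthetic.generate_cohort(cfg, tiles="none")

patients = manifest.drop_duplicates("patient_id")
print(f"patients: {len(patients)}  slides: {len(manifest)}  tiles: {len(truth.tile_phenotype)}")
print("\nper institution (patients / poor outcomes):")
for inst, grp in patients.groupby("institution"):
    print(f"  {inst:5s} {len(grp):4d} patients, {int((grp['outcome'] == 'poor').sum()):3d} poor")
print(f"\nobserved event rate: {patients['event'].mean():.1%}")
print(f"artifact tiles:      {truth.tile_phenotype['is_artifact'].mean():.1%}")

# the printed published-cohort arithmetic the generator mirrors
preset = synthetic.manifest_from_counts("results")
print(f"\n'results' preset: {len(preset)} patients "
      f"({(preset['outcome'] == 'good').sum()} good / {(preset['outcome'] == 'poor').sum()} poor)")
# Patients, slides and tiles are deterministic in the seed, so every
# downstream stage can be tested against these planted labels.
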