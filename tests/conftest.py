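import numpy as np
import pandas as pd
import pytest

from histopheno import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """163-patient default cohort, manifest + ground truth only (no images)."""
    cfg = synthetic.SyntheticConfig(seed=7)
    manifest, _, truth = synthetic.generate_cohort(cfg, tiles="none")
    return cfg, manifest, truth


@pytest.fixture(scope="session")
def tiny_cohort_images():
    """Very small cohort with rendered tile images."""
    cfg = synthetic.SyntheticConfig(
        seed=3,
        n_patients_per_institution={"NYU": 3, "UCSF": 4, "BWH": 3},
        tiles_per_slide=(8, 15),
        tile_px=32,
    )
    manifest, store, truth = synthetic.generate_cohort(cfg, tiles="images")
    return cfg, manifest, store, truth


@pytest.fixture(scope="session")
def clustered_embeddings(small_cohort):
    """Bypass embeddings + Leiden assignment on a 3,000-tile subsample."""
    from histopheno import clustering

    _, manifest, truth = small_cohort
    tiles = truth.tile_phenotype.sample(3000, random_state=0).reset_index(drop=True)
    emb = synthetic.sample_embeddings(tiles["phenotype"].to_numpy(), seed=7)
    graph = clustering.build_knn_graph(emb, 30)
    assignment = clustering.leiden_cluster(
        graph, 1.0, seed=0, tile_ids=tiles["tile_id"].to_numpy()
    )
    meta = tiles.merge(manifest[["slide_id", "institution"]].drop_duplicates(), on="slide_id")
    return emb, tiles, meta, assignment


@pytest.fixture()
def survival_fixture():
    """8-patient mixed-censoring fixture used against brute-force oracles."""
    return pd.DataFrame(
        {
            "time": [2.0, 3.0, 3.5, 5.0, 6.0, 8.0, 9.0, 11.0],
            "event": [1, 1, 0, 1, 0, 1, 0, 1],
            "score": [3.2, 2.5, 1.0, 2.8, 0.5, 1.7, 0.2, -0.4],
        }
    )
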