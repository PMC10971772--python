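import numpy as np
import pytest

from cyclemur import SimConfig, gen_ranges, gen_tracks, gen_tree
from cyclemur.gls import phylo_correlation, spatial_structure


@pytest.fixture(scope="session")
def small_world():
    """A 20-species synthetic world shared by the slower model tests."""
    cfg = SimConfig(n_storms=20, n_species=20, seed=42)
    ranges = gen_ranges(cfg)
    tree = gen_tree(cfg)
    ids = [r.species_id for r in ranges]
    P, _ = phylo_correlation(tree, ids)
    D = spatial_structure(np.array([r.centroid for r in ranges]))
    return {"cfg": cfg, "ranges": ranges, "tree": tree, "ids": ids, "P": P, "D": D}


@pytest.fixture(scope="session")
def synthetic_tracks():
    cfg = SimConfig(n_storms=20, n_species=5, seed=7, bbox=(0.0, 0.0, 500.0, 500.0))
    return cfg, gen_tracks(cfg)
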