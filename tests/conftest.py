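import numpy as np
import pytest

from crispr3d import (
    ContactMatrix,
    DensityFeatureSpec,
    SyntheticCrisprParams,
    SyntheticHiCParams,
    all_pairs,
    assemble,
    build_graph,
    simulate_dataset,
)


def random_contact_matrix(seed: int, n: int = 12, edge_p: float = 0.5) -> ContactMatrix:
    """Random sparse symmetric contact matrix for oracle comparisons."""
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, 1)
    keep = rng.random(len(iu)) < edge_p
    vals = rng.uniform(0.1, 5.0, int(keep.sum()))
    return ContactMatrix("chrT", 10_000, n, iu[keep] + 1, ju[keep] + 1, vals)


@pytest.fixture(scope="session")
def planted():
    """One planted synthetic dataset shared across read-only tests.

    80-bin chromosome with TAD blocks and coverage noise; 400 sites whose
    efficiency decreases with local 3D density (density_effect = -1) plus a
    GC effect and moderate noise.  The planted feature is a small-n Distance
    computed through the real contacts -> graph -> distances pipeline.
    """
    hic = SyntheticHiCParams(
        n_bins=80,
        decay_exponent=1.0,
        tad_boundaries=(30, 55),
        tad_enrichment=2.0,
        coverage_noise_sd=0.25,
        seed=11,
    )
    crispr = SyntheticCrisprParams(
        n_sites=400, density_effect=-1.0, sequence_effect=0.5, noise_sd=0.3, seed=12
    )
    contacts, dists, table, sites = simulate_dataset(hic, crispr)
    return {
        "contacts": contacts,
        "distances": dists,
        "table": table,
        "sites": sites,
        "planted_feature": table.feature_names[0],
    }


@pytest.fixture(scope="session")
def planted_fm(planted):
    """Assembled 426-column feature matrix (+efficiency) for the planted data."""
    return assemble(
        planted["sites"], planted["table"], include_3d=planted["planted_feature"]
    )


@pytest.fixture(scope="session")
def small_distances():
    """Path distances of a dense 30-bin noisy chromosome (no planting)."""
    hic = SyntheticHiCParams(n_bins=30, coverage_noise_sd=0.3, seed=21)
    from crispr3d import generate_contacts

    return all_pairs(build_graph(generate_contacts(hic)))
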