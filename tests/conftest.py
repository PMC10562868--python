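import numpy as np
import pytest

from ripcohort import (
    CountExperiment,
    NBParams,
    ProfileClustering,
    RIPEnrichment,
    build_lfc_matrix,
    generate_truth,
    simulate_counts,
)


@pytest.fixture(scope="session")
def demo_run():
    """A small but complete simulate -> enrich -> filter -> cluster run,
    shared across tests that only read from it."""
    truth = generate_truth(400, n_factors=6, k=4, center_separation=2.0,
                           gene_noise_sd=0.3, seed=7)
    data = simulate_counts(truth, NBParams(dispersion=0.1, n_replicates=3), seed=8)
    experiment = CountExperiment(counts=data.counts, samples=data.samples)
    results = RIPEnrichment(experiment).fit()
    universe = results.filter_universe()
    profile = build_lfc_matrix(results.results, universe)
    model = ProfileClustering(profile, k=4, n_starts=20).fit(seed=0)
    return {
        "truth": truth,
        "experiment": experiment,
        "results": results,
        "universe": universe,
        "profile": profile,
        "cluster_model": model,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
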