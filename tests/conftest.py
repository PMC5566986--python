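import numpy as np
import pytest

import dyadscan as ds


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset shared across tests: 300 genes, 5 planted
    dyads, default study-shaped sample design."""
    params = ds.SimulationParams(n_genes=300, n_planted_dyads=5, seed=1)
    matrix, samples, evidence, truth = ds.simulate_dataset(params)
    return params, matrix, samples, evidence, truth


@pytest.fixture(scope="session")
def small_run(small_dataset):
    """Stage-by-stage analysis of the small dataset (MYCN_NA cohort)."""
    _, matrix, samples, evidence, truth = small_dataset
    th = ds.Thresholds()
    scores = ds.consensus_score(evidence, th.consensus_votes_min)
    surf = ds.select_surfaceome(matrix, scores)
    gstats = ds.gene_stats(surf, samples, "MYCN_NA", th)
    screened = ds.screen(gstats, th)
    m_log = ds.log2_transform(surf.subset_genes(screened), th.pseudocount)
    dyads = ds.apply_filters(
        ds.dyad_scan(m_log, samples, "MYCN_NA", th), gstats, th
    )
    ranked, summary = ds.rank_dyads(dyads)
    return {
        "thresholds": th,
        "surface": surf,
        "gstats": gstats,
        "screened": screened,
        "dyads": dyads,
        "ranked": ranked,
        "summary": summary,
        "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
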