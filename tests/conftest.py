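"""Shared fixtures: small simulated populations and benchmark replicates.

The heavyweight fixtures (full-scale benchmark replicates) are session-scoped
and shared between the acceptance tests so each replicate is simulated once.
"""

import numpy as np
import pytest

from genosel import SimScenario, generate_replicate, maf_filter, accuracy, bias_slope


@pytest.fixture(scope="session")
def tiny_scenario():
    """Miniature population for fast structural tests."""
    return SimScenario(
        n_chromosomes=2, chrom_length_cM=100.0, markers_per_chrom=11,
        qtl_per_chrom=5, ne=20, n_generations=50,
        marker_mutation_rate=5e-3, qtl_mutation_rate=1e-3,
        n_training=40, n_candidates=30,
    )


@pytest.fixture(scope="session")
def tiny_replicate(tiny_scenario):
    return generate_replicate(tiny_scenario, 42)


def filtered_training(rep, threshold=0.05):
    """MAF-filter a replicate's training set and subset candidates identically."""
    gm, pt = rep.training
    gm_cand, tbv = rep.candidates
    filtered, _ = maf_filter(gm, threshold)
    keep = set(filtered.snp_ids)
    mask = np.array([s in keep for s in gm_cand.snp_ids])
    return (filtered.codes.astype(np.float64), pt.y,
            gm_cand.codes[:, mask].astype(np.float64), tbv)


def fit_and_score(rep, estimator, threshold=0.05):
    """Fit an estimator on a replicate's filtered training set; return
    (accuracy, bias slope, fitted estimator)."""
    U, y, Uc, tbv = filtered_training(rep, threshold)
    estimator.fit(U, y)
    gbv = estimator.predict(Uc)
    return accuracy(gbv, tbv), bias_slope(tbv, gbv), estimator


@pytest.fixture(scope="session")
def data1_replicates():
    """Ten sparse-marker benchmark replicates (1010 markers)."""
    sc = SimScenario.data1()
    return [generate_replicate(sc, np.random.SeedSequence(entropy=0, spawn_key=(i,)))
            for i in range(10)]


@pytest.fixture(scope="session")
def data2_replicates():
    """Four dense-marker benchmark replicates (10100 markers)."""
    sc = SimScenario.data2()
    return [generate_replicate(sc, np.random.SeedSequence(entropy=0, spawn_key=(100 + i,)))
            for i in range(4)]
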