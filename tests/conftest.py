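"""Shared fixtures: one seeded toy study reused across the suite.

A 60 kb synthetic chromosome with a variant-dense 'locus' region and
promoter-like targets, a diploid sample with bimodal CpG methylation and
ten planted differential regions, a 3X-tiled boosted probe panel, and
captured DNA/BS/EM read sets for both conditions.  Session-scoped so the
simulations run once.
"""

from __future__ import annotations

import numpy as np
import pytest

import methpanel as mp

SEED = 20230824

LOCUS = mp.GenomicInterval("chr1", 10_000, 40_000)
PROMOTERS = [
    mp.GenomicInterval("chr1", 42_000 + i * 600, 42_000 + i * 600 + 150)
    for i in range(20)
]
DMR_SPEC = [
    (mp.GenomicInterval("chr1", 15_000 + i * 1_500, 15_000 + i * 1_500 + 300), 0.3)
    for i in range(10)
]


@pytest.fixture(scope="session")
def toy_reference():
    return mp.simulate_reference(
        length=60_000,
        gc_target=0.45,
        cpg_rate=0.02,
        repeat_spec=mp.RepeatSpec(count=4, unit_length=25, copies=8),
        seed=SEED,
    )


@pytest.fixture(scope="session")
def toy_truth(toy_reference):
    truth = mp.simulate_diploid(
        toy_reference,
        snv_rate=1e-3,
        het_fraction=0.8,
        dense_region=LOCUS,
        dense_multiplier=4.0,
        seed=SEED + 1,
    )
    return mp.assign_methylation(truth, dmr_spec=DMR_SPEC, seed=SEED + 2)


@pytest.fixture(scope="session")
def toy_panel(toy_reference):
    return mp.design_panel(
        {"locus": [LOCUS], "promoters": PROMOTERS},
        toy_reference,
        tiling_density={"locus": 3, "promoters": 1},
    )


def _reads(truth, panel, conversion, condition, seed, n=20_000):
    return mp.simulate_capture_reads(
        truth,
        panel,
        n_fragments=n,
        conversion=conversion,
        condition=condition,
        seed=seed,
    )


@pytest.fixture(scope="session")
def dna_obs(toy_truth, toy_panel):
    return _reads(toy_truth, toy_panel, mp.ConversionModel.none(), "A", SEED + 10)


@pytest.fixture(scope="session")
def dna_obs_rep(toy_truth, toy_panel):
    return _reads(toy_truth, toy_panel, mp.ConversionModel.none(), "A", SEED + 11)


@pytest.fixture(scope="session")
def bs_obs_a(toy_truth, toy_panel):
    return _reads(toy_truth, toy_panel, mp.ConversionModel.bisulfite(), "A", SEED + 12)


@pytest.fixture(scope="session")
def bs_obs_b(toy_truth, toy_panel):
    return _reads(toy_truth, toy_panel, mp.ConversionModel.bisulfite(), "B", SEED + 13)


@pytest.fixture(scope="session")
def em_obs_a(toy_truth, toy_panel):
    return _reads(toy_truth, toy_panel, mp.ConversionModel.enzymatic(), "A", SEED + 14)


@pytest.fixture(scope="session")
def em_obs_b(toy_truth, toy_panel):
    return _reads(toy_truth, toy_panel, mp.ConversionModel.enzymatic(), "B", SEED + 15)


@pytest.fixture(scope="session")
def bs_table_a(bs_obs_a, toy_reference):
    return mp.quantify(bs_obs_a, toy_reference, sample="A", library="BS", min_cov=10)


@pytest.fixture(scope="session")
def bs_table_b(bs_obs_b, toy_reference):
    return mp.quantify(bs_obs_b, toy_reference, sample="B", library="BS", min_cov=10)


@pytest.fixture(scope="session")
def em_table_a(em_obs_a, toy_reference):
    return mp.quantify(em_obs_a, toy_reference, sample="A", library="EM", min_cov=10)


@pytest.fixture(scope="session")
def em_table_b(em_obs_b, toy_reference):
    return mp.quantify(em_obs_b, toy_reference, sample="B", library="EM", min_cov=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
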