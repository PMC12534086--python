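"""Shared fixtures: the synthetic Vitellogenin-like gene, its allele pool,
and a hand-built toy gene whose splicing can be checked by eye."""

from __future__ import annotations

import pytest

from beemas import simulate
from beemas.catalog import build_catalog_from_consensus
from beemas.genemodel import GeneModel


@pytest.fixture(scope="session")
def vg_model() -> GeneModel:
    return simulate.vitellogenin_like_model(seed=0)


@pytest.fixture(scope="session")
def pool(vg_model):
    return simulate.polline_pool(vg_model)


@pytest.fixture(scope="session")
def population():
    return simulate.polline_population(seed=0)


@pytest.fixture(scope="session")
def records(pool, population):
    """Noiseless truth records for all clean samples (truth variant ids)."""
    return simulate.truth_records(pool, population)


@pytest.fixture(scope="session")
def pol_records(records):
    return [r for r in records if r.stock == "Pol-line"]


@pytest.fixture(scope="session")
def catalog_result(vg_model, records):
    """Catalogue rebuilt from the noiseless consensus sequences."""
    samples = [
        (r.sample_id, r.colony, r.stock, r.caste, r.sequence, r.ploidy) for r in records
    ]
    return build_catalog_from_consensus(samples, vg_model)


@pytest.fixture(scope="session")
def toy_model() -> GeneModel:
    """Two exons (1-9, 20-28), CDS 4..25: spliced CDS = ATG GCT GAA TAA.

    gene:  TTT ATG GCT | tttttttttt | GAA TAA CCC
           123 456 789   10......19   20.....  28
    """
    seq = "TTTATGGCT" + "T" * 10 + "GAATAACCC"
    return GeneModel("toy", seq, exons=((1, 9), (20, 28)), cds_start=4, cds_end=25)
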