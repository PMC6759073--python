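import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from codonstats import CdsRecord, SpeciesSpec, generate_species
from codonstats.io import SpeciesCollection


def make_records(seqs, species_id="sp1"):
    return [CdsRecord(seq_id=f"{species_id}_g{i}", species_id=species_id, sequence=s)
            for i, s in enumerate(seqs)]


@pytest.fixture
def uniform_null_species():
    """Small single-species corpus with no planted structure (null model)."""
    spec = SpeciesSpec(
        species_id="null", domain="Bacteria", gc_target=0.5,
        arginine_profile=(1, 1, 1, 1, 1, 1), optimal_set={},
        stickiness=0.0, n_genes=30, gene_length_range=(300, 900),
        expression_spread=0.0, seed=123)
    records, abundance, truth = generate_species(spec)
    return spec, records, abundance, truth


@pytest.fixture
def null_collection(uniform_null_species):
    spec, records, abundance, _ = uniform_null_species
    return SpeciesCollection(spec.species_id, spec.domain, "p", records), abundance
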