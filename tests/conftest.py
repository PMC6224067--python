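"""Shared fixtures: small genomes with planted, ground-truthed fragments."""

import pytest

from aflp import combo_from_label, plant_fragment, simulate_genome


@pytest.fixture(scope="session")
def toy_genome():
    # EcoRI site at 3 (cut 4), MseI site at 12 (cut 13)
    return "AAAGAATTCTTTTTAACCC"


@pytest.fixture(scope="session")
def cag_agg():
    return combo_from_label("CAG_AGG")


@pytest.fixture(scope="session")
def planted(cag_agg):
    """A 2 kb genome with one planted CAG_AGG fragment of insert 56."""
    genome = simulate_genome(2000, seed=11)
    genome, truth = plant_fragment(genome, cag_agg, insert_size=56, position=700, seed=3)
    return genome, truth
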