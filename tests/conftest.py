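"""Shared fixtures: small deterministic synthetic families."""

import pytest

from clefam import synthdata


@pytest.fixture(scope="session")
def default_family():
    """Default family: 6 clades x 20 genes, 6 duplication events."""
    cfg = synthdata.FamilySimConfig(seed=0)
    return synthdata.generate_family(cfg)


@pytest.fixture(scope="session")
def small_family():
    """Compact family for fast graph/embedding tests."""
    cfg = synthdata.FamilySimConfig(n_clades=3, genes_per_clade=6,
                                    duplication_events=2, seed=1)
    return synthdata.generate_family(cfg)
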