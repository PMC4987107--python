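import pytest

from catoolkit.components import ComponentCatalog, ComponentLabel, load_default_catalog
from catoolkit.core_model import load_default_registry, parse_architecture
from catoolkit.proteome_io import GenomeTable, ProteomeRecord


@pytest.fixture(scope="session")
def registry():
    """The packaged curated calcium-binding superfamily registry."""
    return load_default_registry()


@pytest.fixture(scope="session")
def catalog():
    """The packaged example component catalog (influx/efflux/decoding/relay)."""
    return load_default_catalog()


@pytest.fixture
def toy_genome():
    """Five proteins, four distinct architectures, three calcium-binding ones."""
    rows = {
        "A": "47473",
        "B": "47473,_gap_",
        "C": "56112",
        "D": "47473",
        "E": "49562,56112",
    }
    return GenomeTable(
        "toy",
        tuple(ProteomeRecord(pid, parse_architecture(s)) for pid, s in rows.items()),
    )


@pytest.fixture
def mini_catalog():
    """Two-component catalog: one calcium-binding, one calcium-independent."""
    return ComponentCatalog(
        (
            ComponentLabel("decoding-CDPK", "decoding", True),
            ComponentLabel("relay-muscle-contraction", "relay", False),
        )
    )


def make_genome(genome_id, arch_strings):
    """GenomeTable with one protein per architecture string (auto ids)."""
    return GenomeTable(
        genome_id,
        tuple(
            ProteomeRecord(f"{genome_id}_p{i}", parse_architecture(s))
            for i, s in enumerate(arch_strings)
        ),
    )
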