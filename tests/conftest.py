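import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from rmscan.model import GeneRecord, Replicon, Role, RMType, Thresholds, Topology


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture
def linear_replicon():
    return Replicon(id="chr", genome_id="G1", length=1_000_000, topology=Topology.LINEAR)


@pytest.fixture
def circular_replicon():
    return Replicon(id="pCIRC", genome_id="G1", length=100_000, topology=Topology.CIRCULAR)


def make_gene(
    gene_id="g1",
    genome_id="G1",
    replicon_id="chr",
    start=10_000,
    end=11_000,
    strand="+",
    role=Role.RE,
    rm_type=RMType.II,
    corrupted=False,
    protein_seq="M" + "ACDEFGHIKLMNPQRSTVWY" * 10,
    system_id=None,
    product=None,
    arcs=None,
):
    return GeneRecord(
        gene_id=gene_id,
        genome_id=genome_id,
        replicon_id=replicon_id,
        start=start,
        end=end,
        strand=strand,
        role=role,
        rm_type=rm_type,
        corrupted=corrupted,
        protein_seq=protein_seq,
        system_id=system_id,
        product=product,
        arcs=arcs,
    )


@pytest.fixture
def gene_factory():
    return make_gene
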