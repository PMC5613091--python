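import pytest

from plasmidfusion.synthetic import (CompositePlasmidSpec,
                                     generate_composite_plasmid,
                                     martelella_like_genome)


def small_fusion_spec(**kwargs) -> CompositePlasmidSpec:
    """A scaled-down fusion plasmid (40-kb backbone + 16-kb insertion) that
    keeps every planted structure of the full-size default."""
    return CompositePlasmidSpec.pmm259_like(
        backbone_length=40_000, insertion_length=16_000, **kwargs)


@pytest.fixture(scope="session")
def small_composite():
    """(replicon, truth, hit table) for the scaled fusion plasmid."""
    return generate_composite_plasmid(small_fusion_spec(), seed=7)


@pytest.fixture(scope="session")
def genome_bundle():
    """The synthetic four-replicon Martelella-like genome set."""
    return martelella_like_genome(seed=11)


GENBANK_MINIMAL = """\
LOCUS       TESTREP                   60 bp    DNA     circular BCT 01-JAN-2020
DEFINITION  synthetic test replicon.
ACCESSION   TESTREP
FEATURES             Location/Qualifiers
     CDS             3..11
                     /locus_tag="T_0001"
                     /product="hypothetical protein"
     CDS             complement(20..28)
                     /locus_tag="T_0002"
                     /product="replicase RepC"
     CDS             join(55..60,1..6)
                     /locus_tag="T_0003"
                     /product="wrapping protein"
ORIGIN
        1 atgaaacccg ggtttaaacc cgggtttaaa cccgggttta aacccgggtt taaacccggg
//
"""


@pytest.fixture()
def genbank_file(tmp_path):
    p = tmp_path / "mini.gbk"
    p.write_text(GENBANK_MINIMAL)
    return p
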