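import pytest

from microjxn.exon_model import GeneModel, build_classifier
from microjxn.synthetic_data import toy_gene_model


@pytest.fixture
def toy_model() -> GeneModel:
    """+ strand model with the canonical 3/18/22 bp microexon architecture."""
    return toy_gene_model()


@pytest.fixture
def toy_classifier(toy_model):
    return build_classifier(toy_model)


@pytest.fixture
def minus_model() -> GeneModel:
    """The toy model reflected through a genomic pivot onto the - strand."""
    pivot = 10000
    plus = toy_gene_model()
    exons = [
        {
            "name": e.name,
            "start": pivot - e.end,
            "end": pivot - e.start,
            "kind": e.kind,
        }
        for e in plus.exons
    ]
    return GeneModel.from_dict(
        {
            "gene_id": plus.gene_id,
            "chrom": plus.chrom,
            "strand": "-",
            "anchor": plus.anchor,
            "terminal": plus.terminal,
            "exons": exons,
        }
    )
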