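import pandas as pd
import pytest

from crtkit.harmonize import GeneModels
from crtkit.simulate import gen_reference
from crtkit.simulate.scenarios import scaled_screen as make_screen  # noqa: F401


@pytest.fixture(scope="session")
def ref():
    return gen_reference(seed=11, n_chromosomes=2, chrom_length=400_000, n_genes=10)


@pytest.fixture(scope="session")
def toy_gene_models():
    """One plus- and one minus-strand gene on a 100 kb chromosome."""
    genes = pd.DataFrame(
        {
            "gene": ["A", "B"],
            "chrom": ["chr1", "chr1"],
            "strand": ["+", "-"],
            "start": [50_000, 80_000],
            "end": [56_000, 86_000],
            "coding": [True, True],
        }
    )
    tss = pd.DataFrame(
        {
            "gene": ["A", "B"],
            "chrom": ["chr1", "chr1"],
            "strand": ["+", "-"],
            "pos": [50_000, 85_999],
        }
    )
    exons = pd.DataFrame(
        {
            "gene": ["A", "B"],
            "chrom": ["chr1", "chr1"],
            "start": [50_100, 80_100],
            "end": [50_400, 80_400],
        }
    )
    return GeneModels(genes=genes, tss=tss, exons=exons, chromosomes={"chr1": 100_000})
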