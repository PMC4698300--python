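import io

import pytest

from cnvrecur.genome import CNVRecord, GenomeBuild, Patient
from cnvrecur.prioritization import read_expression
from cnvrecur.synthetic import SyntheticSpec, generate_all


@pytest.fixture
def toy_genome():
    """Single 10 kb chromosome, no exclusions."""
    return GenomeBuild("toy", (("chrT", 10_000),))


@pytest.fixture
def two_chrom_genome():
    return GenomeBuild("toy2", (("chrA", 1_000_000), ("chrB", 500_000)))


@pytest.fixture(scope="session")
def bundle():
    """Default planted synthetic bundle, seed 1 (shared; treat as read-only)."""
    return generate_all(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def bundle_expression(bundle):
    return read_expression(io.StringIO(bundle.expression_tsv))


def make_cnv(chrom, start, end, pid="P1", cnv_type="deletion"):
    return CNVRecord(chrom, start, end, pid, cnv_type)
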