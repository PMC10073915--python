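import numpy as np
import pandas as pd
import pytest

from sexbiasevo.core_io import ExpressionMatrix


def make_expression(gene_values: dict, samples: list[tuple[str, str, str, str]]) -> ExpressionMatrix:
    """Build a small ExpressionMatrix from {gene: [values]} and
    (sample_id, breed, sex, tissue) tuples."""
    sheet = pd.DataFrame(
        samples, columns=["sample_id", "breed", "sex", "tissue"]
    ).set_index("sample_id")
    values = pd.DataFrame(gene_values, index=sheet.index).T
    return ExpressionMatrix(values, sheet)


@pytest.fixture
def two_sex_samples():
    """5 males + 5 females of one breed/tissue."""
    return [(f"w_g_M{i}", "wild", "M", "gonad") for i in range(1, 6)] + [
        (f"w_g_F{i}", "wild", "F", "gonad") for i in range(1, 6)
    ]


@pytest.fixture
def minimal_vcf(tmp_path):
    """Two-sample VCF with a biallelic SNP, a missing-GT site, a
    multi-allelic site and an indel."""
    text = "\n".join(
        [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "##contig=<ID=chr1,length=1000>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2",
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1",
            "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0",
            "chr1\t300\t.\tC\tG,T\t.\tPASS\t.\tGT\t0/1\t0/2",
            "chr1\t400\t.\tCA\tC\t.\tPASS\t.\tGT\t0/1\t0/0",
        ]
    )
    path = tmp_path / "mini.vcf"
    path.write_text(text + "\n")
    return path
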