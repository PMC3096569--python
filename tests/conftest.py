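import numpy as np
import pytest

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=1000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0|1
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.
1\t300\trs3\tG\tA,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/0
"""

# rs1 with REF and ALT swapped and genotypes complemented: same data
# under the opposite allele coding.
VCF_SWAPPED_TEXT = VCF_TEXT.replace(
    "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0|1",
    "1\t100\trs1\tG\tA\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0\t1|0",
)


@pytest.fixture
def vcf_path(tmp_path):
    p = tmp_path / "pair.vcf"
    p.write_text(VCF_TEXT)
    return p


@pytest.fixture
def vcf_swapped_path(tmp_path):
    p = tmp_path / "pair_swapped.vcf"
    p.write_text(VCF_SWAPPED_TEXT)
    return p


@pytest.fixture
def coupling_calls():
    """Perfect-coupling sample: every individual homozygous, A == B."""
    g = np.array([2] * 10 + [0] * 10, dtype=np.int8)
    return g, g.copy()


def random_tables(rng, n_tables, n_max=60):
    """Random 3x3 genotype tables with at least one individual."""
    out = []
    while len(out) < n_tables:
        n = rng.integers(1, n_max)
        probs = rng.dirichlet(np.ones(9))
        t = rng.multinomial(n, probs).reshape(3, 3)
        if t.sum() >= 1:
            out.append(t)
    return out
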