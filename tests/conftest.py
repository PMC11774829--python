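import numpy as np
import pytest

from adenosig import MutationRecord, make_reference, synthetic_signature_matrix
from adenosig.catalogue import classify_alleles


@pytest.fixture(scope="session")
def signatures():
    """The bundled synthetic 16-signature matrix."""
    return synthetic_signature_matrix()


@pytest.fixture(scope="session")
def reference_path(tmp_path_factory):
    """A seeded 100 kb synthetic reference with .fai index."""
    path = tmp_path_factory.mktemp("ref") / "reference.fa"
    return make_reference(path, seed=11, n_contigs=2, contig_length=100_000)


@pytest.fixture(scope="session")
def reference(reference_path):
    import pyfaidx

    return pyfaidx.Fasta(str(reference_path))


def make_record(chrom="chr1", pos=100, ref="C", alt="A", depth=100, vaf=0.4,
                sample="s1", callers=("callerA",)):
    return MutationRecord(
        sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
        var_type=classify_alleles(ref, alt), depth=depth, vaf=vaf,
        callers=frozenset(callers),
    )


def write_vcf(path, rows, contig="chr1", length=100_000, fmt="AD:DP"):
    """Write a minimal single-sample VCF for tests.

    rows: list of (pos, ref, alt, ad_ref, ad_alt, dp) or raw body strings.
    """
    header = (
        "##fileformat=VCFv4.2\n"
        f"##contig=<ID={contig},length={length}>\n"
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n"
    )
    body = []
    for row in rows:
        if isinstance(row, str):
            body.append(row)
        else:
            pos, ref, alt, ad_ref, ad_alt, dp = row
            body.append(
                f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
                f"AD:DP\t{ad_ref},{ad_alt}:{dp}"
            )
    path.write_text(header + "\n".join(body) + ("\n" if body else ""))
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
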