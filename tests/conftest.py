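import pytest

from omegasim import (
    SyntheticVcfSpec,
    build_model,
    load_variants,
    read_reference,
    write_reference_and_vcf,
)


@pytest.fixture(scope="session")
def jc69():
    return build_model("JC69", mu=1.0)


@pytest.fixture(scope="session")
def k2p_ts_biased():
    return build_model("K2P", alpha=4.0, beta=1.0)


@pytest.fixture(scope="session")
def context_inputs(tmp_path_factory):
    """Synthetic reference contig + matching VCF, loaded once per session."""
    d = tmp_path_factory.mktemp("ctx")
    fasta_path, vcf_path = write_reference_and_vcf(SyntheticVcfSpec(n_variants=100, contig_length=3000, seed=11), d)
    reference = read_reference(fasta_path)
    variants, skips = load_variants(str(vcf_path), reference)
    return {
        "fasta_path": fasta_path,
        "vcf_path": vcf_path,
        "reference": reference,
        "variants": variants,
        "skips": skips,
    }
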