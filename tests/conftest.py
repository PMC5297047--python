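import pytest

from xspec import synthdata as sd


@pytest.fixture(scope="session")
def reference_100kb():
    spec = sd.SyntheticGenomeSpec(n_chroms=1, chrom_length=100_000,
                                  gc_fraction=0.5, seed=7)
    return sd.generate_reference(spec)


@pytest.fixture(scope="session")
def truth_2000(reference_100kb):
    """2000 somatic SNVs + germline SNPs at zebrafish-like density."""
    return sd.plant_variants(
        reference_100kb, n_somatic=2000, germline_rate=0.005, seed=3)


@pytest.fixture(scope="session")
def fasta_100kb(reference_100kb, tmp_path_factory):
    path = tmp_path_factory.mktemp("ref") / "reference.fa"
    sd.write_fasta(reference_100kb, path)
    return path


@pytest.fixture(scope="session")
def gene_bed(truth_2000, tmp_path_factory):
    path = tmp_path_factory.mktemp("bed") / "genes.bed"
    truth_2000.gene_model.to_bed(path)
    return path
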