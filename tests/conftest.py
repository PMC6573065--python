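import pytest

from mediascape.synthetic import gen_apms_dataset, gen_genome_fixture


@pytest.fixture(scope="session")
def apms_default():
    return gen_apms_dataset(seed=7)


@pytest.fixture(scope="session")
def genome_default():
    return gen_genome_fixture(seed=11)


@pytest.fixture(scope="session")
def genome_files(tmp_path_factory, genome_default):
    out = tmp_path_factory.mktemp("genome_fixture")
    return genome_default.to_dir(out), genome_default
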