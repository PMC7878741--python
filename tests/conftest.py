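import pytest

from aluterm.gene_model import build_model
from aluterm.synthetic_data import fig7_preset, generate_fixture
from aluterm.ucsc_io import read_genepred, read_rmsk, read_tapas


@pytest.fixture(scope="session")
def fig7_fixture(tmp_path_factory):
    """One generated fig7-preset fixture shared by the session."""
    outdir = tmp_path_factory.mktemp("fig7")
    files, truth = generate_fixture(fig7_preset(42), outdir)
    return files, truth


@pytest.fixture(scope="session")
def fig7_parsed(fig7_fixture):
    files, truth = fig7_fixture
    models = [build_model(r) for r in read_genepred(files["refgene"])]
    return {
        "models": models,
        "reps": read_rmsk(files["rmsk"]),
        "apa": read_tapas(files["tapas"]),
        "truth": truth,
        "files": files,
    }
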