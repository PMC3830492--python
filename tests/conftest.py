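import warnings

import pytest

from sulfarray import pipeline, simulate


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale experiment: 200 genes, both lines, quadruplicate dye swap."""
    return simulate.SimulationConfig(n_genes=200, seed=7)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate.generate_experiment(small_config)


@pytest.fixture(scope="session")
def written_experiment(small_experiment, tmp_path_factory):
    """The small experiment written to disk in the pipeline input formats."""
    outdir = tmp_path_factory.mktemp("exp")
    simulate.write_experiment(small_experiment, outdir)
    return outdir


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One complete default pipeline run (1,000 genes) shared across tests."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = pipeline.RunConfig(outdir=str(outdir), seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = pipeline.run_full(cfg)
    return cfg, outdir, manifest
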