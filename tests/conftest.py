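import pytest

from igphase import SampleSheet, SimConfig, default_scheme, simulate_run


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def sheet():
    return SampleSheet(
        samples={"s1": "TATAGCCT", "s2": "ATAGAGGC", "s3": "CCTATCCT"}
    )


MIXTURE = {"IgG1": 0.55, "IgG2": 0.30, "IgG3": 0.08, "IgG4": 0.02, "klMA": 0.05}


@pytest.fixture(scope="session")
def sim_config_factory():
    def make(**overrides):
        params = dict(
            mixtures={"s1": MIXTURE, "s2": MIXTURE, "s3": MIXTURE},
            n_clusters=600,
            seed=11,
        )
        params.update(overrides)
        return SimConfig(**params)

    return make


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, scheme, sheet, sim_config_factory):
    """A small error-free simulated run on disk, shared across tests."""
    outdir = tmp_path_factory.mktemp("simrun")
    config = sim_config_factory(n_clusters=400, contaminant_fraction=0.05)
    truth = simulate_run(config, scheme, sheet, outdir)
    paths = {name: outdir / f"{name}.fastq" for name in ("r1", "r2", "i1", "i2")}
    return {"dir": outdir, "truth": truth, "config": config, **paths}
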