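import pytest
from hypothesis import HealthCheck, settings

from fibronet import pipeline, synth

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def synthetic_data(tmp_path_factory):
    """Full synthetic input set at the default study dimensions (seed 17)."""
    outdir = tmp_path_factory.mktemp("synth")
    paths, manifest = synth.generate_all(outdir, rng_seed=17)
    return paths, manifest


@pytest.fixture(scope="session")
def synthetic_library(synthetic_data):
    from fibronet.library import read_compounds

    paths, manifest = synthetic_data
    return read_compounds(paths["library"]), manifest


@pytest.fixture(scope="session")
def default_config(synthetic_data):
    paths, _ = synthetic_data
    return pipeline.PipelineConfig(
        library=str(paths["library"]),
        predictions=[str(paths["predictions"])],
        gene_sets=str(paths["gene_sets"]),
        interactions=str(paths["interactions"]),
        expression=str(paths["expression"]),
        sample_map=str(paths["sample_map"]),
        disease_links=str(paths["disease_links"]),
    )


@pytest.fixture(scope="session")
def pipeline_run(synthetic_data, default_config, tmp_path_factory):
    """One completed pipeline run on the default synthetic inputs."""
    rundir = tmp_path_factory.mktemp("run")
    summary = pipeline.run_pipeline(default_config, rundir)
    return summary, rundir
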