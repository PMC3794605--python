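import pytest

from methylsplice.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A fast single-chromosome study design shared across module tests."""
    return SimConfig(
        seed=7,
        n_chromosomes=1,
        chrom_length=450_000,
        n_genes=16,
        n_ncrna=2,
        planted_tdmr_count=12,
        n_control_probes=200,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def noise_free_config():
    """Noise-free limit: planted effects are exact per probe and exon."""
    return SimConfig(
        seed=13,
        n_chromosomes=1,
        chrom_length=450_000,
        n_genes=16,
        n_ncrna=2,
        planted_tdmr_count=12,
        n_control_probes=200,
        methyl_noise_sd=0.0,
        expr_noise_sd=0.0,
        dead_probe_fraction=0.0,
    )


@pytest.fixture(scope="session")
def noise_free_dataset(noise_free_config):
    return simulate_dataset(noise_free_config)


@pytest.fixture(scope="session")
def small_pipeline_dir(tmp_path_factory, small_config):
    """A completed pipeline run on the small design."""
    import dataclasses

    from methylsplice.pipeline import PipelineConfig, run_pipeline

    cfg = PipelineConfig(sim=dataclasses.replace(small_config))
    workdir = tmp_path_factory.mktemp("pipeline_run")
    run_pipeline(cfg, workdir)
    return workdir
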