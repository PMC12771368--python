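import pytest

from isopeak.sim import SimConfig, make_toy_genome, simulate_reads, write_fixture


def clean_sim_config(seed: int = 11, reads: int = 30, **overrides) -> SimConfig:
    """Error-free, full-length, jitter-free simulation settings."""
    params = dict(seed=seed, reads_per_isoform=reads,
                  completeness_5p=1.0, completeness_3p=1.0,
                  end_jitter_sd=0.0, subst_rate=0.0, indel_rate=0.0,
                  polya_len=(20, 20))
    params.update(overrides)
    return SimConfig(**params)


def noisy_sim_config(seed: int = 21, reads: int = 50, **overrides) -> SimConfig:
    """Truncation (mean completeness 0.95), end jitter sd 3, 2% substitutions,
    1% indels, splice-boundary wobble on 30% of junctions."""
    params = dict(seed=seed, reads_per_isoform=reads, splice_jitter_prob=0.3)
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture(scope="session")
def clean_sim():
    sim = clean_sim_config()
    genome, transcripts = make_toy_genome(sim)
    data = simulate_reads(genome, transcripts, sim)
    return sim, genome, transcripts, data


@pytest.fixture(scope="session")
def clean_fixture(clean_sim, tmp_path_factory):
    _, genome, transcripts, data = clean_sim
    out = tmp_path_factory.mktemp("clean_fixture")
    paths = write_fixture(data, out)
    return genome, transcripts, paths


@pytest.fixture(scope="session")
def noisy_fixture(tmp_path_factory):
    sim = noisy_sim_config()
    genome, transcripts = make_toy_genome(sim)
    data = simulate_reads(genome, transcripts, sim)
    out = tmp_path_factory.mktemp("noisy_fixture")
    paths = write_fixture(data, out)
    return genome, transcripts, paths
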