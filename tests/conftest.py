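import numpy as np
import pytest

from epistate import pipeline, synthgen
from epistate.regionio import Region


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_regions(rng, n, chroms=("chr1", "chr2"), max_pos=100_000, kind="te", prefix="r"):
    regions = []
    for i in range(n):
        start = int(rng.integers(0, max_pos - 200))
        length = int(rng.integers(50, 2000))
        regions.append(
            Region(
                id=f"{prefix}{i}",
                chrom=str(rng.choice(list(chroms))),
                start=start,
                end=min(start + length, max_pos),
                strand="+" if rng.random() < 0.5 else "-",
                kind=kind,
            )
        )
    return regions


@pytest.fixture(scope="session")
def small_synth_config():
    return synthgen.SyntheticConfig(
        seed=11,
        chromosomes={"chr1": 700_000, "chr2": 500_000},
        n_promoters=60,
        n_tes=120,
    )


@pytest.fixture(scope="session")
def small_annotation(small_synth_config):
    return synthgen.simulate_annotation(small_synth_config)


@pytest.fixture(scope="session")
def small_truth(small_synth_config, small_annotation):
    return synthgen.make_truth(small_synth_config, small_annotation)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One small end-to-end pipeline run shared by integration tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    config = pipeline.PipelineConfig(
        outdir=outdir,
        seed=7,
        synthetic={
            "n_promoters": 60,
            "n_tes": 120,
            "chromosomes": {"chr1": 700_000, "chr2": 500_000},
        },
        som={"rlen": 800},
    )
    report = pipeline.run_all(config)
    return config, report
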