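import numpy as np
import pytest

from hoxclans.scoring import blosum62
from hoxclans.pairwise_similarity import dedup, karlin_altschul_params
from hoxclans.profile_hmm import build_hmm, calibrate, find_domains
from hoxclans.synthetic_data import GeneratorConfig, generate_benchmark
from hoxclans.cluster_classify import compare_regions


@pytest.fixture(scope="session")
def matrix():
    return blosum62()


@pytest.fixture(scope="session")
def ka_stats(matrix):
    return karlin_altschul_params(matrix)


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark (fixed seed)."""
    return generate_benchmark(GeneratorConfig(rng_seed=0))


@pytest.fixture(scope="session")
def database(benchmark):
    return dedup(benchmark.records)


@pytest.fixture(scope="session")
def core_hmm(benchmark):
    return build_hmm(benchmark.seed_alignment("core60"), name="core60")


@pytest.fixture(scope="session")
def core_cal(core_hmm, database):
    lengths = np.array([len(r.seq) for r in database])
    return calibrate(core_hmm, 5000, lengths, rng=0)


@pytest.fixture(scope="session")
def core_hits(core_hmm, core_cal, database):
    """find_domains results for every database record (core model)."""
    return {r.id: find_domains(core_hmm, core_cal, r, 10.0, len(database))
            for r in database}


@pytest.fixture(scope="session")
def comparison(benchmark, matrix, ka_stats):
    """The three-region comparison on the default benchmark."""
    seed_al = {"core60": benchmark.seed_alignment("core60"),
               "extended": benchmark.seed_alignment("extended")}
    return compare_regions(
        benchmark.records, benchmark.truth, seed_al, benchmark.seed_ids,
        matrix=matrix, stats=ka_stats, calibration_replicates=5000,
        rng_seed=0,
    )
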