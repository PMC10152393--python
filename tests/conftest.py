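"""Shared fixtures: the default synthetic benchmark, built once per session.

The benchmark genome is the documented default study condition: a 2-Mb
i.i.d. background (seed 20230417) carrying 12 planted proviruses — 8 with
intact env ORFs across 3 families (one 6-copy family) and 4 with decayed
env — with 600-bp LTRs diverged at the monotreme neutral rate.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from erv_env_miner.pipeline import run_pipeline
from erv_env_miner.synthetic_data import SimConfig, build_profile_db, make_genome

BENCHMARK_SEED = 20230417


@pytest.fixture(scope="session")
def bench_config() -> SimConfig:
    return SimConfig(seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def benchmark(bench_config):
    """(genome, truths, families) for the default benchmark."""
    return make_genome(bench_config)


@pytest.fixture(scope="session")
def profile_db(benchmark, bench_config):
    """(profiles, class_map) built from the benchmark family templates."""
    _genome, _truths, families = benchmark
    return build_profile_db(families, bench_config.seed)


@pytest.fixture(scope="session")
def bench_run(benchmark, profile_db, tmp_path_factory):
    """(report, out_dir) of a full pipeline run on the benchmark."""
    genome, _truths, _families = benchmark
    profiles, class_map = profile_db
    out = tmp_path_factory.mktemp("e2e")
    report = run_pipeline([genome], profiles, out, class_map=class_map)
    return report, out
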