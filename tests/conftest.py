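"""Shared fixtures: one small simulated tetraploid genome per session."""
from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from tetracomp.models import CollinearBlock, GenePair
from tetracomp.pipeline import run_pipeline
from tetracomp.simulate import SimParams, simulate_tetraploid, write_bundle

settings.register_profile(
    "det", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


SMALL = dict(seed=1, n_scaffold_quartets=2, genes_per_scaffold=40,
             n_breaks=4, n_palindromes=2, n_tandems=1)


@pytest.fixture(scope="session")
def small_params():
    return SimParams(**SMALL)


@pytest.fixture(scope="session")
def small_bundle(small_params):
    return simulate_tetraploid(small_params)


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(small_bundle, str(outdir))
    return paths


@pytest.fixture(scope="session")
def small_config(small_bundle_dir):
    p = small_bundle_dir
    return {
        "species": "synthetic",
        "inputs": {
            "gff": p["gff"], "cds": p["cds"], "proteins": p["proteins"],
            "hits": p["hits"], "classmap": p["classmap"],
            "self_hits": p["self_hits"], "pairs": p["pairs"],
            "trees": p["trees"], "vcf": p["vcf"], "depth": p["depth"],
        },
    }


@pytest.fixture(scope="session")
def small_run(small_config):
    """(SpeciesSummary, artifacts) of the full pipeline on the small genome."""
    return run_pipeline(small_config)


def make_block(block_id: int, sa: str, sb: str, ra0: int, rb0: int, n: int = 5,
               orientation: str = "same", category: str = "homolog") -> CollinearBlock:
    """A synthetic collinear block with ``n`` consecutive anchor pairs."""
    pairs = []
    for i in range(n):
        rb = rb0 + i if orientation == "same" else rb0 - i
        pairs.append(GenePair(f"b{block_id}a{i}", f"b{block_id}b{i}",
                              sa, sb, ra0 + i, rb))
    return CollinearBlock(block_id=block_id, scaffold_a=sa, scaffold_b=sb,
                          pairs=pairs, orientation=orientation, category=category)
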