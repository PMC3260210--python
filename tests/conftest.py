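"""Shared fixtures: seeded reference, family pool, and the benchmark bundle.

The benchmark bundle (2-Mb genome, 60 clean implants across all five
classes) is expensive to scan and classify, so it is built once per session
and shared between the end-to-end tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import acds
from acds.classify import classify_catalog
from acds.tir_scan import ScanParams, scan_genome

BENCHMARK_SEED = 42

# the matched configuration for mismatch-free implants; mismatch tolerance
# is exercised separately by the degradation tests
EXACT_SCAN = ScanParams(tir_mm=0, tsd_mm=0)


@pytest.fixture(scope="session")
def ac_ref():
    return acds.make_ac_reference(seed=1)


@pytest.fixture(scope="session")
def pool():
    return acds.FamilyPool.from_rng(np.random.default_rng(1234))


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


@pytest.fixture(scope="session")
def benchmark_bundle():
    return acds.implant_genome(seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def benchmark_calls(benchmark_bundle):
    return scan_genome(benchmark_bundle.genome, EXACT_SCAN)


@pytest.fixture(scope="session")
def benchmark_classified(benchmark_bundle, benchmark_calls):
    return classify_catalog(benchmark_calls, benchmark_bundle.genome,
                            benchmark_bundle.ac_ref,
                            benchmark_bundle.ds1_consensus)


def random_dna_py(rng: np.random.Generator, n: int) -> str:
    """Plain random DNA helper for oracle tests."""
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
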