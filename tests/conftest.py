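import pytest
from hypothesis import HealthCheck, settings

from evcargo.counting import count_genes
from evcargo.synthetic_data import (
    ReferenceConfig,
    build_reference,
    default_profile,
    simulate_library,
)
from evcargo.toy_aligner import align_library

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

REF_SEED = 101


@pytest.fixture(scope="session")
def ref():
    """Default toy reference: RNY5 + background genes + pseudogene decoys."""
    return build_reference(seed=REF_SEED)


@pytest.fixture(scope="session")
def ref_nodecoy():
    """Decoy-free reference: every RNY5-derived read maps uniquely."""
    cfg = ReferenceConfig(n_perfect_decoys=0, n_near_decoys=0)
    return build_reference(cfg, seed=REF_SEED)


def run_library(ref_bundle, name, n_reads, seed, workdir, error_rate=0.001):
    """Simulate + align + count one library; returns a small result bag."""
    workdir.mkdir(parents=True, exist_ok=True)
    profile = default_profile(name, ref_bundle, read_count=n_reads, error_rate=error_rate)
    fastq = workdir / f"{name}.fastq"
    truth_sam = workdir / f"{name}.truth.sam"
    sam = workdir / f"{name}.sam"
    truth = simulate_library(profile, ref_bundle, fastq, truth_sam, seed=seed)
    align_stats = align_library(fastq, ref_bundle, sam)
    counts = count_genes(sam, ref_bundle.annotations, library_id=name)
    return {
        "profile": profile,
        "truth": truth,
        "fastq": fastq,
        "truth_sam": truth_sam,
        "sam": sam,
        "align_stats": align_stats,
        "counts": counts,
    }


@pytest.fixture(scope="session")
def bj_ev_small(ref, tmp_path_factory):
    """A 100k-read BJ-EV library shared across fast tests."""
    wd = tmp_path_factory.mktemp("bj_ev_small")
    return run_library(ref, "bj_ev", 100_000, seed=2024, workdir=wd)


@pytest.fixture(scope="session")
def bj_cell_small(ref, tmp_path_factory):
    wd = tmp_path_factory.mktemp("bj_cell_small")
    return run_library(ref, "bj_cell", 100_000, seed=2025, workdir=wd)
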