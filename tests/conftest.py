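import numpy as np
import pytest

import pefrag as pf


@pytest.fixture(scope="session")
def small_genome():
    """10-kb random repeat-free genome."""
    return pf.make_genome(10_000, seed=11)


@pytest.fixture(scope="session")
def clean_library(small_genome):
    """Error-free 50x library (read length 100, fragment 300 +/- 30)."""
    cfg = pf.SimConfig(read_length=100, frag_mean=300, coverage=50,
                       error_rate=0.0, seed=5)
    return pf.simulate_library(small_genome, cfg)


@pytest.fixture(scope="session")
def clean_graph(clean_library):
    pairs, _ = clean_library
    reads = [r for pe in pairs for r in (pe.read1, pe.read2)]
    return pf.build_contigs(reads, pf.AssemblyConfig(k=31))


def tile_reads(genome: str, read_length: int = 100, step: int = 1):
    """Error-free reads tiling a genome at the given step."""
    out = []
    for i in range(0, len(genome) - read_length + 1, step):
        out.append(pf.SeqRecord(id=f"r{i}", sequence=genome[i : i + read_length]))
    return out


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[c] for c in rng.integers(0, 4, size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
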