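import numpy as np
import pytest

from magderep.core_io import GenomeRecord
from magderep.synth import SynthConfig, generate_mag_set


def make_genome(genome_id: str, *seqs: str) -> GenomeRecord:
    return GenomeRecord.from_raw(
        genome_id, [(f"{genome_id}_c{i}", s) for i, s in enumerate(seqs)]
    )


def random_seq(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[c] for c in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def small_mag_set():
    """2 species x 3 MAGs at 60 kb: shared fixture for pipeline-level tests."""
    config = SynthConfig(
        n_species=2,
        mags_per_species=3,
        genome_length=60_000,
        n_contigs=6,
        aux_blocks_per_genome=3,
        aux_block_len=1500,
        seed=42,
    )
    return generate_mag_set(config)
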