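import numpy as np
import pytest

from srnasurv.alignments import AlignedRead, cap_multimappers, map_reads_exact
from srnasurv.simulate import SimConfig, SimRead, collapse_reads, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """One shared synthetic dataset (default Dicer-dominant mixture)."""
    return simulate_dataset(SimConfig(seed=11, n_reads=4000))


@pytest.fixture(scope="session")
def mapped(dataset):
    """Capped alignments of the shared dataset's collapsed reads."""
    alignments, unmapped = map_reads_exact(collapse_reads(dataset.reads), dataset.genome)
    kept, frac = cap_multimappers(alignments)
    return {"all": alignments, "kept": kept, "discarded_fraction": frac, "unmapped": unmapped}


def sim_to_alignments(reads: list[SimRead]) -> list[AlignedRead]:
    """Turn simulated reads directly into unique alignments at their truth coordinates."""
    return [
        AlignedRead(
            read_id=f"sim{i}",
            sequence=r.sequence,
            chrom=r.chrom,
            start=r.start,
            end=r.end,
            strand=r.strand,
            n_hits=1,
            copies=1,
        )
        for i, r in enumerate(reads)
    ]


def random_genome(seed: int, length: int, chrom: str = "chr1") -> dict[str, str]:
    rng = np.random.default_rng(seed)
    return {chrom: "".join(rng.choice(list("ACGT"), size=length))}
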