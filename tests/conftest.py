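import numpy as np
import pytest

from netrend import (GenotypeDataset, MarkerMap, recode_to_minor)
from netrend.io import MISSING


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_marker_map(positions, chrom="1", prefix="m"):
    positions = np.asarray(positions, dtype=np.int64)
    if np.isscalar(chrom) or isinstance(chrom, str):
        chroms = np.array([chrom] * len(positions), dtype=object)
    else:
        chroms = np.array(list(chrom), dtype=object)
    return MarkerMap(
        chromosome=chroms,
        marker_id=np.array([f"{prefix}{i}" for i in range(len(positions))],
                           dtype=object),
        position_bp=positions,
    )


def random_genotype_dataset(rng, n_ind=12, n_markers=8, missing_rate=0.0,
                            chrom="1", spacing=100_000):
    """Random minor-allele-coded dataset (the GenotypeDataset invariant)."""
    counts = rng.integers(0, 3, size=(n_ind, n_markers)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(counts.shape) < missing_rate
        counts[mask] = MISSING
    # ensure no all-missing column
    for j in range(n_markers):
        if (counts[:, j] == MISSING).all():
            counts[0, j] = 1
    counts = recode_to_minor(counts)
    positions = spacing * np.arange(1, n_markers + 1)
    return GenotypeDataset(
        markers=make_marker_map(positions, chrom=chrom),
        counts=counts,
        sample_ids=[f"i{k}" for k in range(n_ind)],
    )


@pytest.fixture
def dataset_factory():
    return random_genotype_dataset
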