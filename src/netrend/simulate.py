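"""Synthetic data with known ground truth.

Two complementary generators back the validation of the pipeline:

* :func:`simulate_wright_fisher` — a forward-in-time Wright–Fisher
  population of ``2N`` haplotypes on one chromosome with recombination
  (crossover counts Poisson in the map length, uniform breakpoints) and no
  mutation, so the LD that builds up between the uniformly spaced markers
  is produced by drift and recombination alone — exactly the process the
  drift–recombination expectation ``E(r²) = 1/(1 + 4 Ne c)`` models.
  Step-wise demographic change points are supported.

* :func:`generate_ld_profile` — the analytic inverse: a pairwise-LD table
  whose r² values are placed exactly on ``1/(alpha + 4 Ne f(c)) +
  1/(beta n)`` at each bin's midpoint distance, so the full estimation
  pipeline must return exactly ``Ne`` in every bin. This isolates the
  algebra of the estimator from sampling noise.

:func:`write_plink` emits ped/map text files consumable by
:func:`netrend.io.read_plink`, closing the round trip.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError
from .io import (MISSING, GenotypeDataset, HaplotypeDataset, MarkerMap,
                 PairwiseLD, recode_to_minor)
from .trajectory import BinScheme, MappingSpec, map_distance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one Wright–Fisher run.

    ``demography`` lists (generation, N) change points: from that
    generation on the population has the new size. The seed is mandatory —
    there is no silent nondeterminism.
    """

    pop_size: int
    sample_n: int
    n_markers: int
    chrom_length_bp: int
    recomb_rate_per_bp: float       # Morgans per bp
    generations: int
    seed: int
    demography: tuple[tuple[int, int], ...] = field(default_factory=tuple)
    chromosome_label: str = "1"

    def __post_init__(self) -> None:
        if min(self.pop_size, self.sample_n, self.n_markers,
               self.chrom_length_bp, self.generations + 1) <= 0:
            raise ConfigError("all simulation sizes must be positive")
        if self.recomb_rate_per_bp < 0:
            raise ConfigError("recombination rate must be >= 0")
        if self.seed is None:
            raise ConfigError("a seed is mandatory")

    def size_at(self, generation: int) -> int:
        n = self.pop_size
        for g, size in sorted(self.demography):
            if generation >= g:
                n = size
        return n


@dataclass(frozen=True)
class SimulationOutput:
    """Sampled dataset plus the ground truth it was generated under."""

    dataset: GenotypeDataset
    spec: SimulationSpec
    population_frequencies: np.ndarray   # final full-population allele freqs
    haplotypes: np.ndarray = field(repr=False)  # sampled 2n x m, pre-recoding


def _marker_positions(spec: SimulationSpec) -> np.ndarray:
    spacing = spec.chrom_length_bp / spec.n_markers
    return np.round(spacing * np.arange(1, spec.n_markers + 1)).astype(np.int64)


def _next_generation(haps: np.ndarray, n_offspring: int, length_bp: int,
                     rate: float, positions: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """One round of random mating with recombination.

    Each offspring haplotype is a mosaic of the two haplotypes of one
    random parent: crossover count ~ Poisson(map length), breakpoints
    uniform on the chromosome, starting haplotype chosen at random.
    """
    n_parents = haps.shape[0] // 2
    n_hap = 2 * n_offspring
    parents = rng.integers(n_parents, size=n_hap)
    start = rng.integers(2, size=n_hap).astype(np.int8)
    hap_a = haps[2 * parents]
    hap_b = haps[2 * parents + 1]

    n_x = rng.poisson(length_bp * rate, size=n_hap)
    kmax = int(n_x.max()) if n_hap else 0
    if kmax == 0:
        return np.where(start[:, None] == 0, hap_a, hap_b)

    bp = rng.uniform(0.0, length_bp, size=(n_hap, kmax))
    pad = np.arange(kmax)[None, :] >= n_x[:, None]
    bp[pad] = np.inf
    # parity of crossovers left of each marker decides the source haplotype
    crossings = (bp[:, None, :] <= positions[None, :, None]).sum(axis=2)
    which = (start[:, None] + crossings) % 2
    return np.where(which == 0, hap_a, hap_b)


def simulate_wright_fisher(spec: SimulationSpec) -> SimulationOutput:
    """Run the forward simulation and sample a genotype dataset.

    All markers start at allele frequency exactly 0.5 (a random half of the
    ``2N`` founding haplotypes carries the derived allele). After
    ``spec.generations`` rounds, ``sample_n`` diploids are drawn without
    replacement. Monomorphic markers are retained — filtering is the
    estimator's job, not the generator's. Identical specs (same seed) give
    bit-identical output.
    """
    if spec.sample_n > spec.size_at(spec.generations):
        raise ConfigError("sample_n exceeds final population size")
    rng = np.random.default_rng(spec.seed)
    logger.info("Wright-Fisher run: N=%d sample=%d markers=%d seed=%d",
                spec.pop_size, spec.sample_n, spec.n_markers, spec.seed)
    positions = _marker_positions(spec)

    n0 = spec.pop_size
    haps = np.zeros((2 * n0, spec.n_markers), dtype=np.int8)
    for j in range(spec.n_markers):       # exactly half the haplotypes carry 1
        carriers = rng.permutation(2 * n0)[:n0]
        haps[carriers, j] = 1

    for g in range(1, spec.generations + 1):
        n_g = spec.size_at(g)
        haps = _next_generation(haps, n_g, spec.chrom_length_bp,
                                spec.recomb_rate_per_bp, positions, rng)

    pop_freq = haps.mean(axis=0)
    n_final = haps.shape[0] // 2
    chosen = rng.choice(n_final, size=spec.sample_n, replace=False)
    rows = np.empty(2 * spec.sample_n, dtype=np.int64)
    rows[0::2] = 2 * chosen
    rows[1::2] = 2 * chosen + 1
    sampled = haps[rows]

    counts = (sampled[0::2] + sampled[1::2]).astype(np.int8)
    counts = recode_to_minor(counts)
    m = spec.n_markers
    markers = MarkerMap(
        chromosome=np.array([spec.chromosome_label] * m, dtype=object),
        marker_id=np.array([f"snp{j + 1}" for j in range(m)], dtype=object),
        position_bp=positions,
    )
    dataset = GenotypeDataset(
        markers=markers, counts=counts,
        sample_ids=[f"ind{i + 1}" for i in range(spec.sample_n)],
        minor_allele=np.array(["A"] * m, dtype=object),
        major_allele=np.array(["G"] * m, dtype=object),
    )
    return SimulationOutput(dataset=dataset, spec=spec,
                            population_frequencies=pop_freq,
                            haplotypes=sampled)


def sampled_haplotype_dataset(out: SimulationOutput) -> HaplotypeDataset:
    """Phased view of a simulation sample (truth is known, so phase is)."""
    alleles = recode_to_minor(out.haplotypes.astype(np.int8), ploidy=1)
    return HaplotypeDataset(markers=out.dataset.markers, alleles=alleles,
                            sample_ids=out.dataset.sample_ids)


# ---------------------------------------------------------------------------
# analytic LD profiles
# ---------------------------------------------------------------------------

def generate_ld_profile(ne: float, alpha: float, beta: int, n: int,
                        scheme: BinScheme, mapping: MappingSpec,
                        pairs_per_bin: int = 2,
                        chromosome: str = "1") -> list[PairwiseLD]:
    """Noise-free pairwise LD lying exactly on the model expectation.

    For each bin, ``pairs_per_bin`` identical pairs are emitted at the bin's
    midpoint distance with ``r² = 1/(alpha + 4 Ne f(c)) + 1/(beta n)``;
    running the estimation pipeline with the same alpha/beta/mapping must
    return exactly ``ne`` in every bin.
    """
    if min(ne, alpha, beta, n, pairs_per_bin) <= 0:
        raise ConfigError("all profile parameters must be positive")
    pairs: list[PairwiseLD] = []
    for b in range(scheme.tot_bins):
        lo, hi = scheme.edges[b], scheme.edges[b + 1]
        d = int(round((lo + hi) / 2.0))
        d = max(d, int(math.ceil(lo)), 1)
        if d >= hi and b < scheme.tot_bins - 1:
            d = int(hi) - 1
        c = map_distance(d, mapping)
        r2 = 1.0 / (alpha + 4.0 * ne * c) + 1.0 / (beta * n)
        if r2 > 1.0:
            raise ConfigError(
                f"bin {b + 1}: expected r2 {r2:.3f} exceeds 1; "
                "parameters are inconsistent with an r2 profile")
        for _ in range(pairs_per_bin):
            pairs.append(PairwiseLD(chromosome=chromosome, pos_a=1,
                                    pos_b=1 + d, r2=r2, n_obs=n))
    return pairs


# ---------------------------------------------------------------------------
# PLINK text output
# ---------------------------------------------------------------------------

_GENO_FIELDS = {2: "A A", 1: "A G", 0: "G G", MISSING: "0 0"}


def write_plink(dataset: GenotypeDataset, ped_path, map_path) -> None:
    """Write a dataset as PLINK text files (alleles coded A/G, missing 0).

    The count value is written as copies of allele ``A``; reading the files
    back reproduces the count matrix exactly for minor-allele-coded data
    (the dataset invariant) and preserves the missingness mask.
    """
    if dataset.n_markers == 0 or dataset.n_individuals == 0:
        raise ConfigError("cannot write an empty dataset")
    mm = dataset.markers
    with open(map_path, "w") as fh:
        for j in range(dataset.n_markers):
            fh.write(f"{mm.chromosome[j]}\t{mm.marker_id[j]}\t0\t"
                     f"{mm.position_bp[j]}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(dataset.sample_ids):
            geno = "\t".join(_GENO_FIELDS[int(c)] for c in dataset.counts[i])
            fh.write(f"FAM{i + 1}\t{sid}\t0\t0\t0\t-9\t{geno}\n")
    logger.info("wrote %d individuals x %d markers to %s / %s",
                dataset.n_individuals, dataset.n_markers, ped_path, map_path)
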