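"""Pairwise linkage-disequilibrium computation.

Two r² estimators are provided:

* ``genotype`` — squared Pearson product-moment correlation of the two
  allele-count vectors (0/1/2), the estimator used on unphased data. It is
  insensitive to double heterozygotes and matches PLINK's ``--r2``.
* ``haplotype`` — the classical haplotype-frequency form
  ``(p_AB - p_A p_B)^2 / (p_A(1-p_A) p_B(1-p_B))``, usable when gametic
  phase is known.

Missing calls are handled by pairwise-complete deletion: each pair's r² is
computed over the individuals (or haplotypes) observed at both loci, and the
per-pair sample size ``n_obs`` is carried downstream for the sample-size
correction. Pairs are only formed within a chromosome, inside a configurable
physical-distance window.

The all-pairs scan is blocked over leading markers and may be spread over a
thread pool; the result is a deterministic stream (ordered by chromosome
label, then both positions) whose content is independent of thread count.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterator, Union

import numpy as np
import pandas as pd

from .errors import ComputationError, ConfigError, NetrendError
from .io import MISSING, GenotypeDataset, HaplotypeDataset, PairwiseLD

logger = logging.getLogger(__name__)

#: Pairs with fewer complete observations than this are skipped.
MIN_PAIR_OBS = 3

_BLOCK = 512    # leading-marker block size for the pair scan

Dataset = Union[GenotypeDataset, HaplotypeDataset]


class PairSkipped(NetrendError):
    """A single SNP pair could not yield an r² (too few complete
    observations, or a locus monomorphic among them)."""


@dataclass
class LDConfig:
    """Settings for the pairwise r² scan.

    A pair at physical distance delta is admitted iff
    ``min_distance_bp <= delta <= max_distance_bp``.
    """

    maf_threshold: float = 0.05
    min_distance_bp: int = 50_000
    max_distance_bp: int = 4_000_000
    chromosomes: frozenset[str] | None = None
    estimator: str = "genotype"
    threads: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_threshold < 0.5):
            raise ConfigError(
                f"maf_threshold must be in [0, 0.5), got {self.maf_threshold}")
        if self.min_distance_bp >= self.max_distance_bp:
            raise ConfigError("min_distance_bp must be < max_distance_bp")
        if self.min_distance_bp < 0:
            raise ConfigError("min_distance_bp must be >= 0")
        if self.estimator not in ("genotype", "haplotype"):
            raise ConfigError(f"unknown estimator {self.estimator!r}")
        if self.threads < 1:
            raise ConfigError("threads must be >= 1")
        if self.chromosomes is not None:
            self.chromosomes = frozenset(str(c) for c in self.chromosomes)


# ---------------------------------------------------------------------------
# allele frequency / MAF filtering
# ---------------------------------------------------------------------------

def minor_allele_frequency(column: np.ndarray, ploidy: int = 2) -> float:
    """MAF of one marker column of allele counts; missing entries ignored."""
    column = np.asarray(column)
    present = column != MISSING
    n = int(present.sum())
    if n == 0:
        raise ComputationError("all calls missing at marker")
    p = column[present].sum() / (ploidy * n)
    return float(min(p, 1.0 - p))


def maf_filter(dataset: Dataset, threshold: float):
    """Drop markers below the MAF threshold.

    A marker is retained iff its MAF is >= ``threshold``; monomorphic
    markers (MAF exactly 0) are always removed because r² is undefined for
    them. Returns ``(filtered_dataset, report)`` where ``report`` maps
    chromosome label -> number of markers removed there.
    """
    if not (0.0 <= threshold < 0.5):
        raise ConfigError(f"MAF threshold must be in [0, 0.5), got {threshold}")
    maf = dataset.maf()
    keep = (maf >= threshold) & (maf > 0.0)
    if not keep.any():
        raise ComputationError("no markers survive MAF filter")
    removed = ~keep
    report: dict[str, int] = {}
    for c in dataset.markers.chromosomes():
        n = int(removed[dataset.markers.chromosome == c].sum())
        if n:
            report[c] = n
    if report:
        logger.info("MAF filter (threshold %.4g) removed %d marker(s): %s",
                    threshold, int(removed.sum()), report)
    return dataset.subset_markers(keep), report


# ---------------------------------------------------------------------------
# single-pair estimators
# ---------------------------------------------------------------------------

def r2_genotype(x_counts: np.ndarray, y_counts: np.ndarray) -> tuple[float, int]:
    """Squared Pearson correlation of two allele-count vectors.

    Individuals missing at either locus are dropped. Returns ``(r2, n_obs)``
    where ``n_obs`` is the number of complete individuals; raises
    :class:`PairSkipped` when fewer than three remain or a locus has zero
    variance among them.
    """
    x = np.asarray(x_counts, dtype=np.float64)
    y = np.asarray(y_counts, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("count vectors differ in length")
    ok = (np.asarray(x_counts) != MISSING) & (np.asarray(y_counts) != MISSING)
    x, y = x[ok], y[ok]
    n = x.size
    if n < MIN_PAIR_OBS:
        raise PairSkipped(f"insufficient observations (n={n})")
    dx = x - x.mean()
    dy = y - y.mean()
    ssx = float(dx @ dx)
    ssy = float(dy @ dy)
    if ssx == 0.0 or ssy == 0.0:
        raise PairSkipped("monomorphic in complete observations")
    num = float(dx @ dy)
    r2 = num * num / (ssx * ssy)
    return min(r2, 1.0), n


def r2_haplotype(hap_a: np.ndarray, hap_b: np.ndarray) -> tuple[float, int]:
    """Haplotype-frequency r² between two binary haplotype columns.

    Frequencies are computed over haplotypes complete at both loci; returns
    ``(r2, n_obs)`` with ``n_obs`` expressed in individuals (complete
    haplotypes / 2).
    """
    a = np.asarray(hap_a)
    b = np.asarray(hap_b)
    if a.shape != b.shape:
        raise ValueError("haplotype vectors differ in length")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(np.float64), b[ok].astype(np.float64)
    nh = a.size
    if nh < 2 * MIN_PAIR_OBS:
        raise PairSkipped(f"insufficient observations (haplotypes={nh})")
    p_a = a.mean()
    p_b = b.mean()
    p_ab = (a * b).mean()
    denom = p_a * (1.0 - p_a) * p_b * (1.0 - p_b)
    if denom == 0.0:
        raise PairSkipped("monomorphic in complete observations")
    d = p_ab - p_a * p_b
    return min(d * d / denom, 1.0), nh // 2


# ---------------------------------------------------------------------------
# all-pairs scan
# ---------------------------------------------------------------------------

def _chromosome_matrix(dataset: Dataset, config: LDConfig):
    """Resolve the working matrix and per-observation semantics.

    Returns (matrix, obs_divisor) where matrix rows are observations
    (individuals for genotype counts, haplotypes for phased data) and
    ``obs_divisor`` converts complete-observation counts into individuals.
    """
    if config.estimator == "haplotype":
        if not isinstance(dataset, HaplotypeDataset):
            raise ConfigError("haplotype estimator requires phased input")
        return dataset.alleles, 2
    if isinstance(dataset, HaplotypeDataset):
        dataset = dataset.to_genotypes()
    return dataset.counts, 1


def _scan_block(M: np.ndarray, P: np.ndarray, pos: np.ndarray,
                i0: int, i1: int, min_d: int, max_d: int,
                min_obs: int):
    """r² for all admissible pairs whose leading marker lies in [i0, i1).

    ``M`` is the observation matrix with missing entries zeroed, ``P`` the
    presence indicator. Uses pairwise-complete sums assembled from six
    matrix products, so missing data cost no per-pair Python work.
    """
    # widest trailing-marker window needed by this block
    j_lo = int(np.searchsorted(pos, pos[i0] + min_d, side="left"))
    j_hi = int(np.searchsorted(pos, pos[i1 - 1] + max_d, side="right"))
    if j_lo >= j_hi:
        return None
    X, Px = M[:, i0:i1], P[:, i0:i1]
    Y, Py = M[:, j_lo:j_hi], P[:, j_lo:j_hi]
    N = Px.T @ Py
    Sx = X.T @ Py
    Sy = Px.T @ Y
    Sxx = (X * X).T @ Py
    Syy = Px.T @ (Y * Y)
    Sxy = X.T @ Y

    with np.errstate(divide="ignore", invalid="ignore"):
        num = Sxy - Sx * Sy / N
        ssx = Sxx - Sx * Sx / N
        ssy = Syy - Sy * Sy / N
        r2 = (num * num) / (ssx * ssy)

    ia, ja, r2s, ns = [], [], [], []
    skipped = 0
    for li, i in enumerate(range(i0, i1)):
        a = int(np.searchsorted(pos, pos[i] + min_d, side="left"))
        b = int(np.searchsorted(pos, pos[i] + max_d, side="right"))
        a = max(a, i + 1)
        if a >= b:
            continue
        cols = slice(a - j_lo, b - j_lo)
        nn = N[li, cols]
        vx = ssx[li, cols]
        vy = ssy[li, cols]
        good = (nn >= min_obs) & (vx > 0) & (vy > 0)
        skipped += int((~good).sum())
        jj = np.arange(a, b)[good]
        ia.append(np.full(jj.size, i))
        ja.append(jj)
        r2s.append(np.minimum(r2[li, cols][good], 1.0))
        ns.append(nn[good])
    if not ia:
        return (np.empty(0, int), np.empty(0, int),
                np.empty(0), np.empty(0, int), skipped)
    return (np.concatenate(ia), np.concatenate(ja),
            np.concatenate(r2s), np.concatenate(ns).astype(np.int64), skipped)


def compute_pair_table(dataset: Dataset, config: LDConfig) -> pd.DataFrame:
    """All admissible within-chromosome pairs as a DataFrame.

    Columns: ``chrom, pos_a, pos_b, dist, r2, n_obs``, ordered by
    chromosome label then (pos_a, pos_b). The content is identical for any
    ``config.threads``; the thread pool only parallelises leading-marker
    blocks, whose results are concatenated in block order.
    """
    matrix, obs_div = _chromosome_matrix(dataset, config)
    markers = dataset.markers
    min_obs = MIN_PAIR_OBS * obs_div

    chrom_labels = sorted(set(markers.chromosome))
    if config.chromosomes is not None:
        chrom_labels = [c for c in chrom_labels if c in config.chromosomes]
        if not chrom_labels:
            raise ComputationError("no markers on the requested chromosomes")

    tasks = []      # (chrom, pos, M, P, i0, i1)
    for c in chrom_labels:
        idx = np.flatnonzero(markers.chromosome == c)
        if idx.size < 2:
            continue
        sub = matrix[:, idx].astype(np.float64)
        pres = (sub != MISSING).astype(np.float64)
        sub = np.where(sub == MISSING, 0.0, sub)
        pos = markers.position_bp[idx]
        for i0 in range(0, idx.size, _BLOCK):
            tasks.append((c, pos, sub, pres, i0, min(i0 + _BLOCK, idx.size)))

    def run(task):
        c, pos, M, P, i0, i1 = task
        out = _scan_block(M, P, pos, i0, i1,
                          config.min_distance_bp, config.max_distance_bp,
                          min_obs)
        return c, pos, out

    if config.threads > 1 and len(tasks) > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            results = list(pool.map(run, tasks))
    else:
        results = [run(t) for t in tasks]

    frames = []
    total_skipped = 0
    for c, pos, out in results:
        if out is None:
            continue
        ia, ja, r2s, ns, skipped = out
        total_skipped += skipped
        if ia.size == 0:
            continue
        frames.append(pd.DataFrame({
            "chrom": c,
            "pos_a": pos[ia],
            "pos_b": pos[ja],
            "dist": pos[ja] - pos[ia],
            "r2": r2s,
            "n_obs": ns // obs_div,
        }))
    if total_skipped:
        logger.info("skipped %d pair(s) (insufficient observations or "
                    "monomorphic)", total_skipped)
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos_a", "pos_b",
                                     "dist", "r2", "n_obs"])
    return pd.concat(frames, ignore_index=True)


def enumerate_pairs(dataset: Dataset, config: LDConfig) -> Iterator[PairwiseLD]:
    """Yield :class:`PairwiseLD` records for every admissible pair.

    Convenience generator over :func:`compute_pair_table`; the stream order
    is deterministic regardless of thread count.
    """
    table = compute_pair_table(dataset, config)
    for row in table.itertuples(index=False):
        yield PairwiseLD(chromosome=row.chrom, pos_a=int(row.pos_a),
                         pos_b=int(row.pos_b), r2=float(row.r2),
                         n_obs=int(row.n_obs))
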