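"""Reading and writing the file formats used by the Ne-trajectory pipeline.

Supported formats
-----------------
* PLINK text genotypes: a ``.ped`` file (six leading columns ``FID IID PAT
  MAT SEX PHENO`` followed by two allele fields per marker) plus a ``.map``
  file (``chrom  id  [cM]  bp``; the 3- and 4-column dialects are
  auto-detected). Allele codes ``A C G T 1 2`` are accepted, ``0`` means
  missing.
* Pre-computed pairwise-LD tables: delimited text with chromosome, the two
  positions (or a distance), r² and optionally a per-pair sample size.
* The trajectory output table: tab-delimited, one row per distance bin.

Genotypes are recoded on load so that each column counts copies of the
per-locus *minor* allele; r² is invariant to this choice, it only fixes the
reporting convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

from .errors import ComputationError, ConfigError, ParseError

if TYPE_CHECKING:  # pragma: no cover
    from .trajectory import NeEstimate

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call / haplotype allele.
MISSING: int = -1

_ALLELE_CODES = frozenset("ACGT12")
_MISSING_CODE = "0"

TRAJECTORY_HEADER = ("GenAgo", "Ne", "AvgDist", "AvgR2", "SdR2", "NPairs")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Per-marker metadata: chromosome label, id and physical position.

    Markers are stored sorted by position within each chromosome (stable
    sort; chromosomes keep their order of first appearance in the input).
    ``original_index`` records each marker's position in the input file so
    genotype columns can be permuted consistently.
    """

    chromosome: np.ndarray          # dtype=object, str labels compared verbatim
    marker_id: np.ndarray           # dtype=object
    position_bp: np.ndarray         # int64, 1-based physical coordinate
    genetic_pos_cm: np.ndarray | None = None   # read but unused by computation
    original_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.original_index is None:
            self.original_index = np.arange(len(self.position_bp))
        ids = list(self.marker_id)
        if len(set(ids)) != len(ids):
            dup = sorted({m for m in ids if ids.count(m) > 1})
            raise ParseError(f"duplicate marker ids: {', '.join(dup[:5])}")

    def __len__(self) -> int:
        return len(self.position_bp)

    @property
    def n_markers(self) -> int:
        return len(self)

    def chromosomes(self) -> list[str]:
        """Unique chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chromosome:
            seen.setdefault(c)
        return list(seen)

    def subset(self, index: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            chromosome=self.chromosome[index],
            marker_id=self.marker_id[index],
            position_bp=self.position_bp[index],
            genetic_pos_cm=None if self.genetic_pos_cm is None
            else self.genetic_pos_cm[index],
            original_index=self.original_index[index],
        )


@dataclass
class GenotypeDataset:
    """Unphased genotypes: individuals x markers minor-allele counts.

    ``counts`` entries are in {0, 1, 2, MISSING}; column allele frequencies
    are always computed over the non-missing entries only.
    """

    markers: MarkerMap
    counts: np.ndarray              # (n_individuals, n_markers) int8
    sample_ids: list[str]
    minor_allele: np.ndarray | None = None   # dtype=object; None if monomorphic
    major_allele: np.ndarray | None = None
    phased: bool = field(default=False, init=False)

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_markers(self) -> int:
        return self.counts.shape[1]

    @property
    def n_missing(self) -> int:
        return int((self.counts == MISSING).sum())

    def allele_frequency(self) -> np.ndarray:
        """Frequency of the counted allele per marker (non-missing calls)."""
        return _counted_allele_frequency(self.counts, ploidy=2)

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeDataset(
            markers=self.markers.subset(keep),
            counts=self.counts[:, keep],
            sample_ids=self.sample_ids,
            minor_allele=None if self.minor_allele is None else self.minor_allele[keep],
            major_allele=None if self.major_allele is None else self.major_allele[keep],
        )


@dataclass
class HaplotypeDataset:
    """Phased data: (2 x individuals) x markers binary allele matrix.

    Rows ``2j`` and ``2j+1`` are the two haplotypes of individual ``j``.
    Entries are in {0, 1, MISSING}.
    """

    markers: MarkerMap
    alleles: np.ndarray             # (2*n_individuals, n_markers) int8
    sample_ids: list[str]
    minor_allele: np.ndarray | None = None
    major_allele: np.ndarray | None = None
    phased: bool = field(default=True, init=False)

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0] // 2

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_missing(self) -> int:
        return int((self.alleles == MISSING).sum())

    def allele_frequency(self) -> np.ndarray:
        return _counted_allele_frequency(self.alleles, ploidy=1)

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def to_genotypes(self) -> GenotypeDataset:
        """Collapse haplotypes into allele counts (phase discarded)."""
        a, b = self.alleles[0::2], self.alleles[1::2]
        counts = (a + b).astype(np.int8)
        counts[(a == MISSING) | (b == MISSING)] = MISSING
        return GenotypeDataset(
            markers=self.markers, counts=counts, sample_ids=self.sample_ids,
            minor_allele=self.minor_allele, major_allele=self.major_allele,
        )

    def subset_markers(self, keep: np.ndarray) -> "HaplotypeDataset":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return HaplotypeDataset(
            markers=self.markers.subset(keep),
            alleles=self.alleles[:, keep],
            sample_ids=self.sample_ids,
            minor_allele=None if self.minor_allele is None else self.minor_allele[keep],
            major_allele=None if self.major_allele is None else self.major_allele[keep],
        )


@dataclass(frozen=True)
class PairwiseLD:
    """r² for one intra-chromosomal SNP pair at physical distance delta."""

    chromosome: str
    pos_a: int
    pos_b: int
    r2: float
    n_obs: int

    def __post_init__(self) -> None:
        if self.pos_b <= self.pos_a:
            raise ValueError(
                f"pos_b must exceed pos_a (got {self.pos_a}, {self.pos_b})")
        if not (-1e-12 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 out of [0, 1]: {self.r2}")

    @property
    def distance_bp(self) -> int:
        return self.pos_b - self.pos_a


def _counted_allele_frequency(matrix: np.ndarray, ploidy: int) -> np.ndarray:
    present = matrix != MISSING
    n = present.sum(axis=0)
    if np.any(n == 0):
        bad = np.flatnonzero(n == 0)
        raise ComputationError(
            f"all calls missing at marker column(s) {bad[:5].tolist()}")
    total = np.where(present, matrix, 0).sum(axis=0)
    return total / (ploidy * n)


def recode_to_minor(counts: np.ndarray, ploidy: int = 2) -> np.ndarray:
    """Flip columns so the counted allele is the minor one (freq <= 0.5).

    Idempotent: applying it twice equals applying it once. Ties at exactly
    0.5 are left untouched.
    """
    counts = counts.copy()
    present = counts != MISSING
    n = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(present, counts, 0).sum(axis=0) / np.maximum(ploidy * n, 1)
    flip = (p > 0.5) & (n > 0)
    cols = np.flatnonzero(flip)
    sub = counts[:, cols]
    sub = np.where(sub == MISSING, MISSING, ploidy - sub).astype(counts.dtype)
    counts[:, cols] = sub
    return counts


# ---------------------------------------------------------------------------
# PLINK ped/map reading
# ---------------------------------------------------------------------------

def read_map(map_path) -> MarkerMap:
    """Parse a PLINK .map file (3- or 4-column dialect, auto-detected)."""
    chroms: list[str] = []
    ids: list[str] = []
    cms: list[float] = []
    bps: list[int] = []
    ncols: int | None = None
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if ncols is None:
                if len(fields) not in (3, 4):
                    raise ParseError(
                        f"{map_path}: line {lineno}: expected 3 or 4 columns, "
                        f"got {len(fields)}")
                ncols = len(fields)
            elif len(fields) != ncols:
                raise ParseError(
                    f"{map_path}: line {lineno}: inconsistent column count")
            chroms.append(fields[0])
            ids.append(fields[1])
            try:
                if ncols == 4:
                    cms.append(float(fields[2]))
                    bp = int(fields[3])
                else:
                    bp = int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{map_path}: line {lineno}: bad numeric field: {exc}")
            if bp < 0:
                raise ParseError(f"{map_path}: line {lineno}: negative bp")
            bps.append(bp)
    if not bps:
        raise ParseError(f"{map_path}: no markers")
    mm = MarkerMap(
        chromosome=np.array(chroms, dtype=object),
        marker_id=np.array(ids, dtype=object),
        position_bp=np.array(bps, dtype=np.int64),
        genetic_pos_cm=np.array(cms) if ncols == 4 else None,
    )
    return _sort_marker_map(mm)


def _sort_marker_map(mm: MarkerMap) -> MarkerMap:
    """Stable-sort markers by bp within chromosome (first-appearance order)."""
    rank = {c: i for i, c in enumerate(mm.chromosomes())}
    chrom_rank = np.array([rank[c] for c in mm.chromosome])
    order = np.lexsort((mm.position_bp, chrom_rank))
    out = mm.subset(order)
    # duplicate physical positions are legal but worth flagging
    for c in out.chromosomes():
        pos = out.position_bp[out.chromosome == c]
        ndup = len(pos) - len(np.unique(pos))
        if ndup:
            logger.warning("chromosome %s: %d duplicate position(s)", c, ndup)
    return out


def read_plink(ped_path, map_path, phased: bool = False):
    """Load a PLINK text fileset.

    Returns a :class:`GenotypeDataset`, or a :class:`HaplotypeDataset` when
    ``phased=True`` (the caller asserts the two allele fields per marker are
    haplotype-ordered). Columns are recoded against the per-locus minor
    allele; ties at frequency 0.5 are broken by lexicographic allele order.
    """
    markers = read_map(map_path)
    m = markers.n_markers

    sample_ids: list[str] = []
    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                if (len(fields) >= 6 and (len(fields) - 6) % 2 == 0
                        and len(fields) != 6 + 2 * m):
                    raise ParseError(
                        f"{ped_path}: line {lineno}: marker count mismatch "
                        f"(ped has {(len(fields) - 6) // 2} markers, "
                        f"map has {m})")
                raise ParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields, "
                    f"got {len(fields)}")
            sample_ids.append(fields[1])
            rows.append(fields[6:])
    if not rows:
        raise ParseError(f"{ped_path}: no individuals")

    alleles = np.array(rows, dtype=object)   # (n, 2m), original map order
    bad = ~np.isin(alleles, list(_ALLELE_CODES | {_MISSING_CODE}))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"{ped_path}: individual {sample_ids[r]}: "
            f"invalid allele code {alleles[r, c]!r}")

    n = len(rows)
    counts = np.full((n, m), MISSING, dtype=np.int8)
    haps = np.full((2 * n, m), MISSING, dtype=np.int8) if phased else None
    minor = np.empty(m, dtype=object)
    major = np.empty(m, dtype=object)

    # ped columns follow the file order of the map; permute into sorted order
    file_col = markers.original_index
    for j in range(m):
        src = file_col[j]
        a1 = alleles[:, 2 * src]
        a2 = alleles[:, 2 * src + 1]
        miss = (a1 == _MISSING_CODE) | (a2 == _MISSING_CODE)
        obs = np.concatenate([a1[~miss], a2[~miss]])
        uniq, freq = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise ParseError(
                f"marker {markers.marker_id[j]}: more than two alleles "
                f"({', '.join(uniq)})")
        if len(uniq) == 0:
            minor[j] = major[j] = None
            continue
        if len(uniq) == 1:
            minor[j], major[j] = None, uniq[0]
            mn = None
        else:
            # minor = rarer allele; lexicographic tie-break at exactly 0.5
            if freq[0] < freq[1]:
                mn, mj = uniq[0], uniq[1]
            elif freq[1] < freq[0]:
                mn, mj = uniq[1], uniq[0]
            else:
                mn, mj = sorted(uniq)
            minor[j], major[j] = mn, mj
        if mn is None:
            counts[~miss, j] = 0
            if phased:
                haps[np.repeat(~miss, 2), j] = 0
        else:
            cnt = (a1 == mn).astype(np.int8) + (a2 == mn).astype(np.int8)
            counts[:, j] = np.where(miss, MISSING, cnt)
            if phased:
                h = np.empty(2 * n, dtype=np.int8)
                h[0::2] = (a1 == mn)
                h[1::2] = (a2 == mn)
                h[np.repeat(miss, 2)] = MISSING
                haps[:, j] = h

    n_miss = int((counts == MISSING).sum())
    logger.info("loaded %s: %d individuals, %d markers, %d missing calls",
                ped_path, n, m, n_miss)
    if phased:
        return HaplotypeDataset(markers=markers, alleles=haps,
                                sample_ids=sample_ids,
                                minor_allele=minor, major_allele=major)
    return GenotypeDataset(markers=markers, counts=counts,
                           sample_ids=sample_ids,
                           minor_allele=minor, major_allele=major)


# ---------------------------------------------------------------------------
# pre-computed LD tables
# ---------------------------------------------------------------------------

#: Default column layout of LD tables written by this package.
DEFAULT_LD_COLUMNS: Mapping[str, int] = {
    "chrom": 0, "pos_a": 1, "pos_b": 2, "r2": 3, "n_obs": 4,
}

LD_TABLE_HEADER = ("CHR", "POS_A", "POS_B", "R2", "NOBS")


def read_ld_table(path, column_spec: Mapping[str, int] | None = None,
                  n_obs: int | None = None) -> list[PairwiseLD]:
    """Read a delimited pairwise-LD table.

    ``column_spec`` maps the keys ``chrom``, ``r2``, and either
    ``pos_a``/``pos_b`` or ``dist`` (plus optionally ``n_obs``) to 0-based
    column indices. Without a per-pair ``n_obs`` column a global ``n_obs``
    must be supplied. Rows with r² outside [0, 1] or a non-positive distance
    are dropped and counted in the log. A leading non-numeric header line is
    skipped automatically.
    """
    spec = dict(column_spec) if column_spec is not None else None
    records: list[PairwiseLD] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if spec is None:
                spec = dict(DEFAULT_LD_COLUMNS)
                if len(fields) < 5:
                    spec.pop("n_obs")
            needed = {"chrom", "r2"}
            if not needed <= spec.keys():
                raise ConfigError("column_spec must name 'chrom' and 'r2'")
            if "dist" not in spec and not {"pos_a", "pos_b"} <= spec.keys():
                raise ConfigError(
                    "column_spec must name 'pos_a'/'pos_b' or 'dist'")
            try:
                r2 = float(fields[spec["r2"]])
            except (ValueError, IndexError):
                if lineno == 1 and not records:
                    continue    # header line
                raise ParseError(f"{path}: line {lineno}: bad r2 field")
            try:
                chrom = fields[spec["chrom"]]
                if "dist" in spec:
                    pos_a, pos_b = 0, int(float(fields[spec["dist"]]))
                else:
                    pos_a = int(float(fields[spec["pos_a"]]))
                    pos_b = int(float(fields[spec["pos_b"]]))
                if "n_obs" in spec:
                    n = int(float(fields[spec["n_obs"]]))
                elif n_obs is not None:
                    n = int(n_obs)
                else:
                    raise ConfigError(
                        "LD table has no n column and no global n supplied")
            except (ValueError, IndexError):
                raise ParseError(f"{path}: line {lineno}: malformed row")
            if pos_b <= pos_a or not (-1e-12 <= r2 <= 1 + 1e-12):
                n_skipped += 1
                continue
            records.append(PairwiseLD(chromosome=chrom, pos_a=pos_a,
                                      pos_b=pos_b,
                                      r2=float(np.clip(r2, 0.0, 1.0)),
                                      n_obs=n))
    if n_skipped:
        logger.info("%s: skipped %d out-of-range row(s)", path, n_skipped)
    if not records:
        raise ParseError(f"{path}: no LD records")
    return records


def write_ld_table(pairs: Iterable[PairwiseLD], path) -> None:
    """Write pairs in the package's standard 5-column tab-delimited layout."""
    pairs = list(pairs)
    if not pairs:
        raise ParseError("nothing to write: empty pair list")
    with open(path, "w") as fh:
        fh.write("\t".join(LD_TABLE_HEADER) + "\n")
        for p in pairs:
            fh.write(f"{p.chromosome}\t{p.pos_a}\t{p.pos_b}\t"
                     f"{p.r2:.10g}\t{p.n_obs}\n")


# ---------------------------------------------------------------------------
# trajectory output
# ---------------------------------------------------------------------------

def write_trajectory(estimates: Sequence["NeEstimate"], path) -> None:
    """Write the Ne trajectory as a tab-delimited table.

    Columns: generations ago, Ne, mean pair distance (bp), mean adjusted r²,
    its within-bin standard deviation, and the number of SNP pairs in the
    bin. Generations/Ne/distance are printed with 1 decimal, the r²
    statistics with 6 decimals, so identical runs are byte-identical.
    """
    estimates = list(estimates)
    if not estimates:
        raise ComputationError("nothing to write: empty estimate list")
    with open(path, "w") as fh:
        fh.write("\t".join(TRAJECTORY_HEADER) + "\n")
        for e in estimates:
            fh.write(f"{e.generations_ago:.1f}\t{e.ne:.1f}\t"
                     f"{e.mean_distance_bp:.1f}\t{e.mean_r2_adj:.6f}\t"
                     f"{e.sd_r2_adj:.6f}\t{e.n_pairs}\n")
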