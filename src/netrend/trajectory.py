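"""From binned LD decay to an Ne-versus-generations trajectory.

The chain of reasoning: under drift–recombination equilibrium the expected
squared correlation between two loci at recombination fraction ``c`` is
``E(r²) = 1/(alpha + 4 Ne c)`` (``alpha`` = 1 without mutation, 2 or 2.2
with mutation corrections). Observed r² is first corrected for the finite
sample, ``r²_adj = r² - 1/(beta n)`` with ``beta`` = 2 for phased and 1 for
unphased data. Solving for Ne and dating each distance class at
``t = 1/(2 f(c_t))`` generations ago gives one (t, Ne) point per distance
bin:

    Ne(t) = (4 f(c_t))^-1 * (1 / mean(r²_adj) - alpha)

Physical distance delta (bp) is converted to map distance ``d = k * delta``
(Morgans; default k = 1e-8, i.e. 1 Mb = 1 cM) and then to a recombination
fraction through a mapping function (linear, Haldane or Kosambi built in;
further functions can be registered). Larger distances inform more recent
generations.

Distance bins follow a power-law layout: bin ``i`` of ``totBins`` spans

    [minD + (maxD-minD)((i-1)/totBins)^x,  minD + (maxD-minD)(i/totBins)^x)

so ``x = 1`` gives equal widths while ``x > 1`` widens the long-distance
(recent-generation) bins, evening out pair counts per bin.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ComputationError, ConfigError
from .io import PairwiseLD

logger = logging.getLogger(__name__)

_HALF_EPS = 1e-9        # linear mapping clamps at 0.5 - _HALF_EPS

# defaults for the full pipeline (overridable everywhere)
DEFAULT_MIN_DIST = 50_000
DEFAULT_MAX_DIST = 4_000_000
DEFAULT_TOT_BINS = 30
DEFAULT_BIN_EXPONENT = 1.5
DEFAULT_K = 1e-8
DEFAULT_ALPHA = 1.0


# ---------------------------------------------------------------------------
# distance bins
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinScheme:
    """Power-law partition of the distance range into contiguous bins.

    ``edges`` has ``tot_bins + 1`` entries; bin ``i`` (0-based) is the
    half-open interval ``[edges[i], edges[i+1])``, except the last bin which
    is closed at ``max_d``.
    """

    min_d: int
    max_d: int
    tot_bins: int
    x: float
    edges: np.ndarray = field(repr=False)

    def assign(self, distances) -> np.ndarray:
        """Bin index for each distance; -1 when outside [min_d, max_d]."""
        d = np.atleast_1d(np.asarray(distances, dtype=np.float64))
        idx = np.searchsorted(self.edges, d, side="right") - 1
        idx[d == self.max_d] = self.tot_bins - 1
        idx[(d < self.min_d) | (d > self.max_d)] = -1
        return idx

    def midpoints(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def widths(self) -> np.ndarray:
        return np.diff(self.edges)


def make_bins(min_d: int, max_d: int, tot_bins: int, x: float) -> BinScheme:
    """Build the power-law bin scheme.

    Edge ``i`` (0..tot_bins) sits at ``min_d + (max_d-min_d)*(i/tot_bins)^x``.
    """
    if min_d >= max_d:
        raise ConfigError(f"min_d must be < max_d (got {min_d}, {max_d})")
    if tot_bins < 1:
        raise ConfigError("tot_bins must be >= 1")
    if x <= 0:
        raise ConfigError("bin exponent x must be > 0")
    i = np.arange(tot_bins + 1, dtype=np.float64)
    edges = min_d + (max_d - min_d) * (i / tot_bins) ** x
    edges[0] = min_d            # exact endpoints, no float residue
    edges[-1] = max_d
    return BinScheme(min_d=int(min_d), max_d=int(max_d),
                     tot_bins=int(tot_bins), x=float(x), edges=edges)


# ---------------------------------------------------------------------------
# physical -> recombinational distance
# ---------------------------------------------------------------------------

def _linear(d: np.ndarray) -> np.ndarray:
    c = np.minimum(d, 0.5 - _HALF_EPS)
    if np.any(d >= 0.5):
        logger.warning("linear mapping clamped %d distance(s) at c=0.5",
                       int(np.sum(d >= 0.5)))
    return c


def _haldane(d: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def _kosambi(d: np.ndarray) -> np.ndarray:
    return 0.5 * np.tanh(2.0 * d)


_MAPPING_FUNCTIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": _linear,
    "haldane": _haldane,
    "kosambi": _kosambi,
}


def register_mapping_function(name: str,
                              fn: Callable[[np.ndarray], np.ndarray],
                              overwrite: bool = False) -> None:
    """Register an extra map-distance -> recombination-fraction function.

    The hook exists for mapping functions from the older LD literature
    (e.g. the Sved and Sved–Feldman forms) or for organism-specific maps;
    ``fn`` must be monotone non-decreasing with values in [0, 0.5).
    """
    if name in _MAPPING_FUNCTIONS and not overwrite:
        raise ConfigError(f"mapping function {name!r} already registered")
    _MAPPING_FUNCTIONS[name] = fn


def mapping_function_names() -> list[str]:
    return sorted(_MAPPING_FUNCTIONS)


@dataclass(frozen=True)
class MappingSpec:
    """How physical distance becomes a recombination fraction.

    ``k`` is the Morgans-per-bp scale of ``d = k * delta`` (default 1e-8:
    1 Mb per cM); ``function`` names a registered mapping function.
    """

    k: float = DEFAULT_K
    function: str = "linear"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ConfigError(f"k must be > 0, got {self.k}")
        if self.function not in _MAPPING_FUNCTIONS:
            raise ConfigError(
                f"unknown mapping function {self.function!r}; registered: "
                f"{', '.join(mapping_function_names())}")


def map_distance(delta_bp, spec: MappingSpec):
    """Recombination fraction for physical distance(s) in bp.

    Returns a float for scalar input, an array otherwise; always in
    (0, 0.5).
    """
    d = np.asarray(delta_bp, dtype=np.float64)
    if np.any(d <= 0):
        raise ConfigError("physical distance must be > 0")
    c = _MAPPING_FUNCTIONS[spec.function](d * spec.k)
    # c is strictly below 1/2 mathematically; keep it so in float64 too
    c = np.minimum(c, 0.5 - _HALF_EPS)
    if np.isscalar(delta_bp) or np.ndim(delta_bp) == 0:
        return float(c)
    return c


# ---------------------------------------------------------------------------
# corrections
# ---------------------------------------------------------------------------

_ALLOWED_ALPHA = (1.0, 2.0, 2.2)


@dataclass(frozen=True)
class CorrectionSpec:
    """Sample-size and mutation corrections.

    ``alpha`` is the mutation adjustment in the Ne inversion (1 = drift and
    recombination only, 2 or 2.2 with mutation); ``beta`` scales the
    sample-size term of ``r²_adj = r² - 1/(beta n)`` (2 when phase is known,
    1 when not). ``allow_any_alpha`` unlocks arbitrary positive alpha for
    expert use.
    """

    alpha: float = DEFAULT_ALPHA
    beta: int = 1
    allow_any_alpha: bool = False

    def __post_init__(self) -> None:
        if self.beta not in (1, 2):
            raise ConfigError(f"beta must be 1 or 2, got {self.beta}")
        if self.allow_any_alpha:
            if self.alpha <= 0:
                raise ConfigError("alpha must be > 0")
        elif not any(math.isclose(self.alpha, a) for a in _ALLOWED_ALPHA):
            raise ConfigError(
                f"alpha must be one of {_ALLOWED_ALPHA} "
                "(or pass allow_any_alpha=True)")


def adjust_r2(r2, n_obs, beta: int):
    """Sample-size-corrected LD: ``r² - 1/(beta * n)``; may be negative."""
    return np.asarray(r2, dtype=np.float64) - 1.0 / (
        beta * np.asarray(n_obs, dtype=np.float64))


# ---------------------------------------------------------------------------
# binned summaries and Ne estimates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinSummary:
    """Aggregated, sample-size-corrected LD of one distance bin."""

    bin_index: int
    n_pairs: int
    mean_distance_bp: float
    mean_r2_adj: float
    sd_r2_adj: float


@dataclass(frozen=True)
class NeEstimate:
    """One (t, Ne) trajectory point derived from one distance bin.

    ``valid`` is False when the bin's mean adjusted r² or the implied Ne is
    non-positive; such bins are excluded from the main output but kept for
    diagnostics.
    """

    generations_ago: float
    ne: float
    mean_distance_bp: float
    mean_r2_adj: float
    sd_r2_adj: float
    n_pairs: int
    bin_index: int = -1
    valid: bool = True


def _pairs_to_arrays(pairs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(pairs, pd.DataFrame):
        return (pairs["dist"].to_numpy(np.float64),
                pairs["r2"].to_numpy(np.float64),
                pairs["n_obs"].to_numpy(np.float64))
    pairs = list(pairs)
    return (np.array([p.distance_bp for p in pairs], dtype=np.float64),
            np.array([p.r2 for p in pairs], dtype=np.float64),
            np.array([p.n_obs for p in pairs], dtype=np.float64))


def summarize_bins(pairs, scheme: BinScheme,
                   corr: CorrectionSpec) -> list[BinSummary]:
    """Aggregate pairwise LD into per-bin means.

    Each pair's r² is corrected with its own ``n_obs`` first, then pairs
    are grouped by distance bin; per bin the mean/sd (ddof=1; 0 for a
    single pair) of adjusted r² and the mean distance are reported. Empty
    bins are omitted with a warning. ``pairs`` may be an iterable of
    :class:`~netrend.io.PairwiseLD` or the DataFrame produced by
    :func:`netrend.ld.compute_pair_table`.
    """
    dist, r2, n_obs = _pairs_to_arrays(pairs)
    if dist.size == 0:
        raise ComputationError("no pairs in range")
    adj = adjust_r2(r2, n_obs, corr.beta)
    idx = scheme.assign(dist)
    inside = idx >= 0
    if not inside.any():
        raise ComputationError("no pairs in range")
    idx, dist, adj = idx[inside], dist[inside], adj[inside]

    summaries: list[BinSummary] = []
    order = np.argsort(idx, kind="stable")
    idx, dist, adj = idx[order], dist[order], adj[order]
    boundaries = np.flatnonzero(np.diff(idx)) + 1
    groups = np.split(np.arange(idx.size), boundaries)
    occupied = {int(idx[g[0]]) for g in groups}
    for b in range(scheme.tot_bins):
        if b not in occupied:
            logger.warning("bin %d empty (range %.0f-%.0f bp)", b + 1,
                           scheme.edges[b], scheme.edges[b + 1])
    for g in groups:
        b = int(idx[g[0]])
        vals = adj[g]
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        summaries.append(BinSummary(
            bin_index=b, n_pairs=int(vals.size),
            mean_distance_bp=float(dist[g].mean()),
            mean_r2_adj=float(vals.mean()), sd_r2_adj=sd))
    return summaries


def estimate_ne(summary: BinSummary, spec: MappingSpec,
                corr: CorrectionSpec) -> NeEstimate:
    """Invert the drift–recombination expectation for one bin.

    The bin's recombination fraction ``c_t`` comes from its mean pair
    distance; then ``Ne = (1/(4 c_t)) (1/mean_r2_adj - alpha)`` and
    ``t = 1/(2 c_t)`` generations ago.
    """
    c = map_distance(summary.mean_distance_bp, spec)
    t = 1.0 / (2.0 * c)
    if summary.mean_r2_adj > 0:
        ne = (1.0 / (4.0 * c)) * (1.0 / summary.mean_r2_adj - corr.alpha)
    else:
        ne = float("nan")
    valid = summary.mean_r2_adj > 0 and ne > 0
    return NeEstimate(
        generations_ago=t, ne=ne,
        mean_distance_bp=summary.mean_distance_bp,
        mean_r2_adj=summary.mean_r2_adj, sd_r2_adj=summary.sd_r2_adj,
        n_pairs=summary.n_pairs, bin_index=summary.bin_index, valid=valid)


@dataclass(frozen=True)
class TrajectoryResult:
    """Valid trajectory points (sorted most-recent first, i.e. ascending t)
    plus the bins excluded as invalid."""

    estimates: tuple[NeEstimate, ...]
    excluded: tuple[NeEstimate, ...]

    def __iter__(self):
        return iter(self.estimates)

    def __len__(self):
        return len(self.estimates)


def run_trajectory(pairs, scheme: BinScheme, spec: MappingSpec,
                   corr: CorrectionSpec) -> TrajectoryResult:
    """Full bin → correct → map → invert pipeline.

    Returns valid estimates sorted by generations-ago ascending (largest
    distances, hence most recent generations, first); invalid bins are
    returned separately for the diagnostics sidecar.
    """
    summaries = summarize_bins(pairs, scheme, corr)
    estimates = [estimate_ne(s, spec, corr) for s in summaries]
    valid = sorted((e for e in estimates if e.valid),
                   key=lambda e: e.generations_ago)
    excluded = tuple(e for e in estimates if not e.valid)
    if not valid:
        raise ComputationError("no valid Ne estimates")
    if excluded:
        logger.info("excluded %d bin(s) with non-positive adjusted r2 or Ne",
                    len(excluded))
    return TrajectoryResult(estimates=tuple(valid), excluded=excluded)
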