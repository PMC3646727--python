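"""Genome representation and closed-form block-sharing quantities.

A pair of present-day chromosomes that coalesce at a site along a pedigree
path of ``n`` meioses share around that site an identical-by-descent (IBD)
block whose length is governed by recombination accumulated over those ``n``
meioses.  Modelling recombination as a homogeneous Poisson process on the
genetic map, a chromosome of genetic length ``G`` Morgans is cut into pieces
by the ``n`` meioses, and the expected number of pieces of length at least
``x`` Morgans is

    K(n, x) = exp(-n*x) * (1 + n*(G - x)),   0 <= x <= G,

with ``K(n, x) = 0`` for ``x > G``.  Everything downstream — expected block
counts given a coalescent-time distribution, ancestor-number conversions,
block-age distributions — is a linear functional of this kernel.

All lengths in this module are in **Morgans**; conversion to the centiMorgan
scale used at the I/O boundary is exactly a factor of 100.  Meioses depth
``n`` is a dimensionless path length; an ancestor at depth ``n`` lived
``n/2`` generations, i.e. ``(n/2) * generation_time`` years, in the past.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "TimeGrid",
    "CoalescentCurve",
    "default_map",
    "uniform_map",
    "make_time_grid",
    "expected_pieces",
    "true_block_intensity",
    "expected_blocks_ge",
    "path_survival",
    "genetic_ancestors_per_generation",
    "ancestors_in_meioses_range",
    "genealogical_from_genetic",
    "block_age_fractions",
    "mean_block_age",
]

#: Sex-averaged autosomal lengths (cM) in the usual chromosome order, from a
#: standard human linkage map; used only for their relative sizes — the
#: shipped default rescales them so the autosomes total 32 Morgans.
_AUTOSOME_CM = np.array(
    [286.3, 268.6, 223.2, 214.5, 204.1, 192.0, 187.2, 168.0, 166.4, 181.1,
     158.2, 174.7, 125.9, 120.4, 141.3, 134.8, 128.5, 117.2, 107.7, 108.3,
     62.8, 74.1]
)


@dataclass(frozen=True)
class GeneticMap:
    """An ordered set of chromosomes with genetic lengths in Morgans."""

    names: tuple[str, ...]
    lengths: np.ndarray  # Morgans, one per chromosome

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "lengths", lengths)
        if lengths.ndim != 1 or len(self.names) != lengths.size:
            raise ValueError("names and lengths must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if not np.all(lengths > 0):
            raise ValueError("chromosome lengths must be strictly positive")

    @property
    def total_length(self) -> float:
        """Total map length in Morgans."""
        return float(self.lengths.sum())

    @property
    def n_chromosomes(self) -> int:
        return len(self.names)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        """Read a two-column TSV (chromosome, length_cM); header required."""
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (chromosome, length_cM)")
        return cls(tuple(str(c) for c in df.iloc[:, 0]),
                   df.iloc[:, 1].to_numpy(float) / 100.0)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"chromosome": self.names,
                      "length_cM": self.lengths * 100.0}).to_csv(
            path, sep="\t", index=False)


def default_map(total_morgans: float = 32.0) -> GeneticMap:
    """The 22 human autosomes, rescaled to a given total length.

    The total sex-averaged autosomal map length is about 32 Morgans; the
    within-genome split follows a standard linkage map.
    """
    lengths = _AUTOSOME_CM / _AUTOSOME_CM.sum() * total_morgans
    return GeneticMap(tuple(f"chr{i}" for i in range(1, 23)), lengths)


def uniform_map(n_chromosomes: int = 22, total_morgans: float = 32.0) -> GeneticMap:
    """Equal-length chromosomes; convenient for analytic tests."""
    return GeneticMap(
        tuple(f"chr{i}" for i in range(1, n_chromosomes + 1)),
        np.full(n_chromosomes, total_morgans / n_chromosomes),
    )


@dataclass(frozen=True)
class TimeGrid:
    """Partition of (0, n_J] meioses into intervals, finest at recent times.

    ``endpoints`` holds n_0 = 0 < n_1 < ... < n_J.  The coalescent curve is
    piecewise constant on the J intervals.
    """

    endpoints: np.ndarray
    generation_time: float = 30.0  # years per generation

    def __post_init__(self) -> None:
        ep = np.asarray(self.endpoints, dtype=float)
        object.__setattr__(self, "endpoints", ep)
        if ep[0] != 0.0 or np.any(np.diff(ep) <= 0):
            raise ValueError("endpoints must start at 0 and strictly increase")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")

    @property
    def n_intervals(self) -> int:
        return self.endpoints.size - 1

    @property
    def lower(self) -> np.ndarray:
        return self.endpoints[:-1]

    @property
    def upper(self) -> np.ndarray:
        return self.endpoints[1:]

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.endpoints)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.endpoints[:-1] + self.endpoints[1:])

    def years(self, n) -> np.ndarray:
        """Years before present of an ancestor at meioses depth n."""
        return np.asarray(n, dtype=float) / 2.0 * self.generation_time

    def meioses(self, years) -> np.ndarray:
        """Inverse of :meth:`years`."""
        return 2.0 * np.asarray(years, dtype=float) / self.generation_time

    def interval_of(self, n: float) -> int:
        """Index of the interval (n_{j-1}, n_j] containing n."""
        if not (0 < n <= self.endpoints[-1]):
            raise ValueError(f"n={n} outside grid range (0, {self.endpoints[-1]}]")
        return int(np.searchsorted(self.endpoints, n, side="left")) - 1


def make_time_grid(n_intervals: int = 360, max_meioses: float = 6660.0,
                   generation_time: float = 30.0) -> TimeGrid:
    """Build the default inversion grid: interval widths growing linearly.

    Widths are proportional to the interval index (triangular scheme), so the
    resolution is finest for recent times; at the defaults the deepest
    endpoint is 6,660 meioses = 99,900 years at 30 years per generation.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    if max_meioses <= 0 or (n_intervals > 1 and max_meioses <= n_intervals):
        raise ValueError("max_meioses must exceed n_intervals")
    j = np.arange(n_intervals + 1, dtype=float)
    endpoints = max_meioses * j * (j + 1) / (n_intervals * (n_intervals + 1))
    return TimeGrid(endpoints, generation_time)


@dataclass(frozen=True)
class CoalescentCurve:
    """Coalescent-time distribution mu(n), piecewise constant on a TimeGrid.

    ``values[j]`` is the probability density per unit meioses depth on the
    interval (n_{j-1}, n_j]; the total mass sum(values * widths) is the
    probability a random site's pairwise common ancestor lies within the grid,
    and must not exceed 1.
    """

    grid: TimeGrid
    values: np.ndarray

    _MASS_TOL = 1e-9

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.grid.n_intervals,):
            raise ValueError("values must have one entry per grid interval")
        if np.any(v < 0):
            raise ValueError("coalescent densities must be nonnegative")
        if self.mass > 1.0 + self._MASS_TOL:
            raise ValueError(f"total coalescent mass {self.mass:.6g} exceeds 1")

    @property
    def mass(self) -> float:
        return float(self.values @ self.grid.widths)

    def interval_masses(self) -> np.ndarray:
        return self.values * self.grid.widths

    @classmethod
    def point_mass(cls, grid: TimeGrid, n: float, mass: float = 1.0) -> "CoalescentCurve":
        """All mass in the grid interval containing depth ``n``."""
        j = grid.interval_of(n)
        v = np.zeros(grid.n_intervals)
        v[j] = mass / grid.widths[j]
        return cls(grid, v)

    @classmethod
    def from_epochs(cls, grid: TimeGrid, epochs, generation_time: float | None = None
                    ) -> "CoalescentCurve":
        """Piecewise-constant curve from (years_lo, years_hi, total_mass) epochs.

        Mass is spread uniformly (per unit n) over the part of the grid
        covered by each epoch; epoch boundaries need not align with the grid —
        partial overlaps get a proportional share.
        """
        v = np.zeros(grid.n_intervals)
        lo, hi = grid.lower, grid.upper
        for years_lo, years_hi, mass in epochs:
            a, b = grid.meioses(years_lo), grid.meioses(years_hi)
            if not (0 <= a < b <= grid.endpoints[-1]):
                raise ValueError(f"epoch ({years_lo}, {years_hi}) ya outside grid")
            overlap = np.clip(np.minimum(hi, b) - np.maximum(lo, a), 0.0, None)
            v += mass / (b - a) * (overlap / grid.widths)
        return cls(grid, v)


# ---------------------------------------------------------------------------
# Fragmentation kernel and exact integrals over meioses depth.


def expected_pieces(n, x, chrom_length):
    """Mean number of pieces of length >= x when n meioses cut a chromosome.

    K(n, x) = exp(-n x) (1 + n (G - x)) for 0 <= x <= G, else 0.  Vectorized
    over any broadcastable combination of arguments.
    """
    n = np.asarray(n, dtype=float)
    x = np.asarray(x, dtype=float)
    G = np.asarray(chrom_length, dtype=float)
    if np.any(n < 0) or np.any(x < 0) or np.any(G <= 0):
        raise ValueError("require n >= 0, x >= 0, chromosome length > 0")
    k = np.exp(-n * x) * (1.0 + n * (G - x))
    return np.where(x <= G, k, 0.0)[()]


# The closed forms for the depth integrals below suffer catastrophic
# cancellation when x*n is tiny (1/x^2-scale terms nearly cancel); a short
# Taylor series in x takes over there, with relative error O((x b)^3).
_SERIES_THRESHOLD = 1e-3


def _int_exp(a, b, x):
    """∫_a^b e^{-n x} dn, elementwise in x (x >= 0)."""
    a, b, x = np.broadcast_arrays(np.asarray(a, float), np.asarray(b, float),
                                  np.asarray(x, float))
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        val = (np.exp(-a * x) - np.exp(-b * x)) / x
    series = ((b - a) - x * (b**2 - a**2) / 2.0 + x**2 * (b**3 - a**3) / 6.0)
    return np.where(x * b < _SERIES_THRESHOLD, series, val)


def _int_n_exp(a, b, x):
    """∫_a^b n e^{-n x} dn."""
    a, b, x = np.broadcast_arrays(np.asarray(a, float), np.asarray(b, float),
                                  np.asarray(x, float))
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        def F(n):
            return -(n / x + 1.0 / x**2) * np.exp(-n * x)
        val = F(b) - F(a)
    series = ((b**2 - a**2) / 2.0 - x * (b**3 - a**3) / 3.0
              + x**2 * (b**4 - a**4) / 8.0)
    return np.where(x * b < _SERIES_THRESHOLD, series, val)


def _int_n2_exp(a, b, x):
    """∫_a^b n^2 e^{-n x} dn."""
    a, b, x = np.broadcast_arrays(np.asarray(a, float), np.asarray(b, float),
                                  np.asarray(x, float))
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        def F(n):
            return -(n**2 / x + 2.0 * n / x**2 + 2.0 / x**3) * np.exp(-n * x)
        val = F(b) - F(a)
    series = ((b**3 - a**3) / 3.0 - x * (b**4 - a**4) / 4.0
              + x**2 * (b**5 - a**5) / 10.0)
    return np.where(x * b < _SERIES_THRESHOLD, series, val)


def _genome_K(n, x, gmap: GeneticMap):
    """4 * sum_k K(n, x) over chromosomes, the genome-wide expected count."""
    n = np.asarray(n, dtype=float)[..., None]
    x = np.asarray(x, dtype=float)[..., None]
    G = gmap.lengths
    k = np.exp(-n * x) * (1.0 + n * (G - x))
    return 4.0 * np.where(x <= G, k, 0.0).sum(axis=-1)


def _genome_K_interval(a, b, x, gmap: GeneticMap):
    """∫_a^b 4 * sum_k K(n, x) dn in closed form.

    Broadcast shape: (a, b) x-interval-wise against scalar/array x.
    """
    a = np.asarray(a, dtype=float)[..., None]
    b = np.asarray(b, dtype=float)[..., None]
    x = np.asarray(x, dtype=float)[..., None]
    G = gmap.lengths
    val = _int_exp(a, b, x) + (G - x) * _int_n_exp(a, b, x)
    # the integrand is positive; clip roundoff cancellation near zero
    return 4.0 * np.clip(np.where(x <= G, val, 0.0), 0.0, None).sum(axis=-1)


def _genome_nK_interval(a, b, x, gmap: GeneticMap):
    """∫_a^b n * 4 * sum_k K(n, x) dn in closed form (for mean ages)."""
    a = np.asarray(a, dtype=float)[..., None]
    b = np.asarray(b, dtype=float)[..., None]
    x = np.asarray(x, dtype=float)[..., None]
    G = gmap.lengths
    val = _int_n_exp(a, b, x) + (G - x) * _int_n2_exp(a, b, x)
    return 4.0 * np.clip(np.where(x <= G, val, 0.0), 0.0, None).sum(axis=-1)


def true_block_intensity(n, x, gmap: GeneticMap):
    """Density (per Morgan, per unit coalescent mass) of true blocks at length x.

    The continuous part of -d/dx of the genome-wide kernel:

        4 * sum_k n e^{-n x} (2 + n (G_k - x)),  restricted to x <= G_k.

    The discrete atom at x = G_k (the whole uncut chromosome, mass
    4 e^{-n G_k} per chromosome) is *not* included here; quadratures that
    need exact mass conservation add it separately.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("require n > 0")
    n = n[..., None]
    x = np.asarray(x, dtype=float)[..., None]
    if np.any(x < 0):
        raise ValueError("require x >= 0")
    G = gmap.lengths
    dens = n * np.exp(-n * x) * (2.0 + n * (G - x))
    return 4.0 * np.where(x <= G, dens, 0.0).sum(axis=-1)


def expected_blocks_ge(mu: CoalescentCurve, x, gmap: GeneticMap):
    """Expected genome-wide blocks of length >= x Morgans per pair.

    Sum over grid intervals of mu_j * ∫_interval 4 Σ_k K(n, x) dn, with the
    integral over meioses depth done in closed form (the continuous-n
    convention).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("require x >= 0")
    grid = mu.grid
    # shape (J, ...) per-interval integrals against each x
    per = _genome_K_interval(grid.lower[:, None], grid.upper[:, None],
                             x[None, ...], gmap)
    return (mu.values @ per.reshape(grid.n_intervals, -1)).reshape(x.shape)[()]


def path_survival(n, gmap: GeneticMap):
    """r(n) = 2^{-n} sum_k (1 + n G_k): mean blocks jointly inherited along
    one specific pedigree path of n meioses."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("require n >= 0")
    return (np.exp(-n * np.log(2.0)) *
            (gmap.n_chromosomes + n * gmap.total_length))[()]


def _log_path_survival(n: float, gmap: GeneticMap) -> float:
    return (-n * np.log(2.0)
            + np.log(gmap.n_chromosomes + n * gmap.total_length))


def genetic_ancestors_per_generation(mu: CoalescentCurve, gmap: GeneticMap) -> np.ndarray:
    """Expected genetic common ancestors per grid interval.

    The mean number of IBD blocks of any length inherited from depth n is
    mu(n) * 4 * sum_k (1 + n G_k); integrating over each grid interval gives
    the expected ancestor count attributable to that interval.  Summing over
    the whole grid equals expected_blocks_ge(mu, 0).
    """
    grid = mu.grid
    a, b = grid.lower, grid.upper
    per = 4.0 * (gmap.n_chromosomes * (b - a)
                 + gmap.total_length * (b**2 - a**2) / 2.0)
    return mu.values * per


def ancestors_in_meioses_range(mu: CoalescentCurve, gmap: GeneticMap,
                               n_lo: float, n_hi: float) -> float:
    """Expected ancestors with depth in (n_lo, n_hi], proportional for
    intervals partially covered."""
    grid = mu.grid
    a = np.clip(grid.lower, n_lo, n_hi)
    b = np.clip(grid.upper, n_lo, n_hi)
    per = 4.0 * (gmap.n_chromosomes * (b - a)
                 + gmap.total_length * (b**2 - a**2) / 2.0)
    return float(mu.values @ per)


def genealogical_from_genetic(m: float, n: float, gmap: GeneticMap,
                              log10: bool = False) -> float:
    """Order-of-magnitude genealogical ancestor count m / r(n).

    Computed in log scale, so deep n (where r(n) underflows) never divides by
    zero; with ``log10`` the base-10 logarithm is returned, which stays
    finite even when the count itself overflows the float range.
    """
    if m < 0:
        raise ValueError("require m >= 0")
    if n <= 0:
        raise ValueError("require n > 0")
    if m == 0:
        return -np.inf if log10 else 0.0
    logval = np.log(m) - _log_path_survival(n, gmap)
    if log10:
        return float(logval / np.log(10.0))
    with np.errstate(over="ignore"):
        return float(np.exp(logval))


def block_age_fractions(mu: CoalescentCurve, x: float, gmap: GeneticMap) -> np.ndarray:
    """Distribution over grid intervals of the depth of blocks >= x Morgans."""
    grid = mu.grid
    w = mu.values * _genome_K_interval(grid.lower, grid.upper,
                                      np.full(grid.n_intervals, x), gmap)
    total = w.sum()
    if total <= 0:
        raise ValueError("no blocks expected at this length under mu")
    return w / total


def mean_block_age(mu: CoalescentCurve, x: float, gmap: GeneticMap) -> float:
    """Mean age, in generations, of blocks of length >= x Morgans.

    Uses the exact K-weighted mean depth within each grid interval, i.e.
    E[n/2 | block >= x] under the forward model.
    """
    grid = mu.grid
    xs = np.full(grid.n_intervals, x)
    w = mu.values * _genome_K_interval(grid.lower, grid.upper, xs, gmap)
    wn = mu.values * _genome_nK_interval(grid.lower, grid.upper, xs, gmap)
    total = w.sum()
    if total <= 0:
        raise ValueError("no blocks expected at this length under mu")
    return float(wn.sum() / total / 2.0)
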