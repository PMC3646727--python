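"""Synthetic IBD data with known ground truth.

The generator is the sampling counterpart of the analytic forward model:
true blocks arise by placing Poisson recombination breakpoints on each
chromosome (rate n per Morgan, with the effective depth n drawn uniformly
within each grid interval — the continuous-n convention), cutting the
chromosome into pieces, and retaining each piece independently with the
interval's coalescent mass as probability, for each of the 4 chromosome-copy
pairs.  Observed data then pass through the detection channel: length-
dependent power, signed exponential length errors, a reporting threshold,
and false positives placed uniformly on the map across uniformly chosen
pairs.

Blocks inherited from different depths may overlap on the same pair; this
matches the additive expectation of the forward model and is deliberately
not deduplicated.  Everything is reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channel import DetectionModel, FalsePositiveModel
from .genome import CoalescentCurve, GeneticMap, TimeGrid
from .inversion import KernelOperator, LengthSpectrum

__all__ = [
    "Scenario",
    "simulate_true_blocks",
    "apply_channel",
    "make_labeled_fixture",
    "simulate_scenario",
    "sample_spectrum",
    "preset_curve",
    "default_pairs",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def default_pairs(n_pairs: int) -> list[tuple[str, str]]:
    """Disjoint synthetic pair ids p0000_a/p0000_b, ..."""
    return [(f"p{i:05d}_a", f"p{i:05d}_b") for i in range(n_pairs)]


def _sample_pieces(rng, n_break: int, n_take: int, G_cM: float):
    """Take ``n_take`` random pieces from a chromosome cut at ``n_break``
    uniform breakpoints; returns (start, length) pairs in cM."""
    edges = np.concatenate([[0.0], np.sort(rng.uniform(0.0, G_cM, n_break)),
                            [G_cM]])
    lengths = np.diff(edges)
    idx = rng.choice(n_break + 1, size=n_take, replace=False)
    return [(float(edges[i]), float(lengths[i])) for i in idx]


def simulate_true_blocks(mu: CoalescentCurve, gmap: GeneticMap, n_pairs: int,
                         seed, pairs=None) -> pd.DataFrame:
    """Draw true (error-free) IBD blocks for n_pairs chromosome pairs.

    Expected counts match the analytic kernel: the mean number of blocks of
    length >= x equals expected_blocks_ge(mu, x, gmap) per pair.  Returns a
    block table with a ``depth_n`` column tagging the meioses interval the
    block was inherited from.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = _rng(seed)
    if pairs is None:
        pairs = default_pairs(n_pairs)
    if len(pairs) != n_pairs:
        raise ValueError("pairs must have length n_pairs")
    grid = mu.grid
    masses = mu.interval_masses()
    G_cM = gmap.lengths * 100.0

    rows = []
    for j in np.nonzero(masses > 0)[0]:
        q = masses[j]
        a, b = grid.lower[j], grid.upper[j]
        n_eff = rng.uniform(a, b, size=n_pairs)
        for k, chrom in enumerate(gmap.names):
            lam = n_eff * gmap.lengths[k]
            B = rng.poisson(lam[:, None], size=(n_pairs, 4))
            R = rng.binomial(B + 1, q)
            for p, copy in zip(*np.nonzero(R)):
                for start, length in _sample_pieces(rng, int(B[p, copy]),
                                                    int(R[p, copy]), G_cM[k]):
                    rows.append((pairs[p][0], pairs[p][1], chrom,
                                 start, start + length, float(n_eff[p])))
    df = pd.DataFrame(rows, columns=["sample_a", "sample_b", "chromosome",
                                     "start_cM", "end_cM", "depth_n"])
    return df.sort_values(["sample_a", "chromosome", "start_cM"],
                          ignore_index=True)


def _sample_fp_lengths(rng, fp: FalsePositiveModel, n: int,
                       lo: float, hi: float = 50.0) -> np.ndarray:
    """Inverse-CDF sampling of false-positive lengths from f on (lo, hi]."""
    grid = np.geomspace(lo, hi, 2048)
    cdf = np.concatenate([[0.0],
                          np.cumsum(np.diff(grid)
                                    * 0.5 * (fp.f(grid[1:]) + fp.f(grid[:-1])))])
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


def apply_channel(blocks: pd.DataFrame, det: DetectionModel,
                  fp: FalsePositiveModel | None, n_pairs: int,
                  min_report: float = 1.0, seed=None, pairs=None,
                  gmap: GeneticMap | None = None) -> pd.DataFrame:
    """Push true blocks through the observation channel.

    Each true block of length x survives with probability c(x) and is
    reported with length x + e from the signed-exponential error mixture;
    false positives are added as a Poisson process with intensity
    n_pairs * f per cM of length, on uniformly chosen pairs and positions;
    observed blocks shorter than ``min_report`` cM are dropped.
    """
    rng = _rng(seed)
    out = blocks.copy()
    x = (out["end_cM"] - out["start_cM"]).to_numpy(float)

    if det.exact_lengths:
        y = x
        kept = np.ones(x.size, dtype=bool)
    else:
        kept = rng.random(x.size) < det.c(x)
        pos = rng.random(x.size) < det.gamma(x)
        e_pos = rng.exponential(1.0, x.size) / det.lam_pos(np.maximum(x, 1e-12))
        lm = det.lam_neg(np.maximum(x, 1e-12))
        u = rng.random(x.size)
        e_neg = -np.log1p(u * np.expm1(-lm * x)) / lm  # Exp(lm) | < x
        y = np.where(pos, x + e_pos, x - e_neg)
    out["end_cM"] = out["start_cM"].to_numpy(float) + y
    out = out[kept & (y >= min_report)]

    if fp is not None and n_pairs > 0:
        expected = n_pairs * fp.integral(min_report, np.inf)
        n_fp = rng.poisson(expected)
        if n_fp > 0:
            if pairs is None:
                pairs = default_pairs(n_pairs)
            if gmap is None:
                from .genome import default_map
                gmap = default_map()
            lengths = _sample_fp_lengths(rng, fp, n_fp, min_report)
            G_cM = gmap.lengths * 100.0
            rows = []
            for ln in lengths:
                room = np.clip(G_cM - ln, 0.0, None)
                if room.sum() == 0:
                    continue
                k = rng.choice(G_cM.size, p=room / room.sum())
                start = rng.uniform(0.0, room[k])
                a, b = pairs[rng.integers(len(pairs))]
                rows.append((a, b, gmap.names[k], start, start + ln, np.nan))
            fp_df = pd.DataFrame(rows, columns=["sample_a", "sample_b",
                                                "chromosome", "start_cM",
                                                "end_cM", "depth_n"])
            cols = [c for c in out.columns if c in fp_df.columns]
            out = pd.concat([out[cols], fp_df[cols]], ignore_index=True)
    return out.reset_index(drop=True)


def make_labeled_fixture(det: DetectionModel, fp: FalsePositiveModel | None,
                         n: int, length_range=(0.5, 20.0), seed=None,
                         fp_pair_equivalents: float = 0.0) -> pd.DataFrame:
    """Labeled spike-in fixture for channel fitting.

    ``n`` true lengths uniform on ``length_range`` pass through the channel;
    every record keeps its detection flag and raw inferred length (threshold
    handling is the fitter's job).  False positives, labeled
    true_length_cM = 0, are added with expectation
    fp_pair_equivalents * ∫ f over the length range.
    """
    rng = _rng(seed)
    lo, hi = length_range
    x = rng.uniform(lo, hi, size=int(n))
    if det.exact_lengths:
        detected = np.ones(x.size, dtype=bool)
        y = x.copy()
    else:
        detected = rng.random(x.size) < det.c(x)
        pos = rng.random(x.size) < det.gamma(x)
        e_pos = rng.exponential(1.0, x.size) / det.lam_pos(x)
        lm = det.lam_neg(x)
        u = rng.random(x.size)
        e_neg = -np.log1p(u * np.expm1(-lm * x)) / lm
        y = np.where(pos, x + e_pos, x - e_neg)
    df = pd.DataFrame({"true_length_cM": x, "detected": detected,
                       "inferred_length_cM": np.where(detected, y, np.nan)})
    if fp is not None and fp_pair_equivalents > 0:
        n_fp = rng.poisson(fp_pair_equivalents * fp.integral(lo, hi))
        if n_fp:
            fl = _sample_fp_lengths(rng, fp, n_fp, lo, hi)
            df = pd.concat([df, pd.DataFrame({
                "true_length_cM": 0.0, "detected": True,
                "inferred_length_cM": fl})], ignore_index=True)
    return df


def sample_spectrum(mu: CoalescentCurve, K: KernelOperator, n_pairs: int,
                    seed) -> LengthSpectrum:
    """Poisson-sample a binned spectrum from the forward model: counts
    N_i ~ Poisson(n_pairs * (F + L mu)_i)."""
    rng = _rng(seed)
    mean = n_pairs * K.predicted(mu.values)
    return LengthSpectrum(K.bins, rng.poisson(mean), n_pairs)


def preset_curve(name: str, grid: TimeGrid, mass: float = 0.01,
                 depth_years: float = 2500.0, **kw) -> CoalescentCurve:
    """Named demography presets for scenarios, as coalescent curves.

    constant: uniform density over (0, depth_years]; expansion: density
    rising linearly with depth (small recent population of growing ancestral
    size looking forward = more coalescence further back); bottleneck: a
    burst confined to the middle third of the depth range over a 10x weaker
    background; point_mass: all mass at one depth (kw: years).
    """
    n_max = float(grid.meioses(depth_years))
    lo, hi, w = grid.lower, grid.upper, grid.widths
    mid = grid.midpoints
    if name == "point_mass":
        years = kw.get("years", depth_years)
        return CoalescentCurve.point_mass(grid, grid.meioses(years), mass)
    if name == "constant":
        shape = np.clip(np.minimum(hi, n_max) - lo, 0.0, None) / w
    elif name == "expansion":
        shape = np.where(mid <= n_max, mid / n_max, 0.0)
    elif name == "bottleneck":
        inside = (mid > n_max / 3.0) & (mid <= 2.0 * n_max / 3.0)
        shape = np.where(mid <= n_max, np.where(inside, 1.0, 0.1), 0.0)
    else:
        raise ValueError(f"unknown preset {name!r}")
    total = shape @ w
    return CoalescentCurve(grid, shape * (mass / total))


@dataclass(frozen=True)
class Scenario:
    """A multi-population study design with known ground truth.

    populations: DataFrame (population, n, lon, lat); pair_curves: dict
    keyed by frozenset of population names (a singleton frozenset for
    within-population pairs) -> CoalescentCurve.
    """

    populations: pd.DataFrame
    pair_curves: dict
    gmap: GeneticMap
    det: DetectionModel
    fp: FalsePositiveModel | None
    seed: int = 0
    min_report: float = 1.0

    def curve_for(self, x: str, y: str) -> CoalescentCurve:
        return self.pair_curves[frozenset((x, y))]


def simulate_scenario(s: Scenario, epochs_years=((0, 500), (500, 1500),
                                                 (1500, 2500))):
    """Simulate observed blocks for every pair of individuals in a scenario.

    Returns (blocks, population table, truth) where truth records, per
    population pair, the generating curve and its expected ancestor totals
    in each epoch (for recovery scoring).
    """
    from .genome import ancestors_in_meioses_range

    rng = _rng(s.seed)
    samples = []
    for row in s.populations.itertuples():
        for i in range(int(row.n)):
            samples.append((f"{row.population}_{i:03d}", row.population,
                            row.lon, row.lat))
    pop_table = pd.DataFrame(samples, columns=["sample", "population",
                                               "lon", "lat"])
    by_pop = {p: g["sample"].tolist()
              for p, g in pop_table.groupby("population")}

    all_blocks = []
    truth = {}
    pops = sorted(by_pop)
    for i, x in enumerate(pops):
        for y in pops[i:]:
            mu = s.curve_for(x, y)
            if x == y:
                members = by_pop[x]
                pair_list = [(a, b) for ai, a in enumerate(members)
                             for b in members[ai + 1:]]
            else:
                pair_list = [(a, b) for a in by_pop[x] for b in by_pop[y]]
            if not pair_list:
                continue
            true = simulate_true_blocks(mu, s.gmap, len(pair_list), rng,
                                        pairs=pair_list)
            obs = apply_channel(true, s.det, s.fp, len(pair_list),
                                min_report=s.min_report, seed=rng,
                                pairs=pair_list, gmap=s.gmap)
            all_blocks.append(obs)
            grid = mu.grid
            truth[frozenset((x, y))] = {
                "curve": mu,
                "n_pairs": len(pair_list),
                "epoch_totals": {
                    tuple(e): ancestors_in_meioses_range(
                        mu, s.gmap, grid.meioses(e[0]), grid.meioses(e[1]))
                    for e in epochs_years},
            }
    blocks = pd.concat(all_blocks, ignore_index=True) if all_blocks \
        else pd.DataFrame(columns=["sample_a", "sample_b", "chromosome",
                                   "start_cM", "end_cM"])
    return blocks, pop_table, truth
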