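"""Population-level IBD summaries and raw-call postprocessing.

Blocks are carried as pandas DataFrames with the columns

    sample_a, sample_b, chromosome, start_cM, end_cM[, score]

(positions are genetic, 0-based half-open, per chromosome); raw per-run
segment calls additionally carry ``run_id``.  The operations here mirror the
downstream analyses of a multi-population IBD study: consolidating multiple
stochastic caller runs into blocks, mean sharing rates between populations,
correlations of sharing profiles, exponential decay of sharing with
geographic distance, permutation tests for within-population substructure,
and a genome scan for regions of anomalous IBD coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import mannwhitneyu

__all__ = [
    "IBDBlock",
    "SegmentCall",
    "RateMatrix",
    "SubstructureResult",
    "blocks_frame",
    "postprocess_calls",
    "rate_matrix",
    "sharing_correlation",
    "great_circle_km",
    "distance_decay_fit",
    "substructure_test",
    "genome_scan",
    "mann_whitney_sharing",
]

BLOCK_COLUMNS = ["sample_a", "sample_b", "chromosome", "start_cM", "end_cM"]


@dataclass(frozen=True)
class IBDBlock:
    """A shared segment between two samples, in genetic coordinates (cM)."""

    sample_a: str
    sample_b: str
    chromosome: str
    start: float
    end: float
    score: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("require end > start")
        if self.sample_a == self.sample_b:
            raise ValueError("a block joins two distinct samples")

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentCall(IBDBlock):
    """A raw per-run caller segment with its support score."""

    run_id: int = 0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.score is None or self.score <= 0:
            raise ValueError("segment calls need a positive score")


def blocks_frame(df: pd.DataFrame, require_score: bool = False) -> pd.DataFrame:
    """Validate and normalize a block table (pair order made canonical)."""
    missing = [c for c in BLOCK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"block table missing columns {missing}")
    df = df.copy()
    if np.any(df["end_cM"].to_numpy() <= df["start_cM"].to_numpy()):
        raise ValueError("blocks require end_cM > start_cM")
    a = df["sample_a"].astype(str)
    b = df["sample_b"].astype(str)
    if np.any(a.to_numpy() == b.to_numpy()):
        raise ValueError("blocks require sample_a != sample_b")
    swap = a > b
    df["sample_a"] = a.where(~swap, b)
    df["sample_b"] = b.where(~swap, a)
    if require_score and "score" not in df.columns:
        raise ValueError("score column required")
    return df


def _merge_group(seg: np.ndarray, max_gap: float):
    """Fixpoint merge of sorted [start, end, score] rows; see postprocess_calls."""
    rows = seg[np.argsort(seg[:, 0])].tolist()
    changed = True
    while changed:
        changed = False
        out = [rows[0]]
        for nxt in rows[1:]:
            cur = out[-1]
            gap = nxt[0] - cur[1]
            len_cur = cur[1] - cur[0]
            len_nxt = nxt[1] - nxt[0]
            if gap <= 0 or (gap <= max_gap and gap < max(len_cur, len_nxt)):
                cur[1] = max(cur[1], nxt[1])
                cur[2] = min(cur[2], nxt[2])
                changed = True
            else:
                out.append(nxt)
        rows = out
    return rows


def postprocess_calls(runs: pd.DataFrame, max_gap: float = 5.0,
                      score_cut: float = 1e-9) -> pd.DataFrame:
    """Consolidate multi-run segment calls into IBD blocks.

    Per pair and chromosome: (1) drop segments not overlapping any segment
    from a different run; (2) merge segments separated by a gap shorter than
    at least one of the two and no longer than ``max_gap`` cM, iterated to a
    fixpoint (overlapping segments merge unconditionally); (3) keep only
    merged blocks containing a constituent with score below ``score_cut``.
    The result is idempotent under a rerun with itself duplicated as two runs.
    """
    runs = blocks_frame(runs, require_score=True)
    if "run_id" not in runs.columns:
        raise ValueError("segment calls need a run_id column")
    if runs["run_id"].nunique() < 2:
        raise ValueError("postprocessing requires calls from >= 2 runs")

    out = []
    for (a, b, chrom), g in runs.groupby(["sample_a", "sample_b", "chromosome"],
                                         sort=True):
        s = g["start_cM"].to_numpy(float)
        e = g["end_cM"].to_numpy(float)
        r = g["run_id"].to_numpy()
        sc = g["score"].to_numpy(float)
        # rule 1: overlap with a segment from another run
        ov = (s[:, None] < e[None, :]) & (e[:, None] > s[None, :]) \
            & (r[:, None] != r[None, :])
        keep = ov.any(axis=1)
        if not keep.any():
            continue
        merged = _merge_group(np.column_stack([s[keep], e[keep], sc[keep]]),
                              max_gap)
        for start, end, min_score in merged:
            if min_score < score_cut:
                out.append((a, b, chrom, start, end, min_score))
    return pd.DataFrame(out, columns=BLOCK_COLUMNS + ["score"])


@dataclass(frozen=True)
class RateMatrix:
    """Mean blocks per pair between populations, by length class.

    ``rates`` has shape (n_classes, P, P), symmetric in the population axes;
    within-population entries use n(n-1)/2 pairs and are NaN for singleton
    populations.  ``pair_counts`` holds the distinct-pair denominators.
    """

    populations: tuple[str, ...]
    length_classes: tuple[tuple[float, float], ...]
    rates: np.ndarray
    pair_counts: np.ndarray

    def rate(self, x: str, y: str, class_index: int = 0) -> float:
        i = self.populations.index(x)
        j = self.populations.index(y)
        return float(self.rates[class_index, i, j])


def rate_matrix(blocks: pd.DataFrame, pops: pd.DataFrame,
                min_length: float = 1.0,
                length_classes=None) -> RateMatrix:
    """Mean number of blocks per distinct pair for every population pair.

    ``pops`` maps sample -> population (columns ``sample``, ``population``).
    ``length_classes`` is a list of (lo, hi] cM intervals; by default one
    class [min_length, inf).
    """
    if length_classes is None:
        length_classes = [(min_length, np.inf)]
    pop_of = dict(zip(pops["sample"].astype(str), pops["population"].astype(str)))
    populations = tuple(sorted(set(pop_of.values())))
    pidx = {p: i for i, p in enumerate(populations)}
    sizes = np.zeros(len(populations))
    for s, p in pop_of.items():
        sizes[pidx[p]] += 1

    n_pairs = np.outer(sizes, sizes)
    np.fill_diagonal(n_pairs, sizes * (sizes - 1) / 2.0)

    counts = np.zeros((len(length_classes), len(populations), len(populations)))
    if len(blocks):
        blocks = blocks_frame(blocks)
        unknown = (set(blocks["sample_a"]) | set(blocks["sample_b"])) - set(pop_of)
        if unknown:
            raise ValueError(f"samples without population assignment: "
                             f"{sorted(unknown)[:5]}")
        length = (blocks["end_cM"] - blocks["start_cM"]).to_numpy()
        ia = blocks["sample_a"].map(lambda s: pidx[pop_of[s]]).to_numpy()
        ib = blocks["sample_b"].map(lambda s: pidx[pop_of[s]]).to_numpy()
        for k, (lo, hi) in enumerate(length_classes):
            sel = (length >= lo) & (length < hi)
            np.add.at(counts[k], (ia[sel], ib[sel]), 1.0)
            np.add.at(counts[k], (ib[sel], ia[sel]), 1.0)
            counts[k][np.eye(len(populations), dtype=bool)] /= 2.0

    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(n_pairs > 0, counts / n_pairs, np.nan)
    return RateMatrix(populations, tuple((float(a), float(b))
                                         for a, b in length_classes),
                      rates, n_pairs)


def sharing_correlation(rates: RateMatrix, class_index: int = 0) -> pd.DataFrame:
    """Pearson correlation of sharing profiles I(x, .) and I(y, .) over
    third populations z excluding x and y; diagonal 1 by convention."""
    P = len(rates.populations)
    if P < 4:
        raise ValueError("need >= 4 populations")
    I = rates.rates[class_index]
    out = np.eye(P)
    for i in range(P):
        for j in range(i + 1, P):
            mask = np.ones(P, dtype=bool)
            mask[[i, j]] = False
            a, b = I[i, mask], I[j, mask]
            ok = ~(np.isnan(a) | np.isnan(b))
            a, b = a[ok], b[ok]
            if a.size < 2 or a.std() == 0 or b.std() == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            out[i, j] = out[j, i] = np.corrcoef(a, b)[0, 1]
    return pd.DataFrame(out, index=rates.populations, columns=rates.populations)


_EARTH_RADIUS_KM = 6371.0088


def great_circle_km(lon1, lat1, lon2, lat2) -> float:
    """Haversine great-circle distance in km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    h = (np.sin((lat2 - lat1) / 2.0) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2.0) ** 2)
    return float(2.0 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def distance_decay_fit(rates: RateMatrix, coords: pd.DataFrame, groups,
                       class_index: int = 0) -> pd.DataFrame:
    """Exponential decay of sharing with distance, per pair-class.

    Fits, for each class label, a Poisson GLM of total block counts with
    log link, offset log(pair count) and great-circle distance as the
    covariate — i.e. rate = exp(intercept - decay_per_km * d), weighted by
    sample size through the exposure.  Pairs with zero sharing are included.

    ``coords`` has columns population, lon, lat; ``groups`` is a dict keyed
    by frozenset({pop_x, pop_y}) (or a callable (x, y) -> label); pairs with
    label None are excluded.
    """
    loc = {str(r.population): (float(r.lon), float(r.lat))
           for r in coords.itertuples()}
    if callable(groups):
        label_of = groups
    else:
        label_of = lambda x, y: groups.get(frozenset((x, y)))

    rows = []
    P = len(rates.populations)
    for i in range(P):
        for j in range(i, P):
            x, y = rates.populations[i], rates.populations[j]
            lab = label_of(x, y)
            rate = rates.rates[class_index, i, j]
            n = rates.pair_counts[i, j]
            if lab is None or not np.isfinite(rate) or n <= 0:
                continue
            d = great_circle_km(*loc[x], *loc[y])
            rows.append((lab, d, rate * n, n))
    df = pd.DataFrame(rows, columns=["label", "dist_km", "total", "n_pairs"])

    out = []
    for lab, g in df.groupby("label"):
        if g["dist_km"].nunique() < 3:
            raise ValueError(f"class {lab!r}: need >= 3 distinct distances")
        X = sm.add_constant(g["dist_km"].to_numpy())
        model = sm.GLM(np.round(g["total"].to_numpy()), X,
                       family=sm.families.Poisson(),
                       exposure=g["n_pairs"].to_numpy())
        res = model.fit()
        out.append((lab, float(res.params[0]), float(-res.params[1]),
                    len(g)))
    return pd.DataFrame(out, columns=["label", "intercept",
                                      "decay_per_km", "n_points"]
                        ).set_index("label")


@dataclass(frozen=True)
class SubstructureResult:
    """Permutation test of inhomogeneity of sharing across individuals."""

    pop_x: str
    pop_y: str
    statistic: float  # sd of per-individual block counts
    p_value: float
    z_score: float
    n_blocks: int = 0
    n_perm: int = 0


def substructure_test(blocks: pd.DataFrame, pops: pd.DataFrame,
                      pop_x: str, pop_y: str, n_perm: int = 1000,
                      seed: int | None = None) -> SubstructureResult:
    """Is ancestry shared with ``pop_y`` spread evenly across ``pop_x``?

    The statistic is the standard deviation across the m individuals of
    pop_x of the number of blocks each shares with pop_y.  The null
    reassigns each block end in pop_x to a uniformly random individual
    (k balls in m boxes), ``n_perm`` times; p is the permutation tail
    probability (add-one corrected) and z the normalized statistic.
    """
    pop_of = dict(zip(pops["sample"].astype(str), pops["population"].astype(str)))
    members = sorted(s for s, p in pop_of.items() if p == pop_x)
    m = len(members)
    if m < 2:
        raise ValueError(f"population {pop_x!r} needs >= 2 members")

    counts = dict.fromkeys(members, 0)
    k = 0
    if len(blocks):
        blocks = blocks_frame(blocks)
        for _, row in blocks.iterrows():
            pa = pop_of.get(row["sample_a"])
            pb = pop_of.get(row["sample_b"])
            for s, ps, po in ((row["sample_a"], pa, pb),
                              (row["sample_b"], pb, pa)):
                if ps == pop_x and po == pop_y:
                    counts[s] += 1
                    k += 1
    if k == 0:
        return SubstructureResult(pop_x, pop_y, 0.0, 1.0, 0.0, 0, n_perm)

    obs, p, z = _balls_in_boxes_test(np.array(list(counts.values())),
                                     n_perm, np.random.default_rng(seed))
    return SubstructureResult(pop_x, pop_y, obs, p, z, k, n_perm)


def _balls_in_boxes_test(counts: np.ndarray, n_perm: int,
                         rng: np.random.Generator):
    """Permutation core: sd of box counts vs k balls dropped uniformly into
    m boxes.  Returns (observed sd, add-one permutation p, z-score)."""
    m = counts.size
    k = int(counts.sum())
    obs = float(np.std(counts, ddof=1))
    perm = rng.multinomial(k, np.full(m, 1.0 / m), size=n_perm)
    perm_sd = perm.std(axis=1, ddof=1)
    p = (1.0 + np.sum(perm_sd >= obs)) / (1.0 + n_perm)
    spread = perm_sd.std(ddof=1)
    z = (obs - perm_sd.mean()) / spread if spread > 0 else 0.0
    return obs, float(p), float(z)


def genome_scan(blocks: pd.DataFrame, snp_positions: dict,
                length_cuts=(1.0, 2.5, 4.0, 6.0, 8.0, 10.0),
                window_cM: float = 3.0) -> pd.DataFrame:
    """Per-SNP z-scores of IBD coverage by block-length class.

    For each SNP and length class, counts blocks covering the site; regresses
    coverage on local SNP density (SNPs within a ``window_cM``-wide window,
    i.e. +/- window/2) pooled across chromosomes; and standardizes the
    residuals to mean 0, sd 1.  Chromosomes with < 2 SNPs are skipped.
    """
    cuts = list(length_cuts) + [np.inf]
    classes = list(zip(cuts[:-1], cuts[1:]))
    blocks = blocks_frame(blocks) if len(blocks) else blocks

    frames = []
    for chrom, pos in snp_positions.items():
        pos = np.asarray(pos, dtype=float)
        if pos.size < 2:
            warnings.warn(f"chromosome {chrom!r} has < 2 SNPs; skipped",
                          stacklevel=2)
            continue
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"chromosome {chrom!r}: positions must be sorted")
        half = window_cM / 2.0
        density = (np.searchsorted(pos, pos + half, side="right")
                   - np.searchsorted(pos, pos - half, side="left"))
        cols = {"chromosome": chrom, "pos_cM": pos, "snp_density": density}
        sub = blocks[blocks["chromosome"] == chrom] if len(blocks) else blocks
        for lo, hi in classes:
            if len(sub):
                length = (sub["end_cM"] - sub["start_cM"]).to_numpy()
                sel = (length >= lo) & (length < hi)
                starts = np.sort(sub["start_cM"].to_numpy()[sel])
                ends = np.sort(sub["end_cM"].to_numpy()[sel])
                cov = (np.searchsorted(starts, pos, side="right")
                       - np.searchsorted(ends, pos, side="right"))
            else:
                cov = np.zeros_like(pos)
            cols[f"cov_{lo}_{hi}"] = cov
        frames.append(pd.DataFrame(cols))
    if not frames:
        raise ValueError("no usable chromosomes")
    df = pd.concat(frames, ignore_index=True)

    for lo, hi in classes:
        y = df[f"cov_{lo}_{hi}"].to_numpy(float)
        X = np.column_stack([np.ones(len(df)), df["snp_density"].to_numpy(float)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = resid.std(ddof=1)
        df[f"z_{lo}_{hi}"] = resid / sd if sd > 0 else 0.0
    return df


def mann_whitney_sharing(counts_a, counts_b, alternative: str = "two-sided"):
    """Thin Mann-Whitney U comparison of two per-pair block-count samples."""
    return mannwhitneyu(counts_a, counts_b, alternative=alternative)
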