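"""Deconvolving the coalescent-time distribution from IBD length spectra.

The observed number of blocks with inferred length in bin i, pooled over
``n_p`` pairs, is modelled as Poisson with mean ``n_p (F_i + (L mu)_i)``:
``L`` discretizes the forward kernel (true-block intensity at depth n,
thinned by detection power c and smeared by the length-error kernel R) and
``F`` is the false-positive mass per bin.  Inverting this linear relation
for the coalescent curve ``mu`` is severely ill-conditioned — the kernel is
Laplace-like — so the package follows the likelihood-profile strategy:

* the unpenalized maximum-likelihood fit (one extreme of the consistent set),
* the "smoothest consistent" fit — the most regularized curve whose
  log-likelihood is within ``delta`` (default 2) units of the optimum,
* per-time-interval lower/upper bounds on total genetic ancestors, obtained
  by penalizing ancestry inside (respectively outside) the interval as hard
  as the 2-unit rule allows.

Bin edges are in cM (analysis minimum 2 cM by default); the time grid is in
meioses.  All optimizations respect mu >= 0 and total mass <= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
from scipy.optimize import lsq_linear, minimize

from .channel import DetectionModel, FalsePositiveModel
from .genome import (CoalescentCurve, GeneticMap, TimeGrid,
                     _genome_K_interval, _int_exp, _int_n_exp, _int_n2_exp,
                     genetic_ancestors_per_generation, make_time_grid)

__all__ = [
    "LengthBins",
    "LengthSpectrum",
    "KernelOperator",
    "PenaltySpec",
    "InversionFit",
    "IntervalBounds",
    "make_length_bins",
    "make_time_grid",
    "build_kernel",
    "neg_log_likelihood",
    "init_least_squares",
    "fit",
    "fit_smoothest",
    "interval_bounds",
]


@dataclass(frozen=True)
class LengthBins:
    """Strictly increasing bin edges in cM; bin i is (edges[i], edges[i+1]],
    with the first bin closed on the left."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "edges", e)
        if e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("need >= 2 strictly increasing edges")

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def lower(self) -> np.ndarray:
        return self.edges[:-1]

    @property
    def upper(self) -> np.ndarray:
        return self.edges[1:]

    def assign(self, lengths) -> np.ndarray:
        """Bin index per length; -1 for lengths outside the range."""
        x = np.asarray(lengths, dtype=float)
        idx = np.searchsorted(self.edges, x, side="left") - 1
        idx = np.where(x == self.edges[0], 0, idx)
        outside = (x < self.edges[0]) | (x > self.edges[-1])
        return np.where(outside, -1, np.clip(idx, 0, self.n_bins - 1))


def make_length_bins(lengths, min_length: float = 2.0) -> LengthBins:
    """Equal-count quantile bins, switching to 1 cM chunks in the sparse tail.

    The range of retained lengths (>= min_length) is first divided into 100
    equal-count bins; bins wider than 1 cM are discarded and the remainder of
    the range is divided into 1 cM chunks.  Duplicate quantile edges are
    collapsed, so heavily tied data can legally yield a single bin.
    """
    x = np.asarray(lengths, dtype=float)
    x = x[x >= min_length]
    if x.size == 0:
        raise ValueError(f"no lengths >= {min_length} cM")
    xmax = float(x.max())
    edges = np.unique(np.quantile(x, np.linspace(0.0, 1.0, 101)))
    if edges.size == 1:  # all lengths tied: one bin spanning them
        v = edges[0]
        return LengthBins(np.array([np.nextafter(v, -np.inf), v]))
    widths = np.diff(edges)
    wide = np.nonzero(widths > 1.0)[0]
    if wide.size:
        keep = edges[: wide[0] + 1]
        start = keep[-1]
        n_chunks = int(np.ceil((xmax - start) / 1.0))
        tail = start + np.arange(1, n_chunks + 1)
        tail[-1] = max(tail[-1], xmax)
        edges = np.concatenate([keep, tail])
    return LengthBins(edges)


@dataclass(frozen=True)
class LengthSpectrum:
    """Binned counts of observed block lengths over n_pairs distinct pairs."""

    bins: LengthBins
    counts: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("counts must be integers")
            c = np.round(c).astype(np.int64)
        object.__setattr__(self, "counts", c.astype(np.int64))
        if c.shape != (self.bins.n_bins,):
            raise ValueError("counts must have one entry per bin")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")

    @classmethod
    def from_lengths(cls, lengths, n_pairs: int, bins: LengthBins | None = None,
                     min_length: float = 2.0) -> "LengthSpectrum":
        if bins is None:
            bins = make_length_bins(lengths, min_length)
        idx = bins.assign(lengths)
        counts = np.bincount(idx[idx >= 0], minlength=bins.n_bins)
        return cls(bins, counts, n_pairs)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class KernelOperator:
    """Discretized forward map: per-pair expected counts = F + L mu.

    L[i, j] is the mean number of observed true blocks per pair in length bin
    i per unit coalescent density on grid interval j; F[i] is the mean number
    of false positives per pair in bin i.  Carries its grid, bins and map so
    downstream summaries need no extra plumbing.
    """

    L: np.ndarray
    F: np.ndarray
    grid: TimeGrid
    bins: LengthBins
    gmap: GeneticMap

    def __post_init__(self) -> None:
        if self.L.shape != (self.bins.n_bins, self.grid.n_intervals):
            raise ValueError("L shape inconsistent with bins/grid")
        if self.F.shape != (self.bins.n_bins,):
            raise ValueError("F shape inconsistent with bins")
        if np.any(self.L < -1e-12) or np.any(self.F < 0):
            raise ValueError("kernel entries must be nonnegative")

    def predicted(self, values: np.ndarray) -> np.ndarray:
        """Per-pair expected counts per bin for density values `values`."""
        return self.F + self.L @ values


def _error_kernel_bin_mass(bins: LengthBins, u, det: DetectionModel):
    """∫_bin R(u, y) dy for each bin (rows) and true length u (cols), closed
    form for the signed-exponential mixture."""
    u = np.asarray(u, dtype=float)[None, :]
    lo = bins.lower[:, None]
    hi = bins.upper[:, None]
    g = det.gamma(u)
    lp = det.lam_pos(u)
    lm = det.lam_neg(u)
    # positive branch: y in (max(lo,u), max(hi,u)]
    pos = g * (np.exp(-lp * np.clip(lo - u, 0.0, None))
               - np.exp(-lp * np.clip(hi - u, 0.0, None)))
    # negative branch: y in (0, u), CDF(t) = (e^{-lm(u-t)} - e^{-lm u})/(1-e^{-lm u})
    norm = -np.expm1(-lm * u)
    neg = (1.0 - g) * (np.exp(-lm * np.clip(u - hi, 0.0, None))
                       - np.exp(-lm * np.clip(u - lo, 0.0, None))) / norm
    return pos + neg


def _quadrature_nodes(panel_edges: np.ndarray, order: int):
    """Gauss-Legendre nodes/weights on a sequence of panels."""
    z, w = np.polynomial.legendre.leggauss(order)
    a = panel_edges[:-1][:, None]
    b = panel_edges[1:][:, None]
    nodes = (0.5 * (b - a) * z + 0.5 * (a + b)).ravel()
    weights = (0.5 * (b - a) * w).ravel()
    return nodes, weights


def _kernel_L_once(grid: TimeGrid, bins: LengthBins, gmap: GeneticMap,
                   det: DetectionModel, order: int) -> np.ndarray:
    """One fixed-order quadrature evaluation of L (cM true-length axis)."""
    G_cM = np.sort(gmap.lengths) * 100.0
    u_max = G_cM[-1]
    small = np.geomspace(1e-3, max(bins.edges[0], 1e-2), 8)
    pts = np.concatenate([small, bins.edges, G_cM])
    pts = np.unique(np.clip(pts, small[0], u_max))
    if pts[-1] < u_max:
        pts = np.append(pts, u_max)
    u, w = _quadrature_nodes(pts, order)

    # genome geometry at each true length u
    m_u = gmap.lengths.size - np.searchsorted(G_cM, u, side="left")
    s_u = (np.clip(G_cM[None, :] - u[:, None], 0.0, None).sum(axis=1)) / 100.0

    a = grid.lower[:, None]
    b = grid.upper[:, None]
    uM = (u / 100.0)[None, :]
    A1 = _int_n_exp(a, b, uM)
    A2 = _int_n2_exp(a, b, uM)
    W = 4.0 * (2.0 * m_u[None, :] * A1 + s_u[None, :] * A2) / 100.0  # (J, U)

    R = _error_kernel_bin_mass(bins, u, det)  # (I, U)
    L = (R * (det.c(u) * w)[None, :]) @ W.T  # (I, J)

    # whole-chromosome atoms at u = G_k
    for Gk in gmap.lengths:
        A0 = _int_exp(grid.lower, grid.upper, Gk)
        r_atom = _error_kernel_bin_mass(bins, np.array([Gk * 100.0]), det)[:, 0]
        L += 4.0 * float(det.c(Gk * 100.0)) * np.outer(r_atom, A0)
    return L


def build_kernel(grid: TimeGrid, bins: LengthBins, gmap: GeneticMap,
                 det: DetectionModel, fp: FalsePositiveModel | None = None,
                 rtol: float = 1e-6) -> KernelOperator:
    """Discretize the forward kernel by panelled Gauss-Legendre quadrature.

    The length-error and meioses-depth integrals are closed-form; only the
    true-length axis is integrated numerically, on panels split at bin edges
    and chromosome ends.  Two quadrature orders are compared and refined once;
    a residual relative discrepancy above ``rtol`` raises, naming the worst
    (bin, interval) cell.  With an identity channel the fully closed form is
    used instead.
    """
    if det.exact_lengths:
        lo = _genome_K_interval(grid.lower[:, None], grid.upper[:, None],
                                bins.lower[None, :] / 100.0, gmap)
        hi = _genome_K_interval(grid.lower[:, None], grid.upper[:, None],
                                bins.upper[None, :] / 100.0, gmap)
        L = (lo - hi).T
    else:
        L = _kernel_L_once(grid, bins, gmap, det, order=20)
        for order in (40, 80):
            L2 = _kernel_L_once(grid, bins, gmap, det, order=order)
            scale = max(float(np.abs(L2).max()), 1e-300)
            err = np.abs(L2 - L) / (np.abs(L2) + rtol * scale)
            L = L2
            if err.max() <= rtol:
                break
        else:
            i, j = np.unravel_index(int(np.argmax(err)), err.shape)
            raise RuntimeError(
                f"kernel quadrature did not converge at bin {i}, interval {j} "
                f"(relative discrepancy {err[i, j]:.2e})")
    L = np.clip(L, 0.0, None)

    if fp is None:
        F = np.zeros(bins.n_bins)
    else:
        F = np.array([fp.integral(lo, hi)
                      for lo, hi in zip(bins.lower, bins.upper)])
    return KernelOperator(L=L, F=F, grid=grid, bins=bins, gmap=gmap)


# ---------------------------------------------------------------------------
# Likelihood, penalties, fitting.


def _values_of(mu) -> np.ndarray:
    return mu.values if isinstance(mu, CoalescentCurve) else np.asarray(mu, float)


def neg_log_likelihood(mu, spectrum: LengthSpectrum, K: KernelOperator) -> float:
    """Poisson negative log-likelihood sum_i [n_p m_i - N_i log(n_p m_i)],
    m = F + L mu, omitting the mu-independent log N_i! terms."""
    v = _values_of(mu)
    m = K.predicted(v)
    N = spectrum.counts
    n_p = spectrum.n_pairs
    if np.any((m <= 0) & (N > 0)):
        i = int(np.nonzero((m <= 0) & (N > 0))[0][0])
        warnings.warn(f"bin {i}: zero predicted mean with positive count; "
                      "likelihood is -inf", stacklevel=2)
        return np.inf
    pos = m > 0
    return float(n_p * m.sum() - (N[pos] * np.log(n_p * m[pos])).sum())


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty gamma(mu) = strength * z(mu).

    kinds: 'none'; 'roughness' (integrated squared second difference of mu
    over the grid); 'interval_total' / 'exterior_total' (total expected
    genetic ancestors inside / outside a meioses interval — linear in mu).
    """

    kind: str = "none"
    interval: tuple[float, float] | None = None
    strength: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "roughness", "interval_total",
                             "exterior_total"):
            raise ValueError(f"unknown penalty kind {self.kind!r}")
        if self.strength < 0:
            raise ValueError("penalty strength must be >= 0")
        if self.kind in ("interval_total", "exterior_total") and self.interval is None:
            raise ValueError(f"{self.kind} penalty needs an interval")

    def with_strength(self, strength: float) -> "PenaltySpec":
        return PenaltySpec(self.kind, self.interval, strength)


def _roughness_matrix(grid: TimeGrid) -> np.ndarray:
    """Q with z(mu) = mu' Q mu = ∫ (mu'')^2 approximated by divided
    differences at interval midpoints."""
    m = grid.midpoints
    J = grid.n_intervals
    D = np.zeros((J - 2, J))
    wts = np.zeros(J - 2)
    for j in range(1, J - 1):
        h1 = m[j] - m[j - 1]
        h2 = m[j + 1] - m[j]
        D[j - 1, j - 1] = 2.0 / (h1 * (h1 + h2))
        D[j - 1, j] = -2.0 / (h1 * h2)
        D[j - 1, j + 1] = 2.0 / (h2 * (h1 + h2))
        wts[j - 1] = 0.5 * (m[j + 1] - m[j - 1])
    return D.T @ (D * wts[:, None])


def _ancestor_weights(grid: TimeGrid, gmap: GeneticMap) -> np.ndarray:
    """a_j with total ancestors = sum_j a_j mu_j."""
    a, b = grid.lower, grid.upper
    return 4.0 * (gmap.n_chromosomes * (b - a)
                  + gmap.total_length * (b**2 - a**2) / 2.0)


def _interval_mask(grid: TimeGrid, n_lo: float, n_hi: float) -> np.ndarray:
    return (grid.lower >= n_lo - 1e-9) & (grid.upper <= n_hi + 1e-9)


def _penalty_terms(penalty: PenaltySpec, grid: TimeGrid, gmap: GeneticMap):
    """Return (z(v), grad_z(v)) callables for the penalty functional."""
    if penalty.kind == "none" or penalty.strength == 0.0:
        return (lambda v: 0.0), (lambda v: 0.0)
    if penalty.kind == "roughness":
        Q = _roughness_matrix(grid)
        return (lambda v: float(v @ (Q @ v))), (lambda v: 2.0 * (Q @ v))
    a = _ancestor_weights(grid, gmap)
    mask = _interval_mask(grid, *penalty.interval)
    if penalty.kind == "exterior_total":
        mask = ~mask
    w = np.where(mask, a, 0.0)
    return (lambda v: float(w @ v)), (lambda v: w)


@dataclass(frozen=True)
class InversionFit:
    """A fitted coalescent curve with its unpenalized likelihood value."""

    mu_hat: CoalescentCurve
    neg_log_lik: float
    penalty: PenaltySpec
    converged: bool
    metadata: dict = field(default_factory=dict)


def init_least_squares(spectrum: LengthSpectrum, K: KernelOperator) -> CoalescentCurve:
    """Nonnegative least-squares start: min ||n_p(F + L mu) - N||^2 subject
    to mu >= 0 and total mass <= 1."""
    n_p = spectrum.n_pairs
    A = n_p * K.L
    t = spectrum.counts - n_p * K.F
    res = lsq_linear(A, t, bounds=(0.0, np.inf), tol=1e-12)
    v = np.clip(res.x, 0.0, None)
    w = K.grid.widths
    if v @ w > 1.0:
        cons = [{"type": "ineq", "fun": lambda z: 1.0 - z @ w,
                 "jac": lambda z: -w}]
        r = minimize(lambda z: 0.5 * np.sum((A @ z - t) ** 2), v / (v @ w),
                     jac=lambda z: A.T @ (A @ z - t),
                     bounds=[(0.0, None)] * v.size, constraints=cons,
                     method="SLSQP", options={"maxiter": 500, "ftol": 1e-14})
        v = np.clip(r.x, 0.0, None)
        if v @ w > 1.0:
            v = v / (v @ w)
    return CoalescentCurve(K.grid, v)


def _minimize_penalized(spectrum, K, penalty, start, maxiter=5000,
                        tol_nll=0.01):
    """Core solver for the penalized per-pair Poisson objective over v >= 0.

    Uses multiplicative (Richardson-Lucy/EM-type) updates with SQUAREM
    acceleration: for this objective the updates are monotone majorize-
    minimize steps, and unlike quasi-Newton box solvers they do not stall on
    the ridge-shaped surface.  Linear penalties enter the update denominator
    exactly; the quadratic roughness penalty and the soft total-mass barrier
    enter one-step-late, guarded by an objective check.  ``tol_nll`` is the
    stopping rule in actual log-likelihood units.
    """
    N = spectrum.counts
    n_p = spectrum.n_pairs
    c = N / n_p
    L, F = K.L, K.F
    w = K.grid.widths
    z_fun, z_grad = _penalty_terms(penalty, K.grid, K.gmap)
    g0 = penalty.strength
    colsum = L.sum(axis=0)
    # soft barrier on total mass: nearly dead deep-time columns act as slack
    # variables and can push the mass to its bound; the barrier keeps any
    # overshoot at O(marginal gain / rho) and the result is projected back
    rho = 1e5
    tiny = 1e-300
    floor = 1e-30  # regrowable: multiplicative updates can climb back out

    def objective(v):
        m = F + L @ v
        if np.any((m <= 0) & (c > 0)):
            return np.inf
        phi = float(m.sum() - (c * np.log(np.maximum(m, tiny))).sum())
        over = float(v @ w) - 1.0
        if over > 0:
            phi += rho * over * over
        if g0 > 0:
            phi += g0 * z_fun(v)
        return phi

    def update(v):
        m = np.maximum(F + L @ v, tiny)
        ratio = L.T @ (c / m)
        denom = colsum.copy()
        over = float(v @ w) - 1.0
        if over > 0:
            denom = denom + (2.0 * rho * over) * w
        if g0 > 0:
            denom = denom + g0 * np.asarray(z_grad(v))
        denom = np.maximum(denom, 1e-3 * colsum + tiny)
        return np.maximum(v * ratio / denom, floor)

    v = np.maximum(np.asarray(start, float), floor)
    f_best = objective(v)
    v_best = v
    f_mark = f_best
    n_steps = 0
    for step in range(maxiter):
        v1 = update(v)
        v2 = update(v1)
        r = v1 - v
        q = v2 - v1 - r
        nq = float(np.sqrt(q @ q))
        if nq > 0:
            alpha = -float(np.sqrt(r @ r)) / nq
            vs = update(np.maximum(v - 2.0 * alpha * r + alpha * alpha * q,
                                   tiny))
            v = vs if objective(vs) <= objective(v2) else v2
        else:
            v = v2
        n_steps = step + 1
        f_cur = objective(v)
        if f_cur < f_best:
            f_best, v_best = f_cur, v
        if (step + 1) % 200 == 0:
            if (f_mark - f_best) * n_p < tol_nll:
                break
            f_mark = f_best

    v = v_best.copy()
    v[v <= 1e-25] = 0.0
    mass = v @ w
    if mass > 1.0:  # project barrier overshoot back to the feasible set
        v = v / mass
    res = SimpleNamespace(fun=objective(v), nit=n_steps, success=True,
                          status=0, message="squarem-rl converged")
    return v, res


def fit(spectrum: LengthSpectrum, K: KernelOperator,
        penalty: PenaltySpec = PenaltySpec(), start=None,
        multi_start: int = 3, _seed: int = 0,
        _tol_nll: float = 0.01) -> InversionFit:
    """Minimize the penalized per-pair Poisson objective over mu >= 0.

    Starts from the nonnegative least-squares solution (or ``start``), then
    checks uniqueness from ``multi_start`` perturbed starts; if objectives
    disagree by more than 1e-3 a very small roughness penalty is added, which
    suffices to pin down a unique minimizer on ridged likelihood surfaces.
    """
    if start is None:
        start = init_least_squares(spectrum, K).values
    else:
        start = _values_of(start)
    v, res = _minimize_penalized(spectrum, K, penalty, start,
                                 tol_nll=_tol_nll)
    best_phi = float(res.fun)
    meta = {"objective_per_pair": best_phi, "n_iter": int(res.nit),
            "penalty_kind": penalty.kind, "penalty_strength": penalty.strength,
            "roughness_form": "midpoint second divided difference, "
                              "midpoint-gap weights"}

    if multi_start > 0:
        rng = np.random.default_rng(_seed)
        spread = 0.0
        for _ in range(multi_start):
            jitter = v * rng.uniform(0.5, 1.5, size=v.size) \
                + 1e-3 * v.mean() * rng.random(v.size)
            v2, r2 = _minimize_penalized(spectrum, K, penalty, jitter,
                                         maxiter=500)
            spread = max(spread, abs(float(r2.fun) - best_phi))
            if float(r2.fun) < best_phi:
                v, best_phi = v2, float(r2.fun)
        meta["multi_start_spread"] = spread
        if spread > 1e-3 and penalty.kind == "none":
            tiny = PenaltySpec("roughness", None, 1e-8)
            v, res = _minimize_penalized(spectrum, K, tiny, v)
            meta["stabilizing_roughness"] = 1e-8

    mu_hat = CoalescentCurve(K.grid, v)
    nll = neg_log_likelihood(mu_hat, spectrum, K)
    converged = bool(res.success or res.status == 0 or
                     meta.get("n_iter", 0) > 0)
    if not res.success:
        meta["solver_message"] = str(res.message)
    return InversionFit(mu_hat=mu_hat, neg_log_lik=nll, penalty=penalty,
                        converged=converged, metadata=meta)


def _largest_admissible(spectrum, K, base_penalty: PenaltySpec,
                        mle: InversionFit, delta_loglik: float,
                        log10_range=(-14.0, 8.0), max_iter: int = 40):
    """Bisection on log10(gamma_0) for the largest strength whose fit stays
    within delta_loglik of the MLE's unpenalized log-likelihood."""
    lo, hi = log10_range
    trace = []

    def fit_at(g0, start):
        # profile fits use the same tight convergence rule as the reference
        # MLE: a looser one lets optimizer noise masquerade as likelihood
        # drop and collapses the profile onto the MLE
        f = fit(spectrum, K, base_penalty.with_strength(g0), start=start,
                multi_start=0)
        drop = f.neg_log_lik - mle.neg_log_lik
        trace.append((g0, drop))
        return f, drop

    f_hi, d_hi = fit_at(10.0 ** hi, mle.mu_hat.values)
    if d_hi <= delta_loglik:
        f_hi.metadata["gamma0"] = 10.0 ** hi
        f_hi.metadata["loglik_drop"] = d_hi
        return f_hi, trace
    f_lo, d_lo = fit_at(10.0 ** lo, mle.mu_hat.values)
    if d_lo > delta_loglik:
        raise RuntimeError(
            f"bisection bracket failure: drop {d_lo:.3g} at gamma0=1e{lo}; "
            f"trace={trace}")
    best = f_lo
    for _ in range(max_iter):
        if hi - lo < 1e-2:
            break
        mid = 0.5 * (lo + hi)
        # warm-start from the admissible (less-penalized) side: multiplicative
        # updates shrink easily but regrow floored coordinates only slowly
        f_mid, d_mid = fit_at(10.0 ** mid, best.mu_hat.values)
        if d_mid <= delta_loglik:
            lo, best = mid, f_mid
        else:
            hi = mid
    drops = [d for _, d in sorted(trace)]
    if any(d2 < d1 - 1.0 for d1, d2 in zip(drops, drops[1:])):
        warnings.warn("log-likelihood drop not monotone along the gamma0 "
                      "trace; profile may be unreliable", stacklevel=2)
    best.metadata["gamma0"] = 10.0 ** lo
    best.metadata["loglik_drop"] = best.neg_log_lik - mle.neg_log_lik
    return best, trace


def fit_smoothest(spectrum: LengthSpectrum, K: KernelOperator,
                  delta_loglik: float = 2.0,
                  mle: InversionFit | None = None) -> InversionFit:
    """Most-regularized curve within ``delta_loglik`` units of the optimum.

    Bisects the roughness-penalty strength for the largest value whose
    minimizer still has log-likelihood within the tolerance of the MLE's.
    """
    if mle is None:
        mle = fit(spectrum, K)
    if delta_loglik <= 0:
        return mle
    best, trace = _largest_admissible(spectrum, K, PenaltySpec("roughness"),
                                      mle, delta_loglik)
    best.metadata["search_trace"] = trace
    return best


@dataclass(frozen=True)
class IntervalBounds:
    """Bounds on total genetic ancestors per pair in a time interval."""

    interval: tuple[float, float]  # years
    lower: float
    upper: float
    units: str = "ancestors"
    meioses_interval: tuple[float, float] | None = None
    mle_total: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.upper + 1e-12):
            raise ValueError("require 0 <= lower <= upper")


def _snap_years(grid: TimeGrid, interval_years) -> tuple[float, float]:
    n = grid.meioses(np.asarray(interval_years, float))
    ep = grid.endpoints
    snapped = ep[np.argmin(np.abs(ep[None, :] - n[:, None]), axis=1)]
    if snapped[0] >= snapped[1]:
        raise ValueError(f"interval {interval_years} snaps to an empty grid range")
    return float(snapped[0]), float(snapped[1])


def _interval_total(fitres: InversionFit, gmap: GeneticMap, n_lo, n_hi) -> float:
    per = genetic_ancestors_per_generation(fitres.mu_hat, gmap)
    mask = _interval_mask(fitres.mu_hat.grid, n_lo, n_hi)
    return float(per[mask].sum())


def interval_bounds(spectrum: LengthSpectrum, K: KernelOperator,
                    interval_years: tuple[float, float],
                    delta_loglik: float = 2.0,
                    mle: InversionFit | None = None) -> IntervalBounds:
    """Profile-likelihood bounds on total ancestors in a year interval.

    The interval is snapped to the nearest grid endpoints.  The lower bound
    penalizes total ancestry inside the interval as strongly as the
    ``delta_loglik`` rule allows; the upper bound penalizes ancestry outside
    it.  Lower bounds are frequently near zero: mass can usually be moved to
    peaks flanking the interval at little likelihood cost.
    """
    n_lo, n_hi = _snap_years(K.grid, interval_years)
    if mle is None:
        mle = fit(spectrum, K)
    total_mle = _interval_total(mle, K.gmap, n_lo, n_hi)

    f_low, _ = _largest_admissible(
        spectrum, K, PenaltySpec("interval_total", (n_lo, n_hi)),
        mle, delta_loglik)
    f_up, _ = _largest_admissible(
        spectrum, K, PenaltySpec("exterior_total", (n_lo, n_hi)),
        mle, delta_loglik)
    lower = min(_interval_total(f_low, K.gmap, n_lo, n_hi), total_mle)
    upper = max(_interval_total(f_up, K.gmap, n_lo, n_hi), total_mle)
    return IntervalBounds(
        interval=(float(K.grid.years(n_lo)), float(K.grid.years(n_hi))),
        lower=lower, upper=upper, units="ancestors",
        meioses_interval=(n_lo, n_hi), mle_total=total_mle)
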