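"""Hierarchical Binomial-Poisson mixture model for paired-insertion counts.

For cell ``i`` and region ``j`` the observed count ``x_ij`` is generated as

    Z_ij ~ Bernoulli(pi_j)                       open / closed state
    y_ij | Z_ij ~ Poisson(lambda_c_j * s_j)      if open
                  Poisson(lambda_c_j)            if closed
    x_ij | y_ij ~ Binomial(y_ij, p_i)            per-cell observation thinning

with ``pi_j`` the proportion of open cells, ``lambda_c_j`` the background cut
rate of closed chromatin (GC-dependent in real data), ``s_j >= 1`` the
signal-to-noise ratio of open over closed, and ``p_i`` the cell-specific
observation probability.  Binomial thinning of a Poisson is Poisson, so the
marginal of ``x_ij`` within a component is Poisson(rate * p_i); the truncated
double sum is kept as the reference computation and the closed form as the
fast path.

The module exposes the individual estimators as functions and wraps them in a
:class:`PICMixtureModel` / :class:`PICMixtureResults` pair for the usual
``model.fit() -> results`` workflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountMatrix, ModelParams, SimulationTruth
from .smoothing import GamFit, fit_gam

logger = logging.getLogger(__name__)

_TAIL_MASS = 1e-12


def _effective_trunc(rate: float, trunc: int, kmax: int) -> int:
    """Extend the truncation bound until the Poisson tail mass is < 1e-12."""
    t = max(int(trunc), int(kmax))
    while stats.poisson.sf(t, rate) > _TAIL_MASS and t < 10_000:
        t = int(t * 1.5) + 10
    return t


def marginal_pmf(
    k,
    lambda_c: float,
    s: float,
    p: float,
    open_state: bool = True,
    trunc: int = 50,
    adaptive: bool = True,
) -> np.ndarray:
    """Marginal probability of observing count ``k`` in one component.

    Computes the truncated double sum
    ``sum_{y>=k} Poisson(y; rate) * Binomial(k; y, p)`` with
    ``rate = lambda_c * s`` for the open component and ``lambda_c`` for the
    closed one (i.e. s = 1).  With ``adaptive`` the bound is extended until
    the neglected Poisson tail is below 1e-12; the result then agrees with
    the thinned-Poisson closed form ``Poisson(k; rate * p)`` to truncation
    error.
    """
    k = np.atleast_1d(np.asarray(k))
    if np.any(k < 0) or np.any(k != np.floor(k)):
        raise ValueError("counts must be non-negative integers")
    k = k.astype(int)
    rate = lambda_c * (s if open_state else 1.0)
    t = _effective_trunc(rate, trunc, k.max()) if adaptive else max(trunc, int(k.max()))
    y = np.arange(t + 1)
    pois = stats.poisson.pmf(y, rate)
    # Binomial(k; y, p) is zero for y < k, so the full grid sum equals the sum from y=k
    binom = stats.binom.pmf(k[:, None], y[None, :], p)
    out = binom @ pois
    return out


def thinned_poisson_pmf(k, lambda_c: float, s: float, p: float, open_state: bool = True):
    """Closed-form marginal: Binomial thinning of Poisson is Poisson(rate*p)."""
    rate = lambda_c * (s if open_state else 1.0)
    return stats.poisson.pmf(np.asarray(k), rate * p)


def posterior_open(
    x,
    pi: float,
    lambda_c,
    s,
    p,
    trunc: int = 50,
) -> np.ndarray:
    """Posterior probability that a cell is open given its observed count.

    ``P(Z=1 | x) = pi f_open(x) / (pi f_open(x) + (1 - pi) f_closed(x))``
    where the component marginals are the truncated-sum pmfs above.  ``x``
    and ``p`` may be aligned vectors (per-cell counts and observation
    probabilities); ``lambda_c`` and ``s`` are scalars per region.
    """
    x = np.atleast_1d(np.asarray(x, dtype=int))
    p = np.broadcast_to(np.asarray(p, dtype=float), x.shape)
    lambda_c = float(lambda_c)
    s = float(s)
    if pi == 0.0:
        return np.zeros(x.shape)
    if pi == 1.0:
        return np.ones(x.shape)
    rate_open = lambda_c * s
    t = _effective_trunc(rate_open, trunc, int(x.max()))
    y = np.arange(t + 1)
    pois_open = stats.poisson.pmf(y, rate_open)
    pois_closed = stats.poisson.pmf(y, lambda_c)
    binom = stats.binom.pmf(x[:, None], y[None, :], p[:, None])
    f_open = binom @ pois_open
    f_closed = binom @ pois_closed
    denom = pi * f_open + (1.0 - pi) * f_closed
    with np.errstate(invalid="ignore", divide="ignore"):
        post = np.where(denom > 0, pi * f_open / denom, pi)
    return np.clip(post, 0.0, 1.0)


def simulate(params: ModelParams, n_cells: int, seed: int | None = None) -> SimulationTruth:
    """Draw (Z, y, x) for ``n_cells`` cells from the three-level hierarchy.

    If ``params.p`` is shorter than ``n_cells`` the per-cell observation
    probabilities are sampled from it with replacement.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    p = params.p
    if len(p) == n_cells:
        p_cells = p.copy()
    else:
        p_cells = rng.choice(p, size=n_cells, replace=True)
    r = params.n_regions
    pi = params.pi[:, None]
    lam = params.lambda_c[:, None]
    s = params.s[:, None]
    Z = (rng.random((r, n_cells)) < pi).astype(np.int8)
    rate = lam * np.where(Z == 1, s, 1.0)
    y = rng.poisson(rate)
    x = rng.binomial(y, p_cells[None, :])
    return SimulationTruth(Z=Z, y=y, x=x, params=params, p_cells=p_cells, seed=seed)


def estimate_p(
    m: CountMatrix,
    p_max: float = 0.9,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> np.ndarray:
    """Estimate per-cell observation probabilities by moment matching.

    Under the model, E[x_ij] = q_i * mu_j factorizes over cells and regions.
    Alternate ``q_i <- sum_j x_ij / sum_j mu_j`` and
    ``mu_j <- sum_i x_ij / sum_i q_i`` until the relative change drops below
    ``tol``, then rescale so ``max_i q_i = p_max`` (the factorization only
    identifies q up to scale).
    """
    if m.n_regions < 100:
        raise ValueError("need >= 100 regions to estimate observation probabilities")
    x = m.dense().astype(float)
    cell_tot = x.sum(axis=0)
    region_tot = x.sum(axis=1)
    if np.any(cell_tot == 0):
        raise ValueError("cells with zero total count cannot be calibrated")
    q = cell_tot / cell_tot.max()
    for it in range(max_iter):
        mu = region_tot / q.sum()
        q_new = cell_tot / mu.sum()
        rel = np.max(np.abs(q_new - q) / np.maximum(q, 1e-300))
        q = q_new
        if rel < tol:
            break
    else:
        raise RuntimeError("observation-probability estimation did not converge")
    q = q / q.max() * p_max
    return q


@dataclass
class BackgroundFit:
    """Per-peak background-rate predictions and the GAM behind them."""

    lambda_peaks: np.ndarray
    gam: GamFit
    lambda_bg: np.ndarray
    retained: np.ndarray  # boolean mask over background regions
    n_filtered: int
    frac_filtered: float


def estimate_lambda_bg(
    bg_counts: CountMatrix,
    p_hat: np.ndarray,
    gc_bg: np.ndarray,
    gc_peaks: np.ndarray,
    iqr_multiplier: float = 10.0,
    iqr_mode: str = "absolute",
    floor: float = 1e-6,
) -> BackgroundFit:
    """Estimate per-peak background rates from flank-region counts.

    Flanks are assumed fully closed, so the first moment gives
    ``lambda_c_k = mean_k(x) / mean(p_hat)``.  Rates above the outlier
    threshold (``10 * IQR`` read literally by default, or ``Q3 + 10 * IQR``
    with ``iqr_mode='q3_offset'``) are excluded from the GAM of rate on GC;
    peak rates are the GAM predictions at the peaks' GC, floored at a small
    positive constant because the Gaussian-error fit can dip non-positive.
    """
    gc_bg = np.asarray(gc_bg, dtype=float)
    gc_peaks = np.asarray(gc_peaks, dtype=float)
    if len(gc_bg) != bg_counts.n_regions:
        raise ValueError("background GC vector misaligned with background matrix")
    p_bar = float(np.mean(p_hat))
    lam_bg = bg_counts.dense().mean(axis=1) / p_bar
    q1, q3 = np.percentile(lam_bg, [25, 75])
    iqr = q3 - q1
    if iqr_mode == "absolute":
        threshold = iqr_multiplier * iqr
    elif iqr_mode == "q3_offset":
        threshold = q3 + iqr_multiplier * iqr
    else:
        raise ValueError("iqr_mode must be 'absolute' or 'q3_offset'")
    retained = lam_bg <= threshold
    n_filtered = int((~retained).sum())
    if retained.sum() < 50:
        raise ValueError(
            f"only {int(retained.sum())} background regions retained; need >= 50"
        )
    if n_filtered:
        logger.info(
            "%d background regions (%.1f%%) filtered by the IQR rule",
            n_filtered,
            100 * n_filtered / len(lam_bg),
        )
    gam = fit_gam(gc_bg[retained], lam_bg[retained])
    lam_peaks = np.maximum(gam.predict(gc_peaks), floor)
    return BackgroundFit(
        lambda_peaks=lam_peaks,
        gam=gam,
        lambda_bg=lam_bg,
        retained=retained,
        n_filtered=n_filtered,
        frac_filtered=n_filtered / len(lam_bg),
    )


def _pi_s_for_pool(
    x_pool: np.ndarray,
    p_w: float,
    lambda_c: np.ndarray,
    pi_grid: np.ndarray,
    s_grid: np.ndarray,
    adequacy_factor: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Grid-search (pi, s) per region for one pool of cells.

    The model pmf within the pool is the two-component thinned-Poisson
    mixture at the pool's common observation probability.  The L2 distance
    to the empirical pmf is quadratic in pi for fixed s, so the full grid is
    evaluated in closed form; a local refinement around the grid optimum
    follows.  The empirical support per region is {0, ..., K_r} with
    ``K_r = max observed count + 2``, enforced via cumulative sums.
    """
    n_regions, n_pool = x_pool.shape
    kmax_r = x_pool.max(axis=1) + 2
    kmax = int(kmax_r.max())
    ks = np.arange(kmax + 1)

    # empirical pmf per region
    emp = np.zeros((n_regions, kmax + 1))
    for r in range(n_regions):
        cnt = np.bincount(x_pool[r], minlength=kmax + 1)
        emp[r] = cnt / n_pool

    pi_hat = np.empty(n_regions)
    s_hat = np.empty(n_regions)
    for r in range(n_regions):
        lam = float(lambda_c[r])
        K = int(kmax_r[r])
        e = emp[r, : K + 1]
        k_sub = ks[: K + 1]
        p_closed = stats.poisson.pmf(k_sub, lam * p_w)

        # parsimony: a two-parameter mixture can always chase multinomial
        # sampling noise, so if the closed-only model already explains the
        # empirical pmf to within its expected sampling error we report
        # "no open component" rather than a spurious (pi, s)
        d2_closed = float(np.sum((p_closed - e) ** 2))
        noise_floor = adequacy_factor * float(
            np.sum(p_closed * (1 - p_closed))
        ) / n_pool
        if d2_closed <= noise_floor:
            pi_hat[r], s_hat[r] = 0.0, 1.0
            continue

        def best_on(s_vals: np.ndarray, pi_vals: np.ndarray):
            p_open = stats.poisson.pmf(k_sub[None, :], lam * s_vals[:, None] * p_w)
            a_mat = p_open - p_closed[None, :]  # (n_s, K+1)
            b_min_e = p_closed - e
            aa = np.sum(a_mat**2, axis=1)  # (n_s,)
            ac = a_mat @ b_min_e  # (n_s,)
            dd = float(np.sum(b_min_e**2))
            # distance^2 = pi^2 aa + 2 pi ac + dd
            d2 = (
                pi_vals[:, None] ** 2 * aa[None, :]
                + 2 * pi_vals[:, None] * ac[None, :]
                + dd
            )
            idx = np.unravel_index(np.argmin(d2), d2.shape)
            return pi_vals[idx[0]], s_vals[idx[1]]

        pi0, s0 = best_on(s_grid, pi_grid)
        # local refinement around the coarse optimum
        pi_fine = np.clip(np.linspace(pi0 - 0.01, pi0 + 0.01, 21), 0.0, 1.0)
        ratio = (s_grid[-1] / s_grid[0]) ** (1.0 / (len(s_grid) - 1))
        s_fine = np.clip(
            np.geomspace(s0 / ratio, s0 * ratio, 21), s_grid[0], s_grid[-1]
        )
        pi_hat[r], s_hat[r] = best_on(s_fine, pi_fine)
    return pi_hat, s_hat


def estimate_pi_s(
    m: CountMatrix,
    p_hat: np.ndarray,
    lambda_c: np.ndarray,
    pool_size: int = 100,
    s_max: float = 500.0,
    n_s_grid: int = 60,
    adequacy_factor: float = 5.0,
) -> pd.DataFrame:
    """Estimate per-region open proportions and signal-to-noise ratios.

    With cell-specific p the pair (pi_j, s_j) is unidentifiable from single
    observations, but within a pool of cells of similar p it is.  Cells are
    sorted by ``p_hat`` and chunked into pools of ``pool_size`` (a remainder
    pool smaller than half the pool size is dropped); per pool the pool-mean
    p replaces the individual values, the empirical count pmf is matched to
    the mixture pmf in L2 over a (pi, s) grid with local refinement, and the
    final estimates are the means over pools.  Pools whose empirical pmf the
    closed-only model already explains to within ``adequacy_factor`` times
    the expected multinomial sampling error contribute (0, 1) — without this
    the two free mixture parameters chase pure noise in signal-free regions.

    Returns a DataFrame with columns ``region, pi_hat, s_hat, all_zero``.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    lambda_c = np.broadcast_to(
        np.asarray(lambda_c, dtype=float), (m.n_regions,)
    )
    if m.n_cells < pool_size:
        raise ValueError("need at least one full pool of cells")
    x = m.dense().astype(int)
    order = np.argsort(p_hat, kind="stable")
    pools: list[np.ndarray] = []
    for start in range(0, len(order), pool_size):
        chunk = order[start : start + pool_size]
        if len(chunk) < pool_size and len(chunk) < pool_size / 2:
            break
        pools.append(chunk)

    all_zero = x.sum(axis=1) == 0
    if np.any(all_zero):
        logger.info("%d all-zero region(s): pi=0, s=1 assigned", int(all_zero.sum()))

    pi_grid = np.arange(0.01, 1.00, 0.01)
    s_grid = np.geomspace(1.0, s_max, n_s_grid)
    pi_acc = np.zeros((len(pools), m.n_regions))
    s_acc = np.zeros((len(pools), m.n_regions))
    for w, cells in enumerate(pools):
        p_w = float(np.mean(p_hat[cells]))
        pi_acc[w], s_acc[w] = _pi_s_for_pool(
            x[:, cells], p_w, lambda_c, pi_grid, s_grid,
            adequacy_factor=adequacy_factor,
        )
    pi_hat = pi_acc.mean(axis=0)
    s_hat = s_acc.mean(axis=0)
    pi_hat[all_zero] = 0.0
    s_hat[all_zero] = 1.0
    return pd.DataFrame(
        {
            "region": m.region_ids,
            "pi_hat": pi_hat,
            "s_hat": s_hat,
            "all_zero": all_zero,
        }
    )


def auroc(truth, score) -> float:
    """Rank-based AUROC with tie correction (average ranks).

    ``truth`` is the binary state vector, ``score`` the predictor (here the
    posterior open probability).  Raises if only one class is present.
    """
    truth = np.asarray(truth).astype(bool).ravel()
    score = np.asarray(score, dtype=float).ravel()
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined with a single class")
    ranks = stats.rankdata(score)
    return float((ranks[truth].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def simulation_grid(
    lambda_list,
    s_list,
    pi: float = 0.3,
    n_cells: int = 10_000,
    reps: int = 30,
    p_source=None,
    seed: int = 0,
    trunc: int = 50,
) -> pd.DataFrame:
    """Mean AUROC and mean count over a (lambda_c, s) simulation grid.

    For each grid point and repetition: simulate one region for ``n_cells``
    cells, compute the posterior with the *true* generating parameters, and
    score it against the simulated states.  ``p_source`` is a vector of
    observation probabilities sampled with replacement per cell (default:
    constant 0.5).  Repetition seeds derive from ``seed``; single-class
    draws (no open or no closed cells) are skipped.
    """
    if p_source is None:
        p_source = np.array([0.5])
    p_source = np.asarray(p_source, dtype=float)
    rows = []
    for gi, lam in enumerate(lambda_list):
        for si, s in enumerate(s_list):
            params = ModelParams(
                p=p_source, pi=np.array([pi]), lambda_c=np.array([lam]), s=np.array([s])
            )
            aucs, counts = [], []
            for rep in range(reps):
                rng_seed = np.random.SeedSequence([seed, gi, si, rep])
                truth = simulate(params, n_cells, seed=rng_seed)
                xr = truth.x[0]
                post = posterior_open(
                    xr, pi, lam, s, truth.p_cells, trunc=trunc
                )
                counts.append(xr.mean())
                try:
                    aucs.append(auroc(truth.Z[0], post))
                except ValueError:
                    continue
            rows.append(
                {
                    "lambda_c": lam,
                    "s": s,
                    "pi": pi,
                    "mean_auroc": float(np.mean(aucs)) if aucs else np.nan,
                    "sd_auroc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else np.nan,
                    "mean_count": float(np.mean(counts)),
                    "n_reps": len(aucs),
                }
            )
    return pd.DataFrame(rows)


class PICMixtureModel:
    """Hierarchical mixture model bound to a peak count matrix.

    Parameters
    ----------
    counts
        Region x cell paired-insertion count matrix over peaks.
    background, background_gc
        Optional flank-region count matrix and its GC fractions, used to
        estimate the GC-dependent background rate.
    region_gc
        GC fraction per peak (required when ``background`` is given).
    lambda_c
        Known/fixed background rates per peak; alternative to fitting them
        from a background matrix.
    """

    def __init__(
        self,
        counts: CountMatrix,
        background: CountMatrix | None = None,
        background_gc: np.ndarray | None = None,
        region_gc: np.ndarray | None = None,
        lambda_c: np.ndarray | None = None,
    ):
        self.counts = counts
        self.background = background
        self.background_gc = background_gc
        self.region_gc = region_gc if region_gc is not None else counts.region_gc
        self.fixed_lambda_c = lambda_c
        if background is not None and (
            background_gc is None or self.region_gc is None
        ):
            raise ValueError("background fitting needs background_gc and region_gc")
        if background is None and lambda_c is None:
            raise ValueError("provide either a background matrix or lambda_c")

    def fit(
        self,
        p_max: float = 0.9,
        pool_size: int = 100,
        iqr_multiplier: float = 10.0,
        iqr_mode: str = "absolute",
    ) -> "PICMixtureResults":
        p_hat = estimate_p(self.counts, p_max=p_max)
        if self.background is not None:
            bg_fit = estimate_lambda_bg(
                self.background,
                p_hat,
                self.background_gc,
                self.region_gc,
                iqr_multiplier=iqr_multiplier,
                iqr_mode=iqr_mode,
            )
            lam = bg_fit.lambda_peaks
        else:
            bg_fit = None
            lam = np.broadcast_to(
                np.asarray(self.fixed_lambda_c, dtype=float), (self.counts.n_regions,)
            ).copy()
        pis = estimate_pi_s(self.counts, p_hat, lam, pool_size=pool_size)
        params = ModelParams(
            p=p_hat,
            pi=pis["pi_hat"].to_numpy(),
            lambda_c=lam,
            s=pis["s_hat"].to_numpy(),
        )
        return PICMixtureResults(self, params, bg_fit, pis["all_zero"].to_numpy())


class PICMixtureResults:
    """Fitted parameters, posterior computation, and a summary table."""

    def __init__(
        self,
        model: PICMixtureModel,
        params: ModelParams,
        background_fit: BackgroundFit | None,
        all_zero: np.ndarray,
    ):
        self.model = model
        self.params = params
        self.background_fit = background_fit
        self.all_zero = all_zero

    def posterior(self, trunc: int = 50) -> np.ndarray:
        """Region x cell matrix of posterior open probabilities."""
        x = self.model.counts.dense().astype(int)
        out = np.empty(x.shape)
        for j in range(x.shape[0]):
            out[j] = posterior_open(
                x[j],
                float(self.params.pi[j]),
                float(self.params.lambda_c[j]),
                float(self.params.s[j]),
                self.params.p,
                trunc=trunc,
            )
        return out

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.model.counts.region_ids,
                "pi_hat": self.params.pi,
                "s_hat": self.params.s,
                "lambda_c_hat": self.params.lambda_c,
                "all_zero": self.all_zero,
            }
        )

    def simulate(self, n_cells: int, seed: int | None = None) -> SimulationTruth:
        return simulate(self.params, n_cells, seed=seed)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Hierarchical PIC mixture model",
            "=" * 46,
            f"cells:   {len(p.p):>8d}   regions: {p.n_regions:>8d}",
            f"p    mean {np.mean(p.p):8.4f}   range [{p.p.min():.4f}, {p.p.max():.4f}]",
            f"pi   mean {np.mean(p.pi):8.4f}   range [{p.pi.min():.4f}, {p.pi.max():.4f}]",
            f"s    mean {np.mean(p.s):8.2f}   range [{p.s.min():.2f}, {p.s.max():.2f}]",
            f"lam  mean {np.mean(p.lambda_c):8.5f}   range "
            f"[{p.lambda_c.min():.5f}, {p.lambda_c.max():.5f}]",
            f"all-zero regions: {int(self.all_zero.sum())}",
        ]
        if self.background_fit is not None:
            bf = self.background_fit
            lines.append(
                f"background regions filtered: {bf.n_filtered} "
                f"({100 * bf.frac_filtered:.1f}%)"
            )
        return "\n".join(lines)
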