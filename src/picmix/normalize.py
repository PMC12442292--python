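"""Depth normalization transforms and their diagnostics.

Implements the TF-IDF family used across the single-cell ATAC ecosystem
(Signac, ArchR/scOpen, Cusanovich, Hill, Cell Ranger ATAC flavors), the
depth/variance diagnostics that expose why TF-IDF is not a depth
normalization, LSI, GC-bias curves, full-quantile and GC-stratified quantile
normalization, and the mock-null differential test used to measure residual
GC bias in log-fold changes.

Notation: for a regions x cells count matrix with entries ``x[j, i]``,

* ``TF[j, i] = x[j, i] / sum_j' x[j', i]`` — each cell's counts as proportions;
* ``CPTT = TF * 1e4`` — counts per ten thousand;
* ``IDF[j] = N / sum_i x[j, i] = 1 / mu_j`` — inverse of the region mean.

All logs in the TF-IDF flavors are natural logs; log-fold changes use log2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from .datatypes import CountMatrix, Embedding, NormalizedMatrix
from .smoothing import GamFit, fit_gam, lowess_curve

logger = logging.getLogger(__name__)

# Table of flavors: (formula tag, binarize by default)
TFIDF_FLAVORS: dict[str, bool] = {
    "signac": False,
    "archr": True,
    "cusanovich": True,
    "hill": True,
    "cellranger": False,
}


def _dense(m: CountMatrix) -> np.ndarray:
    return m.dense().astype(float)


def term_frequency(m: CountMatrix) -> NormalizedMatrix:
    """Per-cell proportions: each cell's column sums to 1.

    Raises on cells with zero total count (their proportions are undefined),
    listing the offending barcodes.
    """
    x = _dense(m)
    totals = x.sum(axis=0)
    zero = totals == 0
    if np.any(zero):
        bad = [m.cell_barcodes[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"cells with zero total count: {bad}")
    return NormalizedMatrix(
        x / totals, list(m.region_ids), list(m.cell_barcodes), flavor="tf"
    )


def cptt(m: CountMatrix) -> NormalizedMatrix:
    """Counts per ten thousand: TF scaled by 1e4."""
    tf = term_frequency(m)
    return NormalizedMatrix(
        tf.values * 1e4, tf.region_ids, tf.cell_barcodes, flavor="cptt"
    )


def idf(m: CountMatrix) -> pd.Series:
    """Per-region inverse document frequency, ``N / region_total = 1 / mu_j``.

    Regions with zero total count get NaN (flagged, not an error); downstream
    transforms exclude them.
    """
    totals = m.region_totals().astype(float)
    n = m.n_cells
    with np.errstate(divide="ignore"):
        w = np.where(totals > 0, n / totals, np.nan)
    if np.any(totals == 0):
        logger.info(
            "%d region(s) with zero total excluded from IDF", int((totals == 0).sum())
        )
    return pd.Series(w, index=m.region_ids, name="idf")


def tfidf_transform(
    m: CountMatrix, flavor: str = "signac", binarize: bool | None = None
) -> NormalizedMatrix:
    """Apply one of the ecosystem's TF-IDF flavors.

    =========== ================================== =================
    flavor      formula (natural log)              binarize default
    =========== ================================== =================
    signac      log(TF * 1e4 * IDF + 1)            no
    archr       TF * log(IDF + 1)                  yes
    cusanovich  TF * log(IDF + 1)                  yes
    hill        log(TF * 1e5 + 1) * log(IDF)       yes
    cellranger  log(IDF)                           no
    =========== ================================== =================

    ``binarize=True`` replaces counts by 1{x > 0} before computing TF and
    IDF.  Zero-total regions are excluded (rows set to 0 and recorded in the
    log) since their IDF is undefined.
    """
    if flavor not in TFIDF_FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r}; choose from {sorted(TFIDF_FLAVORS)}")
    if binarize is None:
        binarize = TFIDF_FLAVORS[flavor]

    x = _dense(m)
    if binarize:
        x = (x > 0).astype(float)
    work = CountMatrix(x.astype(int), m.region_ids, m.cell_barcodes)
    tf = term_frequency(work).values
    w = idf(work).to_numpy()
    dead = ~np.isfinite(w)
    w = np.where(dead, 0.0, w)

    if flavor == "signac":
        out = np.log(tf * 1e4 * w[:, None] + 1.0)
    elif flavor in ("archr", "cusanovich"):
        out = tf * np.log(w[:, None] + 1.0)
    elif flavor == "hill":
        with np.errstate(divide="ignore"):
            logw = np.where(dead, 0.0, np.log(np.where(w > 0, w, 1.0)))
        out = np.log(tf * 1e5 + 1.0) * logw[:, None]
    else:  # cellranger: a per-region constant, no TF term
        with np.errstate(divide="ignore"):
            logw = np.where(dead, 0.0, np.log(np.where(w > 0, w, 1.0)))
        out = np.broadcast_to(logw[:, None], x.shape).copy()
    out[dead, :] = 0.0
    return NormalizedMatrix(
        out, list(m.region_ids), list(m.cell_barcodes), flavor=flavor, binarized=binarize
    )


def depth_diagnostics(m: CountMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell and per-region diagnostic tables.

    The per-cell table holds each cell's total count and the mean of its
    non-zero entries (0, flagged, when the cell is empty) — in sparse ATAC
    data the non-zero mean stays near 1 while totals vary by orders of
    magnitude, i.e. depth lives almost entirely in the zero pattern.  The
    per-region table holds mean, raw variance and variance after IDF scaling
    (= raw variance / mu_j^2, so IDF *amplifies* the mean-variance trend).
    """
    x = _dense(m)
    totals = x.sum(axis=0)
    nz_counts = (x > 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        nz_mean = np.where(nz_counts > 0, totals / np.maximum(nz_counts, 1), 0.0)
    cell_table = pd.DataFrame(
        {
            "barcode": m.cell_barcodes,
            "total": totals,
            "nonzero_mean": nz_mean,
            "all_zero": nz_counts == 0,
        }
    )

    mu = x.mean(axis=1)
    var_raw = x.var(axis=1, ddof=1) if m.n_cells > 1 else np.zeros(m.n_regions)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_idf = np.where(mu > 0, var_raw / mu**2, np.nan)
    region_table = pd.DataFrame(
        {
            "region": m.region_ids,
            "mean": mu,
            "var_raw": var_raw,
            "var_idf": var_idf,
        }
    )
    return cell_table, region_table


def lsi(
    m: CountMatrix,
    flavor: str = "signac",
    n_components: int = 30,
    drop_first: bool = False,
    binarize: bool | None = None,
) -> Embedding:
    """Latent semantic indexing: TF-IDF followed by truncated SVD.

    Cell coordinates are the right singular vectors scaled by their singular
    values; components are ordered by decreasing singular value.
    ``drop_first`` removes the first component (the usual ad-hoc fix for its
    depth correlation).  Rank-deficient input yields fewer components
    (logged).
    """
    norm = tfidf_transform(m, flavor=flavor, binarize=binarize)
    a = norm.values  # regions x cells
    if n_components >= min(a.shape):
        raise ValueError("n_components must be < min(matrix dims)")
    u, svals, vt = np.linalg.svd(a, full_matrices=False)
    tol = max(a.shape) * np.finfo(float).eps * (svals[0] if svals.size else 0.0)
    rank = int((svals > tol).sum())
    k = min(n_components, rank)
    if k < n_components:
        logger.info("rank-deficient matrix: returning %d of %d components", k, n_components)
    # sign convention: largest-magnitude loading of each component positive
    for c in range(k):
        j = np.argmax(np.abs(u[:, c]))
        if u[j, c] < 0:
            u[:, c] = -u[:, c]
            vt[c, :] = -vt[c, :]
    coords = (vt[:k, :].T) * svals[:k]
    var_frac = svals[:k] ** 2 / np.sum(svals**2)
    if drop_first and k > 1:
        coords = coords[:, 1:]
        var_frac = var_frac[1:]
        method = f"LSI-drop1[{flavor}]"
    else:
        method = f"LSI[{flavor}]"
    return Embedding(coords, var_frac, list(m.cell_barcodes), method)


def gc_bias_curve(
    m: CountMatrix,
    gc: np.ndarray,
    groups: pd.Series | list | None = None,
    frac: float = 2.0 / 3.0,
) -> dict[str, pd.DataFrame]:
    """Smoothed curves of mean log(count + 1) against region GC content.

    For each cell group (all cells if ``groups`` is None) the per-region mean
    over that group's cells of log(count + 1) is regressed on GC with a
    lowess smoother.  Returns one (gc_grid, fitted) table per group.
    """
    gc = np.asarray(gc, dtype=float)
    if len(gc) != m.n_regions or np.any(~np.isfinite(gc)):
        raise ValueError("gc must be present (finite) for all regions")
    if m.n_regions < 10:
        raise ValueError("need at least 10 regions for a GC bias curve")
    x = _dense(m)
    if groups is None:
        groups = pd.Series(["all"] * m.n_cells)
    else:
        groups = pd.Series(list(groups))
    curves: dict[str, pd.DataFrame] = {}
    for g in groups.unique():
        cols = np.flatnonzero((groups == g).to_numpy())
        mean_log = np.log1p(x[:, cols]).mean(axis=1)
        grid, fitted = lowess_curve(gc, mean_log, frac=frac)
        curves[str(g)] = pd.DataFrame({"gc": grid, "fitted": fitted})
    return curves


def _average_ties(raw: np.ndarray, out: np.ndarray) -> np.ndarray:
    """Give tied input values within each column their averaged output.

    Crucial for sparse counts: a cell's zeros are indistinguishable, so they
    must all receive the same normalized value (the mean of the reference
    quantiles their rank range spans) rather than arbitrary position-ordered
    reference values.
    """
    res = out.copy()
    for c in range(raw.shape[1]):
        col = raw[:, c]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        starts = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        sums = np.add.reduceat(out[order, c], starts)
        lens = np.diff(np.r_[starts, len(col)])
        res[order, c] = np.repeat(sums / lens, lens)
    return res


def full_quantile_normalize(values: np.ndarray, ties: str = "positional") -> np.ndarray:
    """Full-quantile normalization of a features x samples matrix.

    Sort each column, replace each rank by the median across columns at that
    rank, and unsort.  Within-column rank order is preserved.  With
    ``ties='positional'`` (default) reference values are assigned through a
    tie by original row position, so all columns share exactly the same
    sorted value multiset afterwards; ``ties='average'`` instead gives tied
    values the mean of the reference values over their rank range (tied
    entries — e.g. a sparse cell's zeros — then share one output value).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 columns")
    if ties not in ("average", "positional"):
        raise ValueError("ties must be 'average' or 'positional'")
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = np.median(sorted_vals, axis=1)
    out = np.empty_like(values)
    np.put_along_axis(out, order, reference[:, None], axis=0)
    if ties == "average":
        out = _average_ties(values, out)
    return out


def smooth_gcfq(
    values: np.ndarray,
    gc: np.ndarray,
    n_bins: int = 10,
    ties: str = "positional",
    groups=None,
    weight_window: float = 0.05,
) -> np.ndarray:
    """GC-stratified full-quantile normalization with smoothing.

    Features are stratified into ``n_bins`` equal-frequency GC bins and
    full-quantile normalized within each bin.  Two smoothing mechanisms are
    applied:

    * bin-boundary blending — each feature's normalized value is a weighted
      blend of its own bin's reference quantile function and the nearest
      neighboring bin's, weighted by the distance of the feature's GC to the
      two bin midpoints (with a single bin this reduces exactly to plain
      full-quantile normalization);
    * optional group-aware shrinkage — when ``groups`` assigns samples to
      replicate groups (e.g. donors), each rank's normalized value is a
      compromise ``w * reference + (1 - w) * group reference`` with the
      weight estimated from the between-group share of the quantile variance
      (rolling-median smoothed over ranks).  Ranks whose quantiles differ
      systematically between groups keep their group's quantiles instead of
      being forced to the common reference, so group-level structure —
      including group-level technical bias — survives normalization.  This
      is the behavior that makes the method safe for bulk-like designs but
      leaves replicate-level GC bias in place when samples are single cells.
    """
    values = np.asarray(values, dtype=float)
    gc = np.asarray(gc, dtype=float)
    n_feat, n_samp = values.shape
    if len(gc) != n_feat:
        raise ValueError("gc length must match feature count")
    n_bins = min(n_bins, n_feat)
    group_arr = None
    group_ids: list = []
    if groups is not None:
        group_arr = np.asarray(list(groups))
        if len(group_arr) != n_samp:
            raise ValueError("groups length must match sample count")
        group_ids = list(pd.unique(group_arr))

    gc_order = np.argsort(gc, kind="stable")
    # keep members in original row order inside each bin so ties break by
    # position, exactly as in plain full-quantile normalization
    bin_members = [np.sort(idx) for idx in np.array_split(gc_order, n_bins)]
    bin_mid = np.array([np.median(gc[idx]) for idx in bin_members])

    # per-bin reference quantile functions (value at quantile u in [0,1])
    refs: list[tuple[np.ndarray, np.ndarray]] = []
    for idx in bin_members:
        sub = values[idx, :]
        if len(idx) < 2:
            logger.info("GC bin with <2 features: using global reference")
            sub = values
        sorted_sub = np.sort(sub, axis=0)
        ref = np.median(sorted_sub, axis=1)
        u = (np.arange(len(ref)) + 0.5) / len(ref)
        refs.append((u, ref))

    out = np.empty_like(values)
    for b, idx in enumerate(bin_members):
        nb_ = len(idx)
        if nb_ == 0:
            continue
        sub = values[idx, :]
        order = np.argsort(sub, axis=0, kind="stable")
        ranks = np.empty_like(order)
        np.put_along_axis(ranks, order, np.arange(nb_)[:, None], axis=0)
        u = (ranks + 0.5) / nb_  # per-feature per-sample quantile
        u_own, ref_own = refs[b]
        val_own = np.interp(u, u_own, ref_own)
        if n_bins == 1:
            target = val_own
        else:
            gcs = gc[idx]
            # neighbor bin on the side of the feature's gc vs the midpoint
            nb_idx = np.where(gcs >= bin_mid[b], min(b + 1, n_bins - 1), max(b - 1, 0))
            target = np.empty_like(val_own)
            for nb2 in np.unique(nb_idx):
                sel = nb_idx == nb2
                u_nb, ref_nb = refs[nb2]
                val_nb = np.interp(u[sel, :], u_nb, ref_nb)
                if nb2 == b:
                    target[sel, :] = val_own[sel, :]
                    continue
                d_own = np.abs(gcs[sel] - bin_mid[b])
                d_nb = np.abs(gcs[sel] - bin_mid[nb2])
                wb = d_nb / np.maximum(d_own + d_nb, 1e-300)  # weight on own bin
                target[sel, :] = wb[:, None] * val_own[sel, :] + (1 - wb[:, None]) * val_nb

        if group_arr is not None and len(group_ids) > 1:
            target = _group_shrink(
                sub, order, target, group_arr, group_ids, weight_window
            )
        out[idx, :] = _average_ties(sub, target) if ties == "average" else target
    return out


def _group_shrink(
    sub: np.ndarray,
    order: np.ndarray,
    target: np.ndarray,
    group_arr: np.ndarray,
    group_ids: list,
    weight_window: float,
) -> np.ndarray:
    """Shrink per-rank normalized values toward group-specific quantiles.

    For each rank the weight on the common reference is the within-group
    share of the quantile variance (1 - SSB/SST from the one-way ANOVA
    decomposition of sorted values across samples), median-smoothed over a
    rolling rank window.  Ranks where groups genuinely differ get weight
    near 0 and keep their group's quantiles.
    """
    nb_, n_samp = sub.shape
    sorted_sub = np.take_along_axis(sub, order, axis=0)
    qbar = sorted_sub.mean(axis=1)
    ssb = np.zeros(nb_)
    ghat = {}
    for g in group_ids:
        cols = np.flatnonzero(group_arr == g)
        gmean = sorted_sub[:, cols].mean(axis=1)
        ghat[g] = np.median(sorted_sub[:, cols], axis=1)
        ssb += len(cols) * (gmean - qbar) ** 2
    sst = np.sum((sorted_sub - qbar[:, None]) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(sst > 0, 1.0 - ssb / sst, 1.0)
    w = np.clip(w, 0.0, 1.0)
    window = max(3, int(round(weight_window * nb_)) | 1)
    w = pd.Series(w).rolling(window, center=True, min_periods=1).median().to_numpy()

    target_sorted = np.take_along_axis(target, order, axis=0)
    result_sorted = np.empty_like(target_sorted)
    for g in group_ids:
        cols = np.flatnonzero(group_arr == g)
        result_sorted[:, cols] = (
            w[:, None] * target_sorted[:, cols]
            + (1 - w[:, None]) * ghat[g][:, None]
        )
    out = np.empty_like(target)
    np.put_along_axis(out, order, result_sorted, axis=0)
    return out


@dataclass
class MockNullResult:
    """Mock-null comparison for one cell type: per-region table + GAM fit."""

    table: pd.DataFrame  # region, lfc, wilcoxon_p, gc, gc_bin
    gam: GamFit
    control_donors: list[str]
    treatment_donors: list[str]
    n_cells: tuple[int, int]


def mock_null_test(
    m: CountMatrix,
    donors: pd.Series | list,
    cell_types: pd.Series | list,
    gc: np.ndarray,
    seed: int,
    n_bins: int = 10,
    epsilon: float | None = None,
) -> dict[str, MockNullResult]:
    """Mock-null differential comparison between randomly split donor groups.

    Within each cell type, donors are randomly partitioned (seeded) into a
    mock control group of ``floor(D/2)`` donors and a mock treatment group of
    ``ceil(D/2)``.  Per region: log2 fold change of group pseudobulk means
    (with pseudocount 0.5 / group cell count unless ``epsilon`` is given) and
    a two-group Wilcoxon rank-sum p-value on cell-level counts.  Regions are
    assigned to ``n_bins`` equal-frequency GC bins and a GAM of LFC on GC is
    fitted.  With no true signal the fit should be flat at zero; any
    systematic trend is residual GC bias.

    Cell types represented by a single donor are skipped (logged).
    """
    donors = pd.Series(list(donors))
    cell_types = pd.Series(list(cell_types))
    gc = np.asarray(gc, dtype=float)
    x = _dense(m)
    rng = np.random.default_rng(seed)
    results: dict[str, MockNullResult] = {}
    for ct in cell_types.unique():
        cells = np.flatnonzero((cell_types == ct).to_numpy())
        ct_donors = sorted(donors.iloc[cells].unique())
        if len(ct_donors) < 2:
            logger.info("cell type %s has a single donor; skipped", ct)
            continue
        perm = rng.permutation(len(ct_donors))
        half = len(ct_donors) // 2
        ctrl_d = [ct_donors[i] for i in perm[:half]]
        treat_d = [ct_donors[i] for i in perm[half:]]
        ctrl = cells[donors.iloc[cells].isin(ctrl_d).to_numpy()]
        treat = cells[donors.iloc[cells].isin(treat_d).to_numpy()]

        eps_c = epsilon if epsilon is not None else 0.5 / len(ctrl)
        eps_t = epsilon if epsilon is not None else 0.5 / len(treat)
        mean_c = x[:, ctrl].mean(axis=1)
        mean_t = x[:, treat].mean(axis=1)
        lfc = np.log2((mean_t + eps_t) / (mean_c + eps_c))

        stat_res = mannwhitneyu(
            x[:, treat], x[:, ctrl], axis=1, alternative="two-sided"
        )
        pvals = np.asarray(stat_res.pvalue)

        gc_bin = pd.qcut(gc, q=n_bins, labels=False, duplicates="drop")
        gam = fit_gam(gc, lfc)
        table = pd.DataFrame(
            {
                "region": m.region_ids,
                "lfc": lfc,
                "wilcoxon_p": pvals,
                "gc": gc,
                "gc_bin": gc_bin,
            }
        )
        results[str(ct)] = MockNullResult(
            table=table,
            gam=gam,
            control_donors=ctrl_d,
            treatment_donors=treat_d,
            n_cells=(len(ctrl), len(treat)),
        )
    return results
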