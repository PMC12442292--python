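"""Gene-level aggregation, posterior PCA, and embedding evaluation.

Peak counts are summed by nearest gene (TSS to peak midpoint), the mixture
model is fitted to the aggregated gene x cell matrix, and the posterior open
probabilities are decomposed with PCA.  Because the posterior conditions on
each cell's observation probability, sequencing depth should not dominate the
leading components — in contrast to LSI, whose first component typically
tracks library size.  The comparison is quantified by per-component depth
correlations and per-cell-type silhouette widths.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .datatypes import CountMatrix, Embedding, GeneMap, Region

logger = logging.getLogger(__name__)


def qc_filter_cells(
    atac_totals: pd.Series,
    rna_totals: pd.Series,
    max_atac: float = 100_000,
    max_rna: float = 25_000,
    min_rna: float = 1_000,
) -> list[str]:
    """Barcodes passing multiome QC.

    A cell is removed when ANY of: total ATAC count >= ``max_atac``, total
    RNA count >= ``max_rna``, total RNA count <= ``min_rna`` (both extremes
    of RNA depth are excluded).
    """
    atac_totals, rna_totals = atac_totals.align(rna_totals, join="inner")
    keep = ~(
        (atac_totals >= max_atac) | (rna_totals >= max_rna) | (rna_totals <= min_rna)
    )
    return list(atac_totals.index[keep])


def nearest_gene(peaks: list[Region], genes: list[Region]) -> GeneMap:
    """Assign each peak to the gene whose TSS is closest to the peak midpoint.

    Ties are broken by the lower gene coordinate, then lexicographic gene id.
    Peaks on chromosomes without genes are flagged unassigned.
    """
    by_chrom: dict[str, list[Region]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: (g.tss, g.start, g.id))

    rows = []
    unassigned = []
    for p in peaks:
        cands = by_chrom.get(p.chrom)
        if not cands:
            unassigned.append(p.id)
            continue
        mid = p.midpoint
        best = min(
            cands, key=lambda g: (abs(g.tss - mid), g.start, g.id)
        )
        rows.append(
            {
                "peak_id": p.id,
                "gene_id": best.id,
                "distance": int(round(mid - best.tss)),
            }
        )
    if unassigned:
        logger.info("%d peak(s) on chromosomes without genes left unassigned", len(unassigned))
    return GeneMap(
        assignments=pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance"]),
        unassigned=unassigned,
    )


def aggregate_by_gene(m: CountMatrix, gene_map: GeneMap) -> CountMatrix:
    """Sum peak counts by assigned gene, yielding a gene x cell matrix.

    Unassigned peaks are dropped; column sums are conserved up to them.
    Genes appear in sorted id order; genes with no peaks are absent.
    """
    df = m.to_frame()
    gene_of = gene_map.gene_of()
    assigned = [r for r in m.region_ids if r in gene_of]
    grouped = df.loc[assigned].groupby([gene_of[r] for r in assigned]).sum()
    grouped = grouped.sort_index()
    gc = None
    if m.region_gc is not None:
        gc_s = pd.Series(m.region_gc, index=m.region_ids)
        totals = df.sum(axis=1)
        # gene GC = count-weighted mean of member-peak GC (uniform if all zero)
        rows = []
        genes = pd.Series([gene_of[r] for r in assigned], index=assigned)
        for g in grouped.index:
            members = genes.index[genes == g]
            w = totals.loc[members].to_numpy().astype(float)
            if w.sum() == 0:
                w = np.ones(len(members))
            rows.append(float(np.average(gc_s.loc[members], weights=w)))
        gc = np.array(rows)
    return CountMatrix(
        grouped.to_numpy(),
        list(grouped.index),
        list(grouped.columns),
        cell_labels=m.cell_labels,
        region_gc=gc,
    )


def _fix_signs(components: np.ndarray, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make each component's largest-magnitude loading positive."""
    for c in range(components.shape[0]):
        j = np.argmax(np.abs(components[c]))
        if components[c, j] < 0:
            components[c] = -components[c]
            coords[:, c] = -coords[:, c]
    return components, coords


def posterior_pca(
    posterior: np.ndarray,
    cell_barcodes: list[str],
    n_components: int = 30,
) -> Embedding:
    """PCA of the posterior open-probability matrix (regions/genes x cells).

    The cells x features posterior is centered (not scaled) and decomposed
    with a full SVD; constant features are dropped (logged).  The component
    sign convention (largest-magnitude loading positive) makes the
    decomposition reproducible.
    """
    a = np.asarray(posterior, dtype=float).T  # cells x features
    keep = a.std(axis=0) > 0
    if not np.any(keep):
        raise ValueError("posterior is constant across cells; nothing to decompose")
    if not np.all(keep):
        logger.info("%d constant posterior feature(s) dropped", int((~keep).sum()))
        a = a[:, keep]
    k = min(n_components, min(a.shape) - 1)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(a)
    comps, coords = _fix_signs(pca.components_.copy(), coords)
    return Embedding(
        coordinates=coords,
        variance_fraction=pca.explained_variance_ratio_,
        cell_barcodes=list(cell_barcodes),
        method="posterior-PCA",
    )


def pc_depth_correlation(
    e: Embedding, library_size: np.ndarray, k: int = 10
) -> pd.DataFrame:
    """Pearson correlation of the first ``k`` components with library size.

    Zero-variance components get r = 0 with a flag.
    """
    if k > e.n_components:
        raise ValueError("k exceeds number of components")
    lib = np.asarray(library_size, dtype=float)
    rows = []
    for c in range(k):
        coord = e.coordinates[:, c]
        if np.std(coord) == 0 or np.std(lib) == 0:
            rows.append({"component": c + 1, "pearson_r": 0.0, "degenerate": True})
        else:
            r, _ = pearsonr(coord, lib)
            rows.append({"component": c + 1, "pearson_r": float(r), "degenerate": False})
    return pd.DataFrame(rows)


def silhouette_by_type(
    e: Embedding,
    labels,
    n_components: int = 30,
    approximate: bool = False,
) -> pd.Series:
    """Mean silhouette width per cell type on the leading components.

    Euclidean silhouettes on the first ``n_components`` coordinates.
    ``approximate=True`` uses the centroid-based variant (distances to
    cluster centroids instead of all points), cheap for large n.  Singleton
    labels receive silhouette 0 (flagged in the log).
    """
    labels = pd.Series(list(labels))
    if labels.nunique() < 2:
        raise ValueError("need >= 2 distinct labels")
    k = min(n_components, e.n_components)
    xy = e.coordinates[:, :k]
    counts = labels.value_counts()
    singletons = counts.index[counts == 1]
    if len(singletons):
        logger.info("singleton label(s) %s: silhouette set to 0", list(singletons))

    if approximate:
        # expected distance to a cluster approximated via its centroid plus
        # dispersion: E||x - y||^2 = ||x - c||^2 + mean ||y - c||^2
        cent: dict = {}
        disp: dict = {}
        for g in counts.index:
            pts = xy[(labels == g).to_numpy()]
            cent[g] = pts.mean(axis=0)
            disp[g] = float(np.mean(np.sum((pts - cent[g]) ** 2, axis=1)))
        sil = np.zeros(len(labels))
        label_arr = labels.to_numpy()
        for idx in range(len(labels)):
            own = label_arr[idx]
            if counts[own] == 1:
                continue
            d_own = np.sqrt(np.sum((xy[idx] - cent[own]) ** 2) + disp[own])
            b = min(
                np.sqrt(np.sum((xy[idx] - cent[g]) ** 2) + disp[g])
                for g in counts.index
                if g != own
            )
            denom = max(d_own, b)
            sil[idx] = 0.0 if denom == 0 else (b - d_own) / denom
    else:
        mask = ~labels.isin(singletons).to_numpy()
        sil = np.zeros(len(labels))
        if mask.sum() and labels[mask].nunique() >= 2:
            sil[mask] = silhouette_samples(xy[mask], labels[mask])
    return pd.Series(sil).groupby(labels.to_numpy()).mean()
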