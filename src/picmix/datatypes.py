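"""Core containers shared across the package.

The count matrix is stored regions x cells (features as rows), the common
convention of genomics count files (MatrixMarket + regions.tsv + barcodes.tsv).
Mathematical notation for the mixture model indexes cells first (an N x P
matrix of cells by regions); the mapping between the two is a transposition
and is handled internally wherever it matters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced fragment: two Tn5 insertion loci plus the cell barcode.

    Coordinates are BED-like: 0-based, half-open.  The two insertion loci of
    the fragment are ``start`` and ``end - 1``.  ``support`` is the read
    support reported by the upstream pipeline; it plays no role in counting
    (one fragment contributes one pair).
    """

    chrom: str
    start: int
    end: int
    barcode: str
    support: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.support < 1:
            raise ValueError("fragment support must be >= 1")

    @property
    def insertions(self) -> tuple[int, int]:
        """The two insertion loci (left cut, right cut)."""
        return self.start, self.end - 1


@dataclass
class Region:
    """A genomic interval: a peak, a background flank, or a gene body."""

    id: str
    chrom: str
    start: int
    end: int
    gc: float | None = None
    kind: str = "peak"
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"region {self.id}: end must be > start")
        if self.gc is not None and not (0.0 <= self.gc <= 1.0):
            raise ValueError(f"region {self.id}: gc={self.gc} outside [0, 1]")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def tss(self) -> int:
        """Transcription start site, strand-aware (for kind='gene')."""
        return self.start if self.strand != "-" else self.end - 1


class CountMatrix:
    """Region x cell matrix of non-negative integer paired-insertion counts.

    Parameters
    ----------
    values
        2-D array or sparse matrix, regions in rows, cells in columns.
    region_ids, cell_barcodes
        Row / column identifiers.
    cell_labels
        Optional per-cell annotation (e.g. cell type), aligned to barcodes.
    """

    def __init__(
        self,
        values,
        region_ids: Sequence[str],
        cell_barcodes: Sequence[str],
        cell_labels: Sequence[str] | None = None,
        region_gc: Sequence[float] | None = None,
    ):
        if sp.issparse(values):
            values = sp.csr_matrix(values)
            dense_check = values.data
        else:
            values = np.asarray(values)
            dense_check = values
        if dense_check.size and (
            np.any(dense_check < 0) or np.any(dense_check != np.floor(dense_check))
        ):
            raise ValueError("count matrix entries must be non-negative integers")
        if values.shape != (len(region_ids), len(cell_barcodes)):
            raise ValueError(
                f"shape {values.shape} inconsistent with {len(region_ids)} regions "
                f"x {len(cell_barcodes)} cells"
            )
        self.values = values
        self.region_ids = list(region_ids)
        self.cell_barcodes = list(cell_barcodes)
        if cell_labels is not None and len(cell_labels) != len(cell_barcodes):
            raise ValueError("cell_labels length mismatch")
        self.cell_labels = list(cell_labels) if cell_labels is not None else None
        if region_gc is not None and len(region_gc) != len(region_ids):
            raise ValueError("region_gc length mismatch")
        self.region_gc = (
            np.asarray(region_gc, dtype=float) if region_gc is not None else None
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_regions(self) -> int:
        return self.shape[0]

    @property
    def n_cells(self) -> int:
        return self.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def region_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dense(), index=self.region_ids, columns=self.cell_barcodes
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "CountMatrix":
        return cls(df.to_numpy(), list(df.index), list(df.columns), **kw)


@dataclass
class NormalizedMatrix:
    """Result of a normalization: dense real-valued regions x cells array."""

    values: np.ndarray
    region_ids: list[str]
    cell_barcodes: list[str]
    flavor: str
    binarized: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.region_ids, columns=self.cell_barcodes
        )


@dataclass
class ModelParams:
    """Parameters of the hierarchical mixture model.

    p : per-cell observation probability in (0, 1]
    pi : per-region proportion of open cells in [0, 1]
    lambda_c : per-region background cut rate (> 0)
    s : per-region signal-to-noise ratio (>= 1)
    """

    p: np.ndarray
    pi: np.ndarray
    lambda_c: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        self.pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        self.lambda_c = np.atleast_1d(np.asarray(self.lambda_c, dtype=float))
        self.s = np.atleast_1d(np.asarray(self.s, dtype=float))
        if np.any(self.p <= 0) or np.any(self.p > 1):
            raise ValueError("p must lie in (0, 1]")
        if np.any(self.pi < 0) or np.any(self.pi > 1):
            raise ValueError("pi must lie in [0, 1]")
        if np.any(self.lambda_c < 0):
            raise ValueError("lambda_c must be >= 0")
        if np.any(self.s < 1):
            raise ValueError("s must be >= 1")
        n_reg = {len(self.pi), len(self.lambda_c), len(self.s)}
        if len(n_reg) != 1:
            raise ValueError("pi, lambda_c, s must have equal length")

    @property
    def n_regions(self) -> int:
        return len(self.pi)


@dataclass
class SimulationTruth:
    """Latent states and counts from one draw of the generative model.

    Z : binary regions x cells open/closed indicator
    y : latent paired-cut counts (regions x cells)
    x : observed counts after per-cell binomial thinning
    """

    Z: np.ndarray
    y: np.ndarray
    x: np.ndarray
    params: ModelParams
    p_cells: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.x > self.y):
            raise ValueError("observed counts cannot exceed latent counts")


@dataclass
class Embedding:
    """Cells x components coordinates with per-component variance fractions."""

    coordinates: np.ndarray
    variance_fraction: np.ndarray
    cell_barcodes: list[str]
    method: str

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fraction, dtype=float)
        if np.any(vf < -1e-12) or np.any(vf > 1 + 1e-12):
            raise ValueError("variance fractions must lie in [0, 1]")
        if np.any(np.diff(vf) > 1e-9):
            raise ValueError("components must be ordered by decreasing variance")

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class GeneMap:
    """Peak -> nearest gene assignment with signed TSS distance in bp."""

    assignments: pd.DataFrame  # columns: peak_id, gene_id, distance
    unassigned: list[str] = field(default_factory=list)

    def gene_of(self) -> dict[str, str]:
        return dict(
            zip(self.assignments["peak_id"], self.assignments["gene_id"])
        )
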