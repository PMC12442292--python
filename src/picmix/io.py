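"""Readers and writers for the plain-text genomics formats the package uses.

Fragments are 10x-style 5-column TSV (chrom, start, end, barcode, support),
optionally gzip-compressed.  Regions are BED3+ (0-based, half-open).  Count
matrices travel as a MatrixMarket file plus regions.tsv / barcodes.tsv side
files.  Genomes are FASTA, accessed through pyfaidx.
"""

from __future__ import annotations

import gzip
import io as _io
import logging
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from pyfaidx import Fasta

from .datatypes import CountMatrix, FragmentRecord, Region

logger = logging.getLogger(__name__)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fragments(path: str | Path) -> Iterator[FragmentRecord]:
    """Stream fragment records from a (possibly gzipped) fragments TSV.

    Lines starting with ``#`` are skipped.  Malformed lines raise a
    ``ValueError`` naming the offending line number.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=4 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                support = int(fields[4]) if len(fields) >= 5 else 1
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            try:
                yield FragmentRecord(fields[0], start, end, fields[3], support)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None


def write_fragments(path: str | Path, fragments: Iterable[FragmentRecord]) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.barcode}\t{f.support}\n")


def read_regions_bed(path: str | Path, kind: str = "peak") -> list[Region]:
    """Read a BED3+ file into Region objects.

    The optional 4th column supplies the region id; otherwise the id is
    ``chrom:start-end``.  A 6th column, when present, is taken as strand.
    """
    regions: list[Region] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: BED needs >=3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            rid = fields[3] if len(fields) >= 4 and fields[3] else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) >= 6 else "+"
            regions.append(
                Region(id=rid, chrom=chrom, start=start, end=end, kind=kind, strand=strand)
            )
    return regions


def write_regions_bed(path: str | Path, regions: Iterable[Region]) -> None:
    with open(path, "wt") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\t.\t{r.strand}\n")


def write_count_matrix(
    m: CountMatrix, mtx_path: str | Path, regions_path=None, barcodes_path=None
) -> None:
    """Write counts as MatrixMarket plus regions.tsv / barcodes.tsv side files."""
    mtx_path = Path(mtx_path)
    regions_path = Path(regions_path) if regions_path else mtx_path.with_name("regions.tsv")
    barcodes_path = Path(barcodes_path) if barcodes_path else mtx_path.with_name("barcodes.tsv")
    values = m.values if sp.issparse(m.values) else sp.csr_matrix(m.values)
    scipy.io.mmwrite(str(mtx_path), values.astype(int))
    pd.Series(m.region_ids).to_csv(regions_path, sep="\t", index=False, header=False)
    bc = pd.DataFrame({"barcode": m.cell_barcodes})
    if m.cell_labels is not None:
        bc["label"] = m.cell_labels
    bc.to_csv(barcodes_path, sep="\t", index=False, header=False)


def read_count_matrix(
    mtx_path: str | Path, regions_path=None, barcodes_path=None
) -> CountMatrix:
    mtx_path = Path(mtx_path)
    regions_path = Path(regions_path) if regions_path else mtx_path.with_name("regions.tsv")
    barcodes_path = Path(barcodes_path) if barcodes_path else mtx_path.with_name("barcodes.tsv")
    values = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    region_ids = pd.read_csv(regions_path, sep="\t", header=None)[0].astype(str).tolist()
    bc = pd.read_csv(barcodes_path, sep="\t", header=None)
    barcodes = bc[0].astype(str).tolist()
    labels = bc[1].astype(str).tolist() if bc.shape[1] > 1 else None
    return CountMatrix(values, region_ids, barcodes, cell_labels=labels)


def open_genome(path: str | Path) -> Fasta:
    """Open a FASTA genome (builds the .fai index on first use)."""
    return Fasta(str(path))


def read_gc_table(path: str | Path) -> pd.Series:
    """Read a two-column TSV of (region id, gc fraction)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["region", "gc"])
    return df.set_index("region")["gc"]


def write_gc_table(path: str | Path, regions: Iterable[Region]) -> None:
    with open(path, "wt") as fh:
        for r in regions:
            gc = "" if r.gc is None else f"{r.gc:.6f}"
            fh.write(f"{r.id}\t{gc}\n")
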