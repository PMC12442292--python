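"""Paired-insertion counting (PIC) and region utilities.

A sequenced ATAC fragment carries two Tn5 insertion loci (its two cut sites).
For a region, a fragment contributes exactly one count when *at least one* of
its two insertions falls inside the region.  A long fragment spanning the
whole region with both insertions outside contributes nothing — this is what
distinguishes paired-insertion counting from naive fragment-overlap counting
and removes those false positives.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from pyfaidx import Fasta

from .datatypes import CountMatrix, FragmentRecord, Region

logger = logging.getLogger(__name__)


def pic_count(
    fragments: Iterable[FragmentRecord],
    regions: Sequence[Region],
    barcodes: Sequence[str],
) -> CountMatrix:
    """Build a region x cell paired-insertion count matrix.

    Each fragment contributes one count to every region containing at least
    one of its two insertion loci (``start`` and ``end - 1``).  Fragments
    whose barcode is not in the allowlist are ignored; the support column is
    ignored (fragment files are already deduplicated — one record, one pair).
    Regions may overlap: a fragment is evaluated independently against each.
    """
    if len(barcodes) == 0:
        raise ValueError("barcode allowlist must be non-empty")
    barcode_idx = {b: i for i, b in enumerate(barcodes)}

    # per-chromosome region list sorted by start; lookups walk back from the
    # rightmost start <= locus, bounded by the chromosome's max region width
    by_chrom: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for j, r in enumerate(regions):
        by_chrom[r.chrom].append((r.start, r.end, j))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    starts = {c: np.array([t[0] for t in v]) for c, v in by_chrom.items()}
    max_width = {
        c: max(t[1] - t[0] for t in v) for c, v in by_chrom.items()
    }

    rows: list[int] = []
    cols: list[int] = []
    missing_chroms: set[str] = set()
    for frag in fragments:
        i = barcode_idx.get(frag.barcode)
        if i is None:
            continue
        chrom_regions = by_chrom.get(frag.chrom)
        if chrom_regions is None:
            if frag.chrom not in missing_chroms:
                missing_chroms.add(frag.chrom)
                logger.warning(
                    "fragments on %s have no regions; counted nowhere", frag.chrom
                )
            continue
        left, right = frag.insertions
        st = starts[frag.chrom]
        w = max_width[frag.chrom]
        hit: set[int] = set()
        for locus in (left, right):
            k = int(np.searchsorted(st, locus, side="right")) - 1
            while k >= 0 and locus - chrom_regions[k][0] < w:
                r_start, r_end, j = chrom_regions[k]
                if r_start <= locus < r_end:
                    hit.add(j)
                k -= 1
        for j in hit:
            rows.append(j)
            cols.append(i)

    values = sp.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(regions), len(barcodes)),
    ).tocsr()
    return CountMatrix(values, [r.id for r in regions], list(barcodes))


def flank_background_regions(
    peaks: Sequence[Region], flank_width: int = 500
) -> list[Region]:
    """Background flanks: ``flank_width`` bp immediately up- and downstream of
    each peak, dropping any flank that overlaps *any* peak.

    Negative coordinates are clipped at zero; zero-width results are dropped.
    """
    by_chrom: dict[str, list[Region]] = defaultdict(list)
    for p in peaks:
        by_chrom[p.chrom].append(p)

    flanks: list[Region] = []
    for p in peaks:
        candidates = [
            (max(0, p.start - flank_width), p.start, "up"),
            (p.end, p.end + flank_width, "down"),
        ]
        for start, end, side in candidates:
            if end <= start:
                continue
            overlaps = any(
                q.start < end and start < q.end for q in by_chrom[p.chrom]
            )
            if overlaps:
                continue
            flanks.append(
                Region(
                    id=f"{p.id}_{side}",
                    chrom=p.chrom,
                    start=start,
                    end=end,
                    kind="background",
                )
            )
    return flanks


def gc_content(regions: Sequence[Region], genome: Fasta | dict) -> list[Region]:
    """Fill each region's ``gc`` with (#G + #C) / (#A + #C + #G + #T) over its
    sequence.  Ambiguous bases are excluded from both numerator and
    denominator; an all-ambiguous region keeps ``gc = None``.

    ``genome`` may be a pyfaidx Fasta or a plain dict of chrom -> sequence.
    """
    for r in regions:
        if isinstance(genome, dict):
            if r.chrom not in genome:
                raise KeyError(f"chromosome {r.chrom} absent from genome")
            seq = genome[r.chrom][r.start : r.end]
        else:
            if r.chrom not in genome:
                raise KeyError(f"chromosome {r.chrom} absent from genome")
            seq = str(genome[r.chrom][r.start : r.end])
        seq = seq.upper()
        gc = sum(seq.count(b) for b in "GC")
        at = sum(seq.count(b) for b in "AT")
        total = gc + at
        r.gc = (gc / total) if total > 0 else None
    return list(regions)
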