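"""Synthetic scATAC-seq data with known ground truth.

Generates a small genome (random sequence with controlled per-peak GC), a
non-overlapping fixed-width peak set with background flanks, gene
annotations, a cell table with a right-skewed observation-probability
distribution, and a fragment file realized from the hierarchical mixture:
per cell and peak the open/closed state, latent cut pairs, and observed
fragments are drawn from the Bernoulli-Poisson-Binomial hierarchy, with the
background rate an affine function of peak GC.  Background fragments are
additionally placed in the flank regions so the background-rate estimator is
testable end to end, and long spanning fragments (both insertions outside
any region) can be injected to exercise the paired-insertion zero-count
rule.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, FragmentRecord, ModelParams, Region, SimulationTruth
from .quant import flank_background_regions, gc_content

_BASES = np.array(list("ACGT"))


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    The defaults describe a small but realistic design: 500 bp fixed-width
    peaks with 500 bp flanks, a background rate rising linearly in GC
    (lambda_c = 0.001 + 0.02 * GC, spanning the sparse regime of real data),
    signal-to-noise ratios log-uniform in [10, 100], open proportions around
    0.3 with a subset of cell-type marker peaks, and observation
    probabilities Beta(2, 4)-shaped on (0, 0.9].
    """

    n_chromosomes: int = 1
    chrom_length: int = 300_000
    n_peaks: int = 100
    peak_width: int = 500
    flank_width: int = 500
    n_genes: int = 25
    n_cells: int = 200
    cell_types: tuple[str, ...] = ("typeA", "typeB")
    pi_base: float = 0.3
    marker_fraction: float = 0.4
    pi_marker_open: float = 0.7
    pi_marker_closed: float = 0.05
    p_beta_a: float = 2.0
    p_beta_b: float = 4.0
    p_max: float = 0.9
    lambda0: float = 0.001
    lambda_slope: float = 0.02
    s_min: float = 10.0
    s_max: float = 100.0
    gc_beta_a: float = 2.0
    gc_beta_b: float = 2.0
    gc_lo: float = 0.25
    gc_hi: float = 0.75
    min_fragment_len: int = 50
    spanning_prob: float = 0.01
    seed: int = 0

    def lambda_of_gc(self, gc) -> np.ndarray:
        return self.lambda0 + self.lambda_slope * np.asarray(gc, dtype=float)


@dataclass
class SynthResult:
    """Everything one generator run produced, ground truth included."""

    genome: dict[str, str]
    peaks: list[Region]
    flanks: list[Region]
    genes: list[Region]
    cells: pd.DataFrame  # barcode, type, p
    fragments: list[FragmentRecord]
    truth: SimulationTruth
    pi_by_type: pd.DataFrame  # type x peak open proportions
    config: SynthConfig

    def peak_matrix(self) -> CountMatrix:
        return CountMatrix(
            self.truth.x,
            [p.id for p in self.peaks],
            list(self.cells["barcode"]),
            cell_labels=list(self.cells["type"]),
            region_gc=np.array([p.gc for p in self.peaks]),
        )


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _gc_controlled_seq(rng: np.random.Generator, length: int, gc_target: float) -> np.ndarray:
    """Sequence with an exact GC base count (realized GC = target to rounding)."""
    n_gc = int(round(gc_target * length))
    bases = np.empty(length, dtype=int)
    gc_choices = rng.integers(0, 2, size=n_gc)  # G=2, C=1
    at_choices = rng.integers(0, 2, size=length - n_gc)  # A=0, T=3
    bases[:n_gc] = np.where(gc_choices == 0, 1, 2)
    bases[n_gc:] = np.where(at_choices == 0, 0, 3)
    rng.shuffle(bases)
    return bases


def make_genome(cfg: SynthConfig) -> tuple[dict[str, str], list[Region], list[Region]]:
    """Random genome with GC-controlled peaks and flanks, plus gene annotations.

    Peaks are fixed-width, evenly spaced with room for both flanks; per-peak
    (and per-flank) target GC is drawn from a Beta distribution rescaled to
    [gc_lo, gc_hi].  Raises if the requested peaks cannot be packed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    per_chrom = int(np.ceil(cfg.n_peaks / cfg.n_chromosomes))
    spacing = cfg.chrom_length // (per_chrom + 1)
    needed = cfg.peak_width + 2 * cfg.flank_width + 20
    if spacing < needed:
        raise ValueError(
            f"cannot pack {per_chrom} peaks of {cfg.peak_width}bp (+flanks) "
            f"into {cfg.chrom_length}bp"
        )

    genome: dict[str, str] = {}
    peaks: list[Region] = []
    genes: list[Region] = []
    peak_counter = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        seq = _random_seq(rng, cfg.chrom_length)
        for k in range(per_chrom):
            if peak_counter >= cfg.n_peaks:
                break
            start = (k + 1) * spacing
            end = start + cfg.peak_width
            target = cfg.gc_lo + (cfg.gc_hi - cfg.gc_lo) * rng.beta(
                cfg.gc_beta_a, cfg.gc_beta_b
            )
            seq[start:end] = _gc_controlled_seq(rng, cfg.peak_width, target)
            for fl_start, fl_end in (
                (start - cfg.flank_width, start),
                (end, end + cfg.flank_width),
            ):
                fl_target = cfg.gc_lo + (cfg.gc_hi - cfg.gc_lo) * rng.beta(
                    cfg.gc_beta_a, cfg.gc_beta_b
                )
                seq[fl_start:fl_end] = _gc_controlled_seq(
                    rng, fl_end - fl_start, fl_target
                )
            peaks.append(
                Region(id=f"peak{peak_counter:05d}", chrom=chrom, start=start, end=end)
            )
            peak_counter += 1
        genome[chrom] = "".join(_BASES[seq])

    # genes: TSSs spread along chromosomes, random strand
    per_chrom_genes = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    gene_counter = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        positions = np.sort(
            rng.integers(1000, cfg.chrom_length - 2000, size=per_chrom_genes)
        )
        for pos in positions:
            if gene_counter >= cfg.n_genes:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                Region(
                    id=f"gene{gene_counter:04d}",
                    chrom=chrom,
                    start=int(pos),
                    end=int(pos) + 1000,
                    kind="gene",
                    strand=strand,
                )
            )
            gene_counter += 1

    gc_content(peaks, genome)
    return genome, peaks, genes


def make_cells(cfg: SynthConfig) -> pd.DataFrame:
    """Cell table: barcode, cell type, observation probability p.

    p is drawn from a right-skewed Beta(a, b) scaled to (0, p_max],
    independent of cell type (depth and type uncorrelated by construction).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    types = [cfg.cell_types[i % len(cfg.cell_types)] for i in range(cfg.n_cells)]
    p = cfg.p_max * rng.beta(cfg.p_beta_a, cfg.p_beta_b, size=cfg.n_cells)
    p = np.clip(p, 1e-4, cfg.p_max)
    return pd.DataFrame(
        {
            "barcode": [f"CELL{i:06d}" for i in range(cfg.n_cells)],
            "type": types,
            "p": p,
        }
    )


def _draw_pi_profiles(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-type open proportions: shared baseline plus marker peaks."""
    n_types = len(cfg.cell_types)
    pi = np.full((n_types, cfg.n_peaks), cfg.pi_base)
    n_marker = int(round(cfg.marker_fraction * cfg.n_peaks))
    marker_peaks = rng.choice(cfg.n_peaks, size=n_marker, replace=False)
    owner = rng.integers(0, n_types, size=n_marker)
    for pk, t in zip(marker_peaks, owner):
        pi[:, pk] = cfg.pi_marker_closed
        pi[t, pk] = cfg.pi_marker_open
    return pd.DataFrame(pi, index=list(cfg.cell_types))


def make_fragments(
    cfg: SynthConfig,
    genome: dict[str, str],
    peaks: list[Region],
    cells: pd.DataFrame,
) -> tuple[list[FragmentRecord], SimulationTruth, list[Region], pd.DataFrame]:
    """Realize the hierarchy as physical fragments.

    Per cell x peak: draw Z from the cell type's pi, latent cuts y from
    Poisson(lambda_c(GC) * s or lambda_c(GC)), observed pairs x from
    Binomial(y, p_i); each observed pair becomes a fragment with both
    insertions inside the peak.  Background fragments are placed wholly
    inside flank regions at rate lambda_c(GC_flank) * p_i, and (optionally)
    long spanning fragments with both insertions outside peaks and flanks
    are injected.  Paired-insertion counting of the emitted file over the
    peak set reproduces x exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    flanks = flank_background_regions(peaks, cfg.flank_width)
    gc_content(flanks, genome)

    pi_by_type = _draw_pi_profiles(cfg, rng)
    gc_peaks = np.array([p.gc for p in peaks])
    lam = cfg.lambda_of_gc(gc_peaks)
    s = np.exp(rng.uniform(np.log(cfg.s_min), np.log(cfg.s_max), size=cfg.n_peaks))

    n_cells = len(cells)
    p_cells = cells["p"].to_numpy()
    type_idx = pd.Categorical(
        cells["type"], categories=list(cfg.cell_types)
    ).codes
    pi_cells = pi_by_type.to_numpy()[type_idx, :].T  # peaks x cells

    Z = (rng.random((cfg.n_peaks, n_cells)) < pi_cells).astype(np.int8)
    rate = lam[:, None] * np.where(Z == 1, s[:, None], 1.0)
    y = rng.poisson(rate)
    x = rng.binomial(y, p_cells[None, :])

    fragments: list[FragmentRecord] = []
    barcodes = cells["barcode"].to_numpy()
    min_len = cfg.min_fragment_len
    for j, peak in enumerate(peaks):
        width = peak.width
        hi_len = max(min_len + 1, width - 1)
        cells_with = np.flatnonzero(x[j] > 0)
        for i in cells_with:
            for _ in range(int(x[j, i])):
                frag_len = int(rng.integers(min_len, hi_len))
                frag_len = min(frag_len, width - 1)
                start = int(rng.integers(peak.start, peak.end - frag_len))
                fragments.append(
                    FragmentRecord(peak.chrom, start, start + frag_len, barcodes[i], 1)
                )
        # spanning fragments: both insertions outside peak and flanks
        if cfg.spanning_prob > 0:
            spanning = rng.random(n_cells) < cfg.spanning_prob
            for i in np.flatnonzero(spanning):
                start = peak.start - cfg.flank_width - 10
                end = peak.end + cfg.flank_width + 10
                if start >= 0:
                    fragments.append(
                        FragmentRecord(peak.chrom, start, end, barcodes[i], 1)
                    )

    # background fragments wholly inside flanks
    for fl in flanks:
        lam_fl = float(cfg.lambda_of_gc(fl.gc if fl.gc is not None else 0.5))
        counts = rng.poisson(lam_fl * p_cells)
        for i in np.flatnonzero(counts > 0):
            for _ in range(int(counts[i])):
                hi_len = max(min_len + 1, fl.width - 1)
                frag_len = min(int(rng.integers(min_len, hi_len)), fl.width - 1)
                start = int(rng.integers(fl.start, fl.end - frag_len))
                fragments.append(
                    FragmentRecord(fl.chrom, start, start + frag_len, barcodes[i], 1)
                )

    # population-average open proportion per peak (type mixture)
    type_frac = np.bincount(type_idx, minlength=len(cfg.cell_types)) / n_cells
    pi_avg = type_frac @ pi_by_type.to_numpy()
    params = ModelParams(p=p_cells, pi=pi_avg, lambda_c=lam, s=s)
    truth = SimulationTruth(Z=Z, y=y, x=x, params=params, p_cells=p_cells, seed=cfg.seed)
    return fragments, truth, flanks, pi_by_type


def generate(cfg: SynthConfig) -> SynthResult:
    """Run the full generator: genome, cells, fragments, truth."""
    genome, peaks, genes = make_genome(cfg)
    cells = make_cells(cfg)
    fragments, truth, flanks, pi_by_type = make_fragments(cfg, genome, peaks, cells)
    return SynthResult(
        genome=genome,
        peaks=peaks,
        flanks=flanks,
        genes=genes,
        cells=cells,
        fragments=fragments,
        truth=truth,
        pi_by_type=pi_by_type,
        config=cfg,
    )


def write_outputs(result: SynthResult, outdir: str | Path) -> dict[str, Path]:
    """Write genome.fa, peaks.bed, genes.bed, cells.tsv, fragments.tsv.gz,
    truth tables, and a config echo into ``outdir``."""
    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fa = outdir / "genome.fa"
    with open(fa, "wt") as fh:
        for chrom, seq in result.genome.items():
            fh.write(f">{chrom}\n")
            for k in range(0, len(seq), 80):
                fh.write(seq[k : k + 80] + "\n")
    paths["genome"] = fa

    pio.write_regions_bed(outdir / "peaks.bed", result.peaks)
    pio.write_regions_bed(outdir / "genes.bed", result.genes)
    pio.write_regions_bed(outdir / "flanks.bed", result.flanks)
    pio.write_gc_table(outdir / "gc_peaks.tsv", result.peaks)
    pio.write_gc_table(outdir / "gc_flanks.tsv", result.flanks)
    paths["peaks"] = outdir / "peaks.bed"
    paths["genes"] = outdir / "genes.bed"
    paths["flanks"] = outdir / "flanks.bed"

    result.cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    paths["cells"] = outdir / "cells.tsv"

    frag_path = outdir / "fragments.tsv.gz"
    pio.write_fragments(frag_path, result.fragments)
    paths["fragments"] = frag_path

    pio.write_count_matrix(
        result.peak_matrix(),
        outdir / "truth_x.mtx",
        outdir / "regions.tsv",
        outdir / "barcodes.tsv",
    )
    paths["truth_x"] = outdir / "truth_x.mtx"

    tp = result.truth.params
    pd.DataFrame(
        {
            "region": [p.id for p in result.peaks],
            "pi": tp.pi,
            "s": tp.s,
            "lambda_c": tp.lambda_c,
            "gc": [p.gc for p in result.peaks],
        }
    ).to_csv(outdir / "truth_params.tsv", sep="\t", index=False)
    paths["truth_params"] = outdir / "truth_params.tsv"

    cfg_echo = outdir / "config.tsv"
    pd.Series(dataclasses.asdict(result.config)).astype(str).to_csv(
        cfg_echo, sep="\t", header=False
    )
    paths["config"] = cfg_echo
    return paths
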