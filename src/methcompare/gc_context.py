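"""Local GC context, genomic-context annotation and motif-GC binning.

Local GC context is the GC% of a closed window of +/- ``flank`` bp
around the interrogated cytosine (101 bp at the default flank of 50,
centre base included).  Bisulphite-based methods lose coverage, and can
distort betas, as this local GC% rises.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import read_bed_intervals
from .strand import _fetch, gc_percent

# The 6 non-CG bases of an 8 bp CpG motif can carry 0..6 G/C, and the
# central CG always contributes 2, so GC% takes exactly seven values.
MOTIF_GC_BINS = (25.0, 37.5, 50.0, 62.5, 75.0, 87.5, 100.0)

DEFAULT_SHORE_WIDTH = 2000  # bp flanking a CpG island
DEFAULT_PROMOTER_UPSTREAM = 1500  # bp upstream of the TSS


def window_gc(reference, chrom: str, pos: int, flank: int = 50) -> float:
    """GC% of the closed window [pos - flank, pos + flank].

    NaN when the window runs off either contig end, so truncated
    windows never contribute biased values.
    """
    seq = _fetch(reference, chrom, pos - flank, pos + flank)
    if seq is None:
        return math.nan
    return gc_percent(seq)


def window_gc_many(
    reference, chrom: str, positions, flank: int = 50
) -> np.ndarray:
    """Vectorised :func:`window_gc` over positions of one contig."""
    contig = str(reference[chrom]).upper()
    is_gc = np.frombuffer(contig.encode(), dtype=np.uint8)
    gc_mask = (is_gc == ord("G")) | (is_gc == ord("C"))
    n_mask = is_gc == ord("N")
    cum_gc = np.concatenate([[0], np.cumsum(gc_mask)])
    cum_n = np.concatenate([[0], np.cumsum(n_mask)])
    positions = np.asarray(positions, dtype=np.int64)
    lo = positions - flank  # 1-based
    hi = positions + flank
    out = np.full(positions.shape, np.nan)
    ok = (lo >= 1) & (hi <= len(contig))
    gc = cum_gc[hi[ok]] - cum_gc[lo[ok] - 1]
    nn = cum_n[hi[ok]] - cum_n[lo[ok] - 1]
    denom = (hi[ok] - lo[ok] + 1) - nn
    vals = np.where(denom > 0, 100.0 * gc / np.maximum(denom, 1), np.nan)
    out[ok] = vals
    return out


def _merge_intervals(df: pd.DataFrame) -> dict[str, list[tuple[int, int]]]:
    """Merge 1-based inclusive intervals per chrom (abutting merged too)."""
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        ivs = sorted(zip(sub["start"].astype(int), sub["end"].astype(int)))
        out: list[tuple[int, int]] = []
        for start, end in ivs:
            if start < 1 or end < start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            if out and start <= out[-1][1] + 1:
                out[-1] = (out[-1][0], max(out[-1][1], end))
            else:
                out.append((start, end))
        merged[chrom] = out
    return merged


def _tree(intervals: list[tuple[int, int]]) -> IntervalTree:
    # IntervalTree is half-open; +1 on end makes it 1-based inclusive
    return IntervalTree.from_tuples((s, e + 1) for s, e in intervals)


def _read_genes(genes) -> pd.DataFrame:
    """Gene spans from a GFF3 path or a prebuilt DataFrame.

    The frame needs chrom, start, end (1-based inclusive) and strand.
    """
    if isinstance(genes, pd.DataFrame):
        return genes
    import gffutils

    db = gffutils.create_db(
        str(genes), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = [
        {"chrom": g.seqid, "start": g.start, "end": g.end, "strand": g.strand}
        for g in db.features_of_type("gene")
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def annotate_genomic_context(
    positions: pd.DataFrame,
    islands: pd.DataFrame | str | Path,
    genes: pd.DataFrame | str | Path | None = None,
    shore_width: int = DEFAULT_SHORE_WIDTH,
    promoter_upstream: int = DEFAULT_PROMOTER_UPSTREAM,
) -> pd.DataFrame:
    """Label positions by CpG-island and gene context.

    Each position gets one exclusive label from {island, shore, neither}
    (island wins over shore where they abut) plus independent boolean
    gene_body and promoter labels — a position can carry both, e.g. in
    the body of one gene and the promoter window of an overlapping
    neighbour.  Shores are ``shore_width`` bp each side of a merged
    island; promoters run from ``promoter_upstream`` bp upstream of the
    TSS to the TSS, strand-aware.

    ``islands`` may be a BED path (0-based, converted on read) or a
    DataFrame with 1-based chrom/start/end.
    """
    if not isinstance(islands, pd.DataFrame):
        islands = read_bed_intervals(islands)
    island_ivs = _merge_intervals(islands)
    island_trees = {c: _tree(ivs) for c, ivs in island_ivs.items()}
    shore_trees = {
        c: _tree(
            [(max(1, s - shore_width), max(1, s - 1)) for s, e in ivs if s > 1]
            + [(e + 1, e + shore_width) for s, e in ivs]
        )
        for c, ivs in island_ivs.items()
    }

    body_trees: dict[str, IntervalTree] = {}
    prom_trees: dict[str, IntervalTree] = {}
    if genes is not None:
        gene_df = _read_genes(genes)
        for chrom, sub in gene_df.groupby("chrom"):
            bodies, proms = [], []
            for _, g in sub.iterrows():
                start, end = int(g["start"]), int(g["end"])
                if start < 1 or end < start:
                    raise ValueError(f"invalid gene span {chrom}:{start}-{end}")
                bodies.append((start, end))
                if g["strand"] == "-":
                    proms.append((end, end + promoter_upstream))
                else:
                    proms.append((max(1, start - promoter_upstream), start))
            body_trees[chrom] = _tree(bodies)
            prom_trees[chrom] = _tree(proms)

    labels, in_body, in_prom = [], [], []
    for chrom, pos in zip(positions["chrom"], positions["pos"]):
        pos = int(pos)
        if chrom in island_trees and island_trees[chrom].overlaps_point(pos):
            labels.append("island")
        elif chrom in shore_trees and shore_trees[chrom].overlaps_point(pos):
            labels.append("shore")
        else:
            labels.append("neither")
        in_body.append(
            chrom in body_trees and body_trees[chrom].overlaps_point(pos)
        )
        in_prom.append(
            chrom in prom_trees and prom_trees[chrom].overlaps_point(pos)
        )
    out = positions.copy()
    out["cgi_context"] = labels
    out["gene_body"] = in_body
    out["promoter"] = in_prom
    return out


def bin_by_motif_gc(sites: pd.DataFrame) -> tuple[dict[float, pd.DataFrame], int]:
    """Partition CpG sites into the seven attainable motif-GC% bins.

    Returns (bins, n_missing) where ``bins`` maps each of
    :data:`MOTIF_GC_BINS` to the sites in it and ``n_missing`` counts
    sites excluded for missing motif GC.  A motif-GC value outside the
    seven attainable values indicates a motif without a central CG and
    raises ``ValueError``.
    """
    gc = pd.to_numeric(sites["motif_gc"], errors="raise")
    missing = gc.isna()
    present = sites[~missing]
    gc_present = gc[~missing]
    bad = ~gc_present.isin(MOTIF_GC_BINS)
    if bad.any():
        raise ValueError(
            f"motif GC% {sorted(gc_present[bad].unique())} not attainable "
            "for an 8 bp CpG motif"
        )
    bins = {
        b: present[gc_present == b].reset_index(drop=True) for b in MOTIF_GC_BINS
    }
    return bins, int(missing.sum())
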