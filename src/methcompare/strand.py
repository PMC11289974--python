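"""Strand collapse and strand-symmetry statistics for CpG dinucleotides.

A CpG dinucleotide has a cytosine on the Watson strand at position
``pos`` and a mirrored cytosine on the Crick strand at ``pos + 1``.
Methylation is normally symmetric across strands, so per-strand
disagreement ("absolute delta beta") and per-strand coverage imbalance
("evenness") are diagnostics for artefactual methylation calls.

Statistics that are undefined for a site (e.g. delta beta with
single-strand coverage) are propagated as NaN, never as sentinel
numbers, so downstream filters can distinguish "zero" from "unknown".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import StrandedCytosineRecord

MOTIF_FLANK = 3  # bp either side of the CpG -> 8 bp motif, 5'-NNNCGNNN-3'


@dataclass
class CpGSite:
    """A Watson+Crick-collapsed CpG dinucleotide.

    ``pos`` is the 1-based position of the Watson-strand cytosine; the
    paired Crick cytosine sits at ``pos + 1``.  Either strand's counts
    may be None (no coverage reported on that strand).
    """

    chrom: str
    pos: int
    watson: tuple[int, int] | None  # (n_meth, n_unmeth)
    crick: tuple[int, int] | None
    motif: str | None = None
    motif_gc: float = math.nan
    mcgw: bool | None = None

    @property
    def watson_coverage(self) -> int:
        return sum(self.watson) if self.watson is not None else 0

    @property
    def crick_coverage(self) -> int:
        return sum(self.crick) if self.crick is not None else 0

    @property
    def coverage(self) -> int:
        return self.watson_coverage + self.crick_coverage

    @property
    def beta(self) -> float:
        if self.coverage == 0:
            return math.nan
        meth = (self.watson[0] if self.watson else 0) + (
            self.crick[0] if self.crick else 0
        )
        return meth / self.coverage

    @property
    def beta_watson(self) -> float:
        cov = self.watson_coverage
        return self.watson[0] / cov if cov > 0 else math.nan

    @property
    def beta_crick(self) -> float:
        cov = self.crick_coverage
        return self.crick[0] / cov if cov > 0 else math.nan

    @property
    def evenness(self) -> float:
        return evenness(self.watson_coverage, self.crick_coverage)

    @property
    def absolute_delta_beta(self) -> float:
        bw, bc = self.beta_watson, self.beta_crick
        if math.isnan(bw) or math.isnan(bc):
            return math.nan
        return abs(bw - bc)


def collapse_cpg(
    watson: StrandedCytosineRecord | None,
    crick: StrandedCytosineRecord | None,
) -> CpGSite:
    """Collapse a Watson/Crick record pair into one CpG site.

    Either record may be absent (single-strand coverage); counts on the
    missing strand are treated as zero and its strand-specific beta is
    undefined.  The Crick record must sit exactly one base after the
    Watson record on the same contig.
    """
    if watson is None and crick is None:
        raise ValueError("both strands absent")
    if watson is not None and watson.strand != "+":
        raise ValueError("watson record must have strand '+'")
    if crick is not None and crick.strand != "-":
        raise ValueError("crick record must have strand '-'")
    if watson is not None and crick is not None:
        if watson.chrom != crick.chrom:
            raise ValueError("records on different contigs")
        if crick.pos != watson.pos + 1:
            raise ValueError(
                f"crick position {crick.pos} is not watson position "
                f"{watson.pos} + 1"
            )
    if watson is not None:
        chrom, pos = watson.chrom, watson.pos
    else:
        chrom, pos = crick.chrom, crick.pos - 1
    return CpGSite(
        chrom=chrom,
        pos=pos,
        watson=(watson.n_meth, watson.n_unmeth) if watson else None,
        crick=(crick.n_meth, crick.n_unmeth) if crick else None,
    )


def evenness(cov_watson: int | float, cov_crick: int | float) -> float:
    """Strand-coverage imbalance: max single-strand over combined coverage.

    0.5 when coverage is perfectly evenly split across Watson and Crick;
    1 when coverage is completely dominated by one strand.  NaN at zero
    total coverage.
    """
    total = cov_watson + cov_crick
    if total <= 0:
        return math.nan
    return max(cov_watson, cov_crick) / total


def absolute_delta_beta(
    watson: tuple[int, int] | None, crick: tuple[int, int] | None
) -> float:
    """|beta_Watson - beta_Crick|; NaN unless both strands are covered."""
    if watson is None or crick is None:
        return math.nan
    cov_w, cov_c = sum(watson), sum(crick)
    if cov_w == 0 or cov_c == 0:
        return math.nan
    return abs(watson[0] / cov_w - crick[0] / cov_c)


def collapse_strands(report: pd.DataFrame) -> pd.DataFrame:
    """Collapse a stranded cytosine table into per-CpG rows (vectorised).

    ``report`` is a cytosine-report frame restricted to CG context.
    Watson rows at position p are paired with Crick rows at p + 1; rows
    with no partner are kept as single-strand sites.  Output columns:
    chrom, pos (Watson C), per-strand counts, beta, coverage,
    delta_beta, evenness.
    """
    watson = report[report["strand"] == "+"]
    crick = report[report["strand"] == "-"].copy()
    crick["pos"] = crick["pos"] - 1  # key Crick rows by their Watson C
    merged = pd.merge(
        watson[["chrom", "pos", "n_meth", "n_unmeth"]],
        crick[["chrom", "pos", "n_meth", "n_unmeth"]],
        on=["chrom", "pos"],
        how="outer",
        suffixes=("_w", "_c"),
        sort=True,
    )
    for col in ("n_meth_w", "n_unmeth_w", "n_meth_c", "n_unmeth_c"):
        merged[col] = merged[col].fillna(0).astype(np.int64)
    cov_w = merged["n_meth_w"] + merged["n_unmeth_w"]
    cov_c = merged["n_meth_c"] + merged["n_unmeth_c"]
    cov = cov_w + cov_c
    meth = merged["n_meth_w"] + merged["n_meth_c"]
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(cov > 0, meth / cov.replace(0, 1), np.nan)
        beta_w = np.where(cov_w > 0, merged["n_meth_w"] / cov_w.replace(0, 1), np.nan)
        beta_c = np.where(cov_c > 0, merged["n_meth_c"] / cov_c.replace(0, 1), np.nan)
        even = np.where(cov > 0, np.maximum(cov_w, cov_c) / cov.replace(0, 1), np.nan)
    merged["coverage"] = cov
    merged["beta"] = beta
    merged["delta_beta"] = np.abs(beta_w - beta_c)
    merged["evenness"] = even
    return merged


def gc_percent(seq: str) -> float:
    """Percent G+C of a sequence; N bases are excluded from both sides.

    NaN if the sequence is all N; empty input is an error.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    n_n = seq.count("N")
    denom = len(seq) - n_n
    if denom == 0:
        return math.nan
    return 100.0 * (seq.count("G") + seq.count("C")) / denom


def _fetch(reference, chrom: str, start: int, end: int) -> str | None:
    """1-based inclusive slice from a pyfaidx.Fasta; None if off-contig."""
    if start < 1:
        return None
    contig = reference[chrom]
    if end > len(contig):
        return None
    return str(contig[start - 1 : end]).upper()


def extract_motif(reference, chrom: str, pos: int, flank: int = MOTIF_FLANK) -> str | None:
    """Extract the 8 bp motif (5'-NNNCGNNN-3') around a Watson-strand CpG.

    ``pos`` is the 1-based Watson C position.  Returns None (missing)
    when fewer than ``flank`` bases exist on either side; raises if the
    reference does not carry CG at the site.
    """
    core = _fetch(reference, chrom, pos, pos + 1)
    if core is None or core != "CG":
        if core is not None and core != "CG":
            raise ValueError(f"{chrom}:{pos} is {core!r}, not a CpG")
        return None
    return _fetch(reference, chrom, pos - flank, pos + 1 + flank)


def classify_mcgw(reference, chrom: str, pos: int) -> bool | None:
    """Whether the CpG at ``pos`` sits in an MCGW context (M=A/C, W=A/T).

    MCGW is a reported TET2 binding-preference motif; sites matching it
    could in principle be converted more efficiently during enzymatic
    conversion.  Returns None at contig edges.
    """
    quad = _fetch(reference, chrom, pos - 1, pos + 2)
    if quad is None:
        return None
    if quad[1:3] != "CG":
        raise ValueError(f"{chrom}:{pos} is not a CpG")
    return quad[0] in "AC" and quad[3] in "AT"


def annotate_motifs(sites: pd.DataFrame, reference) -> pd.DataFrame:
    """Add motif, motif_gc and mcgw columns to a collapsed CpG table.

    Motifs containing N get NaN motif_gc (a partial GC% would bias the
    motif-GC bins).
    """
    motifs, gcs, mcgws = [], [], []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        motif = extract_motif(reference, chrom, int(pos))
        motifs.append(motif)
        if motif is None or "N" in motif:
            gcs.append(math.nan)
        else:
            gcs.append(gc_percent(motif))
        mcgws.append(classify_mcgw(reference, chrom, int(pos)))
    out = sites.copy()
    out["motif"] = motifs
    out["motif_gc"] = gcs
    out["mcgw"] = mcgws
    return out
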