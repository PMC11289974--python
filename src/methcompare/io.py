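"""Readers and writers for methylation formats, plus FASTQ rarefaction.

All internal coordinates are 1-based inclusive.  BED-dialect inputs
(bedMethyl, CpG-island BED) use 0-based half-open starts and are
converted on read.  Every text format is read and written transparently
through gzip when the path ends in ``.gz``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

VALID_METHODS = ("EM-seq", "WGBS", "EPIC", "ONT")

CYTOSINE_REPORT_COLUMNS = [
    "chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide",
]

BEDMETHYL_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "rgb", "coverage", "pct_meth",
]


class MethylParseError(ValueError):
    """A malformed line in a methylation text format."""


@dataclass(frozen=True)
class StrandedCytosineRecord:
    """One cytosine on one strand with methylated/unmethylated counts."""

    chrom: str
    pos: int  # 1-based on the strand's reference projection
    strand: str  # '+' Watson, '-' Crick
    n_meth: int
    n_unmeth: int
    context: str = "CG"
    trinucleotide: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("counts must be non-negative")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def beta(self) -> float:
        """Methylated fraction; NaN when the position is uncovered."""
        if self.coverage == 0:
            return float("nan")
        return self.n_meth / self.coverage


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one library/array sample."""

    sample_id: str
    method: str
    patient: str = ""
    visit: str = ""

    def __post_init__(self) -> None:
        if self.method not in VALID_METHODS:
            raise ValueError(
                f"method must be one of {VALID_METHODS}, got {self.method!r}"
            )


class BetaTable:
    """Positions x samples matrix of beta values with sample metadata.

    Parameters
    ----------
    beta
        DataFrame indexed by a ``(chrom, pos)`` MultiIndex, one column
        per sample, values in [0, 1] or NaN.
    samples
        Sequence of :class:`SampleInfo`, one per beta column, in order.
    coverage
        Optional matching DataFrame of non-negative read counts
        (absent for array samples).  Coverage 0 forces beta to NaN.
    """

    def __init__(
        self,
        beta: pd.DataFrame,
        samples: Sequence[SampleInfo],
        coverage: pd.DataFrame | None = None,
    ) -> None:
        if beta.index.nlevels != 2:
            raise ValueError("beta must be indexed by (chrom, pos)")
        if beta.index.has_duplicates:
            dups = beta.index[beta.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate position keys: {dups[:5]}")
        ids = [s.sample_id for s in samples]
        if list(beta.columns) != ids:
            raise ValueError("sample metadata does not match beta columns")
        values = beta.to_numpy(dtype=float)
        bad = (values < 0) | (values > 1)
        if np.any(bad & ~np.isnan(values)):
            raise ValueError("beta values outside [0, 1]")
        if coverage is not None:
            if coverage.shape != beta.shape or list(coverage.columns) != ids:
                raise ValueError("coverage shape does not match beta")
            cov = coverage.to_numpy(dtype=float)
            if np.nanmin(cov, initial=0) < 0:
                raise ValueError("coverage must be non-negative")
            # coverage 0 implies beta missing
            beta = beta.mask(coverage.fillna(0) == 0)
        self.beta = beta
        self.coverage = coverage
        self.samples = pd.DataFrame(
            {
                "method": [s.method for s in samples],
                "patient": [s.patient for s in samples],
                "visit": [s.visit for s in samples],
            },
            index=pd.Index(ids, name="sample_id"),
        )

    @property
    def positions(self) -> pd.MultiIndex:
        return self.beta.index

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def methods(self) -> pd.Series:
        return self.samples["method"]

    def write(self, path: str | Path) -> None:
        """Write the beta matrix as chrom, pos + one column per sample."""
        sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
        out = self.beta.reset_index()
        with open_text(path, "wt") as handle:
            out.to_csv(handle, sep=sep, index=False)


def open_text(path: str | Path, mode: str = "rt"):
    """Open a text file, transparently decompressing ``.gz`` paths."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_delimited(path: str | Path, n_columns: int, what: str) -> pd.DataFrame:
    """Read a headerless tab-delimited file as strings, checking width."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, dtype=str, comment="#",
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=range(n_columns))
    if df.shape[1] < n_columns:
        raise MethylParseError(
            f"{what}: expected >= {n_columns} columns, found {df.shape[1]}"
        )
    missing = df.iloc[:, :n_columns].isna().any(axis=1)
    if missing.any():
        line = int(missing.idxmax()) + 1
        raise MethylParseError(f"{what}: too few fields at line {line}")
    return df


def _to_int(series: pd.Series, name: str, what: str) -> pd.Series:
    numeric = pd.to_numeric(series, errors="coerce")
    bad = numeric.isna() | (numeric % 1 != 0)
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise MethylParseError(f"{what}: non-integer {name} at line {line}")
    return numeric.astype(np.int64)


def read_cytosine_report(
    path: str | Path,
    contexts: Iterable[str] | None = ("CG",),
) -> pd.DataFrame:
    """Read a bismark-style cytosine report into a stranded count table.

    The file is tab-delimited with columns chrom, pos (1-based),
    strand (+/-), methylated count, unmethylated count, context
    (CG/CHG/CHH), trinucleotide.  Lines whose context is not in
    ``contexts`` are dropped (pass ``None`` to keep all).

    Returns a DataFrame with :data:`CYTOSINE_REPORT_COLUMNS`.
    """
    raw = _read_delimited(path, 7, "cytosine report")
    if raw.empty:
        return pd.DataFrame(columns=CYTOSINE_REPORT_COLUMNS)
    df = raw.iloc[:, :7].copy()
    df.columns = CYTOSINE_REPORT_COLUMNS
    df["pos"] = _to_int(df["pos"], "position", "cytosine report")
    df["n_meth"] = _to_int(df["n_meth"], "methylated count", "cytosine report")
    df["n_unmeth"] = _to_int(df["n_unmeth"], "unmethylated count", "cytosine report")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(bad_strand.idxmax()) + 1
        raise MethylParseError(
            f"cytosine report: strand not +/- at line {line}"
        )
    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
        bad = (df["n_meth"] < 0) | (df["n_unmeth"] < 0)
        line = int(bad.idxmax()) + 1
        raise MethylParseError(f"cytosine report: negative count at line {line}")
    if contexts is not None:
        df = df[df["context"].isin(list(contexts))].reset_index(drop=True)
    return df


def write_cytosine_report(df: pd.DataFrame, path: str | Path) -> None:
    with open_text(path, "wt") as handle:
        df[CYTOSINE_REPORT_COLUMNS].to_csv(
            handle, sep="\t", header=False, index=False
        )


def read_bismark_cov(path: str | Path) -> pd.DataFrame:
    """Read a bismark coverage file (1-based start == end, CpG-only).

    Columns: chrom, start, end, percent methylated, count methylated,
    count unmethylated.  Returns chrom, pos, n_meth, n_unmeth, beta.
    """
    raw = _read_delimited(path, 6, "coverage file")
    if raw.empty:
        return pd.DataFrame(columns=["chrom", "pos", "n_meth", "n_unmeth", "beta"])
    df = pd.DataFrame(
        {
            "chrom": raw.iloc[:, 0],
            "pos": _to_int(raw.iloc[:, 1], "position", "coverage file"),
            "n_meth": _to_int(raw.iloc[:, 4], "methylated count", "coverage file"),
            "n_unmeth": _to_int(raw.iloc[:, 5], "unmethylated count", "coverage file"),
        }
    )
    cov = df["n_meth"] + df["n_unmeth"]
    df["beta"] = np.where(cov > 0, df["n_meth"] / cov.replace(0, 1), np.nan)
    return df


def read_bedmethyl(path: str | Path) -> pd.DataFrame:
    """Read a bedMethyl (BED9+2) per-position modified-base summary.

    Starts are 0-based half-open and converted to 1-based positions.
    Methylated counts are reconstructed from the rounded product of
    coverage and percent methylated (ties to even), so that
    n_meth + n_unmeth == coverage for every record.
    """
    raw = _read_delimited(path, 11, "bedMethyl")
    if raw.empty:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "n_meth", "n_unmeth", "coverage"]
        )
    start = _to_int(raw.iloc[:, 1], "start", "bedMethyl")
    if (start < 0).any():
        line = int((start < 0).idxmax()) + 1
        raise MethylParseError(f"bedMethyl: negative start at line {line}")
    coverage = _to_int(raw.iloc[:, 9], "coverage", "bedMethyl")
    pct = pd.to_numeric(raw.iloc[:, 10], errors="coerce")
    if pct.isna().any():
        line = int(pct.isna().idxmax()) + 1
        raise MethylParseError(f"bedMethyl: non-numeric percent at line {line}")
    if ((pct < 0) | (pct > 100)).any():
        bad = (pct < 0) | (pct > 100)
        line = int(bad.idxmax()) + 1
        raise MethylParseError(
            f"bedMethyl: percent outside [0, 100] at line {line}"
        )
    strand = raw.iloc[:, 5]
    bad_strand = ~strand.isin(["+", "-"])
    if bad_strand.any():
        line = int(bad_strand.idxmax()) + 1
        raise MethylParseError(f"bedMethyl: strand not +/- at line {line}")
    # numpy rint rounds half to even
    n_meth = np.rint(coverage.to_numpy() * pct.to_numpy() / 100.0).astype(np.int64)
    logger.debug("bedMethyl %s: converted 0-based starts to 1-based positions", path)
    return pd.DataFrame(
        {
            "chrom": raw.iloc[:, 0].to_numpy(),
            "pos": (start + 1).to_numpy(),
            "strand": strand.to_numpy(),
            "n_meth": n_meth,
            "n_unmeth": (coverage.to_numpy() - n_meth),
            "coverage": coverage.to_numpy(),
        }
    )


def read_beta_table(
    path: str | Path,
    samples: Sequence[SampleInfo],
    zero_based: bool = False,
) -> BetaTable:
    """Read a delimited beta matrix (chrom, pos, then one column per sample).

    ``zero_based=True`` adds 1 to every position on read (array manifests
    are frequently distributed 0-based).  Duplicate (chrom, pos) keys and
    betas outside [0, 1] raise ``ValueError``.
    """
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] != 2 + len(samples):
        raise ValueError(
            f"beta table has {df.shape[1] - 2} sample columns, "
            f"expected {len(samples)}"
        )
    chrom = df.iloc[:, 0].astype(str)
    pos = df.iloc[:, 1].astype(np.int64)
    if zero_based:
        pos = pos + 1
        logger.debug("beta table %s: adjusted 0-based positions to 1-based", path)
    beta = df.iloc[:, 2:].astype(float)
    beta.columns = [s.sample_id for s in samples]
    beta.index = pd.MultiIndex.from_arrays([chrom, pos], names=["chrom", "pos"])
    return BetaTable(beta, samples)


def _fastq_records(path: str | Path) -> list[tuple[str, str, str, str]]:
    out = []
    with pysam.FastxFile(str(path)) as handle:
        for rec in handle:
            out.append((rec.name, rec.comment or "", rec.sequence, rec.quality or ""))
    return out


def _write_fastq(records, path: str | Path) -> None:
    with open_text(path, "wt") as handle:
        for name, comment, seq, qual in records:
            header = f"@{name} {comment}".rstrip()
            handle.write(f"{header}\n{seq}\n+\n{qual}\n")


def subsample_read_pairs(
    r1: str | Path,
    r2: str | Path,
    out1: str | Path,
    out2: str | Path,
    target: int,
    seed: int,
) -> int:
    """Rarefy a FASTQ pair to exactly ``target`` read pairs.

    Pair indices are drawn uniformly without replacement with a seeded
    generator and applied identically to both mates, preserving pair
    integrity and original ordering.  Identical inputs, target and seed
    produce byte-identical output.  Rarefying every library to the depth
    of the shallowest removes coverage as a confounder in inter-library
    comparisons.

    Returns the number of pairs written.
    """
    recs1 = _fastq_records(r1)
    recs2 = _fastq_records(r2)
    if len(recs1) != len(recs2):
        raise ValueError(
            f"unpaired FASTQ files: {len(recs1)} vs {len(recs2)} records"
        )
    total = len(recs1)
    if target > total:
        raise ValueError(f"target {target} exceeds total pairs {total}")
    if target < 0:
        raise ValueError("target must be non-negative")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(total, size=target, replace=False))
    _write_fastq([recs1[i] for i in idx], out1)
    _write_fastq([recs2[i] for i in idx], out2)
    logger.info("subsampled %d of %d read pairs (seed=%d)", target, total, seed)
    return int(target)


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read BED intervals, converting to 1-based inclusive coordinates."""
    raw = _read_delimited(path, 3, "BED")
    if raw.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    start = _to_int(raw.iloc[:, 1], "start", "BED")
    end = _to_int(raw.iloc[:, 2], "end", "BED")
    if (start < 0).any() or (end <= start).any():
        bad = (start < 0) | (end <= start)
        line = int(bad.idxmax()) + 1
        raise MethylParseError(f"BED: invalid interval at line {line}")
    return pd.DataFrame(
        {"chrom": raw.iloc[:, 0].to_numpy(), "start": (start + 1).to_numpy(),
         "end": end.to_numpy()}
    )
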