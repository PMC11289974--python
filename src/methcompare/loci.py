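"""Reference rotation and coordinate conventions for multicopy loci.

Multicopy loci such as the human 45S rDNA repeat are circularly
permuted between reference builds and read technologies: long reads
need the upstream intergenic spacer in front of the transcribed region,
short reads only a short promoter stub.  Rotating the reference and
expressing positions in signed transcription coordinates (upstream
bases ..., -2, -1 then +1, +2, ... from the transcription start, with
no position 0) lets per-position results from differently anchored
references be compared directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx

from .io import open_text


@dataclass(frozen=True)
class CoordinateMap:
    """Bijection between positions of a sequence and its rotation.

    ``pivot`` bases were moved from the tail to the head; ``forward``
    maps an original 1-based position to its rotated position and
    ``inverse`` undoes it.
    """

    length: int
    pivot: int

    def _check(self, pos) -> np.ndarray:
        pos = np.asarray(pos, dtype=np.int64)
        if np.any(pos < 1) or np.any(pos > self.length):
            raise ValueError(f"position out of range 1..{self.length}")
        return pos

    def forward(self, pos):
        pos = self._check(pos)
        out = (pos - 1 + self.pivot) % self.length + 1
        return int(out) if out.ndim == 0 else out

    def inverse(self, pos):
        pos = self._check(pos)
        out = (pos - 1 - self.pivot) % self.length + 1
        return int(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        old = np.arange(1, self.length + 1)
        return pd.DataFrame({"old_pos": old, "new_pos": self.forward(old)})


def rotate_reference(seq: str, tail_len: int) -> tuple[str, CoordinateMap]:
    """Move the last ``tail_len`` bases of a sequence to its start.

    Returns the rotated sequence (tail followed by head — base multiset
    and length preserved) and the coordinate map from original to
    rotated positions.
    """
    if tail_len < 0 or tail_len > len(seq):
        raise ValueError(
            f"tail_len {tail_len} outside 0..{len(seq)}"
        )
    if tail_len in (0, len(seq)):
        rotated = seq
    else:
        rotated = seq[-tail_len:] + seq[:-tail_len]
    return rotated, CoordinateMap(length=len(seq), pivot=tail_len % max(len(seq), 1))


def rotate_fasta(
    path: str | Path, tail_len: int, out_path: str | Path, line_width: int = 60
) -> CoordinateMap:
    """Rotate a single-contig FASTA; multi-contig inputs are rejected."""
    fasta = pyfaidx.Fasta(str(path))
    names = list(fasta.keys())
    if len(names) != 1:
        raise ValueError(
            f"rotation needs a single-contig FASTA, found {len(names)} contigs"
        )
    seq = str(fasta[names[0]])
    rotated, cmap = rotate_reference(seq, tail_len)
    with open_text(out_path, "wt") as handle:
        handle.write(f">{names[0]} rotated tail_len={tail_len}\n")
        for i in range(0, len(rotated), line_width):
            handle.write(rotated[i : i + line_width] + "\n")
    return cmap


def to_transcription_coords(pos, upstream_len: int):
    """Signed transcription coordinate of a 1-based reference position.

    The first ``upstream_len`` bases map to -upstream_len .. -1 and the
    transcribed region starts at +1; there is no position 0.
    """
    pos_arr = np.asarray(pos, dtype=np.int64)
    if np.any(pos_arr < 1):
        raise ValueError("positions must be >= 1")
    out = np.where(pos_arr <= upstream_len, pos_arr - upstream_len - 1,
                   pos_arr - upstream_len)
    return int(out) if out.ndim == 0 else out


def from_transcription_coords(signed_pos, upstream_len: int):
    """Inverse of :func:`to_transcription_coords`."""
    sp = np.asarray(signed_pos, dtype=np.int64)
    if np.any(sp == 0):
        raise ValueError("transcription coordinates have no position 0")
    out = np.where(sp < 0, sp + upstream_len + 1, sp + upstream_len)
    if np.any(out < 1):
        raise ValueError("coordinate upstream of the reference start")
    return int(out) if out.ndim == 0 else out


def min_coverage_mask(
    sites: pd.DataFrame, min_cov: int = 50
) -> tuple[pd.DataFrame, int]:
    """Drop sites with coverage below ``min_cov`` (kept when equal).

    High-coverage masking is conservative for multicopy loci where all
    methods exceed several hundred fold.  Returns (retained, n_removed).
    """
    keep = sites["coverage"] >= min_cov
    return sites[keep].reset_index(drop=True), int((~keep).sum())
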