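"""Nucleotide-composition signatures and alignment utilities.

Tetranucleotide-frequency (TNF) vectors are the compositional signature used
for contig binning: contigs are tiled into 5-kbp windows and each window's
256 overlapping 4-mer counts are L1-normalized.  A trailing fragment shorter
than 1 kbp is merged into the previous window (or, for a short contig, the
whole contig forms one window if it reaches 1 kbp).  A canonical mode merges
reverse-complement 4-mer pairs into 136 strand-insensitive dimensions.

``trim_alignment`` removes alignment columns whose gap fraction exceeds a
threshold (default 30%, strictly greater) ahead of phylogenetic inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np

from . import config
from .errors import ValidationError

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

ALL_KMERS: tuple[str, ...] = tuple("".join(p) for p in product(_BASES, repeat=4))
_KMER_INDEX = {k: i for i, k in enumerate(ALL_KMERS)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


CANONICAL_KMERS: tuple[str, ...] = tuple(sorted({canonical_kmer(k) for k in ALL_KMERS}))
_CANONICAL_INDEX = {k: i for i, k in enumerate(CANONICAL_KMERS)}


def kmer_labels(canonical: bool = False) -> tuple[str, ...]:
    """Column labels of TNF vectors (256 raw or 136 canonical 4-mers)."""
    return CANONICAL_KMERS if canonical else ALL_KMERS


@dataclass
class TNFVector:
    """L1-normalized tetranucleotide frequencies of one contig window."""

    fragment_id: str
    contig_id: str
    start: int  # 1-based, inclusive
    end: int
    frequencies: np.ndarray
    n_valid_kmers: int

    @property
    def window_span_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def empty(self) -> bool:
        return self.n_valid_kmers == 0


def _window_bounds(length: int, window_bp: int, min_window_bp: int) -> list[tuple[int, int]]:
    if length < min_window_bp:
        return []
    starts = list(range(0, length, window_bp))
    bounds = [(s, min(s + window_bp, length)) for s in starts]
    if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < min_window_bp:
        last = bounds.pop()
        bounds[-1] = (bounds[-1][0], last[1])
    return bounds


def tnf_vectors(
    contig_id: str,
    sequence: str,
    window_bp: int = config.TNF_WINDOW_BP,
    min_window_bp: int = config.TNF_MIN_WINDOW_BP,
    canonical: bool = False,
) -> list[TNFVector]:
    """Tile a contig into windows and compute a TNF vector per window.

    4-mers containing ``N`` are skipped.  Sequences shorter than
    ``min_window_bp`` yield an empty list with a warning; an all-N window is
    kept but flagged empty (zero vector).
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"{contig_id}: non-nucleotide characters {sorted(bad)}")
    bounds = _window_bounds(len(seq), window_bp, min_window_bp)
    if not bounds:
        logger.warning("%s: shorter than %d bp; no TNF windows", contig_id, min_window_bp)
        return []
    index = _CANONICAL_INDEX if canonical else _KMER_INDEX
    dims = len(index)
    out = []
    for w, (lo, hi) in enumerate(bounds):
        counts = np.zeros(dims, dtype=float)
        valid = 0
        chunk = seq[lo:hi]
        for i in range(len(chunk) - 3):
            kmer = chunk[i : i + 4]
            if "N" in kmer:
                continue
            counts[index[canonical_kmer(kmer) if canonical else kmer]] += 1
            valid += 1
        if valid:
            counts /= valid
        out.append(
            TNFVector(
                fragment_id=f"{contig_id}|w{w}",
                contig_id=contig_id,
                start=lo + 1,
                end=hi,
                frequencies=counts,
                n_valid_kmers=valid,
            )
        )
    return out


def tnf_matrix(vectors: list[TNFVector], canonical: bool = False):
    """Stack TNF vectors into a fragments x kmers DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [v.frequencies for v in vectors],
        index=pd.Index([v.fragment_id for v in vectors], name="fragment_id"),
        columns=list(kmer_labels(canonical)),
    )


def trim_alignment(
    sequences: dict[str, str],
    max_gap_fraction: float = config.MAX_GAP_COLUMN_FRACTION,
    gap_char: str = "-",
) -> tuple[dict[str, str], list[int]]:
    """Drop alignment columns whose gap fraction exceeds ``max_gap_fraction``.

    The comparison is strictly greater (a column exactly at the threshold is
    retained).  Row order is preserved; the 0-based indices of removed
    columns are returned alongside the trimmed alignment.
    """
    if not sequences:
        return {}, []
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValidationError(f"aligned sequences have unequal lengths {sorted(lengths)}")
    arr = np.array([list(s) for s in sequences.values()])
    gap_fraction = (arr == gap_char).mean(axis=0)
    removed = np.nonzero(gap_fraction > max_gap_fraction)[0]
    keep = np.nonzero(gap_fraction <= max_gap_fraction)[0]
    trimmed = {
        name: "".join(arr[i, keep]) for i, name in enumerate(sequences)
    }
    return trimmed, removed.tolist()
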