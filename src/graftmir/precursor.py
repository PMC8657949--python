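"""Precursor window extraction and hairpin plausibility scoring.

For a called mature sequence, every exact genomic hit is expanded by a
flank (default 150 nt each side, clipped at contig ends) and oriented to
the hit strand; each window is scored by the maximum number of nested
base pairs (Watson-Crick plus G.U wobble, minimum loop 3) obtained by
dynamic programming.  Windows are ranked by pairs per nucleotide; no
hard accept/reject verdict is issued.  Transcripts containing a mature
sequence are classified by length into mature / pre / pri, where "pre"
additionally requires a hairpin-like pairing density (>= 0.25 pairs/nt
by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assign import GenomeIndex, Hit, match
from .io import as_dna, as_rna, revcomp

log = logging.getLogger("graftmir")

# pairable base combinations on the DNA alphabet (T stands for U):
# Watson-Crick A-U, G-C plus the G.U wobble
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


@dataclass
class PrecursorWindow:
    """A genomic window around one mature-sequence hit."""

    contig: str
    start: int            # 0-based half-open on the forward strand
    end: int
    strand: str
    sequence: str         # oriented to the hit strand
    mature_offset: int
    hairpin_pairs: int
    pairs_per_nt: float


def hairpin_pairs(sequence: str, min_loop: int = 3) -> int:
    """Maximum number of nested base pairs in a sequence.

    Base-pair maximization over nested structures (no pseudoknots) with
    hairpin loops of at least ``min_loop`` unpaired bases; allowed pairs
    are A-U, G-C and the G.U wobble.  The recurrence is evaluated
    diagonal by diagonal with numpy so windows of a few hundred nt score
    in well under a second.
    """
    seq = as_dna(sequence)
    n = len(seq)
    if n < min_loop + 2:
        return 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    # pairability matrix
    can = np.zeros((n, n), dtype=bool)
    for a, b in _PAIRS:
        can |= (arr[:, None] == ord(a)) & (arr[None, :] == ord(b))
    m = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        i = np.arange(0, n - span)
        j = i + span
        best = np.maximum(m[i + 1, j], m[i, j - 1])
        paired = np.where(can[i, j], m[i + 1, j - 1] + 1, 0)
        best = np.maximum(best, paired)
        for t in range(1, span):
            np.maximum(best, m[i, i + t] + m[i + t + 1, j], out=best)
        m[i, j] = best
    return int(m[0, n - 1])


def extract_windows(
    mature_seq: str,
    index: GenomeIndex,
    flank: int = 150,
    min_loop: int = 3,
) -> list[PrecursorWindow]:
    """Candidate precursor windows around every exact genomic hit.

    Each window spans the mature hit +/- ``flank`` nt (clipped at contig
    ends) and is oriented to the hit strand, so the mature sequence
    appears verbatim at ``mature_offset``.  Windows are returned ranked
    by pairs per nucleotide, best first.
    """
    mature = as_dna(mature_seq)
    hits = match(mature, index, max_mismatches=0)
    if not hits:
        log.warning(
            "extract_windows: %s not found in %s genome",
            as_rna(mature), index.species,
        )
        return []
    windows = []
    for hit in hits:
        contig_seq = index.contigs[hit.contig]
        ws = max(0, hit.start - flank)
        we = min(len(contig_seq), hit.end + flank)
        segment = contig_seq[ws:we]
        if hit.strand == "+":
            seq, offset = segment, hit.start - ws
        else:
            seq, offset = revcomp(segment), we - hit.end
        assert seq[offset : offset + len(mature)] == (
            mature if hit.strand == "+" else mature
        )
        pairs = hairpin_pairs(seq, min_loop)
        windows.append(
            PrecursorWindow(
                contig=hit.contig,
                start=ws,
                end=we,
                strand=hit.strand,
                sequence=seq,
                mature_offset=offset,
                hairpin_pairs=pairs,
                pairs_per_nt=pairs / len(seq),
            )
        )
    windows.sort(key=lambda w: (-w.pairs_per_nt, w.contig, w.start))
    return windows


def classify_transcript(
    sequence: str,
    mature_seq: str,
    pre_max: int = 300,
    min_pairs_per_nt: float = 0.25,
    min_loop: int = 3,
) -> str:
    """Classify a transcript containing a mature miRNA as pri/pre/mature.

    mature: length equals the mature length; pre: at most ``pre_max`` nt
    with hairpin pairing density >= ``min_pairs_per_nt``; pri otherwise.
    """
    seq = as_dna(sequence)
    mature = as_dna(mature_seq)
    if mature not in seq:
        raise ValueError("mature sequence not contained in transcript")
    if len(seq) == len(mature):
        return "mature"
    if len(seq) > pre_max:
        return "pri"
    if hairpin_pairs(seq, min_loop) / len(seq) >= min_pairs_per_nt:
        return "pre"
    return "pri"


def windows_table(
    mature_seq: str, windows: Sequence[PrecursorWindow]
) -> pd.DataFrame:
    """Report rows for one mature sequence (coordinates 1-based inclusive)."""
    rows = []
    for w in windows:
        rows.append(
            {
                "mature": as_rna(mature_seq),
                "contig": w.contig,
                "start": w.start + 1,
                "end": w.end,
                "strand": w.strand,
                "length": len(w.sequence),
                "mature_offset": w.mature_offset,
                "hairpin_pairs": w.hairpin_pairs,
                "pairs_per_nt": round(w.pairs_per_nt, 4),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["mature", "contig", "start", "end", "strand", "length",
                 "mature_offset", "hairpin_pairs", "pairs_per_nt"],
    )
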