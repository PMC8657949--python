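"""Read cleaning and tag collapsing.

A raw small-RNA read is cleaned by locating the 3' adaptor (leftmost
exact match of the adaptor's first min(8, len) bases), trimming at that
position, and keeping the insert only if it is 18-30 nt long with at
most three unknown bases.  Rejections are returned as reasons, never
raised.  Clean inserts are collapsed to unique *tags* carrying one read
count per sample; per-sample accounting conserves total read counts.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import PipelineConfig

log = logging.getLogger("graftmir")

REJECT_NO_ADAPTOR = "no_adaptor"
REJECT_LENGTH = "length"
REJECT_UNKNOWN_BASES = "unknown_bases"


@dataclass
class CleanStats:
    """Per-sample read-cleaning accounting (totals conserved)."""

    total_reads: int = 0
    clean_reads: int = 0
    removed_no_adaptor: int = 0
    removed_length: int = 0
    removed_unknown_bases: int = 0

    def check(self) -> None:
        removed = (
            self.removed_no_adaptor
            + self.removed_length
            + self.removed_unknown_bases
        )
        if self.total_reads != self.clean_reads + removed:
            raise AssertionError("clean-read accounting does not conserve totals")


def clean_read(raw_sequence: str, config: PipelineConfig) -> tuple[str | None, str | None]:
    """Clean one raw read; returns ``(insert, None)`` or ``(None, reason)``.

    The adaptor seed is the first min(8, len(adaptor)) adaptor bases; its
    leftmost occurrence marks the insert end.  The unknown-base filter is
    evaluated on the trimmed insert.
    """
    adaptor = config.adaptor_3p
    seed = adaptor[: min(8, len(adaptor))]
    pos = raw_sequence.find(seed)
    if pos < 0:
        return None, REJECT_NO_ADAPTOR
    insert = raw_sequence[:pos]
    if not (config.min_len <= len(insert) <= config.max_len):
        return None, REJECT_LENGTH
    if insert.count("N") > config.max_unknown_bases:
        return None, REJECT_UNKNOWN_BASES
    return insert, None


def clean_sample(
    reads: Iterable[str], config: PipelineConfig
) -> tuple[Counter, CleanStats]:
    """Clean a sample's raw read sequences into a Counter of inserts."""
    inserts: Counter = Counter()
    stats = CleanStats()
    for seq in reads:
        stats.total_reads += 1
        insert, reason = clean_read(seq, config)
        if insert is not None:
            stats.clean_reads += 1
            inserts[insert] += 1
        elif reason == REJECT_NO_ADAPTOR:
            stats.removed_no_adaptor += 1
        elif reason == REJECT_LENGTH:
            stats.removed_length += 1
        else:
            stats.removed_unknown_bases += 1
    stats.check()
    return inserts, stats


def collapse(inserts_per_sample: Mapping[str, Counter]) -> pd.DataFrame:
    """Collapse per-sample insert counters into a tag table.

    Returns a DataFrame with a ``sequence`` column plus one integer count
    column per sample (in the given sample order), sorted by sequence so
    the result is independent of read order.
    """
    sample_ids = list(inserts_per_sample)
    sequences = sorted(set().union(*[set(c) for c in inserts_per_sample.values()]) if sample_ids else set())
    data = {"sequence": sequences}
    for sid in sample_ids:
        counter = inserts_per_sample[sid]
        data[sid] = [counter.get(seq, 0) for seq in sequences]
    table = pd.DataFrame(data, columns=["sequence"] + sample_ids)
    for sid in sample_ids:
        table[sid] = table[sid].astype(int)
    return table


def percent(numerator: float, denominator: float) -> float:
    """100*num/den rounded half-away-from-zero to 2 decimals; NaN if den=0."""
    if denominator == 0:
        return math.nan
    q = (Decimal(numerator) * 100) / Decimal(denominator)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format_percent(value: float) -> str:
    return "NA" if math.isnan(value) else f"{value:.2f}"


def clean_stats_table(stats_per_sample: Mapping[str, CleanStats]) -> pd.DataFrame:
    """Cleaning accounting table (one row per sample)."""
    rows = []
    for sid, st in stats_per_sample.items():
        rows.append(
            {
                "sample_id": sid,
                "total_reads": st.total_reads,
                "clean_reads": st.clean_reads,
                "clean_pct": percent(st.clean_reads, st.total_reads)
                if st.total_reads
                else math.nan,
                "removed_no_adaptor": st.removed_no_adaptor,
                "removed_length": st.removed_length,
                "removed_unknown_bases": st.removed_unknown_bases,
            }
        )
        log.info(
            "clean %s: %d raw -> %d clean (no_adaptor %d, length %d, unknown %d)",
            sid, st.total_reads, st.clean_reads, st.removed_no_adaptor,
            st.removed_length, st.removed_unknown_bases,
        )
    return pd.DataFrame(rows)
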