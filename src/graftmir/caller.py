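"""Mobile miRNA candidate calling.

The stringent presence/absence rule: a partner-genome-derived tag is
called graft-transmissible iff it has zero reads in every self-graft
control replicate and at least ``min_hetero_reads`` reads summed over
the heterograft replicates (presence in every heterograft replicate is
not required).  Candidates whose exact sequence also occurs in the
tissue species' own mature catalog are flagged ambiguous_shared and
excluded from the called set: their origin cannot be decided.  Family
labels come from the nearest equal-length catalog entry (at most 3
substitutions, sense or antisense); the antisense orientation is kept
as a strand note, distinguishing e.g. a mature guide from the star
strand travelling in the opposite polarity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io import ManifestError, PipelineConfig, Sample, as_dna, as_rna, revcomp

log = logging.getLogger("graftmir")

STATUS_CALLED = "called"
STATUS_REJECTED_CONTROL = "rejected_control"
STATUS_REJECTED_ABSENT = "rejected_absent"
STATUS_AMBIGUOUS_SHARED = "ambiguous_shared"

FAMILY_UNKNOWN = "unknown"
_FAMILY_RE = re.compile(r"(mir)(\d+)", re.IGNORECASE)


@dataclass
class MobileCandidate:
    """A partner-derived sequence with its mobility evidence."""

    sequence: str                 # DNA internally; rendered as RNA in reports
    hetero_counts: tuple[int, ...]
    control_counts: tuple[int, ...]
    status: str
    family: str = FAMILY_UNKNOWN
    strand_note: str = "sense"    # orientation relative to the best catalog match
    best_match: str | None = None
    match_distance: int | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def rna(self) -> str:
        return as_rna(self.sequence)


def family_from_name(name: str) -> str:
    """Family label from a catalog entry name (e.g. nb-miR395a -> miR395)."""
    m = _FAMILY_RE.search(name)
    return f"miR{m.group(2)}" if m else name


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def call_candidates(
    partner_tags: pd.DataFrame,
    samples: Sequence[Sample],
    config: PipelineConfig,
) -> list[MobileCandidate]:
    """Apply the control-absence rule to partner-assigned tag counts.

    ``partner_tags`` holds a ``sequence`` column plus one count column
    per sample; ``samples`` supplies the heterograft/control grouping.
    Replicate vectors are ordered by replicate number, so calls are
    invariant to manifest row order.
    """
    hetero = sorted(
        (s for s in samples if s.graft_type == "heterograft"),
        key=lambda s: (s.replicate, s.sample_id),
    )
    control = sorted(
        (s for s in samples if s.graft_type == "homograft"),
        key=lambda s: (s.replicate, s.sample_id),
    )
    if not control:
        raise ManifestError(
            "mobility calling requires >= 1 self-graft control replicate"
        )
    if not hetero:
        raise ManifestError("mobility calling requires >= 1 heterograft replicate")

    candidates = []
    for row in partner_tags.itertuples(index=False):
        h = tuple(int(getattr(row, s.sample_id)) for s in hetero)
        c = tuple(int(getattr(row, s.sample_id)) for s in control)
        if any(c):
            status = STATUS_REJECTED_CONTROL
        elif (
            sum(h) >= config.min_hetero_reads
            and sum(x > 0 for x in h) >= config.min_hetero_replicates
        ):
            status = STATUS_CALLED
        else:
            status = STATUS_REJECTED_ABSENT
        candidates.append(
            MobileCandidate(
                sequence=as_dna(row.sequence),
                hetero_counts=h,
                control_counts=c,
                status=status,
            )
        )
    n_called = sum(c.status == STATUS_CALLED for c in candidates)
    log.info(
        "call: %d partner tags -> %d called, %d rejected_control, %d rejected_absent",
        len(candidates), n_called,
        sum(c.status == STATUS_REJECTED_CONTROL for c in candidates),
        sum(c.status == STATUS_REJECTED_ABSENT for c in candidates),
    )
    return candidates


def annotate_family(
    sequence: str,
    catalog: Mapping[str, str],
    max_distance: int = 3,
) -> tuple[str, str, str | None, int | None]:
    """Best-matching family for a sequence against a mature catalog.

    Returns ``(family, strand_note, entry_name, distance)``.  Only
    equal-length entries are compared (substitution distance); ties are
    broken lexicographically by entry name, sense before antisense.  No
    entry within ``max_distance`` substitutions -> family "unknown".
    """
    sequence = as_dna(sequence)
    best: tuple[int, str, int] | None = None  # (distance, name, 0=sense/1=antisense)
    ties = 0
    for name in sorted(catalog):
        entry = catalog[name]
        if len(entry) != len(sequence):
            continue
        for strand_rank, query in ((0, sequence), (1, revcomp(sequence))):
            cand = (_hamming(query, entry), name, strand_rank)
            if best is None or cand < best:
                if best is not None and cand[0] == best[0]:
                    ties += 1
                best = cand
            elif best is not None and cand[0] == best[0]:
                ties += 1
    if best is None or best[0] > max_distance:
        return FAMILY_UNKNOWN, "sense", None, None
    distance, name, strand_rank = best
    if ties:
        log.info(
            "annotate_family: %d equal-distance catalog matches for %s; "
            "kept %s (lexicographic tie-break)",
            ties + 1, as_rna(sequence), name,
        )
    return (
        family_from_name(name),
        "sense" if strand_rank == 0 else "antisense",
        name,
        distance,
    )


def annotate_candidates(
    candidates: Sequence[MobileCandidate],
    catalog: Mapping[str, str],
    max_distance: int = 3,
) -> list[MobileCandidate]:
    """Fill family/strand_note for every candidate (in place; returned)."""
    for cand in candidates:
        family, strand, name, dist = annotate_family(
            cand.sequence, catalog, max_distance
        )
        cand.family = family
        cand.strand_note = strand
        cand.best_match = name
        cand.match_distance = dist
    return list(candidates)


def flag_shared(
    candidates: Sequence[MobileCandidate],
    tissue_catalog: Mapping[str, str],
) -> list[MobileCandidate]:
    """Demote candidates sharing an exact sense sequence with the tissue
    species' own catalog to ambiguous_shared.

    Identity is sense-strand only: a candidate whose reverse complement
    (but not itself) occurs in the other catalog keeps its status and is
    distinguished by its antisense strand note instead.
    """
    own_seqs = {as_dna(s) for s in tissue_catalog.values()}
    for cand in candidates:
        if cand.sequence in own_seqs:
            cand.status = STATUS_AMBIGUOUS_SHARED
    return list(candidates)


def count_families(candidates: Sequence[MobileCandidate]) -> int:
    """Number of distinct miRNA families among called candidates."""
    return len({c.family for c in candidates if c.status == STATUS_CALLED})


def candidates_table(
    candidates: Sequence[MobileCandidate],
    hetero_ids: Sequence[str],
    control_ids: Sequence[str],
) -> pd.DataFrame:
    """Candidate report table: RNA sequence, length,
    family, per-replicate heterograft and control counts, plus status
    and strand note."""
    rows = []
    for c in candidates:
        row = {
            "sequence": c.rna,
            "length": c.length,
            "family": c.family,
            "strand_note": c.strand_note,
        }
        for sid, n in zip(hetero_ids, c.hetero_counts):
            row[sid] = n
        for sid, n in zip(control_ids, c.control_counts):
            row[sid] = n
        row["status"] = c.status
        row["best_match"] = c.best_match or ""
        rows.append(row)
    cols = ["sequence", "length", "family", "strand_note",
            *hetero_ids, *control_ids, "status", "best_match"]
    return pd.DataFrame(rows, columns=cols)
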