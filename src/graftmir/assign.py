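"""Annotation filtering and hierarchical two-genome exact-match assignment.

Tags are first removed if they (or their reverse complement) occur
verbatim inside any annotation sequence (rRNA/tRNA/snRNA/snoRNA/repeat
stand-ins); the survivors are the total sRNA set.  Each surviving tag is
then mapped full-length against the tissue's own genome via a k-mer
seed index; only tags with no own-genome hit are re-mapped against the
graft partner's genome.  A tag with an own-genome hit is therefore never
categorized as partner-derived, which is what absorbs cross-species
shared sequences and makes their mobility undecidable.

Matching supports 0 (default) or 1 substitutions.  With 1 mismatch the
seeding enumerates every 1-substitution variant of the tag's first
k-mer in addition to the exact first k-mer, which is complete for a
single substitution at any tag length >= k (an offset-k second seed is
also used when the tag spans two full k-mers).

Coordinates are 0-based half-open internally and rendered 1-based
inclusive in reports.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .io import read_fasta, revcomp
from .readqc import CleanStats, percent

log = logging.getLogger("graftmir")

CAT_ANNOTATION = "annotation"
CAT_OWN = "own"
CAT_PARTNER = "partner"
CAT_UNASSIGNED = "unassigned"

_BASES = "ACGT"


@dataclass(frozen=True)
class Hit:
    """A full-length genome match of a tag (0-based half-open interval)."""

    contig: str
    start: int
    end: int
    strand: str  # + | -
    mismatches: int


class GenomeIndex:
    """Exact-match k-mer index over the forward strand of one genome.

    Minus-strand hits are found by matching the reverse complement of
    the query against the forward index.  k-mers containing N are not
    indexed; contigs shorter than k are skipped with a warning.
    """

    def __init__(self, species: str, contigs: Mapping[str, str], k: int = 12):
        if k < 8:
            raise ValueError("k must be >= 8")
        self.species = species
        self.k = k
        self.contigs = dict(contigs)
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.contigs.items():
            if len(seq) < k:
                log.warning(
                    "index %s: contig %s shorter than k=%d, skipped",
                    species, name, k,
                )
                continue
            for off in range(len(seq) - k + 1):
                kmer = seq[off : off + k]
                if "N" in kmer:
                    continue
                self.kmers.setdefault(kmer, []).append((name, off))

    @classmethod
    def from_fasta(cls, species: str, path: str | Path, k: int = 12) -> "GenomeIndex":
        return cls(species, read_fasta(path), k)


def _hamming(a: str, b: str, limit: int) -> int:
    """Substitution count between equal-length strings, capped at limit+1."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def _seed_kmers(query: str, k: int, max_mismatches: int) -> list[tuple[int, str]]:
    """(offset, k-mer) seeds guaranteeing a hit with <= max_mismatches."""
    seeds = [(0, query[:k])]
    if max_mismatches >= 1:
        if len(query) >= 2 * k:
            seeds.append((k, query[k : 2 * k]))
        # one substitution may fall inside the first k-mer: enumerate its
        # 1-substitution variants so seeding stays complete for short tags
        first = query[:k]
        for i, base in enumerate(first):
            for alt in _BASES:
                if alt != base:
                    seeds.append((0, first[:i] + alt + first[i + 1 :]))
    return seeds


def match(seq: str, index: GenomeIndex, max_mismatches: int = 0) -> list[Hit]:
    """All full-length genome hits of a tag with <= max_mismatches subs."""
    if len(seq) < index.k:
        raise ValueError(f"tag shorter than k={index.k}: {seq!r}")
    found: dict[tuple[str, int, str], int] = {}
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        n = len(query)
        for off, kmer in _seed_kmers(query, index.k, max_mismatches):
            for contig, pos in index.kmers.get(kmer, ()):
                start = pos - off
                if start < 0 or start + n > len(index.contigs[contig]):
                    continue
                key = (contig, start, strand)
                if key in found:
                    continue
                d = _hamming(index.contigs[contig][start : start + n], query, max_mismatches)
                if d <= max_mismatches:
                    found[key] = d
    return sorted(
        (
            Hit(contig, start, start + len(seq), strand, d)
            for (contig, start, strand), d in found.items()
        ),
        key=lambda h: (h.contig, h.start, h.strand),
    )


# ---------------------------------------------------------------------------
# Annotation filtering
# ---------------------------------------------------------------------------

def filter_annotations(
    tags: pd.DataFrame, annotations: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split tags into (kept, removed) by exact annotation substring match.

    A tag is removed iff its sequence or its reverse complement occurs
    verbatim inside any annotation sequence.  The kept tags are the
    "total sRNA" set entering genome mapping.
    """
    blob = "\n".join(annotations.values())
    removed_mask = [
        (seq in blob) or (revcomp(seq) in blob) for seq in tags["sequence"]
    ]
    removed_mask = pd.Series(removed_mask, index=tags.index)
    return tags[~removed_mask].copy(), tags[removed_mask].copy()


# ---------------------------------------------------------------------------
# Hierarchical assignment
# ---------------------------------------------------------------------------

@dataclass
class AssignmentResult:
    """Per-tag categories and per-sample read accounting.

    ``per_tag`` has one row per tag: sequence, category (annotation /
    own / partner / unassigned), hit counts, and the first hit's
    coordinates (1-based inclusive) in the genome of its category.
    ``accounting`` has one row per sample with read-weighted totals; the
    invariants total_srna = mapped_own + unmapped_own and unmapped_own =
    remapped_partner + unassigned hold by construction.
    """

    per_tag: pd.DataFrame
    accounting: pd.DataFrame
    own_species: str
    partner_species: str


def assign(
    tags: pd.DataFrame,
    own_index: GenomeIndex,
    partner_index: GenomeIndex,
    annotations: Mapping[str, str],
    sample_ids: Sequence[str],
    max_mismatches: int = 0,
    clean_stats: Mapping[str, CleanStats] | None = None,
) -> AssignmentResult:
    """Annotation-filter then hierarchically assign tags to the two genomes."""
    kept, removed = filter_annotations(tags, annotations)

    rows = []
    for seq in removed["sequence"]:
        rows.append(
            dict(sequence=seq, category=CAT_ANNOTATION, n_own_hits=0,
                 n_partner_hits=0, contig="", start=0, end=0, strand="",
                 mismatches=-1)
        )
    for seq in kept["sequence"]:
        own_hits = match(seq, own_index, max_mismatches)
        if own_hits:
            cat, hits, n_own, n_partner = CAT_OWN, own_hits, len(own_hits), 0
        else:
            partner_hits = match(seq, partner_index, max_mismatches)
            if partner_hits:
                cat, hits, n_own, n_partner = (
                    CAT_PARTNER, partner_hits, 0, len(partner_hits)
                )
            else:
                cat, hits, n_own, n_partner = CAT_UNASSIGNED, [], 0, 0
        best = hits[0] if hits else None
        rows.append(
            dict(
                sequence=seq,
                category=cat,
                n_own_hits=n_own,
                n_partner_hits=n_partner,
                contig=best.contig if best else "",
                start=best.start + 1 if best else 0,   # 1-based in reports
                end=best.end if best else 0,           # inclusive end
                strand=best.strand if best else "",
                mismatches=best.mismatches if best else -1,
            )
        )
    per_tag = pd.DataFrame(
        rows,
        columns=["sequence", "category", "n_own_hits", "n_partner_hits",
                 "contig", "start", "end", "strand", "mismatches"],
    ).sort_values("sequence", kind="mergesort", ignore_index=True)

    counts = tags.set_index("sequence")[list(sample_ids)]
    cat_of = per_tag.set_index("sequence")["category"]
    acc_rows = []
    for sid in sample_ids:
        by_cat = counts[sid].groupby(cat_of).sum()
        n_ann = int(by_cat.get(CAT_ANNOTATION, 0))
        n_own = int(by_cat.get(CAT_OWN, 0))
        n_partner = int(by_cat.get(CAT_PARTNER, 0))
        n_unassigned = int(by_cat.get(CAT_UNASSIGNED, 0))
        n_total = n_own + n_partner + n_unassigned
        row = {
            "sample_id": sid,
            "annotation_removed": n_ann,
            "total_srna": n_total,
            "mapped_own": n_own,
            "mapped_own_pct": percent(n_own, n_total) if n_total else math.nan,
            "unmapped_own": n_partner + n_unassigned,
            "remapped_partner": n_partner,
            "remapped_partner_pct": percent(n_partner, n_total)
            if n_total
            else math.nan,
            "unassigned": n_unassigned,
        }
        if clean_stats and sid in clean_stats:
            st = clean_stats[sid]
            row = {
                "sample_id": sid,
                "total_reads": st.total_reads,
                "clean_reads": st.clean_reads,
                "clean_pct": percent(st.clean_reads, st.total_reads)
                if st.total_reads
                else math.nan,
                **{k: v for k, v in row.items() if k != "sample_id"},
            }
        acc_rows.append(row)
        log.info(
            "assign %s: %d sRNA reads, %d own (%.2f%%), %d re-mapped to "
            "partner, %d unassigned, %d annotation-removed",
            sid, n_total, n_own,
            0.0 if n_total == 0 else 100 * n_own / n_total,
            n_partner, n_unassigned, n_ann,
        )
    accounting = pd.DataFrame(acc_rows)
    return AssignmentResult(
        per_tag=per_tag,
        accounting=accounting,
        own_species=own_index.species,
        partner_species=partner_index.species,
    )
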