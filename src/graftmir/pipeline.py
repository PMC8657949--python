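"""End-to-end orchestration: clean -> assign -> call, per graft direction.

A *direction* is one tissue role (scion or rootstock): its samples share
a tissue species (the "own" genome) and the heterograft samples name
the partner species whose genome unmapped tags are re-mapped against.
Running both directions with roles swapped covers root-to-shoot and
shoot-to-root movement with the identical code path.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .assign import CAT_PARTNER, AssignmentResult, GenomeIndex, assign
from .caller import (
    MobileCandidate,
    annotate_candidates,
    call_candidates,
    candidates_table,
    count_families,
    flag_shared,
)
from .io import ManifestError, PipelineConfig, Sample, read_fastq, write_report
from .readqc import CleanStats, clean_sample, clean_stats_table, collapse

log = logging.getLogger("graftmir")


def clean_libraries(
    samples: Sequence[Sample],
    config: PipelineConfig,
    reads_by_sample: Mapping[str, Iterable[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, CleanStats]]:
    """Clean every sample's reads and collapse them into one tag table.

    Reads come from each sample's FASTQ unless ``reads_by_sample``
    supplies raw sequences directly (the in-memory path used when
    chaining straight from the simulator).
    """
    inserts: dict[str, Counter] = {}
    stats: dict[str, CleanStats] = {}
    for sample in samples:
        if reads_by_sample is not None:
            raw = reads_by_sample[sample.sample_id]
        else:
            raw = (seq for _, seq, _ in read_fastq(sample.fastq_path))
        inserts[sample.sample_id], stats[sample.sample_id] = clean_sample(raw, config)
    return collapse(inserts), stats


@dataclass
class DirectionResult:
    """One direction's assignment, accounting and mobility calls."""

    tissue_role: str
    own_species: str
    partner_species: str
    assignment: AssignmentResult
    candidates: list[MobileCandidate]
    hetero_ids: list[str]
    control_ids: list[str]

    @property
    def called(self) -> list[MobileCandidate]:
        return [c for c in self.candidates if c.status == "called"]

    @property
    def n_families(self) -> int:
        return count_families(self.candidates)

    def candidates_table(self) -> pd.DataFrame:
        return candidates_table(self.candidates, self.hetero_ids, self.control_ids)


def run_direction(
    tissue_role: str,
    samples: Sequence[Sample],
    tags: pd.DataFrame,
    genome_indexes: Mapping[str, GenomeIndex],
    annotations: Mapping[str, str],
    catalogs: Mapping[str, Mapping[str, str]],
    config: PipelineConfig,
    clean_stats: Mapping[str, CleanStats] | None = None,
) -> DirectionResult:
    """Assign and call mobile candidates for one tissue role."""
    group = [s for s in samples if s.tissue_role == tissue_role]
    if not group:
        raise ManifestError(f"no samples with tissue_role {tissue_role!r}")
    own_species = {s.tissue_species for s in group}
    if len(own_species) != 1:
        raise ManifestError(
            f"{tissue_role} samples span several tissue species: {sorted(own_species)}"
        )
    own = own_species.pop()
    partners = {s.partner_species for s in group if s.graft_type == "heterograft"}
    if len(partners) != 1:
        raise ManifestError(
            f"{tissue_role} heterograft samples must share one partner species, "
            f"got {sorted(partners)}"
        )
    partner = partners.pop()

    sample_ids = [s.sample_id for s in group]
    sub = tags[["sequence"] + sample_ids]
    sub = sub[sub[sample_ids].sum(axis=1) > 0].reset_index(drop=True)

    assignment = assign(
        sub,
        genome_indexes[own],
        genome_indexes[partner],
        annotations,
        sample_ids,
        max_mismatches=config.max_mismatches,
        clean_stats=clean_stats,
    )
    partner_seqs = assignment.per_tag.loc[
        assignment.per_tag["category"] == CAT_PARTNER, "sequence"
    ]
    partner_tags = sub[sub["sequence"].isin(set(partner_seqs))].reset_index(drop=True)
    candidates = call_candidates(partner_tags, group, config)
    annotate_candidates(candidates, catalogs[partner])
    flag_shared(candidates, catalogs[own])
    hetero_ids = [
        s.sample_id
        for s in sorted(
            (s for s in group if s.graft_type == "heterograft"),
            key=lambda s: (s.replicate, s.sample_id),
        )
    ]
    control_ids = [
        s.sample_id
        for s in sorted(
            (s for s in group if s.graft_type == "homograft"),
            key=lambda s: (s.replicate, s.sample_id),
        )
    ]
    result = DirectionResult(
        tissue_role=tissue_role,
        own_species=own,
        partner_species=partner,
        assignment=assignment,
        candidates=candidates,
        hetero_ids=hetero_ids,
        control_ids=control_ids,
    )
    log.info(
        "direction %s (%s tissue, partner %s): %d called in %d families",
        tissue_role, own, partner, len(result.called), result.n_families,
    )
    return result


def run_all(
    samples: Sequence[Sample],
    genomes: Mapping[str, Mapping[str, str]],
    annotations: Mapping[str, str],
    catalogs: Mapping[str, Mapping[str, str]],
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    reads_by_sample: Mapping[str, Iterable[str]] | None = None,
) -> dict[str, DirectionResult]:
    """Run the whole pipeline for every tissue role present.

    With ``out_dir`` the tag table, cleaning stats and per-direction
    assignment/accounting/candidate reports are written as TSV.
    """
    tags, stats = clean_libraries(samples, config, reads_by_sample)
    indexes = {
        species: GenomeIndex(species, contigs, config.k)
        for species, contigs in genomes.items()
    }
    results: dict[str, DirectionResult] = {}
    for role in sorted({s.tissue_role for s in samples}):
        results[role] = run_direction(
            role, samples, tags, indexes, annotations, catalogs, config, stats
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(tags, out / "tags.tsv", sort_by=["sequence"])
        write_report(clean_stats_table(stats), out / "clean_stats.tsv",
                     sort_by=["sample_id"])
        for role, res in results.items():
            write_report(res.assignment.per_tag, out / f"assignment_{role}.tsv",
                         sort_by=["sequence"])
            write_report(res.assignment.accounting, out / f"accounting_{role}.tsv",
                         sort_by=["sample_id"])
            write_report(res.candidates_table(), out / f"candidates_{role}.tsv",
                         sort_by=["status", "family", "sequence"])
    return results
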