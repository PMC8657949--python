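"""Readers, writers, sample manifest and pipeline configuration.

All sequences are held internally in the DNA alphabet (A, C, G, T, N);
RNA inputs (mature miRNA catalogs are conventionally printed with U) are
converted on read, and reports render miRNA sequences back with U.

The sample manifest is a TSV with the columns

    sample_id  tissue_species  partner_species  graft_type  tissue_role
    replicate  fastq_path

where ``graft_type`` is ``heterograft`` or ``homograft`` and
``tissue_role`` is ``scion`` or ``rootstock``.  Homograft samples act as
the self-graft negative controls for the mobility call.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import IO, Iterator, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger("graftmir")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GRAFT_TYPES = ("heterograft", "homograft")
TISSUE_ROLES = ("scion", "rootstock")

MANIFEST_COLUMNS = (
    "sample_id",
    "tissue_species",
    "partner_species",
    "graft_type",
    "tissue_role",
    "replicate",
    "fastq_path",
)


class FormatError(ValueError):
    """A malformed input file (FASTQ/FASTA/TSV)."""


class ManifestError(ValueError):
    """An invalid sample manifest."""


class ConfigError(ValueError):
    """An invalid pipeline configuration."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def as_dna(seq: str) -> str:
    """Uppercase and convert U to T (internal canonical alphabet)."""
    return seq.upper().replace("U", "T")


def as_rna(seq: str) -> str:
    """Render an internal DNA sequence as RNA (T to U) for reports."""
    return seq.upper().replace("T", "U")


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Stream ``(read_id, sequence, quality)`` from a 4-line FASTQ file.

    Sequences are uppercased with U normalized to T.  A malformed record
    (sequence/quality length mismatch, truncated record) raises
    :class:`FormatError` naming the offending record number.
    """
    with _open_text(path) as fh:
        parser = FastqGeneralIterator(fh)
        record_no = 0
        while True:
            try:
                title, seq, qual = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise FormatError(
                    f"malformed FASTQ record {record_no + 1} in {path}: {exc}"
                ) from exc
            record_no += 1
            if len(seq) != len(qual):
                raise FormatError(
                    f"malformed FASTQ record {record_no} in {path}: "
                    "sequence and quality lengths differ"
                )
            yield title.split()[0] if title else "", as_dna(seq), qual


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``name -> sequence`` map.

    Names are taken up to the first whitespace; multi-line sequences are
    concatenated; duplicate names are fatal.
    """
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in out:
                raise FormatError(f"duplicate FASTA name {record.id!r} in {path}")
            out[record.id] = as_dna(str(record.seq))
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, rna: bool = False) -> None:
    """Write a ``name -> sequence`` map as FASTA (optionally rendered as RNA)."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{as_rna(seq) if rna else seq}\n")


def write_fastq(reads: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Sample manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sample:
    """One sequenced library: a tissue of one graft member."""

    sample_id: str
    tissue_species: str
    partner_species: str
    graft_type: str      # heterograft | homograft
    tissue_role: str     # scion | rootstock
    replicate: int
    fastq_path: str

    def __post_init__(self) -> None:
        if self.graft_type not in GRAFT_TYPES:
            raise ManifestError(
                f"{self.sample_id}: graft_type must be one of {GRAFT_TYPES}, "
                f"got {self.graft_type!r}"
            )
        if self.tissue_role not in TISSUE_ROLES:
            raise ManifestError(
                f"{self.sample_id}: tissue_role must be one of {TISSUE_ROLES}, "
                f"got {self.tissue_role!r}"
            )
        if self.replicate < 1:
            raise ManifestError(f"{self.sample_id}: replicate must be >= 1")
        if self.graft_type == "heterograft" and self.partner_species == self.tissue_species:
            raise ManifestError(
                f"{self.sample_id}: heterograft sample with identical tissue "
                f"and partner species {self.tissue_species!r}"
            )
        if self.graft_type == "homograft" and self.partner_species != self.tissue_species:
            raise ManifestError(
                f"{self.sample_id}: homograft sample must have "
                "partner_species equal to tissue_species"
            )


def validate_manifest(samples: Sequence[Sample]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ManifestError(f"duplicate sample_id(s): {dup}")
    if not samples:
        raise ManifestError("empty manifest")


def load_manifest(path: str | Path, check_fastq: bool = True) -> list[Sample]:
    """Load and validate the TSV sample manifest.

    ``fastq_path`` entries are resolved relative to the manifest's
    directory; with ``check_fastq`` a missing FASTQ is fatal.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ManifestError(f"manifest {path} lacks column(s) {missing}")
    samples = []
    for row in table.itertuples(index=False):
        fastq = str(Path(path.parent) / row.fastq_path)
        sample = Sample(
            sample_id=row.sample_id,
            tissue_species=row.tissue_species,
            partner_species=row.partner_species,
            graft_type=row.graft_type,
            tissue_role=row.tissue_role,
            replicate=int(row.replicate),
            fastq_path=fastq,
        )
        if check_fastq and not Path(fastq).exists():
            raise ManifestError(f"{sample.sample_id}: FASTQ not found: {fastq}")
        samples.append(sample)
    validate_manifest(samples)
    groups = manifest_groups(samples)
    log.info(
        "manifest %s: %d samples in %d (graft_type, tissue_role) groups",
        path, len(samples), len(groups),
    )
    return samples


def manifest_groups(samples: Sequence[Sample]) -> dict[tuple[str, str], list[Sample]]:
    """Samples grouped by (graft_type, tissue_role), replicate-ordered."""
    groups: dict[tuple[str, str], list[Sample]] = {}
    for s in samples:
        groups.setdefault((s.graft_type, s.tissue_role), []).append(s)
    for key in groups:
        groups[key].sort(key=lambda s: (s.replicate, s.sample_id))
    return groups


def write_manifest(samples: Sequence[Sample], path: str | Path) -> None:
    rows = []
    for s in samples:
        d = {f: getattr(s, f) for f in MANIFEST_COLUMNS}
        d["fastq_path"] = Path(s.fastq_path).name
        rows.append(d)
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline.

    Defaults follow the study design: clean reads are 18-30 nt inserts
    with at most 3 unknown bases and a detectable 3' adaptor; genome
    matching is exact (0 mismatches) on a k=12 seed index; a mobile call
    needs >= 1 heterograft read and zero reads in every self-graft
    control replicate.
    """

    min_len: int = 18
    max_len: int = 30
    max_unknown_bases: int = 3
    adaptor_3p: str = "TGGAATTCTCGGGTGCCAAGG"
    k: int = 12
    max_mismatches: int = 0
    min_hetero_reads: int = 1
    min_hetero_replicates: int = 1
    precursor_flank: int = 150
    pre_max: int = 300
    min_loop: int = 3
    min_pairs_per_nt: float = 0.25
    expression_bins: tuple[float, ...] = (-1.0, 0.5, 1.5, 2.5)
    seed: int = 0

    def __post_init__(self) -> None:
        self.expression_bins = tuple(float(x) for x in self.expression_bins)
        if self.min_len > self.max_len:
            raise ConfigError("min_len must be <= max_len")
        if self.k > self.min_len:
            raise ConfigError("k must be <= min_len")
        if self.max_mismatches not in (0, 1):
            raise ConfigError("max_mismatches must be 0 or 1")
        if not self.adaptor_3p:
            raise ConfigError("adaptor_3p must be non-empty")
        if any(
            b >= a for a, b in zip(self.expression_bins[1:], self.expression_bins)
        ):
            raise ConfigError("expression_bins edges must be strictly increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["expression_bins"] = list(self.expression_bins)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(
    table: pd.DataFrame,
    path: str | Path,
    sort_by: Sequence[str] | None = None,
) -> None:
    """Write a report table as TSV (header row, UTF-8, deterministic order).

    ``sort_by`` names the sort-key columns; a stable sort is used so that
    re-running on the same input yields a byte-identical file.
    """
    if sort_by:
        table = table.sort_values(list(sort_by), kind="mergesort")
    try:
        table.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")
    except OSError as exc:
        raise FormatError(f"cannot write report {path}: {exc}") from exc


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
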