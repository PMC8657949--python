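"""Synthetic heterograft small-RNA data with known truth.

Two toy species genomes are generated as random sequence with miRNA
loci planted at recorded coordinates.  Each locus is a designed hairpin
(5' flank + mature + loop + reverse-complemented mature + 3' flank), so
the mature sequence and its star arm both occur in the genome and the
precursor window folds with a high pairing density.  Loci come in three
classes:

* ``shared``  - the mature sequence is character-identical between the
  two species' catalogs (the cross-species confound: such tags map to
  the recipient's own genome and their mobility is undecidable);
* ``variant`` - the mature differs from its family counterpart in the
  other species by one central substitution, so no run of >= 18
  identical bases is shared;
* ``unique``  - present in one species only.

Outside shared loci the two genomes share no exact substring of length
>= ``min_len`` (enforced by construction and verified; generation is
retried with fresh randomness on the astronomically rare collision).

Libraries emulate the grafting design: per tissue, heterograft
replicates plus self-graft control replicates.  Per-locus abundance
follows a log-uniform law spanning four orders of magnitude; for
heterograft samples each mobile locus of the partner species
additionally contributes ``mobile_fraction`` of its donor-side
abundance, with a floor of one cross-border read per replicate (the
generator emulates the regime where mobile candidates are repeatedly
detected across heterograft replicates).  Self-graft controls contain
no partner-species-only sequences.  Background reads are drawn from
planted rRNA/tRNA-like annotation decoys and from random positions of
the tissue's own genome; a fraction of background reads lacks the 3'
adaptor (read-through failure).  Per-base substitution errors are
applied to inserts.  All randomness is derived by hashing
``(seed, stage, sample, locus)`` keys, so one stream is shared per
(sample, locus) and outputs are byte-identical for a fixed seed.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    PipelineConfig,
    Sample,
    as_rna,
    revcomp,
    write_fasta,
    write_fastq,
    write_manifest,
    write_report,
)

log = logging.getLogger("graftmir")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

CLASS_SHARED = "shared"
CLASS_VARIANT = "variant"
CLASS_UNIQUE = "unique"

_FAMILY_POOL = [
    "miR156", "miR164", "miR395", "miR397", "miR1446", "miR166", "miR168",
    "miR172", "miR399", "miR403", "miR408", "miR2111", "miR159", "miR160",
    "miR162", "miR167", "miR169", "miR171", "miR390", "miR393", "miR394",
    "miR396", "miR398", "miR447", "miR773", "miR823", "miR827", "miR846",
]

_DECOY_KINDS = ("rRNA", "tRNA", "snRNA", "snoRNA")


class SimulationError(RuntimeError):
    pass


def _stream(*key) -> np.random.Generator:
    """Deterministic RNG stream keyed by (seed, stage, ids...)."""
    digest = hashlib.sha256(":".join(map(str, key)).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


@dataclass(frozen=True)
class PlantedLocus:
    """One planted miRNA locus with its genomic truth coordinates."""

    species: str
    locus_id: str
    family: str
    locus_class: str      # shared | variant | unique
    strand: str
    contig: str
    precursor_start: int  # 0-based half-open, forward strand
    precursor_end: int
    mature_start: int
    mature_end: int
    mature_seq: str       # DNA, sense (mature) orientation
    mobile: bool
    abundance: float      # log-uniform [1, 1e4] relative abundance


@dataclass
class SimDesign:
    """Study-design parameters of the synthetic heterograft experiment.

    Defaults emulate the deposited design: two species, three
    heterograft plus three self-graft replicates per tissue, 18-30 nt
    reads, a small mobile fraction crossing the graft union (more loci
    moving shoot-to-root than root-to-shoot), sequencing errors and
    adaptor read-through.
    """

    species: tuple[str, str] = ("At", "Nb")   # (scion species, rootstock species)
    n_unique: int = 8        # per species
    n_variant: int = 4       # per species (cross-species family pairs)
    n_shared: int = 2        # identical mature in both catalogs
    n_mobile_scion_species: int = 8     # shoot-to-root moving loci
    n_mobile_rootstock_species: int = 6  # root-to-shoot moving loci
    mobile_locus_ids: frozenset[str] | None = None  # explicit override
    genome_len: int = 20000
    mature_len: int = 21
    hairpin_flank: int = 10
    hairpin_loop: int = 8
    library_depth: int = 50000
    mobile_fraction: float = 0.2
    error_rate: float = 0.001
    adaptor_readthrough_fraction: float = 0.95
    background_fraction: float = 0.2
    n_decoys: int = 4
    decoy_len: int = 240
    replicates: int = 3
    read_length: int = 50
    min_len: int = 18
    max_len: int = 30
    adaptor_3p: str = "TGGAATTCTCGGGTGCCAAGG"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mobile_fraction", "error_rate",
                     "adaptor_readthrough_fraction", "background_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.library_depth < 1:
            raise SimulationError("library_depth must be >= 1")
        if self.mature_len < self.min_len or self.mature_len > self.max_len:
            raise SimulationError("mature_len must lie within [min_len, max_len]")
        if self.mobile_locus_ids is not None:
            self.mobile_locus_ids = frozenset(self.mobile_locus_ids)

    @property
    def n_loci_per_species(self) -> int:
        return self.n_unique + self.n_variant + self.n_shared


@dataclass
class SimWorld:
    """Generated genomes, annotation decoys, catalogs and locus truth."""

    design: SimDesign
    genomes: dict[str, dict[str, str]]       # species -> contig -> sequence
    annotations: dict[str, str]
    catalogs: dict[str, dict[str, str]]      # species -> entry name -> mature (DNA)
    loci: list[PlantedLocus]

    def loci_of(self, species: str) -> list[PlantedLocus]:
        return [l for l in self.loci if l.species == species]

    def mobile_loci_of(self, species: str) -> list[PlantedLocus]:
        return [l for l in self.loci_of(species) if l.mobile]


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _design_matures(design: SimDesign, attempt: int) -> dict[str, list[tuple[str, str, str]]]:
    """Per species: list of (family, locus_class, mature_seq)."""
    sp_a, sp_b = design.species
    n_fam = design.n_shared + design.n_variant + 2 * design.n_unique
    families = list(_FAMILY_POOL)
    while len(families) < n_fam:
        families.append(f"miR{9000 + len(families)}")
    out: dict[str, list[tuple[str, str, str]]] = {sp_a: [], sp_b: []}
    idx = 0
    L = design.mature_len
    for _ in range(design.n_shared):
        fam = families[idx]; idx += 1
        mature = _random_dna(_stream(design.seed, attempt, "mature", fam), L)
        out[sp_a].append((fam, CLASS_SHARED, mature))
        out[sp_b].append((fam, CLASS_SHARED, mature))
    for _ in range(design.n_variant):
        fam = families[idx]; idx += 1
        rng = _stream(design.seed, attempt, "mature", fam)
        base = _random_dna(rng, L)
        # one central substitution: no shared run of >= min_len remains
        pos = L // 2
        alt = "ACGT"[(_BASE_INDEX[base[pos]] + 1 + rng.integers(0, 3)) % 4]
        variant = base[:pos] + alt + base[pos + 1 :]
        out[sp_a].append((fam, CLASS_VARIANT, base))
        out[sp_b].append((fam, CLASS_VARIANT, variant))
    for species in (sp_a, sp_b):
        for _ in range(design.n_unique):
            fam = families[idx]; idx += 1
            mature = _random_dna(
                _stream(design.seed, attempt, "mature", species, fam), L
            )
            out[species].append((fam, CLASS_UNIQUE, mature))
    return out


def _select_mobile(design: SimDesign, matures: Mapping[str, list]) -> set[str]:
    if design.mobile_locus_ids is not None:
        return set(design.mobile_locus_ids)
    sp_a, sp_b = design.species
    chosen: set[str] = set()
    for species, n_mobile in (
        (sp_a, design.n_mobile_scion_species),
        (sp_b, design.n_mobile_rootstock_species),
    ):
        eligible = [
            f"{species}_{fam}"
            for fam, cls, _ in matures[species]
            if cls != CLASS_SHARED
        ]
        if n_mobile > len(eligible):
            raise SimulationError(
                f"{species}: {n_mobile} mobile loci requested but only "
                f"{len(eligible)} non-shared loci exist"
            )
        chosen.update(eligible[:n_mobile])
    return chosen


def make_genomes(design: SimDesign, max_attempts: int = 20) -> SimWorld:
    """Generate genomes, annotation decoys, catalogs and the truth table.

    Loci are spaced evenly along a single contig per species; the
    cross-genome substring check (no common >= min_len-mer outside
    shared loci, either orientation) is verified explicitly.
    """
    last_err = None
    for attempt in range(max_attempts):
        try:
            return _make_genomes_once(design, attempt)
        except SimulationError as exc:
            if "cannot place" in str(exc):
                raise
            last_err = exc
    raise SimulationError(f"genome generation failed after {max_attempts} attempts: {last_err}")


def _make_genomes_once(design: SimDesign, attempt: int) -> SimWorld:
    sp_a, sp_b = design.species
    matures = _design_matures(design, attempt)
    mobile_ids = _select_mobile(design, matures)

    L = design.mature_len
    pre_len = 2 * design.hairpin_flank + 2 * L + design.hairpin_loop
    n_loci = design.n_loci_per_species
    spacing = design.genome_len // (n_loci + 1)
    if spacing < pre_len + 2 * design.min_len:
        raise SimulationError(
            "cannot place loci without overlap at the requested density; "
            "enlarge genome_len or reduce the locus count"
        )

    genomes: dict[str, dict[str, str]] = {}
    catalogs: dict[str, dict[str, str]] = {}
    loci: list[PlantedLocus] = []
    for species in (sp_a, sp_b):
        contig = f"{species}_chr1"
        backbone = list(
            _random_dna(_stream(design.seed, attempt, "genome", species),
                        design.genome_len)
        )
        catalog: dict[str, str] = {}
        for i, (fam, cls, mature) in enumerate(matures[species]):
            rng = _stream(design.seed, attempt, "locus", species, fam)
            flank5 = _random_dna(rng, design.hairpin_flank)
            loop = _random_dna(rng, design.hairpin_loop)
            flank3 = _random_dna(rng, design.hairpin_flank)
            precursor = flank5 + mature + loop + revcomp(mature) + flank3
            strand = "+" if rng.random() < 0.5 else "-"
            pos = spacing * (i + 1)
            inserted = precursor if strand == "+" else revcomp(precursor)
            backbone[pos : pos + pre_len] = list(inserted)
            if strand == "+":
                m_start = pos + design.hairpin_flank
            else:
                # in rc(precursor) the mature arm sits mirror-symmetrically
                m_start = pos + pre_len - design.hairpin_flank - L
            locus_id = f"{species}_{fam}"
            abundance = float(
                10 ** (4 * _stream(design.seed, attempt, "abundance",
                                   species, locus_id).random())
            )
            loci.append(
                PlantedLocus(
                    species=species,
                    locus_id=locus_id,
                    family=fam,
                    locus_class=cls,
                    strand=strand,
                    contig=contig,
                    precursor_start=pos,
                    precursor_end=pos + pre_len,
                    mature_start=m_start,
                    mature_end=m_start + L,
                    mature_seq=mature,
                    mobile=locus_id in mobile_ids,
                    abundance=abundance,
                )
            )
            catalog[f"{species.lower()}-{fam}"] = mature
        genomes[species] = {contig: "".join(backbone)}
        catalogs[species] = catalog

    # planted coordinates must read back correctly
    for locus in loci:
        contig_seq = genomes[locus.species][locus.contig]
        segment = contig_seq[locus.mature_start : locus.mature_end]
        expected = locus.mature_seq if locus.strand == "+" else revcomp(locus.mature_seq)
        if segment != expected:
            raise SimulationError(f"locus {locus.locus_id}: coordinate bookkeeping error")

    # cross-genome disjointness outside shared loci, both orientations
    k = design.min_len
    genome_a = genomes[sp_a][f"{sp_a}_chr1"]
    genome_b = genomes[sp_b][f"{sp_b}_chr1"]
    set_a = _kmer_set(genome_a, k) | _kmer_set(revcomp(genome_a), k)
    set_b = _kmer_set(genome_b, k)
    # windows overlapping a shared-locus region by even one base may match
    # across genomes (the overhang can coincide); allow the whole region
    # padded by k-1 on either side
    allowed: set[str] = set()
    for locus in loci:
        if locus.locus_class == CLASS_SHARED and locus.species == sp_a:
            lo = max(0, locus.precursor_start - (k - 1))
            hi = min(len(genome_a), locus.precursor_end + (k - 1))
            region = genome_a[lo:hi]
            allowed |= _kmer_set(region, k) | _kmer_set(revcomp(region), k)
    stray = (set_a & set_b) - allowed
    if stray:
        raise SimulationError(
            f"genomes share {len(stray)} non-designed {k}-mer(s); retrying"
        )

    # annotation decoys (shared across species), disjoint from both genomes
    annotations: dict[str, str] = {}
    for i in range(design.n_decoys):
        kind = _DECOY_KINDS[i % len(_DECOY_KINDS)]
        for tries in range(10):
            seq = _random_dna(
                _stream(design.seed, attempt, "decoy", i, tries), design.decoy_len
            )
            dk = _kmer_set(seq, k) | _kmer_set(revcomp(seq), k)
            if not (dk & set_a) and not (dk & set_b):
                break
        else:
            raise SimulationError("could not generate genome-disjoint decoys")
        annotations[f"{kind}_decoy_{i + 1}"] = seq

    log.info(
        "make_genomes: %d loci per species (%d shared, %d variant, %d unique), "
        "%d mobile total",
        n_loci, design.n_shared, design.n_variant, design.n_unique, len(mobile_ids),
    )
    return SimWorld(
        design=design,
        genomes=genomes,
        annotations=annotations,
        catalogs=catalogs,
        loci=loci,
    )


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

def make_manifest(design: SimDesign, fastq_dir: str | Path = ".") -> list[Sample]:
    """The grafting design as a manifest: heterograft and self-graft
    replicates for both tissues (e.g. AGS/ACS scions, NGR/NCR rootstocks)."""
    sp_a, sp_b = design.species
    a0, b0 = sp_a[0].upper(), sp_b[0].upper()
    samples = []
    for r in range(1, design.replicates + 1):
        samples.append(Sample(f"{a0}GS{r}", sp_a, sp_b, "heterograft", "scion", r,
                              str(Path(fastq_dir) / f"{a0}GS{r}.fastq")))
    for r in range(1, design.replicates + 1):
        samples.append(Sample(f"{a0}CS{r}", sp_a, sp_a, "homograft", "scion", r,
                              str(Path(fastq_dir) / f"{a0}CS{r}.fastq")))
    for r in range(1, design.replicates + 1):
        samples.append(Sample(f"{b0}GR{r}", sp_b, sp_a, "heterograft", "rootstock", r,
                              str(Path(fastq_dir) / f"{b0}GR{r}.fastq")))
    for r in range(1, design.replicates + 1):
        samples.append(Sample(f"{b0}CR{r}", sp_b, sp_b, "homograft", "rootstock", r,
                              str(Path(fastq_dir) / f"{b0}CR{r}.fastq")))
    return samples


def _stochastic_round(expected: float, rng: np.random.Generator) -> int:
    base = math.floor(expected)
    return int(base + (rng.random() < expected - base))


def _apply_errors(insert: str, rng: np.random.Generator, count: int,
                  error_rate: float) -> list[str]:
    """``count`` copies of insert with iid per-base substitution errors.

    Draws are laid out row-major, so the first reads of a larger batch
    reuse exactly the error fate of a smaller batch from the same
    stream (this is what makes mobile read counts monotone in
    mobile_fraction for a fixed seed).
    """
    if count == 0:
        return []
    if error_rate <= 0:
        return [insert] * count
    n = len(insert)
    mask = rng.random((count, n)) < error_rate
    shifts = rng.integers(1, 4, (count, n))
    out = [insert] * count
    bad_rows = np.nonzero(mask.any(axis=1))[0]
    if len(bad_rows):
        base_idx = np.array([_BASE_INDEX[b] for b in insert], dtype=np.int64)
        for row in bad_rows:
            idx = base_idx.copy()
            hit = mask[row]
            idx[hit] = (idx[hit] + shifts[row][hit]) % 4
            out[row] = _BASES[idx].tobytes().decode()
    return out


def _build_read(insert: str, rng: np.random.Generator, design: SimDesign,
                with_adaptor: bool) -> str:
    body = insert + (design.adaptor_3p if with_adaptor else "")
    if len(body) < design.read_length:
        body += _random_dna(rng, design.read_length - len(body))
    return body[: design.read_length]


def simulate_library(
    sample: Sample, design: SimDesign, world: SimWorld
) -> list[tuple[str, str, str]]:
    """Simulate one sample's FASTQ records ``(read_id, sequence, quality)``.

    miRNA reads always read through into the 3' adaptor; the
    adaptor-read-through fraction below 1 removes the adaptor from a
    share of background reads only.
    """
    own = sample.tissue_species
    partner = sample.partner_species
    own_loci = world.loci_of(own)
    sum_own = sum(l.abundance for l in own_loci)
    mirna_budget = design.library_depth * (1.0 - design.background_fraction)

    reads: list[tuple[str, str, str]] = []

    def emit(insert: str, count: int, rng, locus_id: str, with_adaptor=True):
        for i, mutated in enumerate(
            _apply_errors(insert, rng, count, design.error_rate)
        ):
            seq = _build_read(mutated, rng, design, with_adaptor)
            reads.append(
                (f"{sample.sample_id}:{locus_id}:{i + 1}", seq, "I" * len(seq))
            )

    # endogenous miRNA reads from the tissue's own loci
    for locus in own_loci:
        rng = _stream(design.seed, "count", sample.sample_id, locus.locus_id)
        expected = mirna_budget * locus.abundance / sum_own
        count = _stochastic_round(expected, rng)
        emit(locus.mature_seq, count, rng, locus.locus_id)

    # graft-transmitted reads from the partner's mobile loci
    if sample.graft_type == "heterograft" and design.mobile_fraction > 0:
        donor_loci = world.mobile_loci_of(partner)
        sum_donor = sum(l.abundance for l in world.loci_of(partner))
        for locus in donor_loci:
            rng = _stream(design.seed, "count", sample.sample_id, locus.locus_id)
            expected = (
                design.mobile_fraction
                * mirna_budget
                * locus.abundance
                / sum_donor
            )
            count = max(1, _stochastic_round(expected, rng))
            emit(locus.mature_seq, count, rng, locus.locus_id)

    # background: annotation decoys + random own-genome fragments
    n_background = round(design.background_fraction * design.library_depth)
    rng = _stream(design.seed, "background", sample.sample_id)
    decoy_names = sorted(world.annotations)
    contig_name, contig_seq = next(iter(world.genomes[own].items()))
    for i in range(n_background):
        length = int(rng.integers(design.min_len, design.max_len + 1))
        if rng.random() < 0.5 and decoy_names:
            source = world.annotations[decoy_names[int(rng.integers(len(decoy_names)))]]
        else:
            source = contig_seq
        pos = int(rng.integers(0, len(source) - length + 1))
        insert = source[pos : pos + length]
        if rng.random() < 0.5:
            insert = revcomp(insert)
        mutated = _apply_errors(insert, rng, 1, design.error_rate)[0]
        with_adaptor = rng.random() < design.adaptor_readthrough_fraction
        seq = _build_read(mutated, rng, design, with_adaptor)
        reads.append((f"{sample.sample_id}:bg:{i + 1}", seq, "I" * len(seq)))

    log.info("simulate %s: %d reads", sample.sample_id, len(reads))
    return reads


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def truth_table(world: SimWorld) -> pd.DataFrame:
    rows = []
    for l in world.loci:
        rows.append(
            {
                "species": l.species,
                "locus_id": l.locus_id,
                "family": l.family,
                "class": l.locus_class,
                "strand": l.strand,
                "contig": l.contig,
                "precursor_start": l.precursor_start + 1,  # 1-based in reports
                "precursor_end": l.precursor_end,
                "mature_start": l.mature_start + 1,
                "mature_end": l.mature_end,
                "mature_seq": as_rna(l.mature_seq),
                "mobile": l.mobile,
                "abundance": round(l.abundance, 4),
            }
        )
    return pd.DataFrame(rows)


def simulate_to_dir(
    design: SimDesign, out_dir: str | Path
) -> tuple[SimWorld, list[Sample], dict[str, Path]]:
    """Run the full simulation and write every artifact to ``out_dir``.

    Emits per-species genome and catalog FASTA, the annotation FASTA,
    truth.tsv, manifest.tsv and one FASTQ per sample.  Catalogs are
    rendered as RNA; genomes and annotations as DNA.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world = make_genomes(design)
    samples = make_manifest(design, out)
    paths: dict[str, Path] = {}
    for species, contigs in world.genomes.items():
        p = out / f"genome_{species}.fa"
        write_fasta(contigs, p)
        paths[f"genome_{species}"] = p
    p = out / "annotations.fa"
    write_fasta(world.annotations, p)
    paths["annotations"] = p
    for species, catalog in world.catalogs.items():
        p = out / f"catalog_{species}.fa"
        write_fasta(catalog, p, rna=True)
        paths[f"catalog_{species}"] = p
    p = out / "truth.tsv"
    write_report(truth_table(world), p, sort_by=["species", "locus_id"])
    paths["truth"] = p
    for sample in samples:
        write_fastq(simulate_library(sample, design, world), sample.fastq_path)
    p = out / "manifest.tsv"
    write_manifest(samples, p)
    paths["manifest"] = p
    return world, samples, paths


def config_for_design(design: SimDesign, **overrides) -> PipelineConfig:
    """A pipeline configuration consistent with a simulation design."""
    return PipelineConfig(
        min_len=design.min_len,
        max_len=design.max_len,
        adaptor_3p=design.adaptor_3p,
        seed=design.seed,
        **overrides,
    )
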