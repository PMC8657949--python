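"""Shared fixtures: the published worked example and a small simulation."""

from __future__ import annotations

import pandas as pd
import pytest

from graftmir import (
    PipelineConfig,
    Sample,
    SimDesign,
    config_for_design,
    make_genomes,
    make_manifest,
    simulate_library,
)

# The published worked example: six rootstock-species mature sequences
# recovered in heterograft scions, with per-replicate read counts in the
# three heterograft scion libraries (AGS1-3) and the three self-graft
# control libraries (ACS1-3, all zero).
WORKED_EXAMPLE = [
    # (sequence, family, printed length, heterograft counts)
    ("UGACAGAAGAGAGUGGGC", "miR156", 18, (4, 9, 6)),
    ("UGGAGAAGCAGGGCACAUGC", "miR164", 20, (1, 1, 1)),
    ("CUGAAGUGUUUGGGGGAACUCU", "miR395", 22, (3, 13, 1)),
    ("UUCUGAACUCUCUCCCUCAAU", "miR1446", 21, (0, 3, 0)),
    ("UCAUUGAGUGCAGCGUUGAUGA", "miR397", 22, (1, 3, 5)),
    ("CUGAAGUGUUUGGGGGAACUCCG", "miR395", 23, (25, 47, 45)),
]

# Printed read-accounting pairs: (numerator, denominator, printed %)
ACCOUNTING_EXAMPLES = [
    (62_481_229, 77_896_720, 80.21),   # AGS clean
    (57_001_571, 76_187_700, 74.82),   # ACS clean
    (62_307_593, 68_325_049, 91.19),   # NGR clean
    (223_052_992, 256_050_792, 87.11), # NCR clean
    (25_206_466, 41_991_400, 60.03),   # AGS mapped
    (20_766_148, 34_161_421, 60.79),   # ACS mapped
    (36_897_829, 52_616_678, 70.13),   # NGR mapped
    (112_256_797, 166_724_440, 67.33), # NCR mapped
    (298_739, 41_991_400, 0.71),       # AGS re-mapped
    (237_220, 34_161_421, 0.69),       # ACS re-mapped
    (152_412, 52_616_678, 0.29),       # NGR re-mapped
    (89_082, 166_724_440, 0.05),       # NCR re-mapped
]


def scion_samples() -> list[Sample]:
    """Three heterograft scion replicates + three self-graft controls."""
    samples = []
    for r in (1, 2, 3):
        samples.append(
            Sample(f"AGS{r}", "At", "Nb", "heterograft", "scion", r, f"AGS{r}.fastq")
        )
    for r in (1, 2, 3):
        samples.append(
            Sample(f"ACS{r}", "At", "At", "homograft", "scion", r, f"ACS{r}.fastq")
        )
    return samples


def worked_example_tags() -> pd.DataFrame:
    rows = []
    for seq, _family, _length, hetero in WORKED_EXAMPLE:
        row = {"sequence": seq.replace("U", "T")}
        for i, n in enumerate(hetero, 1):
            row[f"AGS{i}"] = n
        for i in (1, 2, 3):
            row[f"ACS{i}"] = 0
        rows.append(row)
    return pd.DataFrame(rows)


def worked_example_catalog() -> dict[str, str]:
    """A rootstock-species mature catalog holding the six entries."""
    catalog = {}
    seen: dict[str, int] = {}
    for seq, family, _length, _ in WORKED_EXAMPLE:
        seen[family] = seen.get(family, 0) + 1
        suffix = chr(ord("a") + seen[family] - 1)
        catalog[f"nb-{family}{suffix}"] = seq.replace("U", "T")
    return catalog


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_design() -> SimDesign:
    """A desk-scale simulation design (error-free, modest depth)."""
    return SimDesign(seed=11, error_rate=0.0, library_depth=5000)


@pytest.fixture(scope="session")
def small_world(small_design):
    return make_genomes(small_design)


@pytest.fixture(scope="session")
def small_samples(small_design):
    return make_manifest(small_design)


@pytest.fixture(scope="session")
def small_reads(small_design, small_world, small_samples):
    return {
        s.sample_id: simulate_library(s, small_design, small_world)
        for s in small_samples
    }


@pytest.fixture(scope="session")
def small_config(small_design) -> PipelineConfig:
    return config_for_design(small_design)
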