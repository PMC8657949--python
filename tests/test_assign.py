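"""Genome index, seeded matching vs a brute-force oracle, and assignment."""

import numpy as np
import pandas as pd
import pytest

from graftmir import (
    GenomeIndex,
    assign,
    filter_annotations,
    match,
    percent,
    revcomp,
)


def brute_force_hits(tag: str, contigs: dict[str, str], max_mm: int):
    """Independent oracle: exhaustive both-strand sliding-window scan."""
    out = set()
    n = len(tag)
    for strand, query in (("+", tag), ("-", revcomp(tag))):
        q = np.frombuffer(query.encode(), dtype=np.uint8)
        for name, seq in contigs.items():
            if len(seq) < n:
                continue
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(arr, n)
            mm = (windows != q).sum(axis=1)
            for start in np.nonzero(mm <= max_mm)[0]:
                out.add((name, int(start), strand, int(mm[start])))
    return out


def random_genome(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestGenomeIndex:
    def test_kmer_positions(self):
        idx = GenomeIndex("sp", {"c": "AAAACCCC"}, k=8)
        assert idx.kmers["AAAACCCC"] == [("c", 0)]
        idx = GenomeIndex("sp", {"c": "AAAACCCCGG"}, k=8)
        assert ("c", 2) in idx.kmers["AACCCCGG"]

    def test_kmers_spanning_n_absent(self):
        idx = GenomeIndex("sp", {"c": "AAAANAAAAAAAA"}, k=8)
        assert all("N" not in kmer for kmer in idx.kmers)

    def test_short_contig_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="graftmir"):
            idx = GenomeIndex("sp", {"tiny": "ACGT", "ok": "A" * 20}, k=8)
        assert "tiny" in caplog.text
        assert all(c == "ok" for pos in idx.kmers.values() for c, _ in pos)

    def test_index_positions_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        genome = random_genome(rng, 2000)
        k = 12
        idx = GenomeIndex("sp", {"c": genome}, k=k)
        expected: dict[str, list] = {}
        for off in range(len(genome) - k + 1):
            expected.setdefault(genome[off : off + k], []).append(("c", off))
        assert idx.kmers == expected


class TestMatch:
    def test_reverse_complement_read_hits_minus_strand(self):
        genome = "AAAAA" + "TGACAGAAGAGAGTGGGCACA" + "AAAAA"
        idx = GenomeIndex("sp", {"c": genome}, k=12)
        tag = revcomp("TGACAGAAGAGAGTGGGCACA")
        hits = match(tag, idx)
        assert [(h.contig, h.start, h.strand, h.mismatches) for h in hits] == [
            ("c", 5, "-", 0)
        ]

    def test_planted_mature_found_at_truth_coordinates(self, small_world):
        design = small_world.design
        idx = {
            sp: GenomeIndex(sp, contigs, k=12)
            for sp, contigs in small_world.genomes.items()
        }
        for locus in small_world.loci:
            hits = match(locus.mature_seq, idx[locus.species])
            assert (
                locus.contig, locus.mature_start, locus.strand
            ) in {(h.contig, h.start, h.strand) for h in hits}

    @pytest.mark.parametrize("max_mm", [0, 1])
    def test_equals_brute_force_scan(self, max_mm):
        rng = np.random.default_rng(17)
        genome = random_genome(rng, 5000)
        contigs = {"c": genome}
        idx = GenomeIndex("sp", contigs, k=12)
        tags = []
        for _ in range(150):
            length = int(rng.integers(18, 31))
            start = int(rng.integers(0, len(genome) - length))
            tag = genome[start : start + length]
            tag = list(tag)
            for _ in range(int(rng.integers(0, 3))):  # 0-2 mutations
                pos = int(rng.integers(0, length))
                tag[pos] = "ACGT"[int(rng.integers(0, 4))]
            tags.append("".join(tag))
            if rng.random() < 0.3:
                tags.append(revcomp(tags[-1]))
        for tag in tags:
            got = {
                (h.contig, h.start, h.strand, h.mismatches)
                for h in match(tag, idx, max_mm)
            }
            assert got == brute_force_hits(tag, contigs, max_mm), tag


class TestFilterAnnotations:
    ANN = {"rRNA_decoy": "GGGG" + "ACGTACGTACGTACGTACGTA" + "CCCC"}

    def _tags(self, seqs):
        return pd.DataFrame({"sequence": seqs, "S1": [1] * len(seqs)})

    def test_annotation_slice_removed(self):
        kept, removed = filter_annotations(
            self._tags(["ACGTACGTACGTACGTACGTA"]), self.ANN
        )
        assert len(removed) == 1 and len(kept) == 0

    def test_non_matching_tag_kept(self):
        kept, removed = filter_annotations(self._tags(["T" * 21]), self.ANN)
        assert len(kept) == 1 and len(removed) == 0

    def test_reverse_complement_match_removed(self):
        rc_tag = revcomp("ACGTACGTACGTACGTACGTA")
        # oracle: brute-force substring scan of both orientations
        blob = "".join(self.ANN.values())
        assert rc_tag not in blob and revcomp(rc_tag) in blob
        kept, removed = filter_annotations(self._tags([rc_tag]), self.ANN)
        assert len(removed) == 1


class TestAssign:
    @pytest.fixture
    def two_genomes(self):
        rng = np.random.default_rng(23)
        shared = "TGACAGAAGAGAGTGGGCACA"
        own_unique = "CCTGAAGTGTTTGGGGGAACT"
        partner_unique = "TTCTGAACTCTCTCCCTCAAT"
        own = random_genome(rng, 3000) + shared + own_unique + random_genome(rng, 100)
        partner = random_genome(rng, 3000) + shared + partner_unique
        return (
            GenomeIndex("own", {"c": own}, k=12),
            GenomeIndex("partner", {"c": partner}, k=12),
            shared,
            own_unique,
            partner_unique,
        )

    def test_hierarchy_and_partition(self, two_genomes):
        own_idx, partner_idx, shared, own_unique, partner_unique = two_genomes
        tags = pd.DataFrame(
            {
                "sequence": [shared, own_unique, partner_unique, "T" * 21],
                "S1": [10, 5, 3, 2],
            }
        )
        result = assign(tags, own_idx, partner_idx, {}, ["S1"])
        cat = dict(zip(result.per_tag["sequence"], result.per_tag["category"]))
        # shared sequence is absorbed by own-genome mapping, never partner
        assert cat[shared] == "own"
        assert cat[own_unique] == "own"
        assert cat[partner_unique] == "partner"
        assert cat["T" * 21] == "unassigned"
        acc = result.accounting.iloc[0]
        assert acc["total_srna"] == acc["mapped_own"] + acc["unmapped_own"]
        assert acc["unmapped_own"] == acc["remapped_partner"] + acc["unassigned"]
        assert acc["total_srna"] == 20

    def test_remapping_percentage_matches_published_arithmetic(self):
        assert percent(152_412, 52_616_678) == 0.29

    def test_accounting_conserves_clean_reads(self, two_genomes):
        own_idx, partner_idx, *_ = two_genomes
        ann = {"decoy": "A" * 50}
        tags = pd.DataFrame({"sequence": ["A" * 20, "C" * 20], "S1": [7, 4]})
        result = assign(tags, own_idx, partner_idx, ann, ["S1"])
        acc = result.accounting.iloc[0]
        assert acc["annotation_removed"] == 7
        assert acc["annotation_removed"] + acc["total_srna"] == 11
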