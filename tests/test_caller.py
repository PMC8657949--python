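"""Mobility calling: the control-absence rule, family annotation and
shared-sequence exclusion."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graftmir import (
    ManifestError,
    MobileCandidate,
    PipelineConfig,
    annotate_family,
    call_candidates,
    count_families,
    flag_shared,
)
from tests.conftest import (
    WORKED_EXAMPLE,
    scion_samples,
    worked_example_catalog,
    worked_example_tags,
)


def tags_from_vectors(vectors):
    """Build a partner-tag table from (hetero, control) count tuples."""
    rows = []
    for i, (hetero, control) in enumerate(vectors):
        row = {"sequence": "AC" * 9 + "GT" * (i + 1)}  # distinct, >= 18 nt
        for j, n in enumerate(hetero, 1):
            row[f"AGS{j}"] = n
        for j, n in enumerate(control, 1):
            row[f"ACS{j}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


class TestCallCandidates:
    def test_all_six_published_vectors_called(self, config):
        candidates = call_candidates(worked_example_tags(), scion_samples(), config)
        assert len(candidates) == 6
        assert all(c.status == "called" for c in candidates)

    def test_presence_in_every_replicate_not_required(self, config):
        """The (0, 3, 0) row is called: the rule is control absence."""
        tags = tags_from_vectors([((0, 3, 0), (0, 0, 0))])
        (cand,) = call_candidates(tags, scion_samples(), config)
        assert cand.status == "called"

    def test_any_control_read_demotes(self, config):
        tags = tags_from_vectors([((5, 5, 5), (0, 1, 0))])
        (cand,) = call_candidates(tags, scion_samples(), config)
        assert cand.status == "rejected_control"

    def test_absent_in_heterografts_rejected(self, config):
        tags = tags_from_vectors([((0, 0, 0), (0, 0, 0))])
        (cand,) = call_candidates(tags, scion_samples(), config)
        assert cand.status == "rejected_absent"

    def test_no_controls_is_fatal(self, config):
        hetero_only = [s for s in scion_samples() if s.graft_type == "heterograft"]
        with pytest.raises(ManifestError, match="control"):
            call_candidates(worked_example_tags(), hetero_only, config)

    def test_stricter_all_replicate_rule_available(self):
        cfg = PipelineConfig(min_hetero_replicates=3)
        tags = tags_from_vectors([((0, 3, 0), (0, 0, 0)), ((1, 1, 1), (0, 0, 0))])
        first, second = call_candidates(tags, scion_samples(), cfg)
        assert first.status == "rejected_absent"
        assert second.status == "called"

    def test_calls_invariant_under_replicate_reordering(self, config):
        tags = worked_example_tags()
        samples = scion_samples()
        shuffled = [samples[i] for i in (4, 2, 0, 5, 3, 1)]
        a = call_candidates(tags, samples, config)
        b = call_candidates(tags, shuffled, config)
        assert [(c.sequence, c.status, c.hetero_counts) for c in a] == [
            (c.sequence, c.status, c.hetero_counts) for c in b
        ]

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        hetero=st.tuples(*[st.integers(0, 50)] * 3),
        control=st.tuples(*[st.integers(0, 3)] * 3),
        extra_control=st.integers(1, 5),
        extra_hetero=st.integers(1, 5),
    )
    def test_stringency_monotonicity(self, hetero, control, extra_control, extra_hetero):
        """More control reads can only shrink the called set; more
        heterograft reads can only grow it."""
        cfg = PipelineConfig()

        def status(h, c):
            tags = tags_from_vectors([(h, c)])
            return call_candidates(tags, scion_samples(), cfg)[0].status

        base = status(hetero, control)
        more_control = status(hetero, (control[0] + extra_control,) + control[1:])
        more_hetero = status((hetero[0] + extra_hetero,) + hetero[1:], control)
        if base != "called":
            assert more_control != "called"
        if base == "called":
            assert more_hetero == "called"


class TestFamilyAnnotation:
    def test_published_sequences_give_five_families(self, config):
        catalog = worked_example_catalog()
        candidates = call_candidates(worked_example_tags(), scion_samples(), config)
        for cand in candidates:
            family, strand, name, dist = annotate_family(cand.sequence, catalog)
            cand.family = family
        families = {c.family for c in candidates}
        assert families == {"miR156", "miR164", "miR395", "miR397", "miR1446"}
        assert count_families(candidates) == 5

    def test_near_match_within_three_substitutions(self):
        catalog = {"nb-miR395a": "CTGAAGTGTTTGGGGGAACTCT"}
        variant = "CTGAAGTGTTTGGGGGAACACT"  # 1 substitution
        family, strand, name, dist = annotate_family(variant, catalog)
        assert (family, strand, dist) == ("miR395", "sense", 1)

    def test_no_neighbor_within_three_gives_unknown(self):
        catalog = {"nb-miR395a": "CTGAAGTGTTTGGGGGAACTCT"}
        family, *_ = annotate_family("T" * 22, catalog)
        assert family == "unknown"

    def test_equal_distance_tie_broken_lexicographically(self, caplog):
        seq = "CTGAAGTGTTTGGGGGAACTCT"
        catalog = {"nb-miR395b": seq, "nb-miR395a": seq}
        with caplog.at_level("INFO", logger="graftmir"):
            family, _, name, dist = annotate_family(seq, catalog)
        assert (family, name, dist) == ("miR395", "nb-miR395a", 0)
        assert "tie-break" in caplog.text

    def test_antisense_match_noted_not_excluded(self):
        from graftmir import revcomp

        guide = "TGACAGAAGAGAGTGGGCACA"
        catalog = {"at-miR156a": guide}
        star = revcomp(guide)
        family, strand, name, dist = annotate_family(star, catalog)
        assert (family, strand) == ("miR156", "antisense")


class TestFlagShared:
    def _candidate(self, seq):
        return MobileCandidate(
            sequence=seq, hetero_counts=(1, 1, 1), control_counts=(0, 0, 0),
            status="called",
        )

    def test_exact_sense_identity_with_tissue_catalog_is_ambiguous(self):
        seq = "TGACAGAAGAGAGTGGGCACA"
        cand = self._candidate(seq)
        flag_shared([cand], {"at-miR156a": seq})
        assert cand.status == "ambiguous_shared"

    def test_variant_not_flagged(self):
        cand = self._candidate("TGACAGAAGAGAGTGGGCACT")
        flag_shared([cand], {"at-miR156a": "TGACAGAAGAGAGTGGGCACA"})
        assert cand.status == "called"

    def test_reverse_complement_identity_not_flagged(self):
        from graftmir import revcomp

        guide = "TGACAGAAGAGAGTGGGCACA"
        cand = self._candidate(revcomp(guide))
        flag_shared([cand], {"at-miR156a": guide})
        assert cand.status == "called"


class TestCountFamilies:
    def test_empty_called_set(self):
        assert count_families([]) == 0

    def test_same_family_counted_once(self):
        cands = [
            MobileCandidate("A" * 20, (1,), (0,), "called", family="miR395"),
            MobileCandidate("C" * 20, (1,), (0,), "called", family="miR395"),
        ]
        assert count_families(cands) == 1
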