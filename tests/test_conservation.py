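"""Coordinate mapping through gapped alignments and conservation calls."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthoflux.conservation import (
    PositionOutOfRangeError,
    active_site_conserved,
    conservation_block,
    map_position,
    pair_conserved,
)
from orthoflux.orthology import align_pair, all_vs_all, best_hit_per_query, \
    reciprocal_best_hits
from orthoflux.records import AlignmentHit, OrthologPair
from orthoflux.synthetic import ProteomeSimConfig, simulate_proteomes


def _aln(q, s, qstart=1, sstart=1):
    return AlignmentHit(
        query_id="q", subject_id="s", e_value=1e-30, bit_score=100.0,
        percent_identity=90.0, aligned_query=q, aligned_subject=s,
        query_start=qstart, subject_start=sstart,
    )


class TestMapPosition:
    def test_ungapped_offset_arithmetic(self):
        """With an 11-residue subject lead, query position p maps to p + 11,
        checked against direct offset arithmetic for every position."""
        hit = _aln("A" * 250, "A" * 250, qstart=1, sstart=12)
        for pos in (1, 100, 221, 250):
            assert map_position(hit, pos) == pos + 11

    def test_gap_in_query_shifts_mapping(self):
        hit = _aln("AC-E", "ACDE")
        assert map_position(hit, 3) == 4  # the query 'E'

    def test_position_aligned_to_subject_gap_returns_gap(self):
        hit = _aln("ACDE", "AC-E")
        assert map_position(hit, 3) is None

    def test_outside_span_raises_not_gap(self):
        hit = _aln("CDE", "CDE", qstart=5, sstart=5)
        with pytest.raises(PositionOutOfRangeError):
            map_position(hit, 2)
        with pytest.raises(PositionOutOfRangeError):
            map_position(hit, 9)

    @settings(max_examples=60, derandomize=True)
    @given(
        columns=st.lists(
            st.tuples(
                st.sampled_from("MDI"),
                st.sampled_from("ACDEGKLRSTV"),
                st.sampled_from("ACDEGKLRSTV"),
            ),
            min_size=1,
            max_size=40,
        ).filter(lambda cols: any(op == "M" for op, _, _ in cols)),
        qstart=st.integers(1, 20),
        sstart=st.integers(1, 20),
    )
    def test_round_trip_property_random_alignments(self, columns, qstart,
                                                   sstart):
        """For arbitrary gapped alignments, mapping a query position to the
        subject and back is the identity, and mappings are strictly
        increasing."""
        q = "".join(a if op in "MD" else "-" for op, a, _ in columns)
        s = "".join(b if op in "MI" else "-" for op, _, b in columns)
        hit = _aln(q, s, qstart=qstart, sstart=sstart)
        n_query = sum(1 for c in q if c != "-")
        mapped_pairs = []
        for pos in range(qstart, qstart + n_query):
            mapped = map_position(hit, pos)
            if mapped is not None:
                assert map_position(hit, mapped, "subject->query") == pos
                mapped_pairs.append((pos, mapped))
        for (p1, m1), (p2, m2) in zip(mapped_pairs, mapped_pairs[1:]):
            assert p1 < p2 and m1 < m2

    def test_round_trip_and_monotonicity(self):
        hit = _aln("MK-TAYI-A", "MKQTA-IWA")
        mappable = []
        for pos in range(1, 8):  # query has 7 residues
            mapped = map_position(hit, pos)
            if mapped is not None:
                assert map_position(hit, mapped, "subject->query") == pos
                mappable.append((pos, mapped))
        for (p1, m1), (p2, m2) in zip(mappable, mappable[1:]):
            assert p1 < p2 and m1 < m2


def _pair(q, s):
    fwd = _aln(q, s)
    fwd.query_id, fwd.subject_id = "H1", "Y1"
    rev = _aln(s, q)
    rev.query_id, rev.subject_id = "Y1", "H1"
    return OrthologPair("H1", "Y1", fwd, rev)


class TestActiveSiteConserved:
    def test_identical_sequences_site_conserved(self):
        pair = _pair("MKRTAYI", "MKRTAYI")
        mappings = active_site_conserved(pair, [3], [3])
        assert mappings[0].conserved and pair_conserved(mappings)

    def test_residue_mismatch_not_conserved(self):
        pair = _pair("MKRTAYI", "MKKTAYI")  # R -> K at position 3
        mappings = active_site_conserved(pair, [3], [3])
        assert not mappings[0].conserved

    def test_annotation_disagreement_flagged(self):
        """Mapped position and curated yeast annotation differ by one:
        conservation is denied and the discrepancy noted."""
        pair = _pair("MKRTAYI", "MKRTAYI")
        mappings = active_site_conserved(pair, [3], [4])
        assert not mappings[0].conserved
        assert "disagrees" in mappings[0].note

    def test_missing_yeast_annotation_judged_on_identity(self):
        pair = _pair("MKRTAYI", "MKRTAYI")
        mappings = active_site_conserved(pair, [3], [])
        assert mappings[0].conserved
        assert mappings[0].note == "annotation-absent"

    def test_site_mapping_into_gap_recorded_not_raised(self):
        pair = _pair("MKRTAYI", "MK-TAYI")
        mappings = active_site_conserved(pair, [3], [])
        assert mappings[0].yeast_pos is None
        assert not mappings[0].conserved

    def test_planted_site_fates(self):
        """Preserved planted sites are all conserved; mutated ones never."""
        for fate, expected in (("preserve", True), ("mutate", False)):
            sim = simulate_proteomes(
                ProteomeSimConfig(seed=7, n_pairs=5, site_fate=fate)
            )
            fwd = best_hit_per_query(all_vs_all(sim.human, sim.yeast))
            rev = best_hit_per_query(all_vs_all(sim.yeast, sim.human))
            by_human = {
                p.human_acc: p for p in reciprocal_best_hits(fwd, rev)
            }
            for h_acc, y_acc, _, h_site, _ in sim.truth:
                mappings = active_site_conserved(
                    by_human[h_acc],
                    [h_site],
                    [pos for pos, _ in sim.sites.get(y_acc, [])],
                )
                assert pair_conserved(mappings) is expected


class TestConservationBlock:
    def test_all_identical_window_renders_residues(self):
        hit = _aln("MKRTAYI", "MKRTAYI")
        block = conservation_block(hit, 3)
        assert block.block_string == "MKRTAYI"
        assert block.start <= 3 <= block.end

    def test_positive_mismatch_renders_plus(self):
        # columns: A/A id, C/C id, I/V positive (+3), D/D id
        hit = _aln("ACID", "ACVD")
        block = conservation_block(hit, 0)
        assert block.block_string == "AC+D"

    def test_block_terminates_at_gap_and_nonpositive(self):
        # W/A scores -3 (terminates left); gap terminates right
        hit = _aln("WACI-D", "AACIQD")
        block = conservation_block(hit, 2)
        assert block.block_string == "ACI"
        assert block.start == 1 and block.end == 3

    def test_nonpositive_site_column_gives_length_one_block(self):
        hit = _aln("AWA", "ADA")  # W/D = -4
        block = conservation_block(hit, 1)
        assert block.block_string == "+" or len(block.block_string) == 1
        assert block.start == block.end == 1

    def test_site_column_always_inside_block(self):
        hit = align_pair("MKTAYIAKQRQISFVK", "MKTAYIAKQRQISFVK")
        for col in range(len(hit.aligned_query)):
            block = conservation_block(hit, col)
            assert block.start <= col <= block.end
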