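"""Pairwise alignment, best-hit extraction and RBH classification."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from orthoflux.orthology import (
    KA_K,
    KA_LAMBDA,
    AlignerConfig,
    ConfigurationError,
    align_pair,
    all_vs_all,
    best_hit_per_query,
    classify_queries,
    reciprocal_best_hits,
)
from orthoflux.records import AlignmentHit, HitLabel, InvalidInputError

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXTEND = 12.0, 1.0  # first gap column 12, each further 1


def brute_force_best_score(a: str, b: str) -> float:
    """Exhaustively enumerate every gapped global alignment (affine gaps).

    Pure recursion over the three column types (match, gap-in-a, gap-in-b);
    no shared state with the production aligner. Exponential — keep
    sequences short.
    """

    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(
                best,
                float(BLOSUM62[a[i], b[j]]) + rec(i + 1, j + 1, "M"),
            )
        if i < len(a):  # gap in b
            cost = GAP_EXTEND if prev == "B" else GAP_OPEN
            best = max(best, -cost + rec(i + 1, j, "B"))
        if j < len(b):  # gap in a
            cost = GAP_EXTEND if prev == "A" else GAP_OPEN
            best = max(best, -cost + rec(i, j + 1, "A"))
        return best

    return rec(0, 0, "M")


def raw_score_from_bits(bits: float) -> float:
    return (bits * math.log(2.0) + math.log(KA_K)) / KA_LAMBDA


class TestAlignPair:
    def test_identical_sequences_ungapped_full_identity(self):
        hit = align_pair("ACDE", "ACDE")
        assert hit.percent_identity == 100.0
        assert hit.aligned_query == "ACDE"
        assert hit.aligned_subject == "ACDE"

    def test_single_deletion_gives_one_gap_column(self):
        hit = align_pair("ACDE", "ACE")
        assert len(hit.aligned_query) == len(hit.aligned_subject) == 4
        assert hit.aligned_subject.count("-") == 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidInputError):
            align_pair("", "ACDE")

    def test_score_matches_exhaustive_enumeration(self):
        """Optimal global score equals the brute-force enumeration optimum
        for random short peptide pairs."""
        rng = np.random.default_rng(42)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(12):
            a = "".join(aas[i] for i in rng.integers(20, size=rng.integers(3, 8)))
            b = "".join(aas[i] for i in rng.integers(20, size=rng.integers(3, 8)))
            hit = align_pair(a, b)
            expected = brute_force_best_score(a, b)
            assert raw_score_from_bits(hit.bit_score) == pytest.approx(
                expected, abs=1e-6
            )

    def test_unknown_residue_scored_via_x_fallback(self):
        hit = align_pair("ACU", "ACU")  # U (selenocysteine) not in BLOSUM62
        assert hit.aligned_query == "ACX"

    def test_deterministic(self):
        h1, h2 = align_pair("MKTAYIA", "MKTWYIA"), align_pair("MKTAYIA", "MKTWYIA")
        assert (h1.aligned_query, h1.aligned_subject, h1.bit_score) == (
            h2.aligned_query,
            h2.aligned_subject,
            h2.bit_score,
        )


def _hit(q, s, bits, e):
    return AlignmentHit(query_id=q, subject_id=s, e_value=e, bit_score=bits,
                        percent_identity=50.0)


class TestBestHit:
    def test_singleton_passes(self):
        hits = [_hit("q1", "s1", 50.0, 1e-10)]
        assert best_hit_per_query(hits)["q1"].subject_id == "s1"

    def test_bit_score_then_evalue_tiebreak(self):
        hits = [
            _hit("q1", "sA", 50.0, 1e-6),
            _hit("q1", "sB", 80.0, 1e-20),
            _hit("q1", "sC", 80.0, 1e-18),
        ]
        best = best_hit_per_query(hits)["q1"]
        assert best.subject_id == "sB" and best.e_value == 1e-20

    def test_subject_id_breaks_exact_ties(self):
        hits = [_hit("q1", "sB", 80.0, 1e-20), _hit("q1", "sA", 80.0, 1e-20)]
        assert best_hit_per_query(hits)["q1"].subject_id == "sA"

    def test_all_filtered_query_absent(self):
        hits = [_hit("q1", "s1", 50.0, 1e-3)]
        assert best_hit_per_query(hits, e_threshold=1e-5) == {}

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(InvalidInputError):
            best_hit_per_query([], e_threshold=0.0)


class TestReciprocalBestHits:
    def test_single_mutual_pair(self):
        fwd = {"h1": _hit("h1", "y1", 90, 1e-30)}
        rev = {"y1": _hit("y1", "h1", 88, 1e-28)}
        pairs = reciprocal_best_hits(fwd, rev)
        assert [(p.human_acc, p.yeast_acc) for p in pairs] == [("h1", "y1")]

    def test_many_to_one_yields_single_pair(self):
        fwd = {"h1": _hit("h1", "y1", 90, 1e-30), "h2": _hit("h2", "y1", 60, 1e-12)}
        rev = {"y1": _hit("y1", "h1", 88, 1e-28)}
        pairs = reciprocal_best_hits(fwd, rev)
        assert [(p.human_acc, p.yeast_acc) for p in pairs] == [("h1", "y1")]

    def test_overlapping_namespaces_rejected(self):
        fwd = {"x": _hit("x", "y", 90, 1e-30)}
        rev = {"x": _hit("x", "y", 90, 1e-30)}
        with pytest.raises(ConfigurationError):
            reciprocal_best_hits(fwd, rev)

    def test_matching_property_no_accession_twice(self, planted_proteomes):
        sim = planted_proteomes
        fwd = best_hit_per_query(all_vs_all(sim.human, sim.yeast))
        rev = best_hit_per_query(all_vs_all(sim.yeast, sim.human))
        pairs = reciprocal_best_hits(fwd, rev)
        accs = [p.human_acc for p in pairs] + [p.yeast_acc for p in pairs]
        assert len(accs) == len(set(accs))

    def test_symmetry_swapping_proteomes(self, planted_proteomes):
        sim = planted_proteomes
        fwd_hits = all_vs_all(sim.human, sim.yeast)
        rev_hits = all_vs_all(sim.yeast, sim.human)
        fwd, rev = best_hit_per_query(fwd_hits), best_hit_per_query(rev_hits)
        direct = {
            (p.human_acc, p.yeast_acc)
            for p in reciprocal_best_hits(fwd, rev)
        }
        swapped = {
            (p.yeast_acc, p.human_acc)
            for p in reciprocal_best_hits(rev, fwd)
        }
        assert direct == swapped


class TestClassification:
    def test_no_hit(self):
        cls = classify_queries(["q1"], {}, {})
        assert cls.labels["q1"] == HitLabel.NO_HIT

    def test_collision_winner_reciprocal_loser_paralogous(self):
        fwd = {"h1": _hit("h1", "y1", 90, 1e-30), "h2": _hit("h2", "y1", 60, 1e-12)}
        rev = {"y1": _hit("y1", "h1", 88, 1e-28)}
        cls = classify_queries(["h1", "h2"], fwd, rev)
        assert cls.labels["h1"] == HitLabel.RECIPROCAL
        assert cls.labels["h2"] == HitLabel.PARALOGOUS

    def test_non_mutual_is_one_way(self):
        fwd = {"h3": _hit("h3", "y2", 70, 1e-15)}
        rev = {"y2": _hit("y2", "h9", 75, 1e-17)}
        cls = classify_queries(["h3"], fwd, rev)
        assert cls.labels["h3"] == HitLabel.ONE_WAY_BEST

    def test_counts_sum_to_queries_and_are_exclusive(self):
        fwd = {"h1": _hit("h1", "y1", 90, 1e-30), "h2": _hit("h2", "y1", 60, 1e-12)}
        rev = {"y1": _hit("y1", "h1", 88, 1e-28)}
        cls = classify_queries(["h1", "h2", "h3"], fwd, rev)
        assert sum(cls.counts.values()) == 3
        assert cls.counts[HitLabel.NO_HIT] == 1

    def test_threshold_monotonicity_keeps_reciprocal_pairs(self):
        """Relaxing the E-value cutoff never removes a pair that was
        reciprocal at the stricter cutoff, for a fixed hit table."""
        hits_fwd = [
            _hit("h1", "y1", 90, 1e-30),
            _hit("h2", "y2", 40, 1e-6),
            _hit("h2", "y1", 30, 1e-4),
        ]
        hits_rev = [
            _hit("y1", "h1", 88, 1e-28),
            _hit("y2", "h2", 42, 1e-7),
        ]
        strict = reciprocal_best_hits(
            best_hit_per_query(hits_fwd, 1e-5),
            best_hit_per_query(hits_rev, 1e-5),
        )
        relaxed = reciprocal_best_hits(
            best_hit_per_query(hits_fwd, 1e-3),
            best_hit_per_query(hits_rev, 1e-3),
        )
        strict_set = {(p.human_acc, p.yeast_acc) for p in strict}
        relaxed_set = {(p.human_acc, p.yeast_acc) for p in relaxed}
        assert strict_set <= relaxed_set
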