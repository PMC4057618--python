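"""Candidate filter cascade, pathway comparison, and packaged tables."""

import pytest

from orthoflux.annotation import (
    EnzymeAnnotation,
    PathwayVerdict,
    ReactionChem,
    intersect_with_orthologs,
    is_one_one_one,
    paralog_screen,
    pathway_compare,
    run_filter_cascade,
)
from orthoflux.fixtures import (
    table1_ortholog_pairs,
    table2_annotations,
    table4_yeast_annotations,
)
from orthoflux.records import AlignmentHit, InvalidInputError

FINAL_SIX = ["P13716", "P22830", "P48637", "P49247", "Q96GX9", "Q9Y2Z4"]


def _ann(acc, pathways, subs, prods):
    return EnzymeAnnotation(
        accession=acc,
        pathways=frozenset(pathways),
        reactions=frozenset(
            [ReactionChem(frozenset(subs), frozenset(prods))]
        ),
    )


def _hit(q, s, bits):
    return AlignmentHit(query_id=q, subject_id=s, e_value=1e-30,
                        bit_score=bits, percent_identity=50.0)


class TestOneOneOne:
    def test_single_pathway_single_reaction(self):
        assert is_one_one_one(_ann("a", {"pw"}, {"CID:1"}, {"CID:2"}))

    def test_two_pathways_fails(self):
        ann = EnzymeAnnotation(
            "a", frozenset({"pw1", "pw2"}),
            frozenset([ReactionChem(frozenset({"CID:1"}), frozenset({"CID:2"}))]),
        )
        assert not is_one_one_one(ann)

    def test_two_reactions_same_substrates_different_products(self):
        reactions = frozenset(
            [
                ReactionChem(frozenset({"CID:1"}), frozenset({"CID:2"})),
                ReactionChem(frozenset({"CID:1"}), frozenset({"CID:3"})),
            ]
        )
        assert len(reactions) == 2  # set-cardinality oracle
        ann = EnzymeAnnotation("a", frozenset({"pw"}), reactions)
        assert not is_one_one_one(ann)

    def test_empty_annotation_raises(self):
        with pytest.raises(InvalidInputError):
            is_one_one_one(EnzymeAnnotation("a", frozenset(), frozenset()))


class TestIntersect:
    def test_packaged_tables_give_eleven_survivors(self):
        """The 34 candidate enzymes crossed with the 113 curated ortholog
        pairs leave exactly 11 with a reciprocal best-match ortholog."""
        candidates = set(table2_annotations())
        pairs = table1_ortholog_pairs()
        survivors = intersect_with_orthologs(candidates, pairs)
        assert len(survivors) == 11
        for acc in ("P13716", "P49247", "Q9Y2Z4"):
            assert acc in survivors

    def test_empty_candidates(self):
        assert intersect_with_orthologs(set(), table1_ortholog_pairs()) == []

    def test_disjoint_candidates(self):
        assert intersect_with_orthologs({"NOPE"}, table1_ortholog_pairs()) == []


class TestParalogScreen:
    def test_single_hit_unique(self):
        assert paralog_screen("q", [_hit("q", "s1", 200.0)])

    def test_close_second_not_unique(self):
        hits = [_hit("q", "s1", 200.0), _hit("q", "s2", 190.0)]
        assert not paralog_screen("q", hits)  # margin 10 < 50, ratio 0.95

    def test_distant_second_unique(self):
        hits = [_hit("q", "s1", 200.0), _hit("q", "s2", 100.0)]
        assert paralog_screen("q", hits)

    def test_no_hits_is_error(self):
        with pytest.raises(InvalidInputError):
            paralog_screen("q", [])


class TestPathwayCompare:
    def test_identical_annotations_all_same(self):
        h = _ann("h", {"pw"}, {"CID:1"}, {"CID:2"})
        y = _ann("y", {"pw"}, {"CID:1"}, {"CID:2"})
        cmp_ = pathway_compare(h, y)
        assert cmp_.verdicts == {"pw": PathwayVerdict.SAME}
        assert cmp_.overall_match

    def test_yeast_only_pathway_same_chemistry_tolerated(self):
        h = _ann("P13716", {"porphyrin"}, {"CID:137"}, {"CID:1021"})
        y = _ann(
            "P05373", {"porphyrin", "secondary metabolites"},
            {"CID:137"}, {"CID:1021"},
        )
        cmp_ = pathway_compare(h, y)
        assert cmp_.verdicts["porphyrin"] == PathwayVerdict.SAME
        assert (
            cmp_.verdicts["secondary metabolites"]
            == PathwayVerdict.YEAST_ONLY_SAME_CHEMISTRY
        )
        assert cmp_.overall_match

    def test_disjoint_products_mismatch(self):
        h = _ann("h", {"pw"}, {"CID:1"}, {"CID:2"})
        y = _ann("y", {"pw"}, {"CID:1"}, {"CID:9"})
        cmp_ = pathway_compare(h, y)
        assert cmp_.verdicts["pw"] == PathwayVerdict.MISMATCH
        assert not cmp_.overall_match

    def test_all_six_curated_pairs_match(self):
        """Every curated human/yeast candidate pair participates in the
        same pathway with identical substrate/product compound sets."""
        human = table2_annotations()
        yeast = table4_yeast_annotations()
        pair_of = {
            "P13716": "P05373", "P22830": "P16622", "P48637": "Q08220",
            "P49247": "Q12189", "Q96GX9": "P47095", "Q9Y2Z4": "P48527",
        }
        for h_acc, y_acc in pair_of.items():
            assert pathway_compare(human[h_acc], yeast[y_acc]).overall_match


def _cascade_inputs():
    """Packaged tables + planted conservation/paralog evidence reproducing
    the narrative cascade shape 34 -> 11 -> 10 -> 6."""
    candidates = table2_annotations()
    pairs = table1_ortholog_pairs()
    eleven = intersect_with_orthologs(set(candidates), pairs)
    # one pair fails conservation (planted; identity not asserted by data)
    conservation = {acc: acc != "O95363" for acc in eleven}
    paralog_dropouts = {"O43175", "O95336", "P04180", "Q6PI48"}
    pair_by_human = {p.human_acc: p for p in pairs}
    hit_tables = {}
    for acc in eleven:
        yeast_acc = pair_by_human[acc].yeast_acc
        hits = [_hit(acc, yeast_acc, 200.0)]
        if acc in paralog_dropouts:
            hits.append(_hit(acc, yeast_acc + "_sib", 190.0))
        hit_tables[acc] = hits
    return candidates, pairs, conservation, hit_tables, table4_yeast_annotations()


class TestFilterCascade:
    def test_cascade_shape_34_11_10_6(self):
        candidates, pairs, conservation, hit_tables, yeast_ann = _cascade_inputs()
        report = run_filter_cascade(
            candidates, pairs, conservation, hit_tables, yeast_ann
        )
        assert report.counts == {
            "one_one_one": 34,
            "reciprocal_ortholog": 11,
            "active_site_conserved": 10,
            "unique_ortholog": 6,
            "pathway_match": 6,
        }
        assert report.final_survivors() == FINAL_SIX

    def test_nesting_and_single_reason(self):
        candidates, pairs, conservation, hit_tables, yeast_ann = _cascade_inputs()
        report = run_filter_cascade(
            candidates, pairs, conservation, hit_tables, yeast_ann
        )
        previous = sorted(candidates)
        for stage in report.stages:
            assert set(report.survivors[stage]) <= set(previous)
            previous = report.survivors[stage]
        dropped = set(candidates) - set(report.final_survivors())
        assert dropped == set(report.exclusions)  # exactly one reason each

    def test_permutation_invariance(self):
        candidates, pairs, conservation, hit_tables, yeast_ann = _cascade_inputs()
        report_fwd = run_filter_cascade(
            candidates, pairs, conservation, hit_tables, yeast_ann
        )
        shuffled = dict(reversed(list(candidates.items())))
        report_rev = run_filter_cascade(
            shuffled, list(reversed(pairs)), conservation, hit_tables, yeast_ann
        )
        assert report_fwd.survivors == report_rev.survivors

    def test_missing_conservation_is_hard_error(self):
        candidates, pairs, conservation, hit_tables, yeast_ann = _cascade_inputs()
        conservation = dict(conservation)
        conservation.pop("P13716")
        with pytest.raises(InvalidInputError, match="conservation"):
            run_filter_cascade(
                candidates, pairs, conservation, hit_tables, yeast_ann
            )

    def test_single_pair_toy_all_pass(self):
        h = _ann("H1", {"pw"}, {"CID:1"}, {"CID:2"})
        y = _ann("Y1", {"pw"}, {"CID:1"}, {"CID:2"})
        from orthoflux.records import OrthologPair

        pair = OrthologPair("H1", "Y1", _hit("H1", "Y1", 200.0),
                            _hit("Y1", "H1", 198.0))
        report = run_filter_cascade(
            {"H1": h}, [pair], {"H1": True},
            {"H1": [_hit("H1", "Y1", 200.0)]}, {"Y1": y},
        )
        assert report.final_survivors() == ["H1"]

    def test_empty_input_empty_report(self):
        report = run_filter_cascade({}, [], {}, {}, {})
        assert all(report.survivors[s] == [] for s in report.stages)
        assert len(report.stages) == 5
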