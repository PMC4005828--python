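"""Collision detection, link auditing, generation, redundancy and
completeness."""

import pytest

from inchilink.fixtures import (
    D_SERINE,
    L_SERINE,
    SERINE,
    make_extended,
)
from inchilink.linkqc import (
    Entry,
    EntryCorpus,
    Link,
    check_link_consistency,
    completeness,
    consistency_grid,
    filter_redundant,
    find_collisions,
    generate_links,
    read_links_table,
    sdf_collision_candidates,
    validate_links,
    write_links_table,
)

WATER = "InChI=1S/H2O/h1H2"
ETHANOL = "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3"


def entry(entry_id, inchi=None, extended=None, sdf=None, db="db"):
    return Entry(db, entry_id, inchi=inchi, extended_inchi=extended, sdf=sdf)


class TestCollisions:
    def test_basic_grouping(self):
        entries = [entry("a", WATER), entry("b", WATER), entry("c", ETHANOL)]
        report = find_collisions(entries)
        assert report.groups == (("a", "b"),)
        assert report.pair_count == 1

    def test_empty_corpus(self):
        report = find_collisions([])
        assert report.groups == () and report.pair_count == 0

    def test_canonical_reserialization_detects_spelling_variants(self):
        spelled = "InChI=1S/2H2O/h2*1H2"
        expanded = "InChI=1S/H2O.H2O/h1H2;1H2"
        report = find_collisions([entry("a", spelled), entry("b", expanded)])
        assert report.pair_count == 1

    def test_tautomer_pair_collides_at_standard_level_only(self):
        ext1, ext2 = make_extended(WATER, 1), make_extended(WATER, 2)
        entries = [entry("a", WATER, ext1), entry("b", WATER, ext2)]
        assert find_collisions(entries, "standard").pair_count == 1
        assert find_collisions(entries, "extended").pair_count == 0

    def test_extended_pairs_subset_of_standard(self, scenario):
        std = find_collisions(scenario.entries_a, "standard")
        ext = find_collisions(scenario.entries_a, "extended")
        assert ext.pairs < std.pairs
        assert std.pair_count == scenario.truth.std_collision_pairs
        assert ext.pair_count == scenario.truth.ext_collision_pairs

    def test_entries_without_identifier_are_skipped_and_counted(self):
        report = find_collisions([entry("a", WATER), entry("b", None)])
        assert report.skipped == 1


class TestReviewBundles:
    def test_bundles_from_extended_report(self):
        ext = make_extended(WATER, 1)
        entries = [entry("a", WATER, ext, sdf="mol-a"),
                   entry("b", WATER, ext, sdf="mol-b"),
                   entry("c", WATER, ext)]
        report = find_collisions(entries, "extended")
        bundles = sdf_collision_candidates(report, entries)
        assert len(bundles) == 3
        gaps = [b for b in bundles if not b.complete]
        assert len(gaps) == 2  # both pairs involving c lack one file

    def test_requires_extended_level(self):
        report = find_collisions([], "standard")
        with pytest.raises(ValueError):
            sdf_collision_candidates(report, [])


class TestValidateLinks:
    def test_flags_and_counts(self):
        corpus = EntryCorpus([
            Entry("B", "1", inchi=WATER),
            Entry("B", "2", inchi=None),  # exists, no identifier
        ])
        links = [Link("A", "x", "B", "1"), Link("A", "y", "B", "2"),
                 Link("A", "z", "B", "gone")]
        corpus.add(Entry("A", "x", inchi=WATER))
        corpus.add(Entry("A", "y", inchi=WATER))
        corpus.add(Entry("A", "z", inchi=WATER))
        report = validate_links(links, corpus)
        assert report.total == 3
        assert report.valid == 2
        assert report.with_inchi == 1
        flags = {l.target_id: l.valid for l in report.links}
        assert flags == {"1": True, "2": True, "gone": False}


class TestConsistency:
    def test_self_links_are_consistent_everywhere(self):
        corpus = EntryCorpus([Entry("A", "x", inchi=WATER),
                              Entry("B", "x", inchi=WATER)])
        links = [Link("A", "x", "B", "x")]
        grid = consistency_grid(links, corpus)
        for row in grid.values():
            for report in row.values():
                assert report.inconsistent_fraction == 0.0

    def test_non_comparable_links_excluded_and_counted(self):
        opaque = WATER + "/rH2O/h1H2"
        corpus = EntryCorpus([Entry("A", "x", inchi=opaque),
                              Entry("B", "x", inchi=opaque)])
        report = check_link_consistency([Link("A", "x", "B", "x")], corpus,
                                        "CHsI", "strict")
        assert report.checked == 0
        assert report.not_comparable == 1

    def test_planted_rates_recovered_exactly(self, scenario, corpus):
        """Measured inconsistency fractions equal the construction's truth
        table for all twelve methods, with zero tolerance."""
        validation = validate_links(scenario.links, corpus)
        for (mode, policy), expected in \
                scenario.truth.inconsistent_fraction.items():
            report = check_link_consistency(validation.links, corpus,
                                            mode, policy)
            assert report.checked == scenario.truth.n_checked
            assert report.inconsistent_fraction == pytest.approx(
                expected, abs=0)


class TestGenerateLinks:
    def test_identical_and_compatible_basics(self):
        a = [entry("x", WATER, db="A")]
        b = [entry("y", WATER, db="B")]
        assert len(generate_links(a, b, "identical")) == 1
        assert len(generate_links(a, b, "compatible")) == 1

    def test_stereo_refinement_found_by_compatible_only(self):
        a = [entry("x", L_SERINE, db="A")]
        b = [entry("y", SERINE, db="B")]
        assert generate_links(a, b, "identical") == []
        links = generate_links(a, b, "compatible", "CHsI", "subset")
        assert [(l.source_id, l.target_id) for l in links] == [("x", "y")]

    def test_disjoint_skeletons_produce_no_links(self):
        a = [entry("x", WATER, db="A")]
        b = [entry("y", ETHANOL, db="B")]
        assert generate_links(a, b, "identical") == []
        assert generate_links(a, b, "compatible") == []

    def test_identical_count_matches_truth(self, scenario):
        links = generate_links(scenario.entries_a, scenario.entries_b,
                               "identical")
        assert len(links) == scenario.truth.identical_generated_links


class TestRedundancy:
    def a_entries(self):
        return [Entry("A", "serine", inchi=SERINE),
                Entry("A", "L-serine", inchi=L_SERINE)]

    def test_rule1_removes_less_specific_source(self):
        a = self.a_entries()
        b = [Entry("B", "L-serine", inchi=L_SERINE)]
        links = generate_links(a, b, "compatible", "CHsI", "subset")
        kept = filter_redundant(links, a, b, "CHsI", "subset")
        assert [(l.source_id, l.target_id) for l in kept] == \
            [("L-serine", "L-serine")]

    def test_rule2_removes_more_specific_source(self):
        a = self.a_entries()
        b = [Entry("B", "serine", inchi=SERINE)]
        links = generate_links(a, b, "compatible", "CHsI", "subset")
        kept = filter_redundant(links, a, b, "CHsI", "subset")
        assert [(l.source_id, l.target_id) for l in kept] == \
            [("serine", "serine")]

    def test_identical_identifier_links_never_removed(self):
        # both enantiomer entries and the undefined parent on each side:
        # every same-identifier link must survive filtering
        a = [Entry("A", "ser", inchi=SERINE), Entry("A", "L", inchi=L_SERINE),
             Entry("A", "D", inchi=D_SERINE)]
        b = [Entry("B", "ser", inchi=SERINE), Entry("B", "L", inchi=L_SERINE)]
        links = generate_links(a, b, "compatible", "CHsI", "subset")
        kept = filter_redundant(links, a, b, "CHsI", "subset")
        same = {(l.source_id, l.target_id) for l in links
                if l.source_id == l.target_id}
        assert same <= {(l.source_id, l.target_id) for l in kept}

    def test_filtering_is_idempotent_and_shrinking(self):
        a = self.a_entries()
        b = [Entry("B", "L-serine", inchi=L_SERINE),
             Entry("B", "serine", inchi=SERINE)]
        links = generate_links(a, b, "compatible", "CHsI", "subset")
        once = filter_redundant(links, a, b, "CHsI", "subset")
        twice = filter_redundant(once, a, b, "CHsI", "subset")
        assert set(l.endpoints for l in once) <= \
            set(l.endpoints for l in links)
        assert once == twice


class TestCompleteness:
    def corpus(self):
        return EntryCorpus([Entry("A", "1", inchi=WATER),
                            Entry("A", "2", inchi=ETHANOL),
                            Entry("B", "1", inchi=WATER),
                            Entry("B", "2", inchi=ETHANOL)])

    def test_percentage(self):
        manual = [Link("A", "1", "B", "1"), Link("A", "2", "B", "2")]
        generated = [Link("A", "1", "B", "1", provenance="generated")]
        report = completeness(manual, generated, "same-identifier",
                              entries=self.corpus())
        assert report.percent == pytest.approx(50.0)

    def test_all_found_is_100(self):
        manual = [Link("A", "1", "B", "1")]
        generated = [Link("A", "1", "B", "1"), Link("A", "2", "B", "2")]
        report = completeness(manual, generated, "same-identifier",
                              entries=self.corpus())
        assert report.percent == pytest.approx(100.0)

    def test_empty_restricted_set_is_not_applicable(self):
        manual = [Link("A", "1", "B", "2")]  # water -> ethanol: different
        report = completeness(manual, [], "same-identifier",
                              entries=self.corpus())
        assert not report.applicable and report.percent is None

    def test_monotone_in_generated_set(self):
        manual = [Link("A", "1", "B", "1"), Link("A", "2", "B", "2")]
        small = [Link("A", "1", "B", "1")]
        large = small + [Link("A", "2", "B", "2")]
        r_small = completeness(manual, small, "same-identifier",
                               entries=self.corpus())
        r_large = completeness(manual, large, "same-identifier",
                               entries=self.corpus())
        assert r_large.percent >= r_small.percent

    def test_merged_bidirectional_matching(self):
        manual = [Link("A", "1", "B", "1")]
        generated = [Link("B", "1", "A", "1", provenance="generated")]
        report = completeness(manual, generated, "same-identifier",
                              entries=self.corpus(), merged=True)
        assert report.percent == pytest.approx(100.0)


def test_links_table_round_trip(tmp_path):
    path = tmp_path / "links.tsv"
    links = [Link("A", "1", "B", "2"), Link("B", "2", "A", "1",
                                            provenance="generated")]
    write_links_table(path, links)
    assert read_links_table(path) == links
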