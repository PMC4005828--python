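"""The synthetic-data generator: determinism, declared degrade relations,
truth-table construction and the oracle's own base cases."""

import itertools

import pytest

from inchilink.compare import MODE_NAMES, is_subtype, link_consistent
from inchilink.errors import FixtureError
from inchilink.fixtures import (
    DEGRADE_OPS,
    FixtureSpec,
    SKELETONS,
    brute_force_subtype,
    degrade,
    gen_identifier,
    gen_linked_databases,
    make_extended,
    make_stereo_variant,
    stereo_variants,
)
from inchilink.inchi_model import parse_inchi, serialize_inchi


class TestGenIdentifier:
    def test_deterministic(self, spec):
        assert gen_identifier(spec, 42) == gen_identifier(spec, 42)

    def test_always_parsable_and_canonical(self, spec):
        for seed in range(100):
            text = gen_identifier(spec, seed)
            assert serialize_inchi(parse_inchi(text)) == text

    def test_stereo_disabled_spec(self):
        spec = FixtureSpec(designator_probs=(0, 0, 1), omit_undefined_prob=1.0)
        for seed in range(50):
            p = parse_inchi(gen_identifier(spec, seed))
            assert not any(k in p.sublayers for k in ("b", "t", "m", "s"))

    def test_forced_multicomponent(self):
        spec = FixtureSpec(multi_component_prob=1.0, max_components=2)
        assert any(parse_inchi(gen_identifier(spec, s)).component_count > 1
                   for s in range(20))

    def test_forced_defined_stereo(self, spec):
        for seed in range(30):
            text = gen_identifier(spec, seed, force_defined_stereo=True)
            p = parse_inchi(text).expand()
            t = p.sublayers.get("t", ("",))[0]
            assert any(sign in t for sign in "+-")


class TestDegrade:
    @pytest.mark.parametrize("op", DEGRADE_OPS)
    def test_declared_truth_matches_measured_relation(self, spec, op):
        """The declared (mode, policy) truth of every degrade operation is
        exactly what the comparison measures."""
        checked = 0
        for seed in range(40):
            text = gen_identifier(
                spec, seed,
                force_defined_stereo=op in ("undefine_stereo_center",
                                            "flip_stereo_center"))
            try:
                pair = degrade(parse_inchi(text), op, seed=seed)
            except FixtureError:
                continue
            checked += 1
            for (mode, policy), expected in pair.consistent.items():
                assert link_consistent(pair.original, pair.degraded,
                                       mode, policy) == expected, \
                    (op, seed, mode, policy)
        assert checked >= 30

    def test_undefine_gives_one_way_subtype(self, spec):
        text = gen_identifier(spec, 3, force_defined_stereo=True)
        pair = degrade(parse_inchi(text), "undefine_stereo_center", seed=3)
        assert pair.original_is_subtype
        assert is_subtype(pair.original, pair.degraded, "CHsI", "subset")
        assert not is_subtype(pair.degraded, pair.original, "CHsI", "subset")

    def test_inapplicable_op_signals(self):
        water = parse_inchi("InChI=1S/H2O/h1H2")
        with pytest.raises(FixtureError):
            degrade(water, "undefine_stereo_center", seed=0)

    def test_unknown_op_rejected(self):
        with pytest.raises(FixtureError):
            degrade(parse_inchi("InChI=1S/H2O/h1H2"), "no_such_op", seed=0)


class TestLinkedDatabases:
    def test_deterministic(self, spec):
        a = gen_linked_databases(spec, 7)
        b = gen_linked_databases(spec, 7)
        assert a.entries_a == b.entries_a
        assert a.links == b.links
        assert a.truth == b.truth

    def test_planted_duplicate_count(self):
        scenario = gen_linked_databases(
            FixtureSpec(n_entries_a=200, n_links=150, dup_rate=0.05), 7)
        assert scenario.truth.duplicate_pairs == 10

    def test_stereo_conflict_links_behave_as_planted(self, scenario, corpus):
        conflict_links = [k for k, cls in scenario.link_classes.items()
                          if cls == "stereo_conflict"]
        assert conflict_links
        for src_db, src_id, tgt_db, tgt_id in conflict_links:
            x = corpus.parsed((src_db, src_id))
            y = corpus.parsed((tgt_db, tgt_id))
            for mode in ("CHSI", "CHsI", "ChsI", "Chs-"):
                assert not link_consistent(x, y, mode, "strict")
            for mode in ("Ch-I", "C---"):
                assert link_consistent(x, y, mode, "strict")

    def test_every_identifier_round_trips(self, scenario):
        for entry in itertools.chain(scenario.entries_a, scenario.entries_b):
            if entry.inchi:
                assert serialize_inchi(parse_inchi(entry.inchi)) == entry.inchi
            if entry.extended_inchi:
                assert serialize_inchi(parse_inchi(entry.extended_inchi)) \
                    == entry.extended_inchi

    def test_undersized_corpus_rejected(self):
        with pytest.raises(FixtureError):
            gen_linked_databases(FixtureSpec(n_entries_a=50, n_links=100), 0)


class TestExtended:
    def test_extended_tags_differ(self):
        base = "InChI=1S/H2O/h1H2"
        assert make_extended(base, 1) != make_extended(base, 2)
        p = parse_inchi(make_extended(base, 1))
        assert p.fixed_h is not None and p.version == "1"


class TestBruteForceOracle:
    def test_fully_specified_identity(self):
        x = make_stereo_variant("threonine", {"2": "-", "3": "+"}, "0")
        assert brute_force_subtype(x, x, "CHsI")

    def test_specified_below_unspecified_not_converse(self):
        full = make_stereo_variant("threonine", {"2": "-", "3": "+"}, "0")
        blank = make_stereo_variant("threonine", {"2": "?", "3": "?"}, None)
        assert brute_force_subtype(full, blank, "CHsI")
        assert not brute_force_subtype(blank, full, "CHsI")

    def test_enantiomer_pair_disjoint(self):
        l = make_stereo_variant("serine", {"2": "-"}, "0")
        d = make_stereo_variant("serine", {"2": "-"}, "1")
        assert not brute_force_subtype(l, d, "CHsI")
        assert not brute_force_subtype(d, l, "CHsI")

    def test_center_bound_refusal(self):
        # five defined centers exceed the enumeration bound
        text = ("InChI=1S/C6H14O6/c7-1-3(9)5(11)6(12)4(10)2-8/"
                "h3-12H,1-2H2/t1-,2-,3-,4-,5-/m0/s1")
        p = parse_inchi(text)
        with pytest.raises(FixtureError):
            brute_force_subtype(p, p, "CHsI")

    def test_variants_cover_all_patterns(self):
        variants = stereo_variants("serine")
        # 3 designators, times two orientations for the defined ones
        assert len(variants) == 2 * 2 + 1

    @pytest.mark.parametrize("mode", MODE_NAMES)
    def test_oracle_agrees_with_comparison_on_random_pairs(self, spec, mode):
        variants = stereo_variants("threonine")
        for x, y in itertools.product(variants[:8], variants[:8]):
            assert brute_force_subtype(x, y, mode) == \
                is_subtype(x, y, mode, "strict")
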