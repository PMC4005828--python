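"""The subtype relation: stripping, stereo compatibility, modes and
policies."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from inchilink.compare import (
    MODE_IMPLICATIONS,
    MODE_NAMES,
    component_subtype,
    invert_tetrahedral,
    is_subtype,
    link_consistent,
    stereo_compatible,
    strip,
    strip_hydrogens_from_formula,
)
from inchilink.errors import NotComparableError
from inchilink.fixtures import (
    D_SERINE,
    L_SERINE,
    SERINE,
    FixtureSpec,
    gen_identifier,
    make_stereo_variant,
)
from inchilink.inchi_model import parse_inchi, parse_stereo_tokens

ETHANOL = "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3"


def tokens(text):
    return parse_stereo_tokens(text)


class TestInvert:
    def test_swaps_signs_keeps_undefined(self):
        assert invert_tetrahedral(tokens("2-,3+,4?")) == tokens("2+,3-,4?")

    def test_empty(self):
        assert invert_tetrahedral(()) == ()

    @pytest.mark.parametrize("text", ["", "2-", "2-,3+,4?", "1+,2+"])
    def test_involution(self, text):
        assert invert_tetrahedral(invert_tetrahedral(tokens(text))) \
            == tokens(text)


class TestStereoCompatible:
    def test_defined_in_y_must_be_defined_in_x(self):
        assert stereo_compatible(tokens("2-,1+"), tokens("2-,1?"))
        assert not stereo_compatible(tokens("2-,1?"), tokens("2-,1+"))

    def test_identity(self):
        assert stereo_compatible(tokens("2-,1+"), tokens("2-,1+"))

    def test_empty_x_cannot_cover_defined_y(self):
        assert not stereo_compatible((), tokens("2-,1+"))

    def test_absent_center_in_y_is_unconstrained(self):
        assert stereo_compatible(tokens("2-,3+"), tokens("3+"))


class TestStrip:
    def test_connections_only_drops_hydrogens(self):
        s = strip(parse_inchi(ETHANOL), "C---")
        assert s.formula == ("C2O",)
        assert s.sublayer("c") == ("1-2-3",)
        assert set(s.sublayers) == {"c"}

    @pytest.mark.parametrize("term,expected", [
        ("C2H6O", "C2O"), ("H2O", "O"), ("ClH", "Cl"), ("H3N", "N"),
        ("H2O4S", "O4S"), ("HgH2", "Hg"), ("CH4", "C"),
    ])
    def test_hydrogen_removal_respects_two_letter_symbols(self, term,
                                                          expected):
        assert strip_hydrogens_from_formula(term) == expected

    def test_isotope_stripping_removes_whole_isotopic_layer(self):
        p = parse_inchi(ETHANOL + "/i1+1")
        s = strip(p, "Chs-")
        assert "i" not in s.sublayers
        assert s.sublayer("h") == parse_inchi(ETHANOL).sublayer("h")

    def test_stereo_stripping_covers_isotopic_stereo(self):
        p = parse_inchi(L_SERINE + "/i1+1/t2-/m0/s1")
        s = strip(p, "Ch-I")
        assert not any(k in s.sublayers
                       for k in ("b", "t", "m", "s", "i/t", "i/m", "i/s"))
        assert "i" in s.sublayers

    def test_identity_mode_is_noop(self):
        p = parse_inchi(L_SERINE)
        assert strip(p, "CHSI") == p


class TestComponentSubtype:
    @pytest.mark.parametrize("mode", MODE_NAMES)
    def test_reflexive(self, mode):
        p = parse_inchi(L_SERINE)
        assert component_subtype(p, p, mode)

    def test_m_inversion_example(self):
        # x defines centers 2 and 3; y defines center 3 only, rendered in
        # the opposite orientation: inverting y's /t (with its /m) aligns
        # them, so x is more specific than y.
        x = make_stereo_variant("threonine", {"2": "-", "3": "+"}, "0")
        y = make_stereo_variant("threonine", {"2": "?", "3": "-"}, "1")
        assert component_subtype(x, y, "CHsI")
        assert not component_subtype(y, x, "CHsI")

    def test_skeleton_mismatch_fails_even_connections_only(self):
        x = parse_inchi(ETHANOL)
        y = parse_inchi("InChI=1S/C2H4O2/c1-2(3)4/h1H3,(H,3,4)")
        for mode in MODE_NAMES:
            assert not component_subtype(x, y, mode)

    def test_opaque_identifier_refused_not_false(self):
        p = parse_inchi(ETHANOL + "/rC2H6O/c1-2-3")
        with pytest.raises(NotComparableError):
            component_subtype(p, parse_inchi(ETHANOL), "CHsI")

    def test_extended_identifier_refused_for_subtype(self):
        p = parse_inchi("InChI=1/C2H6O/c1-2-3/h3H,2H2,1H3/f/h3H")
        with pytest.raises(NotComparableError):
            component_subtype(p, p, "CHsI")


class TestIsSubtype:
    def test_additive_allowed_by_subset_only(self):
        compound = parse_inchi(
            "InChI=1S/C2H4O2.H2O/c1-2(3)4;/h1H3,(H,3,4);1H2")
        plain = parse_inchi("InChI=1S/C2H4O2/c1-2(3)4/h1H3,(H,3,4)")
        assert not is_subtype(compound, plain, "CHsI", "strict")
        assert is_subtype(compound, plain, "CHsI", "subset")

    def test_uncovered_component_fails_subset(self):
        compound = parse_inchi(
            "InChI=1S/C2H4O2.H2O/c1-2(3)4;/h1H3,(H,3,4);1H2")
        plain = parse_inchi("InChI=1S/C2H4O2/c1-2(3)4/h1H3,(H,3,4)")
        assert not is_subtype(plain, compound, "CHsI", "subset")

    def test_different_salts_not_linked(self):
        acid_na = parse_inchi(
            "InChI=1S/C2H4O2.Na/c1-2(3)4;/h1H3,(H,3,4);/q;+1/p-1")
        acid_k = parse_inchi(
            "InChI=1S/C2H4O2.K/c1-2(3)4;/h1H3,(H,3,4);/q;+1/p-1")
        assert not is_subtype(acid_na, acid_k, "CHsI", "subset")
        assert not is_subtype(acid_k, acid_na, "CHsI", "subset")

    def test_protonation_difference_ignored_from_chsi_down(self):
        neutral = parse_inchi(ETHANOL)
        protonated = parse_inchi(ETHANOL + "/p+1")
        assert not link_consistent(neutral, protonated, "CHsI")
        assert link_consistent(neutral, protonated, "ChsI")


class TestLinkConsistent:
    def test_identical_consistent_under_all_methods(self):
        p = parse_inchi(L_SERINE)
        for mode, policy in itertools.product(MODE_NAMES,
                                              ("strict", "subset")):
            assert link_consistent(p, p, mode, policy)

    def test_stereo_refinement_consistent_under_chsi_not_chsi_identity(self):
        defined = parse_inchi(L_SERINE)
        undefined = parse_inchi(SERINE)
        assert not link_consistent(defined, undefined, "CHSI")
        assert link_consistent(defined, undefined, "CHsI")

    def test_enantiomers_conflict_until_stereo_ignored(self):
        l, d = parse_inchi(L_SERINE), parse_inchi(D_SERINE)
        for mode in ("CHSI", "CHsI", "ChsI", "Chs-"):
            assert not link_consistent(l, d, mode)
        for mode in ("Ch-I", "C---"):
            assert link_consistent(l, d, mode)

    def test_different_skeletons_inconsistent_everywhere(self):
        x = parse_inchi(ETHANOL)
        y = parse_inchi("InChI=1S/CH4/h1H4")
        for mode, policy in itertools.product(MODE_NAMES,
                                              ("strict", "subset")):
            assert not link_consistent(x, y, mode, policy)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10 ** 6),
       st.integers(min_value=0, max_value=10 ** 6))
def test_mode_and_policy_implication_lattice(seed_a, seed_b):
    """Consistency under a stronger method implies consistency under every
    weaker one, on arbitrary generated pairs (including equal seeds,
    i.e. reflexive pairs)."""
    spec = FixtureSpec()
    x = parse_inchi(gen_identifier(spec, seed_a))
    y = parse_inchi(gen_identifier(spec, seed_b))
    verdict = {(m, pol): link_consistent(x, y, m, pol)
               for m in MODE_NAMES for pol in ("strict", "subset")}
    for strong, weak in MODE_IMPLICATIONS:
        for pol in ("strict", "subset"):
            assert not (verdict[(strong, pol)] and not verdict[(weak, pol)])
    for m in MODE_NAMES:
        assert not (verdict[(m, "strict")] and not verdict[(m, "subset")])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10 ** 6),
       st.integers(min_value=0, max_value=10 ** 6),
       st.integers(min_value=0, max_value=10 ** 6))
def test_subtype_is_transitive_under_strict_policy(sa, sb, sc):
    spec = FixtureSpec()
    ids = [parse_inchi(gen_identifier(spec, s)) for s in (sa, sb, sc)]
    for mode in ("CHsI", "ChsI", "C---"):
        for x, y, z in itertools.permutations(ids, 3):
            if is_subtype(x, y, mode, "strict") and \
                    is_subtype(y, z, mode, "strict"):
                assert is_subtype(x, z, mode, "strict")
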