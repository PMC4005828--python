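"""Deterministic synthetic identifiers, mini-databases, link sets and the
brute-force subtype oracle.

The generator decorates a bundled library of real small-molecule
skeletons (verified identifier strings, frozen as constants) with
stereochemistry, charge, protonation and isotope sub-layers, and
assembles multicomponent identifiers from them.  The decorated strings
are syntactically valid and exercise every comparison path, but they are
not claimed to be canonical outputs of the official algorithm — chemical
realism stops at the skeleton level.

Everything is seeded: identical spec + seed give byte-identical output.
Planted corpora come with exact truth tables (collision pair counts,
per-method inconsistency fractions, identical-link counts) computed from
the construction itself, never from the comparison code under test.
"""

from __future__ import annotations

import random
from dataclasses import asdict, dataclass
from itertools import product
from typing import Mapping, Optional, Sequence, Union

from .compare import MODE_NAMES, MODES, ComparisonMode, strip
from .components import ComponentView, reassemble, split_components
from .errors import FixtureError, InChIStructureError
from .inchi_model import (
    ParsedInChI,
    StereoToken,
    parse_inchi,
    parse_stereo_tokens,
    render_stereo_tokens,
    serialize_inchi,
)
from .linkqc import Entry, Link

__all__ = [
    "Skeleton",
    "SKELETONS",
    "FixtureSpec",
    "gen_identifier",
    "degrade",
    "DegradedPair",
    "gen_linked_databases",
    "LinkedDatabases",
    "TruthTables",
    "brute_force_subtype",
    "make_extended",
    "make_stereo_variant",
    "stereo_variants",
    "make_molfile",
    "TOY_MOLFILES",
    "violation_records",
    "warning_records",
    "CLEAN_ETHANOL_SDF",
]


# ---------------------------------------------------------------------------
# skeleton library
#
# Identifier strings generated once with the official InChI algorithm
# (via its embedded library) from the named structures and frozen here;
# a cross-check against that library lives in the test-suite.

@dataclass(frozen=True)
class Skeleton:
    """A verified stereo-free identifier plus the canonical ids of its
    prochiral tetrahedral centers and double bonds (taken from the fully
    stereo-defined form of the same structure)."""

    name: str
    base: str
    t_centers: tuple[str, ...] = ()
    b_bonds: tuple[str, ...] = ()


SKELETONS: dict[str, Skeleton] = {s.name: s for s in [
    Skeleton("water", "InChI=1S/H2O/h1H2"),
    Skeleton("methane", "InChI=1S/CH4/h1H4"),
    Skeleton("ammonia", "InChI=1S/H3N/h1H3"),
    Skeleton("ethanol", "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3"),
    Skeleton("acetic_acid", "InChI=1S/C2H4O2/c1-2(3)4/h1H3,(H,3,4)"),
    Skeleton("benzene", "InChI=1S/C6H6/c1-2-4-6-5-3-1/h1-6H"),
    Skeleton("glycine", "InChI=1S/C2H5NO2/c3-1-2(4)5/h1,3H2,(H,4,5)"),
    Skeleton("serine",
             "InChI=1S/C3H7NO3/c4-2(1-5)3(6)7/h2,5H,1,4H2,(H,6,7)",
             t_centers=("2",)),
    Skeleton("alanine",
             "InChI=1S/C3H7NO2/c1-2(4)3(5)6/h2H,4H2,1H3,(H,5,6)",
             t_centers=("2",)),
    Skeleton("threonine",
             "InChI=1S/C4H9NO3/c1-2(6)3(5)4(7)8/h2-3,6H,5H2,1H3,(H,7,8)",
             t_centers=("2", "3")),
    Skeleton("tartaric_acid",
             "InChI=1S/C4H6O6/c5-1(3(7)8)2(6)4(9)10/h1-2,5-6H,(H,7,8)(H,9,10)",
             t_centers=("1", "2")),
    Skeleton("ribose_open",
             "InChI=1S/C5H10O5/c6-1-3(8)5(10)4(9)2-7/h1,3-5,7-10H,2H2",
             t_centers=("3", "4", "5")),
    Skeleton("glucose_open",
             "InChI=1S/C6H12O6/c7-1-3(9)5(11)6(12)4(10)2-8/h1,3-6,8-12H,2H2",
             t_centers=("3", "4", "5", "6")),
    Skeleton("butene2", "InChI=1S/C4H8/c1-3-4-2/h3-4H,1-2H3",
             b_bonds=("4-3",)),
    Skeleton("hexadiene24", "InChI=1S/C6H10/c1-3-5-6-4-2/h3-6H,1-2H3",
             b_bonds=("5-3", "6-4")),
    Skeleton("fumaric_acid",
             "InChI=1S/C4H4O4/c5-3(6)1-2-4(7)8/h1-2H,(H,5,6)(H,7,8)",
             b_bonds=("2-1",)),
    Skeleton("sulfuric_acid", "InChI=1S/H2O4S/c1-5(2,3)4/h(H2,1,2,3,4)"),
    Skeleton("sodium_cation", "InChI=1S/Na/q+1"),
    Skeleton("chloride", "InChI=1S/ClH/h1H/p-1"),
]}

#: L-serine and D-serine, frozen for the redundancy-rule worked examples.
L_SERINE = "InChI=1S/C3H7NO3/c4-2(1-5)3(6)7/h2,5H,1,4H2,(H,6,7)/t2-/m0/s1"
D_SERINE = "InChI=1S/C3H7NO3/c4-2(1-5)3(6)7/h2,5H,1,4H2,(H,6,7)/t2-/m1/s1"
SERINE = SKELETONS["serine"].base

#: skeleton names usable inside randomly assembled mixtures (their /p is
#: folded into the identifier-level protons value)
_POOL = tuple(n for n in SKELETONS)
_STEREO_POOL = tuple(n for n, s in SKELETONS.items() if s.t_centers)


# ---------------------------------------------------------------------------
# specification

@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic corpora.

    Per-class link rates mirror the magnitudes observed on real curated
    cross-reference sets: a few percent of links broken at the skeleton
    level, a larger share differing only in stereochemistry, and small
    shares differing in protonation or isotopes; one entry in twenty is a
    planted duplicate.
    """

    # identifier decoration
    multi_component_prob: float = 0.25
    max_components: int = 3
    designator_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)  # + - ?
    omit_undefined_prob: float = 0.5
    charge_prob: float = 0.15
    protonation_prob: float = 0.15
    isotope_prob: float = 0.10
    # corpora
    n_entries_a: int = 200
    n_links: int = 150
    dup_rate: float = 0.05
    tautomer_dup_frac: float = 0.5
    invalid_link_rate: float = 0.02
    missing_inchi_rate: float = 0.02
    # planted inconsistency classes (fractions of checked links)
    undefined_stereo_rate: float = 0.10
    extra_component_rate: float = 0.05
    protonation_rate: float = 0.04
    isotope_rate: float = 0.03
    stereo_conflict_rate: float = 0.05
    skeleton_mismatch_rate: float = 0.03

    @classmethod
    def from_dict(cls, data: Mapping) -> "FixtureSpec":
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {}
        for k, v in data.items():
            if k not in known:
                raise FixtureError(f"unknown fixture spec field {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# identifier generation

def _choose_sign(rng: random.Random, probs) -> str:
    return rng.choices("+-?", weights=probs, k=1)[0]


def _decorated_component(skel: Skeleton, rng: random.Random,
                         spec: FixtureSpec,
                         force_defined_stereo: bool = False
                         ) -> tuple[ParsedInChI, int]:
    """One decorated single-component identifier plus the protons value it
    contributes to the assembled identifier."""
    base = parse_inchi(skel.base).expand()
    sub = dict(base.sublayers)
    protons = base.protons
    sub.pop("p", None)

    t_tokens: list[StereoToken] = []
    for center in skel.t_centers:
        sign = _choose_sign(rng, spec.designator_probs)
        if force_defined_stereo and not any(t.sign != "?" for t in t_tokens) \
                and center == skel.t_centers[-1] and sign == "?":
            sign = rng.choice("+-")
        if sign == "?" and rng.random() < spec.omit_undefined_prob:
            continue
        t_tokens.append(StereoToken(center, sign))
    b_tokens: list[StereoToken] = []
    for bond in skel.b_bonds:
        sign = _choose_sign(rng, spec.designator_probs)
        if force_defined_stereo and not skel.t_centers \
                and bond == skel.b_bonds[-1] and sign == "?" \
                and not any(t.sign != "?" for t in b_tokens):
            sign = rng.choice("+-")
        if sign == "?" and rng.random() < spec.omit_undefined_prob:
            continue
        b_tokens.append(StereoToken(bond, sign))

    defined_t = any(t.sign != "?" for t in t_tokens)
    defined = defined_t or any(t.sign != "?" for t in b_tokens)
    if b_tokens:
        sub["b"] = (render_stereo_tokens(b_tokens),)
    if t_tokens:
        sub["t"] = (render_stereo_tokens(t_tokens),)
    if defined_t:
        sub["m"] = (rng.choice("01"),)
    if defined:
        sub["s"] = ("1",)

    if rng.random() < spec.charge_prob:
        charge = rng.choice(("+1", "-1", "+2"))
        sub["q"] = (charge,)
    if rng.random() < spec.isotope_prob:
        sub["i"] = (f"1{rng.choice(('+1', '+2', '-1'))}",)
    return ParsedInChI("1S", base.formula, sub), protons


def gen_identifier(spec: FixtureSpec, seed: int,
                   force_defined_stereo: bool = False,
                   skeleton: Optional[str] = None) -> str:
    """One syntactically valid identifier over the bundled skeletons."""
    rng = random.Random(f"{seed}:gen")
    return _gen_identifier_rng(spec, rng, force_defined_stereo, skeleton)


def _gen_identifier_rng(spec: FixtureSpec, rng: random.Random,
                        force_defined_stereo: bool = False,
                        skeleton: Optional[str] = None) -> str:
    if skeleton is not None:
        names = [skeleton]
    else:
        pool = _STEREO_POOL if force_defined_stereo else _POOL
        names = [rng.choice(pool)]
        if spec.multi_component_prob > 0 and rng.random() < spec.multi_component_prob:
            extra = rng.randint(1, max(1, spec.max_components - 1))
            names += [rng.choice(_POOL) for _ in range(extra)]
    views: list[ComponentView] = []
    protons = 0
    for i, name in enumerate(names):
        comp, p_contrib = _decorated_component(
            SKELETONS[name], rng, spec,
            force_defined_stereo=force_defined_stereo and i == 0)
        protons += p_contrib
        views.append(ComponentView(comp, i + 1))
    assembled = reassemble(views)
    if rng.random() < spec.protonation_prob:
        protons += rng.choice((-1, 1))
    if protons:
        sub = dict(assembled.sublayers)
        sub["p"] = (f"{protons:+d}",)
        assembled = ParsedInChI(assembled.version, assembled.formula, sub)
    return serialize_inchi(assembled)


def make_extended(standard: str, tautomer_tag: int) -> str:
    """A synthetic extended identifier: the standard layers re-versioned
    as non-standard plus a fixed-hydrogen layer whose content encodes the
    tautomeric form.  Entries for distinct tautomers share the standard
    identifier but differ here."""
    if not standard.startswith("InChI=1S/"):
        raise FixtureError("expected a standard identifier")
    body = standard[len("InChI=1S/"):]
    return f"InChI=1/{body}/f/h{tautomer_tag}H"


# ---------------------------------------------------------------------------
# degradation with declared ground truth

_ALWAYS = frozenset(MODE_NAMES)
#: mode names under which a link between the original and the degraded
#: identifier is inconsistent (same for both policies unless noted)
_OP_INCONSISTENT_MODES: dict[str, frozenset[str]] = {
    "undefine_stereo_center": frozenset({"CHSI"}),
    "flip_stereo_center": frozenset({"CHSI", "CHsI", "ChsI", "Chs-"}),
    "drop_protons": frozenset({"CHSI", "CHsI"}),
    "change_isotope": frozenset({"CHSI", "CHsI", "ChsI", "Ch-I"}),
    "mutate_skeleton": _ALWAYS,
    "add_component": frozenset(),  # strict policy handled separately
}

DEGRADE_OPS = tuple(_OP_INCONSISTENT_MODES)


@dataclass(frozen=True)
class DegradedPair:
    """A degraded identifier plus the by-construction truth about its
    relation to the original: for every (mode, policy) whether a link
    between the two is consistent, and whether the original is a subtype
    of the degraded form under CHsI."""

    original: ParsedInChI
    degraded: ParsedInChI
    op: str
    consistent: Mapping[tuple[str, str], bool]
    original_is_subtype: bool


def _truth_for_op(op: str) -> dict[tuple[str, str], bool]:
    truth = {}
    for mode in MODE_NAMES:
        for policy in ("strict", "subset"):
            if op == "add_component":
                truth[(mode, policy)] = policy == "subset"
            else:
                truth[(mode, policy)] = mode not in _OP_INCONSISTENT_MODES[op]
    return truth


def degrade(p: ParsedInChI, op: str, seed: int) -> DegradedPair:
    """Apply one declared-relation mutation to the first component.

    ``undefine_stereo_center`` makes a defined center undefined (sometimes
    re-rendering the component in the inverted ``/t``+``/m`` orientation,
    which a comparison must treat as the same description);
    ``flip_stereo_center`` plants a genuine stereo conflict;
    ``drop_protons`` toggles the protons sub-layer; ``change_isotope``
    alters the isotopic layer; ``add_component`` appends an additive;
    ``mutate_skeleton`` replaces the first component's skeleton.  Raises
    :class:`FixtureError` when the operation does not apply.
    """
    if op not in _OP_INCONSISTENT_MODES:
        raise FixtureError(f"unknown degrade op {op!r}")
    rng = random.Random(f"{seed}:{op}")
    e = p.expand()
    views = split_components(e)
    first = views[0].inchi

    if op in ("undefine_stereo_center", "flip_stereo_center"):
        t_tokens = list(parse_stereo_tokens(
            first.sublayers.get("t", ("",))[0]))
        b_tokens = list(parse_stereo_tokens(
            first.sublayers.get("b", ("",))[0]))
        t_defined = [i for i, t in enumerate(t_tokens) if t.sign != "?"]
        b_defined = [i for i, t in enumerate(b_tokens) if t.sign != "?"]
        sub = dict(first.sublayers)
        if t_defined:
            idx = rng.choice(t_defined)
            if op == "undefine_stereo_center":
                t_tokens[idx] = StereoToken(t_tokens[idx].center, "?")
                still_defined = [t for t in t_tokens if t.sign != "?"]
                if still_defined and rng.random() < 0.5:
                    # equivalent inverted rendering of the same description
                    t_tokens = [StereoToken(t.center,
                                            {"+": "-", "-": "+", "?": "?"}[t.sign])
                                for t in t_tokens]
                    m = sub.get("m", ("0",))[0]
                    sub["m"] = ("1" if m == "0" else "0",)
                if not still_defined:
                    sub.pop("m", None)
                    if not b_defined:
                        sub.pop("s", None)
            else:
                flip = {"+": "-", "-": "+"}[t_tokens[idx].sign]
                t_tokens[idx] = StereoToken(t_tokens[idx].center, flip)
            sub["t"] = (render_stereo_tokens(t_tokens),)
        elif b_defined:
            idx = rng.choice(b_defined)
            if op == "undefine_stereo_center":
                b_tokens[idx] = StereoToken(b_tokens[idx].center, "?")
                if not any(t.sign != "?" for t in b_tokens):
                    sub.pop("s", None)
            else:
                flip = {"+": "-", "-": "+"}[b_tokens[idx].sign]
                b_tokens[idx] = StereoToken(b_tokens[idx].center, flip)
            sub["b"] = (render_stereo_tokens(b_tokens),)
        else:
            raise FixtureError("identifier has no defined stereo to degrade")
        new_first = ParsedInChI(first.version, first.formula, sub)

    elif op == "drop_protons":
        assembled = e
        sub_all = dict(assembled.sublayers)
        if "p" in sub_all:
            sub_all.pop("p")
        else:
            sub_all["p"] = (rng.choice(("+1", "-1")),)
        degraded = ParsedInChI(e.version, e.formula, sub_all, e.fixed_h, e.opaque)
        return DegradedPair(e, degraded, op, _truth_for_op(op),
                            original_is_subtype=False)

    elif op == "change_isotope":
        sub = dict(first.sublayers)
        current = sub.get("i", ("",))[0]
        sub["i"] = ("1+2",) if current != "1+2" else ("1+1",)
        new_first = ParsedInChI(first.version, first.formula, sub)

    elif op == "add_component":
        extra, p_contrib = _decorated_component(
            SKELETONS["water"], rng, FixtureSpec(charge_prob=0,
                                                 isotope_prob=0))
        new_views = views + [ComponentView(extra, len(views) + 1)]
        degraded = reassemble(new_views)
        return DegradedPair(e, degraded, op, _truth_for_op(op),
                            original_is_subtype=False)

    else:  # mutate_skeleton
        current_heavy = strip(views[0].inchi, "C---")
        candidates = [n for n in _POOL if n != "chloride"]
        rng.shuffle(candidates)
        new_first = None
        for name in candidates:
            cand, _ = _decorated_component(
                SKELETONS[name], rng, FixtureSpec(charge_prob=0,
                                                  isotope_prob=0,
                                                  protonation_prob=0))
            if strip(cand, "C---") != current_heavy:
                new_first = cand
                break
        if new_first is None:  # cannot happen with the bundled library
            raise FixtureError("no alternative skeleton available")
        if "p" in first.sublayers:
            sub = dict(new_first.sublayers)
            sub["p"] = first.sublayers["p"]
            new_first = ParsedInChI(new_first.version, new_first.formula, sub)

    new_views = [ComponentView(new_first, 1)] + [
        ComponentView(v.inchi, i + 2) for i, v in enumerate(views[1:])]
    degraded = reassemble(new_views)
    return DegradedPair(e, degraded, op, _truth_for_op(op),
                        original_is_subtype=(op == "undefine_stereo_center"))


# ---------------------------------------------------------------------------
# linked mini-databases with exact truth tables

#: link classes planted between corpora, in deterministic order
_LINK_CLASSES = ("identical", "undefined_stereo", "extra_component",
                 "protonation", "isotope", "stereo_conflict",
                 "skeleton_mismatch")

_CLASS_TO_OP = {
    "undefined_stereo": "undefine_stereo_center",
    "extra_component": "add_component",
    "protonation": "drop_protons",
    "isotope": "change_isotope",
    "stereo_conflict": "flip_stereo_center",
    "skeleton_mismatch": "mutate_skeleton",
}


@dataclass(frozen=True)
class TruthTables:
    """By-construction expectations for one generated scenario.  The
    inconsistency fractions are percentages of checked links and must be
    reproduced with zero tolerance."""

    n_entries_a: int
    n_entries_b: int
    n_links: int
    n_valid: int
    n_checked: int
    class_counts: Mapping[str, int]
    duplicate_pairs: int
    tautomer_pairs: int
    std_collision_pairs: int
    ext_collision_pairs: int
    inconsistent_fraction: Mapping[tuple[str, str], float]
    identical_generated_links: int


@dataclass(frozen=True)
class LinkedDatabases:
    entries_a: tuple[Entry, ...]
    entries_b: tuple[Entry, ...]
    links: tuple[Link, ...]
    truth: TruthTables
    link_classes: Mapping[tuple[str, str, str, str], str]


def _exact_counts(spec: FixtureSpec, n_checked: int) -> dict[str, int]:
    counts = {
        "undefined_stereo": round(spec.undefined_stereo_rate * n_checked),
        "extra_component": round(spec.extra_component_rate * n_checked),
        "protonation": round(spec.protonation_rate * n_checked),
        "isotope": round(spec.isotope_rate * n_checked),
        "stereo_conflict": round(spec.stereo_conflict_rate * n_checked),
        "skeleton_mismatch": round(spec.skeleton_mismatch_rate * n_checked),
    }
    planted = sum(counts.values())
    if planted > n_checked:
        raise FixtureError("planted class rates exceed the checked link count")
    counts["identical"] = n_checked - planted
    return counts


def gen_linked_databases(spec: FixtureSpec, seed: int) -> LinkedDatabases:
    """Two corpora plus a manual link set with planted duplicates and
    per-class inconsistencies, and the exact truth tables describing them.
    """
    rng = random.Random(f"{seed}:db")
    n_a = spec.n_entries_a
    n_dup = round(n_a * spec.dup_rate)
    n_links = spec.n_links
    if n_links + 2 * n_dup > n_a:
        raise FixtureError(
            "n_entries_a must cover the link sources and duplicate pairs")

    n_invalid = round(spec.invalid_link_rate * n_links)
    n_missing = round(spec.missing_inchi_rate * n_links)
    n_checked = n_links - n_invalid - n_missing
    counts = _exact_counts(spec, n_checked)

    # class assignment per link index (checked classes first, then the
    # unchecked invalid / missing-identifier links)
    classes: list[str] = []
    for cls in _LINK_CLASSES:
        classes.extend([cls] * counts[cls])
    classes.extend(["invalid"] * n_invalid)
    classes.extend(["missing_inchi"] * n_missing)
    rng.shuffle(classes)

    # unique identifier pool for corpus A; stereo-degradable identifiers
    # for sources of the stereo classes
    seen: set[str] = set()
    identifiers: list[str] = []
    for i in range(n_a):
        needs_stereo = i < n_links and classes[i] in (
            "undefined_stereo", "stereo_conflict")
        while True:
            text = _gen_identifier_rng(spec, rng,
                                       force_defined_stereo=needs_stereo)
            if text not in seen:
                seen.add(text)
                identifiers.append(text)
                break

    # planted duplicates live outside the link-source range
    dup_zone = list(range(n_links, n_a))
    rng.shuffle(dup_zone)
    dup_pairs = [(dup_zone[2 * k], dup_zone[2 * k + 1]) for k in range(n_dup)]
    n_tautomer = round(n_dup * spec.tautomer_dup_frac)
    extended: dict[int, str] = {}
    for k, (i, j) in enumerate(dup_pairs):
        identifiers[j] = identifiers[i]
        if k < n_tautomer:  # same standard identifier, different tautomer
            extended[i] = make_extended(identifiers[i], 4)
            extended[j] = make_extended(identifiers[i], 5)
        else:  # true duplicate: extended identifiers collide as well
            extended[i] = make_extended(identifiers[i], 4)
            extended[j] = make_extended(identifiers[i], 4)

    entries_a = []
    for i, text in enumerate(identifiers):
        entries_a.append(Entry("A", f"A{i:04d}", inchi=text,
                               extended_inchi=extended.get(i),
                               sdf=TOY_MOLFILES["ethanol"][0]
                               if i in extended else None))

    # corpus B and the manual link set
    entries_b: list[Entry] = []
    links: list[Link] = []
    link_classes: dict[tuple[str, str, str, str], str] = {}
    for i in range(n_links):
        cls = classes[i]
        source = entries_a[i]
        target_id = f"B{i:04d}"
        if cls == "invalid":
            links.append(Link("A", source.entry_id, "B", f"Bmissing{i:04d}"))
            link_classes[("A", source.entry_id, "B", f"Bmissing{i:04d}")] = cls
            continue
        if cls == "missing_inchi":
            entries_b.append(Entry("B", target_id, inchi=None))
        elif cls == "identical":
            entries_b.append(Entry("B", target_id, inchi=source.inchi))
        else:
            pair = degrade(parse_inchi(source.inchi), _CLASS_TO_OP[cls],
                           seed=rng.randrange(2 ** 31))
            entries_b.append(Entry("B", target_id,
                                   inchi=serialize_inchi(pair.degraded)))
        links.append(Link("A", source.entry_id, "B", target_id))
        link_classes[("A", source.entry_id, "B", target_id)] = cls

    # truth: per-method inconsistent fractions from the class construction
    fractions: dict[tuple[str, str], float] = {}
    for mode in MODE_NAMES:
        for policy in ("strict", "subset"):
            bad = 0
            for cls in _LINK_CLASSES:
                if cls == "identical":
                    continue
                truth = _truth_for_op(_CLASS_TO_OP[cls])
                if not truth[(mode, policy)]:
                    bad += counts[cls]
            fractions[(mode, policy)] = 100.0 * bad / n_checked

    # identical-approach generation truth by plain string counting
    canon_a: dict[str, int] = {}
    for entry in entries_a:
        canon_a[entry.inchi] = canon_a.get(entry.inchi, 0) + 1
    identical_generated = sum(canon_a.get(e.inchi, 0)
                              for e in entries_b if e.inchi)

    truth = TruthTables(
        n_entries_a=n_a,
        n_entries_b=len(entries_b),
        n_links=n_links,
        n_valid=n_links - n_invalid,
        n_checked=n_checked,
        class_counts=counts,
        duplicate_pairs=n_dup,
        tautomer_pairs=n_tautomer,
        std_collision_pairs=n_dup,
        ext_collision_pairs=n_dup - n_tautomer,
        inconsistent_fraction=fractions,
        identical_generated_links=identical_generated,
    )
    return LinkedDatabases(tuple(entries_a), tuple(entries_b), tuple(links),
                           truth, link_classes)


# ---------------------------------------------------------------------------
# brute-force oracle

_MAX_ORACLE_CENTERS = 4


def _completions(tokens: Sequence[StereoToken], universe: Sequence[str],
                 flip: bool) -> frozenset[frozenset[tuple[str, str]]]:
    """Every fully specified assignment the partially defined descriptor
    admits, as sets of (center, physical sign); ``flip`` applies the
    enantiomer-inversion flag."""
    swap = {"+": "-", "-": "+"}
    defined = {t.center: t.sign for t in tokens if t.sign != "?"}
    free = [c for c in universe if c not in defined]
    out = set()
    for assignment in product("+-", repeat=len(free)):
        phys = dict(defined)
        phys.update(zip(free, assignment))
        if flip:
            phys = {c: swap[s] for c, s in phys.items()}
        out.add(frozenset(phys.items()))
    return frozenset(out)


def brute_force_subtype(x: ParsedInChI, y: ParsedInChI,
                        mode: Union[str, ComparisonMode] = "CHsI") -> bool:
    """Subtype decision by exhaustive stereo-completion enumeration.

    For single-component identifiers with at most four stereo centers per
    sub-layer: X is a subtype of Y iff the non-stereo parts agree after
    mode stripping and every completion of X's stereo description (its
    inversion flag applied) is also a completion of Y's.  Independent of
    the per-center comparison in :mod:`inchilink.compare`; used as its
    oracle.
    """
    mode = MODES[mode] if isinstance(mode, str) else mode
    xe, ye = x.expand(), y.expand()
    if xe.component_count != 1 or ye.component_count != 1:
        raise FixtureError("the oracle handles single components only")
    if xe.version != ye.version:
        return False
    sx, sy = strip(xe, mode), strip(ye, mode)

    def slot(p, key):
        v = p.sublayers.get(key)
        return v[0] if v else ""

    if sx.formula != sy.formula:
        return False
    for key in ("c", "h", "q", "i", "i/h"):
        if slot(sx, key) != slot(sy, key):
            return False
    if not mode.ignore_protons and sx.protons != sy.protons:
        return False
    if mode.ignore_stereo:
        return True
    if mode.require_stereo_identity:
        return all(sx.sublayers.get(k) == sy.sublayers.get(k)
                   for k in ("b", "t", "m", "s", "i/b", "i/t", "i/m", "i/s"))

    for s_key in ("s", "i/s"):
        if slot(sy, s_key) and slot(sx, s_key) != slot(sy, s_key):
            return False
    for b_key in ("b", "i/b"):
        bx = parse_stereo_tokens(slot(sx, b_key))
        by = parse_stereo_tokens(slot(sy, b_key))
        universe = sorted({t.center for t in bx} | {t.center for t in by})
        if len(universe) > _MAX_ORACLE_CENTERS:
            raise FixtureError("too many stereo bonds for the oracle bound")
        if not _completions(bx, universe, False) <= _completions(by, universe,
                                                                 False):
            return False
    for t_key, m_key in (("t", "m"), ("i/t", "i/m")):
        tx = parse_stereo_tokens(slot(sx, t_key))
        ty = parse_stereo_tokens(slot(sy, t_key))
        universe = sorted({t.center for t in tx} | {t.center for t in ty})
        if len(universe) > _MAX_ORACLE_CENTERS:
            raise FixtureError("too many stereo centers for the oracle bound")
        flip_x = slot(sx, m_key) == "1"
        flip_y = slot(sy, m_key) == "1"
        if not _completions(tx, universe, flip_x) <= _completions(
                ty, universe, flip_y):
            return False
    return True


# ---------------------------------------------------------------------------
# stereo sweep helpers

def make_stereo_variant(skeleton: str, signs: Mapping[str, str],
                        m: Optional[str]) -> ParsedInChI:
    """A decorated identifier with an explicit designator per tetrahedral
    center of the skeleton ('?' listed, not omitted)."""
    skel = SKELETONS[skeleton]
    base = parse_inchi(skel.base).expand()
    sub = dict(base.sublayers)
    tokens = [StereoToken(c, signs[c]) for c in skel.t_centers]
    if tokens:
        sub["t"] = (render_stereo_tokens(tokens),)
    defined = any(t.sign != "?" for t in tokens)
    if defined:
        sub["m"] = (m if m is not None else "0",)
        sub["s"] = ("1",)
    return ParsedInChI("1S", base.formula, sub)


def stereo_variants(skeleton: str) -> list[ParsedInChI]:
    """Every designator pattern over the skeleton's tetrahedral centers,
    crossed with both inversion-flag orientations where chirality is
    present — the exhaustive input set for the oracle-equivalence sweep."""
    skel = SKELETONS[skeleton]
    out = []
    for pattern in product("+-?", repeat=len(skel.t_centers)):
        signs = dict(zip(skel.t_centers, pattern))
        if all(s == "?" for s in pattern):
            out.append(make_stereo_variant(skeleton, signs, None))
        else:
            out.append(make_stereo_variant(skeleton, signs, "0"))
            out.append(make_stereo_variant(skeleton, signs, "1"))
    return out


# ---------------------------------------------------------------------------
# structure-file fixtures

def make_molfile(title: str, atoms: Sequence[tuple], bonds: Sequence[tuple],
                 properties: Sequence[str] = ()) -> str:
    """Build a V2000 molfile.  ``atoms`` are (symbol[, charge_code
    [, valence]]) tuples, ``bonds`` are (a, b, type) with 1-based atom
    indices; extra property-block lines go in verbatim before ``M  END``.
    """
    lines = [title, "  inchilink fixture", ""]
    lines.append(f"{len(atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for spec_tuple in atoms:
        sym = spec_tuple[0]
        charge_code = spec_tuple[1] if len(spec_tuple) > 1 else 0
        valence = spec_tuple[2] if len(spec_tuple) > 2 else 0
        lines.append(
            f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {sym:<3}"
            f"{0:2d}{charge_code:3d}  0  0  0  0{valence:3d}  0  0  0  0  0")
    for a, b, t in bonds:
        lines.append(f"{a:3d}{b:3d}{t:3d}  0")
    lines.extend(properties)
    lines.append("M  END")
    return "\n".join(lines) + "\n"


#: toy molfiles plus the identifier the official algorithm assigns them,
#: frozen after a one-time run of that algorithm
TOY_MOLFILES: dict[str, tuple[str, str]] = {
    "water": (make_molfile("water", [("O",)], []),
              "InChI=1S/H2O/h1H2"),
    "ethanol": (make_molfile("ethanol", [("C",), ("C",), ("O",)],
                             [(1, 2, 1), (2, 3, 1)]),
                "InChI=1S/C2H6O/c1-2-3/h3H,2H2,1H3"),
    "acetic_acid": (make_molfile("acetic acid",
                                 [("C",), ("C",), ("O",), ("O",)],
                                 [(1, 2, 1), (2, 3, 2), (2, 4, 1)]),
                    "InChI=1S/C2H4O2/c1-2(3)4/h1H3,(H,3,4)"),
    "benzene": (make_molfile("benzene", [("C",)] * 6,
                             [(1, 2, 2), (2, 3, 1), (3, 4, 2), (4, 5, 1),
                              (5, 6, 2), (6, 1, 1)]),
                "InChI=1S/C6H6/c1-2-4-6-5-3-1/h1-6H"),
}

CLEAN_ETHANOL_SDF = TOY_MOLFILES["ethanol"][0] + "$$$$\n"


def violation_records() -> dict[str, str]:
    """One molfile per eligibility reason code, each violating exactly
    that condition."""
    return {
        "NON_ATOM": make_molfile("electron placeholder", [("e-",)], []),
        "GENERAL_ATOM": make_molfile("query atom",
                                     [("C",), ("R#",)], [(1, 2, 1)]),
        "R_GROUP": make_molfile("aliased R-group", [("C",), ("C",)],
                                [(1, 2, 1)], properties=["A    2", "R1"]),
        "UNDEFINED_CHARGE": make_molfile("converted undefined charge",
                                         [("C", 9)], []),
        "ANY_BOND": make_molfile("any bond", [("C",), ("C",)], [(1, 2, 8)]),
        "OPEN_POLYMER": make_molfile("open SRU polymer", [("C",), ("C",)],
                                     [(1, 2, 1)],
                                     properties=["M  STY  1   1 SRU"]),
    }


def warning_records() -> dict[str, str]:
    """Eligible records from the known conversion-failure classes."""
    return {
        "UUB_SYMBOL": make_molfile("deprecated symbol", [("Uub",)], []),
        "HIGH_ATOMIC_NUMBER": make_molfile("transactinide", [("Db",)], []),
        "COORDINATION_BOND": make_molfile("coordination bond",
                                          [("Fe",), ("O",)], [(1, 2, 9)]),
        "AROMATIC_BOND": make_molfile("aromatic bond type",
                                      [("C",), ("C",)], [(1, 2, 4)]),
        "MALFORMED_APO": make_molfile("misformatted attachment point",
                                      [("C",)], [],
                                      properties=["M  APO  1   1  x"]),
    }
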