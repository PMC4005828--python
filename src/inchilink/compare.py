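"""The subtype ("compatibility") relation between identifiers.

Identifier X describes a subtype of what identifier Y describes when X
carries all the information Y carries: X is then *equally or more
specific* than Y.  Non-stereo sub-layers cannot express partial
information, so they must agree exactly wherever the chosen mode keeps
them.  Stereo sub-layers can mark individual centers as undefined (``?``)
and are therefore compared center by center: every conformation defined
in Y must be defined identically in X, while centers undefined or absent
in Y impose no constraint.

Tetrahedral descriptors need one extra step.  Enantiomers share the same
``/t`` string and differ only in the inversion flag ``/m``; moreover the
canonical choice between the two equivalent renderings ``(t, m)`` and
``(inverted t, 1-m)`` can flip when a center becomes undefined.  The
comparison therefore interprets a descriptor through its ``/m`` flag:
when the two flags agree the ``/t`` strings are compared directly, and
when they differ one side is inverted first.  This is exactly the
semantics of the stereo *completion set* (every way of resolving the
undefined centers), which the brute-force oracle in
:mod:`inchilink.fixtures` enumerates explicitly.

Six information modes weaken the relation stepwise:

========  ==========================================================
CHSI      sub-layer identity, including stereo (plain string equality)
CHsI      stereo compared for compatibility instead of identity
ChsI      additionally ignores protonation (the ``/p`` sub-layer)
Chs-      additionally ignores the isotopic layer
Ch-I      like ChsI but ignores the stereo layer (isotopes kept)
C---      heavy atoms and their connections only
========  ==========================================================

Two multicomponent policies exist: *strict* requires the same component
list compared position-wise; *subset* requires the first components to be
comparable and every component of Y to be covered by some component of X,
admitting additives in the more specific identifier.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence, Union

from .components import ComponentView, split_components
from .errors import NotComparableError
from .inchi_model import (
    ParsedInChI,
    StereoToken,
    parse_stereo_tokens,
)

__all__ = [
    "ComparisonMode",
    "MODES",
    "MODE_NAMES",
    "MODE_IMPLICATIONS",
    "POLICIES",
    "POLICY_IMPLICATIONS",
    "invert_tetrahedral",
    "strip",
    "stereo_compatible",
    "component_subtype",
    "is_subtype",
    "link_consistent",
]


@dataclass(frozen=True)
class ComparisonMode:
    """Which information classes a comparison requires identical, requires
    compatible, or ignores.  The four letters stand for heavy atoms and
    connections (C), hydrogens/protonation/charge (H), stereochemistry (S)
    and isotopes (I); a lowercase letter relaxes identity to compatibility
    and ``-`` drops the class."""

    name: str
    require_stereo_identity: bool = False
    ignore_protons: bool = False
    ignore_isotopes: bool = False
    ignore_stereo: bool = False
    connections_only: bool = False


MODES: dict[str, ComparisonMode] = {
    "CHSI": ComparisonMode("CHSI", require_stereo_identity=True),
    "CHsI": ComparisonMode("CHsI"),
    "ChsI": ComparisonMode("ChsI", ignore_protons=True),
    "Chs-": ComparisonMode("Chs-", ignore_protons=True, ignore_isotopes=True),
    "Ch-I": ComparisonMode("Ch-I", ignore_protons=True, ignore_stereo=True),
    "C---": ComparisonMode("C---", ignore_protons=True, ignore_isotopes=True,
                           ignore_stereo=True, connections_only=True),
}

MODE_NAMES = tuple(MODES)

#: (stronger, weaker) pairs: consistency under the stronger mode implies
#: consistency under the weaker one.
MODE_IMPLICATIONS = (
    ("CHSI", "CHsI"),
    ("CHsI", "ChsI"),
    ("ChsI", "Chs-"),
    ("ChsI", "Ch-I"),
    ("Chs-", "C---"),
    ("Ch-I", "C---"),
)

POLICIES = ("strict", "subset")
POLICY_IMPLICATIONS = (("strict", "subset"),)


def _mode(mode: Union[str, ComparisonMode]) -> ComparisonMode:
    if isinstance(mode, ComparisonMode):
        return mode
    try:
        return MODES[mode]
    except KeyError:
        raise ValueError(
            f"unknown mode {mode!r}; valid modes: {', '.join(MODE_NAMES)}")


def _policy(policy: str) -> str:
    if policy not in POLICIES:
        raise ValueError(
            f"unknown policy {policy!r}; valid policies: strict, subset")
    return policy


# ---------------------------------------------------------------------------
# stereo primitives

_SWAP = {"+": "-", "-": "+", "?": "?"}


def invert_tetrahedral(tokens: Sequence[StereoToken]) -> tuple[StereoToken, ...]:
    """Swap ``+`` and ``-`` designators, leaving ``?`` and order alone."""
    return tuple(StereoToken(t.center, _SWAP[t.sign]) for t in tokens)


def stereo_compatible(x_tokens: Sequence[StereoToken],
                      y_tokens: Sequence[StereoToken]) -> bool:
    """True iff every conformation defined in Y is defined identically in
    X.  Centers undefined or absent in Y impose no constraint; X may
    define more."""
    defined_x = {t.center: t.sign for t in x_tokens if t.sign != "?"}
    return all(defined_x.get(t.center) == t.sign
               for t in y_tokens if t.sign != "?")


def _tetrahedral_compatible(x_tokens, x_m, y_tokens, y_m) -> bool:
    """Tetrahedral compatibility honouring the inversion flags: compare
    directly when the flags agree, after inverting one side when they
    differ ('.'/absent flags count as uninverted)."""
    xm = x_m if x_m in ("0", "1") else "0"
    ym = y_m if y_m in ("0", "1") else "0"
    if xm != ym:
        y_tokens = invert_tetrahedral(y_tokens)
    return stereo_compatible(x_tokens, y_tokens)


# ---------------------------------------------------------------------------
# stripping

_H_COUNT_RE = re.compile(r"H(?![a-z])\d*")

_STEREO_KEYS = ("b", "t", "m", "s", "i/b", "i/t", "i/m", "i/s")
_ISOTOPE_KEYS = ("i", "i/h", "i/b", "i/t", "i/m", "i/s")


def strip_hydrogens_from_formula(term: str) -> str:
    """Delete the hydrogen count from one formula term (``C2H6O`` ->
    ``C2O``); two-letter symbols starting with H are untouched."""
    return _H_COUNT_RE.sub("", term)


def strip(p: ParsedInChI, mode: Union[str, ComparisonMode]) -> ParsedInChI:
    """Remove the sub-layers the mode ignores.  Under ``C---`` only the
    hydrogen-free formula and the connections sub-layer survive."""
    mode = _mode(mode)
    e = p.expand()
    if mode.connections_only:
        formula = tuple(strip_hydrogens_from_formula(t) for t in e.formula)
        sub = {}
        if "c" in e.sublayers:
            sub["c"] = e.sublayers["c"]
        return ParsedInChI(e.version, formula, sub, None, e.opaque)
    drop: set[str] = set()
    if mode.ignore_protons:
        drop.add("p")
    if mode.ignore_isotopes:
        drop.update(_ISOTOPE_KEYS)
    if mode.ignore_stereo:
        drop.update(_STEREO_KEYS)
    sub = {k: v for k, v in e.sublayers.items() if k not in drop}
    return ParsedInChI(e.version, e.formula, sub, e.fixed_h, e.opaque)


# ---------------------------------------------------------------------------
# the relation

def _as_component(x: Union[ParsedInChI, ComponentView]) -> ParsedInChI:
    if isinstance(x, ComponentView):
        return x.inchi
    return x


def _require_comparable(p: ParsedInChI) -> None:
    if p.opaque:
        raise NotComparableError(
            "identifier carries unsupported layers and cannot be compared")
    if p.fixed_h is not None:
        raise NotComparableError(
            "extended (fixed-hydrogen) identifiers are compared for "
            "equality only, not for subtype")


def _slot(p: ParsedInChI, key: str) -> str:
    v = p.sublayers.get(key)
    return v[0] if v else ""


def component_subtype(x: Union[ParsedInChI, ComponentView],
                      y: Union[ParsedInChI, ComponentView],
                      mode: Union[str, ComparisonMode]) -> bool:
    """Is the single-component identifier X equally or more specific than
    the single-component identifier Y under the given mode?"""
    mode = _mode(mode)
    xc, yc = _as_component(x), _as_component(y)
    _require_comparable(xc)
    _require_comparable(yc)
    if xc.component_count != 1 or yc.component_count != 1:
        raise ValueError("component_subtype expects single-component inputs")
    if xc.version != yc.version:
        raise NotComparableError("identifier versions differ")
    sx, sy = strip(xc, mode), strip(yc, mode)

    if sx.formula != sy.formula:
        return False
    for key in ("c", "h", "q", "i", "i/h"):
        if _slot(sx, key) != _slot(sy, key):
            return False
    if not mode.ignore_protons and sx.protons != sy.protons:
        return False

    if mode.ignore_stereo:
        return True
    if mode.require_stereo_identity:
        return all(sx.sublayers.get(k) == sy.sublayers.get(k)
                   for k in _STEREO_KEYS)
    # compatibility: per-part treatment of the stereo sub-layers
    for b_key in ("b", "i/b"):
        if not stereo_compatible(parse_stereo_tokens(_slot(sx, b_key)),
                                 parse_stereo_tokens(_slot(sy, b_key))):
            return False
    for t_key, m_key in (("t", "m"), ("i/t", "i/m")):
        if not _tetrahedral_compatible(
                parse_stereo_tokens(_slot(sx, t_key)), _slot(sx, m_key),
                parse_stereo_tokens(_slot(sy, t_key)), _slot(sy, m_key)):
            return False
    for s_key in ("s", "i/s"):
        if _slot(sy, s_key) and _slot(sx, s_key) != _slot(sy, s_key):
            return False
    return True


def is_subtype(x: ParsedInChI, y: ParsedInChI,
               mode: Union[str, ComparisonMode],
               policy: str = "strict") -> bool:
    """Is the entity described by X a subtype of the entity described by Y?

    Under the *strict* policy (X⇔Y) both identifiers must have the same
    number of components and the n-th component of X must be a subtype of
    the n-th component of Y.  Under the *subset* policy (X↔Y) the first
    components must be in the subtype relation and every component of Y
    must be covered by some component of X (reuse permitted), which allows
    linking a compound with its salt but not two different salts.
    """
    mode = _mode(mode)
    policy = _policy(policy)
    _require_comparable(x)
    _require_comparable(y)
    xv = split_components(x)
    yv = split_components(y)
    if policy == "strict":
        if len(xv) != len(yv):
            return False
        return all(component_subtype(a, b, mode) for a, b in zip(xv, yv))
    if not component_subtype(xv[0], yv[0], mode):
        return False
    return all(any(component_subtype(k, l, mode) for k in xv) for l in yv)


def link_consistent(x: ParsedInChI, y: ParsedInChI,
                    mode: Union[str, ComparisonMode],
                    policy: str = "strict") -> bool:
    """A cross-reference link is consistent when one of the linked
    entities is a subtype of the other."""
    return is_subtype(x, y, mode, policy) or is_subtype(y, x, mode, policy)
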