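"""Layered data model, parser and serializer for InChI identifier strings.

An InChI identifier expresses a molecular entity hierarchically in layers
and sub-layers.  The main layer holds the per-component molecular formula,
the heavy-atom connection table (``/c``) and the mobile-hydrogen
description (``/h``).  The charge layer holds the per-component formal
charge (``/q``) and one global count of protons added or removed during
normalization (``/p``).  The stereo layer holds double-bond (``/b``) and
tetrahedral (``/t``) descriptors, the enantiomer-inversion flag (``/m``,
one character per component) and the stereo-type flag (``/s``).  The
isotopic layer (``/i`` plus its own ``h/b/t/m/s`` sub-layers) repeats the
scheme for isotopically labelled entities.  Non-standard identifiers may
additionally carry a fixed-hydrogen layer (``/f``), which pins mobile
hydrogens and thereby distinguishes tautomers; identifiers carrying it are
called *extended* here.

Multicomponent entities are serialized into a single identifier: formula
terms are separated by dots, the other per-component sub-layers by
semicolons.  Two abbreviations occur: a leading multiplicity on a formula
term (``2H2O``) and a repetition shorthand on sub-layer tokens
(``2*1H2``).  Both are preserved as written and expanded on demand;
equality always acts on the expanded form.

This module deliberately knows nothing about structures: generating an
identifier from a connection table is the job of the official external
tool (see :mod:`inchilink.sdf_screen`).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import InChIFormatError, InChIStructureError

__all__ = [
    "ParsedInChI",
    "FixedHLayer",
    "StereoToken",
    "parse_inchi",
    "serialize_inchi",
    "is_standard",
    "parse_stereo_tokens",
    "render_stereo_tokens",
    "read_identifier_table",
    "write_identifier_table",
    "read_inchi_lines",
]

# Per-component sub-layers: one token slot per component (slots may be empty).
PER_COMPONENT_KEYS = ("c", "h", "q", "b", "t", "i", "i/h", "i/b", "i/t")
# One character per component ('0', '1' or '.' for achiral components).
CHAR_KEYS = ("m", "i/m")
# A single token for the whole identifier.
SINGLE_KEYS = ("p", "s", "i/s")

#: canonical serialization order: (key, rendered prefix letter)
_LAYER_ORDER = (
    ("c", "c"), ("h", "h"), ("q", "q"), ("p", "p"),
    ("b", "b"), ("t", "t"), ("m", "m"), ("s", "s"),
    ("i", "i"), ("i/h", "h"), ("i/b", "b"), ("i/t", "t"),
    ("i/m", "m"), ("i/s", "s"),
)

_MAIN_ORDER = ("c", "h", "q", "p", "b", "t", "m", "s")
_ISO_ORDER = ("h", "b", "t", "m", "s")
_FIXED_ORDER = ("h", "q", "b", "t", "m", "s", "i")

_VERSION_RE = re.compile(r"\d[0-9A-Za-z]*")
_FORMULA_TERM_RE = re.compile(r"\d*(?:[A-Z][a-z]?\d*)+")
_MULT_RE = re.compile(r"(\d+)([A-Z].*)")
_REPEAT_RE = re.compile(r"(\d+)\*(.*)")
_INT_RE = re.compile(r"[+-]?\d+")
_STEREO_TOKEN_RE = re.compile(r"(\d+(?:-\d+)?)([+?-])")


@dataclass(frozen=True)
class StereoToken:
    """One stereo descriptor: a canonical atom (``"2"``) or bond
    (``"4-3"``) reference and a designator, ``?`` meaning the conformation
    is not defined."""

    center: str
    sign: str  # one of "+", "-", "?"

    def render(self) -> str:
        return f"{self.center}{self.sign}"


def parse_stereo_tokens(text: str) -> tuple[StereoToken, ...]:
    """Parse one component's ``/b`` or ``/t`` slot content into tokens."""
    if not text:
        return ()
    out = []
    for piece in text.split(","):
        m = _STEREO_TOKEN_RE.fullmatch(piece)
        if m is None:
            raise InChIFormatError(f"malformed stereo token {piece!r}")
        out.append(StereoToken(m.group(1), m.group(2)))
    return tuple(out)


def render_stereo_tokens(tokens: Sequence[StereoToken]) -> str:
    return ",".join(t.render() for t in tokens)


@dataclass(frozen=True)
class FixedHLayer:
    """The non-standard fixed-hydrogen layer: a formula delta plus its own
    sub-layers (keys are plain letters).  Token slot counts are not
    reconciled against the main formula because the layer only lists the
    components whose hydrogen placement differs; extended identifiers are
    compared for equality only."""

    formula: tuple[str, ...] = ()
    sublayers: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def _norm(self):
        sub = {k: tuple(_expand_tokens(v)) for k, v in self.sublayers.items()}
        return (tuple(_expand_formula(self.formula)),
                tuple(sorted((k, v) for k, v in sub.items() if any(v))))

    def __eq__(self, other):
        if not isinstance(other, FixedHLayer):
            return NotImplemented
        return self._norm() == other._norm()

    def __hash__(self):
        return hash(self._norm())


def _expand_tokens(tokens: Iterable[str]) -> list[str]:
    out: list[str] = []
    for tok in tokens:
        m = _REPEAT_RE.fullmatch(tok)
        if m is not None:
            out.extend([m.group(2)] * int(m.group(1)))
        else:
            out.append(tok)
    return out


def _expand_formula(terms: Iterable[str]) -> list[str]:
    out: list[str] = []
    for term in terms:
        m = _MULT_RE.fullmatch(term)
        if m is not None:
            out.extend([m.group(2)] * int(m.group(1)))
        else:
            out.append(term)
    return out


@dataclass(frozen=True)
class ParsedInChI:
    """The layered decomposition of one identifier.

    ``formula`` holds one Hill-order term per component (abbreviated terms
    as written); ``sublayers`` maps a sub-layer key to its per-component
    token slots (``m``/``i/m`` hold one character per component, ``p``,
    ``s`` and ``i/s`` a single global token).  ``opaque`` records trailing
    layers this model does not interpret (e.g. the reconnected layer);
    their presence makes the identifier non-comparable but it still
    round-trips through serialization.
    """

    version: str
    formula: tuple[str, ...]
    sublayers: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    fixed_h: Optional[FixedHLayer] = None
    opaque: tuple[str, ...] = ()

    # -- abbreviation handling -------------------------------------------

    def expand(self) -> "ParsedInChI":
        """Return an equivalent identifier with formula multiplicities and
        ``n*token`` repetitions expanded, validating slot counts."""
        formula = tuple(_expand_formula(self.formula))
        ncomp = len(formula)
        sub: dict[str, tuple[str, ...]] = {}
        for key, tokens in self.sublayers.items():
            if key in PER_COMPONENT_KEYS:
                expanded = tuple(_expand_tokens(tokens))
                if len(expanded) != ncomp:
                    raise InChIStructureError(
                        f"sub-layer /{key} has {len(expanded)} slots for "
                        f"{ncomp} components")
                sub[key] = expanded
            elif key in CHAR_KEYS:
                chars = tuple(tokens)
                if len(chars) != ncomp:
                    raise InChIStructureError(
                        f"sub-layer /{key} has {len(chars)} characters for "
                        f"{ncomp} components")
                sub[key] = chars
            elif key in SINGLE_KEYS:
                if len(tokens) != 1:
                    raise InChIStructureError(
                        f"sub-layer /{key} must hold exactly one token")
                sub[key] = tuple(tokens)
            else:
                raise InChIStructureError(f"unknown sub-layer key {key!r}")
        fixed = self.fixed_h
        if fixed is not None:
            fixed = FixedHLayer(
                tuple(_expand_formula(fixed.formula)),
                {k: tuple(_expand_tokens(v)) for k, v in fixed.sublayers.items()},
            )
        return ParsedInChI(self.version, formula, sub, fixed, self.opaque)

    @property
    def component_count(self) -> int:
        return len(_expand_formula(self.formula))

    @property
    def protons(self) -> int:
        """The global protons value; 0 when the sub-layer is absent."""
        tok = self.sublayers.get("p")
        return int(tok[0]) if tok else 0

    @property
    def comparable(self) -> bool:
        return not self.opaque

    def sublayer(self, key: str) -> tuple[str, ...]:
        """Expanded slots of one sub-layer (empty tuple when absent)."""
        e = self.expand()
        return e.sublayers.get(key, ())

    # -- identity ---------------------------------------------------------

    def _key(self):
        e = self.expand()
        sub = []
        for k, v in e.sublayers.items():
            if k in PER_COMPONENT_KEYS and not any(v):
                continue  # an all-empty layer is never serialized
            if k in CHAR_KEYS and set(v) <= {"."}:
                continue
            sub.append((k, v))
        return (self.version, e.formula, tuple(sorted(sub)),
                e.fixed_h, self.opaque)

    def __eq__(self, other):
        if not isinstance(other, ParsedInChI):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self):
        return hash(self._key())

    def __str__(self) -> str:
        return serialize_inchi(self)


# ---------------------------------------------------------------------------
# parsing

def parse_inchi(text: str) -> ParsedInChI:
    """Parse an identifier string into its layered decomposition.

    Unknown trailing layers (e.g. the reconnected layer ``/r``) are stored
    verbatim in ``opaque``; such an identifier parses but is refused by the
    comparison relation.  A malformed prefix raises
    :class:`InChIFormatError`; a sub-layer whose slot count cannot be
    reconciled with the formula raises :class:`InChIStructureError`.
    """
    if not isinstance(text, str) or not text.startswith("InChI="):
        raise InChIFormatError("identifier must begin with 'InChI='")
    body = text[len("InChI="):]
    if not body:
        raise InChIFormatError("empty identifier body")
    segments = body.split("/")
    version = segments[0]
    if not _VERSION_RE.fullmatch(version):
        raise InChIFormatError(f"malformed version {version!r}")
    if len(segments) < 2 or not segments[1]:
        raise InChIFormatError("missing formula layer")
    formula = tuple(segments[1].split("."))
    for term in formula:
        if not _FORMULA_TERM_RE.fullmatch(term):
            raise InChIFormatError(f"malformed formula term {term!r}")

    sublayers: dict[str, tuple[str, ...]] = {}
    fixed_formula: tuple[str, ...] | None = None
    fixed_sub: dict[str, tuple[str, ...]] = {}
    opaque: list[str] = []

    stage = "main"
    pos = -1  # index of the last accepted prefix within the stage order

    def store(key: str, content: str) -> None:
        if key in CHAR_KEYS:
            chars = tuple(content)
            if not set(chars) <= {"0", "1", "."}:
                raise InChIFormatError(f"malformed /{key} content {content!r}")
            sublayers[key] = chars
        elif key in SINGLE_KEYS:
            if key == "p" and not _INT_RE.fullmatch(content):
                raise InChIFormatError(f"malformed /p content {content!r}")
            if key in ("s", "i/s") and not content.isdigit():
                raise InChIFormatError(f"malformed /{key} content {content!r}")
            sublayers[key] = (content,)
        else:
            sublayers[key] = tuple(content.split(";"))

    for seg in segments[2:]:
        if opaque:
            opaque.append(seg)
            continue
        if not seg or not seg[0].isalpha() or not seg[0].islower():
            raise InChIFormatError(f"malformed layer segment {seg!r}")
        prefix, content = seg[0], seg[1:]

        if stage == "main":
            if prefix == "i":
                stage, pos = "iso", -1
                sublayers["i"] = tuple(content.split(";"))
                continue
            if prefix == "f":
                stage, pos = "fixed", -1
                fixed_formula = tuple(content.split(".")) if content else ()
                continue
            if prefix in _MAIN_ORDER:
                idx = _MAIN_ORDER.index(prefix)
                if idx <= pos:
                    raise InChIFormatError(
                        f"sub-layer /{prefix} repeated or out of order")
                if not content:
                    raise InChIFormatError(f"empty sub-layer /{prefix}")
                store(prefix, content)
                pos = idx
                continue
            opaque.append(seg)
        elif stage == "iso":
            if prefix == "f":
                stage, pos = "fixed", -1
                fixed_formula = tuple(content.split(".")) if content else ()
                continue
            if prefix in _ISO_ORDER:
                idx = _ISO_ORDER.index(prefix)
                if idx <= pos:
                    raise InChIFormatError(
                        f"isotopic sub-layer /{prefix} repeated or out of order")
                if not content:
                    raise InChIFormatError(f"empty isotopic sub-layer /{prefix}")
                store(f"i/{prefix}", content)
                pos = idx
                continue
            opaque.append(seg)
        else:  # fixed-H layer
            if prefix in _FIXED_ORDER:
                idx = _FIXED_ORDER.index(prefix)
                if idx <= pos:
                    raise InChIFormatError(
                        f"fixed-H sub-layer /{prefix} repeated or out of order")
                if not content:
                    raise InChIFormatError(f"empty fixed-H sub-layer /{prefix}")
                fixed_sub[prefix] = tuple(content.split(";"))
                pos = idx
                continue
            opaque.append(seg)

    fixed = None
    if fixed_formula is not None or fixed_sub:
        fixed = FixedHLayer(fixed_formula or (), fixed_sub)

    p = ParsedInChI(version, formula, sublayers, fixed, tuple(opaque))
    p.expand()  # validate slot counts and token syntax eagerly
    _validate_tokens(p)
    return p


def _validate_tokens(p: ParsedInChI) -> None:
    e = p.expand()
    for tok in e.sublayers.get("q", ()):
        if tok and not _INT_RE.fullmatch(tok):
            raise InChIFormatError(f"malformed /q token {tok!r}")
    if p.version == "1S":
        s = e.sublayers.get("s")
        if s and s[0] != "1":
            raise InChIStructureError(
                "standard identifiers allow only absolute stereochemistry (/s1)")


# ---------------------------------------------------------------------------
# serialization

def _compress_tokens(tokens: Sequence[str]) -> str:
    """Join per-component slots with ';', abbreviating runs of identical
    non-empty tokens as ``n*token`` (the format's own shorthand)."""
    pieces: list[str] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        j = i
        while j < len(tokens) and tokens[j] == tok:
            j += 1
        run = j - i
        if tok and run >= 2:
            pieces.append(f"{run}*{tok}")
        else:
            pieces.extend([tok] * run)
        i = j
    return ";".join(pieces)


def _compress_formula(terms: Sequence[str]) -> str:
    pieces: list[str] = []
    i = 0
    while i < len(terms):
        term = terms[i]
        j = i
        while j < len(terms) and terms[j] == term:
            j += 1
        run = j - i
        if run >= 2:
            pieces.append(f"{run}{term}")
        else:
            pieces.append(term)
        i = j
    return ".".join(pieces)


def serialize_inchi(p: ParsedInChI) -> str:
    """Render the canonical string form.  The rendering is representation
    independent: abbreviations are first expanded, then re-compressed by
    the canonical rule, so equal identifiers serialize identically and
    ``parse(serialize(p)) == p``."""
    e = p.expand()  # raises on invariant violations
    parts = [f"InChI={e.version}", _compress_formula(e.formula)]
    for key, letter in _LAYER_ORDER:
        tokens = e.sublayers.get(key)
        if not tokens:
            continue
        if key in CHAR_KEYS:
            if set(tokens) <= {"."}:
                continue
            parts.append(letter + "".join(tokens))
        elif key in SINGLE_KEYS:
            parts.append(letter + tokens[0])
        else:
            if not any(tokens):
                continue
            parts.append(letter + _compress_tokens(tokens))
    if e.fixed_h is not None:
        parts.append("f" + _compress_formula(e.fixed_h.formula))
        for letter in _FIXED_ORDER:
            tokens = e.fixed_h.sublayers.get(letter)
            if tokens and any(tokens):
                parts.append(letter + _compress_tokens(tokens))
    parts.extend(e.opaque)
    return "/".join(parts)


def is_standard(p: ParsedInChI) -> bool:
    """True iff the identifier is a standard one: version ``1S`` and no
    fixed-hydrogen layer."""
    return p.version == "1S" and p.fixed_h is None


# ---------------------------------------------------------------------------
# plain-text interfaces

def read_inchi_lines(path) -> list[str]:
    """Read identifiers from a plain-text file, one per line."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def read_identifier_table(path) -> list[tuple[str, str, Optional[str]]]:
    """Read a TSV table ``entry_id <TAB> inchi [<TAB> extended_inchi]``."""
    rows: list[tuple[str, str, Optional[str]]] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for rec in csv.reader(fh, delimiter="\t"):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            if len(rec) < 2:
                raise InChIFormatError(f"identifier table row too short: {rec!r}")
            entry_id = rec[0].strip()
            inchi = rec[1].strip()
            extended = rec[2].strip() if len(rec) > 2 and rec[2].strip() else None
            rows.append((entry_id, inchi, extended))
    return rows


def write_identifier_table(path, rows: Iterable[Sequence[Optional[str]]]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for row in rows:
            writer.writerow(["" if v is None else v for v in row])
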