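"""Multicomponent algebra: counting, splitting and reassembling components.

A multicomponent identifier is a positional interleaving of single
component descriptions.  Splitting is mechanical for every sub-layer
except the protons sub-layer, which holds one value summed over all
components: by convention the first component view receives the whole
value and the remaining views none.  The stereo-type flag ``/s`` describes
the identifier as a whole and is replicated to every view so that a view
remains a self-contained identifier.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InChIStructureError
from .inchi_model import (
    CHAR_KEYS,
    PER_COMPONENT_KEYS,
    ParsedInChI,
)

__all__ = ["ComponentView", "component_count", "split_components", "reassemble"]


@dataclass(frozen=True)
class ComponentView:
    """A single-component identifier plus its 1-based position in the
    parent, so position-wise comparison stays well defined."""

    inchi: ParsedInChI
    origin: int

    def __post_init__(self):
        if self.inchi.component_count != 1:
            raise InChIStructureError("a component view must hold one component")
        if self.origin < 1:
            raise InChIStructureError("origin index is 1-based")
        if self.origin != 1 and "p" in self.inchi.sublayers:
            raise InChIStructureError(
                "only the first component carries the protons sub-layer")


def component_count(p: ParsedInChI) -> int:
    """Number of components after abbreviation expansion (>= 1)."""
    return p.component_count


def split_components(p: ParsedInChI) -> list[ComponentView]:
    """Slice an expanded identifier into per-component views.

    Each view carries its slot of every per-component sub-layer (empty
    slots drop out), the global protons value goes to view 1 only, and
    ``/s`` (and ``/i-s``) is replicated to every view.
    """
    e = p.expand()
    n = len(e.formula)
    views: list[ComponentView] = []
    for idx in range(n):
        sub: dict[str, tuple[str, ...]] = {}
        for key in PER_COMPONENT_KEYS:
            slots = e.sublayers.get(key)
            if slots and slots[idx]:
                sub[key] = (slots[idx],)
        for key in CHAR_KEYS:
            chars = e.sublayers.get(key)
            if chars and chars[idx] != ".":
                sub[key] = (chars[idx],)
        for key in ("s", "i/s"):
            if key in e.sublayers:
                sub[key] = e.sublayers[key]
        if idx == 0 and "p" in e.sublayers:
            sub["p"] = e.sublayers["p"]
        view = ParsedInChI(e.version, (e.formula[idx],), sub,
                           e.fixed_h if n == 1 else None, e.opaque)
        views.append(ComponentView(view, idx + 1))
    return views


def reassemble(views: list[ComponentView]) -> ParsedInChI:
    """Inverse of :func:`split_components` for expanded identifiers.

    Views are joined in list order.  Conflicting ``/s`` values or a
    protons sub-layer on a non-first view are refused.
    """
    if not views:
        raise InChIStructureError("cannot reassemble zero views")
    version = views[0].inchi.version
    n = len(views)
    parts = [v.inchi.expand() for v in views]
    for i, part in enumerate(parts):
        if part.version != version:
            raise InChIStructureError("views disagree on identifier version")
        if i > 0 and "p" in part.sublayers:
            raise InChIStructureError(
                "protons sub-layer allowed on the first view only")

    formula = tuple(part.formula[0] for part in parts)
    sub: dict[str, tuple[str, ...]] = {}
    for key in PER_COMPONENT_KEYS:
        if any(key in part.sublayers for part in parts):
            sub[key] = tuple(
                part.sublayers.get(key, ("",))[0] for part in parts)
    for key in CHAR_KEYS:
        if any(key in part.sublayers for part in parts):
            sub[key] = tuple(
                part.sublayers.get(key, (".",))[0] for part in parts)
    for key in ("s", "i/s"):
        values = {part.sublayers[key] for part in parts if key in part.sublayers}
        if len(values) > 1:
            raise InChIStructureError(f"views disagree on /{key}")
        if values:
            sub[key] = values.pop()
    if "p" in parts[0].sublayers:
        sub["p"] = parts[0].sublayers["p"]

    fixed = parts[0].fixed_h if n == 1 else None
    return ParsedInChI(version, formula, sub, fixed, parts[0].opaque)
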