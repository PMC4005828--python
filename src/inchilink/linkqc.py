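"""Duplicate detection and cross-reference link quality control.

Two entries of one database sharing a standard identifier form a
*collision*; collisions at the extended-identifier level (fixed-hydrogen
layer included) are a subset of standard-level collisions because the
extended identifier distinguishes tautomers the standard one merges.
True duplicity among the remaining candidates is a manual decision, so
the structure files of extended-level colliding pairs are packaged for
review rather than adjudicated automatically.

Link auditing proceeds in three steps: validity (does the target entry
still exist), consistency (is one linked entity a subtype of the other
under a chosen mode/policy), and completeness (what percentage of the
manually curated links the automatically generated ones contain).
Automatic generation links entries with equal identifiers (*identical*
approach) or with compatible ones (*compatible* approach); the compatible
approach is then thinned by two redundancy rules so an entry is linked
with its indirect subtypes only when the other database does not contain
the same entity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence, Union

from .compare import (
    ComparisonMode,
    MODE_NAMES,
    POLICIES,
    is_subtype,
    link_consistent,
    strip,
)
from .errors import InChIError, NotComparableError
from .inchi_model import ParsedInChI, parse_inchi, serialize_inchi

__all__ = [
    "Entry",
    "Link",
    "CollisionReport",
    "LinkValidationReport",
    "ConsistencyReport",
    "CompletenessReport",
    "EntryCorpus",
    "find_collisions",
    "sdf_collision_candidates",
    "validate_links",
    "check_link_consistency",
    "consistency_grid",
    "generate_links",
    "filter_redundant",
    "completeness",
    "read_links_table",
    "write_links_table",
    "entries_from_identifier_rows",
]


@dataclass(frozen=True)
class Entry:
    """One database record."""

    database: str
    entry_id: str
    inchi: Optional[str] = None
    extended_inchi: Optional[str] = None
    sdf: Optional[str] = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.database, self.entry_id)


@dataclass(frozen=True)
class Link:
    """A directed cross-reference between two entries."""

    source_db: str
    source_id: str
    target_db: str
    target_id: str
    provenance: str = "manual"  # manual | generated
    valid: Optional[bool] = None

    @property
    def endpoints(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return ((self.source_db, self.source_id),
                (self.target_db, self.target_id))

    @property
    def pair_key(self):
        """Unordered endpoint pair, for merged bidirectional link sets."""
        return frozenset(self.endpoints)


class EntryCorpus:
    """Entries of one or more databases indexed by (database, id), with a
    cache of parsed identifiers."""

    def __init__(self, entries: Iterable[Entry] = ()):
        self._by_key: dict[tuple[str, str], Entry] = {}
        self._parsed: dict[tuple[str, str], Optional[ParsedInChI]] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: Entry) -> None:
        if entry.key in self._by_key:
            raise ValueError(f"duplicate entry key {entry.key}")
        self._by_key[entry.key] = entry

    def __contains__(self, key) -> bool:
        return key in self._by_key

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key.values())

    def get(self, key) -> Optional[Entry]:
        return self._by_key.get(key)

    def parsed(self, key) -> Optional[ParsedInChI]:
        """Parsed standard identifier of an entry, or None when absent or
        unparsable."""
        if key not in self._parsed:
            entry = self._by_key.get(key)
            parsed = None
            if entry is not None and entry.inchi:
                try:
                    parsed = parse_inchi(entry.inchi)
                except InChIError:
                    parsed = None
            self._parsed[key] = parsed
        return self._parsed[key]


def _canonical(text: str) -> Optional[str]:
    try:
        return serialize_inchi(parse_inchi(text))
    except InChIError:
        return None


# ---------------------------------------------------------------------------
# collisions

@dataclass(frozen=True)
class CollisionReport:
    level: str  # standard | extended
    groups: tuple[tuple[str, ...], ...]  # entry ids sharing one identifier
    pair_count: int
    skipped: int  # entries lacking the identifier required by the level

    @property
    def pairs(self) -> frozenset[frozenset[str]]:
        out: set[frozenset[str]] = set()
        for group in self.groups:
            out.update(frozenset(p) for p in combinations(group, 2))
        return frozenset(out)


def find_collisions(entries: Iterable[Entry], level: str = "standard"
                    ) -> CollisionReport:
    """Group entries sharing one identifier at the requested level.

    Identifiers are canonically re-serialized before string comparison so
    abbreviation spelling cannot hide or fake a collision.  Entries
    lacking the level's identifier (or carrying an unparsable one) are
    skipped and counted.
    """
    if level not in ("standard", "extended"):
        raise ValueError("level must be 'standard' or 'extended'")
    buckets: dict[str, list[str]] = {}
    skipped = 0
    for entry in entries:
        text = entry.inchi if level == "standard" else entry.extended_inchi
        canonical = _canonical(text) if text else None
        if canonical is None:
            skipped += 1
            continue
        buckets.setdefault(canonical, []).append(entry.entry_id)
    groups = tuple(tuple(ids) for ids in buckets.values() if len(ids) >= 2)
    pair_count = sum(len(g) * (len(g) - 1) // 2 for g in groups)
    return CollisionReport(level, groups, pair_count, skipped)


@dataclass(frozen=True)
class ReviewBundle:
    entry_a: str
    entry_b: str
    sdf_a: Optional[str]
    sdf_b: Optional[str]

    @property
    def complete(self) -> bool:
        return self.sdf_a is not None and self.sdf_b is not None


def sdf_collision_candidates(report: CollisionReport,
                             entries: Iterable[Entry]) -> list[ReviewBundle]:
    """Package extended-level colliding pairs with their structure files
    for manual review; structure-file collisions (and true duplicity) are
    a human verdict, so no automatic one is emitted.  A pair with a
    missing structure file is emitted with a gap marker."""
    if report.level != "extended":
        raise ValueError("structure-file review starts from the extended level")
    sdf_by_id = {e.entry_id: e.sdf for e in entries}
    bundles = []
    for group in report.groups:
        for a, b in combinations(group, 2):
            bundles.append(ReviewBundle(a, b, sdf_by_id.get(a), sdf_by_id.get(b)))
    return bundles


# ---------------------------------------------------------------------------
# link validity

@dataclass(frozen=True)
class LinkValidationReport:
    links: tuple[Link, ...]
    total: int
    valid: int
    with_inchi: int  # valid links whose both endpoints carry identifiers


def validate_links(links: Iterable[Link], entries: EntryCorpus
                   ) -> LinkValidationReport:
    """Flag links whose target entry no longer exists and count how many
    checked links remain (valid and with identifiers on both ends)."""
    out: list[Link] = []
    valid = with_inchi = 0
    for link in links:
        ok = (link.target_db, link.target_id) in entries
        out.append(replace(link, valid=ok))
        if ok:
            valid += 1
            if (entries.parsed((link.source_db, link.source_id)) is not None
                    and entries.parsed((link.target_db, link.target_id))
                    is not None):
                with_inchi += 1
    return LinkValidationReport(tuple(out), len(out), valid, with_inchi)


# ---------------------------------------------------------------------------
# link consistency

@dataclass(frozen=True)
class LinkVerdict:
    link: Link
    consistent: Optional[bool]  # None when the identifiers refused comparison


@dataclass(frozen=True)
class ConsistencyReport:
    mode: str
    policy: str
    checked: int
    inconsistent: int
    not_comparable: int
    verdicts: tuple[LinkVerdict, ...] = field(repr=False, default=())

    @property
    def inconsistent_fraction(self) -> Optional[float]:
        """Percentage of checked links that are inconsistent."""
        if self.checked == 0:
            return None
        return 100.0 * self.inconsistent / self.checked


def check_link_consistency(links: Iterable[Link], entries: EntryCorpus,
                           mode: Union[str, ComparisonMode],
                           policy: str = "strict") -> ConsistencyReport:
    """Fraction of checked links that are inconsistent under one method.

    Only valid links whose endpoints both carry standard identifiers are
    checked; identifiers that refuse comparison (unsupported layers) are
    excluded and counted separately.
    """
    mode_name = mode if isinstance(mode, str) else mode.name
    checked = inconsistent = refused = 0
    verdicts: list[LinkVerdict] = []
    for link in links:
        if link.valid is False:
            continue
        x = entries.parsed((link.source_db, link.source_id))
        y = entries.parsed((link.target_db, link.target_id))
        if x is None or y is None:
            continue
        try:
            ok = link_consistent(x, y, mode, policy)
        except NotComparableError:
            refused += 1
            verdicts.append(LinkVerdict(link, None))
            continue
        checked += 1
        if not ok:
            inconsistent += 1
        verdicts.append(LinkVerdict(link, ok))
    return ConsistencyReport(mode_name, policy, checked, inconsistent,
                             refused, tuple(verdicts))


def consistency_grid(links: Iterable[Link], entries: EntryCorpus
                     ) -> dict[str, dict[str, ConsistencyReport]]:
    """The full policy-by-mode grid of consistency reports."""
    links = list(links)
    return {policy: {m: check_link_consistency(links, entries, m, policy)
                     for m in MODE_NAMES}
            for policy in POLICIES}


# ---------------------------------------------------------------------------
# link generation

def _skeleton_key(p: ParsedInChI) -> tuple[str, ...]:
    """First-component heavy-atom key used to prune candidate pairs: any
    subtype relation requires the first components to agree on the
    hydrogen-free formula and connections."""
    s = strip(p, "C---")
    c = s.sublayers.get("c", ("",) * len(s.formula))
    return (s.formula[0], c[0] if c else "")


def generate_links(entries_a: Iterable[Entry], entries_b: Iterable[Entry],
                   approach: str = "identical",
                   mode: Union[str, ComparisonMode] = "CHsI",
                   policy: str = "subset") -> list[Link]:
    """Generate source->target links from database A to database B.

    ``identical`` links entries whose canonical identifier strings are
    equal; ``compatible`` links entries whose identifiers are consistent
    (one a subtype of the other) under the given mode and policy.
    """
    if approach not in ("identical", "compatible"):
        raise ValueError("approach must be 'identical' or 'compatible'")
    a_list = [e for e in entries_a if e.inchi]
    b_list = [e for e in entries_b if e.inchi]
    links: list[Link] = []
    if approach == "identical":
        b_by_id: dict[str, list[Entry]] = {}
        for e in b_list:
            canonical = _canonical(e.inchi)
            if canonical is not None:
                b_by_id.setdefault(canonical, []).append(e)
        for e in a_list:
            canonical = _canonical(e.inchi)
            if canonical is None:
                continue
            for other in b_by_id.get(canonical, ()):
                links.append(Link(e.database, e.entry_id, other.database,
                                  other.entry_id, provenance="generated",
                                  valid=True))
        return links

    parsed_a = [(e, _parse_or_none(e)) for e in a_list]
    parsed_b = [(e, _parse_or_none(e)) for e in b_list]
    buckets_b: dict[tuple, list[tuple[Entry, ParsedInChI]]] = {}
    for e, p in parsed_b:
        if p is not None and p.comparable and p.fixed_h is None:
            buckets_b.setdefault(_skeleton_key(p), []).append((e, p))
    for e, p in parsed_a:
        if p is None or not p.comparable or p.fixed_h is not None:
            continue
        for other, q in buckets_b.get(_skeleton_key(p), ()):
            try:
                ok = link_consistent(p, q, mode, policy)
            except NotComparableError:
                continue
            if ok:
                links.append(Link(e.database, e.entry_id, other.database,
                                  other.entry_id, provenance="generated",
                                  valid=True))
    return links


def _parse_or_none(entry: Entry) -> Optional[ParsedInChI]:
    try:
        return parse_inchi(entry.inchi) if entry.inchi else None
    except InChIError:
        return None


def filter_redundant(links: Sequence[Link], entries_a: Iterable[Entry],
                     entries_b: Iterable[Entry],
                     mode: Union[str, ComparisonMode] = "CHsI",
                     policy: str = "subset") -> list[Link]:
    """Drop links dominated by a link from a more appropriately specific
    entry of the source database.

    A link X->Y is redundant when another source entry X' also links to Y
    and either (rule 1) X and X' are equally or less specific than Y while
    X' is a strict subtype of X, or (rule 2) X and X' are equally or more
    specific than Y while X is a strict subtype of X'.  "More/less
    specific" and strictness are evaluated with the same mode and policy
    that generated the links; a link whose endpoints share an identical
    identifier can never satisfy either rule.  Conditions are evaluated
    against the given link set, so re-filtering is a no-op.
    """
    by_key_a = {e.key: e for e in entries_a}
    by_key_b = {e.key: e for e in entries_b}
    parsed: dict[tuple[str, str], Optional[ParsedInChI]] = {}

    def get_parsed(key, table):
        if key not in parsed:
            entry = table.get(key)
            parsed[key] = _parse_or_none(entry) if entry else None
        return parsed[key]

    sub_cache: dict[tuple, bool] = {}

    def sub(key_x, key_y, table_x, table_y) -> bool:
        cache_key = (key_x, key_y)
        if cache_key not in sub_cache:
            px = get_parsed(key_x, table_x)
            py = get_parsed(key_y, table_y)
            if px is None or py is None:
                sub_cache[cache_key] = False
            else:
                try:
                    sub_cache[cache_key] = is_subtype(px, py, mode, policy)
                except NotComparableError:
                    sub_cache[cache_key] = False
        return sub_cache[cache_key]

    links_to = {}
    for link in links:
        links_to.setdefault((link.target_db, link.target_id), []).append(link)

    kept: list[Link] = []
    for link in links:
        key_x = (link.source_db, link.source_id)
        key_y = (link.target_db, link.target_id)
        redundant = False
        for other in links_to[key_y]:
            key_xp = (other.source_db, other.source_id)
            if key_xp == key_x:
                continue
            # rule 1: X, X' at most as specific as Y; X' strictly below X
            if (sub(key_y, key_x, by_key_b, by_key_a)
                    and sub(key_y, key_xp, by_key_b, by_key_a)
                    and sub(key_xp, key_x, by_key_a, by_key_a)
                    and not sub(key_x, key_xp, by_key_a, by_key_a)):
                redundant = True
                break
            # rule 2: X, X' at least as specific as Y; X strictly below X'
            if (sub(key_x, key_y, by_key_a, by_key_b)
                    and sub(key_xp, key_y, by_key_a, by_key_b)
                    and sub(key_x, key_xp, by_key_a, by_key_a)
                    and not sub(key_xp, key_x, by_key_a, by_key_a)):
                redundant = True
                break
        if not redundant:
            kept.append(link)
    return kept


# ---------------------------------------------------------------------------
# completeness

@dataclass(frozen=True)
class CompletenessReport:
    restriction: str
    numerator: int
    denominator: int
    applicable: bool

    @property
    def percent(self) -> Optional[float]:
        if not self.applicable:
            return None
        return 100.0 * self.numerator / self.denominator


def completeness(manual_links: Iterable[Link],
                 generated_links: Iterable[Link],
                 restriction: str = "same-identifier",
                 entries: Optional[EntryCorpus] = None,
                 mode: Union[str, ComparisonMode] = "CHsI",
                 policy: str = "subset",
                 merged: bool = False) -> CompletenessReport:
    """Percentage of manually curated links included in the generated set.

    The manual denominator is restricted to links the generation approach
    could produce at all: under ``same-identifier`` to manual links whose
    endpoints share an identifier, under ``compatible`` to manual links
    between compatible entities (which needs ``entries``).  With
    ``merged`` links are matched on unordered endpoint pairs, for
    bidirectional link sets merged across two databases.  An empty
    restricted manual set yields a not-applicable report rather than 0 or
    100.
    """
    if restriction not in ("same-identifier", "compatible"):
        raise ValueError("restriction must be 'same-identifier' or 'compatible'")

    def link_key(link: Link):
        return link.pair_key if merged else (link.endpoints)

    generated_keys = {link_key(l) for l in generated_links}

    def in_restriction(link: Link) -> bool:
        if entries is None:
            raise ValueError("completeness restriction needs the entry corpus")
        x = entries.parsed((link.source_db, link.source_id))
        y = entries.parsed((link.target_db, link.target_id))
        if x is None or y is None:
            return False
        if restriction == "same-identifier":
            return serialize_inchi(x) == serialize_inchi(y)
        try:
            return link_consistent(x, y, mode, policy)
        except NotComparableError:
            return False

    restricted = {link_key(l) for l in manual_links if in_restriction(l)}
    if not restricted:
        return CompletenessReport(restriction, 0, 0, applicable=False)
    hits = len(restricted & generated_keys)
    return CompletenessReport(restriction, hits, len(restricted),
                              applicable=True)


# ---------------------------------------------------------------------------
# plain-text interfaces

def read_links_table(path) -> list[Link]:
    """Read a TSV link table: ``source_db source_id target_db target_id
    [provenance]``."""
    links: list[Link] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for rec in csv.reader(fh, delimiter="\t"):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            if len(rec) < 4:
                raise ValueError(f"link table row too short: {rec!r}")
            provenance = rec[4].strip() if len(rec) > 4 and rec[4].strip() \
                else "manual"
            links.append(Link(rec[0].strip(), rec[1].strip(), rec[2].strip(),
                              rec[3].strip(), provenance=provenance))
    return links


def write_links_table(path, links: Iterable[Link]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for link in links:
            writer.writerow([link.source_db, link.source_id, link.target_db,
                             link.target_id, link.provenance])


def entries_from_identifier_rows(database: str,
                                 rows: Iterable[Sequence[Optional[str]]]
                                 ) -> list[Entry]:
    """Build entries of one database from identifier-table rows
    (entry_id, inchi[, extended_inchi])."""
    out = []
    for row in rows:
        entry_id, inchi = row[0], row[1]
        extended = row[2] if len(row) > 2 else None
        out.append(Entry(database, entry_id, inchi=inchi or None,
                         extended_inchi=extended or None))
    return out
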