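"""V2000 structure-data file reading and identifier-eligibility screening.

Databases distribute entity structures as SDF files in the V2000 molfile
dialect.  Not every record describes a concrete molecule an identifier can
be computed for: structures may contain non-atom elements (electrons,
muonium), general/query atoms (``A``, ``Q``, ``*``, ``R``), atoms aliased
as R-groups, charges left undefined by a format conversion, "any" bonds,
or open polymers (repeating units with an unknown repeat count).  The
screener reports one reason code per violated condition; a record is
eligible iff no reason fires.

The reader is a deliberately field-level one: screening needs the raw
atom-block charge codes, alias blocks and S-group property lines exactly
as written, which chemistry toolkits normalise away while parsing.  It
resolves V2000 charge semantics (an ``M  CHG`` property block supersedes
every atom-block charge field) but performs no perception.

Identifier generation itself is delegated to the official external tool
through a small adapter; when no executable is configured the adapter
signals unavailability instead of failing.
"""

from __future__ import annotations

import os
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._elements import (
    ATOMIC_NUMBER,
    DEPRECATED_ELEMENT_SYMBOLS,
    ELEMENT_SET,
    GENERAL_ATOM_SYMBOLS,
    HYDROGEN_ISOTOPES,
)
from .errors import AdapterConversionError, AdapterUnavailableError

__all__ = [
    "Atom",
    "Bond",
    "SDFRecord",
    "ScreenResult",
    "AdapterOptions",
    "AdapterResult",
    "parse_sdf_v2000",
    "screen_entry",
    "conversion_warnings",
    "to_inchi_adapter",
    "read_adapter_config",
]

#: reason codes of the six eligibility conditions
REASONS = ("NON_ATOM", "GENERAL_ATOM", "R_GROUP", "UNDEFINED_CHARGE",
           "ANY_BOND", "OPEN_POLYMER")

# atom-block charge field codes (V2000): 0 none, 1..3 = +3..+1,
# 4 doublet radical, 5..7 = -1..-3
_CHARGE_CODE = {0: 0, 1: 3, 2: 2, 3: 1, 4: 0, 5: -1, 6: -2, 7: -3}

#: spellings of non-atom "elements" seen in the wild (electron, positron,
#: muonium); anything else outside the periodic table also counts
NON_ATOM_SYMBOLS = frozenset({"e", "e-", "e+", "Mu", "mu", "pos"})

_R_GROUP_ALIAS_RE = re.compile(r"R\d*'*")


@dataclass
class Atom:
    symbol: str
    charge_code: int  # raw atom-block field
    charge: int  # resolved per V2000 semantics
    charge_defined: bool = True
    mass_diff: int = 0
    valence: int = 0
    alias: Optional[str] = None


@dataclass
class Bond:
    a: int  # 1-based atom indices
    b: int
    bond_type: int


@dataclass
class SGroup:
    index: int
    sgroup_type: str
    label: Optional[str] = None  # subscript from an M SMT line


@dataclass
class SDFRecord:
    """One ``$$$$``-terminated record with its resolved atom/bond blocks,
    indexed property lines and the raw text."""

    title: str = ""
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    sgroups: list[SGroup] = field(default_factory=list)
    properties: list[str] = field(default_factory=list)
    raw: str = ""
    error: Optional[str] = None


@dataclass(frozen=True)
class ScreenResult:
    eligible: bool
    reasons: frozenset[str]
    warnings: frozenset[str] = frozenset()


def _int_at(line: str, start: int, width: int, default: int = 0) -> int:
    piece = line[start:start + width].strip()
    if not piece:
        return default
    return int(piece)


def _parse_record(lines: list[str]) -> SDFRecord:
    rec = SDFRecord(raw="\n".join(lines))
    if len(lines) < 4:
        rec.error = "record too short for a molfile header"
        return rec
    rec.title = lines[0].strip()
    counts = lines[3]
    if len(counts) < 33:
        rec.error = "counts line shorter than 33 characters"
        return rec
    version = counts[33:39].strip()
    if version and version != "V2000":
        rec.error = f"unsupported molfile version {version!r}"
        return rec
    try:
        natoms = _int_at(counts, 0, 3)
        nbonds = _int_at(counts, 3, 3)
    except ValueError:
        rec.error = "malformed counts line"
        return rec
    atom_lines = lines[4:4 + natoms]
    bond_lines = lines[4 + natoms:4 + natoms + nbonds]
    if len(atom_lines) < natoms or len(bond_lines) < nbonds:
        rec.error = "atom/bond block shorter than the counts line declares"
        return rec
    try:
        for line in atom_lines:
            symbol = line[31:34].strip()
            code = _int_at(line, 36, 3)
            valence = _int_at(line, 48, 3)
            mass = _int_at(line, 34, 2)
            charge_defined = code in _CHARGE_CODE
            rec.atoms.append(Atom(symbol, code,
                                  _CHARGE_CODE.get(code, 0),
                                  charge_defined, mass, valence))
        for line in bond_lines:
            rec.bonds.append(Bond(_int_at(line, 0, 3), _int_at(line, 3, 3),
                                  _int_at(line, 6, 3)))
    except ValueError:
        rec.error = "malformed atom or bond line"
        return rec

    # property block: alias lines, M CHG/ISO/RAD/STY/SMT ..., up to M END
    i = 4 + natoms + nbonds
    chg_lines: list[list[str]] = []
    while i < len(lines):
        line = lines[i]
        if line.startswith("M  END"):
            break
        rec.properties.append(line)
        if line.startswith("A  "):
            try:
                idx = int(line[3:].strip())
            except ValueError:
                idx = 0
            if i + 1 < len(lines) and 1 <= idx <= len(rec.atoms):
                rec.atoms[idx - 1].alias = lines[i + 1].strip()
                rec.properties.append(lines[i + 1])
                i += 1
        elif line.startswith("M  CHG"):
            chg_lines.append(line.split()[3:])
        elif line.startswith("M  STY"):
            fields = line.split()[3:]
            for idx_s, typ in zip(fields[0::2], fields[1::2]):
                try:
                    rec.sgroups.append(SGroup(int(idx_s), typ))
                except ValueError:
                    rec.error = "malformed S-group type line"
        elif line.startswith("M  SMT"):
            fields = line.split()
            if len(fields) >= 4:
                try:
                    idx = int(fields[2])
                except ValueError:
                    idx = -1
                for sg in rec.sgroups:
                    if sg.index == idx:
                        sg.label = fields[3]
        i += 1

    if chg_lines:
        # an M CHG block supersedes every atom-block charge field
        for atom in rec.atoms:
            atom.charge = 0
            atom.charge_defined = True
        for fields in chg_lines:
            for idx_s, val_s in zip(fields[0::2], fields[1::2]):
                try:
                    idx, val = int(idx_s), int(val_s)
                except ValueError:
                    continue
                if 1 <= idx <= len(rec.atoms):
                    if -15 <= val <= 15:
                        rec.atoms[idx - 1].charge = val
                    else:
                        rec.atoms[idx - 1].charge_defined = False
    return rec


def parse_sdf_v2000(text: str) -> list[SDFRecord]:
    """Split SDF text on ``$$$$`` and parse each record.  A malformed
    record is returned with its ``error`` field set; parsing continues
    with the next record."""
    records = []
    block: list[str] = []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            if any(piece.strip() for piece in block):
                records.append(_parse_record(block))
            block = []
        else:
            block.append(line)
    if any(piece.strip() for piece in block):
        records.append(_parse_record(block))
    return records


# ---------------------------------------------------------------------------
# screening

def screen_entry(r: SDFRecord) -> ScreenResult:
    """Apply the six eligibility conditions to a parsed record.

    Reason codes: ``NON_ATOM`` (an element that is not an atom, e.g. an
    electron placeholder), ``GENERAL_ATOM`` (query symbols A, Q, ``*``, R,
    R#), ``R_GROUP`` (an atom aliased as an R-group), ``UNDEFINED_CHARGE``
    (a charge marker outside V2000 semantics, reachable via converted
    inputs), ``ANY_BOND`` (bond type code 8) and ``OPEN_POLYMER`` (an SRU
    S-group without a fixed repeat count).  Aromatic bonds (type 4) are a
    conversion warning, not an exclusion.
    """
    if r.error is not None:
        raise ValueError(f"cannot screen an unparsed record: {r.error}")
    reasons: set[str] = set()
    for atom in r.atoms:
        sym = atom.symbol
        if sym in GENERAL_ATOM_SYMBOLS:
            reasons.add("GENERAL_ATOM")
        elif (sym not in ELEMENT_SET and sym not in HYDROGEN_ISOTOPES
                and sym not in DEPRECATED_ELEMENT_SYMBOLS):
            reasons.add("NON_ATOM")
        if atom.alias is not None and _R_GROUP_ALIAS_RE.fullmatch(atom.alias):
            reasons.add("R_GROUP")
        if not atom.charge_defined:
            reasons.add("UNDEFINED_CHARGE")
    for bond in r.bonds:
        if bond.bond_type == 8:
            reasons.add("ANY_BOND")
    for sg in r.sgroups:
        if sg.sgroup_type == "SRU":
            if sg.label is None or not sg.label.isdigit():
                reasons.add("OPEN_POLYMER")
    return ScreenResult(not reasons, frozenset(reasons),
                        conversion_warnings(r))


def conversion_warnings(r: SDFRecord) -> frozenset[str]:
    """Classes of records that pass screening but are known to trip
    identifier-generation tools: the deprecated ``Uub`` symbol, atomic
    numbers above 104, coordination bonds, the aromatic bond type 4 and
    misformatted attachment-point (APO) lines."""
    warnings: set[str] = set()
    for atom in r.atoms:
        if atom.symbol in DEPRECATED_ELEMENT_SYMBOLS:
            warnings.add("UUB_SYMBOL")
        elif ATOMIC_NUMBER.get(atom.symbol, 0) > 104:
            warnings.add("HIGH_ATOMIC_NUMBER")
    for bond in r.bonds:
        if bond.bond_type == 4:
            warnings.add("AROMATIC_BOND")
        elif bond.bond_type in (9, 10):
            warnings.add("COORDINATION_BOND")
    for line in r.properties:
        if line.startswith("M  APO"):
            fields = line.split()[3:]
            if len(fields) % 2 or not all(f.lstrip("-").isdigit()
                                          for f in fields):
                warnings.add("MALFORMED_APO")
    return frozenset(warnings)


# ---------------------------------------------------------------------------
# external generator adapter

@dataclass(frozen=True)
class AdapterOptions:
    """Contract for the external official InChI executable: its path, extra
    flags, and the toggle for the optional keto-enol/1,5 tautomeric
    rules."""

    executable: Optional[str] = None
    flags: tuple[str, ...] = ("-AuxNone", "-NoLabels")
    tautomer_rules: bool = False
    timeout: float = 60.0


@dataclass(frozen=True)
class AdapterResult:
    inchi: str
    warnings: frozenset[str]  # e.g. AMBIGUOUS_CENTER, AMBIGUOUS_BOND


def read_adapter_config(path) -> AdapterOptions:
    """Read a flat ``key=value`` adapter config file (keys: ``executable``,
    ``flags`` whitespace-separated, ``tautomer_rules`` 0/1)."""
    values: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
    return AdapterOptions(
        executable=values.get("executable") or None,
        flags=tuple(values.get("flags", "-AuxNone -NoLabels").split()),
        tautomer_rules=values.get("tautomer_rules", "0") == "1",
    )


def _classify_warnings(log_text: str) -> frozenset[str]:
    out: set[str] = set()
    low = log_text.lower()
    if "ambiguous stereo" in low:
        if "center" in low:
            out.add("AMBIGUOUS_CENTER")
        if "bond" in low:
            out.add("AMBIGUOUS_BOND")
    return frozenset(out)


def to_inchi_adapter(r: SDFRecord, options: AdapterOptions) -> AdapterResult:
    """Convert an eligible record through the configured external tool.

    Raises :class:`AdapterUnavailableError` when no executable is
    configured or found (a clean signal, not a crash) and
    :class:`AdapterConversionError` with the tool's message when the tool
    rejects the record.
    """
    result = screen_entry(r)
    if not result.eligible:
        raise ValueError(
            f"record is not eligible for identifier assignment: "
            f"{sorted(result.reasons)}")
    if not options.executable:
        raise AdapterUnavailableError("no identifier generator configured")
    exe = shutil.which(options.executable) or (
        options.executable if os.path.isfile(options.executable) else None)
    if exe is None:
        raise AdapterUnavailableError(
            f"identifier generator {options.executable!r} not found")

    flags = list(options.flags)
    if options.tautomer_rules:
        flags += ["-KET", "-15T"]
    with tempfile.TemporaryDirectory(prefix="inchilink-") as tmp:
        mol = os.path.join(tmp, "input.mol")
        out = os.path.join(tmp, "out.txt")
        log = os.path.join(tmp, "log.txt")
        with open(mol, "w", encoding="utf-8") as fh:
            fh.write(r.raw)
            if not r.raw.endswith("\n"):
                fh.write("\n")
            if "M  END" not in r.raw:
                fh.write("M  END\n")
        try:
            subprocess.run([exe, mol, out, log, *flags], check=False,
                           capture_output=True, timeout=options.timeout)
        except (OSError, subprocess.TimeoutExpired) as exc:
            raise AdapterConversionError(str(exc))
        log_text = ""
        if os.path.exists(log):
            with open(log, encoding="utf-8", errors="replace") as fh:
                log_text = fh.read()
        identifier = None
        if os.path.exists(out):
            with open(out, encoding="utf-8", errors="replace") as fh:
                for line in fh:
                    if line.startswith("InChI="):
                        identifier = line.strip()
                        break
        if identifier is None:
            raise AdapterConversionError(
                log_text.strip() or "the external tool produced no identifier")
        return AdapterResult(identifier, _classify_warnings(log_text))
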