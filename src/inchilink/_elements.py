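"""Periodic-table symbols used for formula handling and SDF screening."""

ELEMENTS: tuple[str, ...] = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds",
    "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
)

ELEMENT_SET = frozenset(ELEMENTS)

#: Hydrogen isotope spellings accepted in structure files.
HYDROGEN_ISOTOPES = frozenset({"D", "T"})

#: Atomic number by symbol (1-based position in ELEMENTS).
ATOMIC_NUMBER = {sym: i + 1 for i, sym in enumerate(ELEMENTS)}

#: Query/general atom symbols allowed by the molfile dialect but not
#: convertible to an identifier.
GENERAL_ATOM_SYMBOLS = frozenset({"A", "Q", "*", "R", "R#"})

#: Deprecated IUPAC placeholder symbols still found in structure files.
#: They denote real atoms (so they pass eligibility screening) but trip
#: identifier-generation tools.
DEPRECATED_ELEMENT_SYMBOLS = frozenset(
    {"Uub", "Uut", "Uuq", "Uup", "Uuh", "Uus", "Uuo"})
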