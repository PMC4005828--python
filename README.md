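# inchilink

Layer-aware InChI comparison and cross-reference link quality control for
small-molecule databases.

## The problem

Databases of small molecules (ontologies like ChEBI, drug collections
like DrugBank, metabolome and ligand resources) cross-reference each
other through curated links, but different databases describe "the same"
compound at different levels of generality: one may store *serine*, the
other *L-serine*; one the neutral form, the other a salt or a different
protonation state.  Plain identifier equality then misclassifies
perfectly sensible links as wrong, and misses genuinely broken ones.

`inchilink` works directly on IUPAC InChI identifiers, which express a
structure hierarchically in layers: molecular formula, heavy-atom
connections (`/c`), mobile hydrogens (`/h`), charge (`/q`) and
normalization protons (`/p`), double-bond (`/b`) and tetrahedral (`/t`)
stereochemistry with the enantiomer-inversion flag (`/m`), and isotopes
(`/i`).  Because the stereo sub-layers can mark individual centers as
undefined (`?`), identifiers can be compared by **information content**
rather than by string equality.

## The relation at the core

Identifier *X* describes a **subtype** of what *Y* describes (*X* is
equally or more specific) when *X* carries all the information *Y*
carries.  Non-stereo sub-layers must agree exactly; stereo sub-layers are
compared center by center — every conformation defined in *Y* must be
defined identically in *X*.  Tetrahedral descriptors are interpreted
through `/m`: when the flags of the two identifiers agree their `/t`
strings are compared directly, when they differ one side is inverted
first (enantiomers share `/t` and differ only in `/m`, and the canonical
rendering can flip when a center becomes undefined).

Six modes weaken the comparison stepwise — `CHSI` (sub-layer identity),
`CHsI` (stereo by compatibility), `ChsI` (ignore protonation), `Chs-`
(also ignore isotopes), `Ch-I` (ignore stereo, keep isotopes), `C---`
(heavy atoms and connections only) — crossed with two multicomponent
policies: `strict` (X⇔Y, same component list, compared position-wise)
and `subset` (X↔Y, the more specific identifier may carry additives such
as counter-ions, but two different salts never link).

A cross-reference link is **consistent** when one of the linked entities
is a subtype of the other.  On top of the relation the package provides:

* **duplicate detection** — entries of one database sharing a standard
  identifier (collisions), with the extended (fixed-hydrogen) level and
  structure-file review bundles forming a nested hierarchy;
* **link auditing** — validity, per-method inconsistency fractions for
  the full 6×2 method grid;
* **link generation** — by identical or by compatible identifiers, with
  two redundancy rules that keep only the most appropriately specific
  partner;
* **completeness** — the percentage of manually curated links contained
  in the generated set;
* **SDF eligibility screening** — the six conditions under which a V2000
  structure record cannot be assigned an identifier at all, plus an
  adapter contract for the official external InChI generator.

## Worked example

Two databases, one holding both *serine* and *L-serine*, the other only
*L-serine*:

```sh
$ cat chebi.tsv
serine    InChI=1S/C3H7NO3/c4-2(1-5)3(6)7/h2,5H,1,4H2,(H,6,7)
L-serine  InChI=1S/C3H7NO3/c4-2(1-5)3(6)7/h2,5H,1,4H2,(H,6,7)/t2-/m0/s1

$ inchilink generate-links --source A=chebi.tsv --target B=drugbank.tsv \
      --approach compatible --mode CHsI --policy subset --filter-redundant
A	L-serine	B	L-serine	generated
```

Both source entries are compatible with the target (L-serine is a
subtype of serine), so two candidate links exist; the redundancy rules
drop `serine → L-serine` because the source database also contains the
exactly matching entry.  Auditing a manual link set over the same
corpora:

```sh
$ inchilink check-links --entries A=chebi.tsv --entries B=drugbank.tsv \
      --links manual.tsv
{
  "CHSI/strict": { "checked": 2, "inconsistent": 1,
                   "inconsistent_percent": 50.0, "not_comparable": 0 },
  "CHsI/strict": { "checked": 2, "inconsistent": 0,
                   "inconsistent_percent": 0.0, "not_comparable": 0 },
  ...
}
```

Under plain identity (`CHSI`) the `serine → L-serine` link counts as
inconsistent (50% of the two checked links); under the subtype relation
(`CHsI`) both links are recognised as consistent (0%).  That gap —
identity overstating inconsistency where curation linked related but
differently specific entities — is exactly what the method grid
measures.

`inchilink fixtures make --seed 3 --out dir/` writes a complete
deterministic scenario (entry tables, link table, screening SDF, truth
tables) for experimentation; all other subcommands consume its files.

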