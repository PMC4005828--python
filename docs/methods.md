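# Methods

## The identifier model

An InChI identifier is modelled as a version tag, an ordered list of
per-component Hill-formula terms, and a map from sub-layer key to
per-component token slots.  Keys cover the main layer (`c`, `h`), the
charge layer (`q` per component, `p` one global signed integer), the
stereo layer (`b`, `t`, `m`, `s`) and the isotopic layer (`i`, `i/h`,
`i/b`, `i/t`, `i/m`, `i/s`).  `m` holds one character per component
(`0`, `1`, or `.` for components without tetrahedral chirality); `s` and
`i/s` one token for the whole identifier.  The two abbreviation forms of
the format — a leading multiplicity on a formula term (`2H2O`) and the
`n*token` repetition shorthand — are preserved as parsed and expanded on
demand; equality and every comparison act on the expanded form, so the
spelling of an identifier can never influence a verdict.

Serialization is representation-independent: the expanded form is
re-compressed by the canonical rule (runs of two or more identical
non-empty tokens become `n*token`, identical adjacent formula terms get
a multiplicity prefix, empty slots are never compressed).  This
reproduces the official tool's conventions on every frozen reference
string, giving `parse∘serialize = id` and `serialize∘parse = id` on
canonical input.

Unknown layers (e.g. the reconnected layer `/r`) are kept verbatim and
flag the identifier *non-comparable*: it still round-trips and can take
part in string-level collision detection, but the subtype relation
refuses it rather than risking a wrong verdict.  The non-standard
fixed-hydrogen layer (`/f`) is parsed with its own formula delta and
sub-layers but compared only for equality: it only ever serves to
distinguish tautomers in collision detection.  Its slot counts are not
reconciled against the main formula, because the layer lists only the
components whose hydrogen placement differs.  For multicomponent
identifiers the fixed-hydrogen layer is likewise not sliced by the
component-splitting operation — a view is meaningful only for the
standard layers.

Degenerate inputs: an identifier must carry a formula (the bare-proton
identifier, which has none, is out of scope); a `1S` identifier with an
`/s` value other than `1` is refused; a per-component sub-layer whose
expanded slot count disagrees with the formula raises a structural
error at parse time.

## Component algebra

Splitting distributes per-component slots positionally, replicates `/s`
to every view (each view must remain a self-contained identifier) and
gives the global protons value to the first view only — the protons
count is a sum over components and cannot be divided, so a formal
convention is needed; assigning it to the first component keeps the
value stable under both comparison policies.  For comparison purposes an
absent protons sub-layer is read as zero, which is its meaning in the
format.  Views keep their 1-based origin index so position-wise
comparison stays well defined; components are never re-sorted after
splitting.

## The subtype relation

After mode-stripping, the non-stereo sub-layers (formula, `c`, `h`, `q`,
`i`, `i/h`, and `p` where kept) must agree exactly — none of them can
express partial information.  Stereo is compared per part:

* `b`: every bond defined (not `?`) in Y must be defined with the same
  designator in X; bonds undefined or absent in Y impose nothing.  A
  center listed with `?` and a center not listed at all are equivalent.
* `t`/`m`: enantiomers share `/t` and differ in `/m`, and the canonical
  choice between the two equivalent renderings `(t, m)` and
  `(inverted t, 1−m)` can flip when a center becomes undefined.  The
  comparison therefore interprets a descriptor through its flag:
  designators are compared directly when the two `/m` values agree and
  after inverting one side when they differ (a `.`/absent flag counts
  as uninverted).  This is provably the subset relation on *completion
  sets* — the sets of fully specified assignments obtained by resolving
  every `?` and applying the inversion flag — which the brute-force
  oracle enumerates explicitly; the test-suite sweeps all designator
  patterns over one to four centers crossed with both orientations and
  requires 100% agreement.  An "accept if either orientation matches"
  variant was considered and rejected: it is not equivalent to
  completion-set inclusion (it would, for example, accept a pair of
  fully defined enantiomers rendered with equal flags).
* `s`/`i/s`: a stereo-type flag present in Y must be matched in X;
  since standard identifiers only ever carry `/s1`, this reduces to
  "X must also declare stereochemistry", which the completion-set
  semantics already implies.  In identity mode (`CHSI`) all stereo
  sub-layers must be string-equal.

Mode stripping: `ChsI` removes exactly the `/p` sub-layer — "ignoring
protonation" is read literally; `/q` and `/h` stay, since charge and
hydrogen counts are distinct information classes (the alternative,
neutralising `/q` as well, would conflate deprotonation with charge
state).  `Chs-` removes the whole isotopic layer including its stereo
sub-layers; `Ch-I` removes `b/t/m/s` in both the main and isotopic
layers; `C---` keeps only the connections sub-layer and the formula with
every hydrogen count deleted (two-letter symbols starting with H are
untouched).

Policies: `strict` requires equal component counts and the subtype
relation position by position.  `subset` requires the first components
to be related and every component of Y to be covered by some component
of X; coverage is existential and non-injective, so one X component may
cover several Y components.  Identifiers differing only in an additive
therefore relate under `subset` but not `strict`, while two different
salts of one compound relate under neither.  These choices make
consistency monotone along the mode chain
CHSI ⊒ CHsI ⊒ ChsI ⊒ {Chs-, Ch-I} ⊒ C--- and from `strict` to
`subset`, which the property tests check on random pairs.

## Duplicate detection and link QC

Collisions group entries by canonically re-serialized identifier
strings at the standard or extended level; entries lacking the level's
identifier are skipped and counted.  Because an extended identifier
refines the standard one, extended-level colliding pairs are a subset
of standard-level pairs; pairs colliding at the extended level are
packaged with their structure files for manual review — true duplicity
is a human judgement and is deliberately not automated.

Link validity means the target entry exists in the loaded corpus; only
valid links with standard identifiers on both ends enter a consistency
measurement, and identifiers that refuse comparison are excluded and
reported separately.  Generation links entries with equal canonical
identifiers or with compatible ones; for the compatible approach,
candidate pairs are pre-filtered by a first-component heavy-atom key,
which is sound because every mode and policy requires the first
components to agree at the `C---` level.

The two redundancy rules drop a link X→Y when another source entry X′
also links to Y and (rule 1) X and X′ are at most as specific as Y while
X′ is strictly below X, or (rule 2) X and X′ are at least as specific as
Y while X is strictly below X′.  "Strictly below" means subtype in one
direction only, and specificity is evaluated with the same mode and
policy that generated the links.  A case analysis shows a link whose
endpoints carry identical identifiers can never satisfy either rule, and
rule conditions are evaluated against the link set given to the filter,
which makes filtering idempotent.

Completeness is the percentage of manually curated links contained in
the generated set, with the manual denominator restricted to links the
generation approach could produce (same-identifier links for the
identical approach, compatible links for the compatible approach).
Whether redundant manual links should also leave the denominator is
genuinely open; the restriction is computed before redundancy filtering
here, and callers can pass the filtered generated set to obtain the
other reading.  An empty restricted denominator yields a not-applicable
report, never 0% or 100%.  Merged bidirectional link sets are matched on
unordered endpoint pairs.

## SDF screening

The V2000 reader is field-level on purpose: the six eligibility
conditions are judgements about the raw file (atom-block charge codes,
alias blocks, S-group lines, bond type codes), which chemistry toolkits
normalise away while building a molecule.  V2000 charge semantics are
respected — an `M  CHG` block supersedes every atom-block charge field.
A malformed record is reported as a record-level error and parsing
continues.

The condition set: non-atom symbols (electron/positron placeholders,
muonium — recognised by a periodic-table whitelist plus D/T, with the
accepted non-atom spellings kept as a configurable constant, since these
have no standard V2000 encoding); general/query atoms (`A`, `Q`, `*`,
`R`, `R#`); atoms aliased as R-groups; undefined charges (unreachable in
a valid SDF but first-class in files converted from other formats);
"any" bonds (type 8); and SRU S-groups without a fixed repeat count.
Aromatic bonds (type 4) are deliberately a warning, not an exclusion —
they are an input-file defect that surfaces at conversion time.  The
same warning channel reports the known conversion-failure classes
(deprecated `Uub`-style symbols, atomic number above 104, coordination
bonds, misformatted attachment-point lines) so that a failed external
conversion can be attributed.

Identifier generation is delegated to the official external tool
through an adapter (executable path, flag set, and the toggle for the
optional keto-enol/1,5 tautomeric rules).  A missing executable is a
clean "adapter unavailable" signal (CLI exit 3), never a crash; tool
warnings about ambiguous stereo descriptions are captured and
classified.

## The synthetic generator and what it shows

The generator decorates a library of real small-molecule skeletons —
verified identifier strings frozen as constants and pinned to the
official algorithm (via its embedded library) in the test-suite — with
stereo designators, inversion flags, charges, protonation, isotopes and
extra components.  Defaults: one entry in four is multicomponent (up to
three components); each prochiral center is `+`/`−`/`?` with probability
0.4/0.4/0.2 and an undefined center is omitted from `/t` half the time
(the two spellings of "undefined" must compare equally); charge,
protonation and isotope decorations appear on 15%, 15% and 10% of
identifiers.

Planted corpora use 200 entries, 150 links and a 5% duplicate rate
(half of the duplicate pairs are tautomer pairs: equal standard,
distinct fixed-hydrogen layers).  Link classes are planted at exact
counts from the per-class rates — 10% stereo refinements, 5% extra
components, 4% protonation changes, 3% isotope changes, 5% stereo
conflicts, 3% skeleton mismatches, 2% dangling targets, 2% targets
without identifiers — magnitudes chosen to echo what curated
cross-reference sets exhibit: skeleton-level breakage in the low
percent, stereo discrepancies several times larger, charge/protonation
in between.  Truth tables (collision pair counts, the 6×2 grid of
inconsistency fractions, identical-link counts) are computed from the
construction — class membership and string equality — never from the
comparison code under test, and the tests require exact recovery with
zero tolerance.

The mutations carry their relation by construction: a stereo refinement
is consistent everywhere except identity mode; a stereo conflict breaks
every stereo-aware mode; protonation breaks `CHSI`/`CHsI` only; an
isotope change breaks everything except `Chs-`/`C---`; an additive
breaks every strict-policy method and no subset-policy method; a
skeleton mutation breaks all twelve.  Stereo mutations always target
the first component so the declared truth cannot be masked by another
component under the subset policy, and a stereo refinement sometimes
re-renders the component in the inverted `/t`+`/m` orientation to
exercise the flag-handling path.

What the generator does not emulate: canonical component ordering and
canonical `(t, m)` selection (decorations are syntactically valid but
not re-canonicalized), tautomer normalization artefacts, real-world
layer statistics, malformed identifiers in the wild.  Passing tests
therefore demonstrate the correctness of the comparison semantics and
the bookkeeping on well-formed identifiers, not robustness against
every output the official tool can produce.

## Problem sizes and numerics

The standard verification runs use 1,000 identifiers for round-trip
identity, an exhaustive ~29,000-pair sweep for oracle equivalence
(designator patterns over skeletons with one to four centers, both
orientations), 10,000 random pairs for the implication lattice, and the
200-entry/150-link planted scenario for collision and rate recovery —
sizes at which every check is exact rather than statistical while the
whole suite stays fast.  All randomness flows through seeded generators
(`random.Random` keyed by a seed and a stream tag); identical spec and
seed reproduce corpora byte for byte.  No floating-point tolerance
appears anywhere: every acceptance comparison is on integers or exact
fractions of them.

## Known limitations

* Identifiers are compared, never generated: without the external
  adapter the package cannot assign identifiers to structures.
* The bare-proton identifier (no formula layer) and V3000 structure
  files are out of scope.
* Fixed-hydrogen layers take part in equality only; a subtype relation
  between extended identifiers is deliberately refused.
* The brute-force oracle is bounded at four stereo centers per
  sub-layer; beyond that it refuses rather than degrades.
* Screening recognises the non-atom spellings it has been taught; an
  exotic placeholder symbol outside the list is still caught as a
  non-periodic symbol, but attributed to the generic reason.
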