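# Methods

This note records the validation model implemented by `cmlcheck`, the
choices made where the design was genuinely open, and what the shipped
corpus does and does not demonstrate.

## Validation model

A document is judged by four ordered checks — well-formedness, structural
(schema-level) validity, convention conformance, and QName/URI
resolvability — each contributing one section to an XML report in the
`http://www.xml-cml.org/report/` namespace. Findings have severities
`valid`, `info`, `warning`, `error` with the aggregation rule: any error ⇒
`INVALID`, else any warning ⇒ `VALID_WITH_WARNINGS`, else `VALID`. A
section may hold a `valid` finding only when it holds no warning and no
error; `info` findings coexist with `valid` and never affect the verdict.
Malformed input stops everything after the well-formedness section, and a
structural error suppresses the convention and URI sections. A convention
error, however, does **not** suppress the URI section: the reference
reports print both, and the verdict is already `INVALID` either way.
Sections never reached are omitted, not emitted empty.

Error locations use a namespace-robust path dialect:
`/*[local-name() = 'N' and namespace-uri() = 'U'][k]` per element step,
where `k` counts preceding siblings with the same expanded name (not all
siblings — either reading matches the reference locations, which all print
`[1]`, but same-name counting uniquely identifies the node). An attribute
appends `@*[local-name() = 'N' and namespace-uri() = 'U']` directly, with
no `/` separator, reproducing the reference serialization byte-for-byte;
the test oracle inserts the slash before evaluating the path as XPath.
Text nodes are preserved in the tree but never cited.

## Structural model

The third-generation CML content model is deliberately relaxed: a CML
element accepts any CML, foreign-namespace or no-namespace child elements
in any order and cardinality, with no mixed content. What remains
checkable at schema level is therefore:

- **vocabulary membership** — an element in the CML namespace whose local
  name is unknown is an error; foreign and no-namespace elements are never
  constrained. The obsoleted mixed-content elements (`annotation`,
  `appinfo`, `documentation`, `relatedEntry`) are simply absent from the
  vocabulary, so using them is a vocabulary error, not a warning.
- **content** — non-whitespace text plus element children on a CML element
  is a mixed-content error; `scalar` is text-only. Whitespace-only text
  between children is formatting, not content.
- **attributes** — each no-namespace attribute on a known CML element is
  checked against its declared datatype (`string`, `integer`, `real`,
  `token-list(n)`, `qname-ref`, closed enumerations); unknown attributes
  are errors; foreign-namespaced attributes pass (the `##other` wildcard).
  A `real-requiring-pair-group` datatype (presence of one coordinate
  demanding its companions) is implemented but unused by default: the
  x3/y3/z3 co-occurrence rule belongs to the molecular convention, where
  co-occurrence constraints are layered by design.
- **deprecated constructs** — numeric bond orders `'1'/'2'/'3'` (aliases
  of `'S'/'D'/'T'`) are warnings, never errors.

The implemented vocabulary is the ~25-element subset used by the built-in
conventions and corpus (the full ~100-element schema is out of scope);
both the element set and the attribute tables are extensible from a YAML
file without code changes.

## Convention scoping

A convention is declared by a `convention` attribute whose QName expands,
via the in-scope namespace bindings, to the convention URI
(`http://www.xml-cml.org/convention/` + name for the built-ins). Its scope
is the declaring element and all descendants. The traversal mirrors a
template/mode rule engine:

- outside any scope the walker descends silently;
- inside a scope the handler sees every element; foreign and no-namespace
  elements draw nothing but do **not** interrupt the mode, so a CML
  element nested inside XHTML inside the scope is still examined;
- a CML element the handler does not speak about draws an informational
  "may be ignored by some processors" finding (the compchem handler opts
  out of this: job documents legitimately carry many parameter/property
  elements);
- a nested declaration switches handlers for the inner subtree;
- a declaration on an inadmissible element (e.g. simpleUnit on
  `molecule`) is one error at the attribute, after which the subtree is
  traversed out of mode so no secondary findings appear;
- unknown convention URIs draw an info and the subtree is traversed out of
  mode ("behaviour is undefined but the default should be to inform");
- a declaration on a non-CML element is ignored entirely — a CML rule
  engine never matches foreign elements.

Because a scope is always a whole subtree, two scopes are either disjoint
or strictly nested; partially-overlapping scopes cannot be expressed, so
no rejection path for them exists.

If a document declares no convention at all, a warning is issued (the
document promises nothing, so conformance is vacuous).

Rule-by-rule, the handlers enforce: **simpleUnit** — declared on
`unitList`; every in-scope `unitList` needs at least one *direct*
`cml:unit` child (a unit nested inside a foreign wrapper does not count,
and the direct-child rule is assessed per `unitList`, so a nested
`unitList` with its own unit passes while its parent fails with exactly
one error). **molecular** — declared on `molecule`; a molecule needs at
least one of molecule/atomArray/name/label/formula and may not have both a
child molecule and a child atomArray; an atomArray needs an atom and a
bondArray a bond; at most one bondArray; atoms need ids, unique within the
*eldest containing molecule* (the outermost ancestor-or-self molecule —
duplicates are reported at the second and later occurrences, so one
duplication yields one error); x3/y3/z3 occur together; a bond references
two distinct existing atoms in the same eldest molecule. **compchem** —
requires a module whose `dictRef` expands to the compchem dictionary's
(`http://xml-cml.org/dictionary/compchem/`) `initialization` entry, with
exactly one molecule that declares the molecular convention (any prefix
bound to the right URI is accepted; the declaration engages the molecular
handler as a nested scope), has an atomArray, and whose atoms all carry
x3/y3/z3. **unit-dictionary** — declared on `dictionary`; entries need a
definition and at most one description; units need ids; a dictionary
without a title is a warning (SHOULD, not MUST).

## URI resolvability

Every attribute declared `qname-ref` (`dictRef`, `convention`, `unitType`,
`units`) is expanded; unbound prefixes are errors, while bound-but-
unreachable URIs are warnings — an offline dictionary should not
invalidate a document. The resolver is pluggable; the default offline
resolver accepts every syntactically absolute URI and performs no network
access, which keeps the distributed test suite deterministic. An online
resolver (stdlib HTTP HEAD, cached per run) is available behind
`--online`.

## Chemistry semantics

- **Formal charge**: explicit `formalCharge` wins; otherwise
  `q = Σ q(child_mol)·count + Σ q(atom)·occupancy·count` recursively, with
  a missing atom charge reading as 0 (the minimal interpretation of an
  unresolved edge case). A non-integral total — possible through
  fractional occupancies — raises rather than rounding silently;
  integrality is tested to 1e-9.
- **Bond perception**: pair (i, j) bonded iff
  `d(i,j) ≤ r_i + r_j + tol`. The defaults are standard single-bond
  covalent radii H 0.37, C 0.77, N 0.75, O 0.73 with tol 0.40 (same
  arbitrary length unit as the coordinates); the table is overridable from
  YAML. The perception criterion itself is this package's choice — the
  reference material fixes only the resulting bond set and mean length on
  the five-atom test molecule (C–N, N–O, 2×C–H; mean 1.2235 ± 1e-4), which
  these defaults reproduce. Output order is canonicalized by sorted id
  pairs, making the result independent of atom order.
- **Average bond length**: arithmetic mean of Euclidean bond lengths;
  undefined (raises) with zero bonds or missing coordinates. Invariance
  under rigid rotation/translation is checked numerically to 1e-9.

## The corpus

`cmlcheck.fixtures` generates every document the behaviour is pinned
against: the 23 simpleUnit reference documents (11 valid with no info, 5
valid with exactly one expected info, 7 invalid with exactly one expected
error), the four namespace-wildcard schema tests, the five-atom reference
molecule, one passing base per convention, and one mutant per rule derived
by `mutate_fixture` — a minimal edit that violates exactly that rule.
Mutations are chosen so only the targeted rule fires (e.g. the compchem
missing-atomArray mutant swaps the atomArray for a `name` child, because
bare removal would also trip molecular's required-child rule). The schema
tests declare no conventions, so they are judged on the structural stage
alone; under the full workflow they would additionally draw the
no-convention warning.

Random inputs for the charge-aggregation property are nested molecule
trees of depth ≤ 4 with charges in [−3, 3] (unset about half the time),
counts in {1, 2, 3} and unit occupancy — integral totals by construction;
200 trees are compared against an independent iterative enumeration
oracle. The acceptance script re-runs a 50-tree version of this self-check
under its `--seed` and recomputes the mean bond length from scratch.

## Limitations

The corpus is synthetic and printed-reference material; it does not
exercise large real-world documents, exotic encodings, or the full CML
element set, and the unit/unitType/dictionary "standard" conventions are
implemented only to the depth of the rules stated above. Passing here
shows the rule engine and report language behave as specified on those
rules — not that every community convention is covered. RDF translation,
document normalization/transformation, the spectroscopy and solid-state
conventions, and any hosted web service are out of scope.
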