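# cmlcheck

Layered validation for Chemical Markup Language (CML) documents, plus the
implicit chemistry semantics that CML molecule trees carry.

CML (namespace `http://www.xml-cml.org/schema`) describes molecules,
reactions, spectra, crystals and computational-chemistry jobs. Its modern
schema is deliberately permissive — almost every element accepts any CML,
foreign-namespace or no-namespace children, in any order — so that
communities can mix chemistry freely with XHTML, MathML or their own
vocabularies. The cost of that freedom is that schema validation alone says
very little. Communities therefore layer *conventions* on top: named,
URI-identified sets of MUST/SHOULD/MAY rules declared inside a document via
the `convention` attribute and scoped to the declaring element and all its
descendants.

`cmlcheck` is for toolmakers and data curators who need a contract at the
boundary: "any document that validates against this convention is safe to
feed to my software." It checks, in order:

1. **well-formedness** of the XML;
2. **structural validity** against a relaxed schema model — CML vocabulary
   membership, no mixed content for CML elements, attribute admissibility
   and datatypes (with closed enumerations for typed attributes such as
   `spectrum/@type ∈ {infrared, massSpectrum, NMR, UV/VIS, other}`), and
   warnings for deprecated constructs such as numeric bond orders
   `order='1'` (alias of `'S'`);
3. **conventions** — built-in handlers for `simpleUnit` (unit lists),
   `molecular` (small molecules: required children, unique atom ids within
   the eldest containing molecule, all-or-none x3/y3/z3 coordinates, bond
   references to two distinct existing atoms), `compchem`
   (computational-chemistry jobs: an initialization module holding exactly
   one fully 3-D molecule that itself declares `molecular`) and
   `unit-dictionary` (entries need definitions, units need ids);
4. **QName/URI resolvability** for `dictRef`, `convention` and their peers.

Findings carry one of four severities which aggregate to the document's
verdict: any *error* ⇒ `INVALID`; else any *warning* ⇒
`VALID_WITH_WARNINGS`; else `VALID` (*info* findings never demote). The
report is itself XML in the `http://www.xml-cml.org/report/` namespace, and
every finding cites its node with a namespace-robust location path such as
`/*[local-name() = 'unitList' and namespace-uri() = '…/schema'][1]`.

Beyond validation, the `chemistry` module implements the implicit semantics
of molecule trees:

- **formal-charge aggregation** — a molecule without `formalCharge`
  derives it recursively:
  `q(mol) = Σ_child q(child)·count(child) + Σ_atom q(atom)·occupancy·count`;
- **bond perception** — atoms *i*, *j* are bonded when
  `d(i,j) ≤ r(elem_i) + r(elem_j) + tol` with single-bond covalent radii
  (H 0.37, C 0.77, N 0.75, O 0.73) and `tol = 0.40`;
- **average bond length** — the arithmetic mean of the Euclidean bond
  lengths (requires full 3-D coordinates).

## Worked example

Validate a unit list that also contains a `molecule` — allowed, but not
part of the simpleUnit convention, so it draws an *info*:

```python
import cmlcheck as cc

doc = b"""<cml:unitList convention="conventions:simpleUnit"
    xmlns:cml="http://www.xml-cml.org/schema"
    xmlns:conventions="http://www.xml-cml.org/convention/">
  <cml:unit/>
  <cml:molecule/>
</cml:unitList>"""

report = cc.validate_document(doc)
print(report.result.value)                 # VALID
print(cc.serialize_report(report).decode())
```

prints:

```xml
<?xml version='1.0' encoding='UTF-8'?>
<report xmlns="http://www.xml-cml.org/report/">
  <well-formed-test>
    <valid>xml is well formed</valid>
  </well-formed-test>
  <schema-validation-test>
    <valid>document conforms to the schema</valid>
  </schema-validation-test>
  <convention-validation-test>
    <info location="/*[local-name() = 'unitList' and namespace-uri() = 'http://www.xml-cml.org/schema'][1]/*[local-name() = 'molecule' and namespace-uri() = 'http://www.xml-cml.org/schema'][1]">molecule is not a part of the http://www.xml-cml.org/convention/simpleUnit convention and may be ignored by some processors.</info>
    <valid>document conforms to all the conventions specified</valid>
  </convention-validation-test>
  <uris-reachable-test>
    <valid>All appropriate URIs were reachable</valid>
    <valid>all dictRefs are resolvable</valid>
  </uris-reachable-test>
</report>
```

The verdict is `VALID`: info findings report MAY-clause territory, not
problems. Had the document contained `<cml:bond order="1"/>` the verdict
would be `VALID_WITH_WARNINGS` (numeric bond orders are deprecated), and a
`unitList` without a direct `cml:unit` child would be `INVALID`.

The chemistry layer, on the five-atom reference molecule shipped with the
test corpus:

```python
from cmlcheck import average_bond_length, molecule_from_node, parse, perceive_bonds
from cmlcheck.fixtures import MOL5_DOCUMENT

mol = molecule_from_node(parse(MOL5_DOCUMENT))
mol.bonds = perceive_bonds(mol)
print([b.atom_ref_pair for b in mol.bonds])
# [('a1', 'a2'), ('a1', 'a4'), ('a1', 'a5'), ('a2', 'a3')]
print(round(average_bond_length(mol), 4))   # 1.2235
```

The distance rule finds the C–N, N–O and two C–H bonds and their mean
length is 1.2235 coordinate units.

There is also a CLI (`cmlcheck FILE [--offline/--online] [--format
xml|text] [--vocab FILE] [--radii FILE]`) whose exit code encodes the
verdict: 0 = VALID, 1 = VALID_WITH_WARNINGS, 2 = INVALID, 3 = usage error.

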