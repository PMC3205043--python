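"""Implicit chemistry semantics carried by CML molecule trees.

Three operations with hard-coded (library-level) semantics:

* recursive formal-charge aggregation — a molecule without an explicit
  ``formalCharge`` derives it from its descendants, weighting child
  molecules by ``count`` and atoms by ``occupancy * count``;
* distance-based bond perception — two atoms are bonded when their
  Cartesian separation does not exceed the sum of their covalent radii
  plus a tolerance;
* average bond length — the arithmetic mean of the Euclidean lengths of
  the bonds, which requires every referenced atom to carry full x3/y3/z3
  coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import yaml

from .document import DocNode


class NonIntegralChargeError(ValueError):
    """Aggregated formal charge is not an integer."""


class MissingCoordinatesError(ValueError):
    """An operation requiring 3-D coordinates met an atom without them."""


class NoBondsError(ValueError):
    """Average bond length is undefined for a molecule with no bonds."""


@dataclass
class AtomView:
    id: str
    element_type: str = ""
    x3: Optional[float] = None
    y3: Optional[float] = None
    z3: Optional[float] = None
    formal_charge: Optional[int] = None
    occupancy: float = 1.0
    count: float = 1.0

    def has_coordinates(self) -> bool:
        return None not in (self.x3, self.y3, self.z3)

    def position(self) -> Tuple[float, float, float]:
        if not self.has_coordinates():
            raise MissingCoordinatesError(
                f"atom {self.id!r} lacks full x3/y3/z3 coordinates"
            )
        return (self.x3, self.y3, self.z3)


@dataclass
class BondView:
    atom_ref_pair: Tuple[str, str]
    order: Optional[str] = None


@dataclass
class MoleculeView:
    formal_charge: Optional[int] = None
    count: float = 1.0
    child_molecules: List["MoleculeView"] = field(default_factory=list)
    atoms: List[AtomView] = field(default_factory=list)
    bonds: List[BondView] = field(default_factory=list)

    def atom_by_id(self, atom_id: str) -> AtomView:
        for atom in self.atoms:
            if atom.id == atom_id:
                return atom
        for child in self.child_molecules:
            try:
                return child.atom_by_id(atom_id)
            except KeyError:
                pass
        raise KeyError(atom_id)


@dataclass
class CovalentRadiusTable:
    """Element symbol -> single-bond covalent radius, plus a slack tolerance.

    Radii and tolerance are in the same (arbitrary) length unit as the
    coordinates; the defaults cover the organic set H/C/N/O.
    """

    radii: Dict[str, float] = field(
        default_factory=lambda: {"H": 0.37, "C": 0.77, "N": 0.75, "O": 0.73}
    )
    tolerance: float = 0.40

    def radius(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise KeyError(f"no covalent radius for element {element!r}") from None

    @classmethod
    def from_yaml(cls, path) -> "CovalentRadiusTable":
        with open(path, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
        table = cls()
        table.radii.update(
            {k: float(v) for k, v in (config.get("radii") or {}).items()}
        )
        if "tolerance" in config:
            table.tolerance = float(config["tolerance"])
        return table


def molecule_from_node(node: DocNode) -> MoleculeView:
    """Build a :class:`MoleculeView` from a parsed ``cml:molecule`` subtree."""
    if not node.is_cml("molecule"):
        raise ValueError("node is not a cml:molecule element")
    mol = MoleculeView(
        formal_charge=_opt_int(node.attribute_value("formalCharge")),
        count=_opt_float(node.attribute_value("count"), 1.0),
    )
    for child in node.element_children():
        if child.is_cml("molecule"):
            mol.child_molecules.append(molecule_from_node(child))
        elif child.is_cml("atomArray"):
            for atom_el in child.element_children():
                if atom_el.is_cml("atom"):
                    mol.atoms.append(_atom_from_node(atom_el))
        elif child.is_cml("bondArray"):
            for bond_el in child.element_children():
                if bond_el.is_cml("bond"):
                    refs = (bond_el.attribute_value("atomRefs2") or "").split()
                    if len(refs) == 2:
                        mol.bonds.append(
                            BondView(tuple(refs), bond_el.attribute_value("order"))
                        )
    return mol


def _atom_from_node(node: DocNode) -> AtomView:
    return AtomView(
        id=node.attribute_value("id") or "",
        element_type=node.attribute_value("elementType") or "",
        x3=_opt_float(node.attribute_value("x3")),
        y3=_opt_float(node.attribute_value("y3")),
        z3=_opt_float(node.attribute_value("z3")),
        formal_charge=_opt_int(node.attribute_value("formalCharge")),
        occupancy=_opt_float(node.attribute_value("occupancy"), 1.0),
        count=_opt_float(node.attribute_value("count"), 1.0),
    )


def _opt_int(value: Optional[str]) -> Optional[int]:
    return None if value is None else int(value)


def _opt_float(value: Optional[str], default: Optional[float] = None) -> Optional[float]:
    return default if value is None else float(value)


_INTEGRALITY_TOL = 1e-9


def effective_formal_charge(mol: MoleculeView) -> int:
    """Explicit ``formalCharge`` if set, else the recursive descendant sum.

    Child molecules contribute ``effective_formal_charge * count``; atoms
    contribute ``formal_charge * occupancy * count`` with a missing atom
    charge reading as zero.  A non-integral total (possible through
    fractional occupancies) raises :class:`NonIntegralChargeError` rather
    than being silently rounded.
    """
    if mol.formal_charge is not None:
        return mol.formal_charge
    total = 0.0
    for child in mol.child_molecules:
        total += effective_formal_charge(child) * child.count
    for atom in mol.atoms:
        if atom.formal_charge is not None:
            total += atom.formal_charge * atom.occupancy * atom.count
    nearest = round(total)
    if abs(total - nearest) > _INTEGRALITY_TOL:
        raise NonIntegralChargeError(
            f"aggregated formal charge {total} is not an integer"
        )
    return int(nearest)


def _distance(a: AtomView, b: AtomView) -> float:
    return math.dist(a.position(), b.position())


def perceive_bonds(
    mol: MoleculeView, radii: Optional[CovalentRadiusTable] = None
) -> List[BondView]:
    """Bond every atom pair closer than the sum of covalent radii + tolerance.

    Returns bonds in canonical order (sorted id pairs); requires full 3-D
    coordinates on every atom.
    """
    radii = radii or CovalentRadiusTable()
    for atom in mol.atoms:
        if not atom.has_coordinates():
            raise MissingCoordinatesError(
                f"atom {atom.id!r} lacks full x3/y3/z3 coordinates"
            )
    bonds = []
    for i, a in enumerate(mol.atoms):
        for b in mol.atoms[i + 1:]:
            threshold = (
                radii.radius(a.element_type)
                + radii.radius(b.element_type)
                + radii.tolerance
            )
            if _distance(a, b) <= threshold:
                bonds.append(BondView(tuple(sorted((a.id, b.id)))))
    bonds.sort(key=lambda bond: bond.atom_ref_pair)
    return bonds


def average_bond_length(mol: MoleculeView) -> float:
    """Arithmetic mean of the Euclidean lengths of the molecule's bonds."""
    if not mol.bonds:
        raise NoBondsError("molecule has no bonds")
    total = 0.0
    for bond in mol.bonds:
        a = mol.atom_by_id(bond.atom_ref_pair[0])
        b = mol.atom_by_id(bond.atom_ref_pair[1])
        total += _distance(a, b)
    return total / len(mol.bonds)
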