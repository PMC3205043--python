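"""Implicit chemistry semantics: charge aggregation, bond perception."""

import math
import random

import pytest

from cmlcheck import (
    AtomView,
    BondView,
    CovalentRadiusTable,
    MissingCoordinatesError,
    MoleculeView,
    NoBondsError,
    NonIntegralChargeError,
    average_bond_length,
    effective_formal_charge,
    molecule_from_node,
    parse,
    perceive_bonds,
)
from cmlcheck.fixtures import MOL5_DOCUMENT, random_molecule_tree


def brute_force_charge(mol):
    """Independent oracle: iterative enumeration of every descendant
    contribution with its multiplier along the path of unset molecules."""
    if mol.formal_charge is not None:
        return mol.formal_charge
    total = 0.0
    stack = [(mol, 1.0)]
    while stack:
        current, mult = stack.pop()
        for atom in current.atoms:
            if atom.formal_charge is not None:
                total += atom.formal_charge * atom.occupancy * atom.count * mult
        for child in current.child_molecules:
            if child.formal_charge is not None:
                total += child.formal_charge * child.count * mult
            else:
                stack.append((child, mult * child.count))
    return round(total)


class TestFormalCharge:
    def test_explicit_attribute_wins(self):
        mol = MoleculeView(formal_charge=-1, atoms=[AtomView("a", formal_charge=5)])
        assert effective_formal_charge(mol) == -1

    def test_unset_atom_charges_read_as_zero(self):
        mol = MoleculeView(
            atoms=[
                AtomView("a", formal_charge=1),
                AtomView("b", formal_charge=-1),
                AtomView("c"),
            ]
        )
        assert effective_formal_charge(mol) == 0

    def test_child_molecule_weighted_by_count(self):
        child = MoleculeView(formal_charge=-1, count=2.0)
        assert effective_formal_charge(MoleculeView(child_molecules=[child])) == -2

    def test_fractional_total_raises(self):
        mol = MoleculeView(
            atoms=[AtomView("a", formal_charge=1, occupancy=0.5)]
        )
        with pytest.raises(NonIntegralChargeError):
            effective_formal_charge(mol)

    def test_matches_brute_force_oracle_on_random_trees(self):
        rng = random.Random(4242)
        for _ in range(200):
            mol = random_molecule_tree(rng)
            assert effective_formal_charge(mol) == brute_force_charge(mol)


def _mol5():
    return molecule_from_node(parse(MOL5_DOCUMENT))


class TestBondPerception:
    def test_mol5_bond_set(self):
        # oracle: hand-computed pairwise distances against radius sums
        # (C-N 1.300, N-O 1.3454 and both C-H 1.1243 within threshold;
        # all N-H, O-H, C-O and H-H separations exceed theirs)
        bonds = perceive_bonds(_mol5())
        assert [b.atom_ref_pair for b in bonds] == [
            ("a1", "a2"), ("a1", "a4"), ("a1", "a5"), ("a2", "a3"),
        ]

    def test_distant_atoms_stay_unbonded(self):
        mol = MoleculeView(
            atoms=[
                AtomView("h1", "H", 0.0, 0.0, 0.0),
                AtomView("h2", "H", 10.0, 0.0, 0.0),
            ]
        )
        assert perceive_bonds(mol) == []

    def test_single_atom_has_no_bonds(self):
        mol = MoleculeView(atoms=[AtomView("a", "C", 0.0, 0.0, 0.0)])
        assert perceive_bonds(mol) == []

    def test_missing_coordinates_raise(self):
        mol = MoleculeView(atoms=[AtomView("a", "C", 0.0, 0.0, None)])
        with pytest.raises(MissingCoordinatesError):
            perceive_bonds(mol)

    def test_invariant_under_reordering_and_translation(self):
        rng = random.Random(7)
        mol = _mol5()
        reference = [b.atom_ref_pair for b in perceive_bonds(mol)]
        shifted = _mol5()
        dx, dy, dz = (rng.uniform(-50, 50) for _ in range(3))
        rng.shuffle(shifted.atoms)
        for atom in shifted.atoms:
            atom.x3 += dx
            atom.y3 += dy
            atom.z3 += dz
        assert [b.atom_ref_pair for b in perceive_bonds(shifted)] == reference

    def test_custom_radius_table(self):
        mol = MoleculeView(
            atoms=[
                AtomView("a", "Xx", 0.0, 0.0, 0.0),
                AtomView("b", "Xx", 2.0, 0.0, 0.0),
            ]
        )
        table = CovalentRadiusTable(radii={"Xx": 1.0}, tolerance=0.1)
        assert len(perceive_bonds(mol, table)) == 1


class TestAverageBondLength:
    def test_mol5_reference_value(self):
        mol = _mol5()
        mol.bonds = perceive_bonds(mol)
        assert average_bond_length(mol) == pytest.approx(1.2235, abs=1e-4)

    def test_unit_bond(self):
        mol = MoleculeView(
            atoms=[
                AtomView("a", "C", 0.0, 0.0, 0.0),
                AtomView("b", "C", 1.0, 0.0, 0.0),
            ],
            bonds=[BondView(("a", "b"))],
        )
        assert average_bond_length(mol) == pytest.approx(1.0)

    def test_no_bonds_raises(self):
        with pytest.raises(NoBondsError):
            average_bond_length(MoleculeView())

    def test_missing_coordinate_raises(self):
        mol = MoleculeView(
            atoms=[
                AtomView("a", "C", 0.0, 0.0, 0.0),
                AtomView("b", "C", 1.0, 0.0, None),
            ],
            bonds=[BondView(("a", "b"))],
        )
        with pytest.raises(MissingCoordinatesError):
            average_bond_length(mol)

    def test_invariant_under_rigid_rotation_and_translation(self):
        mol = _mol5()
        mol.bonds = perceive_bonds(mol)
        reference = average_bond_length(mol)
        # rotate about z by a fixed angle, then about x, then translate
        a, b = 0.7853981633974483, 1.1
        rotated = _mol5()
        for atom in rotated.atoms:
            x, y, z = atom.x3, atom.y3, atom.z3
            x, y = x * math.cos(a) - y * math.sin(a), x * math.sin(a) + y * math.cos(a)
            y, z = y * math.cos(b) - z * math.sin(b), y * math.sin(b) + z * math.cos(b)
            atom.x3, atom.y3, atom.z3 = x + 3.0, y - 2.0, z + 11.0
        rotated.bonds = perceive_bonds(rotated)
        assert average_bond_length(rotated) == pytest.approx(reference, abs=1e-9)


def test_molecule_view_from_cml_subtree_reads_all_attributes():
    doc = (
        '<cml:molecule xmlns:cml="http://www.xml-cml.org/schema" count="2">'
        '<cml:molecule formalCharge="-1" count="3"/>'
        '<cml:atomArray>'
        '<cml:atom id="a1" elementType="N" formalCharge="1" occupancy="0.5" count="2"/>'
        '</cml:atomArray>'
        '<cml:bondArray><cml:bond atomRefs2="a1 a2" order="S"/></cml:bondArray>'
        "</cml:molecule>"
    )
    mol = molecule_from_node(parse(doc))
    assert mol.count == 2.0
    assert mol.child_molecules[0].formal_charge == -1
    atom = mol.atoms[0]
    assert (atom.element_type, atom.formal_charge, atom.occupancy, atom.count) == (
        "N", 1, 0.5, 2.0
    )
    assert mol.bonds[0].atom_ref_pair == ("a1", "a2")
    assert mol.bonds[0].order == "S"
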