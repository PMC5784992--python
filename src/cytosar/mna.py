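"""Multilevel Neighbourhoods of Atoms (MNA) descriptors.

An MNA descriptor is a canonical linear string for one atom and its
bonded neighbourhood to a given depth (the *level*), built over the
hydrogen-complete graph and deliberately blind to bond orders and
stereochemistry:

* level 0 — the atom label alone: ``-X`` for an acyclic atom, bare
  ``X`` for a ring atom, with ``+``/``-`` appended ``|charge|`` times
  for formally charged atoms;
* level k — ``label(sub1sub2...subn)`` where the subs are the
  level-(k-1) descriptors of every bonded neighbour (hydrogens
  included), sorted in ascending byte order before concatenation.

A molecule is represented by the *unique set* of its level-1 and
level-2 descriptors over all atoms, so features are binary and the set
is invariant under atom reordering and stereo changes. Downstream code
treats descriptors as opaque strings; only canonical equality matters.
"""

from __future__ import annotations

from dataclasses import dataclass

from cytosar.errors import InvalidStructureError
from cytosar.structures import Molecule, validate_structure

LEVELS = (1, 2)


@dataclass(frozen=True)
class DescriptorSet:
    """Unique MNA strings (levels 1 and 2 pooled) for one molecule."""

    descriptors: frozenset[str]
    molecule_id: str = ""

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def __contains__(self, item: str) -> bool:
        return item in self.descriptors

    def sorted(self) -> list[str]:
        return sorted(self.descriptors)


def atom_label(mol: Molecule, idx: int) -> str:
    """Level-0 label: ring mark, element symbol, formal-charge marks.

    Acyclic atoms are prefixed ``-``; ring atoms carry no mark. A
    formal charge of +2 appends ``++``, of -1 appends ``-``. Neutral
    validated inputs never exercise the charge suffix, but the label is
    defined for robustness.
    """
    atom = mol.atoms[idx]
    mark = "" if atom.in_ring else "-"
    charge = atom.formal_charge
    suffix = ("+" if charge > 0 else "-") * abs(charge)
    return f"{mark}{atom.element}{suffix}"


def mna_descriptor(mol: Molecule, idx: int, level: int) -> str:
    """Canonical MNA descriptor of ``atom idx`` at the given level.

    Recursive: the level-k string wraps the sorted level-(k-1) strings
    of all bonded neighbours in parentheses after the atom's own
    label. Bond orders never appear.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    label = atom_label(mol, idx)
    if level == 0:
        return label
    subs = sorted(
        mna_descriptor(mol, nb, level - 1) for nb in mol.neighbors[idx]
    )
    return label + "(" + "".join(subs) + ")"


def descriptor_set(mol: Molecule, *, validated: bool = False) -> DescriptorSet:
    """Deduplicated union of level-1 and level-2 descriptors of ``mol``.

    Refuses molecules failing the admissibility criteria unless the
    caller vouches with ``validated=True`` (e.g. when the same report
    was just computed).
    """
    if not validated:
        report = validate_structure(mol)
        if not report.passed:
            raise InvalidStructureError(report)
    descs = {
        mna_descriptor(mol, idx, level)
        for idx in range(len(mol.atoms))
        for level in LEVELS
    }
    return DescriptorSet(frozenset(descs), mol.identifier)
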