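"""Molecular structure parsing, validation, and SDF round-trip.

Molecules are held as an explicit hydrogen-complete graph: every atom
carries its element symbol, formal charge and ring flag; every bond an
integer order in {1, 2, 3} (aromatic systems are kekulized on parse).
Stereochemical annotations are accepted on input and discarded, so
stereoisomers become indistinguishable downstream — descriptor
generation treats them as the same substance.

Admissibility of a structure for modelling is decided by six criteria:

1. every atom is a real element (no query atoms / R-group labels),
2. every bond has order 1, 2 or 3 after kekulization,
3. at least three carbon atoms,
4. a single connected component,
5. every formal charge zero (and hence zero net charge),
6. average molecular weight strictly below 1250 Da.

``validate_structure`` reports *all* violated criteria, never just the
first, so a curation pipeline can log complete reasons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from cytosar.errors import StructureError, StructureParseError

log = logging.getLogger(__name__)

# RDKit mirrors parse diagnostics to its own C++ logger; we surface them
# through exceptions instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")

_PERIODIC_TABLE = Chem.GetPeriodicTable()

#: Criterion codes emitted by :func:`validate_structure`.
ATOM_SYMBOL = "ATOM_SYMBOL"
BOND_TYPE = "BOND_TYPE"
MIN_CARBON = "MIN_CARBON"
MULTI_COMPONENT = "MULTI_COMPONENT"
NOT_NEUTRAL = "NOT_NEUTRAL"
MW_LIMIT = "MW_LIMIT"

_BOND_FROM_ORDER = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, formal charge, ring membership."""

    element: str
    formal_charge: int
    in_ring: bool


@dataclass(frozen=True)
class Bond:
    """Undirected bond between atom indices ``i < j`` with integer order."""

    i: int
    j: int
    order: int


@dataclass
class Molecule:
    """Hydrogen-complete molecular graph.

    ``atoms`` includes every hydrogen (implicit hydrogens are
    materialized on parse); ``bonds`` reference atom indices.
    ``identifier`` is an opaque tag carried through descriptor
    generation and training.
    """

    atoms: list[Atom]
    bonds: list[Bond]
    identifier: str = ""
    _neighbors: list[list[int]] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def neighbors(self) -> list[list[int]]:
        """Adjacency list, built lazily and cached."""
        if self._neighbors is None:
            adj: list[list[int]] = [[] for _ in self.atoms]
            for b in self.bonds:
                adj[b.i].append(b.j)
                adj[b.j].append(b.i)
            self._neighbors = adj
        return self._neighbors

    @property
    def n_heavy_atoms(self) -> int:
        return sum(1 for a in self.atoms if a.element != "H")

    def molecular_weight(self) -> float:
        """Average molecular weight in Daltons, hydrogens included.

        Uses an exactly rounded sum so the value is independent of
        atom ordering.
        """
        return math.fsum(
            _PERIODIC_TABLE.GetAtomicWeight(a.element)
            for a in self.atoms
            if _element_is_real(a.element)
        )


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of the six admissibility criteria for one molecule."""

    passed: bool
    failures: tuple[str, ...]
    molecular_weight: float

    def __post_init__(self):
        assert self.passed == (len(self.failures) == 0)


def _element_is_real(symbol: str) -> bool:
    try:
        return _PERIODIC_TABLE.GetAtomicNumber(symbol) > 0
    except Exception:
        return False


def _rdkit_parse(text: str, fmt: str) -> Chem.Mol:
    if not text:
        raise StructureParseError("empty structure input")
    if fmt == "smiles":
        rd = Chem.MolFromSmiles(text, sanitize=False)
        if rd is None:
            raise StructureParseError(f"unparseable SMILES: {text!r}")
    elif fmt == "molblock":
        rd = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
        if rd is None:
            raise StructureParseError("unparseable MOL (V2000) block")
    else:
        raise ValueError(f"unknown structure format: {fmt!r}")
    problems = Chem.DetectChemistryProblems(rd)
    if problems:
        raise StructureError(
            "; ".join(p.Message() for p in problems)
        )
    Chem.SanitizeMol(rd)
    return rd


def _molecule_from_rdkit(rd: Chem.Mol, identifier: str) -> Molecule:
    """Convert a sanitized RDKit mol into the package's graph form.

    Kekulizes (clearing aromatic flags so bond orders land in {1,2}),
    materializes hydrogens, and drops stereo annotations by simply not
    recording them.
    """
    rd = Chem.Mol(rd)
    try:
        Chem.Kekulize(rd, clearAromaticFlags=True)
    except Chem.KekulizeException as exc:
        raise StructureError(f"kekulization failed: {exc}") from exc
    rd = Chem.AddHs(rd)
    Chem.GetSymmSSSR(rd)  # ring info needed for in_ring flags
    atoms = [
        Atom(a.GetSymbol(), a.GetFormalCharge(), a.IsInRing())
        for a in rd.GetAtoms()
    ]
    bonds = []
    for b in rd.GetBonds():
        order_f = b.GetBondTypeAsDouble()
        order = int(order_f) if float(order_f).is_integer() else 0
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        bonds.append(Bond(min(i, j), max(i, j), order))
    return Molecule(atoms=atoms, bonds=bonds, identifier=identifier)


def parse_structure(
    text: str,
    format: str = "smiles",
    *,
    identifier: str | None = None,
    neutralize: bool = False,
    strip_salts: bool = False,
) -> Molecule:
    """Parse a SMILES string or MOL V2000 block into a :class:`Molecule`.

    Parameters
    ----------
    text : structure text in the given format.
    format : ``"smiles"`` or ``"molblock"``.
    identifier : optional tag; defaults to the input text (SMILES) or
        the molblock title line.
    neutralize : apply protonation-state normalization (uncharging)
        before building the graph. Off by default: by the admissibility
        criteria, charged input is the submitter's problem.
    strip_salts : keep only the largest fragment before validation.
        Off by default to match the single-component criterion.

    Raises
    ------
    StructureParseError : text is not syntactically valid.
    StructureError : valence or kekulization problems.
    """
    rd = _rdkit_parse(text, format)
    if identifier is None:
        if format == "molblock":
            identifier = text.splitlines()[0].strip() or "molblock"
        else:
            identifier = text
    if strip_salts:
        rd = rdMolStandardize.LargestFragmentChooser().choose(rd)
    if neutralize:
        rd = rdMolStandardize.Uncharger().uncharge(rd)
    return _molecule_from_rdkit(rd, identifier)


def _n_components(mol: Molecule) -> int:
    n = len(mol.atoms)
    if n == 0:
        return 0
    seen = [False] * n
    comps = 0
    for start in range(n):
        if seen[start]:
            continue
        comps += 1
        stack = [start]
        seen[start] = True
        while stack:
            cur = stack.pop()
            for nb in mol.neighbors[cur]:
                if not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
    return comps


def validate_structure(mol: Molecule, mw_limit: float = 1250.0) -> ValidationReport:
    """Apply the six admissibility criteria; report every failure.

    The molecular weight bound is strict (a molecule of exactly
    ``mw_limit`` Da fails); neutrality requires every atom's formal
    charge to be zero, which implies zero net charge.
    """
    failures: list[str] = []
    if any(not _element_is_real(a.element) for a in mol.atoms):
        failures.append(ATOM_SYMBOL)
    if any(b.order not in (1, 2, 3) for b in mol.bonds):
        failures.append(BOND_TYPE)
    if sum(1 for a in mol.atoms if a.element == "C") < 3:
        failures.append(MIN_CARBON)
    if _n_components(mol) > 1:
        failures.append(MULTI_COMPONENT)
    if any(a.formal_charge != 0 for a in mol.atoms):
        failures.append(NOT_NEUTRAL)
    mw = mol.molecular_weight()
    if not mw < mw_limit:
        failures.append(MW_LIMIT)
    return ValidationReport(
        passed=not failures,
        failures=tuple(failures),
        molecular_weight=mw,
    )


def to_rdkit(mol: Molecule) -> Chem.Mol:
    """Rebuild a sanitized RDKit mol from the explicit-hydrogen graph."""
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    for b in mol.bonds:
        rw.AddBond(b.i, b.j, _BOND_FROM_ORDER.get(b.order, Chem.BondType.SINGLE))
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


class SDFReader:
    """Iterator over (Molecule, properties) records of a V2000 SDF file.

    Malformed records are skipped with a warning; the running skip
    count is exposed as :attr:`skipped`.
    """

    def __init__(self, path: str | Path):
        path = Path(path)
        if not path.exists():
            raise OSError(f"SDF file not found: {path}")
        self._path = path
        self.skipped = 0

    def __iter__(self) -> Iterator[tuple[Molecule, dict[str, str]]]:
        if self._path.stat().st_size == 0:
            return  # empty file is a valid empty stream
        supplier = Chem.SDMolSupplier(
            str(self._path), sanitize=True, removeHs=False
        )
        for idx, rd in enumerate(supplier):
            if rd is None:
                self.skipped += 1
                log.warning("skipping malformed SDF record %d in %s", idx, self._path)
                continue
            props = {
                k: rd.GetProp(k)
                for k in rd.GetPropNames()
            }
            name = rd.GetProp("_Name") if rd.HasProp("_Name") else f"record_{idx}"
            try:
                mol = _molecule_from_rdkit(rd, identifier=name)
            except (StructureError, StructureParseError):
                self.skipped += 1
                log.warning("skipping unkekulizable SDF record %d in %s", idx, self._path)
                continue
            yield mol, props


def read_sdf(path: str | Path) -> SDFReader:
    """Open an SDF file for streaming; see :class:`SDFReader`."""
    return SDFReader(path)


def write_sdf(
    records: Iterable[tuple[Molecule, Mapping[str, str]] | Molecule],
    path: str | Path,
) -> int:
    """Write molecules (optionally with a property map) to a V2000 SDF.

    Returns the record count. Round trip guarantee: re-reading the file
    reproduces each molecule's heavy-atom graph, formal charges and
    properties.
    """
    writer = Chem.SDWriter(str(path))
    count = 0
    try:
        for rec in records:
            if isinstance(rec, Molecule):
                mol, props = rec, {}
            else:
                mol, props = rec
            rd = to_rdkit(mol)
            rd.SetProp("_Name", mol.identifier)
            for key, value in props.items():
                rd.SetProp(str(key), str(value))
            writer.write(rd)
            count += 1
    finally:
        writer.close()
    return count
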