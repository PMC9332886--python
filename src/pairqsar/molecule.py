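"""Molecular graphs with typed atoms, topological distances and charges.

Structures are parsed with RDKit, hydrogens are made explicit, and the
all-pairs shortest-path matrix (in bond counts) is computed over the
explicit-hydrogen graph.  On top of the raw graph, each atom is assigned
the pharmacophoric flags the descriptor grammar uses (donor, amide
nitrogen, lipophilic, ring sulfur, ...).  Partial charges come from
iterative partial equalization of orbital electronegativity
(Gasteiger-Marsili); 3D coordinates are generated lazily, only when a
geometric descriptor asks for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors

from .errors import (
    MultiComponentError,
    NoGeometryError,
    SmilesParseError,
    UnsupportedElementError,
)

HALOGENS = {"F", "Cl", "Br", "I"}

#: All flags the typing table can assign.
ATOM_FLAGS = (
    "ring_C",
    "ring_S",
    "donor",
    "amide_N",
    "sp3_C",
    "sp2_O",
    "nonring_O",
    "lipophilic",
    "H",
)


@dataclass
class TypingRules:
    """Configurable atom-typing table.

    The defaults are the simplest rules consistent with the descriptor
    semantics: a donor is an N or O carrying at least one hydrogen; an
    amide nitrogen is single-bonded to a carbonyl carbon; lipophilic
    atoms are carbons with no N/O neighbour plus (optionally) sulfur and
    the halogens.  Whether S and halogens count as lipophilic is an open
    interpretation in the field, hence the switches.
    """

    lipophilic_include_sulfur: bool = True
    lipophilic_include_halogens: bool = True


DEFAULT_TYPING_RULES = TypingRules()


@dataclass
class AtomInfo:
    element: str
    in_ring: bool
    aromatic: bool
    hybridization: str  # "sp" | "sp2" | "sp3" | "none"
    n_attached_H: int
    partial_charge: float = 0.0
    flags: set = field(default_factory=set)


@dataclass
class MolecularGraph:
    """Typed molecular graph with explicit hydrogens.

    ``dist[i, j]`` is the number of bonds on the shortest path between
    atoms i and j; ``molweight`` is the summed atomic masses in g/mol.
    The underlying RDKit molecule is kept for IO and charge/geometry
    calculations but all descriptor evaluation goes through the arrays.
    """

    atoms: list
    bonds: list  # unordered index pairs
    dist: np.ndarray
    molweight: float
    coords3d: np.ndarray | None = None
    smiles: str = ""
    rdmol: Chem.Mol | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def flag_mask(self, flag: str) -> np.ndarray:
        """Boolean mask over atoms carrying ``flag``.

        Besides the typing-table flags, bare element symbols ("N", "O",
        "C", "S", ...) are accepted so the descriptor grammar can use
        untyped centers like plain nitrogen.
        """
        if flag in ATOM_FLAGS:
            return np.array([flag in a.flags for a in self.atoms], dtype=bool)
        return np.array([a.element == flag for a in self.atoms], dtype=bool)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)


_HYB_NAMES = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


def _graph_from_rdmol(mol: Chem.Mol, smiles: str = "") -> MolecularGraph:
    atoms = []
    for a in mol.GetAtoms():
        atoms.append(
            AtomInfo(
                element=a.GetSymbol(),
                in_ring=a.IsInRing(),
                aromatic=a.GetIsAromatic(),
                hybridization=_HYB_NAMES.get(a.GetHybridization(), "none"),
                n_attached_H=sum(
                    1 for nb in a.GetNeighbors() if nb.GetAtomicNum() == 1
                ),
            )
        )
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    ]
    dist = Chem.GetDistanceMatrix(mol).astype(int)
    coords = None
    if mol.GetNumConformers() > 0:
        coords = np.asarray(mol.GetConformer().GetPositions(), dtype=float)
    return MolecularGraph(
        atoms=atoms,
        bonds=bonds,
        dist=dist,
        molweight=Descriptors.MolWt(mol),
        coords3d=coords,
        smiles=smiles,
        rdmol=mol,
    )


def parse_molecule(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a typed molecular graph.

    Hydrogens are added explicitly, aromaticity is perceived by RDKit,
    and topological distances are computed for all atom pairs.  Multi
    fragment inputs (salts, mixtures) are rejected; they must be handled
    at curation time.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(str(smiles), "empty input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    if len(Chem.GetMolFrags(mol)) > 1:
        raise MultiComponentError(smiles)
    mol = Chem.AddHs(mol)
    g = _graph_from_rdmol(mol, smiles=smiles)
    return assign_atom_types(g)


def assign_atom_types(
    g: MolecularGraph, rules: TypingRules = DEFAULT_TYPING_RULES
) -> MolecularGraph:
    """Populate pharmacophoric flags on every atom (idempotent, total).

    Typing table:

    * ``H`` — hydrogen.
    * ``ring_C`` / ``ring_S`` — ring-member carbon / sulfur.
    * ``donor`` — N or O bearing at least one hydrogen.
    * ``amide_N`` — N single-bonded to a carbon that is double-bonded to O.
    * ``sp3_C`` — sp3-hybridised carbon.
    * ``sp2_O`` — oxygen participating in a double bond.
    * ``nonring_O`` — oxygen not in a ring.
    * ``lipophilic`` — carbon with no N/O neighbour, plus S and the
      halogens when the rules include them.
    """
    mol = g.rdmol
    for idx, info in enumerate(g.atoms):
        a = mol.GetAtomWithIdx(idx)
        flags = set()
        sym = info.element
        if sym == "H":
            flags.add("H")
        if sym == "C" and info.in_ring:
            flags.add("ring_C")
        if sym == "S" and info.in_ring:
            flags.add("ring_S")
        if sym in ("N", "O") and a.GetTotalNumHs(includeNeighbors=True) >= 1:
            flags.add("donor")
        if sym == "N":
            for b in a.GetBonds():
                if b.GetBondType() != Chem.BondType.SINGLE:
                    continue
                c = b.GetOtherAtom(a)
                if c.GetSymbol() != "C":
                    continue
                if any(
                    bb.GetBondType() == Chem.BondType.DOUBLE
                    and bb.GetOtherAtom(c).GetSymbol() == "O"
                    for bb in c.GetBonds()
                ):
                    flags.add("amide_N")
                    break
        if sym == "C" and info.hybridization == "sp3":
            flags.add("sp3_C")
        if sym == "O" and any(
            b.GetBondType() == Chem.BondType.DOUBLE for b in a.GetBonds()
        ):
            flags.add("sp2_O")
        if sym == "O" and not info.in_ring:
            flags.add("nonring_O")
        if sym == "C" and not any(
            nb.GetSymbol() in ("N", "O") for nb in a.GetNeighbors()
        ):
            flags.add("lipophilic")
        if rules.lipophilic_include_sulfur and sym == "S":
            flags.add("lipophilic")
        if rules.lipophilic_include_halogens and sym in HALOGENS:
            flags.add("lipophilic")
        info.flags = flags
    return g


def compute_partial_charges(g: MolecularGraph, n_iter: int = 8) -> np.ndarray:
    """Gasteiger-Marsili iterative partial equalization charges.

    Charges are stored on the atoms and returned as an array; for a
    neutral molecule they sum to zero (the procedure only shifts charge
    along bonds).  Elements without Gasteiger parameters raise.
    """
    mol = g.rdmol
    AllChem.ComputeGasteigerCharges(mol, nIter=n_iter, throwOnParamFailure=False)
    charges = np.array(
        [
            float(a.GetProp("_GasteigerCharge"))
            + float(a.GetProp("_GasteigerHCharge"))
            for a in mol.GetAtoms()
        ]
    )
    if not np.all(np.isfinite(charges)):
        bad = sorted(
            {
                g.atoms[i].element
                for i in np.flatnonzero(~np.isfinite(charges))
            }
        )
        raise UnsupportedElementError(
            f"no charge parameters for element(s): {bad}"
        )
    for info, q in zip(g.atoms, charges):
        info.partial_charge = float(q)
    return charges


def embed_3d(g: MolecularGraph, seed: int = 42, minimize: bool = True) -> np.ndarray:
    """Generate deterministic 3D coordinates (ETKDG, then MMFF94).

    Coordinates already present on the graph (e.g. from SDF input) take
    precedence and are returned untouched.
    """
    if g.coords3d is not None:
        return g.coords3d
    mol = Chem.Mol(g.rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    conf_id = AllChem.EmbedMolecule(mol, params)
    if conf_id < 0:
        raise NoGeometryError(f"3D embedding failed for {g.smiles!r}")
    if minimize:
        try:
            AllChem.MMFFOptimizeMolecule(mol)
        except Exception:
            pass  # unminimized ETKDG geometry is still usable
    g.coords3d = np.asarray(mol.GetConformer().GetPositions(), dtype=float)
    g.rdmol = mol
    return g.coords3d


def atomic_masses(g: MolecularGraph) -> np.ndarray:
    return np.array([a.GetMass() for a in g.rdmol.GetAtoms()], dtype=float)


# ---------------------------------------------------------------------------
# IO


def read_smiles_file(path) -> list:
    """Read SMILES, one per line; '#' starts a comment."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split()[0])
    return out


def read_sdf(path) -> list:
    """Read a multi-record SDF (V2000); 3D coordinates are honored."""
    graphs = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for mol in supplier:
        if mol is None:
            continue
        mol = Chem.AddHs(mol, addCoords=mol.GetNumConformers() > 0)
        g = _graph_from_rdmol(mol, smiles=Chem.MolToSmiles(mol))
        graphs.append(assign_atom_types(g))
    return graphs


def write_sdf(graphs, path) -> None:
    """Write graphs to SDF with computed atom flags as a property."""
    writer = Chem.SDWriter(str(path))
    try:
        for g in graphs:
            mol = Chem.Mol(g.rdmol)
            flag_str = ";".join(
                f"{i}:{','.join(sorted(a.flags))}" for i, a in enumerate(g.atoms)
            )
            mol.SetProp("pairqsar_atom_flags", flag_str)
            if mol.GetNumConformers() == 0 and g.coords3d is None:
                AllChem.Compute2DCoords(mol)
            writer.write(mol)
    finally:
        writer.close()
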