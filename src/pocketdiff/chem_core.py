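"""Domain types for pocket–ligand complexes, structure I/O and geometry.

Everything downstream (scoring, diffusion, the network) consumes the three
records defined here: :class:`ProteinPocket` (a fixed typed atom cloud),
:class:`LigandAtoms` (a mutable atom cloud with optional bonds) and their
pairing :class:`ProteinLigandComplex`.  Coordinates are Cartesian ångströms in
the frame of the source files; re-centering is always explicit and recorded.

Hydrogens are dropped on input everywhere — the model and the scoring oracle
are heavy-atom only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AtomTypeVocabulary",
    "LigandAtoms",
    "ProteinPocket",
    "ProteinLigandComplex",
    "DEFAULT_VOCAB",
    "load_complex",
    "center_complex",
    "count_protein_neighbors",
    "write_ligand_sdf",
    "read_ligand_sdf",
    "write_pocket_pdb",
]

OTHER = "X"  # designated catch-all element class


@dataclass(frozen=True)
class AtomTypeVocabulary:
    """Ordered element vocabulary defining the K-dimensional atom-type space.

    Per-element chemistry flags are element-level (not environment-aware): they
    feed the empirical scoring oracle, not a protonation model.
    """

    elements: tuple[str, ...]
    vdw_radius: dict[str, float]
    hydrophobic: frozenset[str]
    hbond_donor: frozenset[str]
    hbond_acceptor: frozenset[str]

    def __post_init__(self):
        if len(set(self.elements)) != len(self.elements):
            raise ValueError("vocabulary elements must be unique")
        for el in self.elements:
            if self.vdw_radius[el] <= 0:
                raise ValueError(f"non-positive vdW radius for {el}")

    @property
    def K(self) -> int:
        return len(self.elements)

    def index(self, element: str) -> int:
        """Map an element symbol to its class index; unknowns go to OTHER."""
        el = element.capitalize()
        if el in self.elements:
            return self.elements.index(el)
        return self.elements.index(OTHER)

    def one_hot(self, symbols) -> np.ndarray:
        z = np.zeros((len(symbols), self.K))
        for i, s in enumerate(symbols):
            z[i, self.index(s)] = 1.0
        return z

    def radii_for(self, z: np.ndarray) -> np.ndarray:
        """Per-atom vdW radii from (one-hot or argmax-able) type rows."""
        idx = np.argmax(z, axis=1)
        return np.array([self.vdw_radius[self.elements[i]] for i in idx])

    def flags_for(self, z: np.ndarray, which: str) -> np.ndarray:
        flag_set = getattr(self, which)
        idx = np.argmax(z, axis=1)
        return np.array([self.elements[i] in flag_set for i in idx])


# X-score-style radii; the "other" class gets a generic heavy-atom radius.
DEFAULT_VOCAB = AtomTypeVocabulary(
    elements=("C", "N", "O", "F", "P", "S", "Cl", OTHER),
    vdw_radius={
        "C": 1.9, "N": 1.8, "O": 1.7, "F": 1.5,
        "P": 2.1, "S": 2.0, "Cl": 1.8, OTHER: 1.9,
    },
    hydrophobic=frozenset({"C", "F", "Cl"}),
    hbond_donor=frozenset({"N", "O"}),
    hbond_acceptor=frozenset({"N", "O", "F"}),
)


@dataclass
class LigandAtoms:
    """A ligand atom cloud: coordinates `x` (N,3) Å and type rows `z` (N,K).

    `z` rows are one-hot for clean molecules; guided intermediate states carry
    arbitrary positive rows.  `bonds` is a list of (i, j, order) with i < j.
    """

    x: np.ndarray
    z: np.ndarray
    bonds: list[tuple[int, int, int]] | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.x.ndim != 2 or self.x.shape[1] != 3:
            raise ValueError("ligand coordinates must be (N, 3)")
        if len(self.x) < 1:
            raise ValueError("ligand must contain at least one atom")
        if self.z.shape[0] != self.x.shape[0]:
            raise ValueError("x and z row counts differ")
        if self.bonds is not None:
            n = len(self.x)
            for i, j, _ in self.bonds:
                if i == j:
                    raise ValueError("self-bond")
                if not (0 <= i < n and 0 <= j < n):
                    raise ValueError("bond index out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.x)

    def elements(self, vocab: AtomTypeVocabulary) -> list[str]:
        return [vocab.elements[i] for i in np.argmax(self.z, axis=1)]

    def copy(self) -> "LigandAtoms":
        return LigandAtoms(
            self.x.copy(), self.z.copy(),
            None if self.bonds is None else list(self.bonds),
        )


@dataclass
class ProteinPocket:
    """The fixed protein-side atom cloud.  No operation may mutate `x`."""

    x: np.ndarray
    z: np.ndarray
    is_backbone: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        self.x.setflags(write=False)

    @property
    def n_atoms(self) -> int:
        return len(self.x)


@dataclass
class ProteinLigandComplex:
    pocket: ProteinPocket
    ligand: LigandAtoms
    id: str = ""
    v: float | None = None  # ground-truth normalized affinity in [0, 1]

    def __post_init__(self):
        if self.v is not None and not (0.0 <= self.v <= 1.0):
            raise ValueError("normalized affinity v must lie in [0, 1]")


class StructureParseError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


def _read_protein_atoms(path: str | Path):
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # noqa: BLE001 - rewrap with the filename
        raise StructureParseError(f"cannot parse PDB file {path}: {exc}") from exc
    heavy = arr.element != "H"
    arr = arr[heavy]
    if arr.array_length() == 0:
        raise DegenerateInputError(f"no heavy atoms in {path}")
    backbone = np.isin(arr.atom_name, ["N", "CA", "C", "O"])
    return np.asarray(arr.coord, dtype=np.float64), list(arr.element), backbone


def read_ligand_sdf(path: str | Path, vocab: AtomTypeVocabulary) -> LigandAtoms:
    """Read the first molecule of an SDF/MOL file as heavy-atom LigandAtoms."""
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=False)
    mol = next((m for m in supplier if m is not None), None)
    if mol is None:
        raise StructureParseError(f"cannot parse ligand file {path}")
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() != "H"]
    if not heavy:
        raise DegenerateInputError(f"ligand in {path} has no heavy atoms")
    remap = {old: new for new, old in enumerate(heavy)}
    conf = mol.GetConformer()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in heavy])
    symbols = [mol.GetAtomWithIdx(i).GetSymbol() for i in heavy]
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in remap and j in remap:
            order = int(b.GetBondTypeAsDouble()) or 1
            i, j = sorted((remap[i], remap[j]))
            bonds.append((i, j, order))
    return LigandAtoms(coords, vocab.one_hot(symbols), bonds)


def load_complex(
    protein_path: str | Path,
    ligand_path: str | Path,
    vocab: AtomTypeVocabulary = DEFAULT_VOCAB,
    pocket_radius: float = 10.0,
) -> ProteinLigandComplex:
    """Load a protein/ligand pair and cut the pocket around the ligand.

    The pocket keeps exactly the protein heavy atoms within `pocket_radius` Å
    of any ligand heavy atom.  An empty pocket (e.g. radius 0) is a degenerate
    input and raises rather than returning a hollow complex.
    """
    coords, symbols, backbone = _read_protein_atoms(protein_path)
    ligand = read_ligand_sdf(ligand_path, vocab)
    d = cdist(coords, ligand.x)
    keep = (d.min(axis=1) <= pocket_radius)
    if not keep.any():
        raise DegenerateInputError(
            f"no protein atoms within {pocket_radius} Å of the ligand"
        )
    pocket = ProteinPocket(
        coords[keep], vocab.one_hot([symbols[i] for i in np.flatnonzero(keep)]),
        is_backbone=backbone[keep],
    )
    return ProteinLigandComplex(pocket, ligand, id=Path(protein_path).stem)


def center_complex(
    c: ProteinLigandComplex,
) -> tuple[ProteinLigandComplex, np.ndarray]:
    """Translate the complex so the pocket centroid sits at the origin.

    Returns the centered complex and the translation vector that restores the
    original frame (original = centered + translation).
    """
    if c.pocket.n_atoms == 0:
        raise DegenerateInputError("empty pocket")
    translation = c.pocket.x.mean(axis=0)
    pocket = ProteinPocket(
        c.pocket.x - translation, c.pocket.z.copy(), c.pocket.is_backbone
    )
    ligand = c.ligand.copy()
    ligand.x = ligand.x - translation
    return replace(c, pocket=pocket, ligand=ligand), translation


def count_protein_neighbors(c: ProteinLigandComplex, radius: float = 8.0) -> np.ndarray:
    """Per-ligand-atom count of pocket atoms within `radius` Å (inclusive)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    d = cdist(c.ligand.x, c.pocket.x)
    return (d <= radius).sum(axis=1).astype(int)


def write_ligand_sdf(
    ligands: LigandAtoms | list[LigandAtoms],
    path: str | Path,
    vocab: AtomTypeVocabulary = DEFAULT_VOCAB,
) -> None:
    """Write one or more ligands to an SDF (V2000) file."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    if isinstance(ligands, LigandAtoms):
        ligands = [ligands]
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for lig in ligands:
        mol = Chem.RWMol()
        for el in lig.elements(vocab):
            mol.AddAtom(Chem.Atom(el if el != OTHER else "C"))
        conf = Chem.Conformer(lig.n_atoms)
        for i, (px, py, pz) in enumerate(lig.x):
            conf.SetAtomPosition(i, Point3D(px, py, pz))
        mol.AddConformer(conf)
        for i, j, order in lig.bonds or []:
            mol.AddBond(i, j, Chem.BondType.values[order])
        m = mol.GetMol()
        writer.write(m)
    writer.close()


def write_pocket_pdb(pocket: ProteinPocket, path: str | Path,
                     vocab: AtomTypeVocabulary = DEFAULT_VOCAB) -> None:
    """Write a pocket atom cloud as a minimal PDB (HETATM records)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = pocket.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(pocket.x, dtype=np.float32)
    elements = [vocab.elements[i] for i in np.argmax(pocket.z, axis=1)]
    arr.element = np.array([e if e != OTHER else "C" for e in elements])
    arr.atom_name = np.array(
        [f"{e if e != OTHER else 'C'}{i + 1}" for i, e in enumerate(elements)]
    )
    arr.res_name = np.full(n, "PKT")
    arr.res_id = np.ones(n, dtype=int)
    arr.chain_id = np.full(n, "A")
    arr.hetero = np.ones(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
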