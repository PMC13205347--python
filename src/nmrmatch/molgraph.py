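"""Molecular graphs for molecule--spectrum matching.

Molecules are parsed with RDKit into attributed heavy-atom graphs: one node
per non-hydrogen atom (hydrogens fold into an attached-H count feature) and
a directed-symmetric edge list.  The dataset regime restricts molecules to
C/N/O heavy atoms with at most 16 of them; :func:`validate_molecule` checks
exactly that.  Structural dissimilarity, used to pick hard mismatched pairs,
is Tanimoto similarity over hashed Morgan substructure fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

MAX_HEAVY_ATOMS = 16
ALLOWED_ELEMENTS = ("C", "N", "O")

_HYBRIDIZATIONS = (Chem.HybridizationType.SP, Chem.HybridizationType.SP2,
                   Chem.HybridizationType.SP3)

_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


class FeaturizationError(ValueError):
    """Raised when a molecule falls outside the feature schema's vocabulary."""


@dataclass(frozen=True)
class AtomFeatureSchema:
    """Deterministic atom featurization; block widths sum to ``dim``.

    Blocks: element one-hot over the vocabulary, degree one-hot 0-4,
    attached-H one-hot 0-4, aromatic flag, formal charge one-hot {-1,0,+1},
    hybridization one-hot {sp, sp2, sp3, other}, and three molecule-context
    features broadcast to every atom (heavy-atom count / 16, total attached
    hydrogens / 34, aromatic-atom fraction), padded with zeros up to
    ``dim``.  The context block exists because the molecule-level readout
    pools nodes with per-dimension max and mean, both size-invariant for
    purely atomic features; broadcasting molecule totals is what lets the
    pooled embedding see overall size and composition.
    ``dim`` must be divisible by the attention head count (8 by default).
    """

    element_vocabulary: tuple[str, ...] = ALLOWED_ELEMENTS
    max_degree: int = 4
    max_hydrogens: int = 4
    dim: int = 24

    @property
    def block_widths(self) -> dict[str, int]:
        widths = {
            "element": len(self.element_vocabulary),
            "degree": self.max_degree + 1,
            "hydrogens": self.max_hydrogens + 1,
            "aromatic": 1,
            "charge": 3,
            "hybridization": 4,
            "context": 3,
        }
        used = sum(widths.values())
        if used > self.dim:
            raise ValueError(f"schema blocks need {used} dims, have {self.dim}")
        widths["padding"] = self.dim - used
        return widths

    def molecule_context(self, mol: Chem.Mol) -> np.ndarray:
        n = mol.GetNumAtoms()
        total_h = sum(a.GetTotalNumHs() for a in mol.GetAtoms())
        n_arom = sum(a.GetIsAromatic() for a in mol.GetAtoms())
        return np.array([n / 16.0, total_h / 34.0, n_arom / max(n, 1)],
                        dtype=np.float32)

    def encode_atom(self, atom: Chem.Atom) -> np.ndarray:
        sym = atom.GetSymbol()
        if sym not in self.element_vocabulary:
            raise FeaturizationError(
                f"element {sym!r} outside vocabulary {self.element_vocabulary}")
        x = np.zeros(self.dim, dtype=np.float32)
        off = 0
        x[off + self.element_vocabulary.index(sym)] = 1.0
        off += len(self.element_vocabulary)
        x[off + min(atom.GetDegree(), self.max_degree)] = 1.0
        off += self.max_degree + 1
        x[off + min(atom.GetTotalNumHs(), self.max_hydrogens)] = 1.0
        off += self.max_hydrogens + 1
        x[off] = 1.0 if atom.GetIsAromatic() else 0.0
        off += 1
        charge = int(np.clip(atom.GetFormalCharge(), -1, 1))
        x[off + charge + 1] = 1.0
        off += 3
        hyb = atom.GetHybridization()
        x[off + (_HYBRIDIZATIONS.index(hyb) if hyb in _HYBRIDIZATIONS else 3)] = 1.0
        off += 4
        x[off:off + 3] = self.molecule_context(atom.GetOwningMol())
        return x


@dataclass
class MolecularGraph:
    """Heavy-atom graph: feature matrix X, directed-symmetric edge list."""

    node_features: np.ndarray          # (|V|, d)
    edges: list[tuple[int, int]]       # both (i,j) and (j,i) stored
    atom_elements: list[str]
    smiles: str = ""
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def heavy_atom_count(self) -> int:
        return self.num_nodes

    def edge_index(self) -> np.ndarray:
        """Edges as a (2, E) array of (source, target) columns."""
        if not self.edges:
            return np.zeros((2, 0), dtype=np.int64)
        return np.asarray(self.edges, dtype=np.int64).T

    def validate_shape(self) -> None:
        n = self.num_nodes
        for i, j in self.edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) outside node range {n}")
        eset = set(self.edges)
        for i, j in self.edges:
            if (j, i) not in eset:
                raise ValueError(f"edge ({i},{j}) missing its reverse")


def smiles_to_graph(smiles: str,
                    schema: AtomFeatureSchema | None = None) -> MolecularGraph:
    """Parse a SMILES string into an attributed heavy-atom graph."""
    schema = schema or AtomFeatureSchema()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    X = np.stack([schema.encode_atom(a) for a in mol.GetAtoms()]) \
        if mol.GetNumAtoms() else np.zeros((0, schema.dim), dtype=np.float32)
    edges: list[tuple[int, int]] = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((i, j))
        edges.append((j, i))
    return MolecularGraph(
        node_features=X, edges=edges,
        atom_elements=[a.GetSymbol() for a in mol.GetAtoms()],
        smiles=smiles, mol=mol)


def validate_molecule(graph: MolecularGraph,
                      max_heavy: int = MAX_HEAVY_ATOMS,
                      allowed: tuple[str, ...] = ALLOWED_ELEMENTS
                      ) -> tuple[bool, str]:
    """Accept iff heavy atoms <= ``max_heavy`` and all elements allowed.

    Returns ``(accepted, reason)``; reason is ``"ok"``, ``"size"`` or
    ``"element"``.  Total function: never raises on a well-formed graph.
    """
    if graph.heavy_atom_count > max_heavy:
        return False, "size"
    if any(el not in allowed for el in graph.atom_elements):
        return False, "element"
    return True, "ok"


def morgan_fingerprint(graph: MolecularGraph) -> np.ndarray:
    """Hashed substructure fingerprint (radius 2, 1024 bits) as a 0/1 array."""
    mol = graph.mol if graph.mol is not None else Chem.MolFromSmiles(graph.smiles)
    if mol is None:
        raise SmilesParseError(f"graph carries no parsable SMILES: {graph.smiles!r}")
    fp = _morgan_gen.GetFingerprint(mol)
    arr = np.zeros(1024, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def structural_similarity(a: MolecularGraph, b: MolecularGraph) -> float:
    """Tanimoto similarity of Morgan fingerprints, in [0, 1]; symmetric."""
    fa, fb = morgan_fingerprint(a), morgan_fingerprint(b)
    inter = int(np.sum(fa & fb))
    union = int(np.sum(fa | fb))
    return 1.0 if union == 0 else inter / union


def canonical_smiles(graph_or_smiles) -> str:
    if isinstance(graph_or_smiles, MolecularGraph):
        mol = graph_or_smiles.mol or Chem.MolFromSmiles(graph_or_smiles.smiles)
    else:
        mol = Chem.MolFromSmiles(graph_or_smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {graph_or_smiles!r}")
    return Chem.MolToSmiles(mol)


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read molecules from a .smi (one per line) or CSV with a smiles column.

    Returns (id, smiles) pairs; ids default to zero-based line order.
    """
    import pandas as pd

    path = str(path)
    if path.endswith(".csv"):
        df = pd.read_csv(path)
        if "smiles" not in df.columns:
            raise ValueError("CSV input needs a 'smiles' column")
        ids = df["id"].astype(str) if "id" in df.columns else df.index.astype(str)
        return list(zip(ids, df["smiles"].astype(str)))
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    return [(str(i), smi) for i, smi in enumerate(lines)]


def dump_graph_tables(graph: MolecularGraph, node_path, edge_path) -> None:
    """Debug dump of node features and edges as CSV."""
    import pandas as pd

    nodes = pd.DataFrame(graph.node_features)
    nodes.insert(0, "element", graph.atom_elements)
    nodes.to_csv(node_path, index_label="atom")
    pd.DataFrame(graph.edges, columns=["src", "dst"]).to_csv(edge_path, index=False)
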