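"""SMILES-to-graph conversion with one-hot atom featurisation.

A molecule is represented as an attributed graph ``G = (X, A)``: one node per
heavy atom (hydrogens are implicit and counted as a node *feature*, not as
nodes), an unweighted symmetric binary adjacency matrix with one entry pair
per bond regardless of bond order, and a fixed-layout 0/1 node feature matrix

    [element one-hot | degree one-hot | numH one-hot | implicit-valence one-hot | aromatic]

with default block sizes 43 / 10 / 10 / 10 / 1 (total 74).  Degree is
heavy-atom degree; counts that exceed a block clip into its last slot so that
exotic molecules never crash a large pretraining run.  Elements outside the
vocabulary map to a designated "unknown" slot with a logged warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# Silence RDKit's own console chatter; parse failures are raised as errors.
RDLogger.DisableLog("rdApp.*")

UNKNOWN_ELEMENT = "*"

#: 42 elements seen in drug-like and organometallic chemistry + catch-all "*".
DEFAULT_ELEMENTS: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "P", "Cl", "Br", "I", "B",
    "Si", "Se", "H", "Li", "Na", "K", "Mg", "Ca", "Fe", "Zn",
    "Cu", "Mn", "Co", "Ni", "Mo", "Al", "As", "Sn", "Sb", "Te",
    "Hg", "Pb", "Cr", "V", "Ti", "Cd", "Ag", "Au", "Pt", "Pd",
    "Ru", "W", UNKNOWN_ELEMENT,
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class AtomFeatureConfig:
    """Layout of the one-hot atom feature vector.

    The element vocabulary is fully configurable (orderered, unique, must
    contain the unknown catch-all); the three count blocks clip at their last
    slot.
    """

    element_vocab: tuple[str, ...] = DEFAULT_ELEMENTS
    max_degree: int = 10
    max_num_h: int = 10
    max_implicit_valence: int = 10

    def __post_init__(self) -> None:
        if len(set(self.element_vocab)) != len(self.element_vocab):
            raise ValueError("element_vocab entries must be unique")
        if UNKNOWN_ELEMENT not in self.element_vocab:
            raise ValueError(
                f"element_vocab must contain the unknown symbol {UNKNOWN_ELEMENT!r}"
            )

    @property
    def feature_length(self) -> int:
        return (
            len(self.element_vocab)
            + self.max_degree
            + self.max_num_h
            + self.max_implicit_valence
            + 1
        )

    def element_index(self, symbol: str) -> int:
        try:
            return self.element_vocab.index(symbol)
        except ValueError:
            logger.warning(
                "element %r not in vocabulary; mapped to unknown slot", symbol
            )
            return self.element_vocab.index(UNKNOWN_ELEMENT)


@dataclass(frozen=True)
class AtomDescriptor:
    """The raw per-atom quantities that enter the feature vector."""

    element: str
    degree: int          # heavy-atom degree (implicit hydrogens excluded)
    num_h: int           # total attached hydrogens
    implicit_valence: int
    aromatic: bool

    def __post_init__(self) -> None:
        if min(self.degree, self.num_h, self.implicit_valence) < 0:
            raise ValueError("atom descriptor counts must be non-negative")


@dataclass
class MoleculeGraph:
    """Attributed heavy-atom graph of one molecule."""

    node_features: np.ndarray      # (N, F) 0/1
    adjacency: np.ndarray          # (N, N) symmetric 0/1, zero diagonal
    source_smiles: str
    atom_order: list[int] = field(default_factory=list)  # parser atom indices

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def featurize_atom(desc: AtomDescriptor, config: AtomFeatureConfig) -> np.ndarray:
    """One-hot encode an atom descriptor into the fixed block layout."""
    vec = np.zeros(config.feature_length)
    off = 0
    vec[config.element_index(desc.element)] = 1.0
    off += len(config.element_vocab)
    vec[off + min(desc.degree, config.max_degree - 1)] = 1.0
    off += config.max_degree
    vec[off + min(desc.num_h, config.max_num_h - 1)] = 1.0
    off += config.max_num_h
    vec[off + min(desc.implicit_valence, config.max_implicit_valence - 1)] = 1.0
    off += config.max_implicit_valence
    vec[off] = 1.0 if desc.aromatic else 0.0
    return vec


def atom_descriptor(atom: Chem.Atom) -> AtomDescriptor:
    """Extract the featurised quantities from a parsed atom."""
    return AtomDescriptor(
        element=atom.GetSymbol(),
        degree=atom.GetDegree(),
        num_h=atom.GetTotalNumHs(),
        implicit_valence=atom.GetImplicitValence(),
        aromatic=atom.GetIsAromatic(),
    )


def smiles_to_graph(
    smiles: str, config: AtomFeatureConfig | None = None
) -> MoleculeGraph:
    """Parse a SMILES string into a :class:`MoleculeGraph`.

    Raises
    ------
    SmilesParseError
        If the string does not parse or describes an empty molecule.
    """
    config = config or AtomFeatureConfig()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    if n == 0:
        raise SmilesParseError(f"SMILES describes an empty molecule: {smiles!r}")
    feats = np.zeros((n, config.feature_length))
    for i, atom in enumerate(mol.GetAtoms()):
        feats[i] = featurize_atom(atom_descriptor(atom), config)
    adj = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1.0
    return MoleculeGraph(
        node_features=feats,
        adjacency=adj,
        source_smiles=smiles,
        atom_order=list(range(n)),
    )


def permute_graph(graph: MoleculeGraph, perm: np.ndarray) -> MoleculeGraph:
    """Relabel nodes by a permutation (used to test encoder invariance)."""
    perm = np.asarray(perm)
    return MoleculeGraph(
        node_features=graph.node_features[perm],
        adjacency=graph.adjacency[np.ix_(perm, perm)],
        source_smiles=graph.source_smiles,
        atom_order=[graph.atom_order[i] for i in perm],
    )


# ---------------------------------------------------------------------------
# graph cache


def save_graph_cache(path, graphs: dict[str, MoleculeGraph]) -> None:
    """Serialise a {id: graph} cache to a compressed .npz file.

    Stores per-graph feature and adjacency arrays plus a JSON manifest of ids
    and source SMILES; round-trips exactly through :func:`load_graph_cache`.
    """
    arrays: dict[str, np.ndarray] = {}
    manifest = {}
    for key, g in graphs.items():
        arrays[f"feat_{key}"] = g.node_features
        arrays[f"adj_{key}"] = g.adjacency
        manifest[key] = {"smiles": g.source_smiles, "atom_order": g.atom_order}
    arrays["__manifest__"] = np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_graph_cache(path) -> dict[str, MoleculeGraph]:
    with np.load(path) as data:
        manifest = json.loads(bytes(data["__manifest__"]).decode())
        out = {}
        for key, meta in manifest.items():
            out[key] = MoleculeGraph(
                node_features=data[f"feat_{key}"],
                adjacency=data[f"adj_{key}"],
                source_smiles=meta["smiles"],
                atom_order=list(meta["atom_order"]),
            )
    return out
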