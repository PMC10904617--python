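"""Undirected molecular graphs with node, edge and global features."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MolecularGraph", "GraphError", "graph_from_smiles"]


class GraphError(ValueError):
    pass


@dataclass(frozen=True)
class MolecularGraph:
    """An undirected featured graph.

    ``node_features`` is (n_nodes, node_dim); ``edges`` is a sequence of
    (v, w) pairs with v != w; ``edge_features`` is (n_edges, edge_dim)
    aligned with ``edges`` and, being attached to the undirected edge, is
    symmetric in (v, w) by construction.  ``global_features`` optionally
    carries whole-molecule descriptors.
    """

    node_features: np.ndarray
    edges: tuple[tuple[int, int], ...]
    edge_features: np.ndarray | None = None
    global_features: np.ndarray | None = None

    def __post_init__(self) -> None:
        nf = np.asarray(self.node_features, dtype=float)
        if nf.ndim != 2:
            raise GraphError("node_features must be 2-D (n_nodes, node_dim)")
        object.__setattr__(self, "node_features", nf)
        edges = tuple((int(v), int(w)) for v, w in self.edges)
        n = nf.shape[0]
        for v, w in edges:
            if v == w:
                raise GraphError(f"self-loop at node {v}")
            if not (0 <= v < n and 0 <= w < n):
                raise GraphError(f"edge ({v}, {w}) out of range for {n} nodes")
        object.__setattr__(self, "edges", edges)
        if self.edge_features is not None:
            ef = np.asarray(self.edge_features, dtype=float)
            if ef.ndim != 2 or ef.shape[0] != len(edges):
                raise GraphError("edge_features must align with the edge list")
            object.__setattr__(self, "edge_features", ef)
        if self.global_features is not None:
            object.__setattr__(
                self, "global_features", np.asarray(self.global_features, dtype=float)
            )

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    def neighbours(self) -> list[list[tuple[int, int]]]:
        """Per-node list of (neighbour, edge_index) pairs."""
        adj: list[list[tuple[int, int]]] = [[] for _ in range(self.n_nodes)]
        for e, (v, w) in enumerate(self.edges):
            adj[v].append((w, e))
            adj[w].append((v, e))
        return adj

    def relabel(self, perm) -> "MolecularGraph":
        """Apply a node permutation: new index of old node i is perm[i]."""
        perm = np.asarray(perm, dtype=int)
        if sorted(perm.tolist()) != list(range(self.n_nodes)):
            raise GraphError("perm must be a permutation of node indices")
        inv = np.empty_like(perm)
        inv[perm] = np.arange(self.n_nodes)
        nf = self.node_features[inv]
        edges = tuple((int(perm[v]), int(perm[w])) for v, w in self.edges)
        return MolecularGraph(
            node_features=nf,
            edges=edges,
            edge_features=self.edge_features,
            global_features=self.global_features,
        )


# Minimal atom/bond featurisation for the optional SMILES adapter.  Tests
# use hand-built graphs; this exists so real molecules can be fed through
# the forward pass when a cheminformatics backend is installed.
_ATOM_SET = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "other")


def graph_from_smiles(smiles: str) -> MolecularGraph:
    """Build a featured graph from a SMILES string (requires rdkit)."""
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise GraphError("rdkit is required for SMILES input") from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GraphError(f"could not parse SMILES: {smiles!r}")
    nodes = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        onehot = [1.0 if sym == s else 0.0 for s in _ATOM_SET[:-1]]
        onehot.append(0.0 if sym in _ATOM_SET[:-1] else 1.0)
        nodes.append(
            onehot
            + [
                float(atom.GetDegree()),
                float(atom.GetFormalCharge()),
                float(atom.GetIsAromatic()),
                float(atom.GetTotalNumHs()),
            ]
        )
    edges = []
    efeat = []
    for bond in mol.GetBonds():
        edges.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        efeat.append([float(bond.GetBondTypeAsDouble()), float(bond.GetIsAromatic())])
    return MolecularGraph(
        node_features=np.array(nodes, dtype=float),
        edges=tuple(edges),
        edge_features=np.array(efeat, dtype=float) if efeat else np.zeros((0, 2)),
    )
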