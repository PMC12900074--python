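"""Heterogeneous protein–ligand complex graphs.

The scorer consumes a graph G = (V, E_geometric, E_structural) with three node
kinds: residue-level **protein** nodes (placed at the Cα), **ligand_atom**
nodes, and **aromatic_virtual** nodes placed at aromatic-ring centroids so that
π-system interactions are represented explicitly.  Geometric edges connect
nodes within kind-pair distance cutoffs (with binned distances as attributes,
including Cα–Cα protein adjacency edges); structural edges carry covalent bonds
and interaction-fingerprint (IFP) contacts — hydrogen bonds, π–π stacking,
cation–π and salt bridges.

Ligands enter as explicit atom/bond/aromaticity tables
(:class:`LigandTable`), so the graph core needs no chemistry toolkit; a
SMILES convenience constructor using RDKit is provided separately.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import networkx as nx

from .conformers_io import Frame

NODE_KINDS = ("protein", "ligand_atom", "aromatic_virtual")

#: element vocabulary for integer coding (index 0 = unknown/other)
ELEMENTS = ("X", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "H")

#: coarse residue classes for protein node features
RESIDUE_CLASSES = {
    "ALA": 1, "VAL": 1, "LEU": 1, "ILE": 1, "MET": 1, "PRO": 1, "GLY": 1,  # hydrophobic
    "SER": 2, "THR": 2, "CYS": 2, "ASN": 2, "GLN": 2,                      # polar
    "LYS": 3, "ARG": 3, "HIS": 3,                                          # basic
    "ASP": 4, "GLU": 4,                                                    # acidic
    "PHE": 5, "TYR": 5, "TRP": 5,                                          # aromatic
}

INTERACTION_TYPES = ("covalent", "hbond", "pi_pi", "cation_pi", "salt_bridge", "ring_member")


@dataclass(frozen=True)
class GraphNode:
    kind: str
    coord: tuple[float, float, float]
    feature: tuple[int, ...]  # (element, degree, aromatic, charge class, residue class)

    def __post_init__(self):
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")


@dataclass(frozen=True)
class GraphEdge:
    src: int
    dst: int
    channel: str              # "geometric" | "structural"
    attr: tuple[int, ...]     # geometric: (distance bin, kind-pair code); structural: (type code,)

    def __post_init__(self):
        if self.src == self.dst:
            raise ValueError("self-edges are not allowed")


@dataclass
class ComplexGraph:
    nodes: list[GraphNode]
    edges: list[GraphEdge]
    ligand_node_ids: list[int]
    pocket_node_ids: list[int]

    @property
    def coords(self) -> np.ndarray:
        return np.array([n.coord for n in self.nodes], dtype=float)

    def to_json(self, path=None) -> str:
        payload = {
            "nodes": [asdict(n) for n in self.nodes],
            "edges": [asdict(e) for e in self.edges],
            "ligand_node_ids": list(map(int, self.ligand_node_ids)),
            "pocket_node_ids": list(map(int, self.pocket_node_ids)),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "ComplexGraph":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        nodes = [GraphNode(n["kind"], tuple(n["coord"]), tuple(n["feature"]))
                 for n in payload["nodes"]]
        edges = [GraphEdge(e["src"], e["dst"], e["channel"], tuple(e["attr"]))
                 for e in payload["edges"]]
        return cls(nodes, edges, payload["ligand_node_ids"], payload["pocket_node_ids"])


@dataclass
class LigandTable:
    """Explicit ligand chemistry: elements, coordinates, bonds, flags."""

    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int]]
    aromatic: np.ndarray          # bool per atom
    formal_charge: np.ndarray     # int per atom

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.aromatic = np.asarray(self.aromatic, dtype=bool)
        self.formal_charge = np.asarray(self.formal_charge, dtype=int)
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j})")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_atoms, dtype=int)
        for i, j in self.bonds:
            deg[i] += 1
            deg[j] += 1
        return deg


def ligand_from_smiles(smiles: str, seed: int = 0) -> LigandTable:
    """Perceive a ligand table from SMILES with 3-D coordinates (requires RDKit)."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    AllChem.EmbedMolecule(mol, params)
    conf = mol.GetConformer()
    return LigandTable(
        elements=[a.GetSymbol() for a in mol.GetAtoms()],
        coords=np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]),
        bonds=[(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()],
        aromatic=np.array([a.GetIsAromatic() for a in mol.GetAtoms()]),
        formal_charge=np.array([a.GetFormalCharge() for a in mol.GetAtoms()]),
    )


# ---------------------------------------------------------------------------
# pocket & rings
# ---------------------------------------------------------------------------

def extract_pocket(frame: Frame, ligand_coords: np.ndarray, radius: float = 8.0
                   ) -> list[tuple[str, int]]:
    """Residues with any heavy atom within `radius` Å of any ligand atom.

    The interval is closed: a residue at exactly `radius` is included.
    Returned in (chain, residue_seq) order.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    ligand_coords = np.atleast_2d(np.asarray(ligand_coords, dtype=float))
    heavy = frame.is_heavy
    d = np.linalg.norm(frame.coords[:, None, :] - ligand_coords[None, :, :], axis=-1)
    near_atom = heavy & (d.min(axis=1) <= radius)
    residues = sorted({(str(frame.chain[i]), int(frame.residue_seq[i]))
                       for i in np.flatnonzero(near_atom)})
    if not residues:
        raise ValueError(f"no pocket residues within {radius} Å; increase the radius")
    return residues


def detect_aromatic_rings(ligand: LigandTable) -> list[tuple[list[int], np.ndarray]]:
    """Aromatic rings (smallest-set-of-smallest-rings) and their centroids.

    A ring qualifies when every member atom carries the aromatic flag; the
    centroid is the unweighted mean of member coordinates.  Returns a list of
    (sorted member indices, centroid) ordered by member tuple.
    """
    g = nx.Graph()
    g.add_nodes_from(range(ligand.n_atoms))
    g.add_edges_from(ligand.bonds)
    rings = []
    for cycle in nx.minimum_cycle_basis(g):
        if all(ligand.aromatic[i] for i in cycle):
            members = sorted(int(i) for i in cycle)
            rings.append((members, ligand.coords[members].mean(axis=0)))
    rings.sort(key=lambda r: tuple(r[0]))
    return rings


# ---------------------------------------------------------------------------
# edges
# ---------------------------------------------------------------------------

#: default geometric cutoffs (Å) per unordered node-kind pair
DEFAULT_CUTOFFS = {
    frozenset(("ligand_atom", "ligand_atom")): 4.5,
    frozenset(("ligand_atom", "protein")): 4.5,
    frozenset(("ligand_atom", "aromatic_virtual")): 4.5,
    frozenset(("aromatic_virtual", "protein")): 4.5,
    frozenset(("aromatic_virtual", "aromatic_virtual")): 4.5,
    frozenset(("protein", "protein")): 8.0,  # Cα–Cα intraprotein adjacency
}

DISTANCE_BIN_WIDTH = 0.5  # Å

_KIND_PAIR_CODES = {
    frozenset(("protein", "protein")): 0,
    frozenset(("ligand_atom", "protein")): 1,
    frozenset(("ligand_atom", "ligand_atom")): 2,
    frozenset(("ligand_atom", "aromatic_virtual")): 3,
    frozenset(("aromatic_virtual", "protein")): 4,
    frozenset(("aromatic_virtual", "aromatic_virtual")): 5,
}


def distance_bin(d: float, cutoff: float, width: float = DISTANCE_BIN_WIDTH) -> int:
    """Index of `d` on the fixed grid [0, width, 2·width, …, cutoff]."""
    n_bins = int(np.ceil(cutoff / width))
    return min(int(d / width), n_bins - 1)


def build_geometric_edges(nodes: list[GraphNode],
                          cutoffs: dict | None = None) -> list[GraphEdge]:
    """Distance-cutoff edges (both directions) with binned-distance attributes.

    Distances are measured between node coordinates (protein nodes sit at the
    Cα, so protein–protein edges are the Cα-adjacency channel).
    """
    cutoffs = DEFAULT_CUTOFFS if cutoffs is None else cutoffs
    coords = np.array([n.coord for n in nodes], dtype=float)
    edges: list[GraphEdge] = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            pair = frozenset((nodes[i].kind, nodes[j].kind))
            cutoff = cutoffs.get(pair)
            if cutoff is None or cutoff <= 0:
                raise ValueError(f"no positive cutoff for kind pair {set(pair)}")
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d <= cutoff:
                attr = (distance_bin(d, cutoff), _KIND_PAIR_CODES[pair])
                edges.append(GraphEdge(i, j, "geometric", attr))
                edges.append(GraphEdge(j, i, "geometric", attr))
    return edges


@dataclass(frozen=True)
class IFPThresholds:
    """Minimal interaction-fingerprint cutoffs (Å / degrees)."""

    hbond_dist: float = 3.5
    hbond_angle: float = 120.0
    pi_pi_dist: float = 5.5
    cation_pi_dist: float = 6.0
    salt_bridge_dist: float = 4.0


def detect_interactions(donors: list[tuple[int, np.ndarray | None]],
                        acceptors: list[int],
                        cations: list[int],
                        anions: list[int],
                        ring_nodes: list[int],
                        coords: np.ndarray,
                        thresholds: IFPThresholds = IFPThresholds()) -> list[tuple[str, int, int]]:
    """Built-in minimal IFP detector over annotated node roles.

    Donors are (node id, optional hydrogen coordinate); when the hydrogen is
    supplied the D–H···A angle must exceed the threshold, otherwise the
    distance criterion alone applies.  Returns (type, i, j) tuples.
    """
    out: list[tuple[str, int, int]] = []
    for d_idx, h_coord in donors:
        for a_idx in acceptors:
            if a_idx == d_idx:
                continue
            dist = np.linalg.norm(coords[d_idx] - coords[a_idx])
            if dist > thresholds.hbond_dist:
                continue
            if h_coord is not None:
                v1 = np.asarray(h_coord) - coords[d_idx]
                v2 = np.asarray(h_coord) - coords[a_idx]
                cosang = -np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
                # angle at H between D and A
                ang = np.degrees(np.arccos(np.clip(-cosang, -1, 1)))
                if ang < thresholds.hbond_angle:
                    continue
            out.append(("hbond", d_idx, a_idx))
    for k, r1 in enumerate(ring_nodes):
        for r2 in ring_nodes[k + 1:]:
            if np.linalg.norm(coords[r1] - coords[r2]) <= thresholds.pi_pi_dist:
                out.append(("pi_pi", r1, r2))
    for c in cations:
        for r in ring_nodes:
            if np.linalg.norm(coords[c] - coords[r]) <= thresholds.cation_pi_dist:
                out.append(("cation_pi", c, r))
    for c in cations:
        for a in anions:
            if np.linalg.norm(coords[c] - coords[a]) <= thresholds.salt_bridge_dist:
                out.append(("salt_bridge", c, a))
    return out


def build_structural_edges(n_nodes: int,
                           covalent_bonds: list[tuple[int, int]],
                           interactions: list[tuple[str, int, int]] = ()) -> list[GraphEdge]:
    """Covalent-bond edges plus typed interaction edges (both directions)."""
    edges: list[GraphEdge] = []

    def _add(i: int, j: int, kind: str):
        if not (0 <= i < n_nodes and 0 <= j < n_nodes):
            raise ValueError(f"edge ({i}, {j}) references a missing node")
        code = (INTERACTION_TYPES.index(kind),)
        edges.append(GraphEdge(i, j, "structural", code))
        edges.append(GraphEdge(j, i, "structural", code))

    for i, j in covalent_bonds:
        _add(i, j, "covalent")
    for kind, i, j in interactions:
        if kind not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {kind!r}")
        _add(i, j, kind)
    return edges


# ---------------------------------------------------------------------------
# full assembly
# ---------------------------------------------------------------------------

def _element_code(symbol: str) -> int:
    symbol = symbol.capitalize()
    return ELEMENTS.index(symbol) if symbol in ELEMENTS else 0


def build_complex_graph(frame: Frame,
                        ligand: LigandTable,
                        pocket_radius: float = 8.0,
                        cutoffs: dict | None = None,
                        interactions: list[tuple[str, int, int]] | None = None,
                        auto_ifp: bool = True) -> ComplexGraph:
    """Assemble the full heterogeneous graph for one receptor frame + ligand.

    Node order is canonical: pocket residues by (chain, residue_seq), then
    ligand atoms in table order, then ring-centroid virtual nodes by member
    tuple — so graph construction is invariant to the order pocket atoms appear
    in the input.  Every virtual node is tied to its ring atoms by structural
    ``ring_member`` edges.  Interaction edges come from `interactions` when
    supplied, otherwise from the built-in minimal detector (charged ligand
    atoms / acidic–basic residues / ring centroids).
    """
    residues = extract_pocket(frame, ligand.coords, radius=pocket_radius)
    nodes: list[GraphNode] = []
    res_class = []
    for chain, seq in residues:
        mask = (frame.chain == chain) & (frame.residue_seq == seq) & (frame.atom_name == "CA")
        hit = np.flatnonzero(mask)
        if hit.size != 1:
            raise ValueError(f"pocket residue {chain}:{seq} lacks a unique CA")
        rname = str(frame.res_name[hit[0]])
        cls = RESIDUE_CLASSES.get(rname, 0)
        res_class.append(cls)
        nodes.append(GraphNode("protein", tuple(frame.coords[hit[0]]),
                               (0, 0, 0, 1, cls)))
    n_prot = len(nodes)

    deg = ligand.degree()
    for i in range(ligand.n_atoms):
        charge_class = int(np.sign(ligand.formal_charge[i])) + 1
        nodes.append(GraphNode("ligand_atom", tuple(ligand.coords[i]),
                               (_element_code(ligand.elements[i]), int(deg[i]),
                                int(ligand.aromatic[i]), charge_class, 0)))

    rings = detect_aromatic_rings(ligand)
    ring_node_ids = []
    for members, centroid in rings:
        ring_node_ids.append(len(nodes))
        nodes.append(GraphNode("aromatic_virtual", tuple(centroid),
                               (0, len(members), 1, 1, 0)))

    geometric = build_geometric_edges(nodes, cutoffs=cutoffs)

    covalent = [(n_prot + i, n_prot + j) for i, j in ligand.bonds]
    if interactions is None and auto_ifp:
        coords = np.array([n.coord for n in nodes])
        donors = [(n_prot + i, None) for i in range(ligand.n_atoms)
                  if ligand.elements[i].capitalize() in ("N", "O")]
        acceptors = [p for p, cls in enumerate(res_class) if cls in (2, 4)]
        cations = [n_prot + i for i in range(ligand.n_atoms) if ligand.formal_charge[i] > 0]
        anions = [p for p, cls in enumerate(res_class) if cls == 4]
        interactions = detect_interactions(donors, acceptors, cations, anions,
                                           ring_node_ids, coords)
    structural = build_structural_edges(len(nodes), covalent, interactions or [])
    for rid, (members, _) in zip(ring_node_ids, rings):
        for m in members:
            code = (INTERACTION_TYPES.index("ring_member"),)
            structural.append(GraphEdge(rid, n_prot + m, "structural", code))
            structural.append(GraphEdge(n_prot + m, rid, "structural", code))

    ligand_ids = list(range(n_prot, n_prot + ligand.n_atoms)) + ring_node_ids
    return ComplexGraph(nodes=nodes, edges=geometric + structural,
                        ligand_node_ids=ligand_ids,
                        pocket_node_ids=list(range(n_prot)))
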