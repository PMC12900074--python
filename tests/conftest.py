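import numpy as np
import pytest

from dynaglep import synthdata
from dynaglep.complex_graph import ComplexGraph, GraphEdge, GraphNode, LigandTable


def pdb_atom_line(serial, name, res_name, chain, res_seq, x, y, z, element):
    return (f"ATOM  {serial:>5} {name:<4} {res_name:>3} {chain}{res_seq:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}")


def make_multimodel_pdb(coords_per_model, atoms):
    """coords_per_model: list of (n_atoms, 3); atoms: list of (name, res_name, chain, res_seq, element)."""
    lines = []
    for m, coords in enumerate(coords_per_model, start=1):
        lines.append(f"MODEL     {m:>4}")
        for i, ((name, rn, ch, rs, el), xyz) in enumerate(zip(atoms, coords), start=1):
            lines.append(pdb_atom_line(i, name, rn, ch, rs, *xyz, el))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


TOY_ATOMS = [
    ("CA", "ALA", "A", 1, "C"),
    ("CB", "ALA", "A", 1, "C"),
    ("CA", "GLY", "A", 2, "C"),
    ("CA", "SER", "A", 3, "C"),
    ("OG", "SER", "A", 3, "O"),
]


@pytest.fixture
def toy_pdb(tmp_path):
    rng = np.random.default_rng(0)
    base = rng.normal(0, 5, (len(TOY_ATOMS), 3))
    models = [base + np.array([m, 0.0, 0.0]) for m in range(3)]
    path = tmp_path / "toy.pdb"
    path.write_text(make_multimodel_pdb(models, TOY_ATOMS))
    return path, models


@pytest.fixture(scope="session")
def small_two_state():
    return synthdata.gen_two_state_ensemble(
        synthdata.TwoStateEnsembleSpec(n_frames=20, noise_sd=0.1, seed=7))


@pytest.fixture(scope="session")
def toy_ligand():
    # ethylamine-like fragment with an extra carboxylate oxygen
    return LigandTable(
        elements=["C", "C", "N", "O", "C", "C"],
        coords=np.array([[200.0, 0.0, 1.0], [201.3, 0.0, 1.0], [202.0, 1.0, 1.5],
                         [199.0, 1.0, 1.2], [200.5, -1.0, 2.0], [201.0, 0.5, 3.0]]),
        bonds=[(0, 1), (1, 2), (0, 3), (0, 4), (4, 5)],
        aromatic=np.zeros(6, dtype=bool),
        formal_charge=np.zeros(6, dtype=int),
    )


@pytest.fixture(scope="session")
def toy_complex_graph(small_two_state, toy_ligand):
    from dynaglep.complex_graph import build_complex_graph

    return build_complex_graph(small_two_state.active.frames[0], toy_ligand,
                               pocket_radius=8.0)


def fully_connected_graph(n_nodes, element, rng, kind="ligand_atom"):
    coords = rng.normal(0, 2, (n_nodes, 3))
    nodes = [GraphNode(kind, tuple(coords[i]), (element, 1, 0, 1, 0))
             for i in range(n_nodes)]
    edges = [GraphEdge(i, j, "structural", (0,))
             for i in range(n_nodes) for j in range(n_nodes) if i != j]
    return ComplexGraph(nodes, edges, list(range(n_nodes)), [])
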