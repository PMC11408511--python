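import numpy as np
import pytest

from tauramd.trajectory_io import Topology, Trajectory


def make_topology(atoms, partner_a=("A",), partner_b=("B",)):
    """Build a Topology from rows (name, element, resname, resnum, chain)."""
    names, elements, resnames, resnums, chains = zip(*atoms)
    waters = np.asarray([r in ("HOH", "WAT") for r in resnames])
    table = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
    return Topology(
        atom_names=np.asarray(names),
        elements=np.asarray(elements),
        residue_names=np.asarray(resnames),
        residue_numbers=np.asarray(resnums, dtype=int),
        chain_ids=np.asarray(chains),
        masses=np.asarray([table.get(e, 12.0) for e in elements]),
        is_water=waters,
        partner_a_chains=frozenset(partner_a),
        partner_b_chains=frozenset(partner_b),
    )


# a small two-chain interface with real residue chemistry:
# chain A: LYS1 (cation/donor), ASP2 (anion), GLY3 (backbone-only sidechain)
# chain B: TYR1 (aromatic), SER2 (donor/acceptor), ALA3 (hydrophobic)
_PROTEIN_ATOMS = [
    # LYS A1
    ("N", "N", "LYS", 1, "A"), ("CA", "C", "LYS", 1, "A"),
    ("C", "C", "LYS", 1, "A"), ("O", "O", "LYS", 1, "A"),
    ("CB", "C", "LYS", 1, "A"), ("CG", "C", "LYS", 1, "A"),
    ("CD", "C", "LYS", 1, "A"), ("CE", "C", "LYS", 1, "A"),
    ("NZ", "N", "LYS", 1, "A"),
    # ASP A2
    ("N", "N", "ASP", 2, "A"), ("CA", "C", "ASP", 2, "A"),
    ("C", "C", "ASP", 2, "A"), ("O", "O", "ASP", 2, "A"),
    ("CB", "C", "ASP", 2, "A"), ("CG", "C", "ASP", 2, "A"),
    ("OD1", "O", "ASP", 2, "A"), ("OD2", "O", "ASP", 2, "A"),
    # GLY A3
    ("N", "N", "GLY", 3, "A"), ("CA", "C", "GLY", 3, "A"),
    ("C", "C", "GLY", 3, "A"), ("O", "O", "GLY", 3, "A"),
    # TYR B1
    ("N", "N", "TYR", 1, "B"), ("CA", "C", "TYR", 1, "B"),
    ("C", "C", "TYR", 1, "B"), ("O", "O", "TYR", 1, "B"),
    ("CB", "C", "TYR", 1, "B"), ("CG", "C", "TYR", 1, "B"),
    ("CD1", "C", "TYR", 1, "B"), ("CD2", "C", "TYR", 1, "B"),
    ("CE1", "C", "TYR", 1, "B"), ("CE2", "C", "TYR", 1, "B"),
    ("CZ", "C", "TYR", 1, "B"), ("OH", "O", "TYR", 1, "B"),
    # SER B2
    ("N", "N", "SER", 2, "B"), ("CA", "C", "SER", 2, "B"),
    ("C", "C", "SER", 2, "B"), ("O", "O", "SER", 2, "B"),
    ("CB", "C", "SER", 2, "B"), ("OG", "O", "SER", 2, "B"),
    # ALA B3
    ("N", "N", "ALA", 3, "B"), ("CA", "C", "ALA", 3, "B"),
    ("C", "C", "ALA", 3, "B"), ("O", "O", "ALA", 3, "B"),
    ("CB", "C", "ALA", 3, "B"),
]


@pytest.fixture(scope="session")
def protein_topology():
    return make_topology(_PROTEIN_ATOMS)


@pytest.fixture(scope="session")
def protein_trajectory(protein_topology):
    """Two frames of hand-scattered but interface-forming coordinates."""
    rng = np.random.default_rng(42)
    n = protein_topology.n_atoms
    chain_b = protein_topology.chain_ids == "B"
    frames = []
    base = rng.uniform(-3.0, 3.0, size=(n, 3))
    base[chain_b] += np.array([7.0, 0.0, 0.0])  # partners ~7 A apart
    frames.append(base)
    second = base.copy()
    second[chain_b] += np.array([1.5, 0.5, 0.0])  # ligand partner shifts
    frames.append(second)
    return Trajectory(np.stack(frames), snapshot_interval=10.0,
                      kind="equilibration")


TOY_PDB = """\
CRYST1  50.000  50.000  50.000  90.00  90.00  90.00 P 1
MODEL        1
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  N   ALA B   1       6.000   0.000   0.000  1.00  0.00           N
ATOM      6  CA  ALA B   1       7.450   0.000   0.000  1.00  0.00           C
ATOM      7  C   ALA B   1       8.000   1.400   0.000  1.00  0.00           C
ATOM      8  O   ALA B   1       7.300   2.400   0.000  1.00  0.00           O
ATOM      9  CB  ALA B   1       8.000  -1.000   1.000  1.00  0.00           C
HETATM   10  O   HOH W 101       3.500   0.500   0.000  1.00  0.00           O
HETATM   11  O   HOH W 102       4.000   1.500   0.000  1.00  0.00           O
ENDMDL
END
"""


@pytest.fixture()
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


def multimodel_pdb_text(coord_sets):
    """A minimal 2-atom multi-model PDB with the given coordinates."""
    lines = []
    for m, coords in enumerate(coord_sets, start=1):
        lines.append(f"MODEL     {m:4d}")
        for i, (name, chain, xyz) in enumerate(coords, start=1):
            lines.append(
                f"ATOM  {i:5d}  {name:<3s} GLY {chain}   1    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"           {name[0]}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
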