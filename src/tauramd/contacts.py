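"""Residue-pair contact analysis (PP-REs and BS-REs).

A protein-protein residue pair (PP-RE) is a cross-partner residue pair
within ``ppre_cutoff`` (15 A) in the first frame. Its per-frame
*representative distance* is the minimum over centre-of-mass distances
between chemically compatible interaction groups of the two residues
(donor-acceptor, cation-anion, aromatic-aromatic, aromatic-cation,
hydrophobic-hydrophobic) plus the sidechain-carbon COM pair (backbone
atoms for Gly). Binding-site contacts (BS-REs) are the PP-REs whose
representative distance stays below ``d_rr`` (5.5 A) for strictly more
than half of the pooled equilibration frames.

The per-frame matrix additionally stores the ligand-partner COM
displacement from the first frame (dCOM), the inter-partner COM-COM
distance, and the Calpha RMSD after superposing the receptor Calpha atoms
onto the first frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import (
    ConfigurationError,
    EmptyInterfaceError,
    InconsistentInputError,
    UnassignedResidueError,
)
from .trajectory_io import ResidueKey, Topology, Trajectory


@dataclass
class ContactParams:
    ppre_cutoff: float = 15.0  # A: PP-RE inclusion cutoff (first frame)
    d_rr: float = 5.5  # A: residue-residue contact threshold
    bs_occupancy_fraction: float = 0.5  # strict > over pooled equil frames
    all_group_pairs: bool = False  # use every cross-group pair, not only
    # chemically compatible ones
    ligand_partner: str = "B"

    def __post_init__(self):
        if not (0 < self.d_rr < self.ppre_cutoff):
            raise ConfigurationError("require 0 < d_rr < ppre_cutoff")
        if not (0 <= self.bs_occupancy_fraction < 1):
            raise ConfigurationError("bs_occupancy_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# interaction-group tables (heavy atoms, standard PDB nomenclature)
# ---------------------------------------------------------------------------

_AROMATIC = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
    "HID": ["CG", "ND1", "CD2", "CE1", "NE2"],
    "HIE": ["CG", "ND1", "CD2", "CE1", "NE2"],
    "HIP": ["CG", "ND1", "CD2", "CE1", "NE2"],
}
_CATION = {
    "LYS": ["NZ"],
    "ARG": ["NE", "CZ", "NH1", "NH2"],
    "HIP": ["ND1", "NE2"],  # doubly protonated His
}
_ANION = {
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
}
_SIDECHAIN_DONOR = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "CYS": ["SG"],
    "ASN": ["ND2"], "GLN": ["NE2"], "LYS": ["NZ"], "TRP": ["NE1"],
    "ARG": ["NE", "NH1", "NH2"], "HIS": ["ND1", "NE2"],
    "HID": ["ND1"], "HIE": ["NE2"], "HIP": ["ND1", "NE2"],
}
_SIDECHAIN_ACCEPTOR = {
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "ASN": ["OD1"],
    "GLN": ["OE1"], "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "MET": ["SD"], "HIS": ["ND1", "NE2"], "HID": ["NE2"], "HIE": ["ND1"],
}
_HYDROPHOBIC = {
    "ALA": ["CB"], "VAL": ["CB", "CG1", "CG2"],
    "LEU": ["CB", "CG", "CD1", "CD2"], "ILE": ["CB", "CG1", "CG2", "CD1"],
    "MET": ["CB", "CG", "CE"], "PRO": ["CB", "CG", "CD"],
    "LYS": ["CB", "CG", "CD", "CE"], "ARG": ["CB", "CG", "CD"],
    "THR": ["CG2"], "GLN": ["CB", "CG"], "GLU": ["CB", "CG"],
    "ASP": ["CB"], "ASN": ["CB"], "CYS": ["CB"], "SER": ["CB"],
    "PHE": ["CB"], "TYR": ["CB"], "TRP": ["CB"],
    "HIS": ["CB"], "HID": ["CB"], "HIE": ["CB"], "HIP": ["CB"],
}

STANDARD_RESIDUES = frozenset(
    ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HID",
     "HIE", "HIP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
     "TRP", "TYR", "VAL"]
)

GROUP_NAMES = ("aromatic", "hydrophobic", "hbond_donor", "hbond_acceptor",
               "cation", "anion")

#: chemically compatible cross-partner group pairs (unordered)
COMPATIBLE_PAIRS = frozenset({
    frozenset({"hbond_donor", "hbond_acceptor"}),
    frozenset({"cation", "anion"}),
    frozenset({"aromatic"}),
    frozenset({"aromatic", "cation"}),
    frozenset({"hydrophobic"}),
})


def _builtin_groups(resname: str) -> dict:
    """Group name -> atom-name list for one standard residue type."""
    g = {}
    if resname in _AROMATIC:
        g["aromatic"] = _AROMATIC[resname]
    hydro = _HYDROPHOBIC.get(resname, [])
    if hydro:
        g["hydrophobic"] = hydro
    donors = ["N"] if resname != "PRO" else []
    donors += _SIDECHAIN_DONOR.get(resname, [])
    if donors:
        g["hbond_donor"] = donors
    g["hbond_acceptor"] = ["O", "OXT"] + _SIDECHAIN_ACCEPTOR.get(resname, [])
    if resname in _CATION:
        g["cation"] = _CATION[resname]
    if resname in _ANION:
        g["anion"] = _ANION[resname]
    return g


@dataclass
class GroupAssignment:
    """Per-residue interaction groups as heavy-atom index sets.

    ``groups[residue][group_name]`` is an integer atom-index array; the
    ``sidechain`` entry holds the sidechain carbons (backbone heavy atoms
    for Gly), always present.
    """

    groups: dict  # ResidueKey -> {group_name: np.ndarray of atom indices}

    def residue_groups(self, key: ResidueKey) -> dict:
        return self.groups[key]


def assign_interaction_groups(topology: Topology,
                              overrides: dict = None) -> GroupAssignment:
    """Assign interaction groups from built-in per-residue-type tables.

    ``overrides`` maps residue names to ``{group_name: [atom names]}``
    dicts and takes precedence over the built-in tables; it is also the
    only way to cover nonstandard residues.
    """
    overrides = overrides or {}
    res_atoms = topology.residue_atom_indices()
    unassigned = []
    assignment: dict = {}
    for key, idx in res_atoms.items():
        resname = key.residue_name
        if resname in overrides:
            table = dict(overrides[resname])
        elif resname in STANDARD_RESIDUES:
            table = _builtin_groups(resname)
            table["sidechain"] = None  # resolved below by flags
        else:
            unassigned.append(resname)
            continue
        names = topology.atom_names[idx]
        heavy = topology.is_heavy[idx]
        by_name: dict = {}
        for local, nm in enumerate(names):
            by_name.setdefault(nm, local)
        resolved: dict = {}
        for gname, atom_names in table.items():
            if atom_names is None:  # built-in sidechain group
                if resname == "GLY":
                    local_sel = np.flatnonzero(
                        heavy & topology.is_backbone[idx])
                else:
                    local_sel = np.flatnonzero(
                        heavy & topology.is_sidechain[idx]
                        & (topology.elements[idx] == "C"))
            else:
                local_sel = np.asarray(
                    [by_name[nm] for nm in atom_names if nm in by_name],
                    dtype=int,
                )
            if local_sel.size:
                resolved[gname] = idx[local_sel]
        if "sidechain" not in resolved:
            # fall back to all heavy atoms so every residue carries the
            # mandatory sidechain-carbon group
            resolved["sidechain"] = idx[np.flatnonzero(heavy)]
        assignment[key] = resolved
    if unassigned:
        raise UnassignedResidueError(unassigned)
    return GroupAssignment(assignment)


@dataclass
class PairDistanceMatrix:
    """Per-frame representative distances for the PP-REs of one trajectory."""

    pairs: list  # [(ResidueKey A, ResidueKey B)]
    distances: np.ndarray  # (F, P), A
    times: np.ndarray  # (F,), ps
    delta_com: np.ndarray  # (F,): ligand COM displacement from frame 0, A
    com_com: np.ndarray  # (F,): inter-partner COM distance, A
    rmsd: np.ndarray  # (F,): Calpha RMSD from frame 0, A

    @property
    def n_frames(self) -> int:
        return self.distances.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{a.chain_id}{a.residue_number}{a.residue_name}"
                f"-{b.chain_id}{b.residue_number}{b.residue_name}"
                for a, b in self.pairs]
        df = pd.DataFrame(self.distances, columns=cols)
        df.insert(0, "time_ps", self.times)
        df["delta_com"] = self.delta_com
        df["com_com"] = self.com_com
        df["rmsd"] = self.rmsd
        return df


@dataclass
class BindingSiteContacts:
    """BS-REs: PP-REs in contact for over half of the equilibration."""

    pairs: list  # subset of the PP-RE pair list
    pair_indices: np.ndarray  # columns into the PP-RE matrix
    occupancies: np.ndarray  # fraction of pooled frames with d < d_rr


def _group_com(coords: np.ndarray, idx: np.ndarray, masses: np.ndarray):
    m = masses[idx]
    return (coords[idx] * m[:, None]).sum(axis=0) / m.sum()


def _kabsch_rmsd(ref_all, mov_all, ref_fit, mov_fit):
    """Superpose ``mov`` onto ``ref`` using the fit atoms; RMSD over all."""
    rc = ref_fit.mean(axis=0)
    mc = mov_fit.mean(axis=0)
    if len(ref_fit) < 3:  # too few fit atoms for a rotation: translate only
        moved = mov_all - mc + rc
    else:
        rot, _ = Rotation.align_vectors(ref_fit - rc, mov_fit - mc)
        moved = rot.apply(mov_all - mc) + rc
    return float(np.sqrt(((moved - ref_all) ** 2).sum(axis=1).mean()))


def compute_ppre_series(trajectory: Trajectory, topology: Topology,
                        groups: GroupAssignment,
                        params: ContactParams = None) -> PairDistanceMatrix:
    """Representative distances of all PP-REs over a trajectory.

    PP-RE membership is fixed on the first frame: all cross-partner residue
    pairs with representative distance <= ``ppre_cutoff`` there.
    """
    params = params or ContactParams()
    res_a = [k for k in topology.residues()
             if topology.partner_of_residue(k) == "A"]
    res_b = [k for k in topology.residues()
             if topology.partner_of_residue(k) == "B"]
    if not res_a or not res_b:
        raise EmptyInterfaceError("a partner has no residues")
    masses = topology.masses

    # flatten all (residue, group) COM requests
    com_index: dict = {}  # (key, gname) -> row in the COM table
    com_atoms: list = []
    for key in res_a + res_b:
        for gname, idx in groups.residue_groups(key).items():
            com_index[(key, gname)] = len(com_atoms)
            com_atoms.append(np.asarray(idx))

    # candidate group pairs per residue pair
    pair_list = [(a, b) for a in res_a for b in res_b]
    combo_a, combo_b, combo_pair = [], [], []
    for p, (a, b) in enumerate(pair_list):
        ga = groups.residue_groups(a)
        gb = groups.residue_groups(b)
        for na, ia in ga.items():
            for nb, ib in gb.items():
                if na == "sidechain" or nb == "sidechain":
                    ok = na == nb  # sidechain pairs only with each other
                elif params.all_group_pairs:
                    ok = True
                else:
                    ok = frozenset({na, nb}) in COMPATIBLE_PAIRS
                if ok:
                    combo_a.append(com_index[(a, na)])
                    combo_b.append(com_index[(b, nb)])
                    combo_pair.append(p)
    combo_a = np.asarray(combo_a)
    combo_b = np.asarray(combo_b)
    combo_pair = np.asarray(combo_pair)

    lig_idx = topology.partner_atom_indices(params.ligand_partner)
    rec_partner = "A" if params.ligand_partner.upper() == "B" else "B"
    rec_idx = topology.partner_atom_indices(rec_partner)
    ca_mask = (topology.atom_names == "CA") & ~topology.is_water
    rec_ca = rec_idx[ca_mask[rec_idx]]
    all_ca = np.flatnonzero(ca_mask)
    if rec_ca.size == 0:  # no Calpha atoms: fit on all receptor heavies
        rec_ca = rec_idx[topology.is_heavy[rec_idx]]
        all_ca = np.concatenate([rec_idx, lig_idx])

    n_frames = trajectory.n_frames
    n_pairs = len(pair_list)
    rep = np.empty((n_frames, n_pairs))
    delta_com = np.empty(n_frames)
    com_com = np.empty(n_frames)
    rmsd = np.empty(n_frames)

    coords0 = trajectory.coords[0]
    lig_com0 = _group_com(coords0, lig_idx, masses)
    ref_all_ca = coords0[all_ca]
    ref_fit = coords0[rec_ca]

    for f in range(n_frames):
        coords = trajectory.coords[f]
        coms = np.empty((len(com_atoms), 3))
        for r, idx in enumerate(com_atoms):
            coms[r] = _group_com(coords, idx, masses)
        d = np.linalg.norm(coms[combo_a] - coms[combo_b], axis=1)
        frame_rep = np.full(n_pairs, np.inf)
        np.minimum.at(frame_rep, combo_pair, d)
        rep[f] = frame_rep
        lig_com = _group_com(coords, lig_idx, masses)
        rec_com = _group_com(coords, rec_idx, masses)
        delta_com[f] = np.linalg.norm(lig_com - lig_com0)
        com_com[f] = np.linalg.norm(lig_com - rec_com)
        rmsd[f] = _kabsch_rmsd(ref_all_ca, coords[all_ca],
                               ref_fit, coords[rec_ca])

    keep = np.flatnonzero(rep[0] <= params.ppre_cutoff)
    if keep.size == 0:
        raise EmptyInterfaceError(
            f"no residue pair within {params.ppre_cutoff} A in the first frame"
        )
    return PairDistanceMatrix(
        pairs=[pair_list[i] for i in keep],
        distances=rep[:, keep],
        times=trajectory.times.astype(float),
        delta_com=delta_com,
        com_com=com_com,
        rmsd=rmsd,
    )


def extract_bsres(equil_matrices, params: ContactParams = None
                  ) -> BindingSiteContacts:
    """BS-REs from one or more equilibration PP-RE matrices.

    Occupancy is the fraction of all pooled frames with representative
    distance below ``d_rr``; a pair is kept iff occupancy is strictly
    greater than ``bs_occupancy_fraction``.
    """
    params = params or ContactParams()
    mats = list(equil_matrices)
    if not mats:
        raise InconsistentInputError("no equilibration matrices given")
    pairs = mats[0].pairs
    for m in mats[1:]:
        if m.pairs != pairs:
            raise InconsistentInputError(
                "equilibration replicas have different PP-RE pair lists"
            )
    pooled = np.vstack([m.distances for m in mats])
    occ = (pooled < params.d_rr).mean(axis=0)
    keep = np.flatnonzero(occ > params.bs_occupancy_fraction)
    return BindingSiteContacts(
        pairs=[pairs[i] for i in keep],
        pair_indices=keep,
        occupancies=occ[keep],
    )
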