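"""Interfacial and buried water counting.

A water is *interfacial* when its oxygen lies within ``interface_cutoff``
(3.5 A) of at least one heavy atom of partner A *and* one of partner B —
the bridging reading of "within 3.5 A of both proteins". A disjunctive
``either`` mode (close to at least one partner) is available for
comparison. Buried waters are defined against a user-supplied anchor-atom
selection; the barnase-barstar anchor list from the crystal structure
ships as the ``bnbs`` preset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, SelectionError
from .trajectory_io import Frame, Topology, Trajectory


@dataclass
class WaterParams:
    interface_cutoff: float = 3.5  # A, oxygen to partner heavy atom
    crystal_cutoff: float = 3.4  # A, convention for crystal-structure counts
    mode: str = "bridging"  # or "either"

    def __post_init__(self):
        if self.interface_cutoff <= 0 or self.crystal_cutoff <= 0:
            raise ConfigurationError("cutoffs must be positive")
        if self.mode not in ("bridging", "either"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")


@dataclass
class AnchorSpec:
    """One anchor entry: atoms of a specific residue of one partner.

    ``atoms`` is a tuple of atom names, or the strings ``"oxygens"`` (all
    oxygen atoms of the residue) or ``"backbone_NO"`` (backbone N and O).
    """

    partner: str  # "A" or "B"
    residue_number: int
    atoms: object = "oxygens"
    residue_name: str = None  # optional sanity check


#: buried-water anchors for barnase (partner A) / barstar (partner B):
#: oxygens of D35/D39 (barstar), OD2 of D54 (barstar), backbone N/O of
#: L42/R83 (barnase) and D35/V45 (barstar)
BNBS_BURIED_ANCHORS = (
    AnchorSpec("B", 35, "oxygens", "ASP"),
    AnchorSpec("B", 39, "oxygens", "ASP"),
    AnchorSpec("B", 54, ("OD2",), "ASP"),
    AnchorSpec("A", 42, "backbone_NO", "LEU"),
    AnchorSpec("A", 83, "backbone_NO", "ARG"),
    AnchorSpec("B", 35, "backbone_NO", "ASP"),
    AnchorSpec("B", 45, "backbone_NO", "VAL"),
)

ANCHOR_PRESETS = {"bnbs": BNBS_BURIED_ANCHORS}


def _water_oxygens(topology: Topology) -> np.ndarray:
    wi = topology.water_records
    return wi[topology.elements[wi] == "O"]


def water_residue_ids(topology: Topology, oxygen_indices) -> list:
    return [(str(topology.chain_ids[i]), int(topology.residue_numbers[i]))
            for i in oxygen_indices]


def interfacial_waters(frame: Frame, topology: Topology,
                       params: WaterParams = None):
    """Count waters bridging the two partners in one frame.

    Returns ``(count, water ids)`` where ids are (chain, residue number)
    of the qualifying water oxygens. With no waters in the topology an
    empty result is returned.
    """
    params = params or WaterParams()
    ox = _water_oxygens(topology)
    if ox.size == 0:
        import warnings

        warnings.warn("topology has no water records", stacklevel=2)
        return 0, []
    coords = frame.coordinates
    hits = []
    for partner in ("A", "B"):
        idx = topology.partner_atom_indices(partner)
        heavy = idx[topology.is_heavy[idx]]
        tree = cKDTree(coords[heavy])
        d, _ = tree.query(coords[ox], k=1)
        hits.append(d <= params.interface_cutoff)
    close_a, close_b = hits
    mask = (close_a & close_b) if params.mode == "bridging" \
        else (close_a | close_b)
    chosen = ox[mask]
    return int(mask.sum()), water_residue_ids(topology, chosen)


def interfacial_water_series(trajectory: Trajectory, topology: Topology,
                             params: WaterParams = None):
    """Per-frame interfacial water counts with their mean and SD."""
    counts = []
    for fr in trajectory.frames():
        c, _ = interfacial_waters(fr, topology, params)
        counts.append(c)
    counts = np.asarray(counts)
    sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    return counts, float(counts.mean()), sd


def resolve_anchors(topology: Topology, anchor_selection) -> np.ndarray:
    """Resolve anchor specs (or a preset name) to atom indices."""
    if isinstance(anchor_selection, str):
        try:
            anchor_selection = ANCHOR_PRESETS[anchor_selection]
        except KeyError:
            raise SelectionError(
                f"unknown anchor preset {anchor_selection!r}") from None
    out, unmatched = [], []
    for spec in anchor_selection:
        chains = topology.partner_chains(spec.partner)
        mask = (np.isin(topology.chain_ids, list(chains))
                & (topology.residue_numbers == spec.residue_number)
                & ~topology.is_water)
        if spec.residue_name is not None:
            mask &= topology.residue_names == spec.residue_name
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            unmatched.append(spec)
            continue
        if spec.atoms == "oxygens":
            sel = idx[topology.elements[idx] == "O"]
        elif spec.atoms == "backbone_NO":
            sel = idx[np.isin(topology.atom_names[idx], ["N", "O"])]
        else:
            sel = idx[np.isin(topology.atom_names[idx], list(spec.atoms))]
        if sel.size == 0:
            unmatched.append(spec)
        else:
            out.append(sel)
    if unmatched:
        raise SelectionError(
            "anchor spec(s) did not resolve: "
            + "; ".join(f"partner {s.partner} residue {s.residue_number} "
                        f"atoms {s.atoms}" for s in unmatched)
        )
    return np.unique(np.concatenate(out))


def buried_waters(frame: Frame, topology: Topology, anchor_selection,
                  params: WaterParams = None, cutoff: float = None):
    """Count waters whose oxygen is within ``cutoff`` of any anchor atom.

    ``anchor_selection`` is a sequence of :class:`AnchorSpec`, a preset
    name, or a ready array of atom indices. The default cutoff is the
    interface cutoff (3.5 A).
    """
    params = params or WaterParams()
    if cutoff is None:
        cutoff = params.interface_cutoff
    if isinstance(anchor_selection, np.ndarray):
        anchors = anchor_selection
    else:
        anchors = resolve_anchors(topology, anchor_selection)
    if anchors.size == 0:
        raise SelectionError("anchor selection resolved to no atoms")
    ox = _water_oxygens(topology)
    if ox.size == 0:
        import warnings

        warnings.warn("topology has no water records", stacklevel=2)
        return 0, []
    tree = cKDTree(frame.coordinates[anchors])
    d, _ = tree.query(frame.coordinates[ox], k=1)
    mask = d <= cutoff
    return int(mask.sum()), water_residue_ids(topology, ox[mask])
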