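"""Structures, trajectories and campaign layout.

Conventions: coordinates in Angstrom, times in picoseconds, 0-based frame
indices. A residue is identified by ``(chain_id, residue_number,
residue_name)``. The two binding partners are sets of chain ids ("A" side
and "B" side); by convention the random force is applied to partner B (the
"ligand" partner, typically the smaller protein).

PDB files (including multi-model files used as trajectories) are parsed
with MDAnalysis. A plain-text frame container is provided for desk-scale
trajectories; binary MD formats are supported through any adapter object
exposing ``n_atoms`` and ``iter_frames()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Protocol, Sequence, runtime_checkable

import numpy as np
import yaml

from .errors import (
    ConfigurationError,
    InvalidInputError,
    InvalidLayoutError,
)

WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3"})

#: atom names treated as backbone (heavy atoms and their hydrogens)
BACKBONE_NAMES = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HN"}
)


class ResidueKey(NamedTuple):
    chain_id: str
    residue_number: int
    residue_name: str


@dataclass
class Topology:
    """Static description of the atoms of a two-partner complex."""

    atom_names: np.ndarray
    elements: np.ndarray
    residue_names: np.ndarray
    residue_numbers: np.ndarray
    chain_ids: np.ndarray
    masses: np.ndarray
    is_water: np.ndarray
    partner_a_chains: frozenset
    partner_b_chains: frozenset
    is_heavy: np.ndarray = field(default=None)
    is_backbone: np.ndarray = field(default=None)
    is_sidechain: np.ndarray = field(default=None)
    water_records: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.atom_names)
        for name in ("elements", "residue_names", "residue_numbers", "chain_ids",
                     "masses", "is_water"):
            if len(getattr(self, name)) != n:
                raise InvalidInputError(f"topology field {name!r} has wrong length")
        if self.is_heavy is None:
            self.is_heavy = np.asarray(
                [e.upper() not in ("H", "D") for e in self.elements]
            )
        if self.is_backbone is None:
            self.is_backbone = np.asarray(
                [(not w) and a in BACKBONE_NAMES
                 for a, w in zip(self.atom_names, self.is_water)]
            )
        if self.is_sidechain is None:
            self.is_sidechain = ~self.is_backbone & ~self.is_water
        if self.water_records is None:
            self.water_records = np.flatnonzero(self.is_water)
        overlap = self.partner_a_chains & self.partner_b_chains
        if overlap:
            raise ConfigurationError(
                f"chains assigned to both partners: {sorted(overlap)}"
            )
        unassigned = {
            c for c, w in zip(self.chain_ids, self.is_water)
            if not w and c not in self.partner_a_chains
            and c not in self.partner_b_chains
        }
        if unassigned:
            raise InvalidInputError(
                f"non-water atoms in chains {sorted(unassigned)} belong to "
                "neither partner"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def partner_chains(self, partner: str) -> frozenset:
        if partner.upper() == "A":
            return self.partner_a_chains
        if partner.upper() == "B":
            return self.partner_b_chains
        raise ConfigurationError(f"unknown partner {partner!r} (use 'A' or 'B')")

    def partner_atom_indices(self, partner: str) -> np.ndarray:
        chains = self.partner_chains(partner)
        mask = ~self.is_water & np.isin(self.chain_ids, list(chains))
        return np.flatnonzero(mask)

    def partner_of_residue(self, key: ResidueKey) -> str:
        if key.chain_id in self.partner_a_chains:
            return "A"
        if key.chain_id in self.partner_b_chains:
            return "B"
        raise ConfigurationError(f"residue {key} belongs to neither partner")

    def residues(self, include_water: bool = False) -> list:
        """Residue keys in order of first appearance."""
        seen, out = set(), []
        for i in range(self.n_atoms):
            if self.is_water[i] and not include_water:
                continue
            key = ResidueKey(str(self.chain_ids[i]), int(self.residue_numbers[i]),
                             str(self.residue_names[i]))
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def residue_atom_indices(self, include_water: bool = False) -> dict:
        """Mapping residue key -> array of atom indices."""
        idx: dict = {}
        for i in range(self.n_atoms):
            if self.is_water[i] and not include_water:
                continue
            key = ResidueKey(str(self.chain_ids[i]), int(self.residue_numbers[i]),
                             str(self.residue_names[i]))
            idx.setdefault(key, []).append(i)
        return {k: np.asarray(v) for k, v in idx.items()}


@dataclass
class Frame:
    coordinates: np.ndarray  # (n_atoms, 3), Angstrom
    time: float = 0.0  # ps from trajectory start
    frame_index: int = 0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise InvalidInputError("frame coordinates must have shape (n_atoms, 3)")


@dataclass
class Trajectory:
    """Ordered frames at a fixed snapshot interval.

    ``coords`` has shape (n_frames, n_atoms, 3); frame ``i`` is stamped at
    ``i * snapshot_interval`` ps.
    """

    coords: np.ndarray
    snapshot_interval: float = 10.0  # ps
    max_duration: float = 40.0  # ns
    kind: str = "ramd"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InvalidInputError("trajectory coords must have shape (F, N, 3)")
        if self.coords.shape[0] == 0:
            raise InvalidInputError("empty trajectory")
        if self.snapshot_interval <= 0:
            raise ConfigurationError("snapshot_interval must be positive")
        if self.kind not in ("equilibration", "ramd"):
            raise ConfigurationError(f"unknown trajectory kind {self.kind!r}")
        if self.kind == "ramd" and self.duration_ns > self.max_duration * (1 + 1e-9):
            raise InvalidInputError(
                f"ramd trajectory duration {self.duration_ns:.3f} ns exceeds "
                f"max_duration {self.max_duration} ns"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.snapshot_interval

    @property
    def duration_ns(self) -> float:
        return (self.n_frames - 1) * self.snapshot_interval / 1000.0

    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield Frame(self.coords[i], time=i * self.snapshot_interval,
                        frame_index=i)


@runtime_checkable
class TrajectoryAdapter(Protocol):
    """Contract for plugging in binary MD formats (XTC/DCD readers etc.)."""

    n_atoms: int

    def iter_frames(self) -> Iterable[np.ndarray]:
        """Yield (n_atoms, 3) coordinate arrays in Angstrom, in time order."""
        ...


@dataclass
class PartnerSpec:
    """Chain-id assignment of the two binding partners."""

    partner_a: Sequence[str]
    partner_b: Sequence[str]

    def __post_init__(self):
        if not self.partner_a or not self.partner_b:
            raise ConfigurationError("each partner needs at least one chain id")


def _guess_elements(names: np.ndarray, mda_elements=None) -> np.ndarray:
    if mda_elements is not None and all(e for e in mda_elements):
        return np.asarray([str(e).capitalize() for e in mda_elements])
    from MDAnalysis.topology.guessers import guess_types

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.asarray([str(t).capitalize() for t in guess_types(names)])


def read_structure(path, partner_spec: PartnerSpec):
    """Read a PDB file into a :class:`Topology` and its first :class:`Frame`.

    Crystal waters (residue names HOH/WAT/...) are retained and indexed in
    ``water_records``. Alternate locations other than blank/'A' are dropped;
    insertion-code duplicates are dropped with a warning.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = u.atoms

    # altloc filtering: keep blank or 'A'
    try:
        altlocs = atoms.altLocs
        keep = np.asarray([a in ("", "A") for a in altlocs])
    except AttributeError:
        keep = np.ones(len(atoms), dtype=bool)

    # insertion-code duplicates: keep the first icode seen per (chain, resid)
    try:
        icodes = atoms.icodes
    except AttributeError:
        icodes = np.asarray([""] * len(atoms))
    try:
        chain_ids = atoms.chainIDs
    except AttributeError:
        chain_ids = atoms.segids
    resids = atoms.resids
    first_icode: dict = {}
    dropped = 0
    for i in range(len(atoms)):
        if not keep[i]:
            continue
        rkey = (chain_ids[i], int(resids[i]))
        ic = first_icode.setdefault(rkey, icodes[i])
        if icodes[i] != ic:
            keep[i] = False
            dropped += 1
    if dropped:
        warnings.warn(
            f"dropped {dropped} atoms with duplicate insertion codes", stacklevel=2
        )

    sel = np.flatnonzero(keep)
    names = np.asarray(atoms.names)[sel]
    resnames = np.asarray(atoms.resnames)[sel]
    try:
        mda_elements = np.asarray(atoms.elements)[sel]
    except Exception:
        mda_elements = None
    elements = _guess_elements(names, mda_elements)
    masses = np.asarray(atoms.masses)[sel]
    if not np.all(masses > 0):
        # fall back to a coarse table when the file carries no usable masses
        table = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                 "S": 32.06, "P": 30.974}
        masses = np.asarray([table.get(e, 12.0) for e in elements])
    chain_arr = np.asarray([str(c) for c in chain_ids])[sel]
    is_water = np.isin(resnames, list(WATER_RESNAMES))

    a_chains = frozenset(str(c) for c in partner_spec.partner_a)
    b_chains = frozenset(str(c) for c in partner_spec.partner_b)
    present = set(chain_arr)
    missing = (a_chains | b_chains) - present
    if missing:
        raise ConfigurationError(
            f"partner_spec names chain(s) absent from file: {sorted(missing)}"
        )

    top = Topology(
        atom_names=names,
        elements=elements,
        residue_names=resnames,
        residue_numbers=np.asarray(resids)[sel].astype(int),
        chain_ids=chain_arr,
        masses=masses,
        is_water=is_water,
        partner_a_chains=a_chains,
        partner_b_chains=b_chains,
    )
    for partner in ("A", "B"):
        idx = top.partner_atom_indices(partner)
        if not np.any(top.is_heavy[idx]):
            raise InvalidInputError(f"partner {partner} has no heavy atoms")
    coords = np.asarray(u.trajectory[0].positions, dtype=float)[sel]
    return top, Frame(coords, time=0.0, frame_index=0)


def read_trajectory(source, topology: Topology, snapshot_interval: float = 10.0,
                    kind: str = "ramd", max_duration: float = 40.0) -> Trajectory:
    """Read a trajectory from a multi-model PDB, a frame-container file, a
    list of coordinate arrays, or an adapter object.

    Every frame must carry exactly ``topology.n_atoms`` atoms.
    """
    frames: list = []
    if isinstance(source, (list, tuple)) and len(source) == 0:
        raise InvalidInputError("empty trajectory")
    if isinstance(source, TrajectoryAdapter) and not isinstance(
        source, (str, Path, list, tuple, np.ndarray)
    ):
        frames = [np.asarray(f, dtype=float) for f in source.iter_frames()]
    elif isinstance(source, (list, tuple)) and source and isinstance(
        source[0], (np.ndarray, list)
    ):
        frames = [np.asarray(f, dtype=float) for f in source]
    elif isinstance(source, np.ndarray):
        frames = [np.asarray(f, dtype=float) for f in source]
    else:
        path = Path(source)
        if path.suffix.lower() == ".pdb":
            import MDAnalysis as mda

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u = mda.Universe(str(path))
                frames = [np.asarray(ts.positions, dtype=float)
                          for ts in u.trajectory]
        else:
            coords, interval = read_frames(path)
            if snapshot_interval is None:
                snapshot_interval = interval
            frames = list(coords)
    if not frames:
        raise InvalidInputError("empty trajectory")
    for i, f in enumerate(frames):
        if f.shape != (topology.n_atoms, 3):
            raise InvalidInputError(
                f"frame {i} has {f.shape[0] if f.ndim == 2 else 'malformed'} "
                f"atoms, expected {topology.n_atoms}"
            )
    return Trajectory(np.stack(frames), snapshot_interval=snapshot_interval,
                      kind=kind, max_duration=max_duration)


# ---------------------------------------------------------------------------
# plain-text frame container: one file per trajectory
# ---------------------------------------------------------------------------

_CONTAINER_MAGIC = "# tauramd-frames 1"


def write_frames(path, trajectory: Trajectory) -> None:
    """Write a trajectory to the internal plain-text container."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_CONTAINER_MAGIC}\n")
        fh.write(f"{trajectory.n_atoms} {trajectory.snapshot_interval!r}\n")
        flat = trajectory.coords.reshape(trajectory.n_frames, -1)
        np.savetxt(fh, flat, fmt="%.8f")


def read_frames(path):
    """Read the internal container; returns (coords (F, N, 3), interval_ps)."""
    path = Path(path)
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _CONTAINER_MAGIC:
            raise InvalidInputError(f"{path} is not a tauramd frame container")
        header = fh.readline().split()
        n_atoms, interval = int(header[0]), float(header[1])
        flat = np.loadtxt(fh, ndmin=2)
    if flat.size == 0:
        raise InvalidInputError(f"{path}: empty trajectory")
    if flat.shape[1] != 3 * n_atoms:
        raise InvalidInputError(f"{path}: malformed coordinate block")
    return flat.reshape(-1, n_atoms, 3), interval


# ---------------------------------------------------------------------------
# campaign layout: replicas x RAMD trajectories
# ---------------------------------------------------------------------------


@dataclass
class Replica:
    replica_id: str
    equilibration: object = None  # path or Trajectory
    ramd: list = field(default_factory=list)  # paths or Trajectories


@dataclass
class CampaignLayout:
    replicas: list
    min_traj_per_replica: int = 15
    min_replicas: int = 5

    @classmethod
    def from_manifest(cls, path, **kwargs) -> "CampaignLayout":
        """Load a YAML manifest mapping replica_id -> trajectory paths."""
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        base = path.parent
        replicas = []
        for rid, entry in doc["replicas"].items():
            eq = entry.get("equilibration")
            replicas.append(Replica(
                replica_id=str(rid),
                equilibration=str(base / eq) if eq else None,
                ramd=[str(base / p) for p in entry.get("ramd", [])],
            ))
        return cls(replicas, **kwargs)


@dataclass
class ValidationReport:
    underfilled_replicas: list  # (replica_id, n_traj)
    too_few_replicas: bool
    messages: list

    @property
    def ok(self) -> bool:
        return not self.underfilled_replicas and not self.too_few_replicas


def validate_campaign(layout: CampaignLayout) -> ValidationReport:
    """Check replica counts against the recommended campaign size.

    Underfilled campaigns are warned about, never rejected; a trajectory
    assigned to more than one replica is an error.
    """
    seen: dict = {}
    for rep in layout.replicas:
        for t in rep.ramd:
            key = str(t) if isinstance(t, (str, Path)) else id(t)
            if key in seen:
                raise InvalidLayoutError(
                    f"trajectory {t!r} assigned to replicas "
                    f"{seen[key]!r} and {rep.replica_id!r}"
                )
            seen[key] = rep.replica_id

    underfilled = [(rep.replica_id, len(rep.ramd)) for rep in layout.replicas
                   if len(rep.ramd) < layout.min_traj_per_replica]
    too_few = len(layout.replicas) < layout.min_replicas
    messages = [
        f"replica {rid!r} has {n} trajectories "
        f"(< {layout.min_traj_per_replica} recommended)"
        for rid, n in underfilled
    ]
    if too_few:
        messages.append(
            f"campaign has {len(layout.replicas)} replicas "
            f"(< {layout.min_replicas} recommended)"
        )
    return ValidationReport(underfilled, too_few, messages)
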