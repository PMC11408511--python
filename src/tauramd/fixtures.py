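"""Deterministic synthetic fixtures with known ground truth.

Each generator plants a truth (contact distances and occupancies, an
event-time distribution, a fingerprint partition, water placements) and
returns it alongside the constructed inputs, so tests can compare module
output against an answer that was *not* produced by the code under test.

The contact fixture exploits a comb geometry: residue pairs are spread
far apart along x (100 A spacing), so each partner-A residue sees exactly
one partner-B residue within the PP-RE cutoff and every planted pair
distance can be dialed in exactly per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FixtureError
from .simulator import TOY_GROUP_OVERRIDES, TOY_RESNAME
from .trajectory_io import Topology, Trajectory


@dataclass
class FixtureSpec:
    scenario: str
    seed: int = 0
    planted: dict = field(default_factory=dict)


def _comb_topology(n_pairs: int) -> Topology:
    """n single-bead residues per partner, pairs isolated along x."""
    n = 2 * n_pairs
    return Topology(
        atom_names=np.asarray(["CA"] * n),
        elements=np.asarray(["C"] * n),
        residue_names=np.asarray([TOY_RESNAME] * n),
        residue_numbers=np.concatenate([np.arange(1, n_pairs + 1)] * 2),
        chain_ids=np.asarray(["R"] * n_pairs + ["L"] * n_pairs),
        masses=np.ones(n),
        is_water=np.zeros(n, dtype=bool),
        partner_a_chains=frozenset({"R"}),
        partner_b_chains=frozenset({"L"}),
    )


@dataclass
class ContactFixture:
    topology: Topology
    trajectory: Trajectory
    group_overrides: dict
    planted_distances: np.ndarray  # (F, n_pairs)
    expected_ppre: list  # pair indices within cutoff at frame 0
    expected_bsre: list  # pair indices with occupancy > threshold
    expected_occupancy: np.ndarray


def make_contact_fixture(planted_distances, ppre_cutoff: float = 15.0,
                         d_rr: float = 5.5,
                         occupancy_threshold: float = 0.5) -> ContactFixture:
    """Trajectory whose pair distances equal ``planted_distances`` exactly.

    ``planted_distances`` is (n_frames, n_pairs); pair ``i`` is partner-A
    residue ``i+1`` vs partner-B residue ``i+1``. Expected PP-RE and
    BS-RE sets are computed from the planted numbers by direct counting.
    """
    planted = np.asarray(planted_distances, dtype=float)
    if planted.ndim != 2 or planted.size == 0:
        raise FixtureError("planted_distances must be (n_frames, n_pairs)")
    if np.any(planted <= 0):
        raise FixtureError("planted distances must be positive")
    n_frames, n_pairs = planted.shape
    if np.any(planted >= 100.0 / 2):
        raise FixtureError("planted distances must stay below the 50 A "
                           "comb isolation limit")
    top = _comb_topology(n_pairs)
    coords = np.zeros((n_frames, 2 * n_pairs, 3))
    for i in range(n_pairs):
        coords[:, i, 0] = 100.0 * i  # receptor bead fixed
        coords[:, n_pairs + i, 0] = 100.0 * i + planted[:, i]
    traj = Trajectory(coords, snapshot_interval=10.0, kind="equilibration")

    expected_ppre = [i for i in range(n_pairs)
                     if planted[0, i] <= ppre_cutoff]
    occ = (planted < d_rr).mean(axis=0)
    expected_bsre = [i for i in expected_ppre
                     if occ[i] > occupancy_threshold]
    return ContactFixture(top, traj, dict(TOY_GROUP_OVERRIDES), planted,
                          expected_ppre, expected_bsre, occ)


@dataclass
class EventFixture:
    times: np.ndarray
    true_median: float
    distribution: str


def make_event_fixture(distribution: str, n: int, seed: int = 0,
                       mu: float = 0.0, sigma: float = 0.5,
                       scale: float = 1.0,
                       value: float = 1.0) -> EventFixture:
    """Event times from a known distribution, with its exact median.

    lognormal(mu, sigma): median exp(mu); exponential(scale): median
    scale ln 2; constant(value): median value.
    """
    if n < 2:
        raise FixtureError("need at least 2 event times")
    rng = np.random.default_rng(seed)
    if distribution == "lognormal":
        times = rng.lognormal(mean=mu, sigma=sigma, size=n)
        median = float(np.exp(mu))
    elif distribution == "exponential":
        times = rng.exponential(scale=scale, size=n)
        median = float(scale * np.log(2.0))
    elif distribution == "constant":
        times = np.full(n, float(value))
        median = float(value)
    else:
        raise FixtureError(f"unknown distribution {distribution!r}")
    return EventFixture(times, median, distribution)


@dataclass
class ClusterFixture:
    fingerprints: np.ndarray  # (n_rows, n_cols) bool
    true_labels: np.ndarray  # planted partition, 0-based blocks
    delta_com: np.ndarray  # increases with block index
    trajectory_ids: np.ndarray


def make_cluster_fixture(n_per_block: int = 30, n_cols: int = 12,
                         seed: int = 0, flip_prob: float = 0.0
                         ) -> ClusterFixture:
    """Two well-separated fingerprint blocks with increasing dCOM.

    Block 0 occupies the first half of the columns, block 1 the second
    half; ``flip_prob`` optionally adds bit noise (0 keeps the planted
    partition exactly recoverable).
    """
    if n_cols < 4:
        raise FixtureError("need at least 4 fingerprint columns")
    rng = np.random.default_rng(seed)
    half = n_cols // 2
    rows, labels = [], []
    for block in range(2):
        base = np.zeros(n_cols, dtype=bool)
        if block == 0:
            base[:half] = True
        else:
            base[half:] = True
        for _ in range(n_per_block):
            row = base.copy()
            if flip_prob > 0:
                flips = rng.random(n_cols) < flip_prob
                row ^= flips
            rows.append(row)
            labels.append(block)
    fp = np.asarray(rows)
    labels = np.asarray(labels)
    dcom = np.where(labels == 0,
                    rng.uniform(1.0, 3.0, size=len(labels)),
                    rng.uniform(10.0, 15.0, size=len(labels)))
    tids = np.asarray([f"traj-{i % 5}" for i in range(len(labels))])
    return ClusterFixture(fp, labels, dcom, tids)


@dataclass
class WaterFixture:
    topology: Topology
    frame_coordinates: np.ndarray
    expected_interfacial: int
    expected_water_ids: list


def make_water_fixture() -> WaterFixture:
    """Crafted frame: two single-residue partners 6 A apart plus four
    waters at hand-placed positions; two bridge both partners."""
    # partner A heavy atom at origin, partner B heavy atom at (6, 0, 0)
    n_protein = 2
    waters = np.asarray([
        [3.0, 0.0, 0.0],   # 3.0 from both: bridging
        [3.0, 1.0, 0.0],   # ~3.16 from both: bridging
        [0.5, 3.0, 0.0],   # close to A only
        [20.0, 0.0, 0.0],  # far from both
    ])
    n_w = len(waters)
    top = Topology(
        atom_names=np.asarray(["CA", "CA"] + ["O"] * n_w),
        elements=np.asarray(["C", "C"] + ["O"] * n_w),
        residue_names=np.asarray([TOY_RESNAME, TOY_RESNAME]
                                 + ["HOH"] * n_w),
        residue_numbers=np.asarray([1, 1] + list(range(101, 101 + n_w))),
        chain_ids=np.asarray(["R", "L"] + ["W"] * n_w),
        masses=np.asarray([12.0, 12.0] + [16.0] * n_w),
        is_water=np.asarray([False, False] + [True] * n_w),
        partner_a_chains=frozenset({"R"}),
        partner_b_chains=frozenset({"L"}),
    )
    coords = np.vstack([[0.0, 0.0, 0.0], [6.0, 0.0, 0.0], waters])
    return WaterFixture(top, coords, 2, [("W", 101), ("W", 102)])
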