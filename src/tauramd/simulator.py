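"""Coarse-grained two-body Langevin simulator with the RAMD force protocol.

Two semi-rigid bead bodies (receptor and ligand) are bound by native
contacts modelled as Morse wells; non-native cross-body bead pairs feel a
capped soft repulsion, and the receptor is loosely tethered to its initial
position. Dynamics are overdamped Langevin in reduced units (k_B T = 1,
lengths in Angstrom, time in ps):

    dx = (F / gamma) dt + sqrt(2 T dt / gamma) N(0, 1)

The random-acceleration protocol adds a constant-magnitude external force
along a random unit vector u to the ligand, distributed over its beads by
mass-weighting (so the per-bead forces sum to the COM force). The ligand
COM displacement is checked every ``check_interval`` fs; if it is below
``min_displacement`` (0.025 A), u is redrawn uniformly on the sphere. A
trajectory stops when the body COM separation reaches ``stop_distance``
(70 A in the all-atom convention; a few bound-state separations for the
toy) or is censored at ``max_duration``.

Force magnitudes are quoted in the all-atom convention (kcal/mol/A, e.g.
17 or 19) and mapped linearly to reduced units via ``force_scale``.

"Mutants" are built by scaling the well depth ``D_e`` of chosen contacts,
the coarse-grained analogue of alanine substitution at an interface
residue.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, IntegrationFailureError
from .residence import DissociationEvent
from .trajectory_io import Topology, Trajectory


def splitmix64(*values) -> int:
    """Deterministic 64-bit mix of integers (seed derivation)."""
    state = np.uint64(0x9E3779B97F4A7C15)
    for v in values:
        state = np.uint64((int(state) + int(v)) % 2**64)
        z = state
        z = np.uint64(((int(z) ^ (int(z) >> 30)) * 0xBF58476D1CE4E5B9) % 2**64)
        z = np.uint64(((int(z) ^ (int(z) >> 27)) * 0x94D049BB133111EB) % 2**64)
        state = np.uint64(int(z) ^ (int(z) >> 31))
    return int(state)


@dataclass
class NativeContact:
    ligand_bead: int
    receptor_bead: int
    rest_length: float  # A
    well_depth: float  # D_e, k_B T
    range_a: float = 1.0  # 1/A, Morse range parameter


@dataclass
class ToyComplex:
    """Two semi-rigid bead bodies bound by native Morse contacts."""

    receptor_positions: np.ndarray  # (R, 3), A
    ligand_positions: np.ndarray  # (L, 3), A
    receptor_masses: np.ndarray
    ligand_masses: np.ndarray
    receptor_springs: list  # (i, j, rest, k)
    ligand_springs: list
    contacts: list  # NativeContact
    restraint_k: float = 5.0  # receptor tether to initial positions, kT/A^2
    repulsion_strength: float = 2.0  # kT, capped soft cross-body repulsion
    repulsion_range: float = 4.0  # A

    def __post_init__(self):
        nr = len(self.receptor_positions)
        nl = len(self.ligand_positions)
        for c in self.contacts:
            if not (0 <= c.ligand_bead < nl and 0 <= c.receptor_bead < nr):
                raise ConfigurationError(
                    f"contact (ligand {c.ligand_bead}, receptor "
                    f"{c.receptor_bead}) references a nonexistent bead "
                    f"(ligand has {nl}, receptor has {nr} beads)"
                )
            if c.rest_length <= 0:
                raise ConfigurationError("contact rest length must be > 0")
            if c.well_depth < 0:
                raise ConfigurationError("contact well depth must be >= 0")

    @property
    def n_receptor(self) -> int:
        return len(self.receptor_positions)

    @property
    def n_ligand(self) -> int:
        return len(self.ligand_positions)

    def mutate(self, contact_index: int, depth_scale: float) -> "ToyComplex":
        """Return a copy with one contact's well depth scaled (a coarse
        alanine substitution); everything else is untouched."""
        contacts = [replace(c) for c in self.contacts]
        contacts[contact_index] = replace(
            contacts[contact_index],
            well_depth=contacts[contact_index].well_depth * depth_scale,
        )
        return replace(self, contacts=contacts)


@dataclass
class RAMDParams:
    """Random-force protocol and integrator settings."""

    force_magnitude: float = 17.0  # kcal/mol/A (all-atom convention)
    check_interval: float = 100.0  # fs between displacement checks
    min_displacement: float = 0.025  # A
    stop_distance: float = 70.0  # A, COM-COM separation (all-atom default)
    max_duration: float = 40.0  # ns
    timestep: float = 0.02  # ps
    temperature: float = 1.0  # reduced (k_B T)
    friction: float = 1.0  # reduced (gamma)
    snapshot_interval: float = 10.0  # ps
    force_scale: float = 0.1  # reduced force per (kcal/mol/A)
    seed: int = 0

    def __post_init__(self):
        for name in ("check_interval", "min_displacement", "stop_distance",
                     "max_duration", "timestep", "temperature", "friction",
                     "snapshot_interval", "force_scale"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.force_magnitude < 0:
            raise ConfigurationError("force_magnitude must be >= 0")
        steps = self.check_interval / 1000.0 / self.timestep
        if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
            raise ConfigurationError(
                "check_interval must be an integer multiple of the timestep"
            )

    @property
    def reduced_force(self) -> float:
        return self.force_magnitude * self.force_scale

    @property
    def steps_per_check(self) -> int:
        return int(round(self.check_interval / 1000.0 / self.timestep))

    @property
    def steps_per_snapshot(self) -> int:
        return max(1, int(round(self.snapshot_interval / self.timestep)))


def build_toy_complex(n_receptor: int, n_ligand: int, contact_spec,
                      seed: int = 0, body_radius: float = 3.0,
                      contact_gap: float = 5.0, spring_k: float = 25.0,
                      morse_a: float = 0.4, restraint_k: float = 5.0,
                      ) -> ToyComplex:
    """Build a bound two-body complex, deterministic given ``seed``.

    ``contact_spec`` lists ``(ligand_bead, receptor_bead, well_depth)``
    triples. Beads are scattered within each body, the ligand is offset so
    the bodies face each other across ``contact_gap``, and every native
    contact's rest length is set to its built distance, so the complex
    starts at mechanical rest.
    """
    if n_receptor < 1 or n_ligand < 1:
        raise ConfigurationError("bead counts must be >= 1")
    rng = np.random.default_rng(splitmix64(seed, 0xB0D1))

    def blob(n, center):
        pts = rng.normal(scale=body_radius / 2.0, size=(n, 3))
        pts -= pts.mean(axis=0)
        return pts + center

    offset = 2 * body_radius + contact_gap
    rec = blob(n_receptor, np.zeros(3))
    lig = blob(n_ligand, np.array([offset, 0.0, 0.0]))

    def springs(pts):
        out = []
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                out.append((i, j, float(np.linalg.norm(pts[i] - pts[j])),
                            spring_k))
        return out

    contacts = []
    for entry in contact_spec:
        lig_i, rec_i, depth = entry
        if not (0 <= lig_i < n_ligand and 0 <= rec_i < n_receptor):
            raise ConfigurationError(
                f"contact (ligand {lig_i}, receptor {rec_i}) references a "
                f"nonexistent bead (ligand has {n_ligand}, receptor has "
                f"{n_receptor} beads)"
            )
        r0 = float(np.linalg.norm(lig[lig_i] - rec[rec_i]))
        contacts.append(NativeContact(int(lig_i), int(rec_i), r0,
                                      float(depth), morse_a))

    return ToyComplex(
        receptor_positions=rec,
        ligand_positions=lig,
        receptor_masses=np.ones(n_receptor),
        ligand_masses=np.ones(n_ligand),
        receptor_springs=springs(rec),
        ligand_springs=springs(lig),
        contacts=contacts,
        restraint_k=restraint_k,
    )


def external_forces(masses: np.ndarray, direction: np.ndarray,
                    magnitude: float) -> np.ndarray:
    """Mass-weighted distribution of a COM force over the ligand beads."""
    weights = masses / masses.sum()
    return magnitude * weights[:, None] * direction[None, :]


class _ForceField:
    """Precompiled force arrays for one ToyComplex."""

    def __init__(self, complex: ToyComplex):
        self.nr = complex.n_receptor
        self.nl = complex.n_ligand
        rs = complex.receptor_springs
        ls = complex.ligand_springs
        springs = [(i, j, r0, k) for (i, j, r0, k) in rs] + [
            (self.nr + i, self.nr + j, r0, k) for (i, j, r0, k) in ls]
        if springs:
            arr = np.asarray(springs, dtype=float)
            self.sp_i = arr[:, 0].astype(int)
            self.sp_j = arr[:, 1].astype(int)
            self.sp_r0 = arr[:, 2]
            self.sp_k = arr[:, 3]
        else:
            self.sp_i = np.zeros(0, dtype=int)
            self.sp_j = np.zeros(0, dtype=int)
            self.sp_r0 = self.sp_k = np.zeros(0)
        native = {(c.ligand_bead, c.receptor_bead) for c in complex.contacts}
        self.ct_l = np.asarray([self.nr + c.ligand_bead
                                for c in complex.contacts], dtype=int)
        self.ct_r = np.asarray([c.receptor_bead for c in complex.contacts],
                               dtype=int)
        self.ct_r0 = np.asarray([c.rest_length for c in complex.contacts])
        self.ct_de = np.asarray([c.well_depth for c in complex.contacts])
        self.ct_a = np.asarray([c.range_a for c in complex.contacts])
        rep = [(self.nr + li, ri) for li in range(self.nl)
               for ri in range(self.nr) if (li, ri) not in native]
        self.rep_l = np.asarray([p[0] for p in rep], dtype=int)
        self.rep_r = np.asarray([p[1] for p in rep], dtype=int)
        self.rep_eps = complex.repulsion_strength
        self.rep_rc = complex.repulsion_range
        self.restraint_k = complex.restraint_k
        self.rec_ref = complex.receptor_positions.copy()
        self.masses = np.concatenate([complex.receptor_masses,
                                      complex.ligand_masses])

    def forces(self, pos: np.ndarray) -> np.ndarray:
        f = np.zeros_like(pos)
        # intra-body harmonic springs
        if self.sp_i.size:
            dv = pos[self.sp_i] - pos[self.sp_j]
            r = np.linalg.norm(dv, axis=1)
            mag = -self.sp_k * (r - self.sp_r0) / np.maximum(r, 1e-12)
            fv = mag[:, None] * dv
            np.add.at(f, self.sp_i, fv)
            np.add.at(f, self.sp_j, -fv)
        # native contacts: Morse attraction for r > r0, harmonic (matched
        # curvature 2 De a^2) for r < r0 so compression forces stay bounded
        if self.ct_l.size:
            dv = pos[self.ct_l] - pos[self.ct_r]
            r = np.linalg.norm(dv, axis=1)
            dr = r - self.ct_r0
            e = np.exp(-self.ct_a * np.maximum(dr, 0.0))
            dudr = np.where(
                dr > 0.0,
                2.0 * self.ct_de * self.ct_a * (1.0 - e) * e,
                2.0 * self.ct_de * self.ct_a ** 2 * dr,
            )
            mag = -dudr / np.maximum(r, 1e-12)
            fv = mag[:, None] * dv
            np.add.at(f, self.ct_l, fv)
            np.add.at(f, self.ct_r, -fv)
        # capped soft repulsion for non-native cross-body pairs
        if self.rep_l.size and self.rep_eps > 0:
            dv = pos[self.rep_l] - pos[self.rep_r]
            r = np.linalg.norm(dv, axis=1)
            inside = r < self.rep_rc
            if np.any(inside):
                mag = np.zeros_like(r)
                mag[inside] = (2.0 * self.rep_eps / self.rep_rc
                               * (1.0 - r[inside] / self.rep_rc))
                fv = (mag / np.maximum(r, 1e-12))[:, None] * dv
                np.add.at(f, self.rep_l, fv)
                np.add.at(f, self.rep_r, -fv)
        # receptor tether
        if self.restraint_k > 0:
            f[: self.nr] -= self.restraint_k * (pos[: self.nr] - self.rec_ref)
        return f


@dataclass
class RAMDRun:
    trajectory: Trajectory
    event: DissociationEvent
    redraw_count: int
    final_positions: np.ndarray
    seed: int


def run_ramd_trajectory(complex: ToyComplex, params: RAMDParams,
                        seed: int = None, start_positions: np.ndarray = None,
                        trajectory_id: str = "t0", replica_id: str = "r0",
                        record_trajectory: bool = True) -> RAMDRun:
    """Integrate one RAMD trajectory until dissociation or the time cap.

    Returns the recorded trajectory (snapshots every
    ``params.snapshot_interval`` ps), the dissociation event (censored at
    ``max_duration`` if the stop distance is never reached), and the count
    of force-direction redraws.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    ff = _ForceField(complex)
    nr, nl = ff.nr, ff.nl
    if start_positions is not None:
        pos = np.array(start_positions, dtype=float)
    else:
        pos = np.vstack([complex.receptor_positions,
                         complex.ligand_positions]).astype(float)
    masses = ff.masses
    lig_m = masses[nr:]
    rec_m = masses[:nr]
    dt = params.timestep
    gamma = params.friction
    noise_sigma = np.sqrt(2.0 * params.temperature * dt / gamma)
    fmag = params.reduced_force
    steps_check = params.steps_per_check
    steps_snap = params.steps_per_snapshot
    max_steps = int(round(params.max_duration * 1000.0 / dt))

    def lig_com(p):
        return (p[nr:] * lig_m[:, None]).sum(axis=0) / lig_m.sum()

    def rec_com(p):
        return (p[:nr] * rec_m[:, None]).sum(axis=0) / rec_m.sum()

    def random_unit(rng):
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    u = random_unit(rng)
    redraws = 0
    last_check_com = lig_com(pos)
    snapshots = [pos.copy()]
    ext = external_forces(lig_m, u, fmag) if fmag > 0 else None

    event_time = None
    step = 0
    while step < max_steps:
        step += 1
        f = ff.forces(pos)
        if ext is not None:
            f[nr:] += ext
        pos = pos + (f / gamma) * dt + noise_sigma * rng.normal(size=pos.shape)
        if not np.all(np.isfinite(pos)):
            raise IntegrationFailureError(
                f"non-finite coordinates at step {step} "
                f"(t = {step * dt:.3f} ps); reduce the timestep"
            )
        if step % steps_check == 0:
            com = lig_com(pos)
            if np.linalg.norm(com - last_check_com) < params.min_displacement:
                u = random_unit(rng)
                if fmag > 0:
                    ext = external_forces(lig_m, u, fmag)
                redraws += 1
            last_check_com = com
        if step % steps_snap == 0 and record_trajectory:
            snapshots.append(pos.copy())
        sep = np.linalg.norm(lig_com(pos) - rec_com(pos))
        if sep >= params.stop_distance:
            event_time = step * dt
            break

    censored = event_time is None
    time = params.max_duration * 1000.0 if censored else event_time
    traj = Trajectory(
        np.stack(snapshots) if record_trajectory else pos[None],
        snapshot_interval=params.snapshot_interval,
        max_duration=params.max_duration,
        kind="ramd",
    )
    event = DissociationEvent(trajectory_id, replica_id, float(time),
                              criterion="com_com", censored=censored)
    return RAMDRun(traj, event, redraws, pos, seed)


def run_equilibration(complex: ToyComplex, params: RAMDParams,
                      duration_ps: float = 50.0, seed: int = 0,
                      record_trajectory: bool = True):
    """Short unbiased run (no external force, no stop criterion)."""
    p = replace(params, force_magnitude=0.0,
                max_duration=duration_ps / 1000.0, stop_distance=1e9)
    run = run_ramd_trajectory(complex, p, seed=seed,
                              record_trajectory=record_trajectory)
    traj = Trajectory(run.trajectory.coords,
                      snapshot_interval=params.snapshot_interval,
                      kind="equilibration")
    return traj, run.final_positions


@dataclass
class ReplicaResult:
    replica_id: str
    start_positions: np.ndarray
    equilibration: Trajectory
    trajectories: list  # Trajectory
    events: list  # DissociationEvent
    seeds: list


@dataclass
class ToyCampaignResult:
    replicas: list  # ReplicaResult
    params: RAMDParams
    base_seed: int

    @property
    def events(self) -> list:
        return [e for r in self.replicas for e in r.events]

    def events_by_replica(self) -> dict:
        return {r.replica_id: list(r.events) for r in self.replicas}

    @property
    def censored_fraction(self) -> float:
        ev = self.events
        return float(np.mean([e.censored for e in ev])) if ev else 0.0


def run_campaign(complex: ToyComplex, params: RAMDParams, n_replicas: int = 5,
                 n_traj: int = 15, base_seed: int = 0,
                 equilibration_ps: float = 50.0,
                 record_trajectories: bool = True) -> ToyCampaignResult:
    """Replicated RAMD campaign: each replica starts from the end state of
    its own short unbiased equilibration; all seeds derive from
    ``base_seed`` via splitmix64, so reruns are bitwise identical."""
    if n_replicas < 1 or n_traj < 1:
        raise ConfigurationError("n_replicas and n_traj must be >= 1")
    replicas = []
    for r in range(n_replicas):
        rid = f"replica-{r + 1}"
        eq_seed = splitmix64(base_seed, r, 0xE0)
        eq_traj, start = run_equilibration(
            complex, params, duration_ps=equilibration_ps, seed=eq_seed,
            record_trajectory=record_trajectories)
        trajs, events, seeds = [], [], [eq_seed]
        for t in range(n_traj):
            seed = splitmix64(base_seed, r, t + 1)
            seeds.append(seed)
            try:
                run = run_ramd_trajectory(
                    complex, params, seed=seed, start_positions=start,
                    trajectory_id=f"{rid}/traj-{t + 1}", replica_id=rid,
                    record_trajectory=record_trajectories)
            except IntegrationFailureError as exc:
                raise IntegrationFailureError(
                    f"{rid}, trajectory {t + 1}: {exc}") from exc
            trajs.append(run.trajectory)
            events.append(run.event)
        replicas.append(ReplicaResult(rid, start, eq_traj, trajs, events,
                                      seeds))
    return ToyCampaignResult(replicas, params, base_seed)


# ---------------------------------------------------------------------------
# bridging the toy model to the contact-analysis stack
# ---------------------------------------------------------------------------

TOY_RESNAME = "BEA"

#: group override making each bead its own hydrophobic interaction centre
TOY_GROUP_OVERRIDES = {TOY_RESNAME: {"hydrophobic": ["CA"],
                                     "sidechain": ["CA"]}}


def toy_topology(complex: ToyComplex) -> Topology:
    """One single-atom residue per bead: receptor chain R, ligand chain L.

    Lets the PP-RE/BS-RE machinery, the dissociation criteria and the
    fingerprint clustering run unchanged on toy campaigns (representative
    distances reduce to bead-bead distances)."""
    nr, nl = complex.n_receptor, complex.n_ligand
    n = nr + nl
    return Topology(
        atom_names=np.asarray(["CA"] * n),
        elements=np.asarray(["C"] * n),
        residue_names=np.asarray([TOY_RESNAME] * n),
        residue_numbers=np.concatenate(
            [np.arange(1, nr + 1), np.arange(1, nl + 1)]),
        chain_ids=np.asarray(["R"] * nr + ["L"] * nl),
        masses=np.concatenate([complex.receptor_masses,
                               complex.ligand_masses]),
        is_water=np.zeros(n, dtype=bool),
        partner_a_chains=frozenset({"R"}),
        partner_b_chains=frozenset({"L"}),
    )
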