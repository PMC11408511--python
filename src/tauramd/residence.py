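"""Residence-time estimation from forced-dissociation trajectories.

Five criteria define the dissociation time of a single trajectory:

``com_com``
    first frame at which the inter-partner centre-of-mass distance exceeds
    the stop distance (70 A in the all-atom convention), i.e. the standard
    protocol's recorded unbinding time;
``by_residue_first``
    first frame in which the *mean* representative distance over binding-
    site contacts (BS-REs) exceeds the contact threshold d_rr;
``by_residue_last``
    last frame in which that mean is below d_rr;
``many_contacts_last``
    last frame in which the number of formed contacts (representative
    distance < d_rr) is strictly greater than 50% of the BS-REs;
``few_contacts_first``
    first frame in which that count is strictly less than 50%.

Per replica, the time for half of the trajectories to dissociate (the 50%
point of the empirical CDF, a linearly interpolated median) is computed;
bootstrapping over random 80% subsamples yields tau_repl and SD_repl, and
their mean/SD over replicas yields tau_RAMD and SD_RAMD. If an SD exceeds
half its residence time, more sampling is advised (more trajectories for a
flagged replica, more replicas for a flagged campaign).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import BindingSiteContacts, ContactParams, PairDistanceMatrix
from .errors import ConfigurationError, InsufficientDataError

CRITERIA = (
    "com_com",
    "by_residue_first",
    "by_residue_last",
    "many_contacts_last",
    "few_contacts_first",
)


@dataclass
class DissociationEvent:
    """Dissociation time of one trajectory under one criterion."""

    trajectory_id: str
    replica_id: str
    time: float  # ps
    criterion: str = "com_com"
    censored: bool = False


def dissociation_time(pair_matrix: PairDistanceMatrix,
                      bsres: BindingSiteContacts = None,
                      criterion: str = "com_com",
                      params: ContactParams = None,
                      stop_distance: float = 70.0,
                      trajectory_id: str = "", replica_id: str = "",
                      ) -> DissociationEvent:
    """Apply one dissociation criterion to a per-frame distance matrix.

    If the criterion is never met the event is censored at the last frame.
    """
    if criterion not in CRITERIA:
        raise ConfigurationError(f"unknown criterion {criterion!r}")
    params = params or ContactParams()
    times = pair_matrix.times
    last = len(times) - 1

    def event(idx):
        return DissociationEvent(trajectory_id, replica_id, float(times[idx]),
                                 criterion, censored=False)

    def censored():
        return DissociationEvent(trajectory_id, replica_id, float(times[last]),
                                 criterion, censored=True)

    if criterion == "com_com":
        hit = np.flatnonzero(pair_matrix.com_com > stop_distance)
        return event(hit[0]) if hit.size else censored()

    if bsres is None or len(bsres.pair_indices) == 0:
        raise ConfigurationError(
            f"criterion {criterion!r} requires a nonempty BS-RE set"
        )
    d = pair_matrix.distances[:, bsres.pair_indices]  # (F, n_bsre)
    if criterion == "by_residue_first":
        hit = np.flatnonzero(d.mean(axis=1) > params.d_rr)
        return event(hit[0]) if hit.size else censored()
    if criterion == "by_residue_last":
        hit = np.flatnonzero(d.mean(axis=1) < params.d_rr)
        return event(hit[-1]) if hit.size else censored()

    counts = (d < params.d_rr).sum(axis=1)
    half = 0.5 * d.shape[1]
    if criterion == "many_contacts_last":
        hit = np.flatnonzero(counts > half)
        return event(hit[-1]) if hit.size else censored()
    # few_contacts_first
    hit = np.flatnonzero(counts < half)
    return event(hit[0]) if hit.size else censored()


def cdf50(times) -> float:
    """Time at which half of the trajectories have dissociated.

    Linear-interpolated 50th percentile of the sorted times: with 1-based
    order statistics and h = 0.5 (n - 1),
    tau = t_(floor(h)+1) + (h - floor(h)) (t_(floor(h)+2) - t_(floor(h)+1)).
    Censored times participate at their cap value.
    """
    t = np.sort(np.asarray(times, dtype=float))
    n = t.size
    if n < 2:
        raise InsufficientDataError("cdf50 needs at least 2 dissociation times")
    h = 0.5 * (n - 1)
    lo = int(np.floor(h))
    frac = h - lo
    if frac == 0.0:
        return float(t[lo])
    return float(t[lo] + frac * (t[lo + 1] - t[lo]))


def bootstrap_tau(times, rounds: int = 50000, fraction: float = 0.8,
                  seed: int = 0, replace: bool = False):
    """Bootstrap the CDF-midpoint residence time of one replica.

    Each round draws ``m = round(fraction * n)`` times (without replacement
    by default, i.e. random subsampling) and computes :func:`cdf50`;
    ``tau_repl`` is the mean and ``SD_repl`` the sample standard deviation
    over rounds. Deterministic given ``seed``.
    """
    t = np.asarray(times, dtype=float)
    n = t.size
    if n < 3:
        raise InsufficientDataError("bootstrap needs at least 3 times")
    if not (0.0 < fraction <= 1.0):
        raise ConfigurationError("fraction must be in (0, 1]")
    m = int(round(fraction * n))
    m = max(m, 2)
    rng = np.random.default_rng(seed)
    if replace:
        idx = rng.integers(0, n, size=(rounds, m))
    else:
        # without replacement per round: first m of a random permutation
        keys = rng.random((rounds, n))
        idx = np.argsort(keys, axis=1)[:, :m]
    samples = np.sort(t[idx], axis=1)
    h = 0.5 * (m - 1)
    lo = int(np.floor(h))
    frac = h - lo
    if frac == 0.0:
        medians = samples[:, lo]
    else:
        medians = samples[:, lo] + frac * (samples[:, lo + 1] - samples[:, lo])
    tau_repl = float(medians.mean())
    sd_repl = float(medians.std(ddof=1))
    return tau_repl, sd_repl


@dataclass
class ReplicaEstimate:
    replica_id: str
    tau_repl: float  # ns
    sd_repl: float  # ns
    n_traj: int
    censored_fraction: float = 0.0
    flagged: bool = False  # SD_repl > 0.5 tau_repl: add trajectories


@dataclass
class TauEstimate:
    """Aggregated residence-time estimate over replicas."""

    replicas: list
    tau_ramd: float  # ns
    sd_ramd: float  # ns
    campaign_flagged: bool  # SD_RAMD > 0.5 tau_RAMD: add replicas
    criterion: str = "com_com"
    censored_fraction: float = 0.0
    bootstrap_rounds: int = 50000
    bootstrap_fraction: float = 0.8
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "tau_ramd_ns": self.tau_ramd,
            "sd_ramd_ns": self.sd_ramd,
            "campaign_flagged": self.campaign_flagged,
            "criterion": self.criterion,
            "censored_fraction": self.censored_fraction,
            "bootstrap": {
                "rounds": self.bootstrap_rounds,
                "fraction": self.bootstrap_fraction,
                "seed": self.seed,
            },
            "replicas": [
                {
                    "replica_id": r.replica_id,
                    "tau_repl_ns": r.tau_repl,
                    "sd_repl_ns": r.sd_repl,
                    "n_traj": r.n_traj,
                    "censored_fraction": r.censored_fraction,
                    "flagged": r.flagged,
                }
                for r in self.replicas
            ],
        }


def aggregate_tau(replica_estimates) -> tuple:
    """tau_RAMD / SD_RAMD as mean and sample SD of the replica values."""
    reps = list(replica_estimates)
    if len(reps) < 2:
        raise InsufficientDataError("aggregation needs at least 2 replicas")
    taus = np.asarray([r.tau_repl for r in reps], dtype=float)
    tau_ramd = float(taus.mean())
    sd_ramd = float(taus.std(ddof=1))
    for r in reps:
        r.flagged = r.sd_repl > 0.5 * r.tau_repl
    campaign_flagged = sd_ramd > 0.5 * tau_ramd
    return tau_ramd, sd_ramd, campaign_flagged


def estimate_residence_time(events_by_replica: dict, criterion: str = "com_com",
                            rounds: int = 50000, fraction: float = 0.8,
                            seed: int = 0, replace: bool = False) -> TauEstimate:
    """Full estimator: per-replica bootstrap then aggregation over replicas.

    ``events_by_replica`` maps replica_id -> list of DissociationEvent
    (times in ps; censored events enter at their cap time). Returned taus
    are in ns.
    """
    reps = []
    for i, (rid, events) in enumerate(sorted(events_by_replica.items())):
        times_ns = np.asarray([e.time for e in events], dtype=float) / 1000.0
        tau, sd = bootstrap_tau(times_ns, rounds=rounds, fraction=fraction,
                                seed=_mix(seed, i), replace=replace)
        cens = float(np.mean([e.censored for e in events]))
        reps.append(ReplicaEstimate(rid, tau, sd, len(events),
                                    censored_fraction=cens))
    tau_ramd, sd_ramd, campaign_flagged = aggregate_tau(reps)
    all_events = [e for ev in events_by_replica.values() for e in ev]
    return TauEstimate(
        replicas=reps, tau_ramd=tau_ramd, sd_ramd=sd_ramd,
        campaign_flagged=campaign_flagged, criterion=criterion,
        censored_fraction=float(np.mean([e.censored for e in all_events])),
        bootstrap_rounds=rounds, bootstrap_fraction=fraction, seed=seed,
    )


def recommend_force_magnitude(censoring_by_force: dict,
                              max_censoring: float = 0.10):
    """Smallest force magnitude whose censored fraction (for the slowest
    system) stays below ``max_censoring``; None if none qualifies."""
    for force in sorted(censoring_by_force):
        if censoring_by_force[force] < max_censoring:
            return force
    return None


def _mix(seed: int, k: int) -> int:
    # stable per-replica substream below 2**31
    return (int(seed) * 1000003 + k * 7919) % (2**31 - 1)
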