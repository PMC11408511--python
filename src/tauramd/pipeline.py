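"""End-to-end toy study: simulate -> contacts -> tau -> pathways.

Runs replicated RAMD campaigns for one or more toy systems (a wild type
and its contact-weakened mutants), computes PP-RE matrices and BS-REs,
extracts dissociation times under all five criteria, bootstraps residence
times, clusters dissociation fingerprints and builds transition flow
graphs, and returns a residence-time ranking across systems.

Length thresholds are scaled to the coarse-grained geometry: the contact
threshold d_rr is set just above the longest native-contact rest length
and the stop distance to about four bound-state COM separations, mirroring
how the all-atom protocol's 5.5 A / 70 A relate to atomic contact
distances and protein sizes. The standard-protocol (com_com) events are
the ones recorded by the simulator when the separation crosses the stop
distance, as in the original protocol; the frame-based criteria are
evaluated from the stored snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import (
    ContactParams,
    assign_interaction_groups,
    compute_ppre_series,
    extract_bsres,
)
from .errors import EmptySelectionError
from .pathways import (
    ClusterConfig,
    build_binary_matrix,
    cluster_frames,
    flow_graph,
    jaccard_matrix,
    last_contact_clusters,
    select_cluster_frames,
)
from .residence import CRITERIA, dissociation_time, estimate_residence_time
from .simulator import (
    RAMDParams,
    TOY_GROUP_OVERRIDES,
    ToyComplex,
    run_campaign,
    splitmix64,
    toy_topology,
)


def toy_contact_params(complex: ToyComplex, margin: float = 1.15,
                       cutoff_factor: float = 2.2) -> ContactParams:
    """Contact thresholds scaled to the toy geometry."""
    max_rest = max(c.rest_length for c in complex.contacts)
    d_rr = margin * max_rest
    return ContactParams(ppre_cutoff=cutoff_factor * d_rr, d_rr=d_rr)


def toy_ramd_params(complex: ToyComplex, force_magnitude: float = 17.0,
                    stop_factor: float = 4.0, max_duration: float = 4.0,
                    **kwargs) -> RAMDParams:
    """RAMD parameters with the stop distance scaled to the bound state."""
    rec_com = complex.receptor_positions.mean(axis=0)
    lig_com = complex.ligand_positions.mean(axis=0)
    sep = float(np.linalg.norm(rec_com - lig_com))
    return RAMDParams(force_magnitude=force_magnitude,
                      stop_distance=stop_factor * sep,
                      max_duration=max_duration, **kwargs)


@dataclass
class SystemStudy:
    """All analysis products of one toy system's campaign."""

    name: str
    campaign: object  # ToyCampaignResult
    contact_params: ContactParams
    bsres: object
    matrices: dict  # trajectory_id -> PairDistanceMatrix
    events: dict  # criterion -> {trajectory_id: DissociationEvent}
    tau: dict  # criterion -> TauEstimate
    cluster_model: object = None
    flow: object = None
    last_contacts: object = None

    def tau_table(self) -> pd.DataFrame:
        rows = []
        for crit, est in self.tau.items():
            rows.append({
                "system": self.name, "criterion": crit,
                "tau_ramd_ns": est.tau_ramd, "sd_ramd_ns": est.sd_ramd,
                "censored_fraction": est.censored_fraction,
                "campaign_flagged": est.campaign_flagged,
            })
        return pd.DataFrame(rows)


def analyze_campaign(name: str, complex: ToyComplex, campaign,
                     contact_params: ContactParams = None,
                     cluster_config: ClusterConfig = None,
                     bootstrap_rounds: int = 5000, seed: int = 0,
                     cluster: bool = True,
                     compute_tau: bool = True) -> SystemStudy:
    """Run the full analysis stack on a finished toy campaign."""
    params = contact_params or toy_contact_params(complex)
    top = toy_topology(complex)
    groups = assign_interaction_groups(top, TOY_GROUP_OVERRIDES)

    equil_mats = []
    matrices = {}
    for rep in campaign.replicas:
        equil_mats.append(compute_ppre_series(rep.equilibration, top, groups,
                                              params))
        for traj, ev in zip(rep.trajectories, rep.events):
            matrices[ev.trajectory_id] = compute_ppre_series(
                traj, top, groups, params)
    bsres = extract_bsres(equil_mats, params)

    sim_events = {e.trajectory_id: e for e in campaign.events}
    events: dict = {c: {} for c in CRITERIA}
    for tid, mat in matrices.items():
        sim_ev = sim_events[tid]
        events["com_com"][tid] = sim_ev  # engine-recorded stop crossing
        for crit in CRITERIA:
            if crit == "com_com":
                continue
            events[crit][tid] = dissociation_time(
                mat, bsres, crit, params,
                stop_distance=campaign.params.stop_distance,
                trajectory_id=tid, replica_id=sim_ev.replica_id)

    tau = {}
    if compute_tau:
        for ci, crit in enumerate(CRITERIA):
            by_replica: dict = {}
            for ev in events[crit].values():
                by_replica.setdefault(ev.replica_id, []).append(ev)
            tau[crit] = estimate_residence_time(
                by_replica, criterion=crit, rounds=bootstrap_rounds,
                seed=splitmix64(seed, ci) % 2**31)

    study = SystemStudy(name, campaign, params, bsres, matrices, events, tau)
    if cluster:
        config = cluster_config or ClusterConfig(k=4, seed=seed % 2**31)
        try:
            selection = select_cluster_frames(
                matrices, events["by_residue_first"], config)
        except EmptySelectionError:
            return study
        binary = build_binary_matrix(selection, params)
        if binary.n_rows >= 2 and binary.matrix.shape[1] >= 1:
            D = jaccard_matrix(binary)
            k = config.k
            if isinstance(k, int) and binary.n_rows < k:
                return study
            study.cluster_model = cluster_frames(D, binary, config)
            study.flow = flow_graph(study.cluster_model, selection)
            study.last_contacts = last_contact_clusters(binary, None, config)
    return study


def run_toy_study(systems: dict, force_magnitude: float = 17.0,
                  n_replicas: int = 5, n_traj: int = 15, base_seed: int = 0,
                  bootstrap_rounds: int = 5000,
                  ramd_params: RAMDParams = None,
                  cluster_config: ClusterConfig = None,
                  cluster: bool = True) -> dict:
    """Simulate and analyze a set of toy systems.

    ``systems`` maps system name -> ToyComplex (e.g. a wild type and
    mutants). Returns ``{"studies": {...}, "ranking": DataFrame}`` where
    the ranking orders systems by decreasing standard-protocol tau_RAMD.
    """
    studies = {}
    for i, (name, cx) in enumerate(systems.items()):
        params = ramd_params or toy_ramd_params(cx, force_magnitude)
        campaign = run_campaign(cx, params, n_replicas=n_replicas,
                                n_traj=n_traj,
                                base_seed=splitmix64(base_seed, i) % 2**31)
        studies[name] = analyze_campaign(
            name, cx, campaign, cluster_config=cluster_config,
            bootstrap_rounds=bootstrap_rounds,
            seed=splitmix64(base_seed, i, 0xA) % 2**31, cluster=cluster)

    rows = []
    for name, st in studies.items():
        est = st.tau["com_com"]
        rows.append({
            "system": name,
            "tau_ramd_ns": est.tau_ramd,
            "sd_ramd_ns": est.sd_ramd,
            "censored_fraction": est.censored_fraction,
            "n_events": len(st.events["com_com"]),
        })
    ranking = (pd.DataFrame(rows)
               .sort_values("tau_ramd_ns", ascending=False)
               .reset_index(drop=True))
    return {"studies": studies, "ranking": ranking}


def default_wt_complex(seed: int = 1, n_receptor: int = 5, n_ligand: int = 3,
                       well_depth: float = 4.5, morse_a: float = 0.4):
    """The reference toy complex: 5+3 beads, four native contacts."""
    from .simulator import build_toy_complex

    spec = [(0, 0, well_depth), (1, 1, well_depth), (2, 2, well_depth),
            (0, 1, well_depth)]
    return build_toy_complex(n_receptor, n_ligand, spec, seed=seed,
                             morse_a=morse_a)
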