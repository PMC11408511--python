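# tauramd

Relative residence times and dissociation pathways of protein–protein
complexes from random-acceleration molecular dynamics (RAMD)
trajectories.

## The problem

The residence time τ = 1/k_off of a protein–protein complex — hours for
tight pairs like barnase–barstar — is far beyond the reach of
equilibrium MD. The τRAMD protocol accelerates unbinding by applying an
additional force of fixed magnitude and *random* orientation to the
center of mass of one partner, re-orienting it whenever it stops
producing motion, and estimates **relative** residence times from the
distribution of forced-dissociation times over replicated trajectory
campaigns. Because no unbinding coordinate is chosen in advance, the
trajectories also reveal *how* complexes dissociate: which residue
contacts persist longest, and along which routes the partners separate.

This package is for computational structural biologists who have (or
simulate) such campaigns and need the analysis stack:

- **Contacts** — per-frame representative distances for all cross-partner
  residue pairs (PP-REs: within 15 Å, minimum over compatible
  interaction-group COM distances) and binding-site contacts (BS-REs:
  below d_rr = 5.5 Å for over half the equilibration frames).
- **Residence times** — five dissociation criteria per trajectory
  (COM-separation stop, mean-BS-RE-distance first/last crossing,
  contact-count majority first/last); per replica the 50% point of the
  event-time CDF (interpolated median), bootstrapped (50 000 rounds, 80%
  subsamples) to τ_repl ± SD_repl, averaged over replicas to
  τ_RAMD ± SD_RAMD with sampling-adequacy flags.
- **Pathways** — binary interaction fingerprints of pre-dissociation
  frames, Jaccard distances, k-means clusters ordered by the ligand COM
  displacement (ΔCOM), inter-cluster transition flow graphs, and
  hierarchical grouping of the last contacts to break.
- **Waters** — bridging interfacial and anchor-defined buried water
  counts.
- **Kinetics** — harmonization of experimental k_off/k_on/K_i across
  literature series (WT-normalized), error-propagated derived constants,
  and log–log comparison of computed vs experimental residence times.
- **Toy simulator** — a coarse-grained two-body Langevin model
  implementing the full random-force protocol (displacement checks,
  direction redraws, stop distance, replica scheme), so the entire
  pipeline runs end to end in minutes without an MD engine. Contact
  "mutations" (scaled well depths) emulate alanine substitutions.

## Worked example

```python
from tauramd.pipeline import default_wt_complex, run_toy_study

wt = default_wt_complex(seed=1)
mutant = wt.mutate(0, 0.5)   # halve the first contact's well depth
study = run_toy_study({"WT": wt, "D35A-like": mutant},
                      n_replicas=3, n_traj=8, base_seed=42)
print(study["ranking"].to_string(index=False))
est = study["studies"]["WT"].tau["com_com"]
print(f"WT tau_RAMD = {est.tau_ramd:.3f} +/- {est.sd_ramd:.3f} ns")
model = study["studies"]["WT"].cluster_model
print("cluster mean dCOM (A):", model.mean_delta_com.round(1))
```

prints

```
   system  tau_ramd_ns  sd_ramd_ns  censored_fraction  n_events
       WT     0.169212    0.036059                0.0        24
D35A-like     0.136423    0.017063                0.0        24
WT tau_RAMD = 0.169 +/- 0.036 ns
cluster mean dCOM (A): [12.5 13.1 17.8 28.9]
```

The ranking orders systems by decreasing residence time: weakening one
native contact shortens τ_RAMD (0.136 vs 0.169 ns — toy units are
meaningful only relatively), with no censored trajectories. The four
fingerprint clusters ascend in mean ΔCOM, tracing the route from the
bound state (small displacement) to near-complete separation.

The same workflow is available from the shell:

```sh
tauramd simulate --config sim.yaml --out campaign/
tauramd contacts --campaign campaign/
tauramd tau --campaign campaign/ --criterion by_residue_first --seed 1
tauramd cluster --campaign campaign/ --k 4 --seed 1
tauramd kinetics --table exp.csv --reference schreiber1995
```

See `docs/methods.md` for the model, parameter conventions, and the
reasoning behind every default.

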