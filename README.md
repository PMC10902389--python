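# memclust

Quantitative analyses for peripheral membrane proteins that form
nanoclusters on lipid bilayers — built around the KRAS4b / RAF1(RBDCRD)
system, but generic in its parts:

* **Diffusion states from single-particle tracks.**  A switching Brownian
  motion simulator and a displacement hidden Markov model: K diffusive
  states with per-state diffusion coefficient `D_k`, stationary occupancy
  `π_k` and lifetime `τ_k`; observed 2D displacements in state k are
  zero-mean Gaussian with per-axis variance `2·D_k·Δt + 2σ_loc²`.  Fitting
  is Baum–Welch EM with BIC model selection over K; MSD curves are fitted
  with `MSD = 4·D·t + b` (free diffusion) or the square-corral confinement
  form `MSD(t) = (L²/3)(1 − e^{−12Dt/L²}) + 4σ_loc²`.
* **Lipid-mediated colocalization.**  A minimal simulator of two protein
  species on a periodic membrane coupled *only* through a scalar lipid
  composition field (deposition + diffusion + relaxation + gradient
  sensing; no direct protein–protein force), plus single-linkage cluster
  detection (inclusive `r_max = 5 nm`, periodic minimum image) and cluster
  composition / diffusion-versus-size statistics.
* **Membrane contacts and secondary structure.**  Per-residue lipid
  contact probability (Cα-to-phosphorus distance ≤ 8.5 Å) and β-strand
  content of the membrane-inserting loops, both binned by insertion depth
  `d_z` at 2 nm.
* **NMR.**  Chemical shift perturbation
  `Δδ_NH = sqrt((ΔδH² + (ΔδN/5)²)/2)` with a mean + 1 SD significance
  rule, and PRE ratios `I/I0` with propagated errors
  `ratio·sqrt(SN_I⁻² + SN_I0⁻²)` and per-spin-label normalization.

Every stage has a synthetic-data generator with known ground truth, so the
whole chain is testable without any external data.  See
`docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate tracks at the measured three-state parameters for KRAS on an
8-lipid bilayer, then recover the states:

```python
from memclust import (SimulationConfig, fit_hmm, select_model,
                      simulate_tracks, three_state_kras)

model = three_state_kras()          # pi=(0.11, 0.72, 0.17), D=(4.0, 0.66, 0.18)
tracks = simulate_tracks(model, SimulationConfig(n_tracks=5000, seed=1))

best = select_model(tracks, k_max=4, seed=0, sigma_loc=0.02)
print(best.K)
print(best.summary())
```

prints

```
3
   state   D_um2_s  occupancy_pct  lifetime_s
0      1  4.022980      10.953159    0.025702
1      2  0.660552      71.367911    0.162931
2      3  0.178262      17.678930    0.328614
```

BIC picks three states; the fast/intermediate/slow diffusion coefficients
(µm²/s) and occupancies land on the generator truth.  Lifetimes use the
per-frame convention `τ = Δt/(1 − P_ii)`, which for the intermediate state
reads 0.163 s against a continuous-time 0.13 s — see `docs/methods.md` for
why those differ at Δt = 10 ms.

The same objects drive the rest of the chain:

```python
from memclust import (CouplingParams, MembraneSimulation, cluster_statistics,
                      make_scene)

scene = make_scene(n_particles=60, box=300.0, seed=0)
hist = MembraneSimulation(scene, CouplingParams()).run(
    n_steps=4000, seed=42, record_every=100, discard_frames=10)
rep = cluster_statistics(hist, r_max=5.0)
print(round(rep.monomer_fraction, 2), round(rep.fold_change, 2))
```

prints `0.66 3.43` on this configuration: about two thirds of the proteins
are monomers at equilibrium, and the RBDCRD-bound species — which couples
to the lipid field three times more strongly — is severalfold more likely
to sit within 5 nm of a neighbor, with no direct attraction anywhere in
the model.

A thin CLI mirrors the library
(`memclust simulate-tracks | msd | hmm | macrosim | cluster-stats |
structure | nmr | pipeline`), e.g.

```sh
memclust hmm --tracks tracks.csv --kmax 4 --seed 7 --out fit.json
```

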