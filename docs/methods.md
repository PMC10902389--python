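# Methods

`memclust` implements the quantitative analysis chain for studies of
peripheral membrane-protein nanoclustering: diffusion-state inference from
single-particle tracks, a minimal lipid-field colocalization simulator with
cluster statistics, membrane-contact and secondary-structure statistics on
structure ensembles, and NMR chemical-shift-perturbation (CSP) and
paramagnetic-relaxation-enhancement (PRE) computations.  Because the raw
microscopy, molecular-dynamics and NMR data of such studies are rarely
redistributable, every pipeline stage is paired with a synthetic-data
generator with known ground truth; all tests run against those generators.

## Switching-diffusion model and track simulator

Tracks follow a K-state switching Brownian motion.  Hidden state k has
diffusion coefficient `D_k` (µm²/s); the state path is a continuous-time
Markov chain with rate matrix `Q`, discretized to the per-frame chain
`P = exp(Q·Δt)` so that switches occur only at frame boundaries.  This
matches the assumption of the displacement HMM used downstream, which keeps
parameter recovery well-posed.  The displacement over one frame interval is
an isotropic Gaussian with per-axis variance `2·D_k·Δt`; independent
`N(0, σ_loc²)` localization noise is added to each stored coordinate, so a
measured displacement has per-axis variance `2·D_k·Δt + 2·σ_loc²`.  Motion
blur during the exposure is not modeled; `σ_loc` absorbs static error
(default 0.02 µm).  Track lengths are minimum-plus-geometric (memoryless
photobleaching), minimum 7 frames to match the track-filter retention rule;
blinking drops frames independently, creating gaps that downstream code
treats as sequence breaks, never reorderings.

### Rate matrix from occupancies and lifetimes

Experimental reports typically print per-state occupancies `π_i` and
lifetimes `τ_i` but not a full rate matrix.  `build_rate_matrix` constructs
the unique reversible (detailed-balance) generator consistent with both: it
solves for symmetric coefficients `f_ij ≥ 0` with `q_ij = π_j·f_ij` under
the K exit-rate constraints `Σ_{j≠i} π_j f_ij = 1/τ_i`.  With K(K−1)/2
unknowns this is exactly determined at K = 3.  Detailed balance then gives
`π·Q = 0` identically.  Infeasible combinations (a negative `f_ij`) raise
an error naming the state pair — notably, a two-state chain is only
feasible when `π_1/τ_1 = π_2/τ_2`, which is the stationarity flux balance
itself.

### Default study conditions

The three-state presets encode the measured parameters for KRAS4b on an
8-lipid supported bilayer.  KRAS alone: occupancies (11, 72, 17)%,
intermediate state D = 0.66 µm²/s with τ = 0.13 s, slow state
D = 0.18 µm²/s with τ = 0.31 s.  The fast state is only loosely
characterized experimentally (D ≈ 4 µm²/s, no printed lifetime); given the
measured occupancies and lifetimes, stationarity confines the fast
lifetime to a narrow window (≈ 0.018–0.022 s), and the preset uses
τ₁ = 0.02 s.  A consequence worth stating plainly: those same constraints
force the fast→intermediate rate to ≈ 45–50 s⁻¹; no stationary chain can
combine the printed occupancies and lifetimes with a substantially lower
fast→intermediate rate, so the simulator's own chain is the reference for
rate-recovery tests.  For the RBDCRD-bound condition the measured anchor is
the slow-state occupancy, 47% (up from 17%), with all D slightly reduced
(slow ≈ 0.16 µm²/s); the remaining values — occupancies (8, 45, 47)%,
D = (3.5, 0.60, 0.16) µm²/s, τ = (0.017, 0.10, 0.40) s — are package
defaults consistent with the reported trends (shortened intermediate
lifetime, dominant slow state), chosen once and fixed.

## MSD analysis

Track filtering follows standard SPT practice: tracks persisting more than
6 frames are retained (≥ 7 observations), a single-step displacement above
5 pixels (pixel size 0.16 µm) splits the track, at most one blink frame may
be bridged (longer gaps split).  Time-averaged MSD uses all displacement
pairs within gap-free runs; pairs spanning a blink are excluded rather than
rescaled, to avoid lag mixing.  The ensemble curve is the
pair-count-weighted mean of per-track curves (both are returned; the
weighted-pool and per-track views answer slightly different questions and
the choice is exposed).

Brownian fits use weighted least squares of `MSD = 4·D·t + b` over the
first 4 lags by default — the short-lag regime minimizes confinement bias —
with pair counts as weights; `b` captures the `4σ_loc²` noise floor.  A
negative fitted D is flagged, never clamped.  Confined fits use the
square-corral closed form `MSD(t) = (L²/3)(1 − exp(−12·D·t/L²)) + 4σ_loc²`
(the long-time plateau of reflecting Brownian motion in an L×L box is
`L²/3`); the model name is recorded in the result metadata since other
confinement geometries yield different constants.  A curvature statistic,
`MSD(t_max)/(4·D_short·t_max)`, classifies curves as Brownian (≈ 1) or
confined (below a 0.75 default threshold).

## Displacement HMM

Inference is Baum–Welch EM on per-track displacement sequences with
isotropic Gaussian emissions, per-axis variance `v_k = 2·D_k·Δt + 2σ_loc²`.
The number of states is selected by BIC over K = 1..4 (ties toward smaller
K); the criterion table is attached to the results for audit.  This is an
explicit-likelihood stand-in for the variational-Bayes treatments common in
the SPT literature: the generative model is identical, and at thousands of
tracks the Occam behavior of BIC and the variational bound agree; the
method string in the output records the substitution.

Numerical choices: sequences are length-sorted and padded so the forward
and backward recursions run on shrinking array prefixes; per-iteration
monotonicity of the log-likelihood is asserted (a decrease raises an
internal error).  Restarts (10 by default) are initialized by
quantile-splitting the observed squared displacements — deterministic and
scale-aware — then perturbed; each restart runs a short burn-in (8
iterations) and only the best continues to convergence (relative tolerance
1e-7).  States are reported sorted by descending D.  Occupancies are
posterior-weighted displacement counts.  Lifetimes use `τ_i = Δt/(1−P_ii)`;
note this per-frame definition exceeds the continuous-time lifetime when
`Δt` is not small compared to `τ` (for τ_ct = 0.13 s at Δt = 10 ms the
discrete-chain value is ≈ 0.165 s), which is a property of the estimator
convention, not an inference error.  Transition rates are emitted in both
conventions found in the literature: pairwise `r_ij = P_ij/Δt` and total
exit `(1−P_ii)/Δt`.

σ_loc is a fixed input (default: the simulator's recorded value, else 0),
not a fitted parameter: with i.i.d. Gaussian displacement emissions a
shared σ_loc is not identifiable separately from the per-state variances —
any σ_loc up to the smallest `v_k/2` yields the same likelihood — and
estimating it would require modeling the noise-induced negative
displacement autocorrelation, which this model class deliberately omits.

## Lipid-field colocalization simulator

The simulator realizes one mechanism class: protein colocalization mediated
purely by the lipid environment, with no direct protein–protein forces.
Two species (RAS and RAS–RBDCRD, ~50/50, with rare species switching
representing effector binding/unbinding and faster orientational-state
switching) diffuse on a periodic box.  Each protein deposits a Gaussian
perturbation (σ = 4 nm) into a single scalar composition field φ, which
diffuses (D_φ = 10⁶ nm²/s) and relaxes toward zero (rate 10⁴ s⁻¹, i.e. a
0.1 ms fingerprint memory); proteins drift up the field gradient with
sensing strength ε.  The steady fingerprint amplitude of a stationary
particle without field diffusion is deposition/relaxation, which serves as
a closed-form check.  The field update is explicit and refuses to run when
`D_φ·dt/h² > 0.25`; the driver defaults to half that bound.

This is a one-field surrogate, not a reproduction of any production
continuum membrane model: real parameterizations couple many lipid species
to orientational-state catalogs that are not public.  Consequently all
cluster-composition percentages from the simulator are qualitative.  The
desk-scale defaults (box 300 nm, 60 particles, grid 2 nm, D_p = 1 µm²/s)
were chosen so the mechanism is clearly expressed within seconds of
compute: the RBDCRD-bound species senses the field 3× more strongly than
free RAS, and the default ε places the equilibrated monomer fraction near
70% with a rapidly decaying cluster-size distribution — the regime reported
for such systems.  The full-scale geometry (1000 nm, 300 particles) runs
with the same code.

Cluster analysis is single-linkage with an inclusive 5 nm threshold
(distance ≤ r_max joins), implemented by iterative frontier expansion under
the periodic minimum image; an independent union–find oracle checks the
partition in tests.  Reported statistics: time-averaged monomer fraction,
cluster-size histogram, per-size percentage of particles bound to RBDCRD,
per-species colocalization probability (≥ 1 neighbor within r_max) and
their ratio as a fold change.  Diffusion versus cluster size matches
cluster identity between consecutive frames by majority membership (ties to
the lower id) and uses single-interval MSD estimates for particles whose
cluster size persists; sizes with < 5 observations are flagged low-n, since
sparsely sampled large clusters produce unstable estimates (an effect known
from simulation studies of cluster diffusion).

## Structure statistics

Insertion depth d_z is the distance along the bilayer normal between the
centre of mass of the membrane-inserting loop Cα atoms (loops 145–148 and
158–161, mass-uniform) and the bilayer COM (all lipid atoms by default; a
phosphorus-only mode exists), reported in nm and binned at 2 nm over
[0, 8) nm with a closed last edge; bins are right-open.  A residue is in
contact when the distance from its Cα to the nearest lipid phosphorus atom
is ≤ 8.5 Å (boundary inclusive); per-residue contact probability is the
per-bin frame fraction with at least one contact, over the CRD window
136–188 (configurable — published figures sometimes highlight 137–185).
Empty bins are omitted, not reported as zero.

β-strand content is read from DSSP-alphabet codes supplied per residue
(classic DSSP output files are parsed; the DSSP algorithm itself is not
re-implemented).  "Total β-strand length" is counted as the number of
strand residues (code E; isolated bridges B excluded by default, toggleable)
within the 141–164 window — the total-count reading of "total length" —
with the longest single run emitted as a secondary statistic; restriction
to the two loops only is configurable, defaulting to the full window.
The synthetic ensemble encodes β length = max(0, round(6 − d_z)), i.e.
longer strands at deeper insertion, so per-bin means and the decreasing
trend are exactly recoverable.

## NMR

CSP: `Δδ_NH = sqrt((ΔδH² + (ΔδN/5)²)/2)`; the significance threshold is
the mean plus one standard deviation of all computed values; residues with
missing assignments are excluded from both the computation and the
threshold and listed.  PRE: `ratio = (I/I0)·f` with per-spin-label
normalization factors f (headgroup Gd³⁺ 1.0, doxyl-5 1.18, doxyl-14 1.32);
error `= ratio·sqrt(SN_I⁻² + SN_I0⁻²)`.  Normalization multiplies by
default — the factors rescale unaffected residues toward 1 — with a
division mode behind a flag, since the convention is not universal.  Ratios
are not clipped at 1.  Residues with ratio ≤ 0.5 (inclusive) are classified
proximal to the spin label.  Exclusion lists (overlapped or very weak
peaks) are configuration, not hard-coded.

## What the synthetic generators do and do not show

The track generator reproduces the displacement statistics, state-switching
kinetics, blinking and finite-length censoring of SPT data, but not motion
blur, spatially varying background, detection/linking errors or
non-Markovian trapping; parameter-recovery results therefore validate the
estimator chain under its own model class, not the upstream detection
stack.  The field simulator demonstrates the lipid-mediated mechanism and
its qualitative signatures (monomer fraction decreasing with coupling,
cluster enrichment in the strongly coupled species, diffusion decreasing
with cluster size), not quantitative cluster statistics of any production
model.  Toy structures place ideal Cα/P geometries, so contact and strand
statistics are exact by construction; they do not test PDB edge cases
beyond the reader's round trip.

## Problem sizes

Recovery tests use 5000 tracks of mean length 50 (≈ 250k displacements)
per seed and 10 seeds per condition, the scale at which published HMM
analyses of such data operate; unit tests use smaller sets (400–2500
tracks) sized so that sampling error stays well inside the asserted
tolerances.  Field-simulator tests run 1200–4000 steps at the desk scale,
several fingerprint relaxation times past equilibration.
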