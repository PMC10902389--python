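"""Lipid-field-mediated protein colocalization on a periodic membrane.

A deliberately minimal continuum-style simulator of two protein species
(RAS and RAS bound to RBDCRD) diffusing on a periodic 2D bilayer patch.
The only coupling between proteins is indirect, through a single scalar
lipid-composition field φ(x, y):

* every protein deposits a Gaussian perturbation into φ at its position
  (its "lipid fingerprint"), at a species- and orientation-dependent rate;
* φ diffuses and relaxes back toward zero (explicit scheme, stability
  checked);
* every protein feels a drift ε·∇φ up the composition gradient, so
  proteins are attracted into each other's fingerprints — and into their
  own, which slows them down.

There is no pairwise protein force anywhere in the code path: switch the
coupling off and trajectories are independent Brownian motions.  Proteins
also switch orientational state and (much more rarely) species, as
independent Poisson events.

Length unit nm, time unit s.  The companion cluster analysis implements
single-linkage clustering by iterative frontier expansion under the
periodic minimum-image metric, plus cluster-composition and
diffusion-versus-size statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RAS = 0
RAS_RBDCRD = 1
SPECIES_NAMES = {RAS: "RAS", RAS_RBDCRD: "RAS_RBDCRD"}


class StabilityError(RuntimeError):
    """Explicit field update would be unstable at this time step."""


@dataclass
class SpeciesParams:
    """Lipid coupling of one protein species.

    ``deposition`` and ``epsilon`` are per orientation state: deposition
    in field units/s (steady-state fingerprint amplitude is
    deposition/relaxation when the field does not diffuse) and sensing
    strength ε in nm²/s per unit field gradient.  ``d_p`` is the bare
    protein diffusion coefficient (nm²/s).
    """

    deposition: tuple = (1.0e4, 1.0e4)
    epsilon: tuple = (3.0e6, 3.0e6)
    d_p: float = 1.0e6
    orientation_switch_rate: float = 1.0e3   # 1/s, symmetric

    @property
    def n_orientations(self) -> int:
        if len(self.deposition) != len(self.epsilon):
            raise ValueError("deposition and epsilon must align per orientation")
        return len(self.deposition)


@dataclass
class CouplingParams:
    """Field dynamics plus per-species coupling.

    Species switching (RBDCRD arriving or leaving) must be much rarer
    than orientation switching; this is validated.
    """

    species: dict = field(default_factory=lambda: {
        RAS: SpeciesParams(deposition=(0.5e4, 1.0e4), epsilon=(2.5e6, 5.0e6)),
        RAS_RBDCRD: SpeciesParams(deposition=(1.0e4, 2.0e4),
                                  epsilon=(7.5e6, 15.0e6)),
    })
    d_phi: float = 1.0e6            # field diffusion, nm²/s
    relaxation_rate: float = 1.0e4  # 1/s
    kernel_sigma: float = 4.0       # nm, fingerprint width
    species_switch_rate: float = 1.0  # 1/s, both directions ("extremely low")

    def __post_init__(self) -> None:
        if min(self.d_phi, self.relaxation_rate, self.kernel_sigma) < 0:
            raise ValueError("field parameters must be non-negative")
        for sp in self.species.values():
            if self.species_switch_rate > 0.1 * max(sp.orientation_switch_rate, 1e-300):
                raise ValueError(
                    "species switching must be far rarer than orientation switching")

    def scaled(self, factor: float) -> "CouplingParams":
        """Copy with all sensing strengths ε multiplied by ``factor``."""
        newsp = {
            k: replace(sp, epsilon=tuple(factor * e for e in sp.epsilon))
            for k, sp in self.species.items()
        }
        return replace(self, species=newsp)


@dataclass
class MembraneScene:
    """Particle positions, labels and the lipid field on a periodic box."""

    box: float                      # nm
    positions: np.ndarray           # (N, 2) nm, wrapped into [0, box)
    species: np.ndarray             # (N,) int
    orientation: np.ndarray         # (N,) int
    phi: np.ndarray                 # (M, M) grid
    h: float                        # grid spacing nm
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.mod(np.asarray(self.positions, float), self.box)
        self.species = np.asarray(self.species, int)
        self.orientation = np.asarray(self.orientation, int)
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("lipid field must be finite")
        M = self.phi.shape[0]
        if self.phi.shape != (M, M) or abs(M * self.h - self.box) > 1e-9:
            raise ValueError("grid shape must tile the box: M*h == box")

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def copy(self) -> "MembraneScene":
        return MembraneScene(box=self.box, positions=self.positions.copy(),
                             species=self.species.copy(),
                             orientation=self.orientation.copy(),
                             phi=self.phi.copy(), h=self.h, time=self.time)


def make_scene(n_particles: int = 60, box: float = 300.0, h: float = 2.0,
               frac_rbdcrd: float = 0.5, n_orientations: int = 2,
               seed: int = 0) -> MembraneScene:
    """Random initial scene: uniform positions, ~50/50 species split."""
    rng = np.random.default_rng(seed)
    M = int(round(box / h))
    n_bound = int(round(frac_rbdcrd * n_particles))
    species = np.array([RAS_RBDCRD] * n_bound + [RAS] * (n_particles - n_bound))
    rng.shuffle(species)
    return MembraneScene(
        box=box,
        positions=rng.uniform(0, box, size=(n_particles, 2)),
        species=species,
        orientation=rng.integers(0, n_orientations, size=n_particles),
        phi=np.zeros((M, M)), h=h)


def min_image(d: np.ndarray, box: float) -> np.ndarray:
    """Minimum-image convention displacement components."""
    return d - box * np.round(d / box)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _kernel(sigma: float, h: float):
    """Gaussian stamp with peak amplitude 1, truncated at 3σ."""
    half = max(int(np.ceil(3.0 * sigma / h)), 1)
    ax = np.arange(-half, half + 1) * h
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    return np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2)), half


def step_scene(scene: MembraneScene, params: CouplingParams, dt_sim: float,
               rng: np.random.Generator) -> MembraneScene:
    """Advance the scene by one time step (in place; scene returned).

    Order: field deposition → field diffusion/relaxation → particle drift
    plus Brownian step → orientation and species Poisson switching.
    """
    h, M = scene.h, scene.phi.shape[0]
    if params.d_phi * dt_sim / h ** 2 > 0.25:
        raise StabilityError(
            f"d_phi*dt/h^2 = {params.d_phi * dt_sim / h ** 2:.3g} > 0.25; "
            "reduce dt_sim or refine the stability margin")
    phi = scene.phi
    stamp, half = _kernel(params.kernel_sigma, h)

    # (i) deposition: Gaussian fingerprints at particle positions
    for p in range(scene.n_particles):
        sp = params.species[scene.species[p]]
        rate = sp.deposition[scene.orientation[p] % sp.n_orientations]
        if rate == 0.0:
            continue
        ci = int(np.floor(scene.positions[p, 0] / h))
        cj = int(np.floor(scene.positions[p, 1] / h))
        ii = (np.arange(ci - half, ci + half + 1)) % M
        jj = (np.arange(cj - half, cj + half + 1)) % M
        phi[np.ix_(ii, jj)] += rate * dt_sim * stamp

    # field diffusion + relaxation (explicit, periodic)
    if params.d_phi > 0:
        lap = (np.roll(phi, 1, 0) + np.roll(phi, -1, 0)
               + np.roll(phi, 1, 1) + np.roll(phi, -1, 1) - 4.0 * phi) / h ** 2
        phi += dt_sim * params.d_phi * lap
    if params.relaxation_rate > 0:
        phi -= dt_sim * params.relaxation_rate * phi

    # (ii) particle update: drift ε·∇φ (bilinear) + Brownian step
    gx = (np.roll(phi, -1, 0) - np.roll(phi, 1, 0)) / (2.0 * h)
    gy = (np.roll(phi, -1, 1) - np.roll(phi, 1, 1)) / (2.0 * h)
    pos = scene.positions
    u = pos / h - 0.5          # gradient samples live at cell centres
    i0 = np.floor(u[:, 0]).astype(int)
    j0 = np.floor(u[:, 1]).astype(int)
    fx = u[:, 0] - i0
    fy = u[:, 1] - j0
    i0m, i1m = i0 % M, (i0 + 1) % M
    j0m, j1m = j0 % M, (j0 + 1) % M

    def interp(g):
        return ((1 - fx) * (1 - fy) * g[i0m, j0m] + fx * (1 - fy) * g[i1m, j0m]
                + (1 - fx) * fy * g[i0m, j1m] + fx * fy * g[i1m, j1m])

    drift = np.stack([interp(gx), interp(gy)], axis=1)
    eps = np.empty(scene.n_particles)
    d_p = np.empty(scene.n_particles)
    for p in range(scene.n_particles):
        sp = params.species[scene.species[p]]
        eps[p] = sp.epsilon[scene.orientation[p] % sp.n_orientations]
        d_p[p] = sp.d_p
    noise = rng.normal(size=pos.shape) * np.sqrt(2.0 * d_p * dt_sim)[:, None]
    scene.positions = np.mod(pos + eps[:, None] * drift * dt_sim + noise,
                             scene.box)

    # (iii) switching as independent Poisson events
    for p in range(scene.n_particles):
        sp = params.species[scene.species[p]]
        if sp.n_orientations > 1 and \
                rng.random() < 1.0 - np.exp(-sp.orientation_switch_rate * dt_sim):
            others = [o for o in range(sp.n_orientations)
                      if o != scene.orientation[p] % sp.n_orientations]
            scene.orientation[p] = others[rng.integers(len(others))]
    if params.species_switch_rate > 0:
        flip = rng.random(scene.n_particles) \
            < 1.0 - np.exp(-params.species_switch_rate * dt_sim)
        scene.species[flip] = 1 - scene.species[flip]

    scene.time += dt_sim
    return scene


@dataclass
class SceneHistory:
    """Recorded snapshots: (time, positions, species) per frame."""

    box: float
    times: list = field(default_factory=list)
    positions: list = field(default_factory=list)
    species: list = field(default_factory=list)

    def append(self, scene: MembraneScene) -> None:
        self.times.append(scene.time)
        self.positions.append(scene.positions.copy())
        self.species.append(scene.species.copy())

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in range(self.n_frames):
            n = len(self.positions[k])
            rows.append(pd.DataFrame({
                "frame": k, "id": np.arange(n),
                "species": [SPECIES_NAMES[s] for s in self.species[k]],
                "x_nm": self.positions[k][:, 0],
                "y_nm": self.positions[k][:, 1]}))
        return pd.concat(rows, ignore_index=True)


class MembraneSimulation:
    """Driver: advance a scene and record snapshots at a fixed cadence."""

    def __init__(self, scene: MembraneScene, params: CouplingParams,
                 dt_sim: float | None = None):
        self.scene = scene
        self.params = params
        # default dt from the stability rule with a 2x margin
        if dt_sim is None:
            dt_sim = 0.125 * scene.h ** 2 / max(params.d_phi, 1e-300)
        self.dt_sim = dt_sim

    def run(self, n_steps: int, seed: int, record_every: int = 100,
            discard_frames: int = 0) -> SceneHistory:
        """Run ``n_steps`` steps; record every ``record_every`` steps.

        ``discard_frames`` drops the first recorded frames (equilibration).
        """
        rng = np.random.default_rng(seed)
        hist = SceneHistory(box=self.scene.box)
        for k in range(1, n_steps + 1):
            step_scene(self.scene, self.params, self.dt_sim, rng)
            if k % record_every == 0:
                hist.append(self.scene)
        hist.times = hist.times[discard_frames:]
        hist.positions = hist.positions[discard_frames:]
        hist.species = hist.species[discard_frames:]
        return hist


# ---------------------------------------------------------------------------
# cluster analysis
# ---------------------------------------------------------------------------

def find_clusters(positions: np.ndarray, r_max: float = 5.0,
                  box: float | None = None) -> np.ndarray:
    """Single-linkage clusters by iterative frontier expansion.

    A seed point opens a cluster; all unassigned points within ``r_max``
    (inclusive) of any point already in the cluster are added, and the
    search repeats until no additions; then the next unassigned point
    seeds a new cluster.  Distances use the periodic minimum image when
    ``box`` is given.  Returns integer labels, one per point.
    """
    pos = np.asarray(positions, float)
    n = len(pos)
    if box is not None and r_max >= box / 2:
        raise ValueError("r_max must be < box/2 under periodic boundaries")
    d = pos[:, None, :] - pos[None, :, :]
    if box is not None:
        d = min_image(d, box)
    adj = (d ** 2).sum(-1) <= r_max ** 2
    labels = np.full(n, -1, dtype=int)
    current = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        labels[i] = current
        frontier = np.array([i])
        while frontier.size:
            reach = adj[frontier].any(axis=0) & (labels < 0)
            new = np.flatnonzero(reach)
            labels[new] = current
            frontier = new
        current += 1
    return labels


@dataclass
class ClusterReport:
    """Time-averaged cluster statistics over a scene history."""

    monomer_fraction: float
    size_histogram: pd.DataFrame     # size, mean_count, particle_fraction
    pct_bound_by_size: pd.DataFrame  # size, pct_bound, n_particles
    coloc_probability: dict          # species name -> P(>=1 neighbor in r_max)
    fold_change: float               # coloc RAS_RBDCRD / coloc RAS
    n_frames: int
    r_max: float


def cluster_statistics(history: SceneHistory, r_max: float = 5.0) -> ClusterReport:
    """Cluster size distribution, composition and colocalization odds.

    ``pct_bound_by_size`` gives, per cluster size s, the percentage of
    particles in size-s clusters that carry RBDCRD.  The colocalization
    probability of a species is the fraction of particle-frames with at
    least one neighbor within ``r_max``; the fold change is their ratio
    (RBDCRD-bound over free).
    """
    if history.n_frames < 1:
        raise ValueError("history has no frames")
    size_counts: dict[int, int] = {}
    part_in_size: dict[int, int] = {}
    bound_in_size: dict[int, int] = {}
    monomer_particles = 0
    total_particles = 0
    coloc = {RAS: 0, RAS_RBDCRD: 0}
    totals = {RAS: 0, RAS_RBDCRD: 0}
    for pos, spe in zip(history.positions, history.species):
        labels = find_clusters(pos, r_max=r_max, box=history.box)
        sizes = np.bincount(labels)
        per_particle = sizes[labels]
        total_particles += len(pos)
        monomer_particles += int((per_particle == 1).sum())
        for s in np.unique(sizes):
            size_counts[int(s)] = size_counts.get(int(s), 0) + int((sizes == s).sum())
        for s, sp in zip(per_particle, spe):
            part_in_size[int(s)] = part_in_size.get(int(s), 0) + 1
            if sp == RAS_RBDCRD:
                bound_in_size[int(s)] = bound_in_size.get(int(s), 0) + 1
        has_neighbor = per_particle > 1
        for sp in (RAS, RAS_RBDCRD):
            m = spe == sp
            totals[sp] += int(m.sum())
            coloc[sp] += int(has_neighbor[m].sum())

    hist_df = pd.DataFrame({
        "size": sorted(size_counts),
        "mean_count": [size_counts[s] / history.n_frames for s in sorted(size_counts)],
        "particle_fraction": [part_in_size[s] / total_particles
                              for s in sorted(size_counts)],
    })
    pct_df = pd.DataFrame({
        "size": sorted(part_in_size),
        "pct_bound": [100.0 * bound_in_size.get(s, 0) / part_in_size[s]
                      for s in sorted(part_in_size)],
        "n_particles": [part_in_size[s] for s in sorted(part_in_size)],
    })
    p_coloc = {SPECIES_NAMES[sp]: (coloc[sp] / totals[sp] if totals[sp] else np.nan)
               for sp in (RAS, RAS_RBDCRD)}
    p_ras = p_coloc[SPECIES_NAMES[RAS]]
    fold = p_coloc[SPECIES_NAMES[RAS_RBDCRD]] / p_ras if p_ras else np.inf
    return ClusterReport(
        monomer_fraction=monomer_particles / total_particles,
        size_histogram=hist_df, pct_bound_by_size=pct_df,
        coloc_probability=p_coloc, fold_change=fold,
        n_frames=history.n_frames, r_max=r_max)


def _match_clusters(labels_a: np.ndarray, labels_b: np.ndarray) -> dict:
    """Map each cluster in frame A to its majority-overlap cluster in B.

    Ties break toward the lower cluster id in B.
    """
    out = {}
    for ca in np.unique(labels_a):
        members = labels_b[labels_a == ca]
        ids, counts = np.unique(members, return_counts=True)
        out[int(ca)] = int(ids[np.argmax(counts)])  # first max = lowest id
    return out


def diffusion_vs_cluster_size(history: SceneHistory, r_max: float = 5.0,
                              min_obs: int = 5) -> pd.DataFrame:
    """MSD-based diffusion estimates for particles grouped by cluster size.

    For every consecutive frame pair, particles whose cluster keeps the
    same size s and identity (matched by majority membership) contribute
    one single-interval estimate D = |Δr|²/(4·Δt).  Reports per size the
    mean, spread and sample count; sizes with fewer than ``min_obs``
    observations are flagged low-n.
    """
    if history.n_frames < 2:
        raise ValueError("need at least two recorded frames")
    values: dict[int, list[float]] = {}
    for k in range(history.n_frames - 1):
        dt = history.times[k + 1] - history.times[k]
        la = find_clusters(history.positions[k], r_max=r_max, box=history.box)
        lb = find_clusters(history.positions[k + 1], r_max=r_max, box=history.box)
        match = _match_clusters(la, lb)
        sa = np.bincount(la)[la]
        sb = np.bincount(lb)[lb]
        dr = min_image(history.positions[k + 1] - history.positions[k],
                       history.box)
        d_est = (dr ** 2).sum(axis=1) / (4.0 * dt)
        persistent = (sa == sb) & (np.array([match[c] for c in la]) == lb)
        for s, ok, d in zip(sa, persistent, d_est):
            if ok:
                values.setdefault(int(s), []).append(float(d))
    rows = []
    for s in sorted(values):
        v = np.asarray(values[s])
        rows.append({"size": s, "D_nm2_s": v.mean(),
                     "D_um2_s": v.mean() * 1e-6,
                     "D_std_nm2_s": v.std(ddof=1) if len(v) > 1 else np.nan,
                     "n_obs": len(v), "low_n": len(v) < min_obs})
    return pd.DataFrame(rows)
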