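"""Membrane-contact and secondary-structure statistics on structure ensembles.

Works on ensembles of single-snapshot structures (protein + lipid bilayer).
Two observables are computed, both binned by the insertion depth ``d_z`` of
the membrane-binding loops:

* per-residue lipid contact probability — a residue is "in contact" in a
  frame when the distance from its Cα to the nearest lipid phosphorus atom
  is within a cutoff (default 8.5 Å);
* total β-strand length inside the loop-bearing analysis window, read from
  per-residue secondary-structure codes (DSSP alphabet, ``E`` = strand).

``d_z`` is the distance along the bilayer normal between the centre of mass
of the hydrophobic/cationic loop Cα atoms and the centre of mass of the
bilayer, reported in nanometres.  Coordinates are Ångström throughout this
module; ``d_z`` alone is converted to nm at the interface, matching how the
statistics are usually plotted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROTEIN = "protein"
LIPID = "lipid"


@dataclass
class StructureFrame:
    """One structure snapshot: protein atoms plus lipid atoms.

    Arrays are index-aligned, coordinates in Å.  ``roles`` assigns each atom
    to the protein or the lipid bilayer.  ``ss`` optionally carries a
    per-residue secondary-structure code map ``{resid: code}`` in the DSSP
    alphabet.
    """

    names: np.ndarray          # atom names, e.g. "CA", "P"
    resids: np.ndarray         # residue ids (int)
    resnames: np.ndarray
    roles: np.ndarray          # PROTEIN | LIPID per atom
    coords: np.ndarray         # (n_atoms, 3) Å
    normal_axis: int = 2
    ss: dict | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in frame {self.label!r}")
        for arr in ("names", "resids", "resnames", "roles"):
            setattr(self, arr, np.asarray(getattr(self, arr)))
        n = len(self.coords)
        if not all(len(getattr(self, a)) == n
                   for a in ("names", "resids", "resnames", "roles")):
            raise ValueError("atom attribute arrays must be index-aligned")

    # -- selections ------------------------------------------------------
    def ca_coords(self, resid_range: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """(resids, coords) of protein Cα atoms inside an inclusive range."""
        lo, hi = resid_range
        m = ((self.roles == PROTEIN) & (self.names == "CA")
             & (self.resids >= lo) & (self.resids <= hi))
        return self.resids[m], self.coords[m]

    def lipid_coords(self, atom_name: str | None = None) -> np.ndarray:
        m = self.roles == LIPID
        if atom_name is not None:
            m &= self.names == atom_name
        return self.coords[m]


@dataclass
class ContactSpec:
    """Analysis windows, cutoffs and binning for the structure statistics.

    Defaults follow standard practice for a RAF1 CRD / bilayer system:
    contacts are scored over the CRD (residues 136-188) with an 8.5 Å
    Cα-to-phosphorus cutoff; the secondary-structure window is 141-164 with
    the two membrane-inserting loops at 145-148 and 158-161; ``d_z`` is
    binned at 2 nm.
    """

    contact_range: tuple[int, int] = (136, 188)
    cutoff: float = 8.5                      # Å
    loop1: tuple[int, int] = (145, 148)
    loop2: tuple[int, int] = (158, 161)
    ss_range: tuple[int, int] = (141, 164)
    dz_bin_width: float = 2.0                # nm
    dz_max: float = 8.0                      # nm
    restrict_ss_to_loops: bool = False
    include_bridge: bool = False             # count DSSP 'B' as strand
    bilayer_com_atoms: str | None = None     # None = all lipid atoms; "P" = P only

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        for rng in (self.contact_range, self.loop1, self.loop2, self.ss_range):
            if rng[1] < rng[0]:
                raise ValueError(f"empty residue range {rng}")

    @property
    def dz_edges(self) -> np.ndarray:
        return np.arange(0.0, self.dz_max + self.dz_bin_width / 2, self.dz_bin_width)

    def loop_resids(self) -> np.ndarray:
        return np.concatenate([np.arange(self.loop1[0], self.loop1[1] + 1),
                               np.arange(self.loop2[0], self.loop2[1] + 1)])

    def strand_codes(self) -> set:
        return {"E", "B"} if self.include_bridge else {"E"}


def compute_dz(frame: StructureFrame, spec: ContactSpec | None = None) -> float:
    """Loop insertion depth d_z in nm for one frame.

    |COM_z(loop Cα, mass-uniform) − COM_z(bilayer)| along the bilayer
    normal, converted Å → nm.  The bilayer COM uses all lipid atoms by
    default (``spec.bilayer_com_atoms = "P"`` switches to phosphorus only).
    """
    spec = spec or ContactSpec()
    ax = frame.normal_axis
    want = set(spec.loop_resids().tolist())
    m = (frame.roles == PROTEIN) & (frame.names == "CA") & np.isin(frame.resids, list(want))
    got = set(frame.resids[m].tolist())
    if got != want:
        missing = sorted(want - got)
        raise ValueError(f"loop residues missing Cα atoms: {missing}")
    loop_z = frame.coords[m, ax].mean()
    lip = frame.lipid_coords(spec.bilayer_com_atoms)
    if len(lip) == 0:
        raise ValueError("frame has no lipid atoms")
    return abs(loop_z - lip[:, ax].mean()) / 10.0


def _dz_bin(dz: float, spec: ContactSpec) -> int | None:
    """Right-open bins [0,2), [2,4), ... ; the last bin is closed."""
    edges = spec.dz_edges
    if dz < edges[0] or dz > edges[-1]:
        return None
    idx = int(np.searchsorted(edges, dz, side="right")) - 1
    return min(idx, len(edges) - 2)


def contact_probability(frames, spec: ContactSpec | None = None) -> pd.DataFrame:
    """Per-residue lipid contact probability, by d_z bin.

    For every residue r in the contact range and every populated d_z bin b:
    the fraction of frames in b in which min over lipid P atoms of
    |Cα_r − P| is within the cutoff (≤, boundary included).  Empty bins are
    absent from the output rather than reported as zero.

    Returns a tidy frame with columns ``residue, bin_lo, bin_hi,
    probability, n_frames``.
    """
    spec = spec or ContactSpec()
    edges = spec.dz_edges
    hits: dict[int, dict[int, int]] = {}
    counts: dict[int, int] = {}
    resid_order: list[int] = []
    for fr in frames:
        b = _dz_bin(compute_dz(fr, spec), spec)
        if b is None:
            continue
        resids, ca = fr.ca_coords(spec.contact_range)
        p = fr.lipid_coords("P")
        if len(p) == 0:
            raise ValueError(f"frame {fr.label!r} has no lipid P atoms")
        # min distance from each Cα to any P
        d2 = ((ca[:, None, :] - p[None, :, :]) ** 2).sum(-1)
        contact = np.sqrt(d2.min(axis=1)) <= spec.cutoff
        counts[b] = counts.get(b, 0) + 1
        row = hits.setdefault(b, {})
        for rid, c in zip(resids.tolist(), contact.tolist()):
            if rid not in row:
                row[rid] = 0
                if rid not in resid_order:
                    resid_order.append(rid)
            row[rid] += int(c)
    records = []
    for b in sorted(hits):
        for rid in sorted(hits[b]):
            records.append({
                "residue": rid,
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "probability": hits[b][rid] / counts[b],
                "n_frames": counts[b],
            })
    return pd.DataFrame.from_records(
        records, columns=["residue", "bin_lo", "bin_hi", "probability", "n_frames"])


def _frame_beta_length(frame: StructureFrame, spec: ContactSpec) -> tuple[int, int]:
    """(total strand residue count, longest strand run) in the SS window."""
    if frame.ss is None:
        raise ValueError(f"frame {frame.label!r} has no secondary-structure codes")
    lo, hi = spec.ss_range
    resids = np.arange(lo, hi + 1)
    if spec.restrict_ss_to_loops:
        resids = resids[np.isin(resids, spec.loop_resids())]
    missing = [int(r) for r in resids if r not in frame.ss]
    if missing:
        raise ValueError(
            f"frame {frame.label!r}: secondary structure missing for residues {missing}")
    codes = spec.strand_codes()
    flags = [frame.ss[int(r)] in codes for r in resids]
    total = int(sum(flags))
    longest = run = 0
    for f in flags:
        run = run + 1 if f else 0
        longest = max(longest, run)
    return total, longest


def beta_strand_length(frames, spec: ContactSpec | None = None):
    """β-strand content per d_z bin.

    Per frame, the total number of residues with strand code inside the
    analysis window (optionally restricted to the two loops); per bin the
    mean over frames plus a population histogram of the per-frame totals.
    The longest single run is also reported as a secondary statistic.

    Returns ``(summary, histogram)`` DataFrames: summary has columns
    ``bin_lo, bin_hi, mean_beta_len, mean_longest_run, n_frames``;
    histogram has ``bin_lo, bin_hi, beta_len, count``.
    """
    spec = spec or ContactSpec()
    edges = spec.dz_edges
    per_bin: dict[int, list[tuple[int, int]]] = {}
    for fr in frames:
        b = _dz_bin(compute_dz(fr, spec), spec)
        if b is None:
            continue
        per_bin.setdefault(b, []).append(_frame_beta_length(fr, spec))
    rows, hrows = [], []
    for b in sorted(per_bin):
        totals = np.array([t for t, _ in per_bin[b]])
        runs = np.array([r for _, r in per_bin[b]])
        rows.append({"bin_lo": edges[b], "bin_hi": edges[b + 1],
                     "mean_beta_len": totals.mean(),
                     "mean_longest_run": runs.mean(),
                     "n_frames": len(totals)})
        for val, cnt in zip(*np.unique(totals, return_counts=True)):
            hrows.append({"bin_lo": edges[b], "bin_hi": edges[b + 1],
                          "beta_len": int(val), "count": int(cnt)})
    summary = pd.DataFrame.from_records(
        rows, columns=["bin_lo", "bin_hi", "mean_beta_len", "mean_longest_run", "n_frames"])
    hist = pd.DataFrame.from_records(
        hrows, columns=["bin_lo", "bin_hi", "beta_len", "count"])
    return summary, hist
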