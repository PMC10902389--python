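"""File formats and run configuration.

Track tables travel as plain CSV (``track_id,frame,x_um,y_um[,state]``,
UTF-8, frames 0-based).  Structure ensembles are standard single-model PDB
files read through MDAnalysis; secondary structure comes from classic DSSP
output tables parsed with Biopython.  Stochastic pipeline outputs embed the
package version, a config hash and the seed so a run can be reproduced
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .structure import LIPID, PROTEIN, StructureFrame
from .tracks import TRACK_COLUMNS, TrackSet

#: lipid residue names recognized when classifying PDB atoms
DEFAULT_LIPID_RESNAMES = frozenset({
    "POC", "POPC", "PAPC", "POPE", "PAPE", "DIPE", "DOPE", "PAPS", "POPS",
    "PIP2", "SAPI", "DPSM", "PSM", "CHOL", "CHL1", "DMPC", "DMPS",
})


class TrackFileError(ValueError):
    """A track CSV is empty or malformed."""


def read_tracks(path, dt: float = 0.01, pixel_size: float = 0.16) -> TrackSet:
    """Read a track CSV; malformed rows raise with their line number.

    Out-of-order frames are sorted with a warning; an empty file is an
    explicit error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TrackFileError(f"{path}: empty track file") from None
    if df.empty:
        raise TrackFileError(f"{path}: no track rows")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFileError(f"{path}: missing columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        vals = [row.track_id, row.frame, row.x_um, row.y_um]
        if any(pd.isna(v) for v in vals):
            raise TrackFileError(f"{path}: malformed row at line {i}")
    frames_sorted = df.sort_values(["track_id", "frame"]).reset_index(drop=True)
    if not frames_sorted[["track_id", "frame"]].equals(
            df[["track_id", "frame"]].reset_index(drop=True)):
        warnings.warn(f"{path}: frames out of order; sorted", stacklevel=2)
    df = frames_sorted
    if df.duplicated(["track_id", "frame"]).any():
        bad = df[df.duplicated(["track_id", "frame"])].index[0] + 2
        raise TrackFileError(f"{path}: duplicate frame near line {bad}")
    return TrackSet(data=df, dt=dt, pixel_size=pixel_size)


def write_tracks(tracks: TrackSet, path) -> None:
    """Write the canonical track CSV (lossless round trip, gaps retained)."""
    cols = TRACK_COLUMNS + (["state"] if tracks.has_state else [])
    tracks.data[cols].to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def read_structure_ensemble(paths, lipid_resnames=DEFAULT_LIPID_RESNAMES,
                            normal_axis: int = 2) -> list[StructureFrame]:
    """Read single-model PDB files into :class:`StructureFrame` objects.

    Atoms are classified as lipid when their residue name is in
    ``lipid_resnames``, protein otherwise.
    """
    import MDAnalysis as mda

    frames = []
    for p in map(Path, np.atleast_1d(paths)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(p))
        resnames = u.atoms.resnames
        roles = np.where(np.isin(resnames, list(lipid_resnames)), LIPID, PROTEIN)
        frames.append(StructureFrame(
            names=u.atoms.names.copy(), resids=u.atoms.resids.copy(),
            resnames=resnames.copy(), roles=roles,
            coords=u.atoms.positions.astype(float),
            normal_axis=normal_axis, label=p.name))
    return frames


def write_structure(frame: StructureFrame, path) -> None:
    """Write a :class:`StructureFrame` as a single-model PDB file."""
    import MDAnalysis as mda

    n = len(frame.coords)
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    u.add_TopologyAttr("names", frame.names)
    u.add_TopologyAttr("resids", frame.resids)
    u.add_TopologyAttr("resnames", frame.resnames)
    u.atoms.positions = frame.coords
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_dssp(path, chain: str = "A") -> dict[int, str]:
    """Parse a classic DSSP output table into {resid: ss_code}.

    Blank (coil) codes are normalized to ``"C"``.
    """
    from Bio.PDB.DSSP import make_dssp_dict

    dmap, keys = make_dssp_dict(str(path))
    out = {}
    for (ch, (_, resseq, _)), rec in dmap.items():
        if ch != chain:
            continue
        code = rec[1]
        out[int(resseq)] = "C" if code in ("-", " ") else code
    if not out:
        raise ValueError(f"{path}: no residues for chain {chain!r}")
    return out


def attach_secondary_structure(frames, ss_map: dict[int, str],
                               required=None) -> None:
    """Attach one DSSP map to every frame, checking residue coverage.

    ``required`` (iterable of resids) defaults to each frame's protein
    residues; missing ids raise an error naming the frame.
    """
    for fr in frames:
        need = set(int(r) for r in
                   (required if required is not None
                    else fr.resids[fr.roles == PROTEIN]))
        missing = sorted(need - set(ss_map))
        if missing:
            raise ValueError(
                f"frame {fr.label!r}: DSSP lacks residues {missing}")
        fr.ss = dict(ss_map)


# ---------------------------------------------------------------------------
# run configuration / provenance
# ---------------------------------------------------------------------------

def provenance(config: dict) -> dict:
    """Version + config-hash + seed stamp embedded in pipeline outputs."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {"package": "memclust", "version": __version__,
            "config_sha256": hashlib.sha256(blob).hexdigest()[:16],
            "seed": config.get("seed")}


KNOWN_SECTIONS = {"seed", "out_dir", "simulate", "msd", "hmm", "macrosim",
                  "structure", "nmr"}


class ConfigError(ValueError):
    """Invalid run configuration (unknown keys, missing inputs)."""


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the configured subset of pipeline stages.

    Recognized sections: ``simulate`` (track generation), ``msd``,
    ``hmm``, ``macrosim``, ``structure``, ``nmr``.  Unknown top-level keys
    are rejected.  Returns a report dict (also written as
    ``report.json`` when ``out_dir`` is set) whose every section carries
    the provenance stamp.
    """
    from . import hmm as hmm_mod
    from . import macro, msd, nmr, structure, synthetic

    unknown = set(config) - KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    out_dir = Path(out_dir or config.get("out_dir", "."))
    stamp = provenance({**config, "seed": seed})
    report: dict = {"provenance": stamp}

    tracks = None
    if "simulate" in config:
        sim = dict(config["simulate"])
        model = synthetic.DiffusionStateModel.from_occupancies(
            pi=sim["pi"], tau=sim["tau"], D=sim["D"],
            dt=sim.get("dt", 0.01), sigma_loc=sim.get("sigma_loc", 0.02))
        cfg = synthetic.SimulationConfig(
            n_tracks=sim.get("n_tracks", 1000),
            mean_track_length=sim.get("mean_track_length", 50),
            blink_probability=sim.get("blink_probability", 0.0), seed=seed)
        tracks = synthetic.simulate_tracks(model, cfg)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_tracks(tracks, out_dir / "tracks.csv")
        report["simulate"] = {"n_tracks": int(tracks.n_tracks),
                              "n_rows": len(tracks)}

    if "msd" in config:
        opts = dict(config["msd"])
        tr = tracks if tracks is not None else read_tracks(
            opts["tracks"], dt=opts.get("dt", 0.01))
        filtered, frep = msd.filter_tracks(tr, msd.FilterRules())
        curve, _ = msd.compute_msd(filtered,
                                   max_lag_frames=opts.get("max_lag_frames", 20))
        fit = msd.fit_brownian(curve, n_fit_lags=opts.get("n_fit_lags", 4))
        report["msd"] = {"D_app_um2_s": fit.D, "offset_um2": fit.offset,
                         "n_tracks": frep.n_tracks_out}
        if out_dir:
            out_dir.mkdir(parents=True, exist_ok=True)
            curve.to_frame().to_csv(out_dir / "msd.csv", index=False)

    if "hmm" in config:
        opts = dict(config["hmm"])
        tr = tracks if tracks is not None else read_tracks(
            opts["tracks"], dt=opts.get("dt", 0.01))
        res = hmm_mod.select_model(tr, k_max=opts.get("k_max", 4), seed=seed,
                                   sigma_loc=opts.get("sigma_loc"))
        report["hmm"] = res.to_dict()
        report["hmm"]["criterion_table"] = res.criterion_table.to_dict("records")

    if "macrosim" in config:
        opts = dict(config["macrosim"])
        scene = macro.make_scene(
            n_particles=opts.get("n_particles", 60),
            box=opts.get("box_nm", 300.0), seed=seed)
        sim = macro.MembraneSimulation(scene, macro.CouplingParams())
        hist = sim.run(n_steps=opts.get("n_steps", 1000), seed=seed,
                       record_every=opts.get("record_every", 100))
        rep = macro.cluster_statistics(hist, r_max=opts.get("r_max", 5.0))
        report["macrosim"] = {
            "monomer_fraction": rep.monomer_fraction,
            "fold_change": rep.fold_change,
            "coloc_probability": rep.coloc_probability,
        }
        if out_dir:
            out_dir.mkdir(parents=True, exist_ok=True)
            hist.to_frame().to_csv(out_dir / "scenes.csv", index=False)

    if "structure" in config:
        opts = dict(config["structure"])
        spec = structure.ContactSpec()
        frames = read_structure_ensemble(opts["pdb_files"])
        if "dssp" in opts:
            attach_secondary_structure(frames, read_dssp(opts["dssp"]))
        contacts = structure.contact_probability(frames, spec)
        report["structure"] = {"n_frames": len(frames),
                               "n_contact_rows": len(contacts)}
        if out_dir:
            out_dir.mkdir(parents=True, exist_ok=True)
            contacts.to_csv(out_dir / "contacts.csv", index=False)
            if all(fr.ss is not None for fr in frames):
                beta, _ = structure.beta_strand_length(frames, spec)
                beta.to_csv(out_dir / "beta_length.csv", index=False)

    if "nmr" in config:
        opts = dict(config["nmr"])
        df = pd.read_csv(opts["peaks"])
        table = nmr.PeakTable(df, exclusions=opts.get("exclusions", []))
        mode = opts.get("mode", "csp")
        if mode == "csp":
            out = nmr.csp(table)
        elif mode == "pre":
            out = nmr.pre_ratio(table,
                                norm_factor=opts.get("norm_factor", 1.0))
        else:
            raise ConfigError(f"unknown nmr mode {mode!r}")
        report["nmr"] = {"mode": mode, "n_residues": len(out)}
        if out_dir:
            out_dir.mkdir(parents=True, exist_ok=True)
            out.to_csv(out_dir / f"nmr_{mode}.csv", index=False)

    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
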