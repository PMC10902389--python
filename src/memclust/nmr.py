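"""Chemical-shift perturbation and PRE-ratio analysis of HSQC peak tables.

CSP combines the ¹H and ¹⁵N chemical-shift changes of a backbone amide into
Δδ_NH = sqrt((ΔδH² + (ΔδN/5)²)/2); residues above the mean + 1 SD of all
computed values are flagged significant.  PRE ratios I/I0 compare peak
heights with and without a paramagnetic tag; their error propagates the two
signal-to-noise ratios, error = (I/I0)·sqrt(SN_I⁻² + SN_I0⁻²).  Ratios may
be rescaled by a per-spin-label normalization factor (headgroup Gd³⁺ 1.0,
acyl-chain doxyl-5 1.18, doxyl-14 1.32) so that unaffected residues sit
near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default multiplicative normalization per spin-label condition
NORM_FACTORS = {"gd": 1.0, "doxyl5": 1.18, "doxyl14": 1.32}

PEAK_COLUMNS = ["residue", "dH_free", "dH_bound", "dN_free", "dN_bound",
                "I", "I0", "SN_I", "SN_I0"]


@dataclass
class PeakTable:
    """Per-residue NMR observables for CSP and PRE computation.

    ``data`` columns follow :data:`PEAK_COLUMNS`; shift columns may be NaN
    for unassigned residues, intensity columns NaN where no PRE data
    exists.  ``exclusions`` lists residue ids dropped from PRE analysis
    (typically overlapped or very weak peaks).
    """

    data: pd.DataFrame
    exclusions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"peak table missing columns {missing}")
        if self.data["residue"].duplicated().any():
            dup = self.data.loc[self.data["residue"].duplicated(), "residue"]
            raise ValueError(f"duplicate residue ids: {sorted(set(dup))}")
        sn = self.data[["SN_I", "SN_I0"]].to_numpy(float)
        has_int = np.isfinite(self.data[["I", "I0"]].to_numpy(float)).all(axis=1)
        if np.any(sn[has_int] <= 0):
            raise ValueError("signal-to-noise must be positive where intensities exist")


def csp(table: PeakTable) -> pd.DataFrame:
    """Per-residue Δδ_NH with a mean + 1·SD significance flag.

    Residues with a missing ¹H or ¹⁵N assignment on either side are
    excluded from the computation (and from the threshold) and reported
    with ``excluded=True``.

    Returns columns ``residue, d_dH, d_dN, delta_nh, significant,
    threshold, excluded``.
    """
    df = table.data
    d_h = df["dH_bound"].to_numpy(float) - df["dH_free"].to_numpy(float)
    d_n = df["dN_bound"].to_numpy(float) - df["dN_free"].to_numpy(float)
    ok = np.isfinite(d_h) & np.isfinite(d_n)
    delta = np.full(len(df), np.nan)
    delta[ok] = np.sqrt((d_h[ok] ** 2 + (d_n[ok] / 5.0) ** 2) / 2.0)
    vals = delta[ok]
    threshold = float(vals.mean() + vals.std(ddof=0)) if vals.size else np.nan
    out = pd.DataFrame({
        "residue": df["residue"].to_numpy(int),
        "d_dH": d_h,
        "d_dN": d_n,
        "delta_nh": delta,
        "significant": ok & (delta > threshold),
        "threshold": threshold,
        "excluded": ~ok,
    })
    return out


def pre_ratio(table: PeakTable, norm_factor: float = 1.0,
              norm_mode: str = "multiply") -> pd.DataFrame:
    """Per-residue PRE ratio I/I0 with propagated error and 1 − ratio.

    ratio = (I/I0) · norm_factor (``norm_mode="divide"`` divides instead);
    error = ratio · sqrt((1/SN_I)² + (1/SN_I0)²).  Ratios are not clipped
    at 1.  Residues on the table's exclusion list, with missing
    intensities, or with I0 = 0 are dropped with an explicit reason.

    Returns columns ``residue, ratio, error, one_minus_ratio,
    excluded, exclusion_reason``.
    """
    if norm_mode not in ("multiply", "divide"):
        raise ValueError("norm_mode must be 'multiply' or 'divide'")
    df = table.data
    res = df["residue"].to_numpy(int)
    I = df["I"].to_numpy(float)
    I0 = df["I0"].to_numpy(float)
    sn_i = df["SN_I"].to_numpy(float)
    sn_i0 = df["SN_I0"].to_numpy(float)

    reason = np.array([""] * len(df), dtype=object)
    reason[np.isin(res, table.exclusions)] = "on exclusion list"
    miss = (reason == "") & ~(np.isfinite(I) & np.isfinite(I0))
    reason[miss] = "missing intensity"
    zero = (reason == "") & (I0 == 0)
    reason[zero] = "zero control intensity"
    ok = reason == ""

    ratio = np.full(len(df), np.nan)
    raw = I[ok] / I0[ok]
    ratio[ok] = raw * norm_factor if norm_mode == "multiply" else raw / norm_factor
    err = np.full(len(df), np.nan)
    err[ok] = ratio[ok] * np.sqrt(1.0 / sn_i[ok] ** 2 + 1.0 / sn_i0[ok] ** 2)
    return pd.DataFrame({
        "residue": res,
        "ratio": ratio,
        "error": err,
        "one_minus_ratio": 1.0 - ratio,
        "excluded": ~ok,
        "exclusion_reason": reason,
    })


def proximity_classify(ratios: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
    """Residues whose PRE ratio is ≤ threshold (boundary included).

    These are the residues close enough to the spin label to be mapped onto
    a structural model.
    """
    df = ratios
    m = (~df["excluded"].to_numpy(bool)) & (df["ratio"].to_numpy(float) <= threshold)
    return np.sort(df.loc[m, "residue"].to_numpy(int))
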