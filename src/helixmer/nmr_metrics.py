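"""Scalar NMR-derived metrics: secondary Cα shifts, concentration-
dependent ¹⁵N chemical-shift perturbations, and solvent-PRE attenuation.

Shift tables are plain pandas DataFrames with columns
``residue`` (int), ``res_type`` (str), ``nucleus`` ("CA", "N", "H"),
``shift_ppm`` (float) and optionally ``condition``.  Random-coil
reference shifts are supplied by the user (literature scales differ);
nothing is hardcoded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "secondary_ca_shift",
    "csp_norm",
    "CspResult",
    "spre_attenuation",
    "EXCLUDED",
]

SHIFT_COLUMNS = ("residue", "res_type", "nucleus", "shift_ppm")

#: sentinel for variants whose resonances broadened beyond detection;
#: such variants carry no CSP value and must never be treated as zero
EXCLUDED = "excluded"


class NmrError(ValueError):
    pass


def _check_table(df: pd.DataFrame, name: str) -> pd.DataFrame:
    for col in SHIFT_COLUMNS:
        if col not in df.columns:
            raise NmrError(f"{name} is missing column {col!r}")
    if df.duplicated(subset=["residue", "nucleus"]).any():
        raise NmrError(f"{name} has duplicate (residue, nucleus) records")
    if not np.all(np.isfinite(df["shift_ppm"])):
        raise NmrError(f"{name} contains non-finite shifts")
    return df


def secondary_ca_shift(observed: pd.DataFrame, random_coil: pd.DataFrame) -> pd.DataFrame:
    """Per-residue secondary Cα shift ΔδCα = δ_obs − δ_rc, in ppm.

    Positive values indicate α-helical structure.  Residues without a
    random-coil reference are absent from the output (not zero).
    Raises if the residue type disagrees between the two tables.
    """
    obs = _check_table(observed, "observed")
    rc = _check_table(random_coil, "random_coil")
    obs_ca = obs[obs["nucleus"] == "CA"]
    rc_ca = rc[rc["nucleus"] == "CA"]
    merged = obs_ca.merge(
        rc_ca[["residue", "res_type", "shift_ppm"]],
        on="residue",
        suffixes=("", "_rc"),
        how="inner",
    )
    mismatch = merged[merged["res_type"] != merged["res_type_rc"]]
    if len(mismatch):
        bad = mismatch[["residue", "res_type", "res_type_rc"]].to_dict("records")
        raise NmrError(f"residue type mismatch between tables: {bad}")
    out = merged[["residue", "res_type"]].copy()
    out["delta_ca_ppm"] = merged["shift_ppm"] - merged["shift_ppm_rc"]
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class CspResult:
    """Normalized CSP of the probe resonance, or an explicit exclusion."""

    delta_n_ppm: Optional[float]
    csp_norm: Optional[float]
    probe_residue: int
    excluded: bool = False
    exclusion_reason: str = ""

    def __bool__(self):  # guard against accidental truthiness use
        raise TypeError("CspResult has no truth value; check .excluded explicitly")


def csp_norm(
    table_high: pd.DataFrame,
    table_low: pd.DataFrame,
    wt_reference_ppm: float,
    probe_residue: int = 328,
    excluded: bool = False,
    exclusion_reason: str = "broadened_beyond_detection",
) -> CspResult:
    """Concentration-dependent ¹⁵N CSP of the probe residue, WT-normalized.

    Δδ¹⁵N = |δ_N(high) − δ_N(low)| for the probe (A328 by default,
    where helix-helix assembly shifts the resonance between a high
    concentration with intermolecular contacts and a low, monomeric
    reference concentration); CSP_norm = Δδ¹⁵N / Δδ¹⁵N(WT).  Variants
    whose probe broadened beyond detection must be passed with
    ``excluded=True`` and yield an explicit exclusion marker, never 0.
    """
    if excluded:
        return CspResult(None, None, probe_residue, True, exclusion_reason)
    if wt_reference_ppm <= 0:
        raise NmrError(f"WT reference CSP must be positive, got {wt_reference_ppm}")
    values = {}
    for name, table in (("high", table_high), ("low", table_low)):
        t = _check_table(table, f"table_{name}")
        row = t[(t["residue"] == probe_residue) & (t["nucleus"] == "N")]
        if len(row) == 0:
            raise NmrError(
                f"probe residue {probe_residue} (15N) missing in the {name}-concentration table"
            )
        values[name] = float(row["shift_ppm"].iloc[0])
    delta = abs(values["high"] - values["low"])
    return CspResult(delta, delta / wt_reference_ppm, probe_residue)


def spre_attenuation(
    intensities_para: pd.DataFrame,
    intensities_ref: pd.DataFrame,
    exposure_threshold: float = 0.1,
) -> pd.DataFrame:
    """Solvent-PRE attenuation profile I_para / I_ref per residue.

    ``intensities_para`` has columns (residue, concentration_mM,
    intensity); ``intensities_ref`` has (residue, intensity) for the
    paramagnet-free sample.  Ratios at or below ``exposure_threshold``
    flag the residue as solvent exposed (0 = complete signal loss).
    """
    for col in ("residue", "concentration_mM", "intensity"):
        if col not in intensities_para.columns:
            raise NmrError(f"paramagnetic table is missing column {col!r}")
    for col in ("residue", "intensity"):
        if col not in intensities_ref.columns:
            raise NmrError(f"reference table is missing column {col!r}")
    ref = intensities_ref.set_index("residue")["intensity"]
    if (ref <= 0).any():
        bad = list(ref[ref <= 0].index)
        raise NmrError(f"zero or negative reference intensity for residues {bad}")
    missing = set(intensities_para["residue"]) - set(ref.index)
    if missing:
        raise NmrError(f"residues {sorted(missing)} lack a reference intensity")
    out = intensities_para.copy()
    out["attenuation"] = out["intensity"].to_numpy() / ref.loc[out["residue"]].to_numpy()
    out["solvent_exposed"] = out["attenuation"] <= exposure_threshold
    return out[["residue", "concentration_mM", "attenuation", "solvent_exposed"]]
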