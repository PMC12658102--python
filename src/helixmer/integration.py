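"""Cross-assay reductions and correlation statistics.

Links the per-variant measurements of a mutagenesis panel — saturation
concentrations from droplet-sedimentation assays, WT-normalized NMR
chemical-shift perturbations, per-residue simulation contact totals,
and cell-based toxicity scores — through plain Pearson/Spearman
correlation with explicit, named exclusion flags (variants whose NMR
resonances broadened beyond detection, that formed no droplets, or
whose assemblies were morphologically irregular are flagged, never
silently dropped).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MutantTable", "csat_estimate", "correlate_measures", "EXCLUSION_REASONS"]

EXCLUSION_REASONS = (
    "broadened_NMR",
    "no_droplets",
    "irregular_morphology",
    "normalization_anchor",
)

MUTANT_COLUMNS = ("variant", "csat_mean", "csat_sd", "excluded", "exclusion_reason")


class IntegrationError(ValueError):
    pass


@dataclass
class MutantTable:
    """Per-variant measurement table with exclusion bookkeeping.

    Thin wrapper over a DataFrame with at least ``variant``,
    ``csat_mean``, ``csat_sd``, ``excluded`` and ``exclusion_reason``
    columns; measurement columns (``csp_norm``, ``n_contact``,
    ``toxicity``) are optional.  The WT row is the normalization
    anchor.
    """

    df: pd.DataFrame

    def __post_init__(self):
        for col in MUTANT_COLUMNS:
            if col not in self.df.columns:
                raise IntegrationError(f"mutant table is missing column {col!r}")
        if (self.df["csat_sd"].fillna(0) < 0).any():
            raise IntegrationError("csat SD must be >= 0")

    @property
    def wt_row(self) -> pd.Series:
        hit = self.df[self.df["variant"].str.upper() == "WT"]
        if len(hit) == 0:
            raise IntegrationError("mutant table has no WT row to normalize against")
        return hit.iloc[0]

    def included(self) -> pd.DataFrame:
        return self.df[~self.df["excluded"].astype(bool)]


def csat_estimate(
    supernatant_uM: dict[float, Sequence[float]] | Sequence[float],
    loading_uM: Optional[float] = None,
) -> dict:
    """Saturation concentration per condition from supernatant replicates.

    After phase separation is induced and droplets are pelleted, the
    protein left in the supernatant equals c_sat.  Input is either a
    mapping ``{salt_mM: replicate values}`` or a bare replicate list for
    a single condition.  Returns mean and sample SD per condition, plus
    flags: ``non_monotone`` when c_sat increases with salt (it should
    not), and ``no_phase_separation`` when the supernatant stays at the
    loading concentration at every condition (no droplets formed).
    """
    if not isinstance(supernatant_uM, dict):
        supernatant_uM = {0.0: list(supernatant_uM)}
    conditions = {}
    means = []
    for salt in sorted(supernatant_uM):
        reps = np.asarray(supernatant_uM[salt], dtype=float)
        entry = {"n": int(reps.size)}
        entry["mean"] = float(reps.mean()) if reps.size else np.nan
        if reps.size >= 2:
            entry["sd"] = float(reps.std(ddof=1))
            entry["sd_available"] = True
        else:
            entry["sd"] = np.nan
            entry["sd_available"] = False
        conditions[float(salt)] = entry
        means.append(entry["mean"])
    flags = []
    if any(not c["sd_available"] for c in conditions.values()):
        flags.append("sd_unavailable")
    if len(means) > 1 and np.any(np.diff(means) > 0):
        flags.append("non_monotone")
    if loading_uM is not None and all(
        m >= 0.9 * loading_uM for m in means if np.isfinite(m)
    ):
        flags.append("no_phase_separation")
    return {"conditions": conditions, "flags": flags}


def correlate_measures(
    table: MutantTable | pd.DataFrame,
    x: str,
    y: str,
    method: str = "pearson",
    normalize_to_wt: bool = False,
) -> dict:
    """Correlation between two per-variant measures.

    Excluded variants and rows with a missing value in either column
    are dropped pairwise (and reported).  ``normalize_to_wt`` divides
    both axes by the WT values — an affine rescaling, so it cannot
    change the correlation coefficient itself; it only puts the axes on
    the fold-over-WT scale used for presentation.  At least three
    complete pairs are required.
    """
    if isinstance(table, pd.DataFrame):
        table = MutantTable(table)
    for col in (x, y):
        if col not in table.df.columns:
            raise IntegrationError(f"no column {col!r} in mutant table")
    df = table.df
    excluded = [
        (row["variant"], row["exclusion_reason"] or "unspecified")
        for _, row in df[df["excluded"].astype(bool)].iterrows()
    ]
    work = table.included()[["variant", x, y]].copy()
    dropped_nan = work[work[[x, y]].isna().any(axis=1)]["variant"].tolist()
    excluded += [(v, "missing_value") for v in dropped_nan]
    work = work.dropna(subset=[x, y])
    if len(work) < 3:
        raise IntegrationError(
            f"need >= 3 complete pairs after exclusions, have {len(work)}"
        )
    xv = work[x].to_numpy(dtype=float)
    yv = work[y].to_numpy(dtype=float)
    if normalize_to_wt:
        wt = table.wt_row
        for name, arr in ((x, xv), (y, yv)):
            ref = float(wt[name])
            if not np.isfinite(ref) or ref == 0:
                raise IntegrationError(f"WT value for {name!r} unusable for normalization")
        xv = xv / float(wt[x])
        yv = yv / float(wt[y])
    if method == "pearson":
        r, p = stats.pearsonr(xv, yv)
    elif method == "spearman":
        r, p = stats.spearmanr(xv, yv)
    else:
        raise IntegrationError(f"method must be pearson|spearman, got {method!r}")
    return {
        "r": float(r),
        "p_value": float(p),
        "n": int(len(work)),
        "method": method,
        "excluded": excluded,
    }
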