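"""Tissue pharmacokinetics and small dosing/mass utilities.

Per-organ concentration-time profiles are reduced to the linear-trapezoid
AUC over the observed span (no extrapolation beyond the last sample).  The
tumor-targeting index used here is

    TE = AUC_tumor / sum over all organs of AUC,

so computing TE for every organ in turn sums to 1, and the relative
targeting efficiency of a test formulation against a reference is
RTE = TE_test / TE_ref.  Group comparisons use classical two-tailed
Student's t-tests (pooled-variance unpaired, or paired), with the usual
star bands at p < 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass
from scipy import stats

__all__ = [
    "PKSummary",
    "auc_trapezoid",
    "targeting_efficiency",
    "relative_targeting_efficiency",
    "compare_groups",
    "significance_stars",
    "adduct_mz",
    "equimolar_dose",
    "build_timecourse",
    "timecourse_auc",
]

ELECTRON_MASS = 0.00054857990907  # Da
_ADDUCT_DELTAS = {
    "[M+H]+": 1.00782503207 - ELECTRON_MASS,
    "[M+Na]+": 22.9897692809 - ELECTRON_MASS,
    "[M]+": -ELECTRON_MASS,
}


def auc_trapezoid(times: Sequence[float], concs: Sequence[float]) -> float:
    """Linear trapezoidal AUC over the observed span; one sample gives 0."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.shape != c.shape or t.ndim != 1 or t.size < 1:
        raise ValueError("times and concs must be equal-length 1-D, size >= 1")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    if t.size == 1:
        return 0.0
    return float(np.trapezoid(c, t))


def targeting_efficiency(auc_by_organ: Mapping[str, float], tumor_label: str) -> float:
    """Tumor share of total exposure: AUC_tumor / sum of all organ AUCs."""
    if tumor_label not in auc_by_organ:
        raise ValueError(f"tumor label {tumor_label!r} not in AUC table")
    if any(v < 0 for v in auc_by_organ.values()):
        raise ValueError("AUC values must be non-negative")
    total = float(sum(auc_by_organ.values()))
    if total == 0:
        raise ValueError("all organ AUCs are zero; TE undefined")
    return float(auc_by_organ[tumor_label]) / total


def relative_targeting_efficiency(te_test: float, te_ref: float) -> float:
    """RTE = TE of the tested drug over TE of the reference drug."""
    if te_ref <= 0:
        raise ValueError("reference TE must be positive")
    return float(te_test) / float(te_ref)


def compare_groups(a: Sequence[float], b: Sequence[float],
                   paired: bool = False) -> tuple[float, float]:
    """Two-tailed Student's t-test: pooled-variance unpaired, or paired.

    Returns ``(t, p)``.  The paired test with zero difference variance is
    degenerate and raises rather than reporting p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        d = a - b
        if np.ptp(d) == 0 and d[0] != 0:
            raise ValueError("constant nonzero paired difference: "
                             "zero variance, t undefined")
        res = stats.ttest_rel(a, b)
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # identical constant samples
        t, p = 0.0, 1.0
    return t, p


def significance_stars(p: float) -> str:
    """'***' p<0.001, '**' p<0.01, '*' p<0.05, 'ns' otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def adduct_mz(formula: str, adduct: str) -> float:
    """Monoisotopic m/z of a singly charged adduct ion.

    ``[M+Na]+`` adds a sodium atom and removes one electron; ``[M+H]+`` adds
    a proton; ``[M]+`` removes one electron only.
    """
    if adduct not in _ADDUCT_DELTAS:
        raise ValueError(f"unsupported adduct {adduct!r}; "
                         f"choose from {sorted(_ADDUCT_DELTAS)}")
    try:
        neutral = _ptmass.calculate_mass(formula=formula)
    except Exception as exc:
        raise ValueError(f"cannot parse formula {formula!r}: {exc}") from exc
    return float(neutral + _ADDUCT_DELTAS[adduct])


def equimolar_dose(dose_ref: float, mass_ref: float, mass_test: float) -> float:
    """Dose of a test compound matching the molar dose of a reference.

    dose_test = dose_ref * mass_test / mass_ref, reported to one decimal
    (mg/kg), matching pharmacology dosing convention.
    """
    if dose_ref <= 0 or mass_ref <= 0 or mass_test <= 0:
        raise ValueError("dose and molar masses must be positive")
    return round(dose_ref * mass_test / mass_ref, 1)


# ---------------------------------------------------------------------------
# Time-course assembly
# ---------------------------------------------------------------------------

def build_timecourse(observations: Sequence[tuple[float, pd.DataFrame]],
                     ) -> pd.DataFrame:
    """Tidy per-organ time course from per-time region summaries.

    ``observations`` is a list of (time_h, region_stats frame) pairs, the
    frames as produced by :func:`vcqmsi.msi_data.region_stats` (indexed by
    organ name with mean/sem/n columns).
    """
    rows = []
    for t, frame in observations:
        for organ, rec in frame.iterrows():
            rows.append({"organ": organ, "time_h": float(t),
                         "mean": float(rec["mean"]), "sem": float(rec["sem"]),
                         "n": int(rec["n"])})
    df = pd.DataFrame(rows).sort_values(["organ", "time_h"]).reset_index(drop=True)
    for organ, sub in df.groupby("organ"):
        if sub["time_h"].duplicated().any():
            raise ValueError(f"duplicate time points for organ {organ!r}")
    return df


def timecourse_auc(timecourse: pd.DataFrame) -> dict[str, float]:
    """Per-organ trapezoidal AUC (pmol*h/mm^2) from a tidy time course."""
    return {
        str(organ): auc_trapezoid(sub["time_h"].to_numpy(), sub["mean"].to_numpy())
        for organ, sub in timecourse.groupby("organ")
    }


@dataclass
class PKSummary:
    """Per-organ AUCs with tumor-targeting statistics."""

    auc: dict[str, float]               # pmol*h/mm^2
    te: float                           # tumor AUC share, in (0, 1]
    tumor_label: str
    reference_group: str | None = None
    rte: float | None = None
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_timecourse(cls, timecourse: pd.DataFrame, tumor_label: str,
                        reference_te: float | None = None,
                        reference_group: str | None = None) -> "PKSummary":
        auc = timecourse_auc(timecourse)
        te = targeting_efficiency(auc, tumor_label)
        rte = (relative_targeting_efficiency(te, reference_te)
               if reference_te is not None else None)
        return cls(auc=auc, te=te, tumor_label=tumor_label,
                   reference_group=reference_group, rte=rte)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"organ": list(self.auc), "auc": list(self.auc.values())})
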