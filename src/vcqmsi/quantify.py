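"""Virtual calibration and absolute quantitation.

The central operation divides the drug ion image pixel-by-pixel by the
predicted relative calibration factor,

    I_cal = I / RCF_predicted,

which removes the tissue-specific matrix effect.  A standard curve (ordinary
least squares of calibrated spot-mean intensity on spiked areal
concentration, free intercept) then converts calibrated intensity into
pmol/mm^2.

``StandardCurve.pearson_r`` is the correlation of the curve's
(concentration, spot-mean) pairs — the field convention for reporting the
linearity of a calibration curve; a pooled per-pixel correlation is exposed
separately as a diagnostic, since single-pixel noise bounds it away from 1
even for a perfect calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .msi_data import IonImage, LabelMap

__all__ = [
    "StandardCurve",
    "QuantMap",
    "calibrate_intensity",
    "fit_standard_curve",
    "quantify_map",
    "spot_table_from_image",
    "pooled_pixel_r",
]


@dataclass
class StandardCurve:
    slope: float              # intensity per (pmol/mm^2)
    intercept: float          # intensity
    pearson_r: float          # r of (concentration, spot mean) pairs
    points: list[tuple[float, float]]  # (concentration, mean intensity) per level
    calibrated: bool
    pooled_r: float = float("nan")     # optional per-pixel diagnostic

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.points]
        if len(concs) < 3:
            raise ValueError("a standard curve needs at least 3 points")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError("curve point concentrations must be strictly increasing")
        if not -1.0 <= self.pearson_r <= 1.0:
            raise ValueError("pearson_r outside [-1, 1]")


@dataclass
class QuantMap:
    """Per-pixel areal concentration in pmol/mm^2."""

    values: np.ndarray
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if np.any(self.values[self.mask] < 0) or np.any(self.values[~self.mask] != 0):
            raise ValueError("concentrations must be >= 0 inside mask, 0 outside")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def calibrate_intensity(drug_image: IonImage, rcf_map: np.ndarray) -> IonImage:
    """Divide the drug image by the per-pixel RCF; mask preserved."""
    rcf_map = np.asarray(rcf_map, dtype=float)
    if rcf_map.shape != drug_image.shape:
        raise ValueError(
            f"rcf map shape {rcf_map.shape} != image shape {drug_image.shape}")
    mask = drug_image.mask
    if np.any(rcf_map[mask] <= 0):
        raise ValueError("RCF must be positive on every masked pixel")
    values = np.zeros_like(drug_image.values)
    values[mask] = drug_image.values[mask] / rcf_map[mask]
    return IonImage(target_mz=drug_image.target_mz, tol_ppm=drug_image.tol_ppm,
                    values=values, mask=mask)


def spot_table_from_image(image: IonImage, truth_labels: LabelMap,
                          conc_map: np.ndarray) -> list[tuple[float, list[float]]]:
    """Group masked pixels into (concentration, per-spot mean intensities).

    Spots are the connected components implied by constant (label, conc)
    runs; here each distinct (tissue label, concentration) pair is treated as
    one replicate spot, which matches the generated layouts where a tissue
    holds one spot per concentration level.
    """
    conc_map = np.asarray(conc_map, dtype=float)
    levels: dict[float, list[float]] = {}
    for lab in sorted(truth_labels.names):
        sel = (truth_labels.labels == lab) & image.mask
        for conc in np.unique(conc_map[sel]):
            if conc <= 0:
                continue
            vals = image.values[sel & (conc_map == conc)]
            if vals.size:
                levels.setdefault(float(conc), []).append(float(vals.mean()))
    return sorted(levels.items())


def fit_standard_curve(spot_table: list[tuple[float, list[float]]],
                       calibrated: bool = True) -> StandardCurve:
    """OLS of spot-mean intensity on concentration, free intercept.

    ``spot_table`` holds, per concentration level, the list of replicate
    calibrated spot means.  The reported Pearson r pools every
    (concentration, spot mean) pair.
    """
    spot_table = sorted((float(c), list(map(float, reps))) for c, reps in spot_table)
    if len(spot_table) < 3:
        raise ValueError(f"need >= 3 distinct concentrations, got {len(spot_table)}")
    concs_pooled, vals_pooled = [], []
    points = []
    for conc, reps in spot_table:
        if not reps:
            raise ValueError(f"no replicates at concentration {conc}")
        points.append((conc, float(np.mean(reps))))
        concs_pooled.extend([conc] * len(reps))
        vals_pooled.extend(reps)
    x = np.array([c for c, _ in points])
    y = np.array([v for _, v in points])
    fit = stats.linregress(x, y)
    r = float(stats.pearsonr(concs_pooled, vals_pooled).statistic)
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                         pearson_r=r, points=points, calibrated=calibrated)


def pooled_pixel_r(image: IonImage, conc_map: np.ndarray) -> float:
    """Per-pixel Pearson r of intensity vs concentration over drugged pixels."""
    conc_map = np.asarray(conc_map, dtype=float)
    sel = image.mask & (conc_map > 0)
    if sel.sum() < 3:
        raise ValueError("need at least 3 drugged pixels")
    return float(stats.pearsonr(conc_map[sel], image.values[sel]).statistic)


def quantify_map(calibrated_image: IonImage, curve: StandardCurve) -> QuantMap:
    """Invert the standard curve per pixel; negative results clamp to 0."""
    if curve.slope <= 0:
        raise ValueError(f"non-identifiable curve: slope {curve.slope} <= 0")
    mask = calibrated_image.mask
    conc = np.zeros_like(calibrated_image.values)
    raw = (calibrated_image.values[mask] - curve.intercept) / curve.slope
    n_clamped = int((raw < 0).sum())
    conc[mask] = np.maximum(raw, 0.0)
    prov = {
        "slope": curve.slope,
        "intercept": curve.intercept,
        "curve_pearson_r": curve.pearson_r,
        "curve_calibrated": curve.calibrated,
        "target_mz": calibrated_image.target_mz,
        "tol_ppm": calibrated_image.tol_ppm,
        "n_negative_clamped": n_clamped,
    }
    return QuantMap(values=conc, mask=mask, provenance=prov)
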