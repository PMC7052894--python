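"""Synthetic MSI phantoms with known ground truth.

Three generators emulate the data a virtual-calibration QMSI study rests on:

* :func:`generate_phantom` — a 2-D whole-body section with labeled organs,
  each with a tissue-specific *matrix factor* (relative ionization response),
  a panel of endogenous metabolite channels, and a spiked drug channel.
* :func:`generate_mimetic_model` — spotted arrays of drug standard in tissue
  homogenate (the "mimetic tissue model"): an equal-concentration variant for
  deriving relative calibration factors and a dilution-series variant for
  standard curves.
* :func:`generate_timecourse` — phantoms at successive post-dose times with
  mono-exponential per-organ concentration decay.

The generative rule for the drug channel is

    intensity = sensitivity * matrix_factor(organ) * concentration * eps,

with ``eps`` multiplicative lognormal noise, plus a uniform additive noise
floor on every channel.  Endogenous channels come in two kinds: *matrix*
features whose per-organ mean is proportional to the matrix factor (their
pixelwise Pearson correlation with the matrix-factor map is driven to a
target value by solving for the within-organ noise), and *marker* features
with independent random per-organ means — tissue-specific metabolites that
carry organ identity but are uncorrelated with the matrix effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .msi_data import LabelMap, SpectrumGrid

__all__ = [
    "OrganShape",
    "EndoFeature",
    "PhantomSpec",
    "MimeticModelSpec",
    "GroundTruth",
    "default_organs",
    "default_panel",
    "generate_phantom",
    "generate_mimetic_model",
    "generate_timecourse",
]

PTX_MZ = 876.3203  # [M+Na]+ of paclitaxel, the default drug channel


@dataclass(frozen=True)
class OrganShape:
    """Axis-aligned geometric primitive painted onto the grid.

    ``center`` and ``size`` are fractions of the grid shape; ``size`` is the
    (row, col) half-axis for ellipses and half-extent for rectangles.
    Later organs overwrite earlier ones, so a body-wide muscle region can be
    listed first and the organs painted inside it.
    """

    name: str
    kind: str  # "ellipse" | "rect"
    center: tuple[float, float]
    size: tuple[float, float]
    matrix_factor: float

    def __post_init__(self) -> None:
        if self.matrix_factor <= 0:
            raise ValueError(f"{self.name}: matrix factor must be positive")

    def paint(self, labels: np.ndarray, value: int) -> None:
        rows, cols = labels.shape
        cr, cc = self.center[0] * rows, self.center[1] * cols
        hr, hc = self.size[0] * rows, self.size[1] * cols
        rr, cc_idx = np.mgrid[0:rows, 0:cols]
        if self.kind == "ellipse":
            inside = ((rr - cr) / hr) ** 2 + ((cc_idx - cc) / hc) ** 2 <= 1.0
        elif self.kind == "rect":
            inside = (np.abs(rr - cr) <= hr) & (np.abs(cc_idx - cc) <= hc)
        else:
            raise ValueError(f"unknown organ shape kind {self.kind!r}")
        labels[inside] = value


@dataclass(frozen=True)
class EndoFeature:
    """One endogenous metabolite channel of the phantom panel."""

    mz: float
    base_level: float
    kind: str  # "matrix" (tracks the matrix factor) | "marker" (organ-specific)
    marker_log_sd: float = 1.0  # several-fold between-organ differences
    marker_cv: float = 0.25     # within-organ pixel noise


def default_organs() -> list[OrganShape]:
    """Eight sagittal-section regions with matrix factors spanning 0.2-1.0.

    Matrix factors are deliberately non-monotone in paint order; the 5-fold
    spread mirrors the tissue-to-tissue response differences that make
    uncalibrated MSI intensities misrepresent concentration.  Region areas
    are kept within roughly a factor of five of each other so every organ
    contributes enough pixels for stable per-organ statistics at desk scale.
    """
    return [
        OrganShape("muscle", "rect", (0.85, 0.50), (0.09, 0.42), 0.75),
        OrganShape("brain", "ellipse", (0.24, 0.09), (0.16, 0.105), 0.90),
        OrganShape("lung", "ellipse", (0.35, 0.30), (0.14, 0.095), 0.45),
        OrganShape("heart", "ellipse", (0.58, 0.27), (0.12, 0.08), 1.00),
        OrganShape("liver", "ellipse", (0.45, 0.48), (0.16, 0.11), 0.20),
        OrganShape("spleen", "rect", (0.24, 0.55), (0.11, 0.065), 0.35),
        OrganShape("kidney", "ellipse", (0.52, 0.68), (0.13, 0.075), 0.30),
        OrganShape("tumor", "ellipse", (0.22, 0.85), (0.16, 0.105), 0.55),
    ]


def default_panel(n_matrix: int = 10, n_marker: int = 10) -> list[EndoFeature]:
    """Endogenous panel: ``n_matrix`` matrix-tracking features and
    ``n_marker`` tissue-marker distractors at distinct metabolite-range m/z."""
    feats = []
    for j in range(n_matrix + n_marker):
        mz = 150.0 + 35.0 * j + 0.0517 * j  # spaced >> 10 ppm, clear of the drug
        kind = "matrix" if j < n_matrix else "marker"
        feats.append(EndoFeature(mz=round(mz, 4), base_level=1000.0, kind=kind))
    return feats


@dataclass
class PhantomSpec:
    """Study conditions for the synthetic whole-body section."""

    shape: tuple[int, int] = (60, 120)
    organs: list[OrganShape] = field(default_factory=default_organs)
    endo_panel: list[EndoFeature] = field(default_factory=default_panel)
    feature_rcf_correlation: float = 0.7
    drug_mz: float = PTX_MZ
    sensitivity: float = 1000.0  # counts per (pmol/mm^2) at matrix factor 1
    noise_sigma: float = 0.15   # log-scale sigma of multiplicative noise
    noise_floor: float = 5.0    # additive uniform [0, floor) counts per channel
    mz_jitter_ppm: float = 1.5  # centroid mass wobble (1 sigma)
    pixel_pitch: tuple[float, float] = (150.0, 500.0)
    seed: int = 7

    def __post_init__(self) -> None:
        names = [o.name for o in self.organs]
        if len(set(names)) != len(names):
            raise ValueError("organ names must be unique")
        if any(o.matrix_factor <= 0 for o in self.organs):
            raise ValueError("matrix factors must be positive")
        if not 0.0 <= self.feature_rcf_correlation <= 1.0:
            raise ValueError("feature_rcf_correlation must be in [0, 1]")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")

    @property
    def organ_names(self) -> list[str]:
        return [o.name for o in self.organs]

    def matrix_factors(self) -> dict[str, float]:
        return {o.name: o.matrix_factor for o in self.organs}

    def label_map(self) -> LabelMap:
        labels = np.zeros(self.shape, dtype=int)
        for i, organ in enumerate(self.organs, start=1):
            organ.paint(labels, i)
        names = {i: o.name for i, o in enumerate(self.organs, start=1)}
        return LabelMap(labels=labels, names=names)


# PTX dilution series of the mimetic standard-curve model (pmol/mm^2)
PTX_SERIES = (0.89, 1.78, 4.45, 8.9, 13.35, 17.8, 35.6, 71.2)
# PTX-R dilution series (pmol/mm^2)
PTXR_SERIES = (0.079, 0.158, 0.79, 1.58, 3.95, 7.9, 15.8, 31.6)


@dataclass
class MimeticModelSpec:
    """Spotted-standard array: tissue-homogenate spots with known drug amount.

    ``concentrations`` is a scalar for the equal-concentration variant or a
    strictly positive series for the dilution-curve variant; in the latter
    case every concentration is spotted in every tissue type so the pooled
    curve spans the full matrix-factor spread at each level.
    """

    tissue_types: Sequence[str] | None = None  # default: all phantom organs
    concentrations: float | Sequence[float] = PTX_SERIES
    replicates: int = 8           # spots per tissue (equal-concentration variant)
    spot_radius: int = 3          # pixels
    spot_spacing: int = 8         # pixels between spot centers
    drug_mz: float = PTX_MZ
    seed: int = 11

    @property
    def is_equal_concentration(self) -> bool:
        return np.isscalar(self.concentrations)

    def concentration_list(self) -> list[float]:
        if self.is_equal_concentration:
            return [float(self.concentrations)]
        return [float(c) for c in self.concentrations]


@dataclass
class GroundTruth:
    """Per-pixel truth emitted alongside every synthetic grid."""

    conc_map: np.ndarray   # pmol/mm^2
    rcf_map: np.ndarray    # raw matrix factor; 0 on background
    labels: LabelMap

    def __post_init__(self) -> None:
        if np.any(self.conc_map < 0):
            raise ValueError("conc_map must be non-negative")
        tissue = self.labels.labels > 0
        if np.any(self.rcf_map[tissue] <= 0) or np.any(self.rcf_map[~tissue] != 0):
            raise ValueError("rcf_map must be positive on tissue and 0 on background")

    def tissue_mask(self) -> np.ndarray:
        return self.labels.labels > 0


# ---------------------------------------------------------------------------
# Panel parameterization shared by phantom and mimetic generators
# ---------------------------------------------------------------------------

def _panel_params(spec: PhantomSpec) -> dict:
    """Per-feature per-organ means and log-noise sigmas.

    Matrix-kind features get per-organ means proportional to the matrix
    factor; their within-organ lognormal noise is solved so the pixelwise
    Pearson correlation with the matrix-factor map over the phantom's tissue
    pixels equals ``spec.feature_rcf_correlation``.  Marker features draw
    independent per-organ means from a seeded stream so the same panel is
    reproduced in every dataset derived from the spec.
    """
    labels = spec.label_map()
    mf = spec.matrix_factors()
    mf_pix = np.array([mf[labels.names[l]] for l in labels.labels[labels.labels > 0]])
    mu, var = float(mf_pix.mean()), float(mf_pix.var())
    second = var + mu * mu
    r = spec.feature_rcf_correlation
    if r > 0 and var > 0:
        v_rel = var * (1.0 / r**2 - 1.0) / second
    else:
        v_rel = None  # r == 0: matrix features become flat + free noise
    rng = np.random.default_rng([int(spec.seed), 9001])
    names = spec.organ_names
    means: list[dict[str, float]] = []
    sigmas: list[float] = []
    for feat in spec.endo_panel:
        if feat.kind == "matrix":
            if v_rel is None:
                m = {n: feat.base_level for n in names}
                sig = math.sqrt(math.log(1.0 + feat.marker_cv**2))
            else:
                m = {n: feat.base_level * mf[n] / mu for n in names}
                sig = math.sqrt(math.log(1.0 + v_rel))
            rng.normal(size=len(names))  # keep marker stream aligned
        elif feat.kind == "marker":
            draws = rng.normal(0.0, feat.marker_log_sd, size=len(names))
            m = {n: feat.base_level * math.exp(d) for n, d in zip(names, draws)}
            sig = math.sqrt(math.log(1.0 + feat.marker_cv**2))
        else:
            raise ValueError(f"unknown feature kind {feat.kind!r}")
        means.append(m)
        sigmas.append(sig)
    return {"means": means, "sigmas": sigmas}


def _emit_grid(spec: PhantomSpec, labels: LabelMap, mf_map: np.ndarray,
               conc_map: np.ndarray, drug_mz: float, rng: np.random.Generator,
               pixel_pitch: tuple[float, float]) -> SpectrumGrid:
    """Materialize peak lists for every tissue (and noisy background) pixel."""
    panel = _panel_params(spec)
    panel_mzs = np.array([f.mz for f in spec.endo_panel])
    all_mzs = np.append(panel_mzs, drug_mz)
    order = np.argsort(all_mzs)
    n_chan = all_mzs.size
    shape = labels.shape
    tissue = labels.labels > 0
    # background pixels are emitted only when they carry a noise floor
    coords = np.argwhere(np.ones(shape, dtype=bool) if spec.noise_floor > 0 else tissue)

    pixels: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    jitter_sigma = spec.mz_jitter_ppm * 1e-6
    for r, c in coords:
        lab = labels.labels[r, c]
        inten = np.zeros(n_chan)
        if lab > 0:
            organ = labels.names[lab]
            for j in range(panel_mzs.size):
                mean = panel["means"][j][organ]
                sig = panel["sigmas"][j]
                inten[j] = mean * math.exp(sig * rng.standard_normal() - 0.5 * sig * sig)
            conc = conc_map[r, c]
            if conc > 0:
                eps = math.exp(spec.noise_sigma * rng.standard_normal())
                inten[-1] = spec.sensitivity * mf_map[r, c] * conc * eps
        if spec.noise_floor > 0:
            inten += rng.uniform(0.0, spec.noise_floor, size=n_chan)
        keep = inten > 0
        if not keep.any():
            continue
        mzs = all_mzs.copy()
        if jitter_sigma > 0:
            mzs = mzs * (1.0 + jitter_sigma * rng.standard_normal(n_chan))
        sel = order[keep[order]]
        pixels[(int(r), int(c))] = (mzs[sel], inten[sel])
    return SpectrumGrid(shape=shape, pixels=pixels, pixel_pitch=pixel_pitch,
                        polarity="positive",
                        metadata={"synthetic": True, "drug_mz": drug_mz})


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec,
                     drug_conc_by_organ: Mapping[str, float] | None = None,
                     seed: int | None = None) -> tuple[SpectrumGrid, GroundTruth]:
    """Whole-body phantom with drug spiked per organ (pmol/mm^2)."""
    drug_conc_by_organ = dict(drug_conc_by_organ or {})
    unknown = set(drug_conc_by_organ) - set(spec.organ_names)
    if unknown:
        raise ValueError(f"unknown organs in drug_conc_by_organ: {sorted(unknown)}")
    labels = spec.label_map()
    mf = spec.matrix_factors()
    mf_map = np.zeros(spec.shape)
    conc_map = np.zeros(spec.shape)
    for lab, name in labels.names.items():
        sel = labels.labels == lab
        mf_map[sel] = mf[name]
        conc_map[sel] = drug_conc_by_organ.get(name, 0.0)
    rng = np.random.default_rng([int(seed if seed is not None else spec.seed), 1])
    grid = _emit_grid(spec, labels, mf_map, conc_map, spec.drug_mz, rng,
                      spec.pixel_pitch)
    truth = GroundTruth(conc_map=conc_map, rcf_map=mf_map, labels=labels)
    return grid, truth


def _spot_centers(n_rows: int, n_cols: int, spacing: int) -> np.ndarray:
    offs = spacing // 2
    centers = [(offs + i * spacing, offs + j * spacing)
               for i in range(n_rows) for j in range(n_cols)]
    return np.array(centers)


def generate_mimetic_model(spec: MimeticModelSpec,
                           phantom: PhantomSpec) -> tuple[SpectrumGrid, GroundTruth]:
    """Spotted mimetic tissue model sharing the phantom's panel statistics.

    Spot layout: dilution-series variant puts concentration level i in row i
    and tissue type j in column j (full conc x tissue grid); the
    equal-concentration variant puts replicate i in row i.
    """
    tissue_types = list(spec.tissue_types or phantom.organ_names)
    missing = set(tissue_types) - set(phantom.organ_names)
    if missing:
        raise ValueError(f"tissue types not in phantom: {sorted(missing)}")
    concs = spec.concentration_list()
    if any(c < 0 for c in concs):
        raise ValueError("concentrations must be non-negative")
    n_rows = spec.replicates if spec.is_equal_concentration else len(concs)
    n_cols = len(tissue_types)
    if spec.spot_spacing < 2 * spec.spot_radius + 1:
        raise ValueError("spot layout overlaps: spacing must exceed spot diameter")
    centers = _spot_centers(n_rows, n_cols, spec.spot_spacing)
    shape = (n_rows * spec.spot_spacing, n_cols * spec.spot_spacing)

    labels_arr = np.zeros(shape, dtype=int)
    conc_map = np.zeros(shape)
    mf_map = np.zeros(shape)
    mf = phantom.matrix_factors()
    names = {j + 1: t for j, t in enumerate(tissue_types)}
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for idx, (cr, ccol) in enumerate(centers):
        i, j = divmod(idx, n_cols)
        tissue = tissue_types[j]
        conc = concs[0] if spec.is_equal_concentration else concs[i]
        inside = (rr - cr) ** 2 + (cc - ccol) ** 2 <= spec.spot_radius ** 2
        labels_arr[inside] = j + 1
        conc_map[inside] = conc
        mf_map[inside] = mf[tissue]
    labels = LabelMap(labels=labels_arr, names=names)

    rng = np.random.default_rng([int(spec.seed), 2])
    # reuse the phantom emission rule on the spot geometry
    spot_phantom = replace(phantom, shape=shape)
    grid = _emit_grid(spot_phantom, labels, mf_map, conc_map, spec.drug_mz, rng,
                      phantom.pixel_pitch)
    truth = GroundTruth(conc_map=conc_map, rcf_map=mf_map, labels=labels)
    return grid, truth


def generate_timecourse(phantom: PhantomSpec, times: Sequence[float],
                        pk: Mapping[str, tuple[float, float]],
                        base_seed: int | None = None,
                        ) -> list[tuple[float, SpectrumGrid, GroundTruth]]:
    """One phantom per time with conc(organ, t) = C0 * exp(-ke * t).

    ``pk`` maps organ name to ``(C0 pmol/mm^2, ke per hour)``.  Each time
    point gets a fresh seed derived from the base seed.
    """
    times = [float(t) for t in times]
    if any(t < 0 for t in times):
        raise ValueError("times must be non-negative")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    for organ, (c0, ke) in pk.items():
        if ke < 0:
            raise ValueError(f"negative elimination rate for {organ}")
    base = int(base_seed if base_seed is not None else phantom.seed)
    out = []
    for i, t in enumerate(times):
        conc = {organ: c0 * math.exp(-ke * t) for organ, (c0, ke) in pk.items()}
        seed_i = (base * 10007 + 17 * i + 3) % (2**31)
        grid, truth = generate_phantom(phantom, conc, seed=seed_i)
        out.append((t, grid, truth))
    return out
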