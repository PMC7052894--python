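"""Core MSI data model: pixel-indexed centroided spectra, imzML I/O,
ion-image extraction within ppm windows, and per-region summaries.

The in-memory container is :class:`SpectrumGrid`, a sparse row-major grid of
centroided peak lists.  Ion images are extracted by aggregating peak
intensities inside a relative mass window ``|mz - target|/target <= tol_ppm
* 1e-6``; summation is the default aggregation because it keeps the image
linear in the underlying peak intensities, which the downstream calibration
model relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumGrid",
    "IonImage",
    "LabelMap",
    "FeatureTable",
    "read_imzml",
    "write_imzml",
    "extract_ion_image",
    "build_feature_table",
    "tissue_mask",
    "region_stats",
    "export_image_csv",
    "export_image_png",
]

Coord = tuple[int, int]


@dataclass
class SpectrumGrid:
    """Sparse grid of centroided spectra.

    Parameters
    ----------
    shape:
        ``(rows, cols)`` of the pixel raster.
    pixels:
        Mapping from 0-based ``(row, col)`` to a ``(mz, intensity)`` pair of
        1-D arrays.  m/z values are strictly ascending within a pixel and
        intensities are non-negative.
    pixel_pitch:
        ``(x, y)`` pixel spacing in micrometres.  The default (150, 500)
        matches an AFADESI stage scanning ~150 um laterally with a 500 um
        line step.
    """

    shape: tuple[int, int]
    pixels: dict[Coord, tuple[np.ndarray, np.ndarray]]
    pixel_pitch: tuple[float, float] = (150.0, 500.0)
    polarity: str = "positive"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        rows, cols = self.shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"grid shape must be positive, got {self.shape}")
        if self.pixel_pitch[0] <= 0 or self.pixel_pitch[1] <= 0:
            raise ValueError(f"pixel pitch must be positive, got {self.pixel_pitch}")
        for (r, c), (mz, inten) in self.pixels.items():
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"pixel {(r, c)} outside grid {self.shape}")
            mz = np.asarray(mz, dtype=float)
            inten = np.asarray(inten, dtype=float)
            if mz.shape != inten.shape:
                raise ValueError(f"pixel {(r, c)}: m/z and intensity length mismatch")
            if mz.size > 1 and not np.all(np.diff(mz) > 0):
                raise ValueError(f"pixel {(r, c)}: m/z not strictly ascending")
            if np.any(inten < 0):
                raise ValueError(f"pixel {(r, c)}: negative intensity")
            self.pixels[(r, c)] = (mz, inten)

    @property
    def pixel_area_mm2(self) -> float:
        """Area of one pixel cell in mm^2 (pitch is in um)."""
        return self.pixel_pitch[0] * self.pixel_pitch[1] * 1e-6

    def occupied(self) -> list[Coord]:
        return sorted(self.pixels.keys())

    def tic_image(self) -> np.ndarray:
        """Total ion current per pixel; unoccupied pixels are 0."""
        tic = np.zeros(self.shape)
        for (r, c), (_, inten) in self.pixels.items():
            tic[r, c] = inten.sum()
        return tic

    def occupancy_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for r, c in self.pixels:
            m[r, c] = True
        return m


@dataclass
class IonImage:
    """Single-channel image of aggregated intensity around ``target_mz``."""

    target_mz: float
    tol_ppm: float
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if np.any(self.values < 0):
            raise ValueError("ion image intensities must be non-negative")
        self.values = np.where(self.mask, self.values, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class LabelMap:
    """Integer region labels on the pixel grid; 0 is background."""

    labels: np.ndarray
    names: Mapping[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class FeatureTable:
    """Pixel-by-feature intensity matrix with explicit pixel coordinates."""

    feature_mzs: np.ndarray
    matrix: np.ndarray
    pixel_index: np.ndarray  # (n_pixels, 2) of (row, col)

    def __post_init__(self) -> None:
        self.feature_mzs = np.asarray(self.feature_mzs, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.pixel_index = np.asarray(self.pixel_index, dtype=int)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.feature_mzs.size:
            raise ValueError("matrix column count must equal number of features")
        if self.pixel_index.shape != (self.matrix.shape[0], 2):
            raise ValueError("pixel_index must be (n_pixels, 2)")
        if np.any(self.matrix < 0):
            raise ValueError("feature intensities must be non-negative")
        keys = {tuple(rc) for rc in self.pixel_index}
        if len(keys) != len(self.pixel_index):
            raise ValueError("duplicate pixel coordinates in pixel_index")

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[0]

    def column(self, j: int) -> np.ndarray:
        return self.matrix[:, j]

    def select(self, keep: np.ndarray) -> "FeatureTable":
        """Subset of feature columns (boolean or integer indexer)."""
        keep = np.asarray(keep)
        return FeatureTable(self.feature_mzs[keep], self.matrix[:, keep], self.pixel_index)


# ---------------------------------------------------------------------------
# imzML I/O (processed mode, via pyimzml)
# ---------------------------------------------------------------------------

def write_imzml(grid: SpectrumGrid, path: str | Path) -> None:
    """Write a grid to an imzML/ibd pair (processed mode, centroid spectra).

    Pixel pitch is not representable by the writer and must be re-supplied
    on read.  A spectrum with zero peaks denotes an unoccupied pixel: a grid
    with no occupied pixels is serialized as one peakless placeholder
    spectrum, and :func:`read_imzml` skips peakless spectra.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    try:
        with ImzMLWriter(str(path), mode="processed", polarity=grid.polarity) as w:
            occupied = grid.occupied()
            for (r, c) in occupied:
                mz, inten = grid.pixels[(r, c)]
                # imzML coordinates are 1-based (x, y)
                w.addSpectrum(np.asarray(mz, dtype=float),
                              np.asarray(inten, dtype=float), (c + 1, r + 1, 1))
            if not occupied:
                w.addSpectrum(np.array([1.0]), np.array([0.0]), (1, 1, 1))
    except OSError as exc:
        raise OSError(f"cannot write imzML to {path}: {exc}") from exc


def read_imzml(path: str | Path,
               pixel_pitch: tuple[float, float] = (150.0, 500.0),
               shape: tuple[int, int] | None = None) -> SpectrumGrid:
    """Read an imzML/ibd pair into a :class:`SpectrumGrid`.

    Coordinates are mapped to a 0-based row-major grid; the grid shape is the
    coordinate bounding box unless ``shape`` is given.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise OSError(f"imzML file not found: {path}")
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # pyimzml raises various parse errors
        raise OSError(f"cannot parse imzML file {path}: {exc}") from exc

    pixels: dict[Coord, tuple[np.ndarray, np.ndarray]] = {}
    max_r = max_c = 0
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        if mz.size == 0 or not np.any(inten > 0):
            # peakless/zero-intensity spectra denote unoccupied pixels
            continue
        if np.any(inten < 0):
            raise ValueError(f"negative intensity in spectrum {i} of {path}")
        order = np.argsort(mz, kind="stable")
        r, c = int(y) - 1, int(x) - 1
        pixels[(r, c)] = (mz[order], inten[order])
        max_r, max_c = max(max_r, r), max(max_c, c)
    if shape is None:
        shape = (max_r + 1, max_c + 1) if pixels else (1, 1)
    polarity = getattr(parser, "polarity", None) or "positive"
    return SpectrumGrid(shape=shape, pixels=pixels, pixel_pitch=pixel_pitch,
                        polarity=polarity, metadata={"source": str(path)})


# ---------------------------------------------------------------------------
# Ion-image extraction and feature tables
# ---------------------------------------------------------------------------

def _aggregate(inten: np.ndarray, how: str) -> float:
    if how == "sum":
        return float(inten.sum())
    if how == "max":
        return float(inten.max())
    raise ValueError(f"unknown aggregation {how!r}; use 'sum' or 'max'")


def extract_ion_image(grid: SpectrumGrid, target_mz: float, tol_ppm: float = 10.0,
                      aggregation: str = "sum",
                      mask: np.ndarray | None = None) -> IonImage:
    """Aggregate peak intensities within ``tol_ppm`` of ``target_mz`` per pixel.

    Pixels with no peak in the window get 0.  ``mask`` restricts the image to
    tissue pixels (default: every occupied pixel).
    """
    if target_mz <= 0:
        raise ValueError(f"target_mz must be positive, got {target_mz}")
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be positive, got {tol_ppm}")
    if aggregation not in ("sum", "max"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if mask is None:
        mask = grid.occupancy_mask()
    half = target_mz * tol_ppm * 1e-6
    lo, hi = target_mz - half, target_mz + half
    values = np.zeros(grid.shape)
    for (r, c), (mz, inten) in grid.pixels.items():
        if not mask[r, c] or mz.size == 0:
            continue
        i0 = int(np.searchsorted(mz, lo, side="left"))
        i1 = int(np.searchsorted(mz, hi, side="right"))
        if i1 > i0:
            values[r, c] = _aggregate(inten[i0:i1], aggregation)
    return IonImage(target_mz=target_mz, tol_ppm=tol_ppm, values=values, mask=mask)


def build_feature_table(grid: SpectrumGrid, feature_mzs: Iterable[float],
                        tol_ppm: float = 10.0,
                        mask: np.ndarray | None = None) -> FeatureTable:
    """Stack masked ion images of ``feature_mzs`` into a pixel x feature matrix."""
    feature_mzs = np.asarray(list(feature_mzs), dtype=float)
    if feature_mzs.size == 0:
        raise ValueError("feature_mzs must be non-empty")
    if mask is None:
        mask = grid.occupancy_mask()
    coords = np.argwhere(mask)
    cols = []
    for mz in feature_mzs:
        img = extract_ion_image(grid, mz, tol_ppm=tol_ppm, aggregation="sum", mask=mask)
        cols.append(img.values[mask.astype(bool)])
    matrix = np.column_stack(cols) if coords.size else np.zeros((0, feature_mzs.size))
    return FeatureTable(feature_mzs=feature_mzs, matrix=matrix, pixel_index=coords)


def tissue_mask(grid: SpectrumGrid, tic_quantile: float = 0.05) -> np.ndarray:
    """Occupied pixels whose TIC exceeds the given quantile of occupied TICs.

    A crude tissue/background separator: background pixels carry only the
    instrument noise floor and sit in the low tail of the TIC distribution.
    """
    if not 0 <= tic_quantile < 1:
        raise ValueError("tic_quantile must be in [0, 1)")
    occ = grid.occupancy_mask()
    tic = grid.tic_image()
    vals = tic[occ]
    if vals.size == 0:
        return occ
    thr = np.quantile(vals, tic_quantile)
    return occ & (tic > thr)


# ---------------------------------------------------------------------------
# Region summaries
# ---------------------------------------------------------------------------

def region_stats(image, labels: LabelMap) -> pd.DataFrame:
    """Mean, SEM and pixel count of ``image`` per labeled region.

    ``image`` may be an IonImage/QuantMap (anything with ``.values``) or a
    bare 2-D array.  Every named label appears in the output, including ones
    with zero pixels (flagged by ``n == 0`` and NaN mean).
    """
    values = np.asarray(getattr(image, "values", image), dtype=float)
    if values.shape != labels.shape:
        raise ValueError(f"image shape {values.shape} != labels shape {labels.shape}")
    rows = []
    for label, name in sorted(labels.names.items()):
        sel = values[labels.labels == label]
        n = int(sel.size)
        if n == 0:
            mean = sem = float("nan")
        else:
            mean = float(sel.mean())
            sem = float(sel.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append({"label": label, "name": name, "mean": mean, "sem": sem, "n": n})
    return pd.DataFrame(rows).set_index("name")


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def _provenance_sidecar(path: Path, provenance: dict) -> None:
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)


def export_image_csv(image, path: str | Path, provenance: dict | None = None) -> None:
    """Write an image as a dense CSV matrix plus a JSON provenance sidecar."""
    path = Path(path)
    values = np.asarray(getattr(image, "values", image), dtype=float)
    np.savetxt(path, values, delimiter=",")
    meta = dict(provenance or {})
    if hasattr(image, "target_mz"):
        meta.setdefault("target_mz", image.target_mz)
        meta.setdefault("tol_ppm", image.tol_ppm)
    _provenance_sidecar(path, meta)


def export_image_png(image, path: str | Path, cmap: str = "viridis",
                     colorbar_label: str = "", provenance: dict | None = None) -> None:
    """Render an image to PNG with a colorbar."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    values = np.asarray(getattr(image, "values", image), dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(values, cmap=cmap, interpolation="nearest")
    fig.colorbar(im, ax=ax, label=colorbar_label)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    _provenance_sidecar(path, dict(provenance or {}))
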