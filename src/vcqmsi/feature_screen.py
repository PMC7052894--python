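"""Selection of natural internal standards.

Endogenous metabolite channels whose intensities track the local matrix
effect are identified by their Pearson correlation with the drug signal
across the pixels of the equal-concentration mimetic model, where intensity
variation reflects matrix effect rather than dose.  Features with r strictly
above the threshold (default 0.4) are selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msi_data import FeatureTable

__all__ = ["ScreenResult", "pearson_screen"]


@dataclass
class ScreenResult:
    feature_mzs: np.ndarray
    r: np.ndarray          # NaN where undefined (zero-variance column)
    selected: np.ndarray   # bool; defined r strictly above threshold
    threshold: float

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature_mz": self.feature_mzs, "r": self.r,
                             "selected": self.selected})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def pearson_screen(features: FeatureTable, drug: np.ndarray,
                   threshold: float = 0.4, log_transform: bool = False,
                   ) -> ScreenResult:
    """Per-feature product-moment correlation with the drug intensity vector.

    Constant (zero-variance) feature columns, or a constant drug vector,
    yield undefined r (NaN) and are never selected.  Selection uses a strict
    inequality, so ties at exactly the threshold are excluded.
    """
    drug = np.asarray(drug, dtype=float)
    if drug.ndim != 1 or features.n_pixels != drug.size:
        raise ValueError(
            f"drug vector length {drug.size} != feature rows {features.n_pixels}")
    if drug.size < 3:
        raise ValueError(f"need at least 3 pixels, got {drug.size}")
    X = features.matrix.astype(float)
    if log_transform:
        X = np.log1p(X)
        drug = np.log1p(drug)
    Xc = X - X.mean(axis=0)
    yc = drug - drug.mean()
    sx = np.sqrt((Xc * Xc).sum(axis=0))
    sy = np.sqrt((yc * yc).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r = np.where((sx == 0) | (sy == 0), np.nan, r)
    selected = np.where(np.isnan(r), False, r > threshold)
    return ScreenResult(feature_mzs=features.feature_mzs.copy(), r=r,
                        selected=selected, threshold=threshold)
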