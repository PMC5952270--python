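"""Statistical total correlation spectroscopy (STOCSY).

Resonances of one molecule rise and fall together across samples, so
correlating a driver variable against every other spectral variable
lights up that molecule's whole multiplet pattern (|r| → 1) while
independently varying metabolites stay near zero.  Run on normalized
but unscaled data: Pearson r is scale-free and the covariance trace
keeps the spectral shape for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import BinnedMatrix, SpectralMatrix


@dataclass
class StocsyResult:
    driver_ppm: float            # center of the variable actually used
    requested_ppm: float
    ppm: np.ndarray
    correlation: np.ndarray
    covariance: np.ndarray
    r_threshold: float

    @property
    def connected(self) -> np.ndarray:
        return np.abs(self.correlation) >= self.r_threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ppm": self.ppm,
            "correlation": self.correlation,
            "covariance": self.covariance,
            "connected": self.connected,
        })


def run_stocsy(B, driver_ppm: float, r_threshold: float = 0.8) -> StocsyResult:
    """Correlate the variable nearest ``driver_ppm`` against all
    variables of a normalized (unscaled) binned or spectral matrix."""
    if isinstance(B, BinnedMatrix):
        if B.scaled:
            raise ValueError("STOCSY runs on normalized, unscaled data")
        centers, X = B.centers, B.data
    elif isinstance(B, SpectralMatrix):
        centers, X = B.ppm, B.data
    else:
        raise TypeError("expected BinnedMatrix or SpectralMatrix")
    if X.shape[0] < 3:
        raise ValueError("STOCSY needs at least 3 samples")
    if not (0.0 < r_threshold <= 1.0):
        raise ValueError("r_threshold must be in (0, 1]")

    j = int(np.argmin(np.abs(centers - driver_ppm)))
    d = X[:, j]
    if d.std(ddof=1) == 0:
        raise ValueError(
            f"driver variable at {centers[j]:.3f} ppm has zero variance")

    n = X.shape[0]
    dc = d - d.mean()
    Xc = X - X.mean(axis=0)
    cov = (dc @ Xc) / (n - 1)
    sd = Xc.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / (dc.std(ddof=1) * np.where(sd == 0, np.nan, sd))
    corr = np.nan_to_num(corr, nan=0.0)
    return StocsyResult(driver_ppm=float(centers[j]),
                        requested_ppm=float(driver_ppm),
                        ppm=centers.copy(), correlation=corr,
                        covariance=cov, r_threshold=r_threshold)
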