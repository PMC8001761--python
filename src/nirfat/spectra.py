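"""NIR scan calibration, 10 nm binning and wavelength-ratio features.

Raw scans are calibrated against dark and light reference scans to percent
reflectance, averaged over duplicate measurements, binned to a 25-point
10 nm grid spanning 850-1090 nm, and expanded into the 300 unordered
wavelength-pair ratio features (lower/higher wavelength, in percent) used
by the fat-mass model. The 850-1090 nm grid is the unique 25-point reading
of the stated range that yields C(25,2) = 300 features; scan content below
850 nm is read and ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import CoverageError, DegenerateReferenceError, ModelDomainError

__all__ = [
    "SITES",
    "GRID_NM",
    "SpectralScan",
    "BinnedReflectance",
    "calibrate_reflectance",
    "bin_to_grid",
    "ratio_features",
    "ratio_pairs",
    "feature_name",
    "build_feature_matrix",
    "RatioFeaturizer",
]

SITES = ("triceps", "subscapular", "thigh", "flank")

#: 25-point analysis grid, 850-1090 nm inclusive, 10 nm step
GRID_NM = np.arange(850, 1091, 10)
_BIN_HALF_WIDTH = 5.0  # half-open [g-5, g+5) windows


@dataclass
class SpectralScan:
    """Raw intensity counts with dark/light references at one site."""

    subject_id: str
    site: str
    wavelengths: np.ndarray
    raw: np.ndarray
    dark: np.ndarray
    light: np.ndarray

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ModelDomainError(f"unknown site {self.site!r}; expected one of {SITES}")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        for name in ("raw", "dark", "light"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.wavelengths.shape:
                raise ModelDomainError(f"{name} length does not match wavelengths")
            setattr(self, name, arr)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ModelDomainError("wavelengths must be strictly increasing")


@dataclass
class BinnedReflectance:
    """Percent reflectance on the 25-point analysis grid."""

    grid: np.ndarray
    reflectance_pct: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.reflectance_pct = np.asarray(self.reflectance_pct, dtype=float)
        if self.grid.shape != self.reflectance_pct.shape:
            raise ModelDomainError("grid and reflectance lengths differ")
        if not np.all(np.isfinite(self.reflectance_pct)) or np.any(self.reflectance_pct <= 0):
            raise ModelDomainError("reflectance_pct must be finite and > 0")


def calibrate_reflectance(scan: SpectralScan, analysis_range=(845.0, 1095.0)) -> np.ndarray:
    """Percent reflectance: 100*(raw - dark)/(light - dark) per wavelength.

    A light reference equal to the dark reference within the analysis range
    means the calibration is undefined there and raises.
    """
    span = scan.light - scan.dark
    in_analysis = (scan.wavelengths >= analysis_range[0]) & (scan.wavelengths < analysis_range[1])
    if np.any(span[in_analysis] == 0):
        raise DegenerateReferenceError("light reference equals dark reference in analysis range")
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = 100.0 * (scan.raw - scan.dark) / span
    return refl


def bin_to_grid(reflectance: np.ndarray, wavelengths: np.ndarray, grid=GRID_NM) -> BinnedReflectance:
    """Average reflectance over half-open 10 nm windows centred on the grid."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    reflectance = np.asarray(reflectance, dtype=float)
    grid = np.asarray(grid, dtype=float)
    values = np.empty_like(grid)
    for i, g in enumerate(grid):
        mask = (wavelengths >= g - _BIN_HALF_WIDTH) & (wavelengths < g + _BIN_HALF_WIDTH)
        if not mask.any():
            raise CoverageError(f"empty bin at {g:.0f} nm")
        values[i] = reflectance[mask].mean()
    return BinnedReflectance(grid=grid, reflectance_pct=values)


def ratio_pairs(grid=GRID_NM) -> list[tuple[int, int]]:
    """All unordered wavelength pairs, lower wavelength first."""
    return list(combinations([int(g) for g in np.asarray(grid)], 2))


def feature_name(site: str, lo: int, hi: int) -> str:
    return f"{site}_{lo}_{hi}"


def ratio_features(binned: BinnedReflectance) -> dict[tuple[int, int], float]:
    """100*R(lower)/R(higher) for every unordered pair of grid wavelengths.

    On the full 25-point grid this is exactly 300 features.
    """
    grid = [int(g) for g in binned.grid]
    refl = dict(zip(grid, binned.reflectance_pct))
    out = {}
    for lo, hi in combinations(grid, 2):
        if refl[hi] == 0:
            raise ModelDomainError(f"zero reflectance at {hi} nm: ratio undefined")
        out[(lo, hi)] = 100.0 * refl[lo] / refl[hi]
    return out


def _scans_from_long(spectra: pd.DataFrame):
    """Iterate SpectralScan objects from a long-format spectra table."""
    group_cols = ["subject_id", "site"]
    if "replicate" in spectra.columns:
        group_cols.append("replicate")
    for key, grp in spectra.groupby(group_cols, sort=True, observed=True):
        grp = grp.sort_values("wavelength_nm")
        yield SpectralScan(
            subject_id=str(key[0]),
            site=str(key[1]),
            wavelengths=grp["wavelength_nm"].to_numpy(),
            raw=grp["raw"].to_numpy(),
            dark=grp["dark"].to_numpy(),
            light=grp["light"].to_numpy(),
        )


def build_feature_matrix(spectra: pd.DataFrame, grid=GRID_NM) -> pd.DataFrame:
    """Subject x (site-ratio) feature matrix from long-format spectra.

    Duplicate scans (same subject and site) are averaged after calibration,
    mirroring the duplicate-measurement protocol. Columns are named
    ``{site}_{lo}_{hi}``; the index is subject_id.
    """
    per_subject_site: dict[tuple[str, str], list[np.ndarray]] = {}
    wl_by_key: dict[tuple[str, str], np.ndarray] = {}
    for scan in _scans_from_long(spectra):
        key = (scan.subject_id, scan.site)
        per_subject_site.setdefault(key, []).append(calibrate_reflectance(scan))
        wl_by_key[key] = scan.wavelengths

    rows: dict[str, dict[str, float]] = {}
    for (sid, site), refls in per_subject_site.items():
        mean_refl = np.mean(refls, axis=0)
        binned = bin_to_grid(mean_refl, wl_by_key[(sid, site)], grid=grid)
        feats = ratio_features(binned)
        row = rows.setdefault(sid, {})
        for (lo, hi), val in feats.items():
            row[feature_name(site, lo, hi)] = val
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "subject_id"
    return out[sorted(out.columns)]


class RatioFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: long-format spectra -> ratio-feature matrix.

    Exposed as an sklearn transformer so the spectral front end composes
    with pipelines; ``fit`` only records the analysis grid.
    """

    def __init__(self, grid=None):
        self.grid = grid

    def fit(self, X: pd.DataFrame, y=None):
        self.grid_ = GRID_NM if self.grid is None else np.asarray(self.grid)
        self.n_features_out_ = len(self.grid_) * (len(self.grid_) - 1) // 2 * len(SITES)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "grid_"):
            self.fit(X)
        return build_feature_matrix(X, grid=self.grid_)
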