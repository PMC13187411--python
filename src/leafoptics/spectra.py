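"""Spectral containers and per-wavelength comparison statistics.

A leaf hyperspectral reflectance (HSR) dataset is a samples x wavelengths
matrix of reflectance fractions in [0, 1], with per-sample metadata.  The
comparison statistics defined here — the per-wavelength mean relative error

    delta_bar(lam) = (1/n) * sum_i |b(lam, i) - a(lam, i)| / |a(lam, i)|,

the per-wavelength Pearson correlation across paired samples, and the
per-wavelength RMSE — quantify how well one spectrum set reproduces another
(e.g. simulated versus measured reflectance).  Contiguous low-correlation
wavebands can be flagged; in measured leaf data these coincide with regions
of very low reflectance where environmental noise dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    DivisionHazardError,
    GridMismatchError,
    InsufficientSamplesError,
    SampleAlignmentError,
    SchemaError,
)

#: metadata columns recognised in spectra tables, in canonical order
META_COLUMNS = ("sample_id", "genotype_id", "environment_id", "replicate_id", "repeat_id")


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing, positive wavelengths in nanometres."""

    wavelengths: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if np.any(wl <= 0):
            raise ValueError("wavelengths must be positive")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """Full 1-nm grid, 400..2450 nm inclusive (2051 points)."""
        return cls(np.arange(400.0, 2451.0))

    @classmethod
    def desk(cls) -> "WavelengthGrid":
        """Coarse 41-nm grid, 400..2450 nm inclusive (51 points).

        Preserves the band geometry of the full grid at a fraction of the
        cost; the default grid for simulation-based tests.
        """
        return cls(np.arange(400.0, 2451.0, 41.0))

    def __len__(self) -> int:
        return self.wavelengths.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.wavelengths, other.wavelengths
        )

    def __hash__(self):
        return hash(self.wavelengths.tobytes())


@dataclass
class SpectralDataset:
    """Samples x wavelengths reflectance matrix plus per-sample metadata.

    ``role`` is a free label (e.g. ``"meas"``, ``"sim"``, ``"re"``) naming the
    dataset's place in a workflow; it is not a subtype.
    """

    grid: WavelengthGrid
    values: np.ndarray
    meta: pd.DataFrame | None = None
    role: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D samples x wavelengths array")
        if v.shape[1] != len(self.grid):
            raise GridMismatchError(
                f"values have {v.shape[1]} columns but grid has {len(self.grid)} wavelengths"
            )
        if v.size and (np.nanmin(v) < 0.0 or np.nanmax(v) > 1.0):
            raise ValueError("reflectance values must lie in [0, 1]")
        self.values = v
        if self.meta is None:
            self.meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(v.shape[0])]})
        if "sample_id" not in self.meta.columns:
            raise SchemaError("metadata must include a sample_id column")
        if len(self.meta) != v.shape[0]:
            raise ValueError("metadata length must equal the number of sample rows")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset(self, rows) -> "SpectralDataset":
        rows = np.asarray(rows)
        return SpectralDataset(
            self.grid, self.values[rows], self.meta.iloc[rows].reset_index(drop=True), self.role
        )


@dataclass
class WavelengthErrorProfile:
    """Per-wavelength error statistics between two paired spectrum sets.

    ``pearson`` is NaN (the undefined marker) wherever either column is
    constant across samples.
    """

    grid: WavelengthGrid
    mean_relative_error: np.ndarray
    pearson: np.ndarray
    rmse: np.ndarray
    n_samples: int

    def __post_init__(self):
        for name in ("mean_relative_error", "pearson", "rmse"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.grid),):
                raise GridMismatchError(f"{name} must have one entry per wavelength")
            setattr(self, name, arr)
        if np.any(self.mean_relative_error < 0) or np.any(self.rmse < 0):
            raise ValueError("error statistics must be nonnegative")


def _check_paired(a: SpectralDataset, b: SpectralDataset) -> None:
    if a.grid != b.grid:
        raise GridMismatchError("datasets are defined on different wavelength grids")
    if a.n_samples != b.n_samples:
        raise ValueError("paired datasets must have the same number of samples")
    # rows are matched by position; silently reordered ids are a hazard
    ia, ib = a.meta["sample_id"].to_numpy(), b.meta["sample_id"].to_numpy()
    if not np.array_equal(ia, ib):
        raise SampleAlignmentError("sample_id ordering differs between paired datasets")


def mean_relative_error_profile(a: SpectralDataset, b: SpectralDataset) -> np.ndarray:
    """Mean relative error of b against a, per wavelength.

    ``a`` plays the measured (denominator) role; the statistic is therefore
    not symmetric in its arguments.
    """
    _check_paired(a, b)
    zero_cols = np.any(a.values == 0.0, axis=0)
    if np.any(zero_cols):
        lam = a.grid.wavelengths[zero_cols][0]
        raise DivisionHazardError(
            f"zero reference reflectance at {lam:g} nm: relative error undefined"
        )
    return np.mean(np.abs(b.values - a.values) / np.abs(a.values), axis=0)


def pearson_profile(a: SpectralDataset, b: SpectralDataset) -> np.ndarray:
    """Pearson correlation across paired samples, per wavelength.

    Returns NaN at wavelengths where either column is constant.
    """
    _check_paired(a, b)
    if a.n_samples < 3:
        raise InsufficientSamplesError("pearson_profile requires at least 3 paired samples")
    xa = a.values - a.values.mean(axis=0)
    xb = b.values - b.values.mean(axis=0)
    sa = np.sqrt(np.sum(xa**2, axis=0))
    sb = np.sqrt(np.sum(xb**2, axis=0))
    defined = (sa > 0) & (sb > 0)
    r = np.full(len(a.grid), np.nan)
    num = np.sum(xa * xb, axis=0)
    r[defined] = num[defined] / (sa[defined] * sb[defined])
    return np.clip(r, -1.0, 1.0, out=r)


def rmse_profile(a: SpectralDataset, b: SpectralDataset) -> np.ndarray:
    """Root mean square difference across paired samples, per wavelength."""
    _check_paired(a, b)
    return np.sqrt(np.mean((b.values - a.values) ** 2, axis=0))


def error_profile(a: SpectralDataset, b: SpectralDataset) -> WavelengthErrorProfile:
    """All three per-wavelength statistics bundled in one profile."""
    return WavelengthErrorProfile(
        grid=a.grid,
        mean_relative_error=mean_relative_error_profile(a, b),
        pearson=pearson_profile(a, b),
        rmse=rmse_profile(a, b),
        n_samples=a.n_samples,
    )


def flag_low_accuracy_bands(
    profile: WavelengthErrorProfile,
    r_threshold: float = 0.8,
    min_width_nm: float = 10.0,
) -> list[tuple[float, float]]:
    """Maximal contiguous wavebands where the Pearson profile is sub-threshold.

    Undefined (NaN) correlations count as sub-threshold: constant columns
    occur exactly where reflectance is pinned near zero, which is the failure
    mode being flagged.  Runs narrower than ``min_width_nm`` are dropped.
    Returns sorted, non-overlapping ``(lambda_start, lambda_end)`` pairs.
    """
    if len(profile.grid) == 0:
        raise ValueError("empty profile")
    if not 0.0 < r_threshold < 1.0:
        raise ValueError("r_threshold must lie in (0, 1)")
    wl = profile.grid.wavelengths
    low = np.isnan(profile.pearson) | (profile.pearson < r_threshold)
    bands: list[tuple[float, float]] = []
    start = None
    for i, flag in enumerate(low):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            bands.append((wl[start], wl[i - 1]))
            start = None
    if start is not None:
        bands.append((wl[start], wl[-1]))
    return [(lo, hi) for lo, hi in bands if hi - lo >= min_width_nm]


# ---------------------------------------------------------------------------
# CSV interface: metadata columns first, then one column per wavelength
# headed by the integer-nm value.


def write_spectra_csv(ds: SpectralDataset, path) -> None:
    """Write a spectra table: metadata columns, then ascending wavelengths."""
    meta_cols = [c for c in META_COLUMNS if c in ds.meta.columns]
    out = ds.meta[meta_cols].copy()
    for j, wl in enumerate(ds.grid.wavelengths):
        header = str(int(wl)) if float(wl).is_integer() else repr(wl)
        out[header] = np.round(ds.values[:, j], 12)
    out.to_csv(path, index=False, float_format="%.9g")


def read_spectra_csv(path, role: str = "") -> SpectralDataset:
    """Read a spectra table, validating the header layout.

    Metadata columns must come first (``sample_id`` mandatory); the remaining
    headers must parse as strictly increasing wavelengths in nm.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: missing mandatory column 'sample_id'")
    meta_cols = [c for c in df.columns if c in META_COLUMNS]
    wl_cols = [c for c in df.columns if c not in META_COLUMNS]
    try:
        wl = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric wavelength header: {exc}") from None
    if wl.size == 0:
        raise SchemaError(f"{path}: no wavelength columns found")
    if np.any(np.diff(wl) <= 0):
        raise SchemaError(f"{path}: wavelength headers must be strictly increasing")
    values = df[wl_cols].to_numpy(dtype=float)
    return SpectralDataset(WavelengthGrid(wl), values, df[meta_cols].copy(), role=role)


def write_error_profile_csv(profile: WavelengthErrorProfile, path) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": profile.grid.wavelengths,
            "mean_relative_error": profile.mean_relative_error,
            "pearson": profile.pearson,
            "rmse": profile.rmse,
        }
    ).to_csv(path, index=False, float_format="%.9g")
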