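"""Reflectance-only inversion of PROSPECT-D and the regeneration cycle.

Inversion estimates the six leaf traits from one measured reflectance
spectrum by bounded nonlinear least squares: the merit function is the RMSE
over wavelengths between the forward-simulated and target reflectance
(transmittance is ignored, the common practice when only reflectance is
measured).  The regeneration cycle chains inversion and forward simulation:

    HSR_meas --invert--> P_inv --forward--> HSR_sim
    HSR_sim  --invert--> P_re  --forward--> HSR_re

Comparing meas vs sim isolates what the forward model cannot represent;
comparing sim vs re isolates pure inversion error, which for spectra on the
model manifold is numerically zero.

The model-fitting surface follows the statsmodels idiom:
``ProspectInversion(dataset, constants).fit()`` returns an
``InversionResults`` object carrying per-sample trait estimates, merits and
diagnostics.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import GridMismatchError, InversionFailure
from .prospect import (
    TRAIT_NAMES,
    LeafTraits,
    OpticalConstants,
    forward_spectrum,
)
from .spectra import SpectralDataset

logger = logging.getLogger(__name__)

#: default per-trait bounds, spanning the ranges of the PROSPECT literature
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "N": (1.0, 4.0),
    "CHL": (0.0, 120.0),
    "CAR": (0.0, 30.0),
    "ANT": (0.0, 40.0),
    "EWT": (0.0, 0.1),
    "LMA": (0.0, 0.05),
}

#: fixed mid-physiological starting point, for reproducible fits
DEFAULT_INIT = LeafTraits(N=1.5, CHL=40.0, CAR=10.0, ANT=1.0, EWT=0.01, LMA=0.005)


@dataclass
class InversionSettings:
    """Optimizer configuration for a reflectance-only inversion."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    init: LeafTraits = DEFAULT_INIT
    merit_tolerance: float = 1e-10
    max_evaluations: int = 5000
    multi_start: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in TRAIT_NAMES:
            lo, hi = self.bounds[name]
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lower < upper")
            v = getattr(self.init, name)
            if not lo <= v <= hi:
                raise ValueError(f"init value for {name} ({v}) outside bounds [{lo}, {hi}]")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in TRAIT_NAMES])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in TRAIT_NAMES])


@dataclass
class CycleResult:
    """All four products of the regeneration cycle, row-aligned with the input."""

    p_inv: list[LeafTraits]
    hsr_sim: SpectralDataset
    p_re: list[LeafTraits]
    hsr_re: SpectralDataset
    merit_inv: np.ndarray
    merit_re: np.ndarray

    def traits_frame(self, which: str = "inv") -> pd.DataFrame:
        traits = self.p_inv if which == "inv" else self.p_re
        merit = self.merit_inv if which == "inv" else self.merit_re
        df = pd.DataFrame([t.as_array() for t in traits], columns=list(TRAIT_NAMES))
        df.insert(0, "sample_id", self.hsr_sim.meta["sample_id"].to_numpy())
        df["merit"] = merit
        return df


def merit(
    traits: LeafTraits, target_reflectance: np.ndarray, constants: OpticalConstants
) -> float:
    """RMSE over wavelengths between simulated and target reflectance."""
    target = np.asarray(target_reflectance, dtype=float)
    if target.shape != (len(constants.grid),):
        raise GridMismatchError("target reflectance does not match the constants' grid")
    sim = forward_spectrum(traits, constants).reflectance
    return float(np.sqrt(np.mean((sim - target) ** 2)))


def _starts(settings: InversionSettings, rng: np.random.Generator) -> list[np.ndarray]:
    """Initial points in unit-box coordinates: the configured init plus
    seeded perturbations around mid-bounds."""
    lo, hi = settings.lower, settings.upper
    span = hi - lo
    u0 = (settings.init.as_array() - lo) / span
    starts = [u0]
    for _ in range(max(settings.multi_start - 1, 0)):
        starts.append(np.clip(0.5 + rng.uniform(-0.35, 0.35, size=len(TRAIT_NAMES)), 0.0, 1.0))
    return starts


def invert_spectrum(
    target_reflectance: np.ndarray,
    constants: OpticalConstants,
    settings: InversionSettings | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[LeafTraits, float]:
    """Estimate the six traits for one reflectance spectrum.

    Bounded trust-region least squares on the per-wavelength residuals, in
    unit-scaled parameter space, best of ``multi_start`` restarts.  The
    returned merit never exceeds the merit at the configured init.
    """
    settings = settings or InversionSettings()
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    target = np.asarray(target_reflectance, dtype=float)
    if target.shape != (len(constants.grid),):
        raise GridMismatchError("target reflectance does not match the constants' grid")
    lo, hi = settings.lower, settings.upper
    span = hi - lo
    sqrt_n = np.sqrt(len(target))

    def residuals(u: np.ndarray) -> np.ndarray:
        traits = LeafTraits.from_array(lo + u * span)
        r = (forward_spectrum(traits, constants).reflectance - target) / sqrt_n
        if not np.all(np.isfinite(r)):
            raise InversionFailure("non-finite merit during optimization", traits=traits)
        return r

    best_u, best_m = None, np.inf
    for u0 in _starts(settings, rng):
        m0 = float(np.sqrt(np.sum(residuals(u0) ** 2)))
        if m0 < best_m:
            best_u, best_m = u0, m0
        if m0 <= settings.merit_tolerance:
            break  # init already optimal; no move (fixed point)
        # dogbox rather than trf: its rectangular trust regions converge
        # cleanly onto active bounds (traits pinned at 0 are common)
        sol = least_squares(
            residuals,
            u0,
            bounds=(0.0, 1.0),
            method="dogbox",
            xtol=2.5e-16,
            ftol=2.5e-16,
            gtol=1e-15,
            max_nfev=settings.max_evaluations,
        )
        m = float(np.sqrt(2.0 * sol.cost))
        if m < best_m:
            best_u, best_m = sol.x, m
        if best_m <= settings.merit_tolerance:
            break
    traits = LeafTraits.from_array(lo + best_u * span)
    return traits, best_m


def invert_dataset(
    ds: SpectralDataset,
    constants: OpticalConstants,
    settings: InversionSettings | None = None,
):
    """Row-wise inversion of a dataset.

    Returns ``(traits_list, merits, failures)`` where ``failures`` is a list
    of ``(sample_id, exception)`` pairs for rows whose optimization failed;
    failed rows carry the init traits and a NaN merit, and processing
    continues.  Deterministic given ``settings.seed``; order preserving.
    """
    settings = settings or InversionSettings()
    if ds.grid != constants.grid:
        raise GridMismatchError("dataset grid does not match the constants' grid")
    traits_out: list[LeafTraits] = []
    merits = np.full(ds.n_samples, np.nan)
    failures: list[tuple[str, Exception]] = []
    ids = ds.meta["sample_id"].to_numpy()
    for i in range(ds.n_samples):
        # per-row substream keyed by sample identity, not row position, so
        # permuting rows permutes results identically
        row_key = zlib.crc32(str(ids[i]).encode())
        rng = np.random.default_rng([settings.seed, row_key])
        try:
            tr, m = invert_spectrum(ds.values[i], constants, settings, rng=rng)
        except InversionFailure as exc:
            logger.warning("inversion failed for sample %s: %s", ids[i], exc)
            failures.append((str(ids[i]), exc))
            tr, m = settings.init, np.nan
        traits_out.append(tr)
        merits[i] = m
    return traits_out, merits, failures


def regeneration_cycle(
    hsr_meas: SpectralDataset,
    constants: OpticalConstants,
    settings: InversionSettings | None = None,
) -> CycleResult:
    """measured -> P_inv -> HSR_sim -> P_re -> HSR_re, with per-leg merits.

    Exactly the two invert/forward arrows; no smoothing or filtering.
    """
    settings = settings or InversionSettings()
    p_inv, merit_inv, fail1 = invert_dataset(hsr_meas, constants, settings)
    sim_values = np.array(
        [forward_spectrum(t, constants).reflectance for t in p_inv]
    )
    hsr_sim = SpectralDataset(constants.grid, sim_values, hsr_meas.meta.copy(), role="sim")
    p_re, merit_re, fail2 = invert_dataset(hsr_sim, constants, settings)
    re_values = np.array(
        [forward_spectrum(t, constants).reflectance for t in p_re]
    )
    hsr_re = SpectralDataset(constants.grid, re_values, hsr_meas.meta.copy(), role="re")
    if fail1 or fail2:
        logger.warning("regeneration cycle had %d failed inversions", len(fail1) + len(fail2))
    return CycleResult(p_inv, hsr_sim, p_re, hsr_re, merit_inv, merit_re)


# ---------------------------------------------------------------------------
# statsmodels-style model / results surface


class ProspectInversion:
    """Mechanistic inversion model for a reflectance dataset.

    Parameters
    ----------
    dataset : SpectralDataset
        Measured (or simulated) reflectance rows to invert.
    constants : OpticalConstants
        Optical-constants table on the same wavelength grid.
    settings : InversionSettings, optional
        Optimizer configuration; defaults are reproducible and documented.
    """

    def __init__(
        self,
        dataset: SpectralDataset,
        constants: OpticalConstants,
        settings: InversionSettings | None = None,
    ):
        if dataset.grid != constants.grid:
            raise GridMismatchError("dataset grid does not match the constants' grid")
        self.dataset = dataset
        self.constants = constants
        self.settings = settings or InversionSettings()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, constants: OpticalConstants, **kwargs):
        """Build from a spectra table in the standard CSV layout (metadata
        columns first, then one column per wavelength)."""
        from .spectra import META_COLUMNS, SpectralDataset, WavelengthGrid

        wl_cols = [c for c in df.columns if c not in META_COLUMNS]
        wl = np.array([float(c) for c in wl_cols])
        meta_cols = [c for c in df.columns if c in META_COLUMNS]
        ds = SpectralDataset(WavelengthGrid(wl), df[wl_cols].to_numpy(float), df[meta_cols].copy())
        return cls(ds, constants, **kwargs)

    def fit(self) -> "InversionResults":
        traits, merits, failures = invert_dataset(self.dataset, self.constants, self.settings)
        return InversionResults(self, traits, merits, failures)


class InversionResults:
    """Per-sample trait estimates from :class:`ProspectInversion.fit`."""

    def __init__(self, model: ProspectInversion, traits, merits, failures):
        self.model = model
        self.traits = traits
        self.merits = np.asarray(merits)
        self.failures = failures

    @property
    def params(self) -> pd.DataFrame:
        df = pd.DataFrame([t.as_array() for t in self.traits], columns=list(TRAIT_NAMES))
        df.insert(0, "sample_id", self.model.dataset.meta["sample_id"].to_numpy())
        df["merit"] = self.merits
        return df

    def simulate(self) -> SpectralDataset:
        """Forward-simulate the fitted traits (the HSR_sim leg)."""
        values = np.array(
            [forward_spectrum(t, self.model.constants).reflectance for t in self.traits]
        )
        return SpectralDataset(
            self.model.constants.grid, values, self.model.dataset.meta.copy(), role="sim"
        )

    def summary(self) -> str:
        df = self.params
        lines = [
            "PROSPECT-D reflectance-only inversion",
            f"  samples: {len(df)}   failed: {len(self.failures)}",
            f"  merit RMSE: median {np.nanmedian(self.merits):.3e}, "
            f"max {np.nanmax(self.merits):.3e}",
            "",
            df[list(TRAIT_NAMES)].describe().loc[["mean", "std", "min", "max"]].to_string(),
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.params.to_csv(path, index=False, float_format="%.9g")
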