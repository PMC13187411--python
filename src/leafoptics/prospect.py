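"""PROSPECT-D forward model: the generalized plate model for leaf optics.

A leaf is modelled as ``N`` identical absorbing plates with rough surfaces,
where ``N`` is real-valued.  Six traits drive the simulation: the structure
parameter N (effective number of mesophyll layers) and five constituent
contents — chlorophyll (CHL, ug/cm2), carotenoids (CAR, ug/cm2),
anthocyanins (ANT, ug/cm2), equivalent water thickness (EWT, cm) and leaf
dry mass per area (LMA, g/cm2).  The brown-pigment constituent of the full
model is excluded: it only occurs in late-senescent leaves.

Per wavelength, the constituent contents and their specific absorption
coefficients give the per-layer absorption ``k``; an isotropic-flux slab
transmission converts ``k`` to the elementary-layer transmissivity; Fresnel
interface averages (the ``tav`` function) give surface reflectivities; a
single-plate system is solved, and the Stokes solution extends it to the
remaining ``N - 1`` interior plates.  Output is directional-hemispherical
reflectance and transmittance on the grid of the optical-constants table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import exp1

from .exceptions import DomainError, GridMismatchError, NonPhysicalLayerError, SchemaError
from .spectra import WavelengthGrid

#: trait order used everywhere a trait vector appears
TRAIT_NAMES = ("N", "CHL", "CAR", "ANT", "EWT", "LMA")
#: absorbing constituents (all traits except the structure parameter)
CONSTITUENTS = ("CHL", "CAR", "ANT", "EWT", "LMA")

#: default incidence half-angle of the top plate, degrees
DEFAULT_ALPHA = 40.0


@dataclass(frozen=True)
class LeafTraits:
    """One leaf's PROSPECT-D inputs."""

    N: float
    CHL: float
    CAR: float
    ANT: float
    EWT: float
    LMA: float

    def __post_init__(self):
        if not np.isfinite(self.as_array()).all():
            raise DomainError("leaf traits must be finite")
        if self.N < 1.0:
            raise DomainError(f"structure parameter N must be >= 1, got {self.N}")
        for name in CONSTITUENTS:
            if getattr(self, name) < 0.0:
                raise DomainError(f"{name} content must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TRAIT_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x) -> "LeafTraits":
        return cls(**dict(zip(TRAIT_NAMES, np.asarray(x, dtype=float))))


@dataclass
class OpticalConstants:
    """Per-wavelength refractive index and specific absorption coefficients.

    ``specific_absorption`` maps each of the five constituents to a
    per-wavelength coefficient K_c(lambda), in units reciprocal to the paired
    trait so that C_c * K_c is dimensionless.
    """

    grid: WavelengthGrid
    refractive_index: np.ndarray
    specific_absorption: dict[str, np.ndarray]

    def __post_init__(self):
        n = np.asarray(self.refractive_index, dtype=float)
        if n.shape != (len(self.grid),):
            raise GridMismatchError("refractive index must have one value per wavelength")
        if np.any(n <= 1.0):
            raise DomainError("refractive index must exceed 1 everywhere")
        self.refractive_index = n
        if set(self.specific_absorption) != set(CONSTITUENTS):
            extra = set(self.specific_absorption) - set(CONSTITUENTS)
            missing = set(CONSTITUENTS) - set(self.specific_absorption)
            raise SchemaError(
                f"specific absorption must cover exactly {CONSTITUENTS}; "
                f"extra={sorted(extra)}, missing={sorted(missing)}"
            )
        for c, k in self.specific_absorption.items():
            k = np.asarray(k, dtype=float)
            if k.shape != (len(self.grid),):
                raise GridMismatchError(f"K_{c} must have one value per wavelength")
            if np.any(k < 0):
                raise DomainError(f"K_{c} must be nonnegative")
            self.specific_absorption[c] = k


@dataclass
class LeafSpectra:
    """Simulated directional-hemispherical reflectance and transmittance."""

    grid: WavelengthGrid
    reflectance: np.ndarray
    transmittance: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.reflectance, dtype=float)
        t = np.asarray(self.transmittance, dtype=float)
        if r.shape != (len(self.grid),) or t.shape != (len(self.grid),):
            raise GridMismatchError("reflectance/transmittance must match the grid")
        eps = 1e-9
        if np.any(r < -eps) or np.any(t < -eps) or np.any(r + t > 1 + eps):
            raise ValueError("non-physical spectra: need R, T >= 0 and R + T <= 1")
        self.reflectance = np.clip(r, 0.0, 1.0)
        self.transmittance = np.clip(t, 0.0, 1.0)


def average_transmissivity(alpha: float, n) -> np.ndarray | float:
    """Mean Fresnel transmissivity tav(alpha, n) of a dielectric interface.

    Transmittance of unpolarized light averaged over incidence angles from 0
    to ``alpha`` degrees, for relative refractive index ``n`` (closed form of
    Stern as used throughout the PROSPECT lineage).  Vectorized over ``n``.
    """
    if not 0.0 < alpha <= 90.0:
        raise DomainError(f"alpha must lie in (0, 90], got {alpha}")
    n = np.asarray(n, dtype=float)
    if np.any(n < 1.0):
        raise DomainError("refractive index must be >= 1")
    scalar = n.ndim == 0
    n = np.atleast_1d(n)
    out = np.ones_like(n)
    m = n > 1.0  # n == 1: no interface, tav = 1
    if np.any(m):
        nn = n[m]
        n2 = nn**2
        npl = n2 + 1.0
        nm = n2 - 1.0
        a = (nn + 1.0) ** 2 / 2.0
        k = -(n2 - 1.0) ** 2 / 4.0
        sa = np.sin(np.radians(alpha)) ** 2
        if alpha == 90.0:
            b1 = 0.0
        else:
            b1 = np.sqrt((sa - npl / 2.0) ** 2 + k)
        b2 = sa - npl / 2.0
        b = b1 - b2
        b3, a3 = b**3, a**3
        ts = (k**2 / (6.0 * b3) + k / b - b / 2.0) - (k**2 / (6.0 * a3) + k / a - a / 2.0)
        tp1 = -2.0 * n2 * (b - a) / npl**2
        tp2 = -2.0 * n2 * npl * np.log(b / a) / nm**2
        tp3 = n2 * (1.0 / b - 1.0 / a) / 2.0
        tp4 = (
            16.0
            * n2**2
            * (n2**2 + 1.0)
            * np.log((2.0 * npl * b - nm**2) / (2.0 * npl * a - nm**2))
            / (npl**3 * nm**2)
        )
        tp5 = 16.0 * n2**3 * (1.0 / (2.0 * npl * b - nm**2) - 1.0 / (2.0 * npl * a - nm**2)) / npl**3
        out[m] = (ts + tp1 + tp2 + tp3 + tp4 + tp5) / (2.0 * sa)
    return float(out[0]) if scalar else out


def layer_transmission(k) -> np.ndarray | float:
    """Transmissivity of the elementary absorbing layer.

    tau(k) = (1 - k) e^{-k} + k^2 E1(k), the exact transmission of an
    isotropically illuminated slab of dimensionless absorption ``k``
    (equivalently 2 * int_0^1 mu e^{-k/mu} dmu).  tau(0) = 1 and tau is
    strictly decreasing.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise DomainError("absorption k must be nonnegative")
    scalar = k.ndim == 0
    k = np.atleast_1d(k)
    tau = np.ones_like(k)
    pos = k > 0
    kp = k[pos]
    tau[pos] = (1.0 - kp) * np.exp(-kp) + kp**2 * exp1(kp)
    tau = np.clip(tau, 0.0, 1.0)
    return float(tau[0]) if scalar else tau


def total_absorption(traits: LeafTraits, constants: OpticalConstants) -> np.ndarray:
    """Per-layer absorption k(lambda) = sum_c C_c K_c(lambda) / N."""
    k = np.zeros(len(constants.grid))
    for c in CONSTITUENTS:
        k += getattr(traits, c) * constants.specific_absorption[c]
    return k / traits.N


def plate_single_layer(tau, n, alpha: float = DEFAULT_ALPHA):
    """Reflectance and transmittance of one absorbing plate.

    ``alpha`` is the incidence half-angle of the illuminated face; interior
    plates use alpha = 90 (diffuse flux).  Vectorized over ``tau`` and ``n``.
    Returns ``(reflectance, transmittance)``.
    """
    tau = np.asarray(tau, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(tau < 0) or np.any(tau > 1):
        raise DomainError("tau must lie in [0, 1]")
    t_top = average_transmissivity(alpha, n_arr)
    t_hemi = average_transmissivity(90.0, n_arr)
    t21 = t_hemi / n_arr**2  # interior exit transmissivity
    r21 = 1.0 - t21
    denom = 1.0 - r21**2 * tau**2
    # r21 < 1 strictly for n > 1, so denom > 0; assert rather than guard
    assert np.all(denom > 0), "single-plate denominator vanished"
    transmittance = t_top * tau * t21 / denom
    reflectance = (1.0 - t_top) + r21 * tau * transmittance
    return reflectance, transmittance


def _stokes(r, t, m):
    """Stokes solution for ``m`` >= 0 identical layers (vectorized, m scalar)."""
    r = np.atleast_1d(np.asarray(r, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    R = np.empty_like(r)
    T = np.empty_like(t)
    if m == 0:
        return np.zeros_like(r), np.ones_like(t)
    conserv = r + t >= 1.0 - 1e-12  # no absorption: Stokes degenerates
    opaque = (t < 1e-300) & ~conserv
    tiny_r = (r < 1e-12) & ~conserv & ~opaque
    regular = ~conserv & ~tiny_r & ~opaque
    if np.any(opaque):
        R[opaque] = r[opaque]
        T[opaque] = 0.0
    if np.any(regular):
        rr, tt = r[regular], t[regular]
        D = np.sqrt((1 + rr + tt) * (1 + rr - tt) * (1 - rr + tt) * (1 - rr - tt))
        rq, tq = rr**2, tt**2
        a = (1 + rq - tq + D) / (2 * rr)
        b = (1 - rq + tq + D) / (2 * tt)
        bm = np.exp(m * np.log(b))  # real-valued layer count
        b2m = bm**2
        a2 = a**2
        denom = a2 * b2m - 1.0
        R[regular] = a * (b2m - 1.0) / denom
        T[regular] = bm * (a2 - 1.0) / denom
    if np.any(tiny_r):
        # purely transmitting limit: layers stack multiplicatively
        T[tiny_r] = np.exp(m * np.log(np.maximum(t[tiny_r], 1e-300)))
        R[tiny_r] = 0.0
    if np.any(conserv):
        tt = t[conserv]
        T[conserv] = tt / (tt + (1.0 - tt) * m)
        R[conserv] = 1.0 - T[conserv]
    return R, T


def stokes_stack(r, t, n_layers: float):
    """Reflectance/transmittance of ``n_layers`` identical plates (Stokes).

    ``n_layers`` is real-valued and >= 1; ``n_layers = 1`` returns the layer
    unchanged.  Raises on non-physical layers with r + t > 1.
    """
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(r < 0) or np.any(t < 0):
        raise DomainError("layer reflectance/transmittance must be nonnegative")
    if np.any(r + t > 1.0 + 1e-12):
        raise NonPhysicalLayerError("layer with reflectance + transmittance > 1")
    if n_layers < 1:
        raise DomainError("n_layers must be >= 1")
    scalar = r.ndim == 0
    R, T = _stokes(r, t, float(n_layers))
    if scalar:
        return float(R[0]), float(T[0])
    return R, T


def forward_spectrum(
    traits: LeafTraits, constants: OpticalConstants, alpha: float = DEFAULT_ALPHA
) -> LeafSpectra:
    """Simulate one leaf's reflectance and transmittance spectra.

    Composes total absorption -> elementary-layer transmission -> single
    plate (incidence ``alpha`` on top, diffuse inside) -> Stokes extension to
    the remaining N - 1 interior plates, coupled by the two-stream adding
    formulas of the plate-model lineage.  Deterministic.
    """
    n = constants.refractive_index
    k = total_absorption(traits, constants)
    tau = layer_transmission(k)
    r_top, t_top = plate_single_layer(tau, n, alpha)
    r90, t90 = plate_single_layer(tau, n, 90.0)
    R_sub, T_sub = _stokes(r90, t90, traits.N - 1.0)
    denom = 1.0 - R_sub * r90
    reflectance = r_top + t_top * R_sub * t90 / denom
    transmittance = t_top * T_sub / denom
    return LeafSpectra(constants.grid, reflectance, transmittance)


def forward_dataset(traits_list, constants: OpticalConstants, alpha: float = DEFAULT_ALPHA):
    """Forward-simulate a sequence of trait sets; returns an (n, n_wl) array."""
    return np.array(
        [forward_spectrum(tr, constants, alpha).reflectance for tr in traits_list]
    )


# ---------------------------------------------------------------------------
# Optical-constants table (CSV): wavelength_nm, refractive_index, K_CHL,
# K_CAR, K_ANT, K_EWT, K_LMA.  Real PROSPECT-D coefficient tables load
# through this same layout when supplied by the user.

_CONSTANTS_COLUMNS = ("wavelength_nm", "refractive_index") + tuple(
    f"K_{c}" for c in CONSTITUENTS
)


def write_constants_csv(constants: OpticalConstants, path) -> None:
    out = {"wavelength_nm": constants.grid.wavelengths,
           "refractive_index": constants.refractive_index}
    for c in CONSTITUENTS:
        out[f"K_{c}"] = constants.specific_absorption[c]
    pd.DataFrame(out).to_csv(path, index=False, float_format="%.9g")


def read_constants_csv(path) -> OpticalConstants:
    """Read an optical-constants table, rejecting unknown absorber columns."""
    df = pd.read_csv(path)
    missing = set(_CONSTANTS_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    extra = [c for c in df.columns if c.startswith("K_") and c not in _CONSTANTS_COLUMNS]
    if extra:
        # a sixth absorber (e.g. brown pigment) must fail loudly, not be ignored
        raise SchemaError(f"{path}: unsupported absorber columns {extra}")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise SchemaError(f"{path}: wavelengths must be strictly increasing")
    return OpticalConstants(
        grid=WavelengthGrid(wl),
        refractive_index=df["refractive_index"].to_numpy(dtype=float),
        specific_absorption={c: df[f"K_{c}"].to_numpy(dtype=float) for c in CONSTITUENTS},
    )
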