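"""Synthetic data generation: optical constants, trait populations, noise,
and multi-environment genotype trials.

Everything downstream of the forward model is testable without measured
data: this module fabricates (i) an optical-constants table whose absorption
bands reproduce the qualitative structure of real leaf optics — carotenoid
and anthocyanin bands nested wholly inside the dominant chlorophyll band
(the masking that makes those two pigments weakly identifiable), water and
dry-matter bands broad and separate in the long-wavelength half; (ii) trait
populations with dataset archetypes (a wide, species-diverse population; a
narrow unimodal crop population; a bimodal, domain-shifted "tropical"
population); (iii) band-localized measurement noise concentrated where
reflectance is low; and (iv) unbalanced two-environment genotype trials with
replicates and repeats for heritability analysis.

Randomness: every operation derives its generator from the user seed and a
fixed per-operation code, so cross-module pipelines are reproducible without
global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SpecError
from .inversion import DEFAULT_BOUNDS
from .prospect import CONSTITUENTS, TRAIT_NAMES, LeafTraits, OpticalConstants, forward_spectrum
from .spectra import SpectralDataset, WavelengthGrid

# fixed per-operation substream codes (operation name -> small int)
_STREAMS = {
    "constants": 11,
    "population": 23,
    "noise": 37,
    "trial": 53,
    "trial_values": 71,
}


def _rng(seed: int, op: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % 2**31, _STREAMS[op]])


# ---------------------------------------------------------------------------
# Optical constants


@dataclass(frozen=True)
class AbsorptionBand:
    """One Gaussian absorption band: centre and width in nm, peak coefficient.

    The band has compact support on centre +/- 3 width; outside it the
    coefficient is exactly zero, which makes nesting statements exact.
    """

    center: float
    width: float
    peak: float

    def evaluate(self, wl: np.ndarray) -> np.ndarray:
        if self.peak < 0:
            raise SpecError("band peak coefficient must be nonnegative")
        out = self.peak * np.exp(-0.5 * ((wl - self.center) / self.width) ** 2)
        out[np.abs(wl - self.center) > 3.0 * self.width] = 0.0
        return out


@dataclass
class ConstantsSpec:
    """Specification of a synthetic optical-constants table."""

    grid: WavelengthGrid = field(default_factory=WavelengthGrid.desk)
    n_base: float = 1.40
    n_amplitude: float = 0.08  # smooth decline of n with wavelength
    bands: dict[str, tuple[AbsorptionBand, ...]] = None

    def __post_init__(self):
        if self.bands is None:
            self.bands = default_absorption_bands()
        if set(self.bands) != set(CONSTITUENTS):
            raise SpecError(f"bands must cover exactly the constituents {CONSTITUENTS}")
        lo, hi = self.grid.wavelengths[0], self.grid.wavelengths[-1]
        for c, bb in self.bands.items():
            for b in bb:
                if not lo <= b.center <= hi:
                    raise SpecError(f"{c} band centred at {b.center} nm lies outside the grid")


def default_absorption_bands() -> dict[str, tuple[AbsorptionBand, ...]]:
    """Default band layout.

    CHL dominates the visible half; CAR (centre 490) and ANT (centre 555)
    sit wholly inside the CHL support, so K_CAR > 0 or K_ANT > 0 implies
    K_CHL > 0 — the chlorophyll-masking configuration.  EWT and LMA occupy
    broad, largely separate bands in the 1100-2450 nm half.  Peak magnitudes
    are calibrated so that typical green leaves are saturated-dark
    (reflectance pinned near the surface term) inside the four classic
    low-reflectance wavebands — 400-500, 600-725, 1860-2025, 2325-2450 nm —
    while the green window (~550 nm), NIR plateau and 1500-1850 nm shoulder
    stay bright and trait-responsive.
    """
    return {
        "CHL": (
            AbsorptionBand(435.0, 48.0, 0.24),
            AbsorptionBand(660.0, 50.0, 0.30),
        ),
        "CAR": (AbsorptionBand(490.0, 30.0, 0.22),),
        "ANT": (AbsorptionBand(555.0, 25.0, 0.09),),
        "EWT": (
            AbsorptionBand(1450.0, 90.0, 40.0),
            AbsorptionBand(1940.0, 110.0, 180.0),
            AbsorptionBand(2450.0, 160.0, 110.0),
        ),
        "LMA": (
            AbsorptionBand(1720.0, 120.0, 30.0),
            AbsorptionBand(2300.0, 140.0, 90.0),
            AbsorptionBand(1200.0, 100.0, 9.0),
        ),
    }


def synthetic_optical_constants(spec: ConstantsSpec | None = None) -> OpticalConstants:
    """Deterministic Gaussian-sum absorption curves per constituent."""
    spec = spec or ConstantsSpec()
    wl = spec.grid.wavelengths
    span = wl[-1] - wl[0] if wl[-1] > wl[0] else 1.0
    x = (wl - wl[0]) / span
    refractive = spec.n_base + spec.n_amplitude * (1.0 - x) ** 2 + 0.01
    absorption = {}
    for c in CONSTITUENTS:
        k = np.zeros_like(wl)
        for band in spec.bands[c]:
            k += band.evaluate(wl)
        absorption[c] = k
    return OpticalConstants(spec.grid, refractive, absorption)


# ---------------------------------------------------------------------------
# Trait populations


@dataclass(frozen=True)
class TraitDistribution:
    """Marginal distribution of one trait.

    kinds: ``truncnorm`` (params mean, sd, lo, hi), ``lognormal`` (params
    median, sigma — long-tailed), ``mixture`` (two-component normal mixture:
    m1, s1, m2, s2, w1 — bimodal), ``point`` (a degenerate value).
    """

    kind: str
    params: tuple

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.kind == "truncnorm":
            mean, sd, lo, hi = self.params
            a, b = (lo - mean) / sd, (hi - mean) / sd
            return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)
        if self.kind == "lognormal":
            median, sigma = self.params
            return stats.lognorm.ppf(u, sigma, scale=median)
        if self.kind == "mixture":
            raise SpecError("mixture sampling is draw-based, not quantile-based")
        if self.kind == "point":
            return np.full_like(np.asarray(u, dtype=float), self.params[0])
        raise SpecError(f"unknown distribution kind {self.kind!r}")

    def sample(
        self, u: np.ndarray, rng: np.random.Generator, component: np.ndarray | None = None
    ) -> np.ndarray:
        if self.kind == "mixture":
            m1, s1, m2, s2, w1 = self.params
            comp = component if component is not None else rng.random(len(u)) < w1
            z = stats.norm.ppf(u)
            return np.where(comp, m1 + s1 * z, m2 + s2 * z)
        return self.ppf(u)


@dataclass
class PopulationSpec:
    """A trait population: per-trait marginals plus dependence structure.

    ``mixture_cohort=True`` makes all mixture-distributed traits share one
    per-sample latent: the same component indicator and the same
    within-component quantile.  Samples then lie on a one-dimensional
    developmental axis (e.g. young vs mature leaves of one species), the
    degenerate joint coverage that defeats models trained on such data.
    """

    distributions: dict[str, TraitDistribution]
    chl_car_rank_corr: float = 0.0
    mixture_cohort: bool = False
    cohort_corr: float = 1.0
    n_samples: int = 200
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        missing = set(TRAIT_NAMES) - set(self.distributions)
        if missing:
            raise SpecError(f"population spec missing traits {sorted(missing)}")
        if not 0.0 <= self.chl_car_rank_corr < 1.0:
            raise SpecError("CHL-CAR rank correlation must lie in [0, 1)")


def wide_population(n_samples: int = 200, seed: int = 0) -> PopulationSpec:
    """Species-diverse archetype: broad coverage of all six traits."""
    return PopulationSpec(
        distributions={
            "N": TraitDistribution("truncnorm", (1.9, 0.5, 1.05, 3.6)),
            "CHL": TraitDistribution("truncnorm", (45.0, 18.0, 12.0, 100.0)),
            "CAR": TraitDistribution("lognormal", (9.0, 0.45)),
            "ANT": TraitDistribution("lognormal", (1.6, 0.9)),
            "EWT": TraitDistribution("truncnorm", (0.013, 0.005, 0.003, 0.04)),
            "LMA": TraitDistribution("truncnorm", (0.006, 0.0025, 0.0012, 0.02)),
        },
        chl_car_rank_corr=0.8,
        n_samples=n_samples,
        seed=seed,
        label="wide",
    )


def crop_population(n_samples: int = 200, seed: int = 0) -> PopulationSpec:
    """Narrow unimodal crop archetype, contained inside the wide coverage."""
    return PopulationSpec(
        distributions={
            "N": TraitDistribution("truncnorm", (1.55, 0.18, 1.15, 2.2)),
            "CHL": TraitDistribution("truncnorm", (55.0, 10.0, 28.0, 82.0)),
            "CAR": TraitDistribution("lognormal", (11.0, 0.22)),
            "ANT": TraitDistribution("lognormal", (0.9, 0.5)),
            "EWT": TraitDistribution("truncnorm", (0.011, 0.0026, 0.005, 0.019)),
            "LMA": TraitDistribution("truncnorm", (0.005, 0.0013, 0.0025, 0.0095)),
        },
        chl_car_rank_corr=0.35,
        n_samples=n_samples,
        seed=seed,
        label="crop",
    )


def tropical_population(n_samples: int = 200, seed: int = 0) -> PopulationSpec:
    """Bimodal, domain-shifted archetype emulating a single tropical species.

    All mixture traits share the cohort indicator: a leaf is either in the
    low cohort (young: low N, CHL, EWT, LMA) or the high cohort, so the
    joint distribution concentrates on two tight clusters along one axis —
    the narrow coverage that makes models trained here extrapolate poorly.
    """
    return PopulationSpec(
        distributions={
            "N": TraitDistribution("mixture", (1.3, 0.08, 2.5, 0.12, 0.5)),
            "CHL": TraitDistribution("mixture", (25.0, 4.0, 65.0, 5.0, 0.5)),
            "CAR": TraitDistribution("lognormal", (6.0, 0.5)),
            "ANT": TraitDistribution("lognormal", (3.0, 0.8)),
            "EWT": TraitDistribution("mixture", (0.006, 0.001, 0.021, 0.002, 0.5)),
            "LMA": TraitDistribution("mixture", (0.003, 0.0005, 0.011, 0.001, 0.5)),
        },
        chl_car_rank_corr=0.6,
        mixture_cohort=True,
        cohort_corr=0.988,
        n_samples=n_samples,
        seed=seed,
        label="tropical",
    )


def sample_trait_population(spec: PopulationSpec) -> pd.DataFrame:
    """Seeded draws from a population spec, truncated to inversion bounds.

    CHL and CAR draws share a Gaussian copula at the requested rank
    correlation; all other traits are independent.  Truncation to the
    default inversion bounds is applied last.
    """
    rng = _rng(spec.seed, "population")
    n = spec.n_samples
    # Gaussian copula over all six traits; only CHL-CAR are coupled
    z = rng.standard_normal((n, len(TRAIT_NAMES)))
    i_chl, i_car = TRAIT_NAMES.index("CHL"), TRAIT_NAMES.index("CAR")
    rho = spec.chl_car_rank_corr
    if rho > 0:
        rho_pearson = 2.0 * np.sin(np.pi * rho / 6.0)  # rank -> normal copula
        z[:, i_car] = rho_pearson * z[:, i_chl] + np.sqrt(1 - rho_pearson**2) * z[:, i_car]
    u = stats.norm.cdf(z)
    cohort = None
    shared_u = None
    if spec.mixture_cohort:
        weights = {
            d.params[4] for d in spec.distributions.values() if d.kind == "mixture"
        }
        if len(weights) > 1:
            raise SpecError("cohort-linked mixtures must share one component weight")
        if weights:
            cohort = rng.random(n) < weights.pop()
            shared_u = rng.standard_normal(n)  # the latent developmental axis
    out = {}
    rho_c = spec.cohort_corr
    for j, name in enumerate(TRAIT_NAMES):
        dist = spec.distributions[name]
        if dist.kind == "mixture" and shared_u is not None:
            z_mix = rho_c * shared_u + np.sqrt(1.0 - rho_c**2) * z[:, j]
            vals = dist.sample(stats.norm.cdf(z_mix), rng, component=cohort)
        else:
            vals = dist.sample(u[:, j], rng, component=cohort)
        lo, hi = DEFAULT_BOUNDS[name]
        vals = np.clip(vals, lo, hi)
        if dist.kind != "point" and np.all(vals == vals[0]) and n > 1:
            raise SpecError(f"truncation left no mass inside bounds for {name}")
        out[name] = vals
    df = pd.DataFrame(out)
    df.insert(0, "sample_id", [f"{spec.label or 'pop'}_{i}" for i in range(n)])
    return df


def traits_from_frame(df: pd.DataFrame) -> list[LeafTraits]:
    return [LeafTraits(**{n: float(row[n]) for n in TRAIT_NAMES}) for _, row in df.iterrows()]


def simulate_spectra(
    traits_df: pd.DataFrame, constants: OpticalConstants, role: str = "sim"
) -> SpectralDataset:
    """Forward-simulate a trait table into a reflectance dataset."""
    values = np.array(
        [forward_spectrum(t, constants).reflectance for t in traits_from_frame(traits_df)]
    )
    meta_cols = [c for c in traits_df.columns if c not in TRAIT_NAMES]
    return SpectralDataset(constants.grid, values, traits_df[meta_cols].copy(), role=role)


def archetype_suite(
    n_samples: int = 400,
    seed: int = 0,
    constants: OpticalConstants | None = None,
    background_sd: float = 0.003,
) -> dict[str, tuple[SpectralDataset, pd.DataFrame]]:
    """The three bundled dataset archetypes, simulated and lightly noised.

    Returns ``{"wide": (spectra, traits), "crop": ..., "tropical": ...}`` on
    a common grid.  Spectra carry mild wavelength-uniform measurement noise
    (sd ``background_sd``): enough to regularize high-capacity regressions
    the way real instrument noise does, while leaving the trait signal
    dominant everywhere.
    """
    constants = constants or synthetic_optical_constants()
    suite: dict[str, tuple[SpectralDataset, pd.DataFrame]] = {}
    makers = [
        ("wide", wide_population),
        ("crop", crop_population),
        ("tropical", tropical_population),
    ]
    for k, (label, maker) in enumerate(makers):
        traits = sample_trait_population(maker(n_samples=n_samples, seed=seed + k))
        ds = simulate_spectra(traits, constants, role=label)
        ds = corrupt_to_measured(
            ds,
            NoiseSpec(
                bands=(), band_sd=0.0, band_jitter=0.0,
                background_sd=background_sd, seed=seed + 10 + k,
            ),
        )
        suite[label] = (ds, traits)
    return suite


# ---------------------------------------------------------------------------
# Measurement noise


#: the four low-reflectance wavebands where measured-vs-simulated errors
#: concentrate in real leaf data
DEFAULT_NOISE_BANDS = ((400.0, 500.0), (600.0, 725.0), (1860.0, 2025.0), (2325.0, 2450.0))


@dataclass
class NoiseSpec:
    """Band-localized measurement noise.

    Within the listed bands: additive Gaussian noise of sd ``band_sd`` plus
    multiplicative jitter of relative sd ``band_jitter``.  Elsewhere:
    additive noise of sd ``background_sd``.  Output clipped to
    [``floor``, ``ceiling``]; the floor is a small positive value because a
    measured reflectance of exactly zero is unphysical (and would poison
    relative-error denominators).
    """

    bands: tuple[tuple[float, float], ...] = DEFAULT_NOISE_BANDS
    band_sd: float = 0.02
    band_jitter: float = 0.6
    background_sd: float = 0.0005
    floor: float = 1e-4
    ceiling: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.band_sd, self.band_jitter, self.background_sd) < 0:
            raise SpecError("noise standard deviations must be nonnegative")

    def in_band(self, wl: np.ndarray) -> np.ndarray:
        mask = np.zeros(wl.shape, dtype=bool)
        for lo, hi in self.bands:
            mask |= (wl >= lo) & (wl <= hi)
        return mask


def corrupt_to_measured(hsr_sim: SpectralDataset, spec: NoiseSpec | None = None) -> SpectralDataset:
    """Inject band-localized noise, emulating a measured dataset."""
    spec = spec or NoiseSpec()
    wl = hsr_sim.grid.wavelengths
    for lo, hi in spec.bands:
        if hi < wl[0] or lo > wl[-1]:
            raise SpecError(f"noise band ({lo}, {hi}) lies outside the grid")
    rng = _rng(spec.seed, "noise")
    mask = spec.in_band(wl)
    v = hsr_sim.values.copy()
    jitter = rng.normal(0.0, spec.band_jitter, size=v.shape)
    add = rng.normal(0.0, spec.band_sd, size=v.shape)
    bg = rng.normal(0.0, spec.background_sd, size=v.shape)
    v[:, mask] = v[:, mask] * (1.0 + jitter[:, mask]) + add[:, mask]
    v[:, ~mask] = v[:, ~mask] + bg[:, ~mask]
    np.clip(v, spec.floor, spec.ceiling, out=v)
    return SpectralDataset(hsr_sim.grid, v, hsr_sim.meta.copy(), role="meas")


# ---------------------------------------------------------------------------
# Multi-environment genotype trials


@dataclass
class TrialSpec:
    """An unbalanced two-environment genotype trial on one trait axis.

    Genotype effects (variance ``sigma2_g``), genotype-by-environment
    effects (``sigma2_ge``) and residual plot noise (``sigma2_eps``) act
    additively on ``trait_axis`` (default CHL, ug/cm2) around the population
    baseline; environments also shift the axis by fixed ``env_shifts``.
    Replicate and repeat counts are drawn uniformly from the given ranges
    per genotype-environment cell (1-2 replicates, 1-3 repeats by default).
    Repeats are technical measurements: they add noise at ``repeat_sd``.
    """

    n_genotypes: int = 100
    n_environments: int = 2
    replicates: tuple[int, int] = (1, 2)
    repeats: tuple[int, int] = (1, 3)
    sigma2_g: float = 2.0
    sigma2_ge: float = 1.0
    sigma2_eps: float = 2.0
    env_shifts: tuple[float, ...] | None = None
    repeat_sd: float = 0.2
    trait_axis: str = "CHL"
    baseline: LeafTraits = LeafTraits(N=1.5, CHL=45.0, CAR=9.0, ANT=1.5, EWT=0.012, LMA=0.006)

    def __post_init__(self):
        if min(self.sigma2_g, self.sigma2_ge, self.sigma2_eps) < 0:
            raise SpecError("variance components must be nonnegative")
        if self.trait_axis not in TRAIT_NAMES:
            raise SpecError(f"unknown trait axis {self.trait_axis!r}")
        if self.env_shifts is None:
            shifts = np.linspace(-1.0, 1.0, self.n_environments) if self.n_environments > 1 else [0.0]
            self.env_shifts = tuple(float(s) for s in shifts)


def simulate_trial_values(spec: TrialSpec, seed: int = 0):
    """Trait values (not spectra) for a genotype trial.

    Returns ``(frame, truth)`` where ``frame`` has columns value,
    genotype_id, environment_id, replicate_id, repeat_id and ``truth`` maps
    component names to generative values.  Repeats share their replicate's
    value up to ``repeat_sd`` technical noise.
    """
    rng = _rng(seed, "trial_values")
    g = rng.normal(0.0, np.sqrt(spec.sigma2_g), size=spec.n_genotypes)
    ge = rng.normal(0.0, np.sqrt(spec.sigma2_ge), size=(spec.n_genotypes, spec.n_environments))
    rows = []
    base = getattr(spec.baseline, spec.trait_axis)
    for i in range(spec.n_genotypes):
        for j in range(spec.n_environments):
            n_rep = int(rng.integers(spec.replicates[0], spec.replicates[1] + 1))
            for r in range(n_rep):
                plot = (
                    base
                    + spec.env_shifts[j]
                    + g[i]
                    + ge[i, j]
                    + rng.normal(0.0, np.sqrt(spec.sigma2_eps))
                )
                n_rpt = int(rng.integers(spec.repeats[0], spec.repeats[1] + 1))
                for q in range(n_rpt):
                    rows.append(
                        {
                            "value": plot + rng.normal(0.0, spec.repeat_sd),
                            "genotype_id": f"g{i:04d}",
                            "environment_id": f"env{j}",
                            "replicate_id": f"rep{r}",
                            "repeat_id": f"rpt{q}",
                        }
                    )
    truth = {
        "sigma2_g": spec.sigma2_g,
        "sigma2_ge": spec.sigma2_ge,
        "sigma2_eps": spec.sigma2_eps,
    }
    return pd.DataFrame(rows), truth


def simulate_population_trial(
    spec: TrialSpec, constants: OpticalConstants, seed: int = 0
) -> SpectralDataset:
    """Genotype trial propagated through the forward model.

    Draws the trial on the trait axis, clamps the axis to its inversion
    bounds, simulates every observation's reflectance, and returns a dataset
    with full genotype/environment/replicate/repeat metadata.
    """
    frame, _ = simulate_trial_values(spec, seed=seed)
    lo, hi = DEFAULT_BOUNDS[spec.trait_axis]
    values = []
    for _, row in frame.iterrows():
        kwargs = {n: getattr(spec.baseline, n) for n in TRAIT_NAMES}
        kwargs[spec.trait_axis] = float(np.clip(row["value"], lo, hi))
        values.append(forward_spectrum(LeafTraits(**kwargs), constants).reflectance)
    meta = frame[["genotype_id", "environment_id", "replicate_id", "repeat_id"]].copy()
    meta.insert(0, "sample_id", [f"obs{i}" for i in range(len(frame))])
    return SpectralDataset(constants.grid, np.array(values), meta, role="meas")
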