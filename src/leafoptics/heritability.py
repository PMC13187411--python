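"""Broad-sense heritability of reflectance from multi-environment trials.

Each wavelength of a measured reflectance dataset is treated as an
individual trait.  For a genotype trial across environments with
replicates, the random-effects model

    value = mu + genotype + environment + genotype x environment + residual

is fitted by REML, and the entry-mean phenotypic variance is

    sigma2_p = sigma2_g + sigma2_ge / n_e + sigma2_eps / (n_e * n_r)

with broad-sense heritability H2 = sigma2_g / sigma2_p in [0, 1].  n_e and
n_r are the numbers of environments and replicates per genotype; for
unbalanced trials they are taken as harmonic means, the standard entry-mean
practice.  Repeats (multiple technical measurements within a replicate) are
averaged to one value per replicate before fitting, since the model has no
repeat term.

REML fits use statsmodels MixedLM with a genotype random intercept and a
genotype-by-environment variance component; the environment main effect is
fixed (it does not enter sigma2_p).  A method-of-moments ANOVA estimator
backs up the rare MixedLM convergence failure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DegenerateDesignError, SchemaError
from .spectra import SpectralDataset, WavelengthGrid

logger = logging.getLogger(__name__)

_REQUIRED_META = ("genotype_id", "environment_id", "replicate_id")


@dataclass
class TrialDesign:
    """Genotype / environment / replicate labels plus effective counts.

    ``n_environments`` and ``n_replicates`` are the effective (possibly
    fractional, harmonic-mean) counts entering the entry-mean variance.
    """

    genotype: np.ndarray
    environment: np.ndarray
    replicate: np.ndarray
    n_environments: float
    n_replicates: float

    @classmethod
    def from_frame(cls, meta: pd.DataFrame) -> "TrialDesign":
        missing = [c for c in _REQUIRED_META if c not in meta.columns]
        if missing:
            raise SchemaError(f"trial metadata missing columns {missing}")
        g = meta["genotype_id"].to_numpy()
        e = meta["environment_id"].to_numpy()
        r = meta["replicate_id"].to_numpy()
        df = pd.DataFrame({"g": g, "e": e, "r": r})
        env_per_geno = df.groupby("g")["e"].nunique().to_numpy(dtype=float)
        rep_per_cell = (
            df.groupby(["g", "e"])["r"].nunique().to_numpy(dtype=float)
        )
        n_e = _harmonic_mean(env_per_geno)
        n_r = _harmonic_mean(rep_per_cell)
        return cls(g, e, r, n_e, n_r)

    @property
    def n_genotypes(self) -> int:
        return len(np.unique(self.genotype))


def _harmonic_mean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise DegenerateDesignError("counts must be positive")
    return float(len(x) / np.sum(1.0 / x))


@dataclass
class VarianceComponents:
    """REML variance components and the entry-mean phenotypic variance."""

    sigma2_g: float
    sigma2_ge: float
    sigma2_eps: float
    sigma2_p: float

    @classmethod
    def from_components(
        cls, sigma2_g: float, sigma2_ge: float, sigma2_eps: float, n_e: float, n_r: float
    ) -> "VarianceComponents":
        sigma2_g = max(float(sigma2_g), 0.0)
        sigma2_ge = max(float(sigma2_ge), 0.0)
        sigma2_eps = max(float(sigma2_eps), 0.0)
        sigma2_p = sigma2_g + sigma2_ge / n_e + sigma2_eps / (n_e * n_r)
        return cls(sigma2_g, sigma2_ge, sigma2_eps, sigma2_p)


def _anova_components(df: pd.DataFrame) -> tuple[float, float, float]:
    """Method-of-moments fallback via expected mean squares (approximate for
    unbalanced data, exact for balanced)."""
    n_e = df["e"].nunique()
    cell = df.groupby(["g", "e"])["y"].agg(["mean", "count", "var"])
    r_bar = float(cell["count"].mean())
    within = cell["var"].dropna()
    ms_eps = float(within.mean()) if len(within) else 0.0
    geno_means = df.groupby("g")["y"].mean()
    ms_g = float(geno_means.var(ddof=1)) * n_e * r_bar
    if n_e > 1:
        cell_means = cell["mean"].unstack()
        inter = cell_means.sub(cell_means.mean(axis=1), axis=0).sub(
            cell_means.mean(axis=0), axis=1
        ) + float(cell_means.to_numpy().mean())
        dof = (cell_means.shape[0] - 1) * (n_e - 1)
        ms_ge = float(np.nansum(inter.to_numpy() ** 2)) / dof * r_bar
        s2_ge = max((ms_ge - ms_eps) / r_bar, 0.0)
        s2_g = max((ms_g - ms_ge) / (n_e * r_bar), 0.0)
    else:
        s2_ge = 0.0
        s2_g = max((ms_g - ms_eps) / r_bar, 0.0)
    return s2_g, s2_ge, max(ms_eps, 0.0)


def variance_components(values, design: TrialDesign) -> VarianceComponents:
    """REML variance components for one trait.

    Repeats within a replicate must be pre-averaged by the caller (see
    :func:`h2_spectrum`, which does this for spectra).  Components are
    truncated at zero; a single-environment design fixes sigma2_ge = 0 with
    a logged note.
    """
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        {"y": values, "g": design.genotype, "e": design.environment, "r": design.replicate}
    )
    if df["g"].nunique() < 2:
        raise DegenerateDesignError("variance components need at least 2 genotypes")
    n_env = df["e"].nunique()
    single_rep = df.groupby(["g", "e"])["r"].nunique().max() == 1
    if n_env == 1 and single_rep:
        # one observation per genotype: genotype and residual are confounded;
        # by convention all between-genotype variance is genotypic
        logger.info("unreplicated single-environment design: residual set to 0")
        s2_g = float(df.groupby("g")["y"].mean().var(ddof=1))
        return VarianceComponents.from_components(
            s2_g, 0.0, 0.0, design.n_environments, design.n_replicates
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if n_env > 1 and not single_rep:
                md = sm.MixedLM.from_formula(
                    "y ~ C(e)", groups="g", re_formula="1",
                    vc_formula={"ge": "0 + C(e)"}, data=df,
                )
                fit = md.fit(reml=True)
                s2_g = float(fit.cov_re.iloc[0, 0])
                s2_ge = float(np.asarray(fit.vcomp).ravel()[0])
                s2_eps = float(fit.scale)
            elif n_env > 1 and single_rep:
                # one replicate per cell: GxE and residual are confounded;
                # the cell-level residual absorbs both and sigma2_ge = 0
                md = sm.MixedLM.from_formula("y ~ C(e)", groups="g", re_formula="1", data=df)
                fit = md.fit(reml=True)
                s2_g = float(fit.cov_re.iloc[0, 0])
                s2_ge = 0.0
                s2_eps = float(fit.scale)
            else:
                logger.info("single environment: sigma2_ge fixed at 0")
                md = sm.MixedLM.from_formula("y ~ 1", groups="g", re_formula="1", data=df)
                fit = md.fit(reml=True)
                s2_g = float(fit.cov_re.iloc[0, 0])
                s2_ge = 0.0
                s2_eps = float(fit.scale)
        if not np.isfinite([s2_g, s2_ge, s2_eps]).all():
            raise ValueError("non-finite REML estimates")
        total_var = float(np.var(values)) or 1.0
        if s2_eps < 1e-9 * total_var:
            # noiseless limit: the REML surface is singular and MixedLM's
            # split between components is arbitrary; moments are exact here
            raise ValueError("degenerate residual variance")
    except Exception as exc:  # convergence/LinAlg failures -> moments fallback
        logger.info("MixedLM unusable (%s); using ANOVA moment estimator", exc)
        s2_g, s2_ge, s2_eps = _anova_components(df)
    return VarianceComponents.from_components(
        s2_g, s2_ge, s2_eps, design.n_environments, design.n_replicates
    )


def broad_sense_h2(vc: VarianceComponents, n_e: float, n_r: float) -> float:
    """H2 = sigma2_g / sigma2_p on the entry-mean basis; NaN if sigma2_p = 0."""
    sigma2_p = vc.sigma2_g + vc.sigma2_ge / n_e + vc.sigma2_eps / (n_e * n_r)
    if sigma2_p == 0.0:
        return np.nan
    return vc.sigma2_g / sigma2_p


@dataclass
class HeritabilityResults:
    """Per-wavelength variance components and H2."""

    grid: WavelengthGrid
    components: list[VarianceComponents]
    h2: np.ndarray
    n_e: float
    n_r: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.grid.wavelengths,
                "sigma2_g": [c.sigma2_g for c in self.components],
                "sigma2_ge": [c.sigma2_ge for c in self.components],
                "sigma2_eps": [c.sigma2_eps for c in self.components],
                "sigma2_p": [c.sigma2_p for c in self.components],
                "h2": self.h2,
                "n_e_eff": self.n_e,
                "n_r_eff": self.n_r,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    def summary(self) -> str:
        h = self.h2[np.isfinite(self.h2)]
        lines = [
            "Broad-sense heritability of reflectance",
            f"  wavelengths: {len(self.grid)}   n_e_eff: {self.n_e:.3g}   n_r_eff: {self.n_r:.3g}",
            f"  H2 range: {h.min():.3f} .. {h.max():.3f}   median: {np.median(h):.3f}",
        ]
        return "\n".join(lines)


class SpectralHeritability:
    """Heritability model over a reflectance dataset with trial metadata.

    ``SpectralHeritability(dataset).fit()`` averages repeats within each
    replicate, then fits the variance-component model independently at each
    wavelength.
    """

    def __init__(self, dataset: SpectralDataset):
        missing = [c for c in _REQUIRED_META if c not in dataset.meta.columns]
        if missing:
            raise SchemaError(f"dataset metadata missing columns {missing}")
        self.dataset = dataset

    def fit(self) -> HeritabilityResults:
        ds = self.dataset
        meta = ds.meta
        keys = ["genotype_id", "environment_id", "replicate_id"]
        # average repeats: one value per genotype x environment x replicate
        frame = pd.DataFrame(ds.values)
        frame[keys] = meta[keys].to_numpy()
        collapsed = frame.groupby(keys, sort=False, as_index=False).mean()
        design = TrialDesign.from_frame(
            collapsed[keys].rename(
                columns=dict(zip(keys, ["genotype_id", "environment_id", "replicate_id"]))
            )
        )
        value_cols = [c for c in collapsed.columns if c not in keys]
        comps = []
        h2 = np.empty(len(ds.grid))
        for j, col in enumerate(value_cols):
            vc = variance_components(collapsed[col].to_numpy(), design)
            comps.append(vc)
            h2[j] = broad_sense_h2(vc, design.n_environments, design.n_replicates)
        return HeritabilityResults(ds.grid, comps, h2, design.n_environments, design.n_replicates)


def h2_spectrum(ds: SpectralDataset) -> HeritabilityResults:
    """Per-wavelength broad-sense heritability of a reflectance dataset."""
    return SpectralHeritability(ds).fit()
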