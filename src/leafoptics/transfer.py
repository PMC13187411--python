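"""Cross-dataset trait-model transferability and one-at-a-time sensitivity.

The transfer protocol: fit a regression model (PLSR with 30 latent
variables, or the NN surrogate) from reflectance to one trait on each full
dataset, then score it on every other full dataset — no internal split; the
diagonal is training-set performance and is labelled as such.  Scores are
the Pearson correlation r and the coefficient of determination
R^2 = 1 - SS_res/SS_tot on the test set, with a clamped copy
max(R^2, -1) for display on a common scale.

The sensitivity analysis varies one trait at a time: each sample keeps its
actual value of the probed trait while the other five are fixed at the
dataset means; the per-wavelength coefficient of variation CV = sigma/mu of
the simulated ensemble measures how strongly that trait moves the spectrum,
and where.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .exceptions import (
    DegenerateResponseError,
    GridMismatchError,
    InsufficientSamplesError,
)
from .prospect import TRAIT_NAMES, LeafTraits, OpticalConstants, forward_spectrum
from .spectra import SpectralDataset, WavelengthGrid

logger = logging.getLogger(__name__)

DEFAULT_N_COMPONENTS = 30


@dataclass
class TraitModel:
    """A fitted reflectance -> trait regression (PLSR)."""

    trait_name: str
    n_components: int
    estimator: PLSRegression
    training_dataset_id: str = ""

    def predict(self, X: SpectralDataset | np.ndarray) -> np.ndarray:
        values = X.values if isinstance(X, SpectralDataset) else np.asarray(X, float)
        return self.estimator.predict(values).ravel()


class Scores(NamedTuple):
    r: float
    r2: float
    r2_clamped: float


def fit_plsr_trait_model(
    X: SpectralDataset,
    y: np.ndarray,
    n_components: int = DEFAULT_N_COMPONENTS,
    trait_name: str = "",
    training_dataset_id: str = "",
) -> TraitModel:
    """Standard PLSR from reflectance columns to one trait.

    Predictors are raw reflectance values; PLSR's standard column
    mean-centering is the only preprocessing (no unit-variance scaling).
    The component count is capped at the feasibility bound
    min(n_samples - 1, n_wavelengths) with a logged warning.
    """
    y = np.asarray(y, dtype=float)
    if X.n_samples < 2:
        raise InsufficientSamplesError("PLSR needs at least 2 training samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("trait values must be finite")
    if np.ptp(y) == 0:
        raise DegenerateResponseError(f"constant response for trait {trait_name!r}")
    cap = min(X.n_samples - 1, len(X.grid))
    if n_components > cap:
        logger.warning(
            "PLSR components capped at %d (requested %d) for trait %r",
            cap, n_components, trait_name,
        )
        n_components = cap
    est = PLSRegression(n_components=n_components, scale=False)
    est.fit(X.values, y)
    return TraitModel(trait_name, n_components, est, training_dataset_id)


def prediction_scores(y_true, y_pred) -> Scores:
    """Pearson r, coefficient of determination R^2, and clamped R^2.

    Constant ``y_true`` makes both undefined (NaN markers).  The clamp
    replaces R^2 < -1 by -1 so failed transfers share a display scale.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 3:
        raise InsufficientSamplesError("scores need at least 3 observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        return Scores(np.nan, np.nan, np.nan)
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    sp = float(np.std(y_pred))
    if sp == 0.0:
        r = np.nan
    else:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return Scores(r, r2, max(r2, -1.0))


@dataclass
class TransferScoreMatrix:
    """train x test x trait grid of (r, R^2, clamped R^2) scores."""

    table: pd.DataFrame  # columns: train_id, test_id, trait, r, r2, r2_clamped

    def get(self, train_id: str, test_id: str, trait: str) -> Scores:
        row = self.table[
            (self.table.train_id == train_id)
            & (self.table.test_id == test_id)
            & (self.table.trait == trait)
        ]
        if row.empty:
            raise KeyError((train_id, test_id, trait))
        row = row.iloc[0]
        return Scores(row.r, row.r2, row.r2_clamped)

    @property
    def train_ids(self) -> list[str]:
        return sorted(self.table.train_id.unique())

    @property
    def test_ids(self) -> list[str]:
        return sorted(self.table.test_id.unique())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.9g")


def transfer_matrix(
    datasets: Mapping[str, tuple[SpectralDataset, pd.DataFrame]],
    traits: Sequence[str] = TRAIT_NAMES,
    model_kind: str = "plsr",
    n_components: int = DEFAULT_N_COMPONENTS,
    surrogate_hyperparams=None,
) -> TransferScoreMatrix:
    """Full train x test x trait transfer grid, including train = test.

    ``datasets`` maps labels to (reflectance dataset, per-sample trait
    table).  Each model is fitted on one full dataset and scored on every
    full dataset; the diagonal entries are training-set performance.
    """
    if len(datasets) < 2:
        raise ValueError("transfer analysis requires at least 2 datasets")
    labels = list(datasets)
    grid0 = datasets[labels[0]][0].grid
    for lab in labels[1:]:
        if datasets[lab][0].grid != grid0:
            raise GridMismatchError(
                f"datasets {labels[0]!r} and {lab!r} are on different grids"
            )
    rows = []
    for train_id in labels:
        X_tr, y_tr = datasets[train_id]
        for trait in traits:
            if model_kind == "plsr":
                model = fit_plsr_trait_model(
                    X_tr, y_tr[trait].to_numpy(), n_components, trait, train_id
                )
            elif model_kind == "surrogate_nn":
                from .surrogate import SurrogateHyperparams, train_surrogate

                hp = surrogate_hyperparams or SurrogateHyperparams.for_trait(trait)
                model = train_surrogate((X_tr, y_tr[trait].to_numpy()), hp)
            else:
                raise ValueError(f"unknown model_kind {model_kind!r}")
            for test_id in labels:
                X_te, y_te = datasets[test_id]
                s = prediction_scores(y_te[trait].to_numpy(), model.predict(X_te))
                rows.append(
                    {
                        "train_id": train_id,
                        "test_id": test_id,
                        "trait": trait,
                        "r": s.r,
                        "r2": s.r2,
                        "r2_clamped": s.r2_clamped,
                    }
                )
    return TransferScoreMatrix(pd.DataFrame(rows))


@dataclass
class SensitivityProfile:
    """Per-wavelength ensemble statistics for one varied trait.

    CV is NaN (undefined marker) where the ensemble mean is zero; such
    wavelengths are excluded from summaries.
    """

    trait_name: str
    grid: WavelengthGrid
    mean: np.ndarray
    sd: np.ndarray
    cv: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": self.trait_name,
                "wavelength_nm": self.grid.wavelengths,
                "mean": self.mean,
                "sd": self.sd,
                "cv": self.cv,
            }
        )


def sensitivity_profiles(
    p_inv: pd.DataFrame, constants: OpticalConstants
) -> dict[str, SensitivityProfile]:
    """One-at-a-time sensitivity of the forward model to each trait.

    For each trait: every sample is re-simulated with that trait at its
    actual value and the other five held at the dataset means; the ensemble
    mean, sd and CV = sd/mean per wavelength form the profile.
    """
    if len(p_inv) < 2:
        raise InsufficientSamplesError("sensitivity analysis needs at least 2 samples")
    means = {n: float(p_inv[n].mean()) for n in TRAIT_NAMES}
    out: dict[str, SensitivityProfile] = {}
    for trait in TRAIT_NAMES:
        ens = []
        for v in p_inv[trait].to_numpy(dtype=float):
            kwargs = dict(means)
            kwargs[trait] = v
            ens.append(forward_spectrum(LeafTraits(**kwargs), constants).reflectance)
        ens = np.array(ens)
        mu = ens.mean(axis=0)
        sd = ens.std(axis=0)
        cv = np.full_like(mu, np.nan)
        nz = mu != 0
        cv[nz] = sd[nz] / mu[nz]
        out[trait] = SensitivityProfile(trait, constants.grid, mu, sd, cv)
    return out


def write_sensitivity_csv(profiles: Mapping[str, SensitivityProfile], path) -> None:
    pd.concat([p.to_frame() for p in profiles.values()], ignore_index=True).to_csv(
        path, index=False, float_format="%.9g"
    )
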