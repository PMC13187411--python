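"""Variance components, broad-sense heritability, and the spectral model."""

import numpy as np
import pandas as pd
import pytest

import leafoptics as lo
from leafoptics.exceptions import DegenerateDesignError, SchemaError
from leafoptics.heritability import TrialDesign, VarianceComponents


def balanced_design(n_geno, n_env=2, n_rep=2):
    g, e, r = [], [], []
    for i in range(n_geno):
        for j in range(n_env):
            for k in range(n_rep):
                g.append(f"g{i}")
                e.append(f"e{j}")
                r.append(f"r{k}")
    return TrialDesign.from_frame(
        pd.DataFrame({"genotype_id": g, "environment_id": e, "replicate_id": r})
    )


class TestBroadSenseH2:
    def test_worked_example(self):
        # 2 / (2 + 1/2 + 2/4) = 2/3
        vc = VarianceComponents.from_components(2.0, 1.0, 2.0, 2, 2)
        assert lo.broad_sense_h2(vc, 2, 2) == pytest.approx(2.0 / 3.0, abs=1e-15)

    def test_no_genetic_variance_gives_zero(self):
        vc = VarianceComponents.from_components(0.0, 1.0, 2.0, 2, 2)
        assert lo.broad_sense_h2(vc, 2, 2) == 0.0

    def test_pure_genetic_variance_gives_one(self):
        vc = VarianceComponents.from_components(3.0, 0.0, 0.0, 2, 2)
        assert lo.broad_sense_h2(vc, 2, 2) == 1.0

    def test_zero_phenotypic_variance_is_undefined(self):
        vc = VarianceComponents.from_components(0.0, 0.0, 0.0, 2, 2)
        assert np.isnan(lo.broad_sense_h2(vc, 2, 2))

    def test_entry_mean_identity_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g, ge, eps = rng.uniform(0, 5, 3)
            n_e, n_r = rng.integers(1, 4), rng.integers(1, 4)
            vc = VarianceComponents.from_components(g, ge, eps, n_e, n_r)
            assert vc.sigma2_p == vc.sigma2_g + vc.sigma2_ge / n_e + vc.sigma2_eps / (
                n_e * n_r
            )

    def test_monotone_in_genetic_variance(self):
        for ge in (0.0, 1.0, 3.0):
            for eps in (0.5, 2.0):
                h2 = [
                    lo.broad_sense_h2(
                        VarianceComponents.from_components(g, ge, eps, 2, 2), 2, 2
                    )
                    for g in np.linspace(0.1, 10, 25)
                ]
                assert np.all(np.diff(h2) > 0)


class TestVarianceComponents:
    def test_noiseless_genotype_signal(self):
        rng = np.random.default_rng(1)
        design = balanced_design(15)
        geno_vals = {f"g{i}": rng.normal(0, 2) for i in range(15)}
        values = np.array([geno_vals[g] for g in design.genotype])
        vc = lo.variance_components(values, design)
        assert vc.sigma2_eps == pytest.approx(0.0, abs=1e-8)
        assert vc.sigma2_ge == pytest.approx(0.0, abs=1e-8)
        between = np.var(list(geno_vals.values()), ddof=1)
        assert vc.sigma2_g == pytest.approx(between, rel=0.05)

    def test_pure_noise_has_no_genetic_variance(self):
        rng = np.random.default_rng(2)
        design = balanced_design(60)
        values = rng.normal(0, 1.0, len(design.genotype))
        vc = lo.variance_components(values, design)
        assert vc.sigma2_g < 0.08
        assert vc.sigma2_eps == pytest.approx(1.0, rel=0.25)

    def test_balanced_trial_component_recovery(self):
        """Generative recovery: sigma2_g=2, sigma2_ge=1, sigma2_eps=2."""
        spec = lo.TrialSpec(
            n_genotypes=100, replicates=(2, 2), repeats=(1, 1), repeat_sd=0.0
        )
        est = {"sigma2_g": [], "sigma2_ge": [], "sigma2_eps": []}
        for seed in range(8):
            frame, truth = lo.simulate_trial_values(spec, seed=seed)
            design = TrialDesign.from_frame(frame)
            vc = lo.variance_components(frame["value"].to_numpy(), design)
            for k in est:
                est[k].append(getattr(vc, k))
        for k, target in [("sigma2_g", 2.0), ("sigma2_ge", 1.0), ("sigma2_eps", 2.0)]:
            assert np.mean(est[k]) == pytest.approx(target, rel=0.15), k

    def test_single_environment_fixes_ge_at_zero(self):
        rng = np.random.default_rng(3)
        design = balanced_design(20, n_env=1, n_rep=3)
        values = rng.normal(0, 1, len(design.genotype))
        vc = lo.variance_components(values, design)
        assert vc.sigma2_ge == 0.0

    def test_fewer_than_two_genotypes_rejected(self):
        design = balanced_design(1)
        with pytest.raises(DegenerateDesignError):
            lo.variance_components(np.zeros(len(design.genotype)), design)

    def test_harmonic_mean_counts_for_unbalanced_designs(self):
        meta = pd.DataFrame(
            {
                "genotype_id": ["a", "a", "a", "b", "b"],
                "environment_id": ["e0", "e0", "e1", "e0", "e0"],
                "replicate_id": ["r0", "r1", "r0", "r0", "r1"],
            }
        )
        design = TrialDesign.from_frame(meta)
        assert design.n_environments == pytest.approx(2 / (1 / 2 + 1 / 1))
        # replicate counts per genotype-environment cell: 2, 1, 2
        assert design.n_replicates == pytest.approx(3 / (1 / 2 + 1 / 1 + 1 / 2))


def spectral_trial(n_geno=40, seed=0, signal_wavelengths=slice(3, 6)):
    """Reflectance-scale trial: genotype effects injected only at some
    wavelengths, environment+residual noise everywhere."""
    rng = np.random.default_rng(seed)
    grid = lo.WavelengthGrid(np.linspace(500.0, 2400.0, 6))
    rows, meta = [], []
    geno_eff = rng.normal(0, 0.05, n_geno)
    for i in range(n_geno):
        for j in range(2):
            for k in range(2):
                base = np.full(len(grid), 0.4)
                base[signal_wavelengths] += geno_eff[i]
                base += rng.normal(0, 0.02, len(grid))  # residual everywhere
                rows.append(np.clip(base, 0, 1))
                meta.append(
                    {"sample_id": f"s{i}_{j}_{k}", "genotype_id": f"g{i}",
                     "environment_id": f"e{j}", "replicate_id": f"r{k}",
                     "repeat_id": "q0"}
                )
    return lo.SpectralDataset(grid, np.array(rows), pd.DataFrame(meta))


class TestSpectralHeritability:
    def test_genotype_signal_localized_in_wavelength(self):
        ds = spectral_trial()
        res = lo.h2_spectrum(ds)
        assert np.all(res.h2[:3] < 0.35)
        assert np.all(res.h2[3:] > 0.6)

    def test_noiseless_single_environment_signal_is_fully_heritable(self):
        rng = np.random.default_rng(4)
        grid = lo.WavelengthGrid(np.array([500.0, 1500.0]))
        n_geno = 10
        rows, meta = [], []
        for i in range(n_geno):
            rows.append([0.2 + 0.3 * rng.random(), 0.5])
            meta.append(
                {"sample_id": f"s{i}", "genotype_id": f"g{i}",
                 "environment_id": "e0", "replicate_id": "r0", "repeat_id": "q0"}
            )
        ds = lo.SpectralDataset(grid, np.array(rows), pd.DataFrame(meta))
        res = lo.h2_spectrum(ds)
        assert res.h2[0] == pytest.approx(1.0, abs=1e-6)
        assert np.isnan(res.h2[1])  # constant column: no phenotypic variance

    def test_matches_direct_per_wavelength_calls(self):
        ds = spectral_trial(n_geno=15, seed=5)
        res = lo.h2_spectrum(ds)
        keys = ["genotype_id", "environment_id", "replicate_id"]
        frame = pd.DataFrame(ds.values)
        frame[keys] = ds.meta[keys].to_numpy()
        collapsed = frame.groupby(keys, sort=False, as_index=False).mean()
        design = TrialDesign.from_frame(collapsed[keys])
        for j in (0, 4):
            vc = lo.variance_components(collapsed[j].to_numpy(), design)
            h2 = lo.broad_sense_h2(vc, design.n_environments, design.n_replicates)
            assert res.h2[j] == pytest.approx(h2, abs=1e-12)

    def test_repeats_are_averaged_before_fitting(self):
        ds = spectral_trial(n_geno=12, seed=6)
        # duplicate every row as a second repeat with offset noise; averaging
        # repeats must keep the fit finite and H2 within [0, 1]
        values = np.concatenate([ds.values, np.clip(ds.values + 0.01, 0, 1)])
        meta2 = ds.meta.copy()
        meta2["repeat_id"] = "q1"
        meta2["sample_id"] = meta2["sample_id"] + "_b"
        meta = pd.concat([ds.meta, meta2], ignore_index=True)
        res = lo.h2_spectrum(lo.SpectralDataset(ds.grid, values, meta))
        finite = np.isfinite(res.h2)
        assert np.all((res.h2[finite] >= 0) & (res.h2[finite] <= 1))

    def test_missing_metadata_rejected(self, wide_spectra):
        with pytest.raises(SchemaError, match="genotype_id"):
            lo.h2_spectrum(wide_spectra)

    def test_results_frame_layout(self):
        ds = spectral_trial(n_geno=10, seed=7)
        frame = lo.h2_spectrum(ds).to_frame()
        assert list(frame.columns) == [
            "wavelength_nm", "sigma2_g", "sigma2_ge", "sigma2_eps", "sigma2_p",
            "h2", "n_e_eff", "n_r_eff",
        ]
        ok = np.isfinite(frame.h2)
        assert ((frame.h2[ok] >= 0) & (frame.h2[ok] <= 1)).all()


class TestEndToEndTrialRecovery:
    def test_h2_recovered_at_trait_sensitive_wavelengths(self, constants):
        """A CHL-axis trial pushed through the forward model recovers the
        generative H2 = 2/3 at CHL-sensitive wavelengths."""
        spec = lo.TrialSpec(
            n_genotypes=60, replicates=(2, 2), repeats=(1, 1), repeat_sd=0.0
        )
        h2_at_edge = []
        wl = constants.grid.wavelengths
        edge = np.argmin(np.abs(wl - 769.0))  # red edge: strong CHL response
        keep = [edge - 1, edge, edge + 1]
        for seed in range(3):
            ds = lo.simulate_population_trial(spec, constants, seed=seed)
            small = lo.SpectralDataset(
                lo.WavelengthGrid(wl[keep]), ds.values[:, keep], ds.meta
            )
            res = lo.h2_spectrum(small)
            h2_at_edge.append(res.h2[1])
        assert np.mean(h2_at_edge) == pytest.approx(2.0 / 3.0, abs=0.12)
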