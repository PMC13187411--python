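"""Plate-model forward engine against independent physical oracles.

Oracles: hemispherical quadrature of the Fresnel transmittance for the
interface average; slab quadrature 2*int mu e^{-k/mu} dmu for the
elementary layer; explicit ray summation for the single plate; iterative
layer-adding for the Stokes stack.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

import leafoptics as lo
from leafoptics.exceptions import DomainError, NonPhysicalLayerError, SchemaError
from leafoptics.prospect import read_constants_csv, write_constants_csv


def fresnel_transmittance(theta, n):
    ci = np.cos(theta)
    st_ = np.sin(theta) / n
    if st_ >= 1:
        return 0.0
    ct = np.sqrt(1 - st_**2)
    rs = ((ci - n * ct) / (ci + n * ct)) ** 2
    rp = ((n * ci - ct) / (n * ci + ct)) ** 2
    return 1 - (rs + rp) / 2


def tav_quadrature(alpha_deg, n):
    a = np.radians(alpha_deg)
    num = quad(lambda t: fresnel_transmittance(t, n) * np.sin(t) * np.cos(t), 0, a, limit=200)[0]
    den = quad(lambda t: np.sin(t) * np.cos(t), 0, a)[0]
    return num / den


def slab_quadrature(k):
    return 2 * quad(
        lambda mu: mu * np.exp(-k / mu), 0, 1, limit=800, epsabs=1e-13, epsrel=1e-13
    )[0]


class TestAverageTransmissivity:
    def test_no_interface_when_n_is_one(self):
        assert lo.average_transmissivity(40.0, 1.0) == 1.0
        assert lo.average_transmissivity(90.0, 1.0) == 1.0

    # frozen from the quadrature oracle above
    @pytest.mark.parametrize(
        "alpha,n,expected",
        [
            (90.0, 1.5, 0.908222040657649),
            (40.0, 1.5, 0.9584240357068674),
            (40.0, 1.3, 0.9819883408606986),
            (40.0, 1.6, 0.9449975551072364),
            (59.0, 1.45, 0.9575401498174343),
        ],
    )
    def test_matches_fresnel_quadrature(self, alpha, n, expected):
        assert lo.average_transmissivity(alpha, n) == pytest.approx(expected, abs=1e-6)

    def test_monotone_decreasing_in_n(self):
        assert lo.average_transmissivity(40.0, 1.3) > lo.average_transmissivity(40.0, 1.6)

    @pytest.mark.parametrize("alpha,n", [(0.0, 1.5), (91.0, 1.5), (40.0, 0.9)])
    def test_domain_errors(self, alpha, n):
        with pytest.raises(DomainError):
            lo.average_transmissivity(alpha, n)

    @given(
        alpha=st.floats(min_value=5.0, max_value=90.0),
        n=st.floats(min_value=1.0, max_value=2.0),
    )
    def test_value_in_unit_interval(self, alpha, n):
        t = lo.average_transmissivity(alpha, n)
        assert 0.0 < t <= 1.0


class TestLayerTransmission:
    def test_limit_value_at_zero(self):
        assert lo.layer_transmission(0.0) == 1.0

    # frozen from the slab quadrature oracle
    @pytest.mark.parametrize(
        "k,expected,tol",
        [(0.5, 0.4432087285504022, 1e-8), (10.0, 7.097525106168658e-06, 1e-10)],
    )
    def test_matches_slab_quadrature_frozen(self, k, expected, tol):
        assert lo.layer_transmission(k) == pytest.approx(expected, abs=tol)

    def test_strong_absorption_is_opaque(self):
        assert lo.layer_transmission(10.0) < 1e-4

    def test_matches_quadrature_on_log_grid(self):
        ks = np.logspace(-6, np.log10(50.0), 25)
        tau = lo.layer_transmission(ks)
        oracle = np.array([slab_quadrature(k) for k in ks])
        assert np.max(np.abs(tau - oracle)) < 1e-8

    def test_strictly_decreasing(self):
        ks = np.linspace(0.0, 5.0, 200)
        assert np.all(np.diff(lo.layer_transmission(ks)) < 0)

    def test_negative_absorption_rejected(self):
        with pytest.raises(DomainError):
            lo.layer_transmission(-0.1)


class TestTotalAbsorption:
    def test_zero_contents_give_zero(self, constants):
        tr = lo.LeafTraits(N=1.5, CHL=0, CAR=0, ANT=0, EWT=0, LMA=0)
        assert np.all(lo.total_absorption(tr, constants) == 0)

    def test_linear_in_contents_and_inverse_in_n(self, constants):
        tr = lo.LeafTraits(N=2.0, CHL=40, CAR=8, ANT=2, EWT=0.01, LMA=0.005)
        k = lo.total_absorption(tr, constants)
        doubled = lo.LeafTraits(N=2.0, CHL=80, CAR=16, ANT=4, EWT=0.02, LMA=0.01)
        assert lo.total_absorption(doubled, constants) == pytest.approx(2 * k, rel=1e-12)
        deep = lo.LeafTraits(N=4.0, CHL=40, CAR=8, ANT=2, EWT=0.01, LMA=0.005)
        assert lo.total_absorption(deep, constants) == pytest.approx(k / 2, rel=1e-12)


class TestSinglePlate:
    def test_opaque_plate(self):
        r, t = lo.plate_single_layer(0.0, 1.4, 40.0)
        assert t == 0.0
        assert r == pytest.approx(1.0 - lo.average_transmissivity(40.0, 1.4), abs=1e-14)

    def test_energy_conserved_without_absorption(self):
        r, t = lo.plate_single_layer(1.0, 1.4, 40.0)
        assert r + t == pytest.approx(1.0, abs=1e-12)

    def test_matches_ray_summation_oracle(self):
        tau, n, alpha = 0.8, 1.4, 40.0
        t_top = tav_quadrature(alpha, n)
        t90 = tav_quadrature(90.0, n)
        t21 = t90 / n**2
        r21 = 1 - t21
        T_sum, R_sum = 0.0, 1 - t_top
        amp = t_top * tau
        for _ in range(10**4):
            T_sum += amp * t21
            amp_up = amp * r21 * tau
            R_sum += amp_up * t21
            amp = amp_up * r21 * tau
        r, t = lo.plate_single_layer(tau, n, alpha)
        # oracle's own interface averages are good to ~1e-9; compare there
        assert t == pytest.approx(T_sum, abs=1e-8)
        assert r == pytest.approx(R_sum, abs=1e-8)


class TestStokesStack:
    def test_single_layer_identity(self):
        assert lo.stokes_stack(0.12, 0.63, 1.0) == pytest.approx((0.12, 0.63), abs=1e-12)

    def test_two_layer_adding_formula(self):
        r, t = 0.1, 0.7
        R2 = r + t**2 * r / (1 - r**2)
        T2 = t**2 / (1 - r**2)
        assert lo.stokes_stack(r, t, 2.0) == pytest.approx((R2, T2), abs=1e-12)

    def test_opaque_stack(self):
        for m in (1.0, 2.5, 4.0):
            R, T = lo.stokes_stack(0.23, 0.0, m)
            assert T == 0.0 and R == pytest.approx(0.23, abs=1e-14)

    def test_nonphysical_layer_rejected(self):
        with pytest.raises(NonPhysicalLayerError):
            lo.stokes_stack(0.6, 0.5, 2.0)

    @pytest.mark.parametrize("n_layers", [2, 3, 4, 5])
    def test_agrees_with_iterative_layer_adding(self, n_layers):
        rng = np.random.default_rng(11)
        for _ in range(20):
            r = rng.uniform(0.01, 0.45)
            t = rng.uniform(0.01, 1 - r - 0.02)
            Ra, Ta = r, t
            for _ in range(n_layers - 1):
                denom = 1 - Ra * r
                Ta, Ra = Ta * t / denom, r + t**2 * Ra / denom
            R, T = lo.stokes_stack(r, t, float(n_layers))
            assert R == pytest.approx(Ra, abs=1e-10)
            assert T == pytest.approx(Ta, abs=1e-10)

    def test_conservative_branch_continuous(self):
        # r + t = 1 exactly vs just below: results should agree closely
        R1, T1 = lo.stokes_stack(0.3, 0.7, 3.0)
        R2, T2 = lo.stokes_stack(0.3, 0.7 - 1e-9, 3.0)
        assert R1 == pytest.approx(R2, abs=1e-6)
        assert T1 == pytest.approx(T2, abs=1e-6)


class TestForwardSpectrum:
    def test_flat_constants_give_flat_spectra(self, desk_grid):
        flat = lo.OpticalConstants(
            desk_grid,
            np.full(len(desk_grid), 1.45),
            {c: np.zeros(len(desk_grid)) for c in lo.CONSTITUENTS},
        )
        tr = lo.LeafTraits(N=2.0, CHL=0, CAR=0, ANT=0, EWT=0, LMA=0)
        sp = lo.forward_spectrum(tr, flat)
        assert np.ptp(sp.reflectance) < 1e-12
        assert np.ptp(sp.transmittance) < 1e-12

    def test_reflectance_decreases_with_chlorophyll(self, constants):
        base = dict(N=1.8, CHL=20.0, CAR=5.0, ANT=1.0, EWT=0.01, LMA=0.005)
        lo_sp = lo.forward_spectrum(lo.LeafTraits(**base), constants)
        base["CHL"] = 60.0
        hi_sp = lo.forward_spectrum(lo.LeafTraits(**base), constants)
        absorbing = constants.specific_absorption["CHL"] > 0
        assert np.all(hi_sp.reflectance[absorbing] <= lo_sp.reflectance[absorbing])
        assert np.any(hi_sp.reflectance[absorbing] < lo_sp.reflectance[absorbing])

    def test_energy_budget_over_random_draws(self, constants):
        rng = np.random.default_rng(21)
        for _ in range(100):
            tr = lo.LeafTraits(
                N=rng.uniform(1.0, 4.0),
                CHL=rng.uniform(0, 120),
                CAR=rng.uniform(0, 30),
                ANT=rng.uniform(0, 40),
                EWT=rng.uniform(0, 0.1),
                LMA=rng.uniform(0, 0.05),
            )
            sp = lo.forward_spectrum(tr, constants)
            total = sp.reflectance + sp.transmittance
            assert np.all(sp.reflectance >= 0) and np.all(sp.transmittance >= 0)
            assert np.all(total <= 1.0 + 1e-9)

    def test_continuity_in_structure_parameter(self, constants):
        base = dict(CHL=40.0, CAR=9.0, ANT=1.5, EWT=0.012, LMA=0.006)
        lo_sp = lo.forward_spectrum(lo.LeafTraits(N=1.999, **base), constants)
        hi_sp = lo.forward_spectrum(lo.LeafTraits(N=2.001, **base), constants)
        assert np.max(np.abs(lo_sp.reflectance - hi_sp.reflectance)) < 1e-3
        assert np.max(np.abs(lo_sp.transmittance - hi_sp.transmittance)) < 1e-3


class TestConstantsTable:
    def test_round_trip(self, constants, tmp_path):
        path = tmp_path / "constants.csv"
        write_constants_csv(constants, path)
        back = read_constants_csv(path)
        assert back.grid == constants.grid
        assert back.refractive_index == pytest.approx(constants.refractive_index, rel=1e-8)

    def test_sixth_absorber_rejected_not_ignored(self, constants, tmp_path):
        path = tmp_path / "constants.csv"
        write_constants_csv(constants, path)
        import pandas as pd

        df = pd.read_csv(path)
        df["K_BROWN"] = 0.01
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="K_BROWN"):
            read_constants_csv(path)

    def test_missing_column_rejected(self, constants, tmp_path):
        path = tmp_path / "constants.csv"
        write_constants_csv(constants, path)
        import pandas as pd

        pd.read_csv(path).drop(columns=["K_EWT"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="K_EWT"):
            read_constants_csv(path)

    def test_invalid_traits_rejected(self):
        with pytest.raises(DomainError):
            lo.LeafTraits(N=0.5, CHL=10, CAR=1, ANT=0, EWT=0.01, LMA=0.005)
        with pytest.raises(DomainError):
            lo.LeafTraits(N=1.5, CHL=-1, CAR=1, ANT=0, EWT=0.01, LMA=0.005)
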