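"""Two-site equilibrium, thermogram simulation and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttrkit.itc import (
    COOPERATIVE,
    NONCOOPERATIVE,
    Thermogram,
    TitrationProtocol,
    TwoSiteITCFitter,
    TwoSiteModel,
    binding_polynomial,
    cooperativity_index,
    fit_thermogram,
    simulate_thermogram,
    solve_free_ligand,
)


def bisect_free_ligand(L_total, P_total, model, iters=120):
    """Independent bisection oracle for the mass-balance root."""
    lo, hi = 0.0, L_total
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        st_ = binding_polynomial(mid, model)
        if mid + P_total * st_.nu - L_total > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


TOLCAPONE = TwoSiteModel.noncooperative(34e-9, -12.8)
M23 = TwoSiteModel.noncooperative(6.2e-9, -16.6)
TAFAMIDIS = TwoSiteModel.from_site_kds(9.9e-9, 260e-9, -6.0, -6.5)


class TestModelConstruction:
    def test_statistical_factor_identity(self):
        """Identical independent sites: K1 = 2k, K2 = k/2, c = 1."""
        k = 1.0 / 34e-9
        assert TOLCAPONE.K1 == pytest.approx(2 * k)
        assert TOLCAPONE.K2 == pytest.approx(k / 2)
        assert cooperativity_index(TOLCAPONE) == pytest.approx(1.0, rel=1e-12)
        assert TOLCAPONE.site_kd1 == pytest.approx(34e-9)
        assert TOLCAPONE.site_kd2 == pytest.approx(34e-9)

    def test_noncooperative_rejects_inconsistent_constants(self):
        with pytest.raises(ValueError):
            TwoSiteModel(K1=1e8, K2=1e8, dH1=-10, dH2=-10, mode=NONCOOPERATIVE)
        with pytest.raises(ValueError):
            TwoSiteModel(K1=2e8, K2=5e7, dH1=-10, dH2=-9, mode=NONCOOPERATIVE)

    def test_negative_cooperativity_index(self):
        """Site Kds 9.9 / 260 nM give c = 9.9/260 ≈ 0.038 < 1."""
        c = cooperativity_index(TAFAMIDIS)
        assert c == pytest.approx(9.9 / 260, rel=1e-9)
        assert c < 1

    @given(a=st.floats(0.1, 10.0))
    @settings(max_examples=25, derandomize=True)
    def test_cooperativity_invariant_under_joint_rescaling(self, a):
        m = TwoSiteModel(K1=a * TAFAMIDIS.K1, K2=a * TAFAMIDIS.K2,
                         dH1=-6.0, dH2=-6.5)
        assert cooperativity_index(m) == pytest.approx(
            cooperativity_index(TAFAMIDIS), rel=1e-12
        )


class TestBindingPolynomial:
    def test_zero_ligand(self):
        st_ = binding_polynomial(0.0, TOLCAPONE)
        assert st_.Z == 1.0 and st_.F0 == 1.0 and st_.nu == 0.0

    def test_saturation_limit(self):
        st_ = binding_polynomial(1.0, TOLCAPONE)  # 1 M >> Kd
        assert st_.F2 == pytest.approx(1.0, abs=1e-6)
        assert st_.nu == pytest.approx(2.0, abs=1e-6)

    def test_half_occupancy_at_micro_kd(self):
        """At L = micro-Kd each identical site is half occupied (ν = 1).

        Cross-checked by brute-force enumeration of the four microstates
        (site A empty/full × site B empty/full)."""
        kd = 34e-9
        st_ = binding_polynomial(kd, TOLCAPONE)
        assert st_.nu == pytest.approx(1.0, rel=1e-12)
        # enumeration: weights 1, L/kd, L/kd, (L/kd)^2 at L = kd
        w = np.array([1.0, 1.0, 1.0, 1.0])
        nu_brute = (w * np.array([0, 1, 1, 2])).sum() / w.sum()
        assert st_.nu == pytest.approx(nu_brute)

    def test_fractions_sum_to_one(self):
        for L in [0.0, 1e-9, 1e-6, 1e-3]:
            st_ = binding_polynomial(L, TAFAMIDIS)
            assert st_.F0 + st_.F1 + st_.F2 == pytest.approx(1.0, abs=1e-12)

    def test_negative_ligand_rejected(self):
        with pytest.raises(ValueError):
            binding_polynomial(-1e-9, TOLCAPONE)


class TestSolveFreeLigand:
    def test_no_binding_limits(self):
        weak = TwoSiteModel(K1=2e-6, K2=5e-7, dH1=-1, dH2=-1)
        st_ = solve_free_ligand(5e-6, 5e-6, weak)
        assert st_.L_free == pytest.approx(5e-6, rel=1e-6)
        st_ = solve_free_ligand(5e-6, 0.0, TOLCAPONE)
        assert st_.L_free == 5e-6

    def test_against_bisection_oracle(self):
        st_ = solve_free_ligand(5e-6, 5e-6, TwoSiteModel.noncooperative(1e-9, -10))
        oracle = bisect_free_ligand(5e-6, 5e-6, TwoSiteModel.noncooperative(1e-9, -10))
        assert st_.L_free == pytest.approx(oracle, rel=1e-9, abs=1e-18)

    def test_mass_conservation_random_instances(self):
        """Solver matches bisection and conserves mass on random draws."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            K1 = 10.0 ** rng.uniform(4, 10)
            K2 = 10.0 ** rng.uniform(4, 10)
            L_tot = 10.0 ** rng.uniform(-8, -4)
            P_tot = 10.0 ** rng.uniform(-8, -4)
            m = TwoSiteModel(K1=K1, K2=K2, dH1=-10, dH2=-10)
            st_ = solve_free_ligand(L_tot, P_tot, m)
            assert st_.nu * P_tot + st_.L_free == pytest.approx(
                L_tot, rel=1e-10, abs=1e-20
            )
            oracle = bisect_free_ligand(L_tot, P_tot, m)
            assert st_.L_free == pytest.approx(oracle, rel=1e-10, abs=1e-18)


class TestSimulateThermogram:
    def test_zero_enthalpy_gives_zero_heat(self):
        m = TwoSiteModel(K1=1e8, K2=2.5e7, dH1=0.0, dH2=0.0)
        tg = simulate_thermogram(m, TitrationProtocol())
        assert np.allclose(tg.heats, 0.0)

    def test_saturated_tail_approaches_dilution_offset(self):
        m = TwoSiteModel.noncooperative(6.2e-9, -16.6, q_dil=-0.2)
        proto = TitrationProtocol(injection_volumes=tuple([2e-6] * 35))
        tg = simulate_thermogram(m, proto)
        assert tg.molar_ratio[-1] > 5
        assert tg.heats[-1] == pytest.approx(-0.2, abs=0.02)

    def test_first_injection_near_full_binding(self):
        """With Kd << protein concentration, essentially all injected ligand
        binds, so the first heat is ~2x the per-step enthalpy average = ΔH."""
        tg = simulate_thermogram(TOLCAPONE, TitrationProtocol())
        assert tg.heats[0] == pytest.approx(-12.8, abs=0.1)

    def test_total_heat_equals_site_enthalpy_sum(self):
        """Integrated heat of a saturating titration = V0·P·(dH1 + dH2),
        within the displacement-correction bound."""
        proto = TitrationProtocol(injection_volumes=tuple([2e-6] * 60))
        tg = simulate_thermogram(TOLCAPONE, proto)
        total = float(np.sum(tg.heats * tg.injection_volumes * proto.syringe_conc))
        expected = proto.cell_volume * proto.cell_conc * (-12.8 * 2)
        # displacement correction and cell outflow bound the discrepancy
        assert total == pytest.approx(expected, rel=0.25)

    def test_molar_ratio_strictly_increasing(self):
        tg = simulate_thermogram(TAFAMIDIS, TitrationProtocol())
        assert np.all(np.diff(tg.molar_ratio) > 0)


class TestFitting:
    def test_noiseless_noncooperative_round_trip(self):
        """Refitting a noiseless simulation recovers micro-Kd 6.2 nM and
        ΔH −16.6 to 1e-6 relative."""
        tg = simulate_thermogram(M23, TitrationProtocol())
        res = fit_thermogram(tg, mode=NONCOOPERATIVE)
        assert res.converged
        assert res.model.site_kd1 == pytest.approx(6.2e-9, rel=1e-6)
        assert res.model.dH1 == pytest.approx(-16.6, rel=1e-6)
        assert res.rss <= 1e-12

    def test_noiseless_cooperative_round_trip(self):
        tg = simulate_thermogram(TAFAMIDIS, TitrationProtocol())
        res = fit_thermogram(tg, mode=COOPERATIVE)
        assert res.model.site_kd1 == pytest.approx(9.9e-9, rel=1e-6)
        assert res.model.site_kd2 == pytest.approx(260e-9, rel=1e-6)
        assert res.model.dH1 == pytest.approx(-6.0, rel=1e-6)
        assert res.model.dH2 == pytest.approx(-6.5, rel=1e-6)

    def test_cooperative_fit_of_noncooperative_data_finds_c_near_one(self):
        tg = simulate_thermogram(TOLCAPONE, TitrationProtocol())
        res = fit_thermogram(tg, mode=COOPERATIVE, fit_q_dil=False)
        assert cooperativity_index(res.model) == pytest.approx(1.0, rel=1e-3)

    def test_estimator_api(self):
        """sklearn-style surface: get_params/set_params/clone and predict."""
        from sklearn.base import clone

        est = TwoSiteITCFitter(mode=NONCOOPERATIVE, n_starts=3)
        assert est.get_params()["n_starts"] == 3
        est2 = clone(est).set_params(n_starts=2)
        assert est2.get_params()["n_starts"] == 2
        tg = simulate_thermogram(TOLCAPONE, TitrationProtocol())
        est.fit(tg)
        assert hasattr(est, "model_")
        np.testing.assert_allclose(est.predict(), tg.heats, atol=1e-9)

    def test_degenerate_and_short_inputs_rejected(self):
        proto = TitrationProtocol()
        with pytest.raises(ValueError):
            TwoSiteITCFitter().fit(np.zeros(19))
        with pytest.raises(ValueError):
            TwoSiteITCFitter(
                protocol=TitrationProtocol(injection_volumes=tuple([2e-6] * 5))
            ).fit(np.ones(5))
        with pytest.raises(ValueError):
            TwoSiteITCFitter().fit(np.ones(7))  # length mismatch vs 19

    def test_thermogram_csv_round_trip(self, tmp_path):
        tg = simulate_thermogram(TOLCAPONE, TitrationProtocol())
        path = tmp_path / "tg.csv"
        tg.to_csv(path)
        back = Thermogram.from_csv(path)
        np.testing.assert_allclose(back.heats, tg.heats, rtol=1e-12)
        np.testing.assert_allclose(back.molar_ratio, tg.molar_ratio, rtol=1e-12)


def test_protocol_yaml(tmp_path):
    path = tmp_path / "protocol.yaml"
    path.write_text(
        "cell_volume_uL: 200\ncell_conc_uM: 5\nsyringe_conc_uM: 100\n"
        "injection_volume_uL: 2\nn_injections: 19\ntemperature_C: 25\n"
    )
    proto = TitrationProtocol.from_yaml(path)
    assert proto.cell_volume == pytest.approx(200e-6)
    assert proto.cell_conc == pytest.approx(5e-6)
    assert len(proto.injection_volumes) == 19
    assert proto.temperature == pytest.approx(298.15)
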