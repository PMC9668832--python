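"""Anisotropic spectral density, forward relaxation model, and fitting."""

import numpy as np
import pandas as pd
import pytest

from amidyn import mfa, synth
from amidyn.constants import DEFAULT_CONSTANTS
from amidyn.mfa import (
    DiffusionTensor,
    LocalDynamics,
    ModelFreeAnalysis,
    aicc,
    anisotropic_J,
    fit_local,
    monte_carlo_errors,
    predict_observables,
    predict_rates,
    select_model,
    segment_mean,
    woessner_components,
)


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


class TestSpectralDensity:
    def test_isotropic_rigid_limit(self):
        tc = 7e-9
        t = DiffusionTensor(*(1 / (6 * tc),) * 3)
        for v in (_unit([1, 0, 0]), _unit([1, 1, 1]), _unit([0.2, -0.5, 0.9])):
            assert anisotropic_J(0.0, t, v) == pytest.approx(0.4 * tc, rel=1e-12)

    def test_amplitudes_sum_to_one_for_random_tensors_and_vectors(self, rng):
        for _ in range(20):
            D = rng.uniform(5e6, 5e7, 3)
            t = DiffusionTensor(*D, rng.uniform(0, 180))
            v = rng.normal(size=(50, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            A, _ = woessner_components(t, v)
            np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)

    @staticmethod
    def _axial_J(omega, Dperp, Dpar, z, S2, tau_int):
        """Independent closed-form axially-symmetric spectral density."""
        c2t = z * z
        s2t = 1 - c2t
        taus = 1.0 / np.array([6 * Dperp, 5 * Dperp + Dpar, 2 * Dperp + 4 * Dpar])
        amps = np.array(
            [(1.5 * c2t - 0.5) ** 2, 3 * s2t * c2t, 0.75 * s2t * s2t]
        )
        out = 0.0
        for a, tk in zip(amps, taus):
            tp = tk * tau_int / (tk + tau_int) if tau_int > 0 else 0.0
            out += a * (S2 * tk / (1 + (omega * tk) ** 2)
                        + (1 - S2) * tp / (1 + (omega * tp) ** 2))
        return 0.4 * out

    @pytest.mark.parametrize("S2,tau_int", [(1.0, 0.0), (0.8, 80e-12)])
    def test_axial_limit_matches_independent_formula(self, S2, tau_int):
        Dperp, Dpar = 1.3e7, 2.1e7
        t = DiffusionTensor(Dperp, Dperp, Dpar)
        for v in (_unit([0.3, 0.4, 0.87]), _unit([1, 0, 0]), _unit([0, 0, 1])):
            for w in (0.0, 4.5e8, 4.4e9):
                expect = self._axial_J(w, Dperp, Dpar, v[2], S2, tau_int)
                got = anisotropic_J(w, t, v, S2, tau_int)
                assert got == pytest.approx(expect, rel=1e-10)

    def test_isotropic_axial_asymmetric_branches_agree_in_shared_limits(self):
        tc = 9e-9
        D = 1 / (6 * tc)
        v = _unit([0.5, -0.3, 0.81])
        iso = DiffusionTensor(D, D, D)
        nearly_axial = DiffusionTensor(D * 0.999999999, D, D * 1.000000001)
        for w in (0.0, 4.5e8, 4.4e9):
            assert anisotropic_J(w, iso, v) == pytest.approx(
                anisotropic_J(w, nearly_axial, v), rel=1e-10
            )

    def test_j_monotone_nonincreasing_in_frequency_for_rigid_vector(self):
        t = DiffusionTensor(1.2e7, 1.4e7, 1.9e7, 35.0)
        v = _unit([0.4, 0.5, 0.77])
        w = np.linspace(0, 5e9, 200)
        J = anisotropic_J(w, t, v, S2=1.0)
        assert np.all(np.diff(J.ravel()) <= 0)
        assert np.all(J >= 0)


class TestForwardModel:
    def test_rex_adds_exactly_to_r2_at_reference_field(self):
        t = DiffusionTensor(1.2e7, 1.4e7, 1.9e7, 35.0)
        v = _unit([0.4, 0.5, 0.77])
        base = predict_observables(t, v, LocalDynamics("x", 0.9, 50e-12, 0.0), 700.0)
        wrex = predict_observables(t, v, LocalDynamics("x", 0.9, 50e-12, 5.0), 700.0)
        assert wrex[1] - base[1] == pytest.approx(5.0, abs=1e-10)
        assert wrex[0] == base[0] and wrex[2] == base[2]

    def test_rex_scales_with_field_squared(self):
        t = DiffusionTensor(1.2e7, 1.4e7, 1.9e7, 35.0)
        v = _unit([0.4, 0.5, 0.77])
        base = predict_observables(t, v, LocalDynamics("x", 0.9, 0.0, 0.0), 950.0)
        wrex = predict_observables(t, v, LocalDynamics("x", 0.9, 0.0, 4.0), 950.0)
        assert wrex[1] - base[1] == pytest.approx(4.0 * (950.0 / 700.0) ** 2, rel=1e-12)

    def test_extreme_narrowing_r1_equals_r2(self):
        # dipolar relaxation only: the CSA term keeps R2/R1 at 7/6 even in
        # the extreme-narrowing limit, so it is switched off here
        from amidyn.constants import NMRConstants

        no_csa = NMRConstants(delta_sigma=-1e-6)
        tc = 10e-12
        t = DiffusionTensor(*(1 / (6 * tc),) * 3)
        r1, r2, _ = predict_observables(
            t, _unit([1, 1, 1]), LocalDynamics("x", 1.0), 700.0, constants=no_csa
        )
        assert r2 == pytest.approx(r1, rel=0.01)

    def test_isotropic_prediction_matches_direct_lipari_szabo(self):
        # dual-implementation oracle: isotropic J substituted by hand into
        # the same relaxation expressions
        tc, S2, ti = 9e-9, 0.85, 50e-12
        t = DiffusionTensor(*(1 / (6 * tc),) * 3)
        c = DEFAULT_CONSTANTS

        def J(w):
            tp = tc * ti / (tc + ti)
            return 0.4 * (S2 * tc / (1 + (w * tc) ** 2)
                          + (1 - S2) * tp / (1 + (w * tp) ** 2))

        f = 700.0
        wH, wN = c.omega_H(f), c.omega_N(f)
        d2, c2 = c.d2, c.c2(f)
        R1 = d2 / 4 * (J(wH - wN) + 3 * J(wN) + 6 * J(wH + wN)) + c2 * J(wN)
        R2 = (d2 / 8 * (4 * J(0) + J(wH - wN) + 3 * J(wN) + 6 * J(wH) + 6 * J(wH + wN))
              + c2 / 6 * (4 * J(0) + 3 * J(wN)))
        NOE = 1 + (c.gamma_H / c.gamma_N) * (d2 / 4) * (6 * J(wH + wN) - J(wH - wN)) / R1
        got = predict_observables(t, _unit([0.3, 0.9, 0.3]),
                                  LocalDynamics("x", S2, ti), f)
        assert got[0] == pytest.approx(R1, rel=1e-12)
        assert got[1] == pytest.approx(R2, rel=1e-12)
        assert got[2] == pytest.approx(NOE, rel=1e-12)


class TestTensorCanonicalisation:
    def test_gamma_wrapped_to_half_circle(self):
        t = DiffusionTensor(1e7, 2e7, 3e7, 215.0).canonical()
        assert 0 <= t.gamma_deg < 180

    def test_d1_d2_swap_is_same_tensor(self):
        a = DiffusionTensor(2e7, 1e7, 3e7, 10.0)
        b = a.canonical()
        assert (b.D1, b.D2) == (1e7, 2e7)
        assert b.gamma_deg == pytest.approx(100.0)
        v = _unit([0.4, 0.5, 0.77])
        for w in (0.0, 4.5e8):
            assert anisotropic_J(w, a, v) == pytest.approx(
                anisotropic_J(w, b, v), rel=1e-12
            )

    def test_gamma_plus_180_gives_identical_spectral_density(self):
        a = DiffusionTensor(1e7, 2e7, 3e7, 35.0)
        b = DiffusionTensor(1e7, 2e7, 3e7, 215.0)
        v = _unit([0.4, 0.5, 0.77])
        assert anisotropic_J(0.0, a, v) == pytest.approx(
            anisotropic_J(0.0, b, v), rel=1e-14
        )


class TestModelSelection:
    def test_equal_chi2_prefers_fewer_parameters(self):
        cands = {"M0": (np.array([0.9]), 1.0), "M3": (np.array([0.9, 0.05, 1.0]), 1.0)}
        assert select_model(cands) == "M0"

    def test_improvement_below_penalty_keeps_simpler_model(self):
        # M3 penalty exceeds M1's by 10; a chi2 gain of 5 must not win
        cands = {"M1": (np.array([0.9, 0.05]), 10.0),
                 "M3": (np.array([0.9, 0.05, 1.0]), 5.0)}
        assert aicc(10.0, 2) < aicc(5.0, 3)
        assert select_model(cands) == "M1"

    def test_strong_planted_exchange_is_selected(self, planted_tensor, rng):
        # 40 residues, Rex >= 3, 2% observable noise: nearly all should
        # land in an Rex-containing model
        n = 40
        vecs = synth.random_unit_vectors(n, seed=3)
        hits = 0
        for i in range(n):
            s2, ti, rex = 0.88, 60e-12, float(rng.uniform(3, 6))
            obs = predict_rates(planted_tensor, vecs[i], np.array([s2]),
                                np.array([ti]), np.array([rex]), (700.0, 950.0))[0]
            err = 0.02 * np.abs(obs)
            err[:, 2] = 0.02
            noisy = rng.normal(obs, err)
            ld = fit_local(noisy, err, planted_tensor, vecs[i], (700.0, 950.0),
                           residue_id=f"A:{i}")
            hits += ld.model_id in ("M2", "M3")
        assert hits >= 0.9 * n


class TestLocalFit:
    def test_noiseless_m3_recovery(self, planted_tensor):
        v = _unit([0.4, 0.5, 0.77])
        truth = LocalDynamics("x", 0.85, 50e-12, 4.0)
        obs = np.array([
            predict_observables(planted_tensor, v, truth, f) for f in (700.0, 950.0)
        ])
        ld = fit_local(obs, np.zeros_like(obs), planted_tensor, v, (700.0, 950.0))
        assert ld.S2 == pytest.approx(0.85, rel=0.01)
        assert ld.tau_int == pytest.approx(50e-12, rel=0.01)
        assert ld.Rex == pytest.approx(4.0, rel=0.01)

    def test_no_exchange_selects_model_without_rex(self, planted_tensor):
        v = _unit([0.4, 0.5, 0.77])
        truth = LocalDynamics("x", 0.9, 80e-12, 0.0)
        obs = np.array([
            predict_observables(planted_tensor, v, truth, f) for f in (700.0, 950.0)
        ])
        ld = fit_local(obs, np.zeros_like(obs), planted_tensor, v, (700.0, 950.0))
        assert "Rex" not in mfa.LOCAL_MODELS[ld.model_id]
        assert ld.Rex == 0.0

    def test_s2_stays_in_unit_interval_on_adversarial_data(self, planted_tensor, rng):
        v = _unit([0.4, 0.5, 0.77])
        for _ in range(5):
            obs = np.abs(rng.normal([[1.0, 20.0, 0.5]] * 2, [[0.5, 10.0, 0.5]] * 2))
            obs[:, 2] = np.clip(obs[:, 2], -3.0, 1.0)
            err = 0.1 * np.abs(obs) + 1e-3
            ld = fit_local(obs, err, planted_tensor, v, (700.0, 950.0))
            assert 0.0 <= ld.S2 <= 1.0


class TestPipeline:
    def test_noiseless_recovery_on_small_dimer(self, small_truth, clean_records):
        est = ModelFreeAnalysis(n_mc=0, n_starts=4)
        est.fit(clean_records, small_truth.vectors)
        true = small_truth.tensor.canonical()
        for attr in ("D1", "D2", "D3"):
            assert getattr(est.tensor_, attr) == pytest.approx(
                getattr(true, attr), rel=0.01
            )
        assert est.tensor_.gamma_deg == pytest.approx(true.gamma_deg, abs=1.0)
        for rid, (s2, ti, rex) in small_truth.locals.items():
            assert est.locals_[rid].S2 == pytest.approx(s2, abs=0.02)
            assert est.locals_[rid].Rex == pytest.approx(rex, abs=0.2)

    def test_zero_observable_errors_collapse_mc_spread(self, small_truth, clean_records):
        est = ModelFreeAnalysis(n_mc=0, n_starts=2)
        est.fit(clean_records, small_truth.vectors)
        model = monte_carlo_errors(est.result_, clean_records, small_truth.vectors,
                                   n_iter=5)
        some = [ld for ld in model.locals.values() if np.isfinite(ld.S2_err)]
        assert some
        assert all(ld.S2_err < 1e-10 for ld in some)

    def test_refit_with_same_seed_is_bit_identical(self, small_truth):
        rec = synth.simulate_observables(small_truth, noise_frac=0.02)
        frames = []
        for _ in range(2):
            est = ModelFreeAnalysis(n_mc=10, n_starts=2, seed=11)
            est.fit(rec, small_truth.vectors)
            frames.append(est.result_.to_frame().to_csv())
        assert frames[0] == frames[1]

    def test_refuses_without_enough_rigid_residues(self, small_truth, clean_records):
        few = clean_records[clean_records["residue_id"].isin(
            [f"A:{i}" for i in range(1, 6)])]
        with pytest.raises(ValueError, match="rigid"):
            mfa.fit_global_tensor(few, small_truth.vectors)


class TestSegmentMean:
    def test_mean_and_sample_sd(self):
        mean, sd = segment_mean({"A:1": 0.92, "A:2": 0.94, "A:3": 0.96},
                                ["A:1", "A:2", "A:3"])
        assert mean == pytest.approx(0.94)
        assert sd == pytest.approx(0.02)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            segment_mean({"A:1": 0.9}, ["B:7"])
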