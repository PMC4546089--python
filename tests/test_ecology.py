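import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from repeatscape import ecology
from repeatscape.ecology import AbundanceVector


def _vec(counts):
    return AbundanceVector([f"F{i}" for i in range(len(counts))],
                           np.asarray(counts, float))


class TestAbundanceVector:
    def test_sorted_descending_with_label_tiebreak(self):
        v = AbundanceVector(["b", "a", "c"], np.array([5.0, 5.0, 9.0]))
        assert v.families == ["c", "a", "b"]
        assert list(v.counts) == [9.0, 5.0, 5.0]

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            _vec([3, 0, 1])


class TestExpectedNull:
    def test_hand_harmonic_values(self):
        np.testing.assert_allclose(
            ecology.expected_null(6, 3), [3.6667, 1.6667, 0.6667], atol=5e-5
        )

    def test_single_family_takes_everything(self):
        assert ecology.expected_null(42, 1)[0] == pytest.approx(42)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(1, 200), st.integers(1, 10 ** 6))
    def test_sums_to_J(self, S, J):
        expected = ecology.expected_null(float(J), S)
        assert np.sum(expected) == pytest.approx(J, rel=1e-9)


def _grid_search_alpha(counts):
    """Independent 1e-4-resolution grid over the preemption likelihood."""
    counts = np.asarray(counts, float)
    J, r = counts.sum(), np.arange(1, len(counts) + 1)
    grid = np.arange(1e-4, 1.0, 1e-4)
    best_a, best_ll = None, -np.inf
    for a in grid:
        e = J * a * (1 - a) ** (r - 1)
        ll = np.sum(counts * np.log(e) - e)
        if ll > best_ll:
            best_a, best_ll = a, ll
    return best_a


class TestPreemption:
    def test_recovers_planted_decay(self):
        r = np.arange(1, 7)
        counts = np.round(1024 * 0.5 * 0.5 ** (r - 1))
        fit = ecology.fit_preemption(_vec(counts))
        assert 0.45 <= fit.parameters["alpha"] <= 0.55
        assert abs(fit.parameters["alpha"] - _grid_search_alpha(counts)) < 1e-3

    def test_two_point_fit_matches_grid_oracle(self):
        fit = ecology.fit_preemption(_vec([3, 1]))
        assert fit.parameters["alpha"] == pytest.approx(
            _grid_search_alpha([3, 1]), abs=1e-3
        )

    def test_log_expected_linear_in_rank(self):
        fit = ecology.fit_preemption(_vec([100, 40, 20, 9, 4]))
        diffs = np.diff(np.log(fit.expected))
        np.testing.assert_allclose(diffs, diffs[0], rtol=1e-9)
        assert diffs[0] == pytest.approx(
            math.log(1 - fit.parameters["alpha"]), rel=1e-9
        )


class TestLognormal:
    def test_parameter_recovery(self):
        hits_mu, hits_sigma = 0, 0
        for seed in range(10):
            counts = ecology.simulate_rad("Lognormal", {"mu": 5, "sigma": 1.0},
                                          S=50, seed=seed)
            fit = ecology.fit_lognormal(_vec(counts))
            hits_mu += 4.5 <= fit.parameters["mu"] <= 5.5
            hits_sigma += 0.7 <= fit.parameters["sigma"] <= 1.3
        assert hits_mu >= 9 and hits_sigma >= 9

    def test_sigma_zero_limit_flat(self):
        e = ecology._lognormal_expected(2.0, 1e-12, 10)
        np.testing.assert_allclose(e, math.exp(2.0), rtol=1e-9)

    def test_expected_decreasing_in_rank(self):
        fit = ecology.fit_lognormal(_vec([500, 100, 50, 20, 10, 5, 2, 1]))
        assert np.all(np.diff(fit.expected) <= 0)


class TestZipf:
    def test_rank_one_is_J_times_p(self):
        fit = ecology.fit_zipf(_vec([400, 200, 100, 60, 40, 20]))
        assert fit.expected[0] == pytest.approx(
            sum([400, 200, 100, 60, 40, 20]) * fit.parameters["p"], rel=1e-9
        )

    def test_parameter_recovery(self):
        # generating with p=0.4, gamma=-1 over S=30 gives a realized total
        # of J*p*H(30), so the identifiable dominance share is the
        # normalized p_eff = 1/H(30) ~ 0.2503; gamma is recovered as-is
        p_eff = 1.0 / np.sum(1.0 / np.arange(1, 31))
        ok_p = ok_g = 0
        for seed in range(20):
            counts = ecology.simulate_rad(
                "Zipf", {"p": 0.4, "gamma": -1.0}, S=30, J=1e4, seed=seed
            )
            fit = ecology.fit_zipf(_vec(counts))
            ok_p += abs(fit.parameters["p"] - p_eff) < 0.05
            ok_g += -1.15 <= fit.parameters["gamma"] <= -0.85
        assert ok_p >= 18 and ok_g >= 18

    def test_p_constrained_to_unit_interval(self):
        fit = ecology.fit_zipf(_vec([10, 10, 10, 10]))
        assert 0 < fit.parameters["p"] <= 1.0


class TestMandelbrot:
    def test_loglik_never_below_zipf(self, rng):
        for _ in range(20):
            counts = np.sort(rng.integers(1, 500, size=int(rng.integers(4, 25))))[::-1]
            vec = _vec(counts)
            assert (ecology.fit_mandelbrot(vec).loglik
                    >= ecology.fit_zipf(vec).loglik - 1e-9)

    def test_beta_zero_reduces_to_zipf(self):
        vec = _vec([300, 150, 90, 60, 40, 30])
        zipf = ecology.fit_zipf(vec)
        r = vec.ranks.astype(float)
        e = vec.J * zipf.parameters["p"] * (r + 0.0) ** zipf.parameters["gamma"]
        assert ecology.poisson_loglik(vec.counts, e) == pytest.approx(
            zipf.loglik, rel=1e-12
        )

    def test_beta_recovery_wide_band(self):
        S, beta, gamma = 30, 5.0, -2.0
        r = np.arange(1, S + 1)
        c = 1.0 / np.sum((r + beta) ** gamma)
        betas = []
        for seed in range(20):
            counts = ecology.simulate_rad(
                "Mandelbrot", {"c": c, "beta": beta, "gamma": gamma},
                S=S, J=1e4, seed=seed,
            )
            fit = ecology.fit_mandelbrot(_vec(counts))
            betas.append(fit.parameters["beta"])
        assert 2.0 <= float(np.median(betas)) <= 10.0


class TestSelectModel:
    def test_brokenstick_data_prefer_null_over_power_laws(self):
        # data drawn from the null (brokenstick) model: the parameter-free
        # Null fit should outrank the penalized power laws by BIC
        for seed in range(10):
            counts = ecology.simulate_rad("Null", {}, S=20, J=2000, seed=seed)
            order = [f.model for f in ecology.select_model(counts)]
            assert order.index("Null") < order.index("Zipf")
            assert order.index("Null") < order.index("Mandelbrot")

    def test_bic_recomputable_and_sorted(self):
        fits = ecology.select_model([120, 60, 30, 15, 8, 4, 2, 1])
        for f in fits:
            S = len(f.expected)
            assert f.bic == pytest.approx(-2 * f.loglik + f.k * math.log(S))
        bics = [f.bic for f in fits]
        assert bics == sorted(bics)

    def test_deterministic(self):
        a = ecology.select_model([90, 40, 22, 11, 6, 3, 1])
        b = ecology.select_model([90, 40, 22, 11, 6, 3, 1])
        assert [(f.model, f.loglik) for f in a] == [(f.model, f.loglik) for f in b]

    def test_dropping_factorial_constant_preserves_ordering(self):
        counts = [120, 60, 30, 15, 8, 4, 2, 1]
        fits = ecology.select_model(counts)
        const = sum(math.lgamma(c + 1) for c in counts)
        with_const = sorted(fits, key=lambda f: -2 * (f.loglik - const)
                            + f.k * math.log(len(counts)))
        assert [f.model for f in fits] == [f.model for f in with_const]


class TestVeganCrossCheck:
    """Frozen reference values computed with R vegan::radfit on the same
    vector (Poisson ML, BIC with k*ln(S)); vegan's log-likelihood keeps
    the ln(a_r!) term, so its BIC differs from ours by exactly twice the
    constant sum(lgamma(a_r+1)) = 763.4739."""

    COUNTS = [120, 60, 30, 15, 8, 4, 2, 1]
    CONST = 763.4739

    def test_preemption_alpha_and_bic(self):
        fit = ecology.fit_preemption(_vec(self.COUNTS))
        assert fit.parameters["alpha"] == pytest.approx(0.495855, abs=1e-4)
        assert fit.bic + 2 * self.CONST == pytest.approx(36.29264, abs=0.01)

    def test_zipf_parameters_and_bic(self):
        fit = ecology.fit_zipf(_vec(self.COUNTS))
        assert fit.parameters["p"] == pytest.approx(0.559928, abs=1e-4)
        assert fit.parameters["gamma"] == pytest.approx(-1.641517, abs=1e-3)
        assert fit.bic + 2 * self.CONST == pytest.approx(57.18827, abs=0.01)

    def test_null_bic(self):
        fit = ecology.fit_null(_vec(self.COUNTS))
        assert fit.bic + 2 * self.CONST == pytest.approx(84.711, abs=0.01)

    def test_model_ranking_matches_vegan(self):
        fits = ecology.select_model(self.COUNTS)
        order = [f.model for f in fits]
        # vegan BIC order on this vector
        assert order[0] == "Preemption"
        assert order.index("Lognormal") < order.index("Zipf")
        assert order[-1] == "Null"


class TestDiversity:
    def test_uniform_four_families(self):
        d = ecology.diversity([10.0, 10.0, 10.0, 10.0])
        assert d.H == pytest.approx(math.log(4))
        assert d.E == pytest.approx(1.0)
        assert d.richness == 4

    def test_single_family(self):
        d = ecology.diversity([7.0])
        assert d.H == 0.0
        assert math.isnan(d.E)

    def test_hand_oracle_skewed(self):
        d = ecology.diversity([0.5, 0.25, 0.25])
        expect = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert d.H == pytest.approx(expect, abs=1e-9)
        assert d.H == pytest.approx(1.0397, abs=1e-4)
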