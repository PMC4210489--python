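"""Episodic birth-death likelihood: rate algebra, propagators, dual paths."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from divshift.episodic import (
    EpisodicBDModel,
    InadmissibleRatesError,
    compose_rates,
    decompose_rates,
    episodic_loglik,
    episodic_loglik_ode,
    propagators,
    propagators_ode,
)
from divshift.trees import BranchingTimes


class TestRateAlgebra:
    @pytest.mark.parametrize(
        "r, tau, lam, mu",
        [
            (0.085, 0.305, 0.122, 0.037),  # pre-shift interval, printed values
            (0.022, 0.935, 0.338, 0.316),  # post-shift interval, printed values
            (0.05, 0.0, 0.05, 0.0),  # pure birth
            (-0.05, 2.0, 0.05, 0.10),  # declining diversity
        ],
    )
    def test_decompose(self, r, tau, lam, mu):
        got_lam, got_mu = decompose_rates(r, tau)
        assert round(got_lam, 3) == pytest.approx(lam)
        assert round(got_mu, 3) == pytest.approx(mu)
        # algebra holds exactly
        assert got_lam - got_mu == pytest.approx(r, abs=1e-15)
        if tau > 0:
            assert got_mu / got_lam == pytest.approx(tau, rel=1e-12)

    @pytest.mark.parametrize("r, tau", [(0.1, 1.0), (0.1, 2.0), (-0.1, 0.5), (0.1, -0.2)])
    def test_inadmissible_pairs(self, r, tau):
        with pytest.raises(InadmissibleRatesError):
            decompose_rates(r, tau)

    @given(
        lam=st.floats(1e-3, 5.0),
        frac=st.floats(0.0, 3.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_compose_decompose_round_trip(self, lam, frac):
        mu = lam * frac
        r, tau = compose_rates(lam, mu)
        if tau == 1.0:
            return  # singular boundary
        lam2, mu2 = decompose_rates(r, tau)
        assert lam2 == pytest.approx(lam, rel=1e-9)
        assert mu2 == pytest.approx(mu, rel=1e-9, abs=1e-12)


@pytest.fixture
def five_tip_bt():
    return BranchingTimes(ages=np.array([4.0, 3.0, 2.0, 1.0]))


class TestLikelihood:
    def test_shift_with_no_rate_change_reduces_to_constant(self, five_tip_bt):
        m0 = EpisodicBDModel(lam=(0.3,), mu=(0.1,), rho=0.6)
        m1 = EpisodicBDModel(lam=(0.3, 0.3), mu=(0.1, 0.1), shift_times=(2.0,), rho=0.6)
        a, b = episodic_loglik(five_tip_bt, m0), episodic_loglik(five_tip_bt, m1)
        assert a == pytest.approx(b, abs=1e-10)

    def test_spec_shift_model_closed_form_matches_ode(self, five_tip_bt):
        model = EpisodicBDModel(
            lam=(0.3, 0.5), mu=(0.1, 0.4), shift_times=(2.5,), rho=0.6
        )
        closed = episodic_loglik(five_tip_bt, model)
        ode = episodic_loglik_ode(five_tip_bt, model)
        assert closed == pytest.approx(ode, rel=1e-6)

    def test_pure_birth_matches_analytic_density(self):
        lam = 0.4
        rng = np.random.default_rng(3)
        ages = np.sort(rng.uniform(0.2, 9.0, 12))[::-1]
        bt = BranchingTimes(ages=ages)
        model = EpisodicBDModel(lam=(lam,), mu=(0.0,))
        # conditioned pure-birth likelihood: each non-crown time contributes
        # ln lam - lam x; the crown contributes -2 lam x1 (p0 = 0 at rho=1)
        analytic = (
            (ages.size - 1) * np.log(lam) - lam * ages[1:].sum() - 2 * lam * ages[0]
        )
        assert episodic_loglik(bt, model) == pytest.approx(analytic, rel=1e-12)

    def test_critical_case_equals_ode(self):
        bt = BranchingTimes(ages=np.array([8.0, 5.0, 2.5, 1.0]))
        model = EpisodicBDModel(lam=(0.2,), mu=(0.2 - 1e-12,), rho=0.7)
        closed = episodic_loglik(bt, model)
        ode = episodic_loglik_ode(bt, model)
        assert closed == pytest.approx(ode, rel=1e-6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        ages = rng.uniform(0.5, 30.0, 15)
        ages[0] = 35.0
        model = EpisodicBDModel(lam=(0.2, 0.1), mu=(0.15, 0.02), shift_times=(12.0,), rho=0.4)
        lls = {
            episodic_loglik(BranchingTimes(ages=rng.permutation(ages)), model)
            for _ in range(5)
        }
        assert max(lls) - min(lls) < 1e-10

    def test_loglik_of_nonempty_required(self):
        with pytest.raises(ValueError):
            BranchingTimes(ages=np.array([]))


class TestPropagators:
    def test_yule_complete_sampling_never_goes_extinct(self):
        model = EpisodicBDModel(lam=(0.3,), mu=(0.0,), rho=1.0)
        u = np.linspace(0, 50, 101)
        p0, logq = propagators(model, u)
        np.testing.assert_allclose(p0, 0.0, atol=1e-14)
        assert np.all(np.isfinite(logq))

    def test_initial_conditions_and_bounds(self):
        model = EpisodicBDModel(
            lam=(0.4, 0.2), mu=(0.3, 0.1), shift_times=(5.0,), rho=0.25
        )
        u = np.linspace(0, 40, 401)
        p0, logq = propagators(model, u)
        assert p0[0] == pytest.approx(1 - 0.25)
        assert logq[0] == pytest.approx(np.log(0.25))
        assert np.all((p0 >= 0) & (p0 <= 1))
        # constant rates, complete sampling: extinction probability rises
        # monotonically toward its mu/lam equilibrium
        full = EpisodicBDModel(lam=(0.4,), mu=(0.3,), rho=1.0)
        p0_full, _ = propagators(full, u)
        assert np.all(np.diff(p0_full) >= -1e-12)
        assert np.all(p0_full <= 0.3 / 0.4 + 1e-12)

    @given(
        lam1=st.floats(0.02, 1.0),
        lam2=st.floats(0.02, 1.0),
        tau1=st.floats(0.0, 1.5),
        tau2=st.floats(0.0, 1.5),
        shift=st.floats(2.0, 18.0),
        rho=st.floats(0.02, 1.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_closed_form_tracks_ode(self, lam1, lam2, tau1, tau2, shift, rho):
        model = EpisodicBDModel(
            lam=(lam1, lam2),
            mu=(lam1 * tau1, lam2 * tau2),
            shift_times=(shift,),
            rho=rho,
        )
        u = np.array([0.5, shift / 2, shift, shift + 1.0, 20.0])
        p0a, qa = propagators(model, u)
        p0b, qb = propagators_ode(model, u)
        np.testing.assert_allclose(p0a, p0b, atol=1e-7)
        np.testing.assert_allclose(qa, qb, rtol=1e-6, atol=1e-7)

    def test_mass_extinction_boundary_maps(self):
        base = EpisodicBDModel(lam=(0.3, 0.3), mu=(0.1, 0.1), shift_times=(4.0,), rho=0.8)
        hit = EpisodicBDModel(
            lam=(0.3, 0.3),
            mu=(0.1, 0.1),
            shift_times=(4.0,),
            rho=0.8,
            boundary_survival=(0.4,),
        )
        u = np.array([3.999999, 4.0])
        p0_base, q_base = propagators(base, u)
        p0_hit, q_hit = propagators(hit, u)
        # just below the boundary the two agree; at the boundary the mass
        # extinction maps p0 -> 1 - s (1 - p0) and q -> s q
        assert p0_hit[0] == pytest.approx(p0_base[0], abs=1e-6)
        assert 1 - p0_hit[1] == pytest.approx(0.4 * (1 - p0_base[1]), rel=1e-6)
        assert q_hit[1] == pytest.approx(q_base[1] + np.log(0.4), abs=1e-6)


class TestModelValidation:
    def test_rates_must_be_admissible(self):
        with pytest.raises(InadmissibleRatesError):
            EpisodicBDModel(lam=(-0.1,), mu=(0.0,))
        with pytest.raises(InadmissibleRatesError):
            EpisodicBDModel(lam=(0.1,), mu=(-0.05,))

    def test_shift_interval_count_consistency(self):
        with pytest.raises(ValueError):
            EpisodicBDModel(lam=(0.1, 0.2), mu=(0.0, 0.0))  # missing shift

    def test_from_r_tau_round_trip(self):
        model = EpisodicBDModel.from_r_tau(
            r=(0.022, 0.085), tau=(0.935, 0.305), shift_times=(53.0,), rho=0.03
        )
        np.testing.assert_allclose(model.r, [0.022, 0.085], rtol=1e-12)
        np.testing.assert_allclose(model.tau, [0.935, 0.305], rtol=1e-12)
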