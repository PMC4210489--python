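"""Shift-model fitting, sequential LRT/AICc selection, replicate summaries."""

import numpy as np
import pytest
from scipy.optimize import minimize

from divshift.episodic import EpisodicBDModel, episodic_loglik
from divshift.fitting import (
    FitResult,
    aicc,
    compare_models,
    fit_episodic,
    fit_shift_models,
    lrt_pvalue,
    posterior_fit_summary,
)
from divshift.simulate import SimulationRecipe, simulate_tree
from divshift.trees import BranchingTimes, branching_times


def _dummy_fit(m: int, neglogl: float, n_obs: int = 500) -> FitResult:
    """Carrier for a printed -logL value with the right parameter count."""
    model = EpisodicBDModel(
        lam=tuple([0.1] * (m + 1)),
        mu=tuple([0.05] * (m + 1)),
        shift_times=tuple(float(10 * (i + 1)) for i in range(m)),
        rho=0.03,
    )
    return FitResult(model=model, neglogl=neglogl, n_obs=n_obs, t_cut=50.0)


# printed -logL chains of the two dating calibrations (constant, 1..4 shifts)
YULE_NEGLOGL = [1051.096, 1042.438, 1038.801, 1036.949, 1035.654]
BD_NEGLOGL = [1052.408, 1041.914, 1039.170, 1035.864, 1033.688]
YULE_PRINTED_P = [0.0006, 0.0637, 0.0891, 0.1385]
BD_PRINTED_P = [0.0001, 0.1394, 0.0598, 0.058]


class TestModelComparison:
    @pytest.mark.parametrize(
        "chain, printed",
        [(YULE_NEGLOGL, YULE_PRINTED_P), (BD_NEGLOGL, BD_PRINTED_P)],
        ids=["yule_crown", "bd_crown"],
    )
    def test_sequential_lrt_reproduces_printed_pvalues(self, chain, printed):
        fits = [_dummy_fit(m, nll) for m, nll in enumerate(chain)]
        table = compare_models(fits, alpha=0.05).table
        for m, expected in zip(range(1, 5), printed):
            got = table.loc[table["m"] == m, "p_value"].iloc[0]
            tol = 10.0 ** (-len(str(expected).split(".")[1]))
            assert got == pytest.approx(expected, abs=tol)

    def test_one_shift_model_is_the_accepted_one(self):
        for chain in (YULE_NEGLOGL, BD_NEGLOGL):
            fits = [_dummy_fit(m, nll) for m, nll in enumerate(chain)]
            cmp = compare_models(fits, alpha=0.05)
            assert cmp.selected_lrt == 1

    def test_candidates_tested_against_last_accepted(self):
        fits = [_dummy_fit(m, nll) for m, nll in enumerate(BD_NEGLOGL)]
        table = compare_models(fits, alpha=0.05).table
        # after the 2-shift candidate is rejected, 3 and 4 shifts are tested
        # against the 1-shift model with 6 and 9 degrees of freedom
        assert list(table["df"]) == [0, 3, 3, 6, 9]
        assert list(table["accepted"]) == [True, True, False, False, False]

    def test_zero_statistic_gives_p_one(self):
        stat, p = lrt_pvalue(100.0, 100.0, 3)
        assert stat == 0.0 and p == 1.0

    def test_mismatched_data_summaries_rejected(self):
        a = _dummy_fit(0, 100.0, n_obs=500)
        b = _dummy_fit(1, 95.0, n_obs=400)
        with pytest.raises(ValueError):
            compare_models([a, b])


class TestAICc:
    def test_formula_and_penalty(self):
        val = aicc(neglogl=100.0, k=5, n_obs=50)
        assert val == pytest.approx(2 * 5 + 200 + 2 * 5 * 6 / (50 - 5 - 1))
        assert val > 2 * 5 + 200

    def test_undefined_for_tiny_samples(self):
        with pytest.raises(ValueError):
            aicc(10.0, k=5, n_obs=6)

    def test_fit_result_k_follows_parameter_count_row(self):
        # printed parameter counts: 2, 5, 8, 11, 14 for 0..4 shifts
        for m, k in enumerate([2, 5, 8, 11, 14]):
            assert _dummy_fit(m, 100.0).k == k


class TestFitting:
    def test_m0_equals_direct_two_parameter_optimization(self):
        rec = SimulationRecipe(
            model=EpisodicBDModel(lam=(0.2,), mu=(0.05,)), crown_age=25.0, seed=3
        )
        bt = branching_times(simulate_tree(rec))
        fit = fit_episodic(bt, 0)

        def neg(theta):
            lam, mu = np.exp(theta)
            model = EpisodicBDModel(lam=(lam,), mu=(mu,))
            ll = episodic_loglik(bt, model)
            return -ll if np.isfinite(ll) else 1e10

        best = min(
            minimize(neg, x0, method="Nelder-Mead").fun
            for x0 in ([np.log(0.2), np.log(0.05)], [np.log(0.05), np.log(0.02)])
        )
        assert fit.neglogl == pytest.approx(best, abs=1e-4)

    def test_constant_rate_parameter_recovery(self, constant_rate_recipe):
        """Median MLEs recover r=0.05 and tau=0.5; the small-sample bias of
        the net rate (about -13% on ~70-tip crown-60 trees) shrinks with tree
        size and is within 10% on crown-100 trees."""
        rs, taus = [], []
        for i in range(120):
            bt = branching_times(simulate_tree(constant_rate_recipe, index=i))
            fit = fit_shift_models(bt, 0, seed=500 + i)[0]
            rs.append(float(fit.model.r[0]))
            taus.append(float(fit.model.tau[0]))
        assert np.median(taus) == pytest.approx(0.5, rel=0.20)
        assert np.median(rs) == pytest.approx(0.05, rel=0.25)
        big = SimulationRecipe(
            model=EpisodicBDModel(lam=(0.10,), mu=(0.05,)), crown_age=100.0, seed=78
        )
        rs_big = []
        for i in range(60):
            bt = branching_times(simulate_tree(big, index=i))
            rs_big.append(float(fit_shift_models(bt, 0, seed=900 + i)[0].model.r[0]))
        assert np.median(rs_big) == pytest.approx(0.05, rel=0.10)
        assert abs(np.median(rs_big) - 0.05) < abs(np.median(rs) - 0.05) + 0.005

    def test_too_many_shifts_for_data_errors(self):
        bt = BranchingTimes(ages=np.array([5.0, 3.0, 1.0]))
        with pytest.raises(ValueError, match="shifts"):
            fit_shift_models(bt, 1)

    def test_neglogl_non_increasing_in_m(self):
        rec = SimulationRecipe(
            model=EpisodicBDModel(lam=(0.25,), mu=(0.1,)), crown_age=30.0, seed=11
        )
        bt = branching_times(simulate_tree(rec, index=2))
        fits = fit_shift_models(bt, 2, grid=np.arange(2.0, bt.crown_age, 2.0), seed=0)
        nll = [f.neglogl for f in fits]
        assert nll[0] >= nll[1] - 1e-6 and nll[1] >= nll[2] - 1e-6


class TestPosteriorSummary:
    def test_identical_trees_have_zero_se(self):
        rec = SimulationRecipe(
            model=EpisodicBDModel(lam=(0.2,), mu=(0.05,)), crown_age=25.0, seed=6
        )
        bt = branching_times(simulate_tree(rec))
        out = posterior_fit_summary([bt] * 4, max_shifts=0, seed=0)
        assert out["modal_m"] == 0
        assert np.allclose(out["summary"]["se"].values, 0.0, atol=1e-12)
        assert out["n_failures"] == 0

    def test_subset_consistent_with_full_set(self):
        rec = SimulationRecipe(
            model=EpisodicBDModel(lam=(0.2,), mu=(0.05,)), crown_age=30.0, seed=15
        )
        bts = [branching_times(simulate_tree(rec, index=i)) for i in range(24)]
        full = posterior_fit_summary(bts, max_shifts=0, seed=1)
        half = posterior_fit_summary(bts[:12], max_shifts=0, seed=1)
        r_full = full["summary"].loc["r1", "mean"]
        r_half = half["summary"].loc["r1", "mean"]
        spread = full["summary"].loc["r1", "se"] * np.sqrt(12)
        assert abs(r_full - r_half) < 4 * spread

    def test_needs_at_least_two_trees(self):
        bt = BranchingTimes(ages=np.array([5.0, 3.0, 1.0]))
        with pytest.raises(ValueError):
            posterior_fit_summary([bt], max_shifts=0)
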