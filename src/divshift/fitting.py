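"""Maximum-likelihood fitting of episodic birth-death models.

The shift-time search mirrors the greedy, backward-in-time scan of the
classical shift-model routine: starting from the constant-rate fit, one shift
is added at a time by trying every age on a 1-Myr grid as the new shift time,
re-optimizing all interval rates at each candidate, keeping the best grid age,
and finally re-refining all continuous parameters with the shift times fixed
at their grid values.  Nested fits are then compared with sequential
likelihood-ratio tests (chi^2, 3 degrees of freedom per added shift: two rates
plus one shift time) and small-sample corrected AIC.

Internally the optimizer works on ``(log lam_i, log mu_i)`` so the turnover
singularity at ``tau = 1`` never appears; results are reported as
``(r_i, tau_i)``.  Negative net diversification (``mu_i > lam_i``) is allowed
by default; with ``allow_negative_r=False`` extinction is re-parameterized as
``mu_i = lam_i * expit(z_i)`` so every interval keeps ``r_i >= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import chi2

from .episodic import EpisodicBDModel, loglik_core
from .trees import BranchingTimes

__all__ = [
    "FitResult",
    "ModelComparisonTable",
    "aicc",
    "lrt_pvalue",
    "fit_episodic",
    "fit_shift_models",
    "compare_models",
    "posterior_fit_summary",
]

_LOGLAM_BOUNDS = (np.log(1e-6), np.log(10.0))
_LOGMU_BOUNDS = (np.log(1e-9), np.log(10.0))
_Z_BOUNDS = (-30.0, 30.0)  # logit of mu/lam when r >= 0 is enforced
_BIG = 1e10


def aicc(neglogl: float, k: int, n_obs: int) -> float:
    """Small-sample corrected AIC, ``2k + 2(-logL) + 2k(k+1)/(n_obs - k - 1)``."""
    if n_obs - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n_obs={n_obs} too small for k={k}")
    return 2.0 * k + 2.0 * neglogl + 2.0 * k * (k + 1) / (n_obs - k - 1)


def lrt_pvalue(neglogl_null: float, neglogl_alt: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio statistic and chi^2 upper-tail p-value of nested fits."""
    stat = 2.0 * (neglogl_null - neglogl_alt)
    return stat, float(chi2.sf(stat, df))


@dataclass(frozen=True)
class FitResult:
    """One fitted episodic model: MLEs, -logL, parameter count, AICc."""

    model: EpisodicBDModel
    neglogl: float
    n_obs: int
    t_cut: float = 0.0
    converged: bool = True
    message: str = ""

    @property
    def m(self) -> int:
        return self.model.m

    @property
    def k(self) -> int:
        # 2 rates for the base interval + (2 rates + 1 shift time) per shift
        return 2 + 3 * self.model.m

    @property
    def aicc(self) -> float:
        return aicc(self.neglogl, self.k, self.n_obs)

    def params(self) -> dict[str, float]:
        """Flat reporting dictionary: r_i, tau_i per interval and shift times."""
        out: dict[str, float] = {}
        for i, (r, tau) in enumerate(zip(self.model.r, self.model.tau), start=1):
            out[f"r{i}"] = float(r)
            out[f"tau{i}"] = float(tau)
        for i, t in enumerate(self.model.shift_times, start=1):
            out[f"shift_time_{i}"] = float(t)
        return out


def _unpack(theta: np.ndarray, allow_negative_r: bool) -> tuple[np.ndarray, np.ndarray]:
    theta = np.asarray(theta, dtype=float)
    lam = np.exp(theta[0::2])
    if allow_negative_r:
        mu = np.exp(theta[1::2])
    else:
        mu = lam * expit(theta[1::2])
    return lam, mu


def _pack(lam, mu, allow_negative_r: bool) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.empty(2 * lam.size)
    theta[0::2] = np.log(lam)
    if allow_negative_r:
        theta[1::2] = np.log(np.maximum(mu, 1e-9))
    else:
        frac = np.clip(mu / lam, 1e-10, 1 - 1e-10)
        theta[1::2] = logit(frac)
    return theta


def _optimize_rates(
    bt: BranchingTimes,
    shifts: tuple[float, ...],
    starts: list[np.ndarray],
    rho: float,
    allow_negative_r: bool,
    conditioning: str,
    tol: float = 1e-8,
):
    """Bounded quasi-Newton over per-interval rates with fixed shift times."""
    n_int = len(shifts) + 1
    bounds = []
    for _ in range(n_int):
        bounds.append(_LOGLAM_BOUNDS)
        bounds.append(_LOGMU_BOUNDS if allow_negative_r else _Z_BOUNDS)

    shifts_arr = np.asarray(shifts, dtype=float)
    ages = bt.ages

    def objective(theta):
        lam, mu = _unpack(theta, allow_negative_r)
        ll = loglik_core(ages, lam, mu, shifts_arr, rho, conditioning)
        return -ll if np.isfinite(ll) else _BIG

    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    lam, mu = _unpack(best.x, allow_negative_r)
    model = EpisodicBDModel(lam=tuple(lam), mu=tuple(mu), shift_times=shifts, rho=rho)
    return model, float(best.fun), bool(best.success), str(best.message)


def _heuristic_start(bt: BranchingTimes, n_int: int, allow_negative_r: bool) -> np.ndarray:
    r0 = max(np.log(max(bt.n, 3) / 2.0) / bt.crown_age, 1e-3)
    lam0 = np.full(n_int, 1.5 * r0)
    mu0 = np.full(n_int, 0.5 * r0)
    return _pack(lam0, mu0, allow_negative_r)


def _random_starts(
    rng: np.random.Generator, base: np.ndarray, n: int, allow_negative_r: bool
) -> list[np.ndarray]:
    starts = []
    lo = np.array([b[0] for b in ([_LOGLAM_BOUNDS, _LOGMU_BOUNDS if allow_negative_r else _Z_BOUNDS] * (base.size // 2))])
    hi = np.array([b[1] for b in ([_LOGLAM_BOUNDS, _LOGMU_BOUNDS if allow_negative_r else _Z_BOUNDS] * (base.size // 2))])
    for _ in range(n):
        x = base + rng.normal(0.0, 1.0, size=base.size)
        starts.append(np.clip(x, lo, hi))
    return starts


def _default_grid(bt: BranchingTimes, step: float = 1.0) -> np.ndarray:
    return np.arange(step, bt.crown_age, step)


def fit_shift_models(
    bt: BranchingTimes,
    max_shifts: int,
    grid: np.ndarray | None = None,
    rho: float = 1.0,
    allow_negative_r: bool = True,
    conditioning: str = "crown_survival",
    n_restarts: int = 5,
    scan_restarts: int = 1,
    seed: int = 0,
) -> list[FitResult]:
    """Greedy chain of fits with 0..max_shifts shift times.

    ``grid`` holds the candidate shift ages on the (re-based) age axis of
    ``bt``; default is every 1 Myr strictly inside (0, crown age).  The fit
    with ``j`` shifts keeps the ``j - 1`` previously found shift times and
    scans the grid for the best additional one (each candidate optimized from
    a warm start plus random restarts), then re-refines all rates jointly with
    ``n_restarts`` random restarts.  Restart streams are seeded for
    reproducibility.
    """
    if max_shifts < 0:
        raise ValueError("max_shifts must be >= 0")
    n_bt = bt.ages.size
    k_max = 2 + 3 * max_shifts
    if k_max + 2 > n_bt:
        raise ValueError(
            f"{max_shifts} shifts need more data: k+2 = {k_max + 2} exceeds the "
            f"{n_bt} branching times"
        )
    if grid is None:
        grid = _default_grid(bt)
    grid = np.asarray(grid, dtype=float)
    grid = grid[(grid > 0) & (grid < bt.crown_age)]
    rng = np.random.default_rng(seed)

    fits: list[FitResult] = []
    base = _heuristic_start(bt, 1, allow_negative_r)
    starts = [base] + _random_starts(rng, base, n_restarts - 1, allow_negative_r)
    model, nll, ok, msg = _optimize_rates(
        bt, (), starts, rho, allow_negative_r, conditioning
    )
    fits.append(FitResult(model, nll, n_bt, bt.t_cut, ok, msg))

    for j in range(1, max_shifts + 1):
        prev = fits[-1]
        prev_shifts = prev.model.shift_times
        best = None
        warm_theta = None
        for cand in grid:
            if any(abs(cand - t) < 1e-9 for t in prev_shifts):
                continue
            shifts = tuple(sorted(prev_shifts + (float(cand),)))
            # warm start: inherit previous model's rates, splitting the
            # interval that contains the candidate
            idx = prev.model.interval_index([cand])[0]
            lam0 = list(prev.model.lam)
            mu0 = list(prev.model.mu)
            lam0.insert(idx, lam0[idx])
            mu0.insert(idx, max(mu0[idx], 1e-6))
            inherit = _pack(lam0, mu0, allow_negative_r)
            starts = [inherit]
            if warm_theta is not None:
                starts.append(warm_theta)
            starts += _random_starts(
                rng, inherit, max(scan_restarts - 1, 0), allow_negative_r
            )
            model, nll, ok, msg = _optimize_rates(
                bt, shifts, starts, rho, allow_negative_r, conditioning, tol=1e-7
            )
            warm_theta = _pack(model.lam, model.mu, allow_negative_r)
            if best is None or nll < best[1]:
                best = (model, nll, ok, msg)
        if best is None:
            raise ValueError("empty shift-time grid")
        # final refinement at the winning shift times
        model0 = best[0]
        base = _pack(model0.lam, model0.mu, allow_negative_r)
        starts = [base] + _random_starts(rng, base, n_restarts - 1, allow_negative_r)
        model, nll, ok, msg = _optimize_rates(
            bt, model0.shift_times, starts, rho, allow_negative_r, conditioning
        )
        if nll > best[1]:  # keep the scan optimum if refinement went uphill
            model, nll, ok, msg = best
        fits.append(FitResult(model, nll, n_bt, bt.t_cut, ok, msg))
    return fits


def fit_episodic(
    bt: BranchingTimes,
    m: int,
    grid: np.ndarray | None = None,
    rho: float = 1.0,
    allow_negative_r: bool = True,
    conditioning: str = "crown_survival",
    n_restarts: int = 5,
    scan_restarts: int = 1,
    seed: int = 0,
) -> FitResult:
    """Fit the episodic model with exactly ``m`` shifts (greedy grid search)."""
    return fit_shift_models(
        bt,
        m,
        grid=grid,
        rho=rho,
        allow_negative_r=allow_negative_r,
        conditioning=conditioning,
        n_restarts=n_restarts,
        scan_restarts=scan_restarts,
        seed=seed,
    )[m]


@dataclass(frozen=True)
class ModelComparisonTable:
    """Sequential LRT chain over nested shift models plus AICc ranking.

    Each candidate with ``m_c`` shifts is tested against the *last accepted*
    model (not simply the previous row); ``df = 3 (m_c - m_a)``.  A candidate
    is accepted iff its chi^2 upper-tail p-value is below ``alpha``.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def selected_lrt(self) -> int:
        """Shift count of the last LRT-accepted model."""
        acc = self.table[self.table["accepted"]]
        return int(acc["m"].iloc[-1]) if len(acc) else 0

    @property
    def selected_aicc(self) -> int:
        """Shift count of the minimum-AICc model."""
        return int(self.table.loc[self.table["aicc"].idxmin(), "m"])


def compare_models(fits: Sequence[FitResult], alpha: float = 0.05) -> ModelComparisonTable:
    """Sequential likelihood-ratio acceptance over a nested chain of fits."""
    if len(fits) == 0:
        raise ValueError("need at least one fit")
    ms = [f.m for f in fits]
    if ms != sorted(ms) or len(set(ms)) != len(ms):
        raise ValueError("fits must be ordered by strictly increasing shift count")
    summaries = {(f.n_obs, round(f.t_cut, 9), f.model.rho) for f in fits}
    if len(summaries) > 1:
        raise ValueError(f"fits disagree on data summary: {summaries}")
    rows = []
    accepted = fits[0]
    for f in fits:
        if f is fits[0]:
            stat, df, p, acc = np.nan, 0, np.nan, True
        else:
            df = 3 * (f.m - accepted.m)
            stat, p = lrt_pvalue(accepted.neglogl, f.neglogl, df)
            acc = p < alpha
            if acc:
                accepted = f
        row = {
            "m": f.m,
            "k": f.k,
            "neglogl": f.neglogl,
            "aicc": f.aicc,
            "lrt_stat": stat,
            "df": df,
            "p_value": p,
            "accepted": acc,
        }
        row.update(f.params())
        rows.append(row)
    table = pd.DataFrame(rows)
    table["min_aicc"] = table["aicc"] == table["aicc"].min()
    return ModelComparisonTable(table=table, alpha=alpha)


def posterior_fit_summary(
    tree_bts: Sequence[BranchingTimes],
    max_shifts: int = 1,
    grid: np.ndarray | None = None,
    rho: float = 1.0,
    allow_negative_r: bool = True,
    conditioning: str = "crown_survival",
    alpha: float = 0.05,
    n_restarts: int = 5,
    scan_restarts: int = 1,
    seed: int = 0,
) -> dict:
    """Replicate the fit + selection chain over a posterior sample of trees.

    Returns per-tree selected shift counts, a failure count, and for the trees
    whose LRT-selected shift count equals the modal one, the mean, standard
    error and 2.5/97.5 percentiles of every free parameter of that model.
    """
    if len(tree_bts) < 2:
        raise ValueError("need at least two trees to summarize")
    selected: list[int] = []
    params_per_tree: list[dict[str, float]] = []
    failures = 0
    for i, bt in enumerate(tree_bts):
        try:
            fits = fit_shift_models(
                bt,
                max_shifts,
                grid=grid,
                rho=rho,
                allow_negative_r=allow_negative_r,
                conditioning=conditioning,
                n_restarts=n_restarts,
                scan_restarts=scan_restarts,
                seed=seed,
            )
            cmp_table = compare_models(fits, alpha=alpha)
            m_sel = cmp_table.selected_lrt
            selected.append(m_sel)
            params_per_tree.append(fits[m_sel].params())
        except Exception:
            failures += 1
            selected.append(-1)
            params_per_tree.append({})
    valid = [m for m in selected if m >= 0]
    if not valid:
        raise RuntimeError("all per-tree fits failed")
    modal_m = int(pd.Series(valid).mode().iloc[0])
    rows = [p for m, p in zip(selected, params_per_tree) if m == modal_m]
    df = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "mean": df.mean(),
            "se": df.std(ddof=1) / np.sqrt(len(df)),
            "q2.5": df.quantile(0.025),
            "q97.5": df.quantile(0.975),
        }
    )
    return {
        "selected_m": selected,
        "modal_m": modal_m,
        "n_trees": len(tree_bts),
        "n_failures": failures,
        "n_summarized": len(df),
        "summary": summary,
    }
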