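"""Likelihood of branching times under an episodic birth-death process.

The model is a birth-death process with piecewise-constant speciation and
extinction rates: rates are constant within time intervals separated by shift
times ``t_1 < ... < t_m`` (ages in Myr before the analysis present), and each
extant lineage is sampled at the present with probability ``rho``.  Interval 0
is the most recent, covering ages in ``[0, t_1)``.

Two propagators on the age axis ``u`` carry the whole likelihood:

* ``p0(u)`` — probability that a lineage alive at age ``u`` leaves no sampled
  descendant at the present, with ``p0(0) = 1 - rho``;
* ``q(u)`` — density propagator of a reconstructed lineage, ``q(0) = rho``.

Within one interval with rates ``lam, mu`` and entry values ``(p~, q~)`` at
the interval's young end, both have closed forms (exponential in ``lam - mu``,
rational when ``lam = mu``); across a shift boundary with survival probability
``s`` they transform as ``p0 -> 1 - s (1 - p0)``, ``q -> s q`` (identity at
``s = 1``, the default: no mass extinction).  The same propagators satisfy the
ODEs ``dp0/du = mu - (lam + mu) p0 + lam p0^2`` and
``dq/du = -(lam + mu) q + 2 lam p0 q``, which :func:`episodic_loglik_ode`
integrates numerically as an independent internal cross-check.

A reconstructed tree with descending branching times ``x_1 > x_2 >= ... >=
x_{n-1}`` (``x_1`` the crown age), conditioned on the crown age and on both
crown lineages having sampled descendants, has

``logL = sum_{i=2}^{n-1} [ln lam(x_i) + ln q(x_i)] + 2 ln q(x_1)
- 2 ln(1 - p0(x_1))``

up to a parameter-independent constant.  Net diversification ``r = lam - mu``
and turnover ``tau = mu / lam`` are the reporting parameterization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .trees import BranchingTimes

__all__ = [
    "EpisodicBDModel",
    "InadmissibleRatesError",
    "decompose_rates",
    "compose_rates",
    "propagators",
    "propagators_ode",
    "loglik_core",
    "episodic_loglik",
    "episodic_loglik_ode",
]

#: below this |lam - mu| the critical-case (lam = mu) limit forms are used
CRITICAL_TOL = 1e-8


class InadmissibleRatesError(ValueError):
    """(r, tau) pair or (lam, mu) pair outside the admissible region."""


def decompose_rates(r: float, tau: float) -> tuple[float, float]:
    """Speciation and extinction from net diversification and turnover.

    ``lam = r / (1 - tau)`` and ``mu = r * tau / (1 - tau)``, so that
    ``lam - mu = r`` and ``mu / lam = tau`` hold exactly.  Negative ``r``
    (declining diversity) is admissible only with ``tau > 1``.
    """
    if tau < 0:
        raise InadmissibleRatesError(f"turnover must be >= 0, got {tau}")
    if tau == 1:
        raise InadmissibleRatesError("turnover = 1 is singular (lam - mu = 0 with r != 0)")
    lam = r / (1.0 - tau)
    mu = r * tau / (1.0 - tau)
    if lam <= 0 or mu < 0:
        raise InadmissibleRatesError(
            f"(r={r}, tau={tau}) implies lam={lam:.4g}, mu={mu:.4g}; "
            "need lam > 0 and mu >= 0"
        )
    return lam, mu


def compose_rates(lam: float, mu: float) -> tuple[float, float]:
    """Net diversification and turnover from speciation and extinction."""
    if lam <= 0 or mu < 0:
        raise InadmissibleRatesError(f"need lam > 0 and mu >= 0, got ({lam}, {mu})")
    return lam - mu, mu / lam


@dataclass(frozen=True)
class EpisodicBDModel:
    """Piecewise-constant birth-death model with sampling at the present.

    ``lam[i]``, ``mu[i]`` are the rates of interval ``i`` (interval 0 most
    recent); ``shift_times`` are ascending ages strictly inside the analyzed
    time span; ``rho`` is the sampling fraction at the analysis present;
    ``boundary_survival[i]`` is the per-lineage survival probability of a mass
    extinction at ``shift_times[i]`` (all 1 by default).
    """

    lam: tuple[float, ...]
    mu: tuple[float, ...]
    shift_times: tuple[float, ...] = ()
    rho: float = 1.0
    boundary_survival: tuple[float, ...] | None = None

    def __post_init__(self):
        lam = tuple(float(v) for v in np.atleast_1d(self.lam))
        mu = tuple(float(v) for v in np.atleast_1d(self.mu))
        shifts = tuple(float(v) for v in np.atleast_1d(self.shift_times)) if len(
            np.atleast_1d(self.shift_times)
        ) else ()
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "shift_times", shifts)
        if len(lam) != len(mu):
            raise ValueError("lam and mu must have the same length")
        if len(lam) != len(shifts) + 1:
            raise ValueError("need exactly one interval more than shift times")
        if any(l <= 0 for l in lam) or any(m < 0 for m in mu):
            raise InadmissibleRatesError("need lam_i > 0 and mu_i >= 0 in every interval")
        if any(t <= 0 for t in shifts) or any(
            b >= a for a, b in zip(shifts[1:], shifts[:-1])
        ):
            raise ValueError("shift times must be strictly positive and ascending")
        if not (0 < self.rho <= 1):
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        bs = self.boundary_survival
        if bs is None:
            bs = tuple(1.0 for _ in shifts)
        else:
            bs = tuple(float(v) for v in np.atleast_1d(bs))
        if len(bs) != len(shifts):
            raise ValueError("need one boundary survival probability per shift time")
        if any(not (0 < s <= 1) for s in bs):
            raise ValueError("boundary survival probabilities must be in (0, 1]")
        object.__setattr__(self, "boundary_survival", bs)

    @classmethod
    def from_r_tau(
        cls,
        r: Sequence[float],
        tau: Sequence[float],
        shift_times: Sequence[float] = (),
        rho: float = 1.0,
        boundary_survival: Sequence[float] | None = None,
    ) -> "EpisodicBDModel":
        pairs = [decompose_rates(ri, ti) for ri, ti in zip(np.atleast_1d(r), np.atleast_1d(tau))]
        return cls(
            lam=tuple(p[0] for p in pairs),
            mu=tuple(p[1] for p in pairs),
            shift_times=tuple(shift_times),
            rho=rho,
            boundary_survival=boundary_survival,
        )

    @property
    def m(self) -> int:
        return len(self.shift_times)

    @property
    def r(self) -> np.ndarray:
        return np.array(self.lam) - np.array(self.mu)

    @property
    def tau(self) -> np.ndarray:
        return np.array(self.mu) / np.array(self.lam)

    def interval_index(self, ages) -> np.ndarray:
        """Interval containing each age (age equal to a shift -> older interval)."""
        return np.searchsorted(np.asarray(self.shift_times), np.asarray(ages), side="right")

    def lam_at(self, ages) -> np.ndarray:
        return np.asarray(self.lam)[self.interval_index(ages)]


def _step_g(g_entry, logq_entry, lam, mu, x):
    """Advance (g, log q) from an interval's young end by age increment x.

    ``g = 1 - p0`` is the probability of leaving a sampled descendant; it is
    propagated directly so that survival probabilities near 0 keep full
    relative precision (the crown-conditioning term takes its logarithm).
    Works on scalars or arrays of x.
    """
    x = np.asarray(x, dtype=float)
    r = lam - mu
    if abs(r) > CRITICAL_TOL:
        s = -r * x
        m = np.maximum(s, 0.0)
        e = g_entry * lam * np.exp(-m) + (r - lam * g_entry) * np.exp(s - m)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = g_entry * r * np.exp(-m) / e
            logq = (
                logq_entry
                + 2.0 * np.log(abs(r))
                + s
                - 2.0 * (m + np.log(np.abs(e)))
            )
    else:
        # critical case lam = mu: g and q are rational in lam * x
        c = 1.0 + g_entry * lam * x
        g = g_entry / c
        logq = logq_entry - 2.0 * np.log(c)
    return g, logq


def _entry_values(model: EpisodicBDModel):
    """(g, log q) at the young edge of every interval, after boundary maps."""
    g = model.rho
    logq = float(np.log(model.rho))
    entries = [(g, logq)]
    lo = 0.0
    for i, t in enumerate(model.shift_times):
        g_t, logq_t = _step_g(g, logq, model.lam[i], model.mu[i], t - lo)
        s = model.boundary_survival[i]
        g = s * float(g_t)
        logq = float(logq_t) + float(np.log(s))
        entries.append((g, logq))
        lo = t
    return entries


def _propagators_g(model: EpisodicBDModel, ages) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form ``g = 1 - p0`` and ``log q`` at arbitrary ages."""
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if np.any(ages < 0):
        raise ValueError("ages must be >= 0")
    entries = _entry_values(model)
    lows = np.concatenate([[0.0], np.asarray(model.shift_times)])
    idx = model.interval_index(ages)
    g = np.empty_like(ages)
    logq = np.empty_like(ages)
    for i in np.unique(idx):
        mask = idx == i
        g_e, logq_e = entries[i]
        g_i, logq_i = _step_g(
            g_e, logq_e, model.lam[i], model.mu[i], ages[mask] - lows[i]
        )
        g[mask] = g_i
        logq[mask] = logq_i
    return g, logq


def propagators(model: EpisodicBDModel, ages) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form ``p0`` and ``log q`` at arbitrary ages."""
    g, logq = _propagators_g(model, ages)
    return 1.0 - g, logq


def _propagators_ode_g(
    model: EpisodicBDModel, ages, rtol: float = 1e-10, atol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """ODE evaluation of ``(g, log q)`` (independent cross-check path).

    Integrates ``d(ln g)/du = (lam - mu) - lam g`` (equivalent to
    ``dp0/du = mu - (lam + mu) p0 + lam p0^2``) and
    ``d(ln q)/du = -(lam + mu) + 2 lam (1 - g)`` interval by interval,
    keeping full relative precision in small survival probabilities.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    if np.any(ages < 0):
        raise ValueError("ages must be >= 0")
    sorted_ages = np.sort(np.unique(ages))
    values: dict[float, tuple[float, float]] = {}
    lng = float(np.log(model.rho))
    logq = float(np.log(model.rho))
    lo = 0.0
    pos = 0
    for i in range(model.m + 1):
        hi = model.shift_times[i] if i < model.m else np.inf
        lam, mu = model.lam[i], model.mu[i]

        def rhs(_, y, lam=lam, mu=mu):
            g = math.exp(y[0])
            return [(lam - mu) - lam * g, -(lam + mu) + 2.0 * lam * (1.0 - g)]

        seg: list[float] = []
        while pos < sorted_ages.size and (sorted_ages[pos] < hi or i == model.m):
            seg.append(float(sorted_ages[pos]))
            pos += 1
        eval_ts = [t for t in seg if t > lo]
        end = hi if i < model.m else (eval_ts[-1] if eval_ts else lo)
        for t in seg:
            if t <= lo:
                values[t] = (lng, logq)
        if end > lo:
            sol = solve_ivp(
                rhs,
                (lo, end),
                [lng, logq],
                t_eval=sorted(set(eval_ts + [end])),
                rtol=rtol,
                atol=atol,
                method="LSODA",
            )
            if not sol.success:  # pragma: no cover
                raise RuntimeError(f"ODE integration failed: {sol.message}")
            for k, t in enumerate(sol.t):
                values[float(t)] = (float(sol.y[0][k]), float(sol.y[1][k]))
            lng, logq = float(sol.y[0][-1]), float(sol.y[1][-1])
        if i < model.m:
            s = model.boundary_survival[i]
            lng = lng + float(np.log(s))
            logq = logq + float(np.log(s))
            lo = hi
    g_out = np.array([math.exp(values[float(t)][0]) for t in ages])
    logq_out = np.array([values[float(t)][1] for t in ages])
    return g_out, logq_out


def propagators_ode(
    model: EpisodicBDModel, ages, rtol: float = 1e-10, atol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """ODE evaluation of ``p0`` and ``log q`` (independent cross-check path)."""
    g, logq = _propagators_ode_g(model, ages, rtol=rtol, atol=atol)
    return 1.0 - g, logq


def loglik_core(
    ages_desc: np.ndarray,
    lam: np.ndarray,
    mu: np.ndarray,
    shifts: np.ndarray,
    rho: float,
    conditioning: str = "crown_survival",
) -> float:
    """Array-level closed-form log-likelihood (no model object, no checks).

    ``ages_desc`` are descending branching times; ``lam``/``mu`` per-interval
    rates (youngest first); ``shifts`` ascending shift ages; boundary survival
    fixed at 1.  Hot path of the fitter; :func:`episodic_loglik` wraps it.
    """
    xa = ages_desc[::-1]  # ascending view
    n_times = xa.size
    crown = xa[-1]
    # block boundaries: interval i covers ages in [shifts[i-1], shifts[i])
    pos = [0]
    for t in shifts:
        pos.append(int(np.searchsorted(xa, t, side="left")))
    pos.append(n_times)
    g = rho
    logq = math.log(rho)
    lo = 0.0
    ll = 0.0
    g_crown = math.nan
    n_int = len(lam)
    for i in range(n_int):
        lam_i = lam[i]
        mu_i = mu[i]
        xs = xa[pos[i] : pos[i + 1]]
        if xs.size:
            r = lam_i - mu_i
            x = xs - lo
            if abs(r) > CRITICAL_TOL:
                s = -r * x
                m = np.maximum(s, 0.0)
                e = g * lam_i * np.exp(-m) + (r - lam_i * g) * np.exp(s - m)
                with np.errstate(divide="ignore", invalid="ignore"):
                    logq_xs = logq + 2.0 * math.log(abs(r)) + s - 2.0 * (m + np.log(np.abs(e)))
            else:
                c = 1.0 + g * lam_i * x
                logq_xs = logq - 2.0 * np.log(c)
            sub = float(np.sum(logq_xs))
            if not math.isfinite(sub):
                return -math.inf
            ll += sub + xs.size * math.log(lam_i)
            if pos[i + 1] == n_times:
                # crown is the last ascending entry: it contributes
                # 2 ln q - (its own ln lam term must be removed)
                ll += float(logq_xs[-1]) - math.log(lam_i)
        # advance entry values to the next boundary (or to the crown for g)
        if i < n_int - 1:
            t_next = shifts[i]
            g_a, logq_a = _step_g(g, logq, lam_i, mu_i, t_next - lo)
            g, logq = float(g_a), float(logq_a)
            if not (math.isfinite(g) and 0.0 < g <= 1.0 + 1e-12):
                return -math.inf
            lo = t_next
        else:
            g_a, _ = _step_g(g, logq, lam_i, mu_i, crown - lo)
            g_crown = float(g_a)
    if not (math.isfinite(g_crown) and 0.0 < g_crown <= 1.0 + 1e-12):
        return -math.inf
    if conditioning == "crown_survival":
        ll -= 2.0 * math.log(g_crown)
    elif conditioning != "none":
        raise ValueError(f"unknown conditioning {conditioning!r}")
    return ll


def _assemble_loglik(bt, model, g_fn, conditioning):
    """Shared logL assembly over a propagator path returning (g, log q)."""
    x = bt.ages
    g, logq = g_fn(model, x)
    if not (np.all(np.isfinite(logq)) and np.all(np.isfinite(g))):
        return -np.inf
    if np.any(g <= 0) or np.any(g > 1 + 1e-12):
        return -np.inf
    loglam = np.log(model.lam_at(x))
    ll = float(np.sum(loglam[1:]) + np.sum(logq[1:]) + 2.0 * logq[0])
    if conditioning == "crown_survival":
        ll -= 2.0 * float(np.log(g[0]))
    elif conditioning != "none":
        raise ValueError(f"unknown conditioning {conditioning!r}")
    return ll


def episodic_loglik(
    bt: BranchingTimes,
    model: EpisodicBDModel,
    conditioning: str = "crown_survival",
) -> float:
    """Closed-form log-likelihood (up to a parameter-independent constant).

    ``conditioning="crown_survival"`` (default) conditions on the crown age
    and on both crown lineages having sampled descendants; ``"none"`` drops
    the survival conditioning.  Returns ``-inf`` for models that are
    numerically inadmissible for these data instead of raising.
    """
    if all(s == 1.0 for s in model.boundary_survival):
        return loglik_core(
            bt.ages,
            np.asarray(model.lam),
            np.asarray(model.mu),
            np.asarray(model.shift_times),
            model.rho,
            conditioning,
        )
    return _assemble_loglik(bt, model, _propagators_g, conditioning)


def episodic_loglik_ode(
    bt: BranchingTimes,
    model: EpisodicBDModel,
    conditioning: str = "crown_survival",
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> float:
    """Log-likelihood with ODE-integrated propagators (cross-check path)."""

    def g_fn(m, ages):
        return _propagators_ode_g(m, ages, rtol=rtol, atol=atol)

    return _assemble_loglik(bt, model, g_fn, conditioning)
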