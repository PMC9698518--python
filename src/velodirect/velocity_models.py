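"""Per-gene kinetic fits and per-cell RNA velocity.

Two estimators are provided.  The steady-state model regresses unspliced on
spliced abundance through the origin, ``gamma_tilde = (u . s) / (s . s)``, and
defines velocity as the residual ``v_i = u_i - gamma_tilde * s_i``.  The
dynamic model fits, per gene, a one-switch induction/repression trajectory of
the splicing ODE with latent cell times by expectation-maximization against a
Gaussian likelihood

    L(theta) = 1/(sqrt(2*pi)*sigma) * exp(-(1/(2n)) * sum_i ||x_i - x_{t_i}(theta)||^2 / sigma^2)

and defines velocity as ``v_i = beta*u_i - gamma*s_i`` (the spliced ODE
right-hand side at the observation).  Because only the phase-space trajectory
is observed and times are latent, rates are identifiable up to a common time
scaling; fitting fixes ``alpha = 1`` and reports rate ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from velodirect.errors import ConfigError, ParameterError, ShapeError
from velodirect.sim_kinetics import KineticParams, _solve_any_times

_SIGMA2_FLOOR = 1e-12


@dataclass
class SteadyStateFit:
    """Per-gene steady-state ratio fit."""

    gamma_tilde: np.ndarray   # gamma/beta ratio per gene (NaN where invalid)
    r2: np.ndarray            # through-origin fit diagnostic
    valid: np.ndarray         # genes with nonzero spliced signal


@dataclass
class DynamicFit:
    """Per-gene dynamic-model EM fit (alpha fixed to 1; rates are ratios)."""

    theta: pd.DataFrame           # columns alpha, beta, gamma, t_switch
    sigma: np.ndarray             # per-gene residual scale (> 0)
    latent_time: np.ndarray       # cells x genes assigned times
    loglik_trace: list            # per-gene array of EM log-likelihoods
    converged: np.ndarray         # per-gene bool
    valid: np.ndarray             # genes with enough signal to fit


@dataclass
class VelocityField:
    """Per-cell x gene signed velocity values."""

    velocity: np.ndarray
    mode: str                     # "steady_state" | "dynamic"
    valid_genes: np.ndarray       # bool mask; invalid genes carry zeros

    def __post_init__(self):
        if self.velocity.shape[1] != self.valid_genes.shape[0]:
            raise ShapeError("valid_genes length must match velocity columns")


def fit_gamma(u: np.ndarray, s: np.ndarray) -> float:
    """Least-squares slope of u on s through the origin: ``(u.s)/(s.s)``."""
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    if u.shape != s.shape:
        raise ShapeError("u and s must have the same shape")
    ss = float(s @ s)
    if ss == 0:
        raise ParameterError("all-zero spliced vector; gene has no steady-state fit")
    return float(u @ s) / ss


def fit_steady_state(Mu: np.ndarray, Ms: np.ndarray) -> SteadyStateFit:
    """Vectorized per-gene steady-state ratio fit on (moment-smoothed) layers.

    Genes with an all-zero spliced signal are flagged invalid (``gamma_tilde``
    NaN) and excluded from velocity genes downstream.
    """
    Mu = np.asarray(Mu, dtype=float)
    Ms = np.asarray(Ms, dtype=float)
    if Mu.shape != Ms.shape:
        raise ShapeError("Mu and Ms must have the same shape")
    ss = (Ms * Ms).sum(axis=0)
    valid = ss > 0
    gamma = np.full(Mu.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma[valid] = (Mu * Ms).sum(axis=0)[valid] / ss[valid]
    resid = Mu - gamma[None, :] * Ms
    tot = ((Mu - Mu.mean(axis=0)) ** 2).sum(axis=0)
    r2 = np.full(Mu.shape[1], np.nan)
    ok = valid & (tot > 0)
    r2[ok] = 1.0 - (resid[:, ok] ** 2).sum(axis=0) / tot[ok]
    return SteadyStateFit(gamma_tilde=gamma, r2=r2, valid=valid)


def steady_state_velocity(u: np.ndarray, s: np.ndarray, fit: SteadyStateFit) -> VelocityField:
    """Velocity as deviation from the steady-state ratio: ``v = u - gamma_tilde * s``."""
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    if u.shape != s.shape or u.shape[1] != fit.gamma_tilde.shape[0]:
        raise ShapeError("layer shapes do not match the steady-state fit")
    v = np.zeros_like(u)
    val = fit.valid
    v[:, val] = u[:, val] - fit.gamma_tilde[val][None, :] * s[:, val]
    return VelocityField(velocity=v, mode="steady_state", valid_genes=val.copy())


def dynamic_likelihood(params: KineticParams, sigma: float,
                       u: np.ndarray, s: np.ndarray, times: np.ndarray) -> float:
    """Gaussian trajectory likelihood of one gene at assigned cell times.

    Returns ``1/(sqrt(2*pi)*sigma) * exp(-(1/(2n)) * sum ||x_obs - x_t||^2 / sigma^2)``.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    times = np.asarray(times, dtype=float)
    if not (u.shape == s.shape == times.shape) or u.size < 1:
        raise ShapeError("u, s, times must be equal-length nonempty vectors")
    ut, st = _solve_any_times(params, times)
    sq = float(((u - ut) ** 2 + (s - st) ** 2).sum())
    n = u.size
    return 1.0 / (math.sqrt(2 * math.pi) * sigma) * math.exp(-sq / (2 * n * sigma**2))


def _loglik_from_sq(sq_sum: float, n: int) -> tuple[float, float]:
    """Profile log-likelihood at the ML sigma (sigma^2 = mean squared residual)."""
    sigma2 = max(sq_sum / n, _SIGMA2_FLOOR)
    ll = -0.5 * math.log(2 * math.pi * sigma2) - sq_sum / (2 * n * sigma2)
    return ll, math.sqrt(sigma2)


def _time_grid(beta: float, gamma: float, t_switch: float, n_grid: int) -> np.ndarray:
    """Dense latent-time grid over one induction/repression cycle."""
    n_on = n_grid // 2
    t_on = np.linspace(0.0, t_switch, n_on)
    t_off = t_switch + np.linspace(0.0, 4.0 / min(gamma, beta), n_grid - n_on + 1)[1:]
    return np.concatenate([t_on, t_off])


def _trajectory(beta: float, gamma: float, t_switch: float, t: np.ndarray):
    p = KineticParams(alpha=1.0, beta=beta, gamma=gamma, t_switch=t_switch)
    return _solve_any_times(p, t)


def fit_dynamic_em(
    u: np.ndarray,
    s: np.ndarray,
    n_grid: int = 200,
    max_iter: int = 30,
    tol: float = 1e-6,
    gamma_tilde_init: Optional[float] = None,
) -> dict:
    """EM fit of the one-switch splicing trajectory for a single gene.

    E-step: assign each cell the latent time minimizing its squared distance
    to the closed-form trajectory, over a dense grid augmented with the cell's
    previous assignment (which makes the log-likelihood trace rigorously
    non-decreasing as the grid moves).  M-step: bounded least squares over
    ``(beta, gamma, t_switch)`` with ``alpha = 1`` fixed; ``sigma^2`` is the
    mean squared residual (the ML profile of the trajectory likelihood).

    Returns a dict with keys ``beta, gamma, t_switch, sigma, latent_time,
    loglik_trace, converged``.  Non-convergence at ``max_iter`` is flagged,
    not raised.
    """
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    if u.shape != s.shape or u.ndim != 1:
        raise ShapeError("u and s must be equal-length vectors")
    n = u.size
    if np.count_nonzero((u != 0) | (s != 0)) < 10:
        raise ParameterError("need >= 10 cells with nonzero signal to fit the dynamic model")

    # deterministic initialization from the steady-state ratio and signal scale
    u_hi = float(np.quantile(u, 0.98))
    beta0 = 1.0 / max(u_hi, 1e-6)
    if gamma_tilde_init is None:
        try:
            gamma_tilde_init = fit_gamma(u, s)
        except ParameterError:
            gamma_tilde_init = 1.0
    gamma0 = float(np.clip(gamma_tilde_init, 1e-3, 1e3)) * beta0

    def _sq_at(beta, gamma, t_switch, t_assigned=None):
        grid = _time_grid(beta, gamma, t_switch, n_grid)
        if t_assigned is not None:
            grid = np.concatenate([grid, np.unique(t_assigned)])
        ug, sg = _trajectory(beta, gamma, t_switch, grid)
        d2 = (u[:, None] - ug[None, :]) ** 2 + (s[:, None] - sg[None, :]) ** 2
        j = np.argmin(d2, axis=1)
        return float(d2[np.arange(n), j].sum()), grid[j]

    # pick the best of a few deterministic t_switch starts
    best = None
    for t_sw0 in (1.0 / beta0, 2.0 / beta0, 4.0 / beta0):
        sq, t_assigned = _sq_at(beta0, gamma0, t_sw0)
        if best is None or sq < best[0]:
            best = (sq, t_assigned, t_sw0)
    sq_sum, t_assigned, t_sw = best
    beta, gamma = beta0, gamma0

    trace = []
    converged = False
    ll_prev = -np.inf
    for _ in range(max_iter):
        # M-step: refine (beta, gamma, t_switch) at fixed assigned times
        def resid(p):
            ut, st = _trajectory(p[0], p[1], p[2], t_assigned)
            return np.concatenate([ut - u, st - s])

        sol = least_squares(
            resid,
            x0=[beta, gamma, t_sw],
            bounds=([1e-6, 1e-6, 1e-4], [1e6, 1e6, 1e6]),
            method="trf",
            max_nfev=60,
        )
        beta, gamma, t_sw = (float(x) for x in sol.x)

        # E-step: reassign times (previous assignment kept as candidates)
        sq_sum, t_assigned = _sq_at(beta, gamma, t_sw, t_assigned)
        ll, sigma = _loglik_from_sq(sq_sum, n)
        trace.append(ll)
        if ll - ll_prev < tol:
            converged = True
            break
        ll_prev = ll

    return {
        "beta": beta,
        "gamma": gamma,
        "t_switch": t_sw,
        "sigma": sigma,
        "latent_time": t_assigned,
        "loglik_trace": np.asarray(trace),
        "converged": converged,
    }


def fit_dynamic(Mu: np.ndarray, Ms: np.ndarray, n_grid: int = 200,
                max_iter: int = 30, tol: float = 1e-6) -> DynamicFit:
    """Per-gene dynamic EM fit over a (moment-smoothed) dataset.

    Genes with fewer than 10 nonzero cells are flagged invalid and skipped.
    """
    Mu = np.asarray(Mu, dtype=float)
    Ms = np.asarray(Ms, dtype=float)
    if Mu.shape != Ms.shape:
        raise ShapeError("Mu and Ms must have the same shape")
    n, g = Mu.shape
    ss = fit_steady_state(Mu, Ms)
    beta = np.full(g, np.nan)
    gamma = np.full(g, np.nan)
    t_switch = np.full(g, np.nan)
    sigma = np.full(g, np.nan)
    latent = np.full((n, g), np.nan)
    traces: list = [None] * g
    converged = np.zeros(g, dtype=bool)
    valid = np.zeros(g, dtype=bool)
    for j in range(g):
        try:
            res = fit_dynamic_em(
                Mu[:, j], Ms[:, j], n_grid=n_grid, max_iter=max_iter, tol=tol,
                gamma_tilde_init=ss.gamma_tilde[j] if ss.valid[j] else None,
            )
        except ParameterError:
            continue
        valid[j] = True
        beta[j], gamma[j], t_switch[j] = res["beta"], res["gamma"], res["t_switch"]
        sigma[j] = res["sigma"]
        latent[:, j] = res["latent_time"]
        traces[j] = res["loglik_trace"]
        converged[j] = res["converged"]
    theta = pd.DataFrame(
        {"alpha": np.ones(g), "beta": beta, "gamma": gamma, "t_switch": t_switch}
    )
    return DynamicFit(theta=theta, sigma=sigma, latent_time=latent,
                      loglik_trace=traces, converged=converged, valid=valid)


def dynamic_velocity(u: np.ndarray, s: np.ndarray, fit: DynamicFit) -> VelocityField:
    """Velocity from the fitted kinetics: ``v = beta*u - gamma*s`` per gene.

    Unfitted genes are excluded (zeros, masked in ``valid_genes``).
    """
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    g = len(fit.theta)
    if u.shape != s.shape or u.shape[1] != g:
        raise ShapeError("layer shapes do not match the dynamic fit")
    v = np.zeros_like(u)
    val = fit.valid
    beta = fit.theta["beta"].to_numpy()
    gamma = fit.theta["gamma"].to_numpy()
    v[:, val] = beta[val][None, :] * u[:, val] - gamma[val][None, :] * s[:, val]
    return VelocityField(velocity=v, mode="dynamic", valid_genes=val.copy())
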