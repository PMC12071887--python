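"""Estimation of the experimentally inaccessible transition constants.

The light-scattering signal cannot separate the recovery of exhausted
platelets (``k1r``), the reversal of inhibition (``k4r``) or the
disaggregation rate (``k7``) from concurrent processes, so these are
obtained by fitting simulated trajectories to observed traces. The loss
is a per-channel range-normalized sum of squared residuals over the
scatter channels, equally weighted; optimization runs a seeded
basin-hopping-style global stage (random log-space perturbations with
accept-if-better) around a quasi-Newton (L-BFGS-B) local stage with
numerical gradients, in log-parameter space. Identifiability is reported
per parameter via finite-difference curvature of the loss at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import FitError
from .model import observables, simulate
from .params import DEFAULT_FITTED
from .trace import Trace

__all__ = ["FitProblem", "FitResult", "fit_model", "r_squared"]


def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot`` in (-inf, 1]."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("series must be aligned and of equal length")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed series has zero variance; R^2 undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


@dataclass
class FitProblem:
    """Free constants with bounds, the fixed measured table, and the
    (protocol, trace) observations the fit must reproduce."""

    free_params: dict  # name -> (lower, upper), 1/s
    observations: list  # of (StimulusProtocol, Trace)
    fixed_params: dict | None = None  # Hill-law table; default measured
    fixed_fitted: dict = field(default_factory=dict)  # pinned hidden constants
    channels: tuple = ("LSI1", "LSI12")
    map_spec: dict | None = None
    rtol: float = 1e-6
    atol: float = 1e-9

    def __post_init__(self):
        for name, (lo, hi) in self.free_params.items():
            if not (0 < lo < hi and np.isfinite(hi)):
                raise ValueError(f"bounds for {name} must be finite and positive")
            if name in self.fixed_fitted:
                raise ValueError(f"{name} is both free and fixed")


@dataclass
class FitResult:
    estimates: dict
    r2: list  # per observation
    loss: float
    loss_history: list
    n_evals: int
    seed: int
    unidentifiable: list
    converged: bool


def _predict(problem: FitProblem, overrides: dict):
    preds = []
    for prot, tr in problem.observations:
        traj = simulate(
            prot,
            param_table=problem.fixed_params,
            fitted=overrides,
            t_eval=tr.t,
            rtol=problem.rtol,
            atol=problem.atol,
        )
        preds.append(observables(traj, problem.map_spec))
    return preds


def fit_model(
    problem: FitProblem,
    global_iters: int = 3,
    seed: int = 0,
    step_dex: float = 0.4,
    local_opts: dict | None = None,
) -> FitResult:
    """Fit the free constants; deterministic given ``seed``.

    ``global_iters`` hop-style perturbations (log-normal steps of
    ``step_dex`` decades) are each polished with L-BFGS-B; the best
    basin wins. Zero free parameters returns the forward-simulation fit
    quality of the fixed constants.
    """
    names = list(problem.free_params)
    fixed = dict(DEFAULT_FITTED)
    fixed.update(problem.fixed_fitted)
    n_eval = [0]

    ranges = {}
    for _, tr in problem.observations:
        for ch in problem.channels:
            r = float(np.ptp(tr.channel(ch)))
            ranges[id(tr), ch] = r if r > 0 else 1.0

    def loss_of(theta):
        overrides = dict(fixed)
        overrides.update(
            {n: 10.0 ** th for n, th in zip(names, theta)}
        )
        n_eval[0] += 1
        total = 0.0
        for (prot, tr), pred in zip(
            problem.observations, _predict(problem, overrides)
        ):
            for ch in problem.channels:
                res = (pred.channel(ch) - tr.channel(ch)) / ranges[id(tr), ch]
                total += float(res @ res)
        return total

    if not names:
        preds = _predict(problem, fixed)
        r2s = [
            np.mean(
                [
                    r_squared(tr.channel(ch), pred.channel(ch))
                    for ch in problem.channels
                ]
            )
            for (_, tr), pred in zip(problem.observations, preds)
        ]
        return FitResult(
            estimates=dict(fixed), r2=r2s, loss=loss_of([]),
            loss_history=[], n_evals=n_eval[0], seed=seed,
            unidentifiable=[], converged=True,
        )

    lb = np.log10([problem.free_params[n][0] for n in names])
    ub = np.log10([problem.free_params[n][1] for n in names])
    bounds = list(zip(lb, ub))
    rng = np.random.default_rng(seed)
    opts = {"maxiter": 60, "ftol": 1e-10, "gtol": 1e-8}
    opts.update(local_opts or {})

    def polish(x0):
        return minimize(
            loss_of, np.clip(x0, lb, ub), method="L-BFGS-B",
            bounds=bounds, options=opts,
        )

    history = []
    best = polish((lb + ub) / 2.0)
    history.append(float(best.fun))
    any_success = best.success
    for _ in range(global_iters):
        x0 = best.x + rng.normal(scale=step_dex, size=len(names))
        cand = polish(x0)
        any_success = any_success or cand.success
        history.append(float(cand.fun))
        if cand.fun < best.fun:
            best = cand
    if not any_success and not np.isfinite(best.fun):
        raise FitError("all optimization starts failed")

    estimates = {n: float(10.0 ** x) for n, x in zip(names, best.x)}
    overrides = dict(fixed)
    overrides.update(estimates)
    preds = _predict(problem, overrides)
    r2s = [
        float(
            np.mean(
                [
                    r_squared(tr.channel(ch), pred.channel(ch))
                    for ch in problem.channels
                ]
            )
        )
        for (_, tr), pred in zip(problem.observations, preds)
    ]

    # flat-loss check: a parameter whose +-20% wiggle moves the loss less
    # than numerical noise is unidentifiable from these observations
    unident = []
    f0 = float(best.fun)
    for i, n in enumerate(names):
        delta = 0.0
        for sgn in (-1.0, 1.0):
            x = best.x.copy()
            x[i] = np.clip(x[i] + sgn * np.log10(1.2), lb[i], ub[i])
            delta = max(delta, abs(loss_of(x) - f0))
        if delta < 1e-4 * (1.0 + f0):
            unident.append(n)

    return FitResult(
        estimates=estimates, r2=r2s, loss=f0, loss_history=history,
        n_evals=n_eval[0], seed=seed, unidentifiable=unident,
        converged=bool(best.success),
    )
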