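"""Hill dose-response fitting for rate constants and normalized readouts.

Activation data follow ``k_max * A**h / (EC50**h + A**h)``; inhibition
data follow ``k_max * IC50**h / (IC50**h + I**h)``. Fits are (optionally
inverse-variance weighted) nonlinear least squares over
``(k_max, half_conc, h)`` with multi-start over log-spaced half-maximal
seeds, since Hill fits have notoriously flat valleys in ``(EC50, h)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError
from .params import HillParams

__all__ = ["DoseResponseDataset", "HillFit", "fit_hill", "eval_hill"]

H_BOUNDS = (0.3, 10.0)


@dataclass
class DoseResponseDataset:
    """Doses (nM unless noted) against responses (1/s rate constants or
    percent-of-control readouts)."""

    # at least as many distinct doses as free Hill parameters are needed
    doses: np.ndarray
    responses: np.ndarray
    response_kind: str = "k"  # k | Vsh | Vagg | AUCagg
    sd: np.ndarray | None = None
    n: int | None = None
    unit: str = "nM"

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must have equal length")
        if np.any(self.doses < 0):
            raise ValueError("doses must be >= 0")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.doses.shape:
                raise ValueError("sd length mismatch")

    @property
    def n_distinct(self):
        return len(np.unique(self.doses))


@dataclass
class HillFit:
    """Fitted Hill parameters with diagnostics."""

    params: HillParams
    r2: float
    stderr: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    residual_norm: float = float("nan")


def eval_hill(p: HillParams, doses):
    """Vectorized Hill evaluation (exact half-maximum at ``half_conc``)."""
    return p.rate(doses)


def fit_hill(
    ds: DoseResponseDataset,
    mode: str = "activation",
    fix_kmax: float | None = None,
    n_starts: int = 5,
) -> HillFit:
    """Weighted nonlinear least-squares Hill fit.

    Uses inverse-variance weights when the dataset carries per-point SDs,
    multi-starts over log-spaced half-maximal seeds, and bounds
    ``half_conc`` within two decades of the dosed range and ``h`` in
    [0.3, 10]. Saturated (dose-independent) data return a flagged
    boundary result rather than an error; fewer distinct doses than free
    parameters raises :class:`FitError` (three doses with all three
    parameters free fit as an exact interpolation, as when refitting
    tabulated three-dose summaries).
    """
    if mode not in ("activation", "inhibition"):
        raise ValueError(f"unknown mode {mode!r}")
    d = ds.doses
    y = ds.responses
    free = 3 if fix_kmax is None else 2
    if ds.n_distinct < free:
        raise FitError(
            f"{ds.n_distinct} distinct doses cannot constrain {free} free "
            "Hill parameters"
        )
    w = np.ones_like(y)
    if ds.sd is not None and np.all(ds.sd > 0):
        w = 1.0 / ds.sd

    pos = d[d > 0]
    span = float(y.max() - y.min())
    scale = max(abs(y).max(), 1e-300)
    flags: list = []
    if span <= 1e-9 * scale:
        # dose-independent responses: the half-max dose is unidentifiable
        flags.append("saturated" if mode == "activation" else "h-unidentifiable")
        p = HillParams(
            k_max=fix_kmax if fix_kmax is not None else float(np.mean(y)),
            half_conc=float(pos.min()) if len(pos) else 1.0,
            h=1.0,
            mode=mode,
            unit=ds.unit,
        )
        return HillFit(params=p, r2=1.0, flags=flags, residual_norm=0.0)

    order = np.argsort(d)
    ys = y[order]
    # largest rise/fall between any ordered pair of doses
    up = float(np.max(ys - np.minimum.accumulate(ys)))
    down = float(np.max(np.maximum.accumulate(ys) - ys))
    wrong_dir = (mode == "activation") != (up >= down)
    non_monotone = min(up, down) > 0.2 * span
    if wrong_dir or non_monotone:
        warnings.warn(
            "responses are not monotone in the direction the chosen Hill "
            "mode implies (beyond noise); fitting anyway",
            stacklevel=2,
        )

    lo_half = float(pos.min()) / 100.0
    hi_half = float(pos.max()) * 100.0
    kmax_hi = 10.0 * abs(y).max()

    def pack(theta):
        if fix_kmax is None:
            kmax, half, h = theta
        else:
            kmax = fix_kmax
            half, h = theta
        return kmax, half, h

    def resid(theta):
        kmax, half, h = pack(theta)
        with np.errstate(over="ignore"):
            r = (d / half) ** h
        occ = r / (1.0 + r)
        model = kmax * occ if mode == "activation" else kmax * (1.0 - occ)
        return (model - y) * w

    best = None
    for half0 in np.geomspace(max(lo_half, 1e-12), hi_half, n_starts):
        x0 = [half0, 1.5]
        lb = [lo_half, H_BOUNDS[0]]
        ub = [hi_half, H_BOUNDS[1]]
        if fix_kmax is None:
            x0 = [abs(y).max() or 1.0] + x0
            lb = [1e-12 * scale] + lb
            ub = [kmax_hi] + ub
        try:
            sol = least_squares(resid, x0, bounds=(lb, ub))
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("all Hill fit starts failed to converge")

    kmax, half, h = pack(best.x)
    ss_res = float(np.sum((resid(best.x) / w) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if np.isclose(half, lo_half) or np.isclose(half, hi_half):
        flags.append("half_conc-at-bound")
    if np.isclose(h, H_BOUNDS[0]) or np.isclose(h, H_BOUNDS[1]):
        flags.append("h-at-bound")

    stderr = {}
    dof = len(y) - len(best.x)
    if dof > 0:
        try:
            cov = np.linalg.inv(best.jac.T @ best.jac) * 2 * best.cost / dof
            names = (
                ["k_max", "half_conc", "h"] if fix_kmax is None
                else ["half_conc", "h"]
            )
            stderr = {
                n: float(np.sqrt(max(cov[i, i], 0.0)))
                for i, n in enumerate(names)
            }
        except np.linalg.LinAlgError:
            pass

    p = HillParams(
        k_max=float(kmax), half_conc=float(half), h=float(h),
        mode=mode, unit=ds.unit,
    )
    return HillFit(
        params=p, r2=r2, stderr=stderr, flags=flags,
        residual_norm=float(np.sqrt(ss_res)),
    )
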