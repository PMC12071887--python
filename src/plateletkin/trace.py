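"""Instrument-like traces and kinetic readouts.

A :class:`Trace` holds light-scatter intensity channels (``LSI1`` at 1
degree tracks aggregation, ``LSI12`` at 12 degrees tracks shape change)
and optionally a fluorescence channel (``FL527``, calcium proxy) on a
strictly increasing time grid, in arbitrary units.

Readouts follow the conventions of low-angle light-scattering
aggregometry:

* ``fit_exponential_rise`` — monoexponential saturation
  ``I(t) = Im - (Im - Io) * exp(-k (t - t0))`` fitted by nonlinear least
  squares with analytic Jacobian; this is how the maximal shape-change and
  integrin-activation rate constants are extracted at saturating agonist.
* ``initial_rate`` — tangent slope at a fixed time from process onset
  (5 s on LSI12 gives Vsh, 20 s on LSI1 gives Vagg), estimated by local
  linear regression for noise robustness.
* ``auc`` — trapezoidal area of the baseline-subtracted channel
  (120 s on LSI1 gives AUCagg, 20 s on FL527 gives AUCCa).
* ``disaggregation_percent`` — percent drop of the signal from its
  maximum, the Disagg readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DegenerateFitError, FitError, TraceRangeError

__all__ = [
    "Trace",
    "ExpFitResult",
    "estimate_baseline",
    "detect_onset",
    "fit_exponential_rise",
    "initial_rate",
    "auc",
    "disaggregation_percent",
    "normalize_to_control",
]


@dataclass
class Trace:
    """Uniformly sampled multichannel trace in arbitrary units."""

    t: np.ndarray
    channels: dict
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or len(self.t) < 2 or np.any(np.diff(self.t) <= 0):
            raise ValueError("trace time axis must be strictly increasing")
        self.channels = {
            k: np.asarray(v, dtype=float) for k, v in self.channels.items()
        }
        for k, v in self.channels.items():
            if v.shape != self.t.shape:
                raise ValueError(f"channel {k!r} length mismatch")

    def channel(self, name) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in trace (has {sorted(self.channels)})"
            ) from None

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t)))

    def first_event_time(self):
        ev = self.annotations.get("events") or []
        times = [e["t"] for e in ev]
        return min(times) if times else None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.t})
        for k, v in self.channels.items():
            df[k] = v
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, annotations=None) -> "Trace":
        chans = {c: df[c].to_numpy() for c in df.columns if c != "t"}
        return cls(df["t"].to_numpy(), chans, annotations or {})


def estimate_baseline(trace: Trace, channel: str, pre_window=5.0) -> float:
    """Median signal over the ``pre_window`` seconds before the first
    annotated event; falls back to the first sample when no pre-event data
    exist."""
    y = trace.channel(channel)
    t0 = trace.first_event_time()
    if t0 is None:
        t0 = trace.t[0]
    sel = (trace.t < t0) & (trace.t >= t0 - pre_window)
    if sel.sum() >= 3:
        return float(np.median(y[sel]))
    return float(y[0])


def _pre_event_noise_sd(trace, channel):
    y = trace.channel(channel)
    t0 = trace.first_event_time()
    if t0 is not None:
        sel = trace.t < t0
        if sel.sum() >= 5:
            return float(np.std(y[sel], ddof=1))
    return 0.0


def detect_onset(trace: Trace, channel: str, n_sigma=3.0) -> float:
    """First time the channel exceeds baseline + ``n_sigma`` * pre-event
    noise SD (plus a tiny floor so noiseless signals work)."""
    y = trace.channel(channel)
    base = estimate_baseline(trace, channel)
    sd = _pre_event_noise_sd(trace, channel)
    thresh = base + n_sigma * sd + 1e-9 + 1e-6 * max(np.ptp(y), 1e-12)
    above = np.nonzero(y > thresh)[0]
    if len(above) == 0:
        raise DegenerateFitError(
            f"channel {channel!r} never exceeds onset threshold"
        )
    return float(trace.t[above[0]])


@dataclass(frozen=True)
class ExpFitResult:
    """Monoexponential-saturation fit: rate constant, plateau, baseline,
    goodness of fit and the rate's standard error."""

    k: float
    i_m: float
    i_o: float
    r2: float
    stderr_k: float
    ok: bool
    t0: float

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        return self.i_m - (self.i_m - self.i_o) * np.exp(-self.k * (t - self.t0))


def fit_exponential_rise(
    trace: Trace,
    channel: str,
    window=None,
    t0=None,
    r2_floor=0.5,
    noise_floor=None,
) -> ExpFitResult:
    """Fit ``I(t) = Im - (Im - Io) exp(-k (t - t0))`` on a trace window.

    ``window`` is ``(t_start, t_stop)``; default the whole trace. ``t0``
    anchors the process onset (default: window start). Fits with an
    analytic Jacobian; a flat signal raises :class:`DegenerateFitError`
    and a fit with r2 below ``r2_floor`` is returned with ``ok=False``.
    """
    t = trace.t
    y = trace.channel(channel)
    if window is not None:
        lo, hi = window
        sel = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        t, y = t[sel], y[sel]
    if len(t) < 10:
        raise ValueError("fit window must contain at least 10 samples")
    if t0 is None:
        t0 = float(t[0])
    tau = t - t0

    rng = float(np.ptp(y))
    floor = noise_floor if noise_floor is not None else max(
        1e-9, 1e-6 * max(abs(y).max(), 1.0)
    )
    if rng < floor:
        raise DegenerateFitError("signal range below noise floor; nothing to fit")

    io0 = float(y[0])
    im0 = float(y.max())
    half = io0 + 0.5 * (im0 - io0)
    above = np.nonzero(y >= half)[0]
    t_half = tau[above[0]] if len(above) and tau[above[0]] > 0 else tau[-1] / 4
    k0 = np.log(2.0) / max(t_half, trace.dt)

    def resid(p):
        k, im, io = p
        return im - (im - io) * np.exp(-k * tau) - y

    def jac(p):
        k, im, io = p
        e = np.exp(-k * tau)
        return np.column_stack(((im - io) * tau * e, 1.0 - e, e))

    sol = least_squares(
        resid, [k0, im0, io0], jac=jac,
        bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
    )
    if not sol.success:
        raise FitError(f"exponential fit did not converge: {sol.message}")
    k, im, io = sol.x
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    dof = max(len(y) - 3, 1)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * ss_res / dof
        stderr_k = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        stderr_k = float("nan")
    return ExpFitResult(
        k=float(k), i_m=float(im), i_o=float(io), r2=max(min(r2, 1.0), 0.0),
        stderr_k=stderr_k, ok=r2 >= r2_floor, t0=t0,
    )


def initial_rate(
    trace: Trace, channel: str, t_eval: float, t_onset=0.0, half_window=2.0
):
    """Tangent slope (AU/s) at ``t_onset + t_eval`` by local linear
    regression over ``+- half_window`` seconds."""
    tc = t_onset + t_eval
    t = trace.t
    if tc < t[0] - 1e-9 or tc > t[-1] + 1e-9:
        raise TraceRangeError(f"evaluation time {tc} s outside trace")
    sel = (t >= tc - half_window) & (t <= tc + half_window)
    if sel.sum() < 3:
        raise TraceRangeError("too few samples in regression window")
    x = t[sel] - tc
    y = trace.channel(channel)[sel]
    return float(np.polyfit(x, y, 1)[0])


def auc(
    trace: Trace, channel: str, window_len: float, t_onset=0.0, baseline=None
):
    """Trapezoidal area (AU*s) of the baseline-subtracted channel over
    ``[t_onset, t_onset + window_len]``."""
    t = trace.t
    t1 = t_onset + window_len
    if t_onset < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise TraceRangeError("AUC window overruns trace")
    if baseline is None:
        baseline = estimate_baseline(trace, channel)
    y = trace.channel(channel) - baseline
    # integrate on the sample grid, with interpolated window endpoints
    tt = np.concatenate(([t_onset], t[(t > t_onset) & (t < t1)], [t1]))
    yy = np.interp(tt, t, y)
    return float(np.trapezoid(yy, tt))


def disaggregation_percent(trace: Trace, channel: str, baseline=None):
    """Percent drop of the signal from its maximum: Disagg readout.

    ``100 * (max - final) / (max - baseline)`` clipped to [0, 100]; a
    monotone rising trace returns 0 (no disaggregation). Invariant to
    affine rescaling of the channel.
    """
    y = trace.channel(channel)
    if baseline is None:
        baseline = estimate_baseline(trace, channel)
    peak = float(y.max())
    if peak - baseline <= 0:
        raise DegenerateFitError("no maximum above baseline")
    final = float(y[-1])
    return float(np.clip(100.0 * (peak - final) / (peak - baseline), 0.0, 100.0))


def normalize_to_control(value, control_value):
    """Express a readout as percent of its paired same-day control."""
    if control_value == 0:
        raise ZeroDivisionError("control readout is zero")
    return 100.0 * value / control_value
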