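"""Estimation of the exhaustion (desensitization) rate constants.

Two protocol families probe the transition into the refractory state:

* *shape-change delay*: weak activation (100 nM ADP) is followed after a
  variable delay by a strong restimulation; the decline of the
  aggregation rate Vagg with delay gives the constant out of the
  shape-changed state (k5).
* *stir pause*: strong activation with stirring halted for a variable
  time; the decline of Vagg after stirring resumes gives the constant out
  of the integrin-active state (k6).

The decline is modeled as first-order in the delay,
``response(delay) = 100 * exp(-k * delay)`` with the zero-delay response
anchored at the 100% control. The dependence of the extracted constant on
the agonist dose follows the inhibitory Hill law (high agonist doses
protect against desensitization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .doseresponse import DoseResponseDataset, HillFit, fit_hill
from .errors import ModelMismatchError

__all__ = [
    "DecayDataset",
    "fit_decay_constant",
    "half_time",
    "dose_dependence_of_decay",
]


@dataclass
class DecayDataset:
    """Vagg (percent of zero-delay control) against wait duration (s)."""

    delays: np.ndarray
    responses: np.ndarray
    agonist_conc: float  # nM, the (re)stimulation dose
    protocol_kind: str = "shape_change_delay"  # or "stir_pause"

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.delays.shape != self.responses.shape:
            raise ValueError("delays and responses must match in length")
        if np.any(self.delays < 0) or np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be >= 0 and strictly increasing")


def fit_decay_constant(ds: DecayDataset):
    """Least-squares fit of ``100 * exp(-k * delay)``; returns ``(k, r2)``.

    Responses that rise with delay contradict first-order decay and raise
    :class:`ModelMismatchError`; responses all at 100% return the k = 0
    boundary.
    """
    if len(ds.delays) < 3:
        raise ValueError("need at least 3 delays")
    d, r = ds.delays, ds.responses
    if np.polyfit(d, r, 1)[0] > 1e-12:
        raise ModelMismatchError(
            "responses increase with delay; not first-order decay"
        )
    if np.allclose(r, 100.0, atol=1e-9):
        return 0.0, 1.0
    # log-linear slope through the 100% anchor as the starting value
    good = (r > 0) & (d > 0)
    k0 = 1e-3
    if good.any():
        k0 = max(
            np.sum(-d[good] * np.log(r[good] / 100.0)) / np.sum(d[good] ** 2),
            1e-6,
        )

    sol = least_squares(
        lambda p: 100.0 * np.exp(-p[0] * d) - r, [k0],
        bounds=([0.0], [np.inf]),
    )
    k = float(sol.x[0])
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return k, r2


def half_time(k: float) -> float:
    """Half-time ln(2)/k in seconds of a first-order process."""
    if not (k > 0 and math.isfinite(k)):
        raise ValueError("half_time requires k > 0")
    return math.log(2.0) / k


def dose_dependence_of_decay(datasets) -> HillFit:
    """Chain decay fits across agonist doses into an inhibitory Hill fit.

    Each dataset gives one (agonist dose, k) point; the resulting
    dependence is fitted with the inhibition-form Hill law, yielding the
    maximal desensitization constant, its IC50 and Hill coefficient.
    """
    datasets = list(datasets)
    if len(datasets) < 3:
        raise ValueError("need decay datasets at >= 3 agonist doses")
    doses = np.array([ds.agonist_conc for ds in datasets], dtype=float)
    ks = np.array([fit_decay_constant(ds)[0] for ds in datasets])
    dr = DoseResponseDataset(doses=doses, responses=ks, response_kind="k")
    return fit_hill(dr, mode="inhibition")
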