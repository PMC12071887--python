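"""Rate constants and their Hill-type concentration dependence.

The phenotype-transition model couples each concentration-dependent rate
constant to the dose of an agonist or inhibitor through a Hill law:

* activation:  ``k(A) = k_max * A**h / (EC50**h + A**h)`` — zero without
  agonist, saturating at ``k_max``;
* inhibition:  ``k(I) = k_max * IC50**h / (IC50**h + I**h)`` — equal to
  ``k_max`` without inhibitor, suppressed at high inhibitor dose.

All concentrations are handled internally in nanomolar; time is in seconds,
so every first-order constant is in 1/s. The platelet–platelet aggregation
step is second order in the integrin-active fraction and its constant
carries units of 1/(% * s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "HillParams",
    "RateConstantSet",
    "hill_activation",
    "hill_inhibition",
    "default_parameter_table",
    "INHIBITOR_ONSET_RATE",
    "CALCIUM_ONSET_RATE",
    "DISAGG_WINDOW_S",
    "AGGREGATION_RATE_SCALE",
    "DEFAULT_FITTED",
]

#: First-order onset rate (1/s) of the cyclic-nucleotide (PKA) inhibitory
#: effect on the shape-change and integrin-activation reactions, and the
#: rest -> inhibited transition at saturating inhibitor.
INHIBITOR_ONSET_RATE = 0.31

#: Slower onset rate (1/s) of inhibition of the calcium-linked response.
CALCIUM_ONSET_RATE = 0.085

#: Disaggregation is only inducible within this window (s) after the
#: aggregation-triggering agonist addition; afterwards aggregates are stable.
DISAGG_WINDOW_S = 180.0

#: Second-order aggregation constant, per (% * s). Chosen so that at 100%
#: integrin-active platelets the pseudo-first-order aggregation rate equals
#: twice the maximal integrin-activation rate, keeping aggregation itself
#: never rate-limiting.
AGGREGATION_RATE_SCALE = 2.0 * 0.03 / 100.0

#: Default values (1/s) for the three constants that cannot be read off a
#: trace directly and are normally obtained by trajectory fitting:
#: ``k1r`` exhausted -> rest recovery, ``k4r`` inhibited -> rest recovery,
#: ``k7`` aggregated -> exhausted disaggregation (active only inside the
#: disaggregation window while an inhibitor is present).
DEFAULT_FITTED = {"k1r": 0.002, "k4r": 0.005, "k7": 0.02}


@dataclass(frozen=True)
class HillParams:
    """One rate constant's sigmoidal dependence on a stimulus concentration.

    Parameters
    ----------
    k_max : float
        Maximal rate constant (1/s), reached at saturating agonist
        (activation mode) or zero inhibitor (inhibition mode).
    half_conc : float
        EC50 or IC50 in ``unit`` (nM unless stated otherwise).
    h : float
        Hill coefficient (dimensionless steepness).
    mode : {"activation", "inhibition"}
    unit : str
        Concentration unit of ``half_conc``; informational.
    """

    k_max: float
    half_conc: float
    h: float
    mode: str = "activation"
    unit: str = "nM"

    def __post_init__(self):
        if self.mode not in ("activation", "inhibition"):
            raise ValueError(f"unknown Hill mode {self.mode!r}")
        if not (self.k_max > 0 and self.half_conc > 0 and self.h > 0):
            raise ValueError("HillParams requires k_max, half_conc, h > 0")
        for v in (self.k_max, self.half_conc, self.h):
            if not math.isfinite(v):
                raise ValueError("non-finite Hill parameter")

    def occupancy(self, conc):
        """Fractional saturation ``conc**h / (half**h + conc**h)`` in [0, 1)."""
        conc = _check_conc(conc)
        with np.errstate(over="ignore"):
            r = (conc / self.half_conc) ** self.h
        return r / (1.0 + r)

    def rate(self, conc):
        """Rate constant at ``conc`` according to the mode."""
        occ = self.occupancy(conc)
        if self.mode == "activation":
            return self.k_max * occ
        return self.k_max * (1.0 - occ)


def hill_activation(conc, p: HillParams):
    """Activating Hill law ``k_max * A**h / (EC50**h + A**h)``.

    Monotone non-decreasing in ``conc``, 0 at zero dose, bounded by
    ``p.k_max``.
    """
    if p.mode != "activation":
        raise ValueError("hill_activation requires activation-mode parameters")
    return p.rate(conc)


def hill_inhibition(conc, p: HillParams):
    """Inhibitory Hill law ``k_max * IC50**h / (IC50**h + I**h)``.

    Monotone non-increasing in ``conc``; equals ``p.k_max`` at zero dose.
    """
    if p.mode != "inhibition":
        raise ValueError("hill_inhibition requires inhibition-mode parameters")
    return p.rate(conc)


def _check_conc(conc):
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0) or not np.all(np.isfinite(conc)):
        raise ValueError("concentration must be finite and >= 0")
    return conc if conc.ndim else float(conc)


@dataclass(frozen=True)
class RateConstantSet:
    """The nine transition constants of the six-phenotype scheme.

    ``k1`` rest->sphered (shape change), ``k2`` sphered->integrin-active,
    ``k3`` integrin-active->aggregated (second order, 1/(%*s)),
    ``k4`` rest->inhibited, ``k4r`` inhibited->rest,
    ``k5`` sphered->exhausted, ``k6`` integrin-active->exhausted,
    ``k7`` aggregated->exhausted (disaggregation), ``k1r`` exhausted->rest.
    All first order in 1/s except ``k3``.
    """

    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    k4r: float = 0.0
    k5: float = 0.0
    k6: float = 0.0
    k7: float = 0.0
    k1r: float = 0.0

    def __post_init__(self):
        for name in ("k1", "k2", "k3", "k4", "k4r", "k5", "k6", "k7", "k1r"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"rate constant {name} must be finite and >= 0")

    def replace(self, **kw) -> "RateConstantSet":
        return replace(self, **kw)

    def as_dict(self) -> dict:
        return {
            n: getattr(self, n)
            for n in ("k1", "k2", "k3", "k4", "k4r", "k5", "k6", "k7", "k1r")
        }


def default_parameter_table() -> dict:
    """Measured Hill laws for the concentration-dependent constants.

    Keys are ``"<constant>:<species>"``. Activation laws drive the forward
    constants k1 (shape change) and k2 (integrin activation); inhibition
    laws give the agonist-dose protection of the desensitization constants
    k5 and k6; ``k1_inhibition``/``k2_inhibition`` are the non-competitive
    suppression of the forward reactions by the cAMP-pathway agonist
    iloprost, and ``k4`` its drive of the rest -> inhibited transition.
    """
    return {
        # shape change (rest -> sphered)
        "k1:ADP": HillParams(0.19, 46.8, 1.27),
        "k1:TRAP": HillParams(0.19, 204.0, 1.24),
        # integrin activation (sphered -> integrin-active)
        "k2:ADP": HillParams(0.03, 589.8, 3.92),
        "k2:TRAP": HillParams(0.03, 2309.0, 6.68),
        # desensitization from shape change; high agonist protects
        "k5:ADP": HillParams(0.0028, 1840.0, 1.4, mode="inhibition"),
        # desensitization from the integrin-active state
        "k6:ADP": HillParams(0.055, 990.0, 1.9, mode="inhibition"),
        # non-competitive inhibition of the forward reactions by iloprost
        "k1_inhibition:iloprost": HillParams(1.0, 0.048, 1.52, mode="inhibition"),
        "k2_inhibition:iloprost": HillParams(1.0, 0.21, 2.14, mode="inhibition"),
        # rest -> inhibited drive: onset rate times Hill occupancy in iloprost
        "k4:iloprost": HillParams(INHIBITOR_ONSET_RATE, 0.21, 2.14),
    }


def require_entries(table: dict, keys) -> None:
    missing = [k for k in keys if k not in table]
    if missing:
        raise ConfigurationError(f"parameter table missing entries: {missing}")
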