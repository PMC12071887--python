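"""Six-phenotype kinetic model of platelet activation, inhibition,
aggregation and exhaustion.

State variables are population fractions (percent of all platelets):

* ``n_rest`` resting discoid platelets,
* ``n_sph`` sphered (shape-changed) platelets,
* ``n_gp`` platelets with activated aIIbb3 integrins,
* ``n_agg`` aggregated platelets (fibrinogen-bridged),
* ``n_exh`` exhausted (refractory) platelets,
* ``n_inh`` inhibited platelets (cAMP/cGMP pathway engaged).

The mass balance

.. code-block:: text

    d n_rest/dt = k4r*n_inh + k1r*n_exh - k4*n_rest - k1*n_rest
    d n_sph /dt = k1*n_rest - k2*n_sph - k5*n_sph
    d n_gp  /dt = k2*n_sph - k3*n_gp**2 - k6*n_gp
    d n_agg /dt = k3*n_gp**2 - k7*n_agg
    d n_exh /dt = k5*n_sph + k6*n_gp + k7*n_agg - k1r*n_exh
    d n_inh /dt = k4*n_rest - k4r*n_inh

conserves the total (the right-hand sides sum to zero); every reaction is
first order except aggregation, which is second order in the
integrin-active fraction. Rate constants are assembled from Hill laws in
the current agonist/inhibitor concentrations; the inhibitory (PKA) effect
is not instantaneous but relaxes first order toward its Hill occupancy
with the measured onset rate, so pre-incubation protocols differ from
co-administration. Stirring gates the aggregation step (no collisions, no
aggregation); disaggregation (k7) is possible only while an inhibitor is
present and within a fixed window after the triggering agonist addition.

Integration is piecewise between protocol events with hard solver
restarts, using a stiff-capable adaptive method (LSODA) and dense output
sampled on a uniform grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegrationError, ProtocolError
from .params import (
    DEFAULT_FITTED,
    DISAGG_WINDOW_S,
    INHIBITOR_ONSET_RATE,
    RateConstantSet,
    default_parameter_table,
    hill_inhibition,
    require_entries,
)
from .protocol import StimulusProtocol
from .trace import Trace

STATE_NAMES = ("n_rest", "n_sph", "n_gp", "n_agg", "n_exh", "n_inh")

__all__ = [
    "STATE_NAMES",
    "PhenotypeState",
    "PhenotypeTrajectory",
    "assemble_rate_constants",
    "simulate",
    "observables",
    "DEFAULT_OBSERVABLE_MAP",
]


@dataclass(frozen=True)
class PhenotypeState:
    """Phenotype fractions (percent) at one time point."""

    t: float
    n_rest: float
    n_sph: float
    n_gp: float
    n_agg: float
    n_exh: float
    n_inh: float

    def as_array(self):
        return np.array([getattr(self, n) for n in STATE_NAMES])

    @property
    def total(self):
        return float(self.as_array().sum())


def _combined_occupancy(table, prefix, concs):
    """Saturating combination of per-species Hill occupancies.

    Independent-receptor combination ``1 - prod(1 - occ_s)`` with the
    largest per-species k_max as the shared ceiling; reduces to the plain
    Hill law for a single species.
    """
    kmax = 0.0
    miss = 1.0
    found = False
    for sp, c in concs.items():
        p = table.get(f"{prefix}:{sp}")
        if p is None or c <= 0:
            continue
        found = True
        kmax = max(kmax, p.k_max)
        miss *= 1.0 - p.occupancy(c)
    if not found:
        return 0.0
    return kmax * (1.0 - miss)


def _desensitization_rate(table, prefix, concs):
    """Agonist-dose-protected desensitization constant.

    Zero when no agonist is present (the source states are unpopulated
    anyway); with agonist on board, the inhibition-form Hill law in the
    agonist dose — high doses protect against exhaustion. With several
    agonists the strongest protection (smallest rate) wins.
    """
    rates = []
    for sp, c in concs.items():
        p = table.get(f"{prefix}:{sp}")
        if p is None or c <= 0:
            continue
        rates.append(hill_inhibition(c, p))
    return min(rates) if rates else 0.0


def _aggregation_constant(table) -> float:
    """Second-order aggregation constant, 1/(% * s).

    Twice the maximal integrin-activation rate divided by 100%, so that at
    full integrin occupancy the pseudo-first-order aggregation rate is
    2 * k2_max and the collision step is never rate-limiting. Zero if the
    table carries no integrin-activation law.
    """
    kmax = [p.k_max for k, p in table.items() if k.startswith("k2:")]
    return 2.0 * max(kmax) / 100.0 if kmax else 0.0


def assemble_rate_constants(
    agonist_concs,
    inhibitor_concs=None,
    inhibitor_exposure=1.0,
    param_table=None,
    stirring=True,
    fitted=None,
    disagg_active=False,
) -> RateConstantSet:
    """Build the full rate-constant set for one stimulus condition.

    Parameters
    ----------
    agonist_concs : mapping species -> concentration (nM)
    inhibitor_concs : mapping species -> concentration (nM)
    inhibitor_exposure : float or mapping
        Per-species inhibitory effect level in [0, 1]; 1 means fully
        equilibrated (default). The non-competitive factor is evaluated at
        ``exposure * I`` instead of ``I``, so freshly added inhibitor has
        no effect until its intracellular action builds up.
    param_table : mapping name -> HillParams, default the measured table.
    stirring : bool
        Stirring off sets the aggregation constant k3 to zero (no
        platelet collisions) while desensitization continues.
    fitted : mapping, optional
        Overrides for the trajectory-fitted constants ``k1r``, ``k4r``,
        ``k7``; defaults from :data:`plateletkin.params.DEFAULT_FITTED`.
    disagg_active : bool
        Whether the disaggregation window is currently open (inhibitor
        present and within the window after agonist addition).
    """
    table = default_parameter_table() if param_table is None else param_table
    inhibitor_concs = inhibitor_concs or {}
    # a dosed agonist with no activation law at all is a configuration error
    require_entries(
        table,
        [
            f"k1:{sp}"
            for sp, c in agonist_concs.items()
            if c > 0 and f"k1:{sp}" not in table and f"k2:{sp}" not in table
        ],
    )
    fit = dict(DEFAULT_FITTED)
    fit.update(fitted or {})

    k1 = _combined_occupancy(table, "k1", agonist_concs)
    k2 = _combined_occupancy(table, "k2", agonist_concs)
    # non-competitive suppression of the forward reactions
    f1 = f2 = 1.0
    for sp, c in inhibitor_concs.items():
        if c <= 0:
            continue
        e = (
            inhibitor_exposure.get(sp, 1.0)
            if hasattr(inhibitor_exposure, "get")
            else float(inhibitor_exposure)
        )
        p1 = table.get(f"k1_inhibition:{sp}")
        p2 = table.get(f"k2_inhibition:{sp}")
        if p1 is not None:
            f1 *= 1.0 - p1.occupancy(e * c)
        if p2 is not None:
            f2 *= 1.0 - p2.occupancy(e * c)
    k1 *= f1
    k2 *= f2

    k3 = _aggregation_constant(table) if stirring else 0.0
    k4 = _combined_occupancy(table, "k4", inhibitor_concs)
    k5 = _desensitization_rate(table, "k5", agonist_concs)
    k6 = _desensitization_rate(table, "k6", agonist_concs)
    k7 = fit["k7"] if (disagg_active and any(
        c > 0 for c in inhibitor_concs.values())) else 0.0
    return RateConstantSet(
        k1=k1, k2=k2, k3=k3, k4=k4, k4r=fit["k4r"],
        k5=k5, k6=k6, k7=k7, k1r=fit["k1r"],
    )


@dataclass
class PhenotypeTrajectory:
    """Sampled solution of the phenotype ODE system.

    ``states`` is an (N, 6) array of fractions in the order of
    :data:`STATE_NAMES`; ``exposure`` the inhibitory effect levels
    (N, n_channels) tracked alongside.
    """

    t: np.ndarray
    states: np.ndarray
    protocol: StimulusProtocol
    param_table: dict
    fitted: dict
    exposure: np.ndarray | None = None

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(np.clip(self.states, 0.0, None), columns=STATE_NAMES)
        df.insert(0, "t", self.t)
        return df

    def state_at(self, i) -> PhenotypeState:
        return PhenotypeState(float(self.t[i]), *np.clip(self.states[i], 0, None))

    def conservation_error(self) -> float:
        """Max relative deviation of the fraction total from 100%."""
        return float(np.max(np.abs(self.states.sum(axis=1) - 100.0)) / 100.0)

    def peak(self, name="n_agg") -> float:
        return float(self.states[:, STATE_NAMES.index(name)].max())

    def final(self, name="n_agg") -> float:
        return float(self.states[-1, STATE_NAMES.index(name)])


def _segment_breakpoints(protocol):
    """Event times plus disaggregation-window closures as solver restarts."""
    pts = set()
    for t0, t1, st in protocol.segments():
        pts.update((t0, t1))
        if (
            st["t_last_agonist"] is not None
            and any(c > 0 for c in st["inhibitors"].values())
        ):
            w = st["t_last_agonist"] + DISAGG_WINDOW_S
            if t0 < w < t1:
                pts.add(w)
    return sorted(pts)


def simulate(
    protocol: StimulusProtocol,
    param_table=None,
    fitted=None,
    y0=None,
    sample_dt=None,
    t_eval=None,
    rtol=1e-8,
    atol=1e-10,
    method="LSODA",
) -> PhenotypeTrajectory:
    """Integrate the phenotype system under a stimulation protocol.

    Starts from 100% resting platelets unless ``y0`` (percent, length 6)
    is given. Events restart the integrator with updated stimulus levels;
    the inhibitory effect level of each (reaction, species) pair relaxes
    first order toward its Hill occupancy with the measured onset rate.

    Returns a :class:`PhenotypeTrajectory` sampled on ``t_eval`` or a
    uniform ``sample_dt`` grid (default the protocol's ``sample_dt``).
    """
    table = default_parameter_table() if param_table is None else param_table
    fit = dict(DEFAULT_FITTED)
    fit.update(fitted or {})
    protocol.validate()

    # inhibitor species with a non-competitive law in the table get an
    # exposure state per affected reaction (shape change, integrin activation)
    inh_species = sorted(
        {
            k.split(":", 1)[1]
            for k in table
            if k.startswith(("k1_inhibition:", "k2_inhibition:"))
        }
    )
    n_e = 2 * len(inh_species)

    if t_eval is None:
        dt = protocol.sample_dt if sample_dt is None else sample_dt
        n = int(round(protocol.t_end / dt))
        t_eval = np.linspace(0.0, n * dt, n + 1)
        t_eval = t_eval[t_eval <= protocol.t_end + 1e-9]
    else:
        t_eval = np.asarray(t_eval, dtype=float)
        if t_eval[0] < 0 or t_eval[-1] > protocol.t_end + 1e-9:
            raise ProtocolError("t_eval outside protocol horizon")

    y = np.zeros(6 + n_e)
    y[0] = 100.0
    if y0 is not None:
        y0 = np.asarray(y0, dtype=float)
        if y0.shape != (6,):
            raise ValueError("y0 must have 6 phenotype fractions")
        y[:6] = y0

    seg_states = list(protocol.segments())
    breaks = _segment_breakpoints(protocol)
    out_t = []
    out_y = []
    if t_eval[0] == 0.0:
        out_t.append(0.0)
        out_y.append(y.copy())

    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        if t1 - t0 <= 0:
            continue
        st = next(s for (a, b, s) in seg_states if a <= t0 < b)
        ag = st["agonists"]
        inh = st["inhibitors"]
        window_open = (
            st["t_last_agonist"] is not None
            and any(c > 0 for c in inh.values())
            and t0 < st["t_last_agonist"] + DISAGG_WINDOW_S - 1e-9
        )
        base = assemble_rate_constants(
            ag, inh, 1.0, table, st["stirring"], fit, disagg_active=window_open
        )
        # static pieces; only the exposure-dependent factors vary in time
        k1b = _combined_occupancy(table, "k1", ag)
        k2b = _combined_occupancy(table, "k2", ag)
        # per (species, reaction): (conc, HillParams, onset, occupancy target)
        fac = []
        for si, sp in enumerate(inh_species):
            c = inh.get(sp, 0.0)
            for ri, pref in enumerate(("k1_inhibition", "k2_inhibition")):
                p = table.get(f"{pref}:{sp}")
                occ = p.occupancy(c) if (p is not None and c > 0) else 0.0
                fac.append((6 + 2 * si + ri, ri, c, p, occ))
        k3, k4, k4r, k5, k6, k7, k1r = (
            base.k3, base.k4, base.k4r, base.k5, base.k6, base.k7, base.k1r
        )

        def rhs(t, yv):
            rest, sph, gp, agg, exh, inhf = yv[:6]
            f1 = f2 = 1.0
            de = np.zeros(n_e)
            for (ix, ri, c, p, occ) in fac:
                e = yv[ix]
                de[ix - 6] = INHIBITOR_ONSET_RATE * (occ - e)
                if p is not None and c > 0:
                    f = 1.0 - p.occupancy(max(e, 0.0) * c)
                    if ri == 0:
                        f1 *= f
                    else:
                        f2 *= f
            k1 = k1b * f1
            k2 = k2b * f2
            agg2 = k3 * gp * gp
            d = np.empty(6 + n_e)
            d[0] = k4r * inhf + k1r * exh - k4 * rest - k1 * rest
            d[1] = k1 * rest - k2 * sph - k5 * sph
            d[2] = k2 * sph - agg2 - k6 * gp
            d[3] = agg2 - k7 * agg
            d[4] = k5 * sph + k6 * gp + k7 * agg - k1r * exh
            d[5] = k4 * rest - k4r * inhf
            d[6:] = de
            return d

        mask = (t_eval > t0 + 1e-12) & (t_eval <= t1 + 1e-12)
        pts = t_eval[mask]
        sol = solve_ivp(
            rhs, (t0, t1), y, method=method, rtol=rtol, atol=atol,
            dense_output=True,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed in segment [{t0}, {t1}]: {sol.message}",
                t=float(sol.t[-1]),
                state=sol.y[:6, -1].copy(),
            )
        if len(pts):
            vals = sol.sol(pts)
            out_t.extend(pts.tolist())
            out_y.extend(vals.T)
        y = sol.y[:, -1].copy()

    t_arr = np.array(out_t)
    y_arr = np.array(out_y)
    return PhenotypeTrajectory(
        t=t_arr,
        states=y_arr[:, :6],
        protocol=protocol,
        param_table=table,
        fitted=fit,
        exposure=y_arr[:, 6:] if n_e else None,
    )


#: Default affine map from phenotype fractions to instrument-like channels.
#: Low-angle scatter (1 degree) tracks aggregates; 12-degree scatter tracks
#: shape-changed and integrin-active single cells; the fluorescence channel
#: is a crude activation proxy.
DEFAULT_OBSERVABLE_MAP = {
    "LSI1": {"baseline": 0.0, "gain": 1.0, "weights": {"n_agg": 1.0}},
    "LSI12": {"baseline": 0.0, "gain": 1.0,
              "weights": {"n_sph": 1.0, "n_gp": 1.0}},
    "FL527": {"baseline": 0.0, "gain": 1.0,
              "weights": {"n_sph": 1.0, "n_gp": 1.0, "n_agg": 1.0}},
}


def observables(traj: PhenotypeTrajectory, map_spec=None) -> Trace:
    """Project a phenotype trajectory onto instrument-like channels.

    Each channel is ``baseline + gain * sum_j w_j * n_j`` — deterministic
    given the map. The generating protocol's event times are copied into
    the trace annotations.
    """
    spec = DEFAULT_OBSERVABLE_MAP if map_spec is None else map_spec
    channels = {}
    for name, m in spec.items():
        w = np.zeros(6)
        for state, wt in m.get("weights", {}).items():
            w[STATE_NAMES.index(state)] = wt
        channels[name] = (
            m.get("baseline", 0.0)
            + m.get("gain", 1.0) * np.clip(traj.states, 0, None) @ w
        )
    ann = {"events": [e.__dict__ for e in traj.protocol.events]}
    return Trace(t=traj.t.copy(), channels=channels, annotations=ann)
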