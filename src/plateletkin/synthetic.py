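"""Synthetic aggregometry data with the statistical structure the
analysis assumes.

Traces are forward simulations of the phenotype model projected onto
instrument channels, with seeded Gaussian noise (additive, optionally
multiplicative, optional linear drift). The default noise is additive
with SD equal to 1% of the full channel scale — conservative for a
laser-diffraction instrument — so estimator checks against these
fixtures probe the code, not the noise. Every noisy fixture can ship its
noiseless twin.

Protocol suites reproduce the standard experiment designs: agonist dose
series, delayed restimulation (shape-change desensitization), stir-pause
(integrin desensitization), inhibitor pre-incubation, and delayed
inhibitor addition (disaggregation window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .doseresponse import DoseResponseDataset
from .model import observables, simulate
from .params import HillParams
from .protocol import StimulusProtocol

__all__ = [
    "NoiseModel",
    "generate_trace",
    "generate_dose_response_dataset",
    "generate_protocol_suite",
]


@dataclass(frozen=True)
class NoiseModel:
    """Seeded instrument-noise description.

    ``additive_sd`` in AU, ``multiplicative_sd`` as a fraction of the
    signal, ``drift`` in AU/s. Default: 1 AU additive on channels scaled
    0-100, no multiplicative term, no drift.
    """

    additive_sd: float = 1.0
    multiplicative_sd: float = 0.0
    drift: float = 0.0
    seed: int | None = 0

    def __post_init__(self):
        if self.additive_sd < 0 or self.multiplicative_sd < 0:
            raise ValueError("noise spreads must be >= 0")


def generate_trace(
    protocol: StimulusProtocol,
    param_table=None,
    map_spec=None,
    noise: NoiseModel | None = None,
    fitted=None,
    sample_dt=None,
    return_truth=False,
):
    """Simulate a protocol and corrupt the channels with seeded noise.

    Deterministic given ``noise.seed``. With ``return_truth=True`` the
    paired noiseless trace is returned alongside.
    """
    traj = simulate(protocol, param_table=param_table, fitted=fitted,
                    sample_dt=sample_dt)
    clean = observables(traj, map_spec)
    if noise is None:
        noise = NoiseModel(additive_sd=0.0)
    rng = np.random.default_rng(noise.seed)
    noisy_channels = {}
    for name in sorted(clean.channels):
        y = clean.channels[name]
        out = y.copy()
        if noise.additive_sd > 0:
            out = out + rng.normal(0.0, noise.additive_sd, y.shape)
        if noise.multiplicative_sd > 0:
            out = out + y * rng.normal(0.0, noise.multiplicative_sd, y.shape)
        if noise.drift:
            out = out + noise.drift * clean.t
        noisy_channels[name] = out
    noisy = clean.__class__(
        t=clean.t.copy(), channels=noisy_channels,
        annotations=dict(clean.annotations),
    )
    return (noisy, clean) if return_truth else noisy


def generate_dose_response_dataset(
    params: HillParams, doses, noise_sd: float = 0.0, seed=0,
    response_kind="k",
) -> DoseResponseDataset:
    """Evaluate a Hill law on a dose grid with seeded multiplicative noise
    (``noise_sd`` as a fraction of each response)."""
    doses = np.asarray(doses, dtype=float)
    resp = np.asarray(params.rate(doses), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp * (1.0 + rng.normal(0.0, noise_sd, resp.shape))
    return DoseResponseDataset(
        doses=doses, responses=resp, response_kind=response_kind,
        unit=params.unit,
    )


# experiment-design grids (doses in nM, times in s)
ADP_DOSE_SERIES = (100.0, 500.0, 2000.0, 10000.0)
ILO_DOSE_SERIES = (0.025, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0)
RESTIM_DOSES = (1000.0, 2000.0, 5000.0)
RESTIM_DELAYS = (60.0, 120.0, 180.0, 300.0, 600.0)
STIR_PAUSES = (30.0, 60.0, 120.0, 300.0)
PRE_INCUBATION_OFFSETS = (180.0, 120.0, 60.0, 30.0, 10.0, 5.0, 2.0)
DISAGG_OFFSETS = (5.0, 30.0, 120.0)


def generate_protocol_suite(kind: str, **kw) -> list:
    """Emit the named family of stimulation protocols.

    Kinds: ``dose_series`` (ADP titration, optionally iloprost
    co-administration titration via ``species="iloprost"``),
    ``shape_change_delay``, ``stir_pause``, ``inhibition_pre``,
    ``disaggregation_post``.
    """
    t0 = kw.get("t_start", 5.0)
    if kind == "dose_series":
        species = kw.get("species", "ADP")
        if species == "ADP":
            doses = kw.get("doses", ADP_DOSE_SERIES)
            t_end = kw.get("t_end", 300.0)
            return [
                StimulusProtocol(
                    events=[dict(t=t0, kind="add_agonist", species="ADP",
                                 conc=c)],
                    t_end=t_end, name=f"ADP-{c:g}nM",
                )
                for c in doses
            ]
        doses = kw.get("doses", ILO_DOSE_SERIES)
        adp = kw.get("adp_conc", 2000.0)
        t_end = kw.get("t_end", 300.0)
        return [
            StimulusProtocol(
                events=[
                    dict(t=t0, kind="add_inhibitor", species=species, conc=c),
                    dict(t=t0, kind="add_agonist", species="ADP", conc=adp),
                ],
                t_end=t_end, name=f"{species}-{c:g}nM+ADP-{adp:g}nM",
            )
            for c in doses
        ]
    if kind == "shape_change_delay":
        high = kw.get("restim_conc", 5000.0)
        delays = kw.get("delays", RESTIM_DELAYS)
        return [
            StimulusProtocol(
                events=[
                    dict(t=t0, kind="add_agonist", species="ADP", conc=100.0),
                    dict(t=t0 + dly, kind="add_agonist", species="ADP",
                         conc=high),
                ],
                t_end=t0 + dly + kw.get("tail", 180.0),
                name=f"restim-{high:g}nM-delay-{dly:g}s",
            )
            for dly in delays
        ]
    if kind == "stir_pause":
        conc = kw.get("conc", 1000.0)
        pauses = kw.get("pauses", STIR_PAUSES)
        t_off = kw.get("t_off", t0 + 2.0)
        return [
            StimulusProtocol(
                events=[
                    dict(t=t0, kind="add_agonist", species="ADP", conc=conc),
                    dict(t=t_off, kind="stir_off"),
                    dict(t=t_off + p, kind="stir_on"),
                ],
                t_end=t_off + p + kw.get("tail", 120.0),
                name=f"stir-pause-{p:g}s-ADP-{conc:g}nM",
            )
            for p in pauses
        ]
    if kind == "inhibition_pre":
        offsets = kw.get("offsets", PRE_INCUBATION_OFFSETS)
        adp = kw.get("adp_conc", 5000.0)
        ilo = kw.get("ilo_conc", 5.0)
        return [
            StimulusProtocol(
                events=[
                    dict(t=t0, kind="add_inhibitor", species="iloprost",
                         conc=ilo),
                    dict(t=t0 + off, kind="add_agonist", species="ADP",
                         conc=adp),
                ],
                t_end=t0 + off + kw.get("tail", 180.0),
                name=f"ilo-pre-{off:g}s",
            )
            for off in offsets
        ]
    if kind == "disaggregation_post":
        offsets = kw.get("offsets", DISAGG_OFFSETS)
        adp = kw.get("adp_conc", 5000.0)
        ilo = kw.get("ilo_conc", 5.0)
        return [
            StimulusProtocol(
                events=[
                    dict(t=t0, kind="add_agonist", species="ADP", conc=adp),
                    dict(t=t0 + off, kind="add_inhibitor", species="iloprost",
                         conc=ilo),
                ],
                t_end=t0 + kw.get("t_end_after", 400.0),
                name=f"ilo-post-{off:g}s",
            )
            for off in offsets
        ]
    raise ValueError(f"unknown protocol suite kind {kind!r}")


def hidden_constant_suite(sample_dt: float = 0.5) -> list:
    """Three-protocol suite designed to identify the hidden constants.

    A low-ADP run (shape change then exhaustion) pins the exhausted->rest
    recovery rate; a high-ADP run anchors the activation chain; a
    high-ADP run with iloprost added shortly after activation at a
    partially suppressing dose both opens the disaggregation window
    (pinning the disaggregation rate) and captures most remaining resting
    platelets into the inhibited pool whose slow, still-observable
    release pins the inhibited->rest rate. A fully suppressing inhibitor
    dose would mask that release; a long delay would leave the inhibited
    pool unpopulated.
    """
    return [
        StimulusProtocol(
            events=[dict(t=5.0, kind="add_agonist", species="ADP", conc=100.0)],
            t_end=600.0, sample_dt=sample_dt, name="low-ADP",
        ),
        StimulusProtocol(
            events=[dict(t=5.0, kind="add_agonist", species="ADP",
                         conc=5000.0)],
            t_end=600.0, sample_dt=sample_dt, name="high-ADP",
        ),
        StimulusProtocol(
            events=[
                dict(t=5.0, kind="add_agonist", species="ADP", conc=5000.0),
                dict(t=8.0, kind="add_inhibitor", species="iloprost",
                     conc=0.2),
            ],
            t_end=600.0, sample_dt=sample_dt, name="high-ADP+iloprost",
        ),
    ]
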