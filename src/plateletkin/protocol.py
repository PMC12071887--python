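"""Scripted stimulation protocols: timed agonist/inhibitor additions and
stirring control for cuvette-style aggregometry runs.

Concentrations are cumulative (each addition adds to the running level of
that species; dilution and degradation are neglected over the ~10 min
horizons modeled). Stirring defaults to on at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ProtocolError

EVENT_KINDS = ("add_agonist", "add_inhibitor", "stir_on", "stir_off")

#: Species treated as platelet agonists by default.
AGONISTS = ("ADP", "TRAP")
#: Species treated as inhibitors (cyclic-nucleotide pathway activators).
INHIBITORS = ("iloprost", "SNP")


@dataclass(frozen=True)
class ProtocolEvent:
    """One timed event: addition of a species or a stirring switch."""

    t: float
    kind: str
    species: str = ""
    conc: float = 0.0  # nM; ignored for stirring events


@dataclass
class StimulusProtocol:
    """Ordered timed events plus the simulation horizon ``t_end`` (s)."""

    events: list = field(default_factory=list)
    t_end: float = 300.0
    sample_dt: float = 0.1
    name: str = ""

    def __post_init__(self):
        self.events = [
            e if isinstance(e, ProtocolEvent) else ProtocolEvent(**e)
            for e in self.events
        ]
        self.validate()

    def validate(self) -> None:
        last = -float("inf")
        for e in self.events:
            if e.kind not in EVENT_KINDS:
                raise ProtocolError(f"unknown event kind {e.kind!r}")
            if e.t < last:
                raise ProtocolError("event times must be non-decreasing")
            if not (0.0 <= e.t <= self.t_end):
                raise ProtocolError(
                    f"event at t={e.t} outside [0, t_end={self.t_end}]"
                )
            if e.conc < 0:
                raise ProtocolError("event concentration must be >= 0")
            last = e.t
        if self.t_end <= 0:
            raise ProtocolError("t_end must be positive")

    def add(self, t, kind, species="", conc=0.0) -> "StimulusProtocol":
        self.events.append(ProtocolEvent(t, kind, species, conc))
        self.events.sort(key=lambda e: e.t)
        self.validate()
        return self

    def event_times(self):
        return sorted({e.t for e in self.events})

    def segments(self):
        """Yield ``(t0, t1, state)`` pieces with constant stimulus levels.

        ``state`` is a dict with keys ``agonists`` (species -> nM),
        ``inhibitors`` (species -> nM), ``stirring`` (bool),
        ``t_last_agonist`` and ``t_last_inhibitor`` (None until the first
        addition with positive dose).
        """
        agonists: dict = {}
        inhibitors: dict = {}
        stirring = True
        t_last_ag = None
        t_last_inh = None
        bounds = [t for t in self.event_times() if t < self.t_end]
        bounds = [0.0] + [t for t in bounds if t > 0.0] + [self.t_end]
        idx = 0
        events = sorted(self.events, key=lambda e: e.t)
        for j in range(len(bounds) - 1):
            t0, t1 = bounds[j], bounds[j + 1]
            while idx < len(events) and events[idx].t <= t0:
                e = events[idx]
                idx += 1
                if e.kind == "add_agonist":
                    if e.conc > 0:
                        agonists[e.species] = agonists.get(e.species, 0.0) + e.conc
                        t_last_ag = e.t
                elif e.kind == "add_inhibitor":
                    if e.conc > 0:
                        inhibitors[e.species] = (
                            inhibitors.get(e.species, 0.0) + e.conc
                        )
                        t_last_inh = e.t
                elif e.kind == "stir_on":
                    stirring = True
                elif e.kind == "stir_off":
                    stirring = False
            yield t0, t1, {
                "agonists": dict(agonists),
                "inhibitors": dict(inhibitors),
                "stirring": stirring,
                "t_last_agonist": t_last_ag,
                "t_last_inhibitor": t_last_inh,
            }

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "t_end": self.t_end,
            "sample_dt": self.sample_dt,
            "events": [
                {"t": e.t, "kind": e.kind, "species": e.species,
                 "conc": e.conc, "unit": "nM"}
                for e in self.events
            ],
        }
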