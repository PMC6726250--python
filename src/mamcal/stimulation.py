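"""IP3 stimulation protocols: constant target, square pulses, staircases.

The IP3 concentration relaxes toward a piecewise-constant target ``P_s(t)``
at rate tau_p; on top of that, square pulses add a constant production rate
M (µM/s) on the open interval (t0, t0 + delta), per the Heaviside
convention H(x) = 0 for x <= 0.  All protocol breakpoints are exposed so
the integrator can restart exactly at them — the square pulse is never
smoothed over.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

__all__ = ["Pulse", "StimulusProtocol", "fig13_staircase"]


@dataclass(frozen=True, slots=True)
class Pulse:
    """A square IP3 production pulse of rate ``M`` µM/s on (t0, t0+delta)."""

    M: float
    t0: float
    delta: float

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"pulse duration must be > 0, got {self.delta!r}")


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant IP3 target plus zero or more square pulses.

    ``segments`` is an ordered tuple of ``(t_start, t_end, P_s)`` covering
    the simulation span contiguously; the target is right-continuous at the
    breakpoints (a segment owns its left edge).
    """

    segments: tuple
    pulses: tuple = ()

    def __post_init__(self) -> None:
        segs = tuple((float(a), float(b), float(ps)) for a, b, ps in self.segments)
        pulses = tuple(
            pl if isinstance(pl, Pulse) else Pulse(*pl) for pl in self.pulses
        )
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "pulses", pulses)
        if not segs:
            raise ValueError("protocol needs at least one segment")
        for a, b, ps in segs:
            if b <= a:
                raise ValueError(f"segment ({a}, {b}) has non-positive length")
            if ps < 0:
                raise ValueError(f"P_s must be >= 0, got {ps!r}")
        for (_, b, _), (a2, _, _) in zip(segs, segs[1:]):
            if a2 != b:
                raise ValueError(
                    f"segments must tile the span contiguously; gap/overlap at {b} vs {a2}"
                )
        object.__setattr__(self, "_starts", tuple(a for a, _, _ in segs))

    # -- constructors ----------------------------------------------------

    @classmethod
    def constant(cls, Ps: float, t_end: float, t_start: float = 0.0,
                 pulses=()) -> "StimulusProtocol":
        """A single-segment protocol with a constant IP3 target."""
        return cls(segments=((t_start, t_end, Ps),), pulses=tuple(pulses))

    @classmethod
    def staircase(cls, times, levels, t_end: float) -> "StimulusProtocol":
        """Steps to ``levels[i]`` at ``times[i]``; ``times[0]`` opens the span."""
        if len(times) != len(levels):
            raise ValueError("times and levels must have equal length")
        edges = list(times) + [t_end]
        return cls(
            segments=tuple(
                (edges[i], edges[i + 1], levels[i]) for i in range(len(levels))
            )
        )

    # -- evaluation ------------------------------------------------------

    @property
    def span(self) -> tuple:
        return (self.segments[0][0], self.segments[-1][1])

    def ps_at(self, t: float) -> float:
        """Piecewise-constant target at time ``t`` (right-continuous)."""
        a0, b0 = self.span
        if not (a0 <= t <= b0):
            raise ValueError(f"t={t!r} outside the protocol span [{a0}, {b0}]")
        i = bisect_right(self._starts, t) - 1
        return self.segments[i][2]

    def pulse_at(self, t: float) -> float:
        """Summed pulse production rate (µM/s) at time ``t``.

        Each pulse contributes M on the open interval t0 < t < t0 + delta
        (zero at the edges, per the Heaviside convention).
        """
        return sum(
            pl.M for pl in self.pulses if pl.t0 < t < pl.t0 + pl.delta
        )

    def breakpoints(self) -> list:
        """Sorted unique times where the right-hand side is discontinuous."""
        pts = set()
        for a, b, _ in self.segments:
            pts.add(a)
            pts.add(b)
        for pl in self.pulses:
            pts.add(pl.t0)
            pts.add(pl.t0 + pl.delta)
        a0, b0 = self.span
        return sorted(t for t in pts if a0 <= t <= b0)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "segments": [list(s) for s in self.segments],
            "pulses": [[pl.M, pl.t0, pl.delta] for pl in self.pulses],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            segments=tuple(tuple(s) for s in d.get("segments", ())),
            pulses=tuple(Pulse(*pl) for pl in d.get("pulses", ())),
        )


def fig13_staircase(t_end: float = 4500.0) -> StimulusProtocol:
    """The cessation-scan staircase: P_s steps 0 -> 0.3 -> 0.6 -> 0.9 -> 1.2 µM
    at t = 500, 1500, 2500 and 3500 s."""
    return StimulusProtocol.staircase(
        times=(0.0, 500.0, 1500.0, 2500.0, 3500.0),
        levels=(0.0, 0.3, 0.6, 0.9, 1.2),
        t_end=t_end,
    )
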