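"""Ion permeation bookkeeping: crossing detection, current and conductance.

A permeation event is a complete traversal: an ion passes from beyond one
bounding plane of the pore cylinder to beyond the other while staying inside
the cylinder radius in between (the strictest convention — entries that
retreat do not count).  Events convert to a current by I = dq/dt and to a
conductance by C = I/U.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError
from .structure import Trajectory
from .units import ELEMENTARY_CHARGE_C

__all__ = [
    "CrossingEvent",
    "ConductanceResult",
    "detect_crossings",
    "compute_current",
    "compute_conductance",
]

_BELOW, _INSIDE, _ABOVE = -1, 0, 1


@dataclass(frozen=True)
class CrossingEvent:
    ion_id: int
    species: str
    charge_e: float
    entry_time_ps: float
    exit_time_ps: float
    direction: int  # +1 = toward +z (extracellular), -1 = toward -z

    def __post_init__(self):
        if self.exit_time_ps <= self.entry_time_ps:
            raise ValueError("exit time must be after entry time")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class ConductanceResult:
    delta_q_C: float
    delta_t_s: float
    current_A: float
    voltage_V: float | None = None
    conductance_S: float | None = None
    event_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.delta_t_s <= 0:
            raise ValueError("dt must be positive")
        assert abs(self.current_A * self.delta_t_s - self.delta_q_C) <= 1e-30 + 1e-12 * abs(
            self.delta_q_C
        )


def _region(z: float, z_lower: float, z_upper: float) -> int:
    if z < z_lower:
        return _BELOW
    if z > z_upper:
        return _ABOVE
    return _INSIDE


def detect_crossings(
    trajectory: Trajectory,
    ion_indices,
    z_lower: float,
    z_upper: float,
    radius: float,
    axis_center=(0.0, 0.0),
    species: str = "ion",
    charge_e: float = 1.0,
) -> list[CrossingEvent]:
    """Detect complete ion traversals of the bounding cylinder (Angstrom).

    Coordinates wrapped by a periodic box are handled through the box stored
    on the trajectory: a per-frame z jump larger than half the box length is
    a periodic image change, which teleports the ion to the other side without
    traversing the pore interior.  Without box information, such a jump cannot
    be told apart from wrapping and is rejected as an error.
    """
    if z_lower >= z_upper:
        raise AnalysisError("z_lower must be below z_upper")
    ion_indices = np.asarray(ion_indices, dtype=int)
    cx, cy = axis_center
    events: list[CrossingEvent] = []
    box_z = None if trajectory.box is None else trajectory.box[:, 2]
    span = z_upper - z_lower

    for ion in ion_indices:
        z = trajectory.coords[:, ion, 2]
        r = np.hypot(
            trajectory.coords[:, ion, 0] - cx, trajectory.coords[:, ion, 1] - cy
        )
        state = _region(z[0], z_lower, z_upper)
        origin = state if state != _INSIDE else None
        entry_time = None
        disqualified = state == _INSIDE and r[0] >= radius
        for i in range(1, trajectory.n_frames):
            dz = z[i] - z[i - 1]
            if box_z is not None and abs(dz) > box_z[i] / 2.0:
                # periodic image jump: reset tracking, no traversal occurred
                state = _region(z[i], z_lower, z_upper)
                origin = state if state != _INSIDE else None
                entry_time = None
                disqualified = state == _INSIDE
                continue
            if box_z is None and abs(dz) > span:
                raise AnalysisError(
                    f"ion {ion}: |dz| = {abs(dz):.1f} A in one frame with no box "
                    "information; coordinates look wrapped, provide the box"
                )
            new_state = _region(z[i], z_lower, z_upper)
            if new_state == _INSIDE:
                if state != _INSIDE:
                    # fresh entry from an outside region
                    origin = state
                    entry_time = trajectory.times[i]
                    disqualified = False
                if r[i] >= radius:
                    disqualified = True
            else:
                if (
                    state == _INSIDE
                    and origin is not None
                    and new_state != origin
                    and not disqualified
                ):
                    events.append(
                        CrossingEvent(
                            ion_id=int(ion),
                            species=species,
                            charge_e=charge_e,
                            entry_time_ps=float(entry_time),
                            exit_time_ps=float(trajectory.times[i]),
                            direction=1 if new_state == _ABOVE else -1,
                        )
                    )
                origin = new_state
                entry_time = None
                disqualified = False
            state = new_state
    events.sort(key=lambda e: e.exit_time_ps)
    return events


def compute_current(
    events: list[CrossingEvent], duration_ps: float
) -> ConductanceResult:
    """Net current from crossing events: I = dq/dt over the analyzed duration."""
    if duration_ps <= 0:
        raise AnalysisError("duration must be positive")
    dq = sum(e.charge_e * e.direction for e in events) * ELEMENTARY_CHARGE_C
    dt = duration_ps * 1e-12
    counts: dict = {}
    for e in events:
        key = (e.species, "+z" if e.direction > 0 else "-z")
        counts[key] = counts.get(key, 0) + 1
    return ConductanceResult(
        delta_q_C=dq,
        delta_t_s=dt,
        current_A=dq / dt,
        event_counts=counts,
    )


def compute_conductance(current_A: float, voltage_V: float) -> float:
    """Ohmic conductance C = I/U in siemens."""
    if voltage_V == 0:
        raise AnalysisError("voltage must be nonzero")
    return current_A / voltage_V
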