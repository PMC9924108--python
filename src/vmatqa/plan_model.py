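"""Domain model for VMAT plans and per-segment delivery dynamics.

The hierarchy mirrors how a dynamic arc is stored by a treatment planning
system: a :class:`VMATPlan` owns one or more :class:`ArcBeam` objects,
each a sequence of :class:`ControlPoint` machine states (gantry angle,
cumulative meterset weight, the two MLC bank position arrays, and four
jaw positions).  All coordinates are IEC 61217, mm at isocenter; bank A
is the X1-side bank, bank B the X2-side, and the leaf-pair index runs
from the most negative y.

Dose rate and gantry speed are not stored in plans.  They are
reconstructed per segment with the standard maximum-constraint model:
the segment duration is whichever of the MU delivery or the gantry
rotation is limiting,

    dt_k = max(dMU_k / DRmax, dtheta_k / GSmax),

so that every moving segment saturates at least one machine limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .machines import MachineModel

__all__ = [
    "ControlPoint",
    "ArcBeam",
    "VMATPlan",
    "SegmentDynamics",
    "QARecord",
    "SITE_LABELS",
    "validate_plan",
    "derive_segment_dynamics",
    "segment_dynamics_arrays",
    "gantry_steps",
    "arc_length",
]

SITE_LABELS = ("IMRS", "HN", "MED_LUNG", "PROSTATE", "OTHER")

_CMW_TOL = 1e-6


@dataclass
class ControlPoint:
    """One sampled machine state along an arc."""

    gantry_angle: float  # deg, [0, 360)
    cumulative_meterset_weight: float  # fraction of beam MU, [0, 1]
    bank_a: np.ndarray  # X1-side leaf-tip positions (mm), one per pair
    bank_b: np.ndarray  # X2-side leaf-tip positions (mm)
    jaw_x1: float
    jaw_x2: float
    jaw_y1: float
    jaw_y2: float

    def __post_init__(self) -> None:
        self.bank_a = np.asarray(self.bank_a, dtype=float)
        self.bank_b = np.asarray(self.bank_b, dtype=float)


@dataclass
class ArcBeam:
    """A single (possibly partial) VMAT arc."""

    beam_id: str
    beam_mu: float
    control_points: list[ControlPoint]
    energy_label: str = "6X"
    rotation_direction: Literal["CW", "CCW"] = "CW"


@dataclass
class VMATPlan:
    """A VMAT plan: a machine reference plus one or more arcs."""

    plan_id: str
    machine: MachineModel
    beams: list[ArcBeam]
    site_label: str = "OTHER"

    @property
    def total_mu(self) -> float:
        return float(sum(b.beam_mu for b in self.beams))


@dataclass(frozen=True)
class SegmentDynamics:
    """Derived delivery state of one inter-control-point segment."""

    delta_mu: float  # MU
    delta_theta: float  # deg
    delta_t: float  # s
    dose_rate: float  # MU/min
    gantry_speed: float  # deg/s


@dataclass(frozen=True)
class QARecord:
    """Measured gamma passing rate for one plan (3%/2 mm, 10% threshold)."""

    plan_id: str
    gpr: float  # percent, [0, 100]


# ---------------------------------------------------------------------------
# gantry unwrapping


def gantry_steps(angles: Sequence[float], direction: str) -> np.ndarray:
    """Per-segment gantry rotation (deg, >= 0) unwrapped around 0/360.

    Each consecutive difference is mapped onto the rotation direction, so
    a CW beam sampled 358, 0, 2 yields steps (2, 2) and a two-point beam
    181 -> 179 CW reports the long way round (358 deg).
    """
    a = np.asarray(angles, dtype=float)
    d = np.diff(a)
    if direction == "CW":
        steps = np.mod(d, 360.0)
    elif direction == "CCW":
        steps = np.mod(-d, 360.0)
    else:
        raise ValueError(f"unknown rotation direction {direction!r}")
    # float fuzz on an exactly-zero step must not wrap to ~360
    steps[steps > 360.0 - 1e-9] = 0.0
    return steps


def arc_length(beam: ArcBeam) -> float:
    """Total unwrapped gantry angle traversed by the beam, in degrees."""
    angles = [cp.gantry_angle for cp in beam.control_points]
    return float(np.sum(gantry_steps(angles, beam.rotation_direction)))


# ---------------------------------------------------------------------------
# validation


def validate_plan(plan: VMATPlan) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the plan is valid.  Violations are data, not
    exceptions: each names the beam, control point and rule broken.
    """
    out: list[str] = []
    machine = plan.machine
    if not plan.beams:
        out.append("plan: no beams")
        return out
    if plan.site_label not in SITE_LABELS:
        out.append(f"plan: unknown site label {plan.site_label!r}")
    if plan.total_mu <= 0:
        out.append("plan: total MU must be > 0")
    for beam in plan.beams:
        out.extend(_validate_beam(beam, machine))
    return out


def _validate_beam(beam: ArcBeam, machine: MachineModel) -> Iterable[str]:
    bid = beam.beam_id
    if beam.beam_mu <= 0:
        yield f"beam {bid}: beam_mu must be > 0"
    cps = beam.control_points
    if len(cps) < 2:
        yield f"beam {bid}: fewer than 2 control points"
        return
    n = machine.n_leaf_pairs
    for k, cp in enumerate(cps):
        if len(cp.bank_a) != n or len(cp.bank_b) != n:
            yield (
                f"beam {bid} cp {k}: leaf count mismatch "
                f"({len(cp.bank_a)}/{len(cp.bank_b)} vs {n} pairs)"
            )
            continue
        if np.any(cp.bank_b - cp.bank_a < -1e-9):
            bad = int(np.argmax(cp.bank_a - cp.bank_b))
            yield f"beam {bid} cp {k}: bank_B < bank_A (first at pair {bad})"
        if not cp.jaw_x1 < cp.jaw_x2:
            yield f"beam {bid} cp {k}: jaw_x1 must be < jaw_x2"
        if not cp.jaw_y1 < cp.jaw_y2:
            yield f"beam {bid} cp {k}: jaw_y1 must be < jaw_y2"
        if not (0.0 <= cp.gantry_angle < 360.0):
            yield f"beam {bid} cp {k}: gantry angle {cp.gantry_angle} outside [0, 360)"
    cmw = np.array([cp.cumulative_meterset_weight for cp in cps])
    if abs(cmw[0]) > _CMW_TOL:
        yield f"beam {bid}: first cumulative meterset weight is {cmw[0]}, expected 0"
    if abs(cmw[-1] - 1.0) > _CMW_TOL:
        yield f"beam {bid}: final cumulative meterset weight is {cmw[-1]}, expected 1"
    if np.any(np.diff(cmw) < -_CMW_TOL):
        k = int(np.argmax(np.diff(cmw) < -_CMW_TOL))
        yield f"beam {bid} cp {k + 1}: cumulative meterset weight decreases"
    # direction consistency: small steps against the stated rotation are
    # violations; near-180 jumps are ambiguous and tolerated.
    angles = np.array([cp.gantry_angle for cp in cps])
    signed = np.mod(np.diff(angles) + 180.0, 360.0) - 180.0
    sign = 1.0 if beam.rotation_direction == "CW" else -1.0
    wrong = (sign * signed < -1e-9) & (np.abs(signed) < 90.0)
    if np.any(wrong):
        k = int(np.argmax(wrong))
        yield (
            f"beam {bid} cp {k + 1}: gantry step opposes rotation direction "
            f"{beam.rotation_direction}"
        )


# ---------------------------------------------------------------------------
# segment dynamics


def segment_dynamics_arrays(
    beam: ArcBeam, machine: MachineModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized segment dynamics: (dmu, dtheta, dt, dose_rate, gantry_speed).

    Units: MU, deg, s, MU/min, deg/s.  Segments with neither MU nor
    rotation get zero duration, dose rate and gantry speed.
    """
    cmw = np.array([cp.cumulative_meterset_weight for cp in beam.control_points])
    dmu = np.diff(cmw) * beam.beam_mu
    dtheta = gantry_steps(
        [cp.gantry_angle for cp in beam.control_points], beam.rotation_direction
    )
    t_mu = dmu / (machine.max_dose_rate / 60.0)
    t_gs = dtheta / machine.max_gantry_speed
    dt = np.maximum(t_mu, t_gs)
    with np.errstate(divide="ignore", invalid="ignore"):
        dr = np.where(dt > 0, dmu / np.where(dt > 0, dt, 1.0) * 60.0, 0.0)
        gs = np.where(dt > 0, dtheta / np.where(dt > 0, dt, 1.0), 0.0)
    return dmu, dtheta, dt, dr, gs


def derive_segment_dynamics(beam: ArcBeam, machine: MachineModel) -> list[SegmentDynamics]:
    """Reconstruct per-segment dose rate and gantry speed.

    Uses the maximum-constraint model described in the module docstring:
    the limiting axis runs at its machine maximum and the other is slowed
    to match, so neither ``dose_rate`` nor ``gantry_speed`` can exceed
    the machine limits.
    """
    dmu, dtheta, dt, dr, gs = segment_dynamics_arrays(beam, machine)
    return [
        SegmentDynamics(
            delta_mu=float(dmu[k]),
            delta_theta=float(dtheta[k]),
            delta_t=float(dt[k]),
            dose_rate=float(dr[k]),
            gantry_speed=float(gs[k]),
        )
        for k in range(len(dmu))
    ]
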