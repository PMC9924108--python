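"""Modulation indices for VMAT plans.

Per control point the MLC/jaw geometry defines an aperture — a union of
jaw-clipped rectangles, one per open leaf pair — on which three shape
metrics are defined:

* aperture area, AA = sum of rectangle areas (mm^2);
* aperture perimeter, AP = boundary length of the union (mm);
* aperture irregularity, AI = AP^2 / (4 pi AA), the isoperimetric
  ratio: 1 for a circle, 4/pi for a single square, larger for ragged
  shapes.

Per beam these are aggregated with segment-MU weights into the beam
area BA and beam irregularity BI, and per plan with beam-MU weights
into the plan-averaged beam area PA and irregularity PI.  Three dynamic
indices complete the six plan-level predictors: mean leaf travel per
degree of arc (LT/AL), and the summed absolute dose-rate and
gantry-speed changes per degree of arc (DR and GS variation).

Weighting convention: each control point carries the MU of the segment
that follows it, so the final control point of a beam has zero weight.
A constant-aperture arc therefore reproduces its own AA and AI exactly
as BA and BI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError
from .machines import MachineModel
from .plan_model import (
    ArcBeam,
    ControlPoint,
    VMATPlan,
    arc_length,
    segment_dynamics_arrays,
)

__all__ = [
    "ApertureShape",
    "ComplexityFeatures",
    "FEATURE_COLUMNS",
    "clipped_openings",
    "aperture_area",
    "aperture_perimeter",
    "aperture_irregularity",
    "beam_aggregates",
    "plan_aggregates",
    "leaf_travel_per_al",
    "dynamics_variations",
    "compute_features",
    "control_point_table",
    "beam_table",
    "features_frame",
]

#: Canonical column order of the six plan-level predictors.
FEATURE_COLUMNS = ["PA_mm2", "PI", "total_MU", "LT_per_AL", "DR_var", "GS_var"]


@dataclass(frozen=True)
class ApertureShape:
    """Jaw-clipped open rectangles of one control point.

    Arrays are parallel and ordered by ``pair_index`` (ascending, i.e.
    from the most negative y).  Pairs whose clipped gap is at or below
    the machine's ``min_gap``, or with no y-overlap with the Y jaws,
    are excluded entirely.
    """

    pair_index: np.ndarray
    x_lo: np.ndarray
    x_hi: np.ndarray
    y_lo: np.ndarray
    y_hi: np.ndarray

    @property
    def n_open(self) -> int:
        return len(self.pair_index)


@dataclass(frozen=True)
class ComplexityFeatures:
    """The six plan-level modulation indices used as GPR predictors."""

    pa: float  # plan-averaged beam area, mm^2
    pi: float  # plan-averaged beam irregularity, dimensionless >= 1
    total_mu: float  # MU
    lt_per_al: float  # mean leaf travel per arc length, mm/deg
    dr_variation: float  # (MU/min)/deg
    gs_variation: float  # (deg/s)/deg

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_COLUMNS, (self.pa, self.pi, self.total_mu,
                                          self.lt_per_al, self.dr_variation,
                                          self.gs_variation)))


# ---------------------------------------------------------------------------
# per-control-point geometry


def clipped_openings(cp: ControlPoint, machine: MachineModel) -> ApertureShape:
    """Clip the MLC opening of one control point against the jaws.

    Per pair the open x interval is ``[max(bank_a, jaw_x1),
    min(bank_b, jaw_x2)]`` and the y interval is the leaf span clipped
    to ``[jaw_y1, jaw_y2]``; pairs whose clipped gap is <= ``min_gap``
    or with an empty y interval are dropped.  A fully closed control
    point yields an empty shape (not an error).
    """
    bounds = machine.leaf_boundaries
    x_lo = np.maximum(cp.bank_a, cp.jaw_x1)
    x_hi = np.minimum(cp.bank_b, cp.jaw_x2)
    y_lo = np.maximum(bounds[:-1], cp.jaw_y1)
    y_hi = np.minimum(bounds[1:], cp.jaw_y2)
    keep = (x_hi - x_lo > machine.min_gap) & (y_hi - y_lo > 0)
    idx = np.flatnonzero(keep)
    return ApertureShape(
        pair_index=idx,
        x_lo=x_lo[idx],
        x_hi=x_hi[idx],
        y_lo=y_lo[idx],
        y_hi=y_hi[idx],
    )


def aperture_area(shape: ApertureShape) -> float:
    """Total area of all MLC openings (mm^2); 0 for an empty shape."""
    return float(np.sum((shape.x_hi - shape.x_lo) * (shape.y_hi - shape.y_lo)))


def aperture_perimeter(shape: ApertureShape) -> float:
    """Boundary length (mm) of the union of the per-pair rectangles.

    Leaf-end (vertical) edges are always exposed and contribute twice
    the pair height.  Horizontal edges contribute the full x extent at
    the bottom of the lowest and top of the highest pair of each
    contiguous run, and between y-adjacent open pairs the length of the
    symmetric difference of their x intervals — so stacked pairs with
    identical intervals merge seamlessly and each maximal run of open
    pairs bounds its own polygon (closed-pair islands are respected).
    """
    m = shape.n_open
    if m == 0:
        return 0.0
    w = shape.x_hi - shape.x_lo
    h = shape.y_hi - shape.y_lo
    vertical = 2.0 * float(np.sum(h))
    if m == 1:
        return vertical + 2.0 * float(w[0])
    contiguous = shape.pair_index[1:] == shape.pair_index[:-1] + 1
    overlap = np.maximum(
        0.0,
        np.minimum(shape.x_hi[1:], shape.x_hi[:-1])
        - np.maximum(shape.x_lo[1:], shape.x_lo[:-1]),
    )
    between = w[:-1] + w[1:] - np.where(contiguous, 2.0 * overlap, 0.0)
    horizontal = float(w[0] + w[-1] + np.sum(between))
    return vertical + horizontal


def aperture_irregularity(shape: ApertureShape) -> float:
    """Isoperimetric ratio AP^2 / (4 pi AA); 1 for a perfect circle."""
    area = aperture_area(shape)
    if area <= 0:
        raise UndefinedMetricError("aperture irregularity undefined for zero-area shape")
    perim = aperture_perimeter(shape)
    return perim * perim / (4.0 * np.pi * area)


# ---------------------------------------------------------------------------
# beam- and plan-level aggregation


def _segment_mu_weights(beam: ArcBeam) -> np.ndarray:
    """Per-control-point MU weight: MU of the following segment, 0 for the last."""
    cmw = np.array([cp.cumulative_meterset_weight for cp in beam.control_points])
    w = np.zeros(len(cmw))
    w[:-1] = np.diff(cmw) * beam.beam_mu
    return w


def _beam_cp_geometry(
    beam: ArcBeam, machine: MachineModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(AA, AP, AI) arrays over control points; AI is NaN where AA = 0."""
    aa = np.empty(len(beam.control_points))
    ap = np.empty_like(aa)
    for k, cp in enumerate(beam.control_points):
        shape = clipped_openings(cp, machine)
        aa[k] = aperture_area(shape)
        ap[k] = aperture_perimeter(shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(aa > 0, ap * ap / (4.0 * np.pi * np.where(aa > 0, aa, 1.0)), np.nan)
    return aa, ap, ai


def beam_aggregates(beam: ArcBeam, machine: MachineModel) -> tuple[float, float]:
    """MU-weighted beam area BA (mm^2) and beam irregularity BI.

    BA averages AA over control points with segment-MU weights (closed
    control points contribute zero area); BI averages AI over the
    control points with open apertures, weights renormalized.  A beam
    closed at every MU-carrying control point has no defined aggregates.
    """
    aa, _, ai = _beam_cp_geometry(beam, machine)
    w = _segment_mu_weights(beam)
    wsum = w.sum()
    if wsum <= 0:
        raise UndefinedMetricError(f"beam {beam.beam_id}: no MU-carrying segments")
    open_w = w[~np.isnan(ai)]
    if open_w.sum() <= 0:
        raise UndefinedMetricError(f"beam {beam.beam_id}: aperture closed everywhere")
    ba = float(np.sum(w * aa) / wsum)
    bi = float(np.sum(w[~np.isnan(ai)] * ai[~np.isnan(ai)]) / open_w.sum())
    return ba, bi


def _mu_weighted(values: list[float], mus: list[float]) -> float:
    v = np.asarray(values, dtype=float)
    m = np.asarray(mus, dtype=float)
    return float(np.sum(v * m) / np.sum(m))


def plan_aggregates(plan: VMATPlan) -> tuple[float, float]:
    """Plan-averaged beam area PA and irregularity PI (beam-MU weights)."""
    bas, bis, mus = [], [], []
    for beam in plan.beams:
        ba, bi = beam_aggregates(beam, plan.machine)
        bas.append(ba)
        bis.append(bi)
        mus.append(beam.beam_mu)
    return _mu_weighted(bas, mus), _mu_weighted(bis, mus)


# ---------------------------------------------------------------------------
# dynamic indices


def _beam_leaf_travel(
    beam: ArcBeam,
    machine: MachineModel,
    participation: Literal["open-pairs", "all"],
) -> float:
    """Mean distance traveled by participating leaves over the arc (mm)."""
    a = np.stack([cp.bank_a for cp in beam.control_points])
    b = np.stack([cp.bank_b for cp in beam.control_points])
    travel_a = np.sum(np.abs(np.diff(a, axis=0)), axis=0)
    travel_b = np.sum(np.abs(np.diff(b, axis=0)), axis=0)
    if participation == "all":
        mask = np.ones(machine.n_leaf_pairs, dtype=bool)
    else:
        mask = np.zeros(machine.n_leaf_pairs, dtype=bool)
        for cp in beam.control_points:
            mask[clipped_openings(cp, machine).pair_index] = True
        if not mask.any():
            raise UndefinedMetricError(f"beam {beam.beam_id}: aperture closed everywhere")
    # both leaves of a participating pair count individually
    return float(np.concatenate([travel_a[mask], travel_b[mask]]).mean())


def leaf_travel_per_al(
    plan: VMATPlan,
    machine: MachineModel | None = None,
    *,
    participation: Literal["open-pairs", "all"] = "open-pairs",
) -> float:
    """Mean MLC leaf travel divided by arc length, MU-weighted over beams.

    A leaf participates if its pair is open (after jaw clipping) at any
    control point of the beam; ``participation="all"`` averages over
    every leaf of both banks instead.  Static-gantry beams have no arc
    length and raise :class:`UndefinedMetricError`.
    """
    machine = machine or plan.machine
    vals, mus = [], []
    for beam in plan.beams:
        al = arc_length(beam)
        if al <= 0:
            raise UndefinedMetricError(f"beam {beam.beam_id}: arc length is 0")
        vals.append(_beam_leaf_travel(beam, machine, participation) / al)
        mus.append(beam.beam_mu)
    return _mu_weighted(vals, mus)


def dynamics_variations(
    plan: VMATPlan, machine: MachineModel | None = None
) -> tuple[float, float]:
    """Mean dose-rate and gantry-speed variation per degree of arc.

    Per beam: the summed absolute change of the derived segment dose
    rate (gantry speed) between consecutive segments, divided by the
    beam arc length; plan value is the beam-MU-weighted mean.
    """
    machine = machine or plan.machine
    drs, gss, mus = [], [], []
    for beam in plan.beams:
        al = arc_length(beam)
        if al <= 0:
            raise UndefinedMetricError(f"beam {beam.beam_id}: arc length is 0")
        _, _, _, dr, gs = segment_dynamics_arrays(beam, machine)
        drs.append(float(np.sum(np.abs(np.diff(dr)))) / al)
        gss.append(float(np.sum(np.abs(np.diff(gs)))) / al)
        mus.append(beam.beam_mu)
    return _mu_weighted(drs, mus), _mu_weighted(gss, mus)


# ---------------------------------------------------------------------------
# assembly


def compute_features(
    plan: VMATPlan,
    machine: MachineModel | None = None,
    *,
    participation: Literal["open-pairs", "all"] = "open-pairs",
) -> ComplexityFeatures:
    """Assemble the six plan-level predictors for one plan."""
    machine = machine or plan.machine
    pa, pi = plan_aggregates(plan)
    dr_var, gs_var = dynamics_variations(plan, machine)
    return ComplexityFeatures(
        pa=pa,
        pi=pi,
        total_mu=plan.total_mu,
        lt_per_al=leaf_travel_per_al(plan, machine, participation=participation),
        dr_variation=dr_var,
        gs_variation=gs_var,
    )


def control_point_table(plan: VMATPlan, machine: MachineModel | None = None) -> pd.DataFrame:
    """Per-control-point intermediates (AA, AP, AI, segment MU) for export."""
    machine = machine or plan.machine
    rows = []
    for beam in plan.beams:
        aa, ap, ai = _beam_cp_geometry(beam, machine)
        w = _segment_mu_weights(beam)
        for k in range(len(beam.control_points)):
            rows.append(
                {
                    "plan_id": plan.plan_id,
                    "beam_id": beam.beam_id,
                    "cp_index": k,
                    "AA_mm2": aa[k],
                    "AP_mm": ap[k],
                    "AI": ai[k],
                    "seg_MU": w[k],
                }
            )
    return pd.DataFrame(rows)


def beam_table(plan: VMATPlan, machine: MachineModel | None = None) -> pd.DataFrame:
    """Per-beam intermediates (BA, BI, MU, arc length) for export."""
    machine = machine or plan.machine
    rows = []
    for beam in plan.beams:
        ba, bi = beam_aggregates(beam, machine)
        rows.append(
            {
                "plan_id": plan.plan_id,
                "beam_id": beam.beam_id,
                "BA_mm2": ba,
                "BI": bi,
                "beam_MU": beam.beam_mu,
                "arc_deg": arc_length(beam),
            }
        )
    return pd.DataFrame(rows)


def features_frame(plans: list[VMATPlan], **kw) -> pd.DataFrame:
    """Feature table for a cohort: plan_id, site, and the six predictors."""
    rows = []
    for plan in plans:
        row = {"plan_id": plan.plan_id, "site": plan.site_label}
        row.update(compute_features(plan, **kw).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
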