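"""Shared test utilities: plan builders, DICOM writer, geometry oracles."""

from __future__ import annotations

import numpy as np

from vmatqa import ArcBeam, ControlPoint, MachineModel, VMATPlan
from vmatqa.complexity import ApertureShape


def make_cp(
    machine: MachineModel,
    opens: dict[int, tuple[float, float]],
    jaws: tuple[float, float, float, float] = (-100.0, 100.0, -210.0, 210.0),
    gantry: float = 0.0,
    cmw: float = 0.0,
) -> ControlPoint:
    """Control point with the given pairs open and all others closed at 0."""
    a = np.zeros(machine.n_leaf_pairs)
    b = np.zeros(machine.n_leaf_pairs)
    for i, (lo, hi) in opens.items():
        a[i], b[i] = lo, hi
    return ControlPoint(gantry, cmw, a, b, *jaws)


def make_beam(
    machine: MachineModel,
    cps: list[ControlPoint],
    mu: float = 100.0,
    beam_id: str = "B1",
    direction: str = "CW",
) -> ArcBeam:
    return ArcBeam(beam_id=beam_id, beam_mu=mu, control_points=cps,
                   rotation_direction=direction)


def make_plan(machine: MachineModel, beams: list[ArcBeam], plan_id: str = "P1",
              site: str = "OTHER") -> VMATPlan:
    return VMATPlan(plan_id=plan_id, machine=machine, beams=beams, site_label=site)


def segment_beam(
    machine: MachineModel,
    seg_mu: list[float],
    seg_theta: list[float],
    opens: dict[int, tuple[float, float]] | None = None,
    start_angle: float = 0.0,
) -> ArcBeam:
    """Beam built from per-segment MU and gantry increments."""
    mu_total = float(np.sum(seg_mu))
    cmw = np.concatenate([[0.0], np.cumsum(seg_mu)]) / mu_total
    angles = np.mod(start_angle + np.concatenate([[0.0], np.cumsum(seg_theta)]), 360.0)
    opens = opens if opens is not None else {30: (-10.0, 10.0)}
    cps = [
        make_cp(machine, opens, gantry=float(angles[k]), cmw=float(cmw[k]))
        for k in range(len(cmw))
    ]
    return make_beam(machine, cps, mu=mu_total)


def translate_plan_x(plan: VMATPlan, dx: float) -> VMATPlan:
    """Shift every leaf position and the X jaws by dx mm."""
    beams = []
    for b in plan.beams:
        cps = [
            ControlPoint(
                cp.gantry_angle, cp.cumulative_meterset_weight,
                cp.bank_a + dx, cp.bank_b + dx,
                cp.jaw_x1 + dx, cp.jaw_x2 + dx, cp.jaw_y1, cp.jaw_y2,
            )
            for cp in b.control_points
        ]
        beams.append(ArcBeam(b.beam_id, b.beam_mu, cps, b.energy_label,
                             b.rotation_direction))
    return VMATPlan(plan.plan_id, plan.machine, beams, plan.site_label)


def quantize_plan(plan: VMATPlan, nd: int = 4) -> VMATPlan:
    """Round all control-point floats so DICOM decimal strings are exact."""
    beams = []
    for b in plan.beams:
        cps = [
            ControlPoint(
                round(cp.gantry_angle, nd), round(cp.cumulative_meterset_weight, 6),
                np.round(cp.bank_a, nd), np.round(cp.bank_b, nd),
                round(cp.jaw_x1, nd), round(cp.jaw_x2, nd),
                round(cp.jaw_y1, nd), round(cp.jaw_y2, nd),
            )
            for cp in b.control_points
        ]
        cps[0].cumulative_meterset_weight = 0.0
        cps[-1].cumulative_meterset_weight = 1.0
        beams.append(ArcBeam(b.beam_id, round(b.beam_mu, 3), cps, b.energy_label,
                             b.rotation_direction))
    return VMATPlan(plan.plan_id, plan.machine, beams, plan.site_label)


# ---------------------------------------------------------------------------
# DICOM writing (tests only; the package itself never writes DICOM)


def write_dicom_rtplan(plan: VMATPlan, path) -> None:
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    ds = Dataset()
    ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.481.5"  # RT Plan Storage
    ds.SOPInstanceUID = generate_uid()
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = plan.plan_id

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.ReferencedBeamSequence = []
    ds.BeamSequence = []
    for i, beam in enumerate(plan.beams, start=1):
        rb = Dataset()
        rb.ReferencedBeamNumber = i
        rb.BeamMeterset = beam.beam_mu
        fg.ReferencedBeamSequence.append(rb)

        b = Dataset()
        b.BeamNumber = i
        b.BeamName = beam.beam_id
        b.TreatmentDeliveryType = "TREATMENT"
        b.FinalCumulativeMetersetWeight = 1.0
        if beam.energy_label.endswith("FFF"):
            mode = Dataset()
            mode.FluenceMode = "NON_STANDARD"
            mode.FluenceModeID = "FFF"
            b.PrimaryFluenceModeSequence = [mode]
        bld = Dataset()
        bld.RTBeamLimitingDeviceType = "MLCX"
        bld.NumberOfLeafJawPairs = plan.machine.n_leaf_pairs
        bld.LeafPositionBoundaries = [float(v) for v in plan.machine.leaf_boundaries]
        b.BeamLimitingDeviceSequence = [bld]

        b.ControlPointSequence = []
        for k, cp in enumerate(beam.control_points):
            c = Dataset()
            c.ControlPointIndex = k
            c.CumulativeMetersetWeight = cp.cumulative_meterset_weight
            c.GantryAngle = cp.gantry_angle
            devs = []
            if k == 0:
                c.GantryRotationDirection = "CW" if beam.rotation_direction == "CW" else "CC"
                c.NominalBeamEnergy = float(
                    "".join(ch for ch in beam.energy_label if ch.isdigit() or ch == ".")
                )
                dx = Dataset()
                dx.RTBeamLimitingDeviceType = "ASYMX"
                dx.LeafJawPositions = [cp.jaw_x1, cp.jaw_x2]
                dy = Dataset()
                dy.RTBeamLimitingDeviceType = "ASYMY"
                dy.LeafJawPositions = [cp.jaw_y1, cp.jaw_y2]
                devs += [dx, dy]
            dm = Dataset()
            dm.RTBeamLimitingDeviceType = "MLCX"
            dm.LeafJawPositions = [float(v) for v in cp.bank_a] + [
                float(v) for v in cp.bank_b
            ]
            devs.append(dm)
            c.BeamLimitingDevicePositionSequence = devs
            b.ControlPointSequence.append(c)
        ds.BeamSequence.append(b)
    ds.FractionGroupSequence = [fg]

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = ds.SOPClassUID
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    fds = FileDataset(str(path), ds, file_meta=meta, preamble=b"\0" * 128)
    fds.save_as(str(path))


# ---------------------------------------------------------------------------
# exhaustive rectilinear oracle for aperture area and perimeter


def oracle_area_perimeter(shape: ApertureShape) -> tuple[float, float]:
    """Rasterize on a grid aligned to every breakpoint; exact for aligned shapes.

    Area is summed over filled cells; perimeter by edge walking (every
    cell edge between filled and unfilled/outside contributes its
    length).  Independent of the analytic union formulas under test.
    """
    if shape.n_open == 0:
        return 0.0, 0.0
    xs = np.unique(np.concatenate([shape.x_lo, shape.x_hi]))
    ys = np.unique(np.concatenate([shape.y_lo, shape.y_hi]))
    cx = 0.5 * (xs[:-1] + xs[1:])
    cy = 0.5 * (ys[:-1] + ys[1:])
    filled = np.zeros((len(cy), len(cx)), dtype=bool)
    for i in range(shape.n_open):
        cols = (cx > shape.x_lo[i]) & (cx < shape.x_hi[i])
        rows = (cy > shape.y_lo[i]) & (cy < shape.y_hi[i])
        filled |= rows[:, None] & cols[None, :]
    dx = np.diff(xs)
    dy = np.diff(ys)
    area = float((filled * np.outer(dy, dx)).sum())
    padded = np.zeros((len(cy) + 2, len(cx) + 2), dtype=bool)
    padded[1:-1, 1:-1] = filled
    vertical_edges = padded[1:-1, 1:] ^ padded[1:-1, :-1]
    horizontal_edges = padded[1:, 1:-1] ^ padded[:-1, 1:-1]
    perimeter = float((vertical_edges * dy[:, None]).sum()) + float(
        (horizontal_edges * dx[None, :]).sum()
    )
    return area, perimeter


def random_control_point(machine: MachineModel, rng: np.random.Generator) -> ControlPoint:
    """Random staircase aperture with islands, clipping and near-closed pairs."""
    n = machine.n_leaf_pairs
    open_mask = rng.random(n) < 0.7
    centers = rng.normal(0.0, 15.0, n)
    half = rng.uniform(0.0, 25.0, n)  # includes gaps below min_gap
    a = np.where(open_mask, centers - half, 0.0)
    b = np.where(open_mask, centers + half, 0.0)
    if rng.random() < 0.3:  # occasional exactly-matching stacked intervals
        i = int(rng.integers(0, n - 1))
        a[i + 1], b[i + 1] = a[i], b[i]
    jaws = (
        float(rng.uniform(-45.0, -5.0)),
        float(rng.uniform(5.0, 45.0)),
        float(rng.uniform(-180.0, -10.0)),
        float(rng.uniform(10.0, 180.0)),
    )
    return ControlPoint(0.0, 0.0, a, b, *jaws)
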