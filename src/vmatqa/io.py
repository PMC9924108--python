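"""Plan readers and writers: DICOM RT Plan input and a JSON plan dialect.

The JSON dialect is a faithful plain-text mirror of the internal model::

    {
      "plan_id": "...", "site": "PROSTATE",
      "machine": {"profile": "Millennium120", "overrides": {...}},
      "beams": [
        {"beam_id": "...", "mu": 312.5, "energy": "10X", "direction": "CW",
         "control_points": [
           {"gantry": 181.0, "cmw": 0.0,
            "bank_a": [...60 floats...], "bank_b": [...],
            "jaws": [x1, x2, y1, y2]},
           ...]}
      ]
    }

DICOM reading covers dynamic-MLC RT Plans as exported by common TPSs:
BeamSequence / ControlPointSequence / BeamLimitingDevicePositionSequence
(MLCX plus ASYMX/X and ASYMY/Y jaws), with beam meterset taken from the
referenced fraction group.  Attributes absent from a control point are
carried forward from the previous one, per the DICOM RT convention.
Writing DICOM is out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np

from .errors import PlanFormatError
from .machines import MachineModel
from .plan_model import ArcBeam, ControlPoint, VMATPlan, SITE_LABELS

__all__ = ["load_plan", "load_plan_json", "save_plan_json", "load_dicom_rtplan"]

_MACHINE_OVERRIDE_KEYS = ("max_dose_rate", "max_gantry_speed", "min_gap")


def load_plan(path: str | Path, machine_profile: str = "Millennium120", **kw) -> VMATPlan:
    """Load a plan from either the JSON dialect or a DICOM RT Plan file.

    Dispatches on the file suffix: ``.json`` goes through
    :func:`load_plan_json`, anything else through
    :func:`load_dicom_rtplan`.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return load_plan_json(path)
    return load_dicom_rtplan(path, machine_profile=machine_profile, **kw)


# ---------------------------------------------------------------------------
# JSON dialect


def save_plan_json(plan: VMATPlan, path: str | Path) -> None:
    """Write a plan to the JSON dialect (lossless up to float repr)."""
    doc: dict[str, Any] = {
        "plan_id": plan.plan_id,
        "site": plan.site_label,
        "machine": {
            "profile": plan.machine.name,
            "overrides": {
                "max_dose_rate": plan.machine.max_dose_rate,
                "max_gantry_speed": plan.machine.max_gantry_speed,
                "min_gap": plan.machine.min_gap,
            },
        },
        "beams": [
            {
                "beam_id": b.beam_id,
                "mu": b.beam_mu,
                "energy": b.energy_label,
                "direction": b.rotation_direction,
                "control_points": [
                    {
                        "gantry": cp.gantry_angle,
                        "cmw": cp.cumulative_meterset_weight,
                        "bank_a": cp.bank_a.tolist(),
                        "bank_b": cp.bank_b.tolist(),
                        "jaws": [cp.jaw_x1, cp.jaw_x2, cp.jaw_y1, cp.jaw_y2],
                    }
                    for cp in b.control_points
                ],
            }
            for b in plan.beams
        ],
    }
    Path(path).write_text(json.dumps(doc))


def _require(doc: dict, key: str, where: str):
    if key not in doc:
        raise PlanFormatError(f"{where}: missing required key {key!r}")
    return doc[key]


def load_plan_json(path: str | Path) -> VMATPlan:
    """Read a plan from the JSON dialect, validating the schema."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise PlanFormatError(f"{path}: not valid JSON ({exc})") from exc
    plan_id = str(_require(doc, "plan_id", "plan"))
    site = str(doc.get("site", "OTHER"))
    if site not in SITE_LABELS:
        raise PlanFormatError(f"plan {plan_id}: unknown site label {site!r}")
    mdoc = _require(doc, "machine", "plan")
    overrides = {
        k: float(v)
        for k, v in (mdoc.get("overrides") or {}).items()
        if k in _MACHINE_OVERRIDE_KEYS
    }
    machine = MachineModel.from_profile(_require(mdoc, "profile", "machine"), **overrides)
    beams = []
    for j, bdoc in enumerate(_require(doc, "beams", "plan")):
        where = f"plan {plan_id} beam {j}"
        cps = []
        for k, cdoc in enumerate(_require(bdoc, "control_points", where)):
            jaws = _require(cdoc, "jaws", f"{where} cp {k}")
            if len(jaws) != 4:
                raise PlanFormatError(f"{where} cp {k}: jaws must be [x1, x2, y1, y2]")
            bank_a = np.asarray(_require(cdoc, "bank_a", f"{where} cp {k}"), dtype=float)
            bank_b = np.asarray(_require(cdoc, "bank_b", f"{where} cp {k}"), dtype=float)
            if len(bank_a) != machine.n_leaf_pairs or len(bank_b) != machine.n_leaf_pairs:
                raise PlanFormatError(
                    f"{where} cp {k}: bank length {len(bank_a)}/{len(bank_b)} "
                    f"does not match {machine.n_leaf_pairs}-pair machine"
                )
            cps.append(
                ControlPoint(
                    gantry_angle=float(_require(cdoc, "gantry", f"{where} cp {k}")),
                    cumulative_meterset_weight=float(_require(cdoc, "cmw", f"{where} cp {k}")),
                    bank_a=bank_a,
                    bank_b=bank_b,
                    jaw_x1=float(jaws[0]),
                    jaw_x2=float(jaws[1]),
                    jaw_y1=float(jaws[2]),
                    jaw_y2=float(jaws[3]),
                )
            )
        beams.append(
            ArcBeam(
                beam_id=str(_require(bdoc, "beam_id", where)),
                beam_mu=float(_require(bdoc, "mu", where)),
                control_points=cps,
                energy_label=str(bdoc.get("energy", "6X")),
                rotation_direction=str(bdoc.get("direction", "CW")),
            )
        )
    return VMATPlan(plan_id=plan_id, machine=machine, beams=beams, site_label=site)


# ---------------------------------------------------------------------------
# DICOM RT Plan


def load_dicom_rtplan(
    path: str | Path,
    machine_profile: str = "Millennium120",
    *,
    machine: MachineModel | None = None,
    site_label: str = "OTHER",
) -> VMATPlan:
    """Read a dynamic-MLC DICOM RT Plan into a :class:`VMATPlan`.

    Beams with zero meterset (setup / QA fields) are skipped.  A beam
    with MU but no MLC positions, fewer than 2 control points, a leaf
    count different from the machine profile, or a non-monotone
    cumulative meterset weight raises :class:`PlanFormatError` naming
    the beam and control point.
    """
    import pydicom

    ds = pydicom.dcmread(str(path), force=True)
    if machine is None:
        machine = MachineModel.from_profile(machine_profile)

    metersets: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            if hasattr(rb, "BeamMeterset"):
                metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    beams: list[ArcBeam] = []
    for beam_ds in getattr(ds, "BeamSequence", []):
        number = int(getattr(beam_ds, "BeamNumber", len(beams) + 1))
        name = str(getattr(beam_ds, "BeamName", f"beam{number}"))
        mu = metersets.get(number, 0.0)
        if mu <= 0:
            continue  # setup / QA beam
        beams.append(_read_beam(beam_ds, name, mu, machine))
    if not beams:
        raise PlanFormatError(f"{path}: no treatment beams with MU found")
    plan_id = str(getattr(ds, "RTPlanLabel", None) or getattr(ds, "SOPInstanceUID", "rtplan"))
    return VMATPlan(plan_id=plan_id, machine=machine, beams=beams, site_label=site_label)


def _read_beam(beam_ds, name: str, mu: float, machine: MachineModel) -> ArcBeam:
    cps_ds = list(getattr(beam_ds, "ControlPointSequence", []))
    if len(cps_ds) < 2:
        raise PlanFormatError(f"beam {name}: fewer than 2 control points")
    final_cmw = float(getattr(beam_ds, "FinalCumulativeMetersetWeight", 1.0) or 1.0)

    energy = None
    first = cps_ds[0]
    if hasattr(first, "NominalBeamEnergy"):
        label = f"{float(first.NominalBeamEnergy):g}"
        fff = False
        for mode in getattr(beam_ds, "PrimaryFluenceModeSequence", []):
            if str(getattr(mode, "FluenceModeID", "")).upper() == "FFF":
                fff = True
        energy = f"{label}FFF" if fff else f"{label}X"

    direction = str(getattr(first, "GantryRotationDirection", "CW"))
    direction = {"CW": "CW", "CC": "CCW", "CCW": "CCW"}.get(direction, "CW")

    n = machine.n_leaf_pairs
    state: dict[str, Any] = {"gantry": None, "jaws": [None] * 4, "mlc": None}
    cps: list[ControlPoint] = []
    prev_cmw = -np.inf
    for k, cp_ds in enumerate(cps_ds):
        if hasattr(cp_ds, "GantryAngle"):
            state["gantry"] = float(cp_ds.GantryAngle) % 360.0
        for dev in getattr(cp_ds, "BeamLimitingDevicePositionSequence", []):
            kind = str(dev.RTBeamLimitingDeviceType).upper()
            vals = [float(v) for v in dev.LeafJawPositions]
            if kind in ("ASYMX", "X"):
                state["jaws"][0], state["jaws"][1] = vals[0], vals[1]
            elif kind in ("ASYMY", "Y"):
                state["jaws"][2], state["jaws"][3] = vals[0], vals[1]
            elif kind in ("MLCX", "MLCY"):
                if len(vals) != 2 * n:
                    raise PlanFormatError(
                        f"beam {name} cp {k}: MLC has {len(vals)} values, "
                        f"expected {2 * n} for a {n}-pair machine"
                    )
                state["mlc"] = vals
        if state["mlc"] is None:
            raise PlanFormatError(f"beam {name} cp {k}: missing MLC positions")
        if any(v is None for v in state["jaws"]) or state["gantry"] is None:
            raise PlanFormatError(f"beam {name} cp {k}: missing jaw or gantry state")
        cmw = float(cp_ds.CumulativeMetersetWeight) / final_cmw
        if cmw < prev_cmw - 1e-9:
            raise PlanFormatError(
                f"beam {name} cp {k}: cumulative meterset weight decreases"
            )
        prev_cmw = cmw
        mlc = state["mlc"]
        cps.append(
            ControlPoint(
                gantry_angle=state["gantry"],
                cumulative_meterset_weight=cmw,
                bank_a=np.array(mlc[:n]),
                bank_b=np.array(mlc[n:]),
                jaw_x1=state["jaws"][0],
                jaw_x2=state["jaws"][1],
                jaw_y1=state["jaws"][2],
                jaw_y2=state["jaws"][3],
            )
        )
    return ArcBeam(
        beam_id=name,
        beam_mu=mu,
        control_points=cps,
        energy_label=energy or "6X",
        rotation_direction=direction,
    )
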