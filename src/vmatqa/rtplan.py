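"""RT Plan ingestion: DICOM RTPLAN -> internal plan model, MU allocation.

DICOM stores a cumulative meterset weight per control point; the complexity
metric needs per-control-point MU.  ``control_point_mu`` converts between
the two, conserving the beam meterset exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _dicom
from ._dicom import Tag
from .mlc import ApertureShape, MlcGeometry

__all__ = [
    "Plan",
    "Arc",
    "ControlPointRecord",
    "read_rtplan",
    "control_point_mu",
    "RtPlanError",
    "NotRtPlanError",
    "NoMlcBeamError",
    "UnsupportedDeviceError",
]

log = logging.getLogger(__name__)


class RtPlanError(ValueError):
    pass


class NotRtPlanError(RtPlanError):
    """The file is DICOM but not an RTPLAN object."""


class NoMlcBeamError(RtPlanError):
    """No treatment beam in the plan carries an MLC sequence."""


class UnsupportedDeviceError(RtPlanError):
    """MLC device without leaf position boundaries (or malformed)."""


@dataclass
class ControlPointRecord:
    """One control point: machine state plus metric values filled in later."""

    index: int
    gantry_angle: float
    mu: float
    aperture: ApertureShape
    cumulative_weight: float = 0.0
    y: float | None = None
    area: float | None = None
    complexity: float | None = None


@dataclass
class Arc:
    beam_id: str
    beam_mu: float
    control_points: list[ControlPointRecord]
    geometry: MlcGeometry
    is_vmat: bool = True

    @property
    def gantry_angles(self) -> np.ndarray:
        return np.array([cp.gantry_angle for cp in self.control_points])


@dataclass
class Plan:
    plan_id: str
    arcs: list[Arc]
    site_label: str | None = None

    @property
    def total_mu(self) -> float:
        return float(sum(a.beam_mu for a in self.arcs))


def control_point_mu(
    cumulative_weights, beam_mu: float, mode: str = "midpoint"
) -> np.ndarray:
    """Allocate a beam's MU among control points from cumulative weights.

    ``midpoint`` (default) splits each delivery segment evenly between its
    two bounding control points, reflecting that the machine interpolates
    apertures between control points.  ``forward`` assigns each segment
    wholly to its leading control point (the last point gets zero).  Both
    conserve ``beam_mu`` exactly.
    """
    w = np.asarray(cumulative_weights, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("need at least two cumulative weights")
    if np.any(np.diff(w) < 0):
        raise ValueError("cumulative meterset weights must be non-decreasing")
    total = w[-1] - w[0]
    if total <= 0:
        raise ValueError("final cumulative weight must exceed the first")
    seg = np.diff(w) * (beam_mu / total)
    mu = np.zeros(w.size)
    if mode == "midpoint":
        mu[:-1] += 0.5 * seg
        mu[1:] += 0.5 * seg
    elif mode == "forward":
        mu[:-1] = seg
    else:
        raise ValueError(f"unknown MU allocation mode {mode!r}")
    return mu


_MLC_TYPES = ("MLCX", "MLCY")
_X_JAW_TYPES = ("ASYMX", "X")
_Y_JAW_TYPES = ("ASYMY", "Y")


def _beam_metersets(ds: dict) -> dict[int, float]:
    groups = ds.get(Tag.FractionGroupSequence, [])
    if not groups:
        return {}
    if len(groups) > 1:
        log.warning("plan has %d fraction groups; using the first", len(groups))
    out: dict[int, float] = {}
    for ref in groups[0].get(Tag.ReferencedBeamSequence, []):
        num = ref.get(Tag.ReferencedBeamNumber)
        meterset = ref.get(Tag.BeamMeterset)
        if num is not None and meterset is not None:
            out[int(num)] = float(meterset)
    return out


def _device_positions(cp: dict) -> dict[str, list[float]]:
    out: dict[str, list[float]] = {}
    for dev in cp.get(Tag.BeamLimitingDevicePositionSequence, []):
        kind = dev.get(Tag.RTBeamLimitingDeviceType)
        pos = dev.get(Tag.LeafJawPositions)
        if kind is None or pos is None:
            continue
        out[kind] = pos if isinstance(pos, list) else [pos]
    return out


def _read_beam(beam: dict, beam_mu: float, mu_mode: str) -> Arc:
    mlc_type = None
    geometry = None
    for dev in beam.get(Tag.BeamLimitingDeviceSequence, []):
        kind = dev.get(Tag.RTBeamLimitingDeviceType, "")
        if kind in _MLC_TYPES:
            mlc_type = kind
            bounds = dev.get(Tag.LeafPositionBoundaries)
            if bounds is None:
                raise UnsupportedDeviceError(
                    f"beam {beam.get(Tag.BeamNumber)}: MLC device without "
                    "leaf position boundaries"
                )
            geometry = MlcGeometry(np.asarray(bounds, dtype=float))
    if geometry is None:
        raise NoMlcBeamError("beam has no MLC device")

    beam_type = beam.get(Tag.BeamType, "DYNAMIC")
    is_vmat = beam_type == "DYNAMIC"
    if not is_vmat:
        log.warning(
            "beam %s is %s (not dynamic); scored as a static-aperture arc",
            beam.get(Tag.BeamName, "?"), beam_type,
        )

    cps = beam.get(Tag.ControlPointSequence, [])
    if len(cps) < 2:
        raise RtPlanError("beam has fewer than two control points")

    n = geometry.n_pairs
    gantry = 0.0
    jaw_x = (-200.0, 200.0)
    jaw_y = (float(geometry.leaf_boundaries[0]), float(geometry.leaf_boundaries[-1]))
    leaves: np.ndarray | None = None
    weights: list[float] = []
    states: list[tuple[float, np.ndarray, tuple, tuple]] = []

    for cp in cps:
        if Tag.GantryAngle in cp:
            gantry = float(cp[Tag.GantryAngle]) % 360.0
        pos = _device_positions(cp)
        for kind in _X_JAW_TYPES:
            if kind in pos:
                jaw_x = (float(pos[kind][0]), float(pos[kind][1]))
        for kind in _Y_JAW_TYPES:
            if kind in pos:
                jaw_y = (float(pos[kind][0]), float(pos[kind][1]))
        if mlc_type in pos:
            vals = np.asarray(pos[mlc_type], dtype=float)
            if vals.size != 2 * n:
                raise UnsupportedDeviceError(
                    f"MLC position list has {vals.size} values; expected {2 * n}"
                )
            leaves = vals
        if leaves is None:
            raise UnsupportedDeviceError(
                "first control point carries no MLC positions"
            )
        weights.append(float(cp.get(Tag.CumulativeMetersetWeight, len(weights))))
        states.append((gantry, leaves.copy(), jaw_x, jaw_y))

    mu = control_point_mu(weights, beam_mu, mode=mu_mode)
    records = []
    for i, (ang, vals, jx, jy) in enumerate(states):
        shape = ApertureShape(
            left=vals[:n],
            right=vals[n:],
            jaws=(jx[0], jx[1], jy[0], jy[1]),
            geometry=geometry,
        )
        records.append(
            ControlPointRecord(
                index=i,
                gantry_angle=ang,
                mu=float(mu[i]),
                aperture=shape,
                cumulative_weight=weights[i],
            )
        )
    beam_id = str(beam.get(Tag.BeamName) or beam.get(Tag.BeamNumber) or "beam")
    return Arc(
        beam_id=beam_id,
        beam_mu=beam_mu,
        control_points=records,
        geometry=geometry,
        is_vmat=is_vmat,
    )


def read_rtplan(path: str, mu_mode: str = "midpoint") -> Plan:
    """Read a DICOM RTPLAN file into the internal plan model.

    One :class:`Arc` is built per treatment beam that carries an MLC device.
    Setup beams and beams with zero meterset are skipped with a warning.
    Leaf positions are sign-normalized (left <= right) by the aperture
    constructor; jaw and MLC positions are carried forward from the last
    control point that specified them.
    """
    ds = _dicom.read_dicom(path)
    modality = ds.get(Tag.Modality)
    if modality != "RTPLAN":
        raise NotRtPlanError(f"{path}: modality is {modality!r}, not an RTPLAN")
    metersets = _beam_metersets(ds)
    arcs: list[Arc] = []
    saw_mlc = False
    for beam in ds.get(Tag.BeamSequence, []):
        name = str(beam.get(Tag.BeamName) or beam.get(Tag.BeamNumber) or "?")
        if beam.get(Tag.TreatmentDeliveryType) == "SETUP":
            log.warning("skipping setup beam %s", name)
            continue
        beam_mu = metersets.get(int(beam.get(Tag.BeamNumber, -1)), 0.0)
        if beam_mu <= 0:
            log.warning("skipping beam %s with zero meterset", name)
            continue
        has_mlc = any(
            dev.get(Tag.RTBeamLimitingDeviceType) in _MLC_TYPES
            for dev in beam.get(Tag.BeamLimitingDeviceSequence, [])
        )
        if not has_mlc:
            log.warning("skipping beam %s without an MLC device", name)
            continue
        saw_mlc = True
        arcs.append(_read_beam(beam, beam_mu, mu_mode))
    if not saw_mlc:
        raise NoMlcBeamError(f"{path}: no beam carries an MLC sequence")
    plan_id = str(ds.get(Tag.RTPlanLabel) or ds.get(Tag.SOPInstanceUID) or path)
    return Plan(plan_id=plan_id, arcs=arcs, site_label=ds.get(Tag.RTPlanName) or None)
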