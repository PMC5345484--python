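"""Synthetic plans and cohorts for testing and calibration without clinical data.

Generators produce the internal plan model directly; ``write_rtplan``
serializes any plan to a minimal but valid DICOM RTPLAN file (dynamic-gantry
beam with MLC, jaw and cumulative-meterset sequences) so the reader can be
exercised round-trip.  All randomness is seeded.  Generated coordinates are
quantized (0.01 mm positions, 1e-6 meterset weights, 0.1 deg angles) so the
decimal-string DICOM encoding round-trips bit-exactly.

The labeled-cohort simulator draws complexities from zero-truncated normal
distributions per QA outcome class.  It is a stand-in for machinery testing:
real institutional complexity histograms are skewed, and the simulator makes
no attempt to reproduce that shape.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._dicom import RTPLAN_SOP_CLASS, Tag, write_dicom
from .cohort import CohortRecord
from .mlc import ApertureShape, MlcGeometry
from .rtplan import Arc, ControlPointRecord, Plan, control_point_mu

__all__ = [
    "ModulationSpec",
    "CohortSpec",
    "default_mlc_geometry",
    "make_rectangle_plan",
    "make_modulated_plan",
    "simulate_cohort",
    "cohort_from_counts",
    "write_rtplan",
]

# Reference-cohort class moments (mm^-1) used as simulator defaults.
DEFAULT_MEAN_PASS = 0.132
DEFAULT_SD_PASS = 0.036
DEFAULT_MEAN_FAIL = 0.170
DEFAULT_SD_FAIL = 0.040
DEFAULT_N_PASS = 649
DEFAULT_N_FAIL = 62


def default_mlc_geometry() -> MlcGeometry:
    """Millennium-style 60-pair bank: 10 outer 10 mm pairs each side, 40 central 5 mm."""
    edges = np.concatenate(
        [
            np.arange(-200.0, -100.0, 10.0),
            np.arange(-100.0, 100.0, 5.0),
            np.arange(100.0, 200.0 + 1e-9, 10.0),
        ]
    )
    return MlcGeometry(edges)


@dataclass(frozen=True)
class ModulationSpec:
    """Controls for the modulated-arc generator."""

    n_control_points: int = 90
    arc_span: float = 358.0  # degrees
    target_radius: float = 30.0  # mm
    sigma: float = 0.0  # mm, leaf-retraction perturbation scale
    seed: int = 0
    mu_total: float = 400.0
    geometry: MlcGeometry = field(default_factory=default_mlc_geometry)

    def __post_init__(self) -> None:
        if self.n_control_points < 2:
            raise ValueError("n_control_points must be >= 2")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.target_radius <= 0:
            raise ValueError("target_radius must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Controls for the labeled-cohort simulator."""

    n_pass: int = DEFAULT_N_PASS
    n_fail: int = DEFAULT_N_FAIL
    mean_pass: float = DEFAULT_MEAN_PASS
    sd_pass: float = DEFAULT_SD_PASS
    mean_fail: float = DEFAULT_MEAN_FAIL
    sd_fail: float = DEFAULT_SD_FAIL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_pass <= 0 or self.mean_fail <= 0:
            raise ValueError("class means must be > 0")
        if self.sd_pass < 0 or self.sd_fail < 0:
            raise ValueError("class SDs must be >= 0")


def _uniform_weights(n_cp: int) -> np.ndarray:
    w = np.round(np.linspace(0.0, 1.0, n_cp), 6)
    w[-1] = 1.0
    return w


def _angles(n_cp: int, arc_span: float, start: float = 180.0) -> np.ndarray:
    return np.round((start + np.linspace(0.0, arc_span, n_cp)) % 360.0, 1)


def _build_arc(
    beam_id: str,
    beam_mu: float,
    geometry: MlcGeometry,
    angles: np.ndarray,
    weights: np.ndarray,
    lefts: np.ndarray,
    rights: np.ndarray,
    jaws: tuple[float, float, float, float],
) -> Arc:
    mu = control_point_mu(weights, beam_mu)
    cps = [
        ControlPointRecord(
            index=i,
            gantry_angle=float(angles[i]),
            mu=float(mu[i]),
            cumulative_weight=float(weights[i]),
            aperture=ApertureShape(
                left=lefts[i], right=rights[i], jaws=jaws, geometry=geometry
            ),
        )
        for i in range(len(weights))
    ]
    return Arc(beam_id=beam_id, beam_mu=beam_mu, control_points=cps, geometry=geometry)


def make_rectangle_plan(
    width: float,
    n_bands: int = 10,
    n_cp: int = 12,
    mu_total: float = 200.0,
    geometry: MlcGeometry | None = None,
) -> Plan:
    """Plan whose every aperture is one identical rectangle spanning whole bands.

    The rectangle opens ``n_bands`` central leaf pairs to ``width`` mm, so
    the plan complexity is analytically ``2*width / (width*height) = 2/height``
    with ``height`` the summed band heights.
    """
    geometry = geometry or default_mlc_geometry()
    if width <= 0:
        raise ValueError("width must be > 0")
    span = float(geometry.leaf_boundaries[-1] - geometry.leaf_boundaries[0])
    if width > span:
        raise ValueError(f"width {width} exceeds the leaf travel range {span}")
    if not 1 <= n_bands <= geometry.n_pairs:
        raise ValueError("n_bands must be between 1 and the number of leaf pairs")
    start = (geometry.n_pairs - n_bands) // 2
    open_pairs = np.zeros(geometry.n_pairs, dtype=bool)
    open_pairs[start : start + n_bands] = True
    y_lo = float(geometry.leaf_boundaries[start])
    y_hi = float(geometry.leaf_boundaries[start + n_bands])

    lefts = np.where(open_pairs, -width / 2.0, 0.0)
    rights = np.where(open_pairs, width / 2.0, 0.0)
    n = n_cp
    jaws = (-width / 2.0 - 5.0, width / 2.0 + 5.0, y_lo - 5.0, y_hi + 5.0)
    arc = _build_arc(
        beam_id="CW1",
        beam_mu=mu_total,
        geometry=geometry,
        angles=_angles(n, 358.0),
        weights=_uniform_weights(n),
        lefts=np.tile(lefts, (n, 1)),
        rights=np.tile(rights, (n, 1)),
        jaws=jaws,
    )
    height = y_hi - y_lo
    return Plan(plan_id=f"RECT-{width:g}x{height:g}", arcs=[arc])


def make_modulated_plan(spec: ModulationSpec) -> Plan:
    """Arc conformal to a circular target, with seeded inward leaf retraction.

    The base aperture at every gantry angle is the circle of
    ``target_radius`` projected at isocenter (a sphere projects to the same
    circle at every angle).  Each open leaf tip is then retracted inward by
    an independent ``|Normal(0, sigma)|`` draw, which adds staircase
    perimeter faster than it removes area, so expected complexity grows with
    ``sigma``; ``sigma = 0`` reproduces the conformal plan exactly.
    """
    geo = spec.geometry
    rng = np.random.default_rng(spec.seed)
    r = spec.target_radius
    mids = (geo.leaf_boundaries[:-1] + geo.leaf_boundaries[1:]) / 2.0
    inside = np.abs(mids) < r
    half = np.where(inside, np.sqrt(np.maximum(r * r - mids * mids, 0.0)), 0.0)

    n = spec.n_control_points
    lefts = np.zeros((n, geo.n_pairs))
    rights = np.zeros((n, geo.n_pairs))
    for i in range(n):
        left = -half.copy()
        right = half.copy()
        if spec.sigma > 0:
            left = left + np.abs(rng.normal(0.0, spec.sigma, geo.n_pairs)) * inside
            right = right - np.abs(rng.normal(0.0, spec.sigma, geo.n_pairs)) * inside
        closed = right - left <= 0
        left[closed] = 0.0
        right[closed] = 0.0
        lefts[i] = np.round(left, 2)
        rights[i] = np.round(right, 2)

    pad = 10.0
    jaws = (-r - pad, r + pad, -r - pad, r + pad)
    arc = _build_arc(
        beam_id="CW1",
        beam_mu=spec.mu_total,
        geometry=geo,
        angles=_angles(n, spec.arc_span),
        weights=_uniform_weights(n),
        lefts=lefts,
        rights=rights,
        jaws=jaws,
    )
    return Plan(plan_id=f"MOD-r{r:g}-s{spec.sigma:g}-seed{spec.seed}", arcs=[arc])


def simulate_cohort(spec: CohortSpec) -> list[CohortRecord]:
    """Labeled cohort with zero-truncated-normal complexities per QA class."""
    rng = np.random.default_rng(spec.seed)

    def draw(n: int, mean: float, sd: float) -> np.ndarray:
        if n == 0:
            return np.empty(0)
        if sd == 0:
            return np.full(n, mean)
        a = (0.0 - mean) / sd
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)

    records = [
        CohortRecord(
            plan_id=f"pass-{i:05d}",
            site="synthetic",
            fractionation="unknown",
            complexity=float(c),
            qa_pass=True,
        )
        for i, c in enumerate(draw(spec.n_pass, spec.mean_pass, spec.sd_pass))
    ]
    records += [
        CohortRecord(
            plan_id=f"fail-{i:05d}",
            site="synthetic",
            fractionation="unknown",
            complexity=float(c),
            qa_pass=False,
        )
        for i, c in enumerate(draw(spec.n_fail, spec.mean_fail, spec.sd_fail))
    ]
    return records


def cohort_from_counts(
    rows: list[tuple[str, str, int, int, int, int]],
    threshold: float = 0.18,
    margin: float = 0.02,
) -> list[CohortRecord]:
    """Deterministic labeled cohort realizing given contingency counts exactly.

    Each row is ``(site, fractionation, n_total, n_fail, n_above,
    n_fail_above)``; records get complexity ``threshold + margin`` when they
    must sit above the threshold and ``threshold - margin`` otherwise, so
    every count is reproduced exactly at that threshold.  Useful for
    verifying contingency arithmetic against published summary tables.
    """
    records: list[CohortRecord] = []
    for site, fx, n_total, n_fail, n_above, n_fail_above in rows:
        if not (0 <= n_fail_above <= min(n_fail, n_above)):
            raise ValueError(f"{site}/{fx}: n_fail_above inconsistent with counts")
        n_pass_above = n_above - n_fail_above
        if n_pass_above > n_total - n_fail:
            raise ValueError(f"{site}/{fx}: more above-threshold passes than passes")
        cells = (
            ("fa", n_fail_above, False, threshold + margin),
            ("fb", n_fail - n_fail_above, False, threshold - margin),
            ("pa", n_pass_above, True, threshold + margin),
            ("pb", n_total - n_fail - n_pass_above, True, threshold - margin),
        )
        for cell, count, qa_pass, complexity in cells:
            records += [
                CohortRecord(
                    plan_id=f"{site}-{fx}-{cell}-{i:04d}",
                    site=site,
                    fractionation=fx,
                    complexity=complexity,
                    qa_pass=qa_pass,
                )
                for i in range(count)
            ]
    return records


def _jaw_item(kind: str, lo: float, hi: float) -> dict:
    return {
        Tag.RTBeamLimitingDeviceType: kind,
        Tag.LeafJawPositions: [lo, hi],
    }


def write_rtplan(plan: Plan, path: str) -> None:
    """Serialize a plan model to a minimal DICOM RTPLAN file."""
    beams = []
    refs = []
    for bi, arc in enumerate(plan.arcs, start=1):
        geo = arc.geometry
        n = geo.n_pairs
        cps = []
        for cp in arc.control_points:
            x_lo, x_hi, y_lo, y_hi = cp.aperture.jaws
            item = {
                Tag.ControlPointIndex: cp.index,
                Tag.GantryAngle: cp.gantry_angle,
                Tag.CumulativeMetersetWeight: cp.cumulative_weight,
                Tag.BeamLimitingDevicePositionSequence: [
                    _jaw_item("ASYMX", x_lo, x_hi),
                    _jaw_item("ASYMY", y_lo, y_hi),
                    {
                        Tag.RTBeamLimitingDeviceType: "MLCX",
                        Tag.LeafJawPositions: list(cp.aperture.left)
                        + list(cp.aperture.right),
                    },
                ],
            }
            cps.append(item)
        beams.append(
            {
                Tag.BeamNumber: bi,
                Tag.BeamName: arc.beam_id,
                Tag.BeamType: "DYNAMIC" if arc.is_vmat else "STATIC",
                Tag.RadiationType: "PHOTON",
                Tag.TreatmentDeliveryType: "TREATMENT",
                Tag.BeamLimitingDeviceSequence: [
                    {Tag.RTBeamLimitingDeviceType: "ASYMX"},
                    {Tag.RTBeamLimitingDeviceType: "ASYMY"},
                    {
                        Tag.RTBeamLimitingDeviceType: "MLCX",
                        Tag.NumberOfLeafJawPairs: n,
                        Tag.LeafPositionBoundaries: list(geo.leaf_boundaries),
                    },
                ],
                Tag.NumberOfControlPoints: len(arc.control_points),
                Tag.FinalCumulativeMetersetWeight: arc.control_points[-1].cumulative_weight,
                Tag.ControlPointSequence: cps,
            }
        )
        refs.append({Tag.ReferencedBeamNumber: bi, Tag.BeamMeterset: arc.beam_mu})
    dataset = {
        Tag.SOPClassUID: RTPLAN_SOP_CLASS,
        Tag.SOPInstanceUID: "1.2.826.0.1.3680043.8.498.1."
        + str(zlib.crc32(plan.plan_id.encode()) % 10**8),
        Tag.Modality: "RTPLAN",
        Tag.RTPlanLabel: plan.plan_id,
        Tag.PatientID: "SYNTH",
        Tag.FractionGroupSequence: [
            {Tag.NumberOfFractionsPlanned: 1, Tag.ReferencedBeamSequence: refs}
        ],
        Tag.BeamSequence: beams,
    }
    if plan.site_label:
        dataset[Tag.RTPlanName] = plan.site_label
    write_dicom(path, dataset)
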