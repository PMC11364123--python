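"""Treatment-plan model and I/O for sliding-window (dynamic MLC) IMRT plans.

The in-memory model is deliberately small: a :class:`Plan` holds beams, each
beam an ordered sequence of control points carrying the two MLC bank
positions, the jaw window and the cumulative meterset fraction.  Everything
downstream (kinematics, complexity metrics, the synthetic dose engine)
consumes only this model, so plans can enter either from DICOM-RT Plan files
or from a simple versioned JSON dialect that is convenient to generate and
diff.

Conventions
-----------
* Leaf positions are millimetres in the IEC beam-limiting-device frame along
  the leaf-travel axis (x).  Bank A is the larger-coordinate side, bank B the
  smaller, so the leaf-pair gap is ``bank_a - bank_b >= 0``.  A closed pair
  has gap 0; a small tolerance (``CLOSED_TOL_MM``) absorbs vendor round-off.
* Only dynamic (sliding-window) beams are modelled; static or step-and-shoot
  beams are rejected, mirroring a SW-IMRT-only clinical workflow.
* Cumulative meterset fractions must be non-decreasing, starting at 0 and
  ending at 1; at fixed dose rate they define the delivery time axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

#: mm tolerance below which a leaf-pair gap is treated as closed.
CLOSED_TOL_MM = 1e-6

#: Dose rate assumed when a plan file does not state one (MU/min).
DEFAULT_DOSE_RATE = 400.0

SITES = ("head_and_neck", "chest_and_abdomen", "pelvis", "limbs")

JSON_SCHEMA_VERSION = "1"


class PlanValidationError(ValueError):
    """A plan, beam or control point violates a model invariant."""


@dataclass(frozen=True)
class ControlPoint:
    """One machine-state snapshot of a dynamic MLC delivery.

    Parameters
    ----------
    index:
        Ordinal position within the beam.
    cumulative_meterset_fraction:
        Fraction of the beam meterset delivered up to this snapshot, in [0, 1].
    bank_a_positions, bank_b_positions:
        Leaf positions (mm) for the two banks, one entry per leaf pair.
        Bank A is the larger-coordinate side: ``bank_b <= bank_a`` pairwise.
    jaw_x, jaw_y:
        Jaw windows (mm) as (low, high) along the leaf-travel axis (x) and
        the leaf-stacking axis (y).
    """

    index: int
    cumulative_meterset_fraction: float
    bank_a_positions: np.ndarray
    bank_b_positions: np.ndarray
    jaw_x: tuple[float, float]
    jaw_y: tuple[float, float]

    def __post_init__(self):
        a = np.asarray(self.bank_a_positions, dtype=float)
        b = np.asarray(self.bank_b_positions, dtype=float)
        object.__setattr__(self, "bank_a_positions", a)
        object.__setattr__(self, "bank_b_positions", b)
        if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
            raise PlanValidationError(
                f"control point {self.index}: bank arrays must be 1-D and of "
                f"equal length (got {a.shape} vs {b.shape})"
            )
        cmf = self.cumulative_meterset_fraction
        if not (0.0 - 1e-12 <= cmf <= 1.0 + 1e-12):
            raise PlanValidationError(
                f"control point {self.index}: cumulative meterset fraction "
                f"{cmf} outside [0, 1]"
            )
        gap = a - b
        bad = np.nonzero(gap < -CLOSED_TOL_MM)[0]
        if bad.size:
            raise PlanValidationError(
                f"control point {self.index}: bank_b > bank_a at leaf index "
                f"{int(bad[0])} (gap {gap[bad[0]]:.6g} mm)"
            )
        if self.jaw_x[1] < self.jaw_x[0] or self.jaw_y[1] < self.jaw_y[0]:
            raise PlanValidationError(
                f"control point {self.index}: jaw window inverted"
            )

    @property
    def n_leaf_pairs(self) -> int:
        return self.bank_a_positions.size

    @property
    def gaps(self) -> np.ndarray:
        """Leaf-pair gaps (mm), clipped to >= 0 within the closed tolerance."""
        return np.clip(self.bank_a_positions - self.bank_b_positions, 0.0, None)


@dataclass(frozen=True)
class Beam:
    """A dynamic MLC beam: meterset, dose rate and the control-point track."""

    id: str
    meterset: float  # MU
    dose_rate: float  # MU/min
    control_points: tuple[ControlPoint, ...]
    leaf_boundaries: np.ndarray  # mm, length n_leaf_pairs + 1

    def __post_init__(self):
        cps = tuple(self.control_points)
        object.__setattr__(self, "control_points", cps)
        lb = np.asarray(self.leaf_boundaries, dtype=float)
        object.__setattr__(self, "leaf_boundaries", lb)
        if len(cps) < 2:
            raise PlanValidationError(f"beam {self.id!r}: needs >= 2 control points")
        if self.meterset <= 0:
            raise PlanValidationError(f"beam {self.id!r}: meterset must be > 0")
        if self.dose_rate <= 0:
            raise PlanValidationError(f"beam {self.id!r}: dose rate must be > 0")
        if np.any(np.diff(lb) <= 0):
            raise PlanValidationError(
                f"beam {self.id!r}: leaf boundaries must be strictly increasing"
            )
        n_pairs = cps[0].n_leaf_pairs
        if lb.size != n_pairs + 1:
            raise PlanValidationError(
                f"beam {self.id!r}: {lb.size} leaf boundaries for {n_pairs} "
                f"leaf pairs (need n_pairs + 1)"
            )
        cmf = np.array([cp.cumulative_meterset_fraction for cp in cps])
        if abs(cmf[0]) > 1e-9 or abs(cmf[-1] - 1.0) > 1e-9:
            raise PlanValidationError(
                f"beam {self.id!r}: meterset fractions must start at 0 and end "
                f"at 1 (got {cmf[0]}..{cmf[-1]})"
            )
        dec = np.nonzero(np.diff(cmf) < 0)[0]
        if dec.size:
            raise PlanValidationError(
                f"beam {self.id!r}: cumulative meterset fraction decreases at "
                f"control point {int(dec[0]) + 1}"
            )
        for cp in cps:
            if cp.n_leaf_pairs != n_pairs:
                raise PlanValidationError(
                    f"beam {self.id!r}: control point {cp.index} has "
                    f"{cp.n_leaf_pairs} leaf pairs, expected {n_pairs}"
                )

    @property
    def n_control_points(self) -> int:
        return len(self.control_points)

    @property
    def n_leaf_pairs(self) -> int:
        return self.control_points[0].n_leaf_pairs

    @property
    def leaf_heights(self) -> np.ndarray:
        """Leaf-pair heights (mm) from the boundary array."""
        return np.diff(self.leaf_boundaries)

    @property
    def meterset_fractions(self) -> np.ndarray:
        return np.array(
            [cp.cumulative_meterset_fraction for cp in self.control_points]
        )


@dataclass(frozen=True)
class Plan:
    """A sliding-window IMRT plan: one treatment site, one or more beams."""

    id: str
    site: str
    prescribed_dose: float  # Gy
    beams: tuple[Beam, ...]

    def __post_init__(self):
        object.__setattr__(self, "beams", tuple(self.beams))
        if not self.beams:
            raise PlanValidationError(f"plan {self.id!r}: empty beams list")
        if self.prescribed_dose <= 0:
            raise PlanValidationError(
                f"plan {self.id!r}: prescribed dose must be > 0 Gy"
            )
        if self.site not in SITES:
            raise PlanValidationError(
                f"plan {self.id!r}: unknown site {self.site!r}; expected one of {SITES}"
            )

    @property
    def total_mu(self) -> float:
        return float(sum(b.meterset for b in self.beams))


# ---------------------------------------------------------------------------
# JSON dialect


def plan_to_dict(plan: Plan) -> dict:
    """Serialize a plan to the JSON plan dialect (schema version 1)."""
    return {
        "schema": JSON_SCHEMA_VERSION,
        "id": plan.id,
        "site": plan.site,
        "prescribed_dose_gy": plan.prescribed_dose,
        "beams": [
            {
                "id": b.id,
                "meterset_mu": b.meterset,
                "dose_rate_mu_min": b.dose_rate,
                "leaf_boundaries_mm": b.leaf_boundaries.tolist(),
                "control_points": [
                    {
                        "cmf": cp.cumulative_meterset_fraction,
                        "bank_a_mm": cp.bank_a_positions.tolist(),
                        "bank_b_mm": cp.bank_b_positions.tolist(),
                        "jaw_x_mm": list(cp.jaw_x),
                        "jaw_y_mm": list(cp.jaw_y),
                    }
                    for cp in b.control_points
                ],
            }
            for b in plan.beams
        ],
    }


def _require(d: dict, key: str, path: str):
    if key not in d:
        raise PlanValidationError(f"missing field {path}.{key}")
    return d[key]


def plan_from_dict(doc: dict) -> Plan:
    """Build a plan from a JSON-dialect document, naming offending fields."""
    schema = doc.get("schema")
    if schema != JSON_SCHEMA_VERSION:
        raise PlanValidationError(
            f"unsupported schema {schema!r} (expected {JSON_SCHEMA_VERSION!r}) at $.schema"
        )
    beams = []
    for i, bd in enumerate(_require(doc, "beams", "$")):
        bpath = f"$.beams[{i}]"
        cps = []
        for j, cpd in enumerate(_require(bd, "control_points", bpath)):
            cpath = f"{bpath}.control_points[{j}]"
            cps.append(
                ControlPoint(
                    index=j,
                    cumulative_meterset_fraction=_require(cpd, "cmf", cpath),
                    bank_a_positions=np.asarray(_require(cpd, "bank_a_mm", cpath), float),
                    bank_b_positions=np.asarray(_require(cpd, "bank_b_mm", cpath), float),
                    jaw_x=tuple(_require(cpd, "jaw_x_mm", cpath)),
                    jaw_y=tuple(_require(cpd, "jaw_y_mm", cpath)),
                )
            )
        beams.append(
            Beam(
                id=str(_require(bd, "id", bpath)),
                meterset=_require(bd, "meterset_mu", bpath),
                dose_rate=bd.get("dose_rate_mu_min", DEFAULT_DOSE_RATE),
                control_points=tuple(cps),
                leaf_boundaries=np.asarray(_require(bd, "leaf_boundaries_mm", bpath), float),
            )
        )
    return Plan(
        id=str(_require(doc, "id", "$")),
        site=_require(doc, "site", "$"),
        prescribed_dose=_require(doc, "prescribed_dose_gy", "$"),
        beams=tuple(beams),
    )


def write_json_plan(plan: Plan, path: str | Path) -> None:
    Path(path).write_text(json.dumps(plan_to_dict(plan), indent=1))


def read_json_plan(path: str | Path) -> Plan:
    with open(path) as fh:
        doc = json.load(fh)
    return plan_from_dict(doc)


# ---------------------------------------------------------------------------
# DICOM-RT Plan


def _is_dynamic_mlc_beam(beam_ds) -> bool:
    """True when the beam is a treatment beam delivered with a moving MLC."""
    if getattr(beam_ds, "TreatmentDeliveryType", "TREATMENT") != "TREATMENT":
        return False
    # Dynamic delivery: MLC positions present in >1 control point.
    n_with_mlc = 0
    for cp in beam_ds.ControlPointSequence:
        for bld in getattr(cp, "BeamLimitingDevicePositionSequence", []):
            if bld.RTBeamLimitingDeviceType in ("MLCX", "MLCY"):
                n_with_mlc += 1
                break
    return n_with_mlc > 1


def read_dicom_plan(path: str | Path, site: str = "pelvis",
                    prescribed_dose: float | None = None) -> Plan:
    """Read a DICOM-RT Plan file into the plan model.

    Only dynamic-MLC (sliding-window) treatment beams are kept; setup/imaging
    beams and static beams are excluded.  Leaf positions are taken from the
    MLCX device in mm (IEC beam-limiting-device frame); jaws default to the
    leaf-boundary extent when absent.  ``site`` and ``prescribed_dose`` may be
    supplied by the caller since RT Plan files do not carry the treatment-site
    vocabulary used here; prescription falls back to DoseReferenceSequence
    when present, else 2 Gy.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTPLAN":
        raise PlanValidationError(f"{path}: not a DICOM-RT Plan (Modality={getattr(ds, 'Modality', None)!r})")

    metersets = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            metersets[int(rb.ReferencedBeamNumber)] = float(rb.BeamMeterset)

    if prescribed_dose is None:
        prescribed_dose = 2.0
        for dr in getattr(ds, "DoseReferenceSequence", []):
            if hasattr(dr, "TargetPrescriptionDose"):
                prescribed_dose = float(dr.TargetPrescriptionDose)
                break

    beams = []
    for beam_ds in getattr(ds, "BeamSequence", []):
        if not _is_dynamic_mlc_beam(beam_ds):
            continue
        # leaf boundaries from the MLC device description
        boundaries = None
        n_pairs = None
        for bld in getattr(beam_ds, "BeamLimitingDeviceSequence", []):
            if bld.RTBeamLimitingDeviceType in ("MLCX", "MLCY"):
                n_pairs = int(bld.NumberOfLeafJawPairs)
                if hasattr(bld, "LeafPositionBoundaries"):
                    boundaries = np.asarray(bld.LeafPositionBoundaries, float)
        if n_pairs is None:
            raise PlanValidationError(
                f"beam {beam_ds.BeamName!r}: no MLC device sequence in an MLC beam"
            )
        if boundaries is None:
            boundaries = np.linspace(-5.0 * n_pairs, 5.0 * n_pairs, n_pairs + 1)

        dose_rate = DEFAULT_DOSE_RATE
        cps = []
        jaw_x = jaw_y = None
        for j, cp_ds in enumerate(beam_ds.ControlPointSequence):
            if hasattr(cp_ds, "DoseRateSet"):
                dose_rate = float(cp_ds.DoseRateSet)
            mlc = None
            for bld in getattr(cp_ds, "BeamLimitingDevicePositionSequence", []):
                kind = bld.RTBeamLimitingDeviceType
                vals = np.asarray(bld.LeafJawPositions, float)
                if kind in ("MLCX", "MLCY"):
                    mlc = vals
                elif kind in ("X", "ASYMX"):
                    jaw_x = (float(vals[0]), float(vals[1]))
                elif kind in ("Y", "ASYMY"):
                    jaw_y = (float(vals[0]), float(vals[1]))
            if mlc is None:
                raise PlanValidationError(
                    f"beam {beam_ds.BeamName!r}: missing MLC position sequence "
                    f"at control point {j}"
                )
            if mlc.size != 2 * n_pairs:
                raise PlanValidationError(
                    f"beam {beam_ds.BeamName!r}: {mlc.size} leaf positions for "
                    f"{n_pairs} pairs at control point {j}"
                )
            # DICOM order: bank B (lower x) first, then bank A.
            bank_b, bank_a = mlc[:n_pairs], mlc[n_pairs:]
            jx = jaw_x or (float(boundaries[0]), float(boundaries[-1]))
            jy = jaw_y or (float(boundaries[0]), float(boundaries[-1]))
            cps.append(
                ControlPoint(
                    index=j,
                    cumulative_meterset_fraction=float(cp_ds.CumulativeMetersetWeight),
                    bank_a_positions=bank_a,
                    bank_b_positions=bank_b,
                    jaw_x=jx,
                    jaw_y=jy,
                )
            )
        # normalize cumulative weights to [0, 1]
        final = float(getattr(beam_ds, "FinalCumulativeMetersetWeight", cps[-1].cumulative_meterset_fraction))
        if final > 0 and abs(final - 1.0) > 1e-9:
            cps = [
                ControlPoint(
                    index=cp.index,
                    cumulative_meterset_fraction=cp.cumulative_meterset_fraction / final,
                    bank_a_positions=cp.bank_a_positions,
                    bank_b_positions=cp.bank_b_positions,
                    jaw_x=cp.jaw_x,
                    jaw_y=cp.jaw_y,
                )
                for cp in cps
            ]
        beams.append(
            Beam(
                id=str(getattr(beam_ds, "BeamName", beam_ds.BeamNumber)),
                meterset=metersets.get(int(beam_ds.BeamNumber), 100.0),
                dose_rate=dose_rate,
                control_points=tuple(cps),
                leaf_boundaries=boundaries,
            )
        )
    if not beams:
        raise PlanValidationError(f"{path}: no dynamic-MLC treatment beams found")
    return Plan(
        id=str(getattr(ds, "RTPlanLabel", Path(path).stem)),
        site=site,
        prescribed_dose=prescribed_dose,
        beams=tuple(beams),
    )


def write_dicom_plan(plan: Plan, path: str | Path) -> None:
    """Write a minimal DICOM-RT Plan carrying the dynamic-MLC description.

    Intended for generating paired fixtures and for interoperability checks;
    the file contains only the beam/control-point payload the reader consumes
    (no patient demographics or references beyond required UIDs).
    """
    import pydicom
    from pydicom.dataset import Dataset, FileDataset
    from pydicom.uid import generate_uid, ExplicitVRLittleEndian

    meta = Dataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.5")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = plan.id
    ds.PatientName = "synthetic^fixture"
    ds.PatientID = plan.id

    dr = Dataset()
    dr.DoseReferenceStructureType = "SITE"
    dr.TargetPrescriptionDose = plan.prescribed_dose
    ds.DoseReferenceSequence = [dr]

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.ReferencedBeamSequence = []
    ds.FractionGroupSequence = [fg]

    ds.BeamSequence = []
    for bn, beam in enumerate(plan.beams, start=1):
        rb = Dataset()
        rb.ReferencedBeamNumber = bn
        rb.BeamMeterset = beam.meterset
        fg.ReferencedBeamSequence.append(rb)

        b = Dataset()
        b.BeamNumber = bn
        b.BeamName = beam.id
        b.TreatmentDeliveryType = "TREATMENT"
        b.BeamType = "DYNAMIC"
        b.RadiationType = "PHOTON"
        b.FinalCumulativeMetersetWeight = 1.0

        bld = Dataset()
        bld.RTBeamLimitingDeviceType = "MLCX"
        bld.NumberOfLeafJawPairs = beam.n_leaf_pairs
        bld.LeafPositionBoundaries = [float(v) for v in beam.leaf_boundaries]
        b.BeamLimitingDeviceSequence = [bld]

        b.ControlPointSequence = []
        for cp in beam.control_points:
            c = Dataset()
            c.ControlPointIndex = cp.index
            c.CumulativeMetersetWeight = cp.cumulative_meterset_fraction
            if cp.index == 0:
                c.DoseRateSet = beam.dose_rate
            seq = []
            for kind, vals in (
                ("ASYMX", list(cp.jaw_x)),
                ("ASYMY", list(cp.jaw_y)),
                ("MLCX", list(cp.bank_b_positions) + list(cp.bank_a_positions)),
            ):
                p = Dataset()
                p.RTBeamLimitingDeviceType = kind
                p.LeafJawPositions = [float(v) for v in vals]
                seq.append(p)
            c.BeamLimitingDevicePositionSequence = seq
            b.ControlPointSequence.append(c)
        ds.BeamSequence.append(b)

    ds.save_as(str(path), enforce_file_format=True)
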