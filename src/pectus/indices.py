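"""Pectus excavatum severity indices from inner-contour landmarks.

Three indices are computed on the slice with the deepest sternal depression:

* Haller index — transverse inner diameter divided by the anteroposterior
  distance from the deepest sternal point to the anterior vertebral body
  (``cd``).  Severity classes: < 3.2 mild, 3.2-3.5 moderate, > 3.5 severe
  (the moderate band is closed at both ends).
* Correction index — ``100 * (ab - cd) / ab`` percent, where ``ab`` is the
  maximal anterior extent of the inner contour above the spine tangent line.
* Asymmetry index — ``R / L``, the ratio of the maximal right- and left-
  hemithorax anteroposterior inner distances.

All distances are in centimeters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import GeometryError, LandmarkError
from .geometry import InnerLandmarks, extract_inner_contour, find_landmarks
from .phantom import AxialSlice
from .slices import SliceSelectionResult

__all__ = ["IndexSet", "PatientReport", "haller_index", "correction_index",
           "asymmetry_index", "severity", "indices_from_landmarks",
           "measure_patient", "SEVERITY_MILD_BELOW", "SEVERITY_SEVERE_ABOVE"]

# Haller-index severity thresholds; the moderate band is inclusive.
SEVERITY_MILD_BELOW = 3.2
SEVERITY_SEVERE_ABOVE = 3.5


@dataclass
class IndexSet:
    """All indices and raw distances measured on one axial slice."""

    haller: float
    correction_pct: float
    asymmetry: float
    severity: str
    transverse_cm: float
    ap_depth_cm: float
    ab_cm: float
    cd_cm: float
    L_cm: float
    R_cm: float
    slice_index: int = 0
    flags: set = field(default_factory=set)

    def as_dict(self) -> dict:
        return {
            "slice_index": self.slice_index,
            "haller": self.haller,
            "correction_pct": self.correction_pct,
            "asymmetry": self.asymmetry,
            "severity": self.severity,
            "transverse_cm": self.transverse_cm,
            "ap_depth_cm": self.ap_depth_cm,
            "ab_cm": self.ab_cm,
            "cd_cm": self.cd_cm,
            "L_cm": self.L_cm,
            "R_cm": self.R_cm,
            "flags": sorted(self.flags),
        }


@dataclass
class PatientReport:
    """Indices for the whole measurement neighborhood of one patient."""

    headline: IndexSet | None
    per_slice: list[IndexSet]
    selection: SliceSelectionResult
    status: str = "ok"
    error: str = ""


def haller_index(lm: InnerLandmarks) -> float:
    """Transverse diameter over residual sternum-to-spine distance."""
    if lm.cd_cm <= 0:
        raise GeometryError(
            "sternum at or behind the anterior vertebral line "
            f"(cd = {lm.cd_cm:.2f} cm); Haller index undefined"
        )
    return lm.transverse_cm / lm.cd_cm


def correction_index(lm: InnerLandmarks) -> float:
    """``100 * (ab - cd) / ab`` percent; flags a dent deeper than the spine line."""
    if lm.ab_cm <= 0:
        raise GeometryError(f"non-positive ab distance ({lm.ab_cm:.2f} cm)")
    if lm.cd_cm < 0:
        lm.flags.add("dent-past-spine")
    return 100.0 * (lm.ab_cm - lm.cd_cm) / lm.ab_cm


def asymmetry_index(lm: InnerLandmarks) -> float:
    """Right over left maximal hemithorax anteroposterior distance."""
    if lm.L_cm <= 0:
        raise GeometryError(f"non-positive left hemithorax chord ({lm.L_cm:.2f} cm)")
    return lm.R_cm / lm.L_cm


def severity(haller: float) -> str:
    """Severity class of a Haller index value."""
    if not haller > 0:
        raise GeometryError(f"Haller index must be positive, got {haller!r}")
    if haller < SEVERITY_MILD_BELOW:
        return "mild"
    if haller <= SEVERITY_SEVERE_ABOVE:
        return "moderate"
    return "severe"


def indices_from_landmarks(lm: InnerLandmarks, slice_index: int = 0) -> IndexSet:
    """Assemble the full index set for one slice from its landmarks."""
    h = haller_index(lm)
    return IndexSet(
        haller=h,
        correction_pct=correction_index(lm),
        asymmetry=asymmetry_index(lm),
        severity=severity(h),
        transverse_cm=lm.transverse_cm,
        ap_depth_cm=lm.cd_cm,
        ab_cm=lm.ab_cm,
        cd_cm=lm.cd_cm,
        L_cm=lm.L_cm,
        R_cm=lm.R_cm,
        slice_index=slice_index,
        flags=set(lm.flags),
    )


def measure_slice(mask, spacing_mm: float, slice_index: int = 0) -> IndexSet:
    """Mask -> contour -> landmarks -> indices for a single slice."""
    contour = extract_inner_contour(mask, spacing_mm)
    lm = find_landmarks(contour)
    return indices_from_landmarks(lm, slice_index=slice_index)


def measure_patient(
    slices: list[AxialSlice],
    masks: list,
    selection: SliceSelectionResult,
) -> PatientReport:
    """Measure every neighborhood slice; the target slice is the headline.

    A landmark failure on a non-target slice is recorded per slice; a failure
    on the target slice downgrades the report status but the remaining
    neighborhood results are still emitted.
    """
    missing = [i for i in selection.neighborhood if i >= len(masks) or masks[i] is None]
    if missing:
        raise LandmarkError(f"masks missing for neighborhood slices {missing}")
    per_slice: list[IndexSet] = []
    headline: IndexSet | None = None
    status, error = "ok", ""
    for i in selection.neighborhood:
        try:
            iset = measure_slice(masks[i], slices[i].spacing_mm, slice_index=i)
        except (GeometryError, LandmarkError) as exc:
            if i == selection.target_index:
                status, error = "error", str(exc)
            continue
        per_slice.append(iset)
        if i == selection.target_index:
            headline = iset
    if headline is None and status == "ok" and selection.target_index not in selection.neighborhood:
        # literal-six mode: the target is excluded by construction; measure it
        # separately as the headline.
        try:
            headline = measure_slice(
                masks[selection.target_index],
                slices[selection.target_index].spacing_mm,
                slice_index=selection.target_index,
            )
        except (GeometryError, LandmarkError) as exc:
            status, error = "error", str(exc)
    return PatientReport(headline=headline, per_slice=per_slice,
                         selection=selection, status=status, error=error)
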