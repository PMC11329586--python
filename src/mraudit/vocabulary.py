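"""Controlled vocabulary of audited acquisition parameters.

Each parameter name is bound to a fixed kind (numeric / categorical /
multivalued), fixed units, and source mappings: a DICOM tag (group,
element), a JSON sidecar key, and optional value transforms applied at
read time so that every reader produces values on the same scale
(milliseconds, millimetres, degrees, Hz/pixel, tesla).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

NUMERIC = "numeric"
CATEGORICAL = "categorical"
MULTIVALUED = "multivalued"

SOURCE_STANDARD = "standard-tag"
SOURCE_PRIVATE = "private-header"
SOURCE_SIDECAR = "sidecar"


@dataclass(frozen=True)
class ParameterSpec:
    """Static description of one vocabulary entry."""

    name: str
    kind: str
    units: str
    dicom_tag: Optional[tuple[int, int]] = None
    sidecar_key: Optional[str] = None
    # transform applied to the raw DICOM value: f(value, vendor) -> value
    dicom_transform: Optional[Callable] = None
    # transform applied to the raw sidecar value: f(value, vendor) -> value
    sidecar_transform: Optional[Callable] = None
    private: bool = False  # lives in a vendor private header (DICOM side)


def _seconds_to_ms(value, vendor):
    return float(value) * 1000.0


def _ge_cm_to_mm(value, vendor):
    # GE reports field-of-view in centimetres; Siemens/Philips in mm.
    v = float(value)
    if vendor and vendor.upper().startswith("GE"):
        return v * 10.0
    return v


_SPECS = [
    ParameterSpec("RepetitionTime", NUMERIC, "ms",
                  dicom_tag=(0x0018, 0x0080), sidecar_key="RepetitionTime",
                  sidecar_transform=_seconds_to_ms),
    ParameterSpec("EchoTime", NUMERIC, "ms",
                  dicom_tag=(0x0018, 0x0081), sidecar_key="EchoTime",
                  sidecar_transform=_seconds_to_ms),
    ParameterSpec("FlipAngle", NUMERIC, "degrees",
                  dicom_tag=(0x0018, 0x1314), sidecar_key="FlipAngle"),
    ParameterSpec("PhaseEncodingDirection", CATEGORICAL, "",
                  dicom_tag=(0x0018, 0x1312),
                  sidecar_key="PhaseEncodingDirection"),
    ParameterSpec("PixelBandwidth", NUMERIC, "Hz/pixel",
                  dicom_tag=(0x0018, 0x0095), sidecar_key="PixelBandwidth"),
    ParameterSpec("EchoTrainLength", NUMERIC, "",
                  dicom_tag=(0x0018, 0x0091), sidecar_key="EchoTrainLength"),
    ParameterSpec("PhaseEncodingSteps", NUMERIC, "",
                  dicom_tag=(0x0018, 0x0089), sidecar_key="PhaseEncodingSteps"),
    ParameterSpec("MagneticFieldStrength", NUMERIC, "T",
                  dicom_tag=(0x0018, 0x0087),
                  sidecar_key="MagneticFieldStrength"),
    ParameterSpec("SequenceVariant", CATEGORICAL, "",
                  dicom_tag=(0x0018, 0x0021), sidecar_key="SequenceVariant"),
    ParameterSpec("FieldOfView", NUMERIC, "mm",
                  dicom_tag=(0x0018, 0x1100), sidecar_key="FieldOfView",
                  dicom_transform=_ge_cm_to_mm),
    ParameterSpec("NumberOfSlices", NUMERIC, "",
                  dicom_tag=(0x0054, 0x0081), sidecar_key="NumberOfSlices"),
    ParameterSpec("SliceThickness", NUMERIC, "mm",
                  dicom_tag=(0x0018, 0x0050), sidecar_key="SliceThickness"),
    ParameterSpec("Angulation", NUMERIC, "degrees",
                  dicom_tag=(0x0018, 0x1120), sidecar_key="Angulation"),
    # Siemens private-header parameters (ASCCONV block). On the BIDS side
    # they may appear as plain sidecar keys.
    ParameterSpec("ShimMode", CATEGORICAL, "",
                  sidecar_key="ShimMode", private=True),
    ParameterSpec("ParallelImaging", CATEGORICAL, "",
                  sidecar_key="ParallelAcquisitionTechnique", private=True),
    ParameterSpec("MultiSliceMode", CATEGORICAL, "",
                  sidecar_key="MultiSliceMode", private=True),
]

VOCABULARY: dict[str, ParameterSpec] = {s.name: s for s in _SPECS}

#: Parameters audited by default in a horizontal audit (user-extensible).
DEFAULT_AUDIT_PARAMETERS = (
    "RepetitionTime", "EchoTime", "FlipAngle", "PhaseEncodingDirection",
    "PixelBandwidth", "EchoTrainLength", "PhaseEncodingSteps", "ShimMode",
    "ParallelImaging", "SequenceVariant", "MagneticFieldStrength",
)

#: Geometry parameters checked between a fieldmap and its paired EPI run.
FIELDMAP_GEOMETRY_PARAMETERS = (
    "FieldOfView", "NumberOfSlices", "SliceThickness", "Angulation",
)

# Phase-encoding tokens are stored source-natively (ROW/COL for DICOM,
# i/j/k with optional polarity sign for BIDS). This optional map collapses
# both dialects onto a bare axis letter; it is applied only when values
# from different sources must be compared.
PED_NORMALIZATION = {
    "ROW": "i", "COL": "j", "COLUMN": "j",
    "i": "i", "i-": "i", "j": "j", "j-": "j", "k": "k", "k-": "k",
}


def normalize_ped(token: str) -> str:
    """Map a source-native phase-encoding token onto a bare axis letter."""
    return PED_NORMALIZATION.get(token, PED_NORMALIZATION.get(token.upper(), token))


@dataclass
class TagMap:
    """Resolved parameter-name -> source-location mapping used by readers.

    Defaults to the full vocabulary; restrict or extend ``entries`` to
    change what a reader extracts.
    """

    entries: dict[str, ParameterSpec] = field(
        default_factory=lambda: dict(VOCABULARY))

    def dicom_tags(self) -> dict[tuple[int, int], ParameterSpec]:
        return {s.dicom_tag: s for s in self.entries.values()
                if s.dicom_tag is not None}

    def sidecar_keys(self) -> dict[str, ParameterSpec]:
        return {s.sidecar_key: s for s in self.entries.values()
                if s.sidecar_key is not None}
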