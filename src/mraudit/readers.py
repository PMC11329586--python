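"""Readers that populate a DatasetHierarchy from DICOM trees, BIDS trees
and flat XML reference-protocol files.

The DICOM walker is layout-agnostic: files are discovered by content
(preamble magic or a parseable header), grouped by SeriesInstanceUID, and
one representative instance per series (lowest InstanceNumber) supplies
the parameter map. Siemens private headers are parsed for shim / parallel
imaging / multi-slice mode; GE and Philips private headers are skipped.
"""

from __future__ import annotations

import json
import logging
import os
import re
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Any, Optional

from . import dicomlite
from .compliance import ReferenceProtocol
from .model import DatasetHierarchy, ParameterValue, Run, normalize_modality_label
from .vocabulary import (CATEGORICAL, NUMERIC, SOURCE_PRIVATE, SOURCE_SIDECAR,
                         SOURCE_STANDARD, VOCABULARY, TagMap)

logger = logging.getLogger(__name__)


class EmptyDatasetError(ValueError):
    """A scan found no usable imaging files at all."""


# ----------------------------------------------------------------------
# Siemens private header (CSA ASCCONV text block)

_ASCCONV_BEGIN = "### ASCCONV BEGIN"
_ASCCONV_END = "### ASCCONV END ###"

PAT_MODES = {1: "NONE", 2: "GRAPPA", 3: "SENSE"}
SHIM_MODES = {0: "NONE", 1: "STANDARD", 2: "ADVANCED", 4: "TUNE_UP"}
MULTI_SLICE_MODES = {1: "SEQUENTIAL", 2: "INTERLEAVED", 4: "SINGLESHOT"}

_ASC_KEYS = {
    "sPat.ucPATMode": ("ParallelImaging", PAT_MODES),
    "sAdjData.uiAdjShimMode": ("ShimMode", SHIM_MODES),
    "sKSpace.ucMultiSliceMode": ("MultiSliceMode", MULTI_SLICE_MODES),
}


def _decode_asc_scalar(text: str, codes: dict[int, str]) -> str:
    text = text.strip()
    if text.startswith('"') and text.endswith('"'):
        return text.strip('"')
    try:
        code = int(text, 16) if text.lower().startswith("0x") else int(text)
    except ValueError:
        return text
    return codes.get(code, f"CODE_{code}")


def parse_siemens_private(header: bytes) -> dict[str, ParameterValue]:
    """Extract shim / iPAT / multi-slice settings from a CSA-style series
    header containing an ASCCONV text block.

    Malformed or absent blocks yield an empty map, never an exception.
    """
    try:
        text = header.decode("latin-1")
    except Exception:
        return {}
    begin = text.find(_ASCCONV_BEGIN)
    if begin < 0:
        return {}
    end = text.find(_ASCCONV_END, begin)
    if end < 0:
        logger.warning("truncated ASCCONV block; private parameters skipped")
        return {}
    body = text[text.index("\n", begin) + 1 if "\n" in text[begin:end] else begin:end]
    out: dict[str, ParameterValue] = {}
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, _, raw = line.partition("=")
        key = key.strip()
        if key in _ASC_KEYS:
            name, codes = _ASC_KEYS[key]
            token = _decode_asc_scalar(raw, codes)
            out[name] = ParameterValue.from_vocab(name, token,
                                                 source=SOURCE_PRIVATE)
    return out


# ----------------------------------------------------------------------
# DICOM tree

def _coerce(spec, raw: Any, vendor: str) -> Any:
    """Apply the vocabulary transform and coerce onto the canonical type."""
    if spec.dicom_transform is not None:
        raw = spec.dicom_transform(raw, vendor)
    if spec.kind == NUMERIC:
        if isinstance(raw, (list, tuple)):
            raw = raw[0]
        return float(raw)
    if spec.kind == CATEGORICAL:
        if isinstance(raw, (list, tuple)):
            raw = raw[0]
        return str(raw)
    if isinstance(raw, (list, tuple)):
        return tuple(raw)
    return (raw,)


def extract_instance_record(tags: dict[tuple[int, int], Any],
                            tagmap: Optional[TagMap] = None) -> dict:
    """Distil one parsed DICOM instance into a JSON-serializable record.

    Records are what the monitoring cache stores per file; a hierarchy is
    rebuilt from records without re-reading unchanged files.
    """
    tagmap = tagmap or TagMap()
    vendor = str(tags.get((0x0008, 0x0070), "")).strip()
    protocol = tags.get((0x0018, 0x1030)) or tags.get((0x0008, 0x103E)) or ""
    instance_number = tags.get((0x0020, 0x0013))
    params: dict[str, Any] = {}
    for tag, spec in sorted(tagmap.dicom_tags().items()):
        if tag in tags:
            params[spec.name] = _coerce(spec, tags[tag], vendor)
    private: dict[str, Any] = {}
    if vendor.upper().startswith("SIEMENS"):
        csa = tags.get((0x0029, 0x1020))
        if isinstance(csa, (bytes, bytearray)):
            private = {n: pv.value
                       for n, pv in parse_siemens_private(bytes(csa)).items()
                       if n in tagmap.entries}
    echo = tags.get((0x0018, 0x0086))
    return {
        "series_uid": str(tags.get((0x0020, 0x000E), "")),
        "subject_id": str(tags.get((0x0010, 0x0020), "")),
        "session_id": str(tags.get((0x0020, 0x000D), "")),
        "modality_label": normalize_modality_label(str(protocol)),
        "vendor": vendor,
        "echo_number": int(echo) if echo not in (None, "") else None,
        "instance_number": int(instance_number)
        if instance_number not in (None, "") else None,
        "acquisition_time": str(tags.get((0x0008, 0x002A), "")) or None,
        "parameters": params,
        "private_parameters": private,
    }


def run_from_record(record: dict, tagmap: Optional[TagMap] = None) -> Run:
    tagmap = tagmap or TagMap()
    params: dict[str, ParameterValue] = {}
    for name, value in record["parameters"].items():
        spec = VOCABULARY[name]
        if spec.kind not in (NUMERIC, CATEGORICAL) and isinstance(value, list):
            value = tuple(value)
        params[name] = ParameterValue.from_vocab(name, value,
                                                 source=SOURCE_STANDARD)
    for name, value in record.get("private_parameters", {}).items():
        params[name] = ParameterValue.from_vocab(name, value,
                                                 source=SOURCE_PRIVATE)
    for name, spec in tagmap.entries.items():
        if name not in params and (spec.dicom_tag is not None or spec.private):
            source = SOURCE_PRIVATE if spec.private else SOURCE_STANDARD
            params[name] = ParameterValue.missing(name, source=source)
    return Run(run_id=record["series_uid"],
               subject_id=record["subject_id"],
               session_id=record["session_id"],
               modality_label=record["modality_label"],
               vendor=record["vendor"],
               echo_number=record["echo_number"],
               acquisition_time=record["acquisition_time"],
               parameters=params)


def build_hierarchy_from_records(records: list[dict],
                                 dataset_name: str = "",
                                 tagmap: Optional[TagMap] = None
                                 ) -> DatasetHierarchy:
    """One Run per distinct series, parameters taken from the instance
    with the lowest InstanceNumber."""
    per_series: dict[str, dict] = {}
    for rec in records:
        uid = rec["series_uid"]
        if not uid:
            continue
        best = per_series.get(uid)
        new_n = rec["instance_number"]
        if best is None:
            per_series[uid] = rec
        else:
            old_n = best["instance_number"]
            if new_n is not None and (old_n is None or new_n < old_n):
                per_series[uid] = rec
    h = DatasetHierarchy(dataset_name=dataset_name, format="dicom")
    for uid in sorted(per_series):
        h.add_run(run_from_record(per_series[uid], tagmap))
    return h


def scan_dicom_tree(root: Path | str,
                    tagmap: Optional[TagMap] = None,
                    dataset_name: Optional[str] = None) -> DatasetHierarchy:
    """Walk ``root`` in any layout and build the hierarchy.

    Non-DICOM files are skipped with a logged count; unreadable files are
    warn-and-skip. A tree with zero DICOM files raises EmptyDatasetError.
    """
    root = Path(root)
    tagmap = tagmap or TagMap()
    records: list[dict] = []
    skipped = 0
    warnings: list[str] = []
    for dirpath, dirnames, filenames in os.walk(root):
        dirnames.sort()
        for fname in sorted(filenames):
            path = Path(dirpath) / fname
            try:
                if not dicomlite.is_dicom_file(path):
                    skipped += 1
                    continue
                tags = dicomlite.read_dicom(path)
            except (dicomlite.DicomParseError, OSError, ValueError) as exc:
                skipped += 1
                msg = f"skipped unreadable file {path}: {exc}"
                warnings.append(msg)
                logger.warning(msg)
                continue
            records.append(extract_instance_record(tags, tagmap))
    if not records:
        raise EmptyDatasetError(f"no DICOM files found under {root}")
    if skipped:
        logger.info("skipped %d non-DICOM/unreadable files under %s",
                    skipped, root)
    h = build_hierarchy_from_records(
        records, dataset_name=dataset_name or root.name, tagmap=tagmap)
    h.warnings.extend(warnings)
    return h


# ----------------------------------------------------------------------
# BIDS tree

_BIDS_ENTITY_RE = re.compile(r"(?P<key>[a-zA-Z0-9]+)-(?P<val>[a-zA-Z0-9+.]+)")
#: entity keys that differentiate acquisitions and join the modality label
_LABEL_ENTITIES = ("task", "acq", "dir")


def parse_bids_filename(name: str) -> tuple[dict[str, str], str]:
    """Split a BIDS basename into its entity map and trailing suffix."""
    stem = name
    for ext in (".nii.gz", ".nii", ".json"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
            break
    parts = stem.split("_")
    entities: dict[str, str] = {}
    suffix = ""
    for part in parts:
        m = _BIDS_ENTITY_RE.fullmatch(part)
        if m:
            entities[m.group("key")] = m.group("val")
        else:
            suffix = part
    return entities, suffix


def _bids_modality_label(datatype: str, entities: dict[str, str],
                         suffix: str) -> tuple[str, str]:
    ent = "_".join(f"{k}-{entities[k]}" for k in _LABEL_ENTITIES
                   if k in entities)
    pieces = [p for p in (datatype, ent, suffix) if p]
    return normalize_modality_label("_".join(pieces)), ent


def read_bids_tree(root: Path | str,
                   tagmap: Optional[TagMap] = None,
                   dataset_name: Optional[str] = None) -> DatasetHierarchy:
    """Build a hierarchy from a BIDS layout (sub-*/[ses-*]/<datatype>/).

    One Run per imaging file; parameters come from the JSON sidecar with
    sidecar-native units converted onto the canonical scale (seconds to
    ms for timing parameters). A missing sidecar yields a run whose
    parameters are all absent, flagged in ``hierarchy.warnings``.
    """
    root = Path(root)
    tagmap = tagmap or TagMap()
    key_specs = tagmap.sidecar_keys()
    h = DatasetHierarchy(dataset_name=dataset_name or root.name,
                         format="bids")
    imaging = sorted(p for p in root.rglob("*")
                     if p.name.endswith((".nii", ".nii.gz"))
                     and p.name.startswith("sub-"))
    if not imaging:
        raise EmptyDatasetError(f"no BIDS imaging files found under {root}")
    for img in imaging:
        rel = img.relative_to(root)
        entities, suffix = parse_bids_filename(img.name)
        subject = f"sub-{entities['sub']}" if "sub" in entities else rel.parts[0]
        session = f"ses-{entities['ses']}" if "ses" in entities else "1"
        datatype = img.parent.name
        label, ent_string = _bids_modality_label(datatype, entities, suffix)
        sidecar = img.with_name(img.name.replace(".nii.gz", ".nii")
                                .replace(".nii", ".json"))
        meta: Optional[dict] = None
        if sidecar.exists():
            try:
                meta = json.loads(sidecar.read_text())
            except (json.JSONDecodeError, OSError) as exc:
                msg = f"invalid sidecar {sidecar}: {exc}"
                h.warnings.append(msg)
                logger.warning(msg)
                continue
        else:
            h.warnings.append(f"missing sidecar for {rel}")
        vendor = str((meta or {}).get("Manufacturer", "")).strip()
        params: dict[str, ParameterValue] = {}
        for key, spec in key_specs.items():
            if meta is not None and key in meta:
                raw = meta[key]
                if spec.sidecar_transform is not None:
                    raw = spec.sidecar_transform(raw, vendor)
                if spec.kind == NUMERIC:
                    raw = float(raw)
                elif spec.kind == CATEGORICAL:
                    raw = str(raw)
                elif isinstance(raw, list):
                    raw = tuple(raw)
                params[spec.name] = ParameterValue.from_vocab(
                    spec.name, raw, source=SOURCE_SIDECAR)
            else:
                params[spec.name] = ParameterValue.missing(
                    spec.name, source=SOURCE_SIDECAR)
        echo = (meta or {}).get("EchoNumber")
        if echo is None and "echo" in entities:
            echo = entities["echo"]
        h.add_run(Run(run_id=str(rel),
                      subject_id=subject,
                      session_id=session,
                      modality_label=label,
                      vendor=vendor,
                      entities=ent_string,
                      echo_number=int(echo) if echo is not None else None,
                      parameters=params))
    return h


# ----------------------------------------------------------------------
# XML reference protocol

def read_reference_xml(path: Path | str) -> ReferenceProtocol:
    """Load a flat XML reference protocol:

    ``<protocol modality="..."><param name="..." value="..." units="..."/>``

    Unknown parameter names are retained and flagged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"reference protocol not found: {path}")
    tree = ET.parse(path)
    root = tree.getroot()
    ref = ReferenceProtocol(
        modality_label=normalize_modality_label(root.get("modality", "")),
        source="external")
    for el in root.findall("param"):
        name = el.get("name", "")
        raw = el.get("value", "")
        spec = VOCABULARY.get(name)
        if spec is None:
            ref.unknown_names.add(name)
            try:
                value: Any = float(raw)
                kind = NUMERIC
            except ValueError:
                value, kind = raw, CATEGORICAL
            ref.entries[name] = ParameterValue(
                name=name, value=value, kind=kind,
                units=el.get("units", ""), source=SOURCE_STANDARD)
            continue
        if spec.kind == NUMERIC:
            value = float(raw)
        elif spec.kind == CATEGORICAL:
            value = raw
        else:
            value = tuple(
                float(p) if _is_number(p) else p for p in raw.split(","))
        ref.entries[name] = ParameterValue.from_vocab(name, value)
    return ref


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def write_reference_xml(ref: ReferenceProtocol, path: Path | str) -> None:
    root = ET.Element("protocol", modality=ref.modality_label)
    for name in sorted(ref.entries):
        pv = ref.entries[name]
        if not pv.present:
            continue
        if isinstance(pv.value, tuple):
            value = ",".join(dicomlite._format_number(v)
                             if isinstance(v, (int, float)) else str(v)
                             for v in pv.value)
        elif isinstance(pv.value, (int, float)):
            value = dicomlite._format_number(pv.value)
        else:
            value = str(pv.value)
        ET.SubElement(root, "param", name=name, value=value, units=pv.units)
    ET.ElementTree(root).write(path, encoding="unicode")
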