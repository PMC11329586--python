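"""Synthetic dataset generator: on-disk DICOM and/or BIDS trees with a
known base protocol and controlled deviation injection.

Every file carries a minimal but standards-shaped payload (2x2 pixel
image for DICOM, empty NIfTI placeholder + JSON sidecar for BIDS).
A manifest records the exact ground truth: every run's final parameter
values and the injected non-compliant subject sets, so audits can be
verified for both false negatives and false positives.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

from . import dicomlite
from .model import normalize_modality_label
from .readers import MULTI_SLICE_MODES, PAT_MODES, SHIM_MODES
from .vocabulary import VOCABULARY

_UID_ROOT = "1.2.826.0.1.3680043.10.1462"

#: DICOM PED token -> BIDS sidecar token
_PED_TO_BIDS = {"ROW": "i", "COL": "j"}

_ASC_CODES = {
    "ParallelImaging": ("sPat.ucPATMode",
                        {v: k for k, v in PAT_MODES.items()}),
    "ShimMode": ("sAdjData.uiAdjShimMode",
                 {v: k for k, v in SHIM_MODES.items()}),
    "MultiSliceMode": ("sKSpace.ucMultiSliceMode",
                       {v: k for k, v in MULTI_SLICE_MODES.items()}),
}
_PRIVATE_PARAMS = tuple(_ASC_CODES)

NUMERIC_SHIFT = "numeric-shift"
CATEGORICAL_FLIP = "categorical-flip"
DROP_FIELD = "drop-field"


@dataclass
class ModalityConfig:
    """One acquisition type with its base parameter map.

    ``base`` holds canonical values: ms / mm / degrees / Hz per pixel,
    DICOM-native PED tokens (ROW/COL). Per-vendor overrides go in
    ``vendor_base``.
    """

    name: str
    base: dict[str, Any]
    datatype: str = "anat"
    suffix: str = "T1w"
    entities: dict[str, str] = field(default_factory=dict)
    vendor_base: dict[str, dict[str, Any]] = field(default_factory=dict)
    runs_per_session: int = 1
    echo_times: Optional[list[float]] = None

    def protocol_name(self) -> str:
        ent = "_".join(f"{k}-{v}" for k, v in self.entities.items())
        return "_".join(p for p in (self.datatype, ent, self.suffix) if p)

    def label(self) -> str:
        return normalize_modality_label(self.protocol_name())

    def params_for(self, vendor: str) -> dict[str, Any]:
        params = dict(self.base)
        params.update(self.vendor_base.get(vendor, {}))
        return params


@dataclass
class DeviationSpec:
    """One injected departure applied to a fraction of subjects."""

    parameter: str
    mode: str  # numeric-shift | categorical-flip | drop-field
    fraction: float
    delta: float = 0.0
    factor: Optional[float] = None
    alternate: Optional[str] = None
    modality: Optional[str] = None  # target modality name; None = all

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction out of [0, 1]: {self.fraction}")
        if self.mode not in (NUMERIC_SHIFT, CATEGORICAL_FLIP, DROP_FIELD):
            raise ValueError(f"unknown deviation mode: {self.mode}")

    def apply(self, value: Any) -> Any:
        if self.mode == NUMERIC_SHIFT:
            if self.factor is not None:
                return float(value) * self.factor
            return float(value) + self.delta
        if self.mode == CATEGORICAL_FLIP:
            return self.alternate
        return None  # drop-field


@dataclass
class FixtureConfig:
    name: str = "synthetic"
    n_subjects: int = 4
    sessions_per_subject: int = 1
    modalities: list[ModalityConfig] = field(default_factory=list)
    vendor_mix: dict[str, float] = field(
        default_factory=lambda: {"SIEMENS": 1.0})
    deviations: list[DeviationSpec] = field(default_factory=list)
    seed: int = 0
    formats: tuple[str, ...] = ("dicom",)

    def __post_init__(self):
        total = sum(self.vendor_mix.values())
        if self.vendor_mix and abs(total - 1.0) > 1e-9:
            raise ValueError(f"vendor proportions must sum to 1, got {total}")

    @classmethod
    def from_dict(cls, raw: dict) -> "FixtureConfig":
        raw = dict(raw)
        raw["modalities"] = [ModalityConfig(**m)
                             for m in raw.get("modalities", [])]
        raw["deviations"] = [DeviationSpec(**d)
                             for d in raw.get("deviations", [])]
        if "formats" in raw:
            raw["formats"] = tuple(raw["formats"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "FixtureConfig":
        import yaml
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_base_protocol() -> dict[str, Any]:
    """A plausible 3T structural protocol used by the stock fixtures."""
    return {
        "RepetitionTime": 2300.0, "EchoTime": 3.0, "FlipAngle": 9.0,
        "PhaseEncodingDirection": "ROW", "PixelBandwidth": 240.0,
        "EchoTrainLength": 1, "PhaseEncodingSteps": 255,
        "MagneticFieldStrength": 3.0, "SequenceVariant": "SP",
        "FieldOfView": 256.0, "NumberOfSlices": 176,
        "SliceThickness": 1.0, "Angulation": 0.0,
        "ShimMode": "STANDARD", "ParallelImaging": "GRAPPA",
        "MultiSliceMode": "SEQUENTIAL",
    }


def default_config(n_subjects: int = 4, seed: int = 0,
                   formats: tuple[str, ...] = ("dicom",),
                   vendor_mix: Optional[dict[str, float]] = None,
                   deviations: Optional[list[DeviationSpec]] = None
                   ) -> FixtureConfig:
    return FixtureConfig(
        n_subjects=n_subjects, seed=seed, formats=formats,
        vendor_mix=vendor_mix or {"SIEMENS": 1.0},
        deviations=deviations or [],
        modalities=[
            ModalityConfig(name="T1w", datatype="anat", suffix="T1w",
                           base=default_base_protocol()),
        ])


# ----------------------------------------------------------------------
# generation

def _subject_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"sub-{i:0{width}d}" for i in range(1, n + 1)]


def _assign_vendors(subjects: list[str], mix: dict[str, float],
                    rng: random.Random) -> dict[str, str]:
    vendors = sorted(mix)
    counts = {v: int(mix[v] * len(subjects)) for v in vendors}
    while sum(counts.values()) < len(subjects):
        # distribute the rounding remainder by largest fractional part
        leftovers = sorted(
            vendors, key=lambda v: (counts[v] - mix[v] * len(subjects), v))
        counts[leftovers[0]] += 1
    shuffled = list(subjects)
    rng.shuffle(shuffled)
    out: dict[str, str] = {}
    i = 0
    for v in vendors:
        for subject in shuffled[i:i + counts[v]]:
            out[subject] = v
        i += counts[v]
    return out


def _select_subjects(subjects: list[str], fraction: float, seed: int,
                     spec_index: int) -> list[str]:
    # first floor(p*n) subjects under a seeded shuffle: exact fraction
    # recovery, independent across deviation specs
    rng = random.Random(seed + 10007 * (spec_index + 1))
    shuffled = list(subjects)
    rng.shuffle(shuffled)
    return sorted(shuffled[:int(fraction * len(subjects))])


def _asc_block(params: dict[str, Any]) -> bytes:
    lines = ["### ASCCONV BEGIN ###"]
    for name in _PRIVATE_PARAMS:
        if name in params and params[name] is not None:
            key, codes = _ASC_CODES[name]
            token = str(params[name])
            code = codes.get(token)
            lines.append(f"{key} = {code if code is not None else _quote(token)}")
    lines.append("### ASCCONV END ###")
    return "\n".join(lines).encode("ascii")


def _quote(token: str) -> str:
    return f'"{token}"'


class _UidFactory:
    def __init__(self, seed: int):
        self.prefix = f"{_UID_ROOT}.{seed}"
        self.counter = 0

    def __call__(self) -> str:
        self.counter += 1
        return f"{self.prefix}.{self.counter}"


def _dicom_elements(subject: str, study_uid: str, series_uid: str,
                    sop_uid: str, instance_number: int, protocol_name: str,
                    vendor: str, echo_number: int,
                    params: dict[str, Any], run_index: int) -> dict:
    el: dict[tuple[int, int], Any] = {
        (0x0008, 0x0016): dicomlite.MR_IMAGE_STORAGE,
        (0x0008, 0x0018): sop_uid,
        (0x0008, 0x002A): f"202401{run_index % 28 + 1:02d}120000",
        (0x0008, 0x0060): "MR",
        (0x0008, 0x0070): vendor,
        (0x0008, 0x103E): protocol_name,
        (0x0010, 0x0010): subject,
        (0x0010, 0x0020): subject,
        (0x0018, 0x0086): echo_number,
        (0x0018, 0x1030): protocol_name,
        (0x0020, 0x000D): study_uid,
        (0x0020, 0x000E): series_uid,
        (0x0020, 0x0011): run_index + 1,
        (0x0020, 0x0013): instance_number,
        (0x0028, 0x0002): 1,
        (0x0028, 0x0010): 2,
        (0x0028, 0x0011): 2,
        (0x0028, 0x0100): 16,
        (0x0028, 0x0101): 16,
        (0x0028, 0x0102): 15,
        (0x0028, 0x0103): 0,
        (0x7FE0, 0x0010): bytes(8),
    }
    for name, value in params.items():
        if value is None or name in _PRIVATE_PARAMS:
            continue
        spec = VOCABULARY[name]
        if spec.dicom_tag is None:
            continue
        if name == "FieldOfView" and vendor.upper().startswith("GE"):
            value = float(value) / 10.0  # GE stores FoV in cm
        if name in ("EchoTrainLength", "PhaseEncodingSteps",
                    "NumberOfSlices"):
            value = int(value)
        el[spec.dicom_tag] = value
    if vendor.upper().startswith("SIEMENS"):
        block = _asc_block(params)
        if len(block) > len("### ASCCONV BEGIN ###\n### ASCCONV END ###"):
            el[(0x0029, 0x0010)] = "SIEMENS CSA HEADER"
            el[(0x0029, 0x1020)] = block
    return el


def _sidecar(vendor: str, echo_number: int,
             params: dict[str, Any]) -> dict[str, Any]:
    meta: dict[str, Any] = {"Manufacturer": vendor, "EchoNumber": echo_number}
    for name, value in params.items():
        if value is None:
            continue
        spec = VOCABULARY[name]
        key = spec.sidecar_key
        if key is None:
            continue
        if name in ("RepetitionTime", "EchoTime"):
            meta[key] = float(value) / 1000.0  # sidecars use seconds
        elif name == "PhaseEncodingDirection":
            meta[key] = _PED_TO_BIDS.get(str(value), str(value))
        elif name in ("EchoTrainLength", "PhaseEncodingSteps",
                      "NumberOfSlices"):
            meta[key] = int(value)
        else:
            meta[key] = value
    return dict(sorted(meta.items()))


def generate(config: FixtureConfig, out_dir: Path | str,
             force: bool = False) -> dict:
    """Emit the configured dataset(s) under ``out_dir`` and return the
    ground-truth manifest (also written as manifest.json)."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"output directory not empty: {out_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)

    subjects = _subject_ids(config.n_subjects)
    rng = random.Random(config.seed)
    vendor_of = _assign_vendors(subjects, config.vendor_mix, rng)

    # resolve deviation targets: (modality label or None) -> subject list
    injections: list[tuple[DeviationSpec, set[str]]] = []
    for i, spec in enumerate(config.deviations):
        chosen = _select_subjects(subjects, spec.fraction, config.seed, i)
        injections.append((spec, set(chosen)))

    uid = _UidFactory(config.seed)
    manifest_runs: list[dict] = []
    noncompliant: dict[str, set[str]] = {}
    noncompliant_by_vendor: dict[str, dict[str, set[str]]] = {}

    dicom_root = out_dir / "dicom"
    bids_root = out_dir / "bids"
    run_counter = 0
    for subject in subjects:
        vendor = vendor_of[subject]
        for ses_i in range(1, config.sessions_per_subject + 1):
            session = f"ses-{ses_i:02d}"
            study_uid = uid()
            for mod in config.modalities:
                label = mod.label()
                base = mod.params_for(vendor)
                echoes = mod.echo_times or [None]
                for run_i in range(1, mod.runs_per_session + 1):
                    for echo_i, echo_te in enumerate(echoes, start=1):
                        params = dict(base)
                        if echo_te is not None:
                            params["EchoTime"] = echo_te
                        injected: dict[str, str] = {}
                        for spec, chosen in injections:
                            if spec.modality not in (None, mod.name,
                                                     label):
                                continue
                            if subject not in chosen:
                                continue
                            if spec.parameter not in params:
                                continue
                            old = params[spec.parameter]
                            new = spec.apply(old)
                            if new == old:
                                continue
                            params[spec.parameter] = new
                            injected[spec.parameter] = spec.mode
                        if injected:
                            noncompliant.setdefault(label, set()).add(subject)
                            (noncompliant_by_vendor
                                 .setdefault(label, {})
                                 .setdefault(vendor, set()).add(subject))
                        else:
                            noncompliant.setdefault(label, set())
                            (noncompliant_by_vendor.setdefault(label, {})
                                 .setdefault(vendor, set()))
                        record = {
                            "subject_id": subject, "session_id": session,
                            "modality": mod.name, "label": label,
                            "vendor": vendor, "run_index": run_i,
                            "echo_number": echo_i,
                            "parameters": {k: v for k, v in
                                           sorted(params.items())},
                            "injected": injected,
                        }
                        if "dicom" in config.formats:
                            record["series_uid"] = _write_dicom_series(
                                dicom_root, uid, subject, session, study_uid,
                                mod, vendor, echo_i, params, run_counter,
                                run_i)
                        if "bids" in config.formats:
                            record["bids_path"] = _write_bids_run(
                                bids_root, subject, session, mod, vendor,
                                echo_i, params, run_i,
                                multi_echo=len(echoes) > 1)
                        manifest_runs.append(record)
                        run_counter += 1

    manifest = {
        "dataset_name": config.name,
        "seed": config.seed,
        "formats": sorted(config.formats),
        "n_subjects": config.n_subjects,
        "vendor_assignment": vendor_of,
        "runs": manifest_runs,
        "noncompliant_subjects": {label: sorted(s)
                                  for label, s in sorted(noncompliant.items())},
        "noncompliant_by_vendor": {
            label: {v: sorted(s) for v, s in sorted(per_vendor.items())}
            for label, per_vendor in sorted(noncompliant_by_vendor.items())},
        "deviations": [dict(asdict(spec), subjects=sorted(chosen))
                       for spec, chosen in injections],
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _write_dicom_series(root: Path, uid: _UidFactory, subject: str,
                        session: str, study_uid: str, mod: ModalityConfig,
                        vendor: str, echo_number: int,
                        params: dict[str, Any], run_counter: int,
                        run_i: int, instances: int = 1) -> str:
    series_uid = uid()
    series_dir = root / subject / session / f"{mod.name}_run-{run_i:02d}" \
        / f"echo-{echo_number}"
    series_dir.mkdir(parents=True, exist_ok=True)
    for n in range(1, instances + 1):
        elements = _dicom_elements(
            subject, study_uid, series_uid, uid(), n, mod.protocol_name(),
            vendor, echo_number, params, run_counter)
        dicomlite.write_dicom(series_dir / f"{n:04d}.dcm", elements)
    return series_uid


def _write_bids_run(root: Path, subject: str, session: str,
                    mod: ModalityConfig, vendor: str, echo_number: int,
                    params: dict[str, Any], run_i: int,
                    multi_echo: bool = False) -> str:
    parts = [subject, session]
    parts += [f"{k}-{v}" for k, v in mod.entities.items()]
    parts.append(f"run-{run_i:02d}")
    if multi_echo:
        parts.append(f"echo-{echo_number}")
    parts.append(mod.suffix)
    stem = "_".join(parts)
    run_dir = root / subject / session / mod.datatype
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / f"{stem}.nii").write_bytes(b"")
    (run_dir / f"{stem}.json").write_text(
        json.dumps(_sidecar(vendor, echo_number, params), indent=2,
                   sort_keys=True) + "\n")
    return str((run_dir / f"{stem}.nii").relative_to(root))


def generate_paired(config: FixtureConfig, out_dir: Path | str,
                    force: bool = False) -> tuple[Path, Path, dict]:
    """Emit the same acquisitions as both DICOM and BIDS trees."""
    import dataclasses
    config = dataclasses.replace(config, formats=("bids", "dicom"))
    out_dir = Path(out_dir)
    manifest = generate(config, out_dir, force=force)
    return out_dir / "dicom", out_dir / "bids", manifest
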