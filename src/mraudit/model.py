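"""In-memory dataset model: parameter values, runs, and the
modality/subject/session hierarchy with bidirectional traversal."""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

from .vocabulary import (CATEGORICAL, MULTIVALUED, NUMERIC, SOURCE_STANDARD,
                         VOCABULARY)


class DuplicateRunError(ValueError):
    """Raised when a run_id is inserted twice into a hierarchy."""


_NORMALIZE_RE = re.compile(r"[^A-Z0-9]+")


def normalize_modality_label(raw: str) -> str:
    """Grouping key for runs: uppercase, punctuation/whitespace collapsed.

    Runs are grouped by acquisition sequence (protocol name), never by
    on-disk layout, so cosmetic differences in naming must not split a
    modality.
    """
    return _NORMALIZE_RE.sub("_", raw.strip().upper()).strip("_")


@dataclass(frozen=True)
class ParameterValue:
    """One observed (or absent) acquisition-parameter value.

    ``value`` is a scalar number, a string token, or a tuple of those;
    ``kind`` and ``units`` are fixed per name by the vocabulary.
    """

    name: str
    value: Any = None
    kind: str = NUMERIC
    units: str = ""
    source: str = SOURCE_STANDARD
    present: bool = True

    def __post_init__(self):
        spec = VOCABULARY.get(self.name)
        if spec is not None:
            if self.kind != spec.kind:
                raise ValueError(
                    f"{self.name}: kind {self.kind!r} conflicts with "
                    f"vocabulary kind {spec.kind!r}")
            if self.units != spec.units:
                raise ValueError(
                    f"{self.name}: units {self.units!r} conflict with "
                    f"vocabulary units {spec.units!r}")
        if not self.present:
            if self.value is not None:
                raise ValueError(f"{self.name}: absent value must be None")
            return
        if self.kind == NUMERIC:
            if not isinstance(self.value, (int, float)) or not math.isfinite(
                    float(self.value)):
                raise ValueError(
                    f"{self.name}: numeric value must be finite, got "
                    f"{self.value!r}")
        elif self.kind == MULTIVALUED:
            if not isinstance(self.value, tuple):
                raise ValueError(f"{self.name}: multivalued value must be a tuple")

    @classmethod
    def from_vocab(cls, name: str, value: Any, source: str = SOURCE_STANDARD,
                   present: bool = True) -> "ParameterValue":
        spec = VOCABULARY[name]
        return cls(name=name, value=value if present else None,
                   kind=spec.kind, units=spec.units, source=source,
                   present=present)

    @classmethod
    def missing(cls, name: str, source: str = SOURCE_STANDARD) -> "ParameterValue":
        return cls.from_vocab(name, None, source=source, present=False)

    def to_json(self) -> dict:
        return {"name": self.name, "value": list(self.value)
                if isinstance(self.value, tuple) else self.value,
                "kind": self.kind, "units": self.units,
                "source": self.source, "present": self.present}


@dataclass
class Run:
    """One acquired series with its extracted parameter map."""

    run_id: str
    subject_id: str
    session_id: str
    modality_label: str
    vendor: str = ""
    entities: str = ""
    echo_number: Optional[int] = None
    parameters: dict[str, ParameterValue] = field(default_factory=dict)
    acquisition_time: Optional[str] = None

    def get(self, name: str) -> Optional[ParameterValue]:
        return self.parameters.get(name)

    def value_of(self, name: str) -> Any:
        pv = self.parameters.get(name)
        return pv.value if pv is not None and pv.present else None

    def sort_key(self) -> tuple:
        return (self.subject_id, self.session_id, self.run_id)

    def to_json(self) -> dict:
        return {
            "run_id": self.run_id, "subject_id": self.subject_id,
            "session_id": self.session_id,
            "modality_label": self.modality_label, "vendor": self.vendor,
            "echo_number": self.echo_number,
            "acquisition_time": self.acquisition_time,
            "parameters": {n: pv.to_json()
                           for n, pv in sorted(self.parameters.items())},
        }


class DatasetHierarchy:
    """Run collection indexed both modality-first and subject-first.

    Both indices always cover exactly the same run set, so traversal in
    either direction (all subjects of one modality for a horizontal
    audit; all modalities of one subject for a vertical audit) is
    consistent by construction.
    """

    def __init__(self, dataset_name: str = "", format: str = "dicom"):
        self.dataset_name = dataset_name
        self.format = format
        self.warnings: list[str] = []
        self._runs: dict[str, Run] = {}
        # modality -> subject -> session -> [run_id]
        self.index_by_modality: dict[str, dict[str, dict[str, list[str]]]] = {}
        # subject -> modality -> [run_id]
        self.index_by_subject: dict[str, dict[str, list[str]]] = {}

    # -- construction ---------------------------------------------------
    def add_run(self, run: Run) -> "DatasetHierarchy":
        if run.run_id in self._runs:
            raise DuplicateRunError(
                f"run_id already present: {run.run_id!r}")
        self._runs[run.run_id] = run
        (self.index_by_modality
             .setdefault(run.modality_label, {})
             .setdefault(run.subject_id, {})
             .setdefault(run.session_id, [])
             .append(run.run_id))
        (self.index_by_subject
             .setdefault(run.subject_id, {})
             .setdefault(run.modality_label, [])
             .append(run.run_id))
        return self

    # -- traversal ------------------------------------------------------
    @property
    def runs(self) -> list[Run]:
        return sorted(self._runs.values(), key=Run.sort_key)

    def __len__(self) -> int:
        return len(self._runs)

    def __contains__(self, run_id: str) -> bool:
        return run_id in self._runs

    def run(self, run_id: str) -> Run:
        return self._runs[run_id]

    @property
    def modalities(self) -> list[str]:
        return sorted(self.index_by_modality)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.index_by_subject)

    def runs_for(self, modality_label: str) -> list[Run]:
        """All runs of a modality in (subject, session, run_id) order."""
        per_subject = self.index_by_modality.get(modality_label, {})
        out = [self._runs[rid]
               for sessions in per_subject.values()
               for rids in sessions.values()
               for rid in rids]
        return sorted(out, key=Run.sort_key)

    def modalities_for(self, subject_id: str) -> set[str]:
        return set(self.index_by_subject.get(subject_id, {}))

    def runs_for_subject(self, subject_id: str,
                         modality_label: Optional[str] = None) -> list[Run]:
        per_modality = self.index_by_subject.get(subject_id, {})
        if modality_label is not None:
            rids: Iterable[str] = per_modality.get(modality_label, [])
        else:
            rids = [rid for lst in per_modality.values() for rid in lst]
        return sorted((self._runs[rid] for rid in rids), key=Run.sort_key)

    def sessions_for_subject(self, subject_id: str) -> list[str]:
        return sorted({r.session_id for r in self.runs_for_subject(subject_id)})

    # -- integrity ------------------------------------------------------
    def check_index_consistency(self) -> None:
        """Assert both indices reach exactly the stored run set."""
        via_modality = sorted(
            rid for per_subj in self.index_by_modality.values()
            for sessions in per_subj.values()
            for rids in sessions.values() for rid in rids)
        via_subject = sorted(
            rid for per_mod in self.index_by_subject.values()
            for rids in per_mod.values() for rid in rids)
        stored = sorted(self._runs)
        if not (via_modality == via_subject == stored):
            raise AssertionError("hierarchy indices are inconsistent")

    def to_json(self) -> dict:
        return {"dataset_name": self.dataset_name, "format": self.format,
                "runs": [r.to_json() for r in self.runs]}
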