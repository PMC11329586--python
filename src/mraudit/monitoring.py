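"""Incremental monitoring over a growing DICOM tree.

State is a single JSON file holding, per seen file, its size, mtime and
content fingerprint plus the extracted header record. Each audit
re-derives the hierarchy from the *current* tree (so deletions are
handled correctly); the state only lets unchanged files skip the header
re-read. The resulting report is therefore always identical to a
from-scratch batch audit of the same tree.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import dicomlite
from .compliance import ToleranceSpec, audit_all, vertical_audit
from .readers import EmptyDatasetError, build_hierarchy_from_records, \
    extract_instance_record
from .reporting import ComplianceReport, build_report
from .vocabulary import TagMap

logger = logging.getLogger(__name__)

STATE_VERSION = 1


@dataclass
class MonitorState:
    files: dict[str, dict] = field(default_factory=dict)
    last_audit: Optional[str] = None
    version: int = STATE_VERSION

    def to_json(self) -> dict:
        return {"version": self.version, "last_audit": self.last_audit,
                "files": self.files}


def load_state(path: Path | str) -> MonitorState:
    """Load monitor state; an unreadable or corrupt file degrades to a
    first-run (empty) state with a warning."""
    path = Path(path)
    if not path.exists():
        return MonitorState()
    try:
        raw = json.loads(path.read_text())
        return MonitorState(files=dict(raw.get("files", {})),
                            last_audit=raw.get("last_audit"),
                            version=int(raw.get("version", STATE_VERSION)))
    except (json.JSONDecodeError, OSError, ValueError, TypeError) as exc:
        logger.warning("unreadable state file %s (%s); treating as first run",
                       path, exc)
        return MonitorState()


def save_state(state: MonitorState, path: Path | str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(state.to_json(), indent=2, sort_keys=True)
                    + "\n")


def _fingerprint(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def detect_new(root: Path | str, state: MonitorState
               ) -> tuple[list[str], MonitorState]:
    """Return (files new or changed since the recorded state, updated
    state). A file counts as changed when its size or content
    fingerprint differs; deleted files are dropped from the state."""
    root = Path(root)
    current: dict[str, dict] = {}
    changed: list[str] = []
    for dirpath, dirnames, filenames in os.walk(root):
        dirnames.sort()
        for fname in sorted(filenames):
            path = Path(dirpath) / fname
            key = str(path.relative_to(root))
            try:
                stat = path.stat()
            except OSError:
                continue
            old = state.files.get(key)
            entry = {"size": stat.st_size, "mtime": stat.st_mtime}
            if old is None:
                entry["sha256"] = _fingerprint(path)
                changed.append(key)
            elif old.get("size") != stat.st_size:
                entry["sha256"] = _fingerprint(path)
                changed.append(key)
            elif old.get("mtime") == stat.st_mtime:
                entry["sha256"] = old.get("sha256")
                if "record" in old:
                    entry["record"] = old["record"]
            else:
                digest = _fingerprint(path)
                entry["sha256"] = digest
                if digest == old.get("sha256"):
                    if "record" in old:
                        entry["record"] = old["record"]
                else:
                    changed.append(key)
            current[key] = entry
    return changed, MonitorState(files=current, last_audit=state.last_audit)


def incremental_audit(root: Path | str,
                      state: MonitorState,
                      tol: ToleranceSpec | float = 0.0,
                      strata_keys: Sequence[str] = (),
                      tagmap: Optional[TagMap] = None,
                      dataset_name: Optional[str] = None,
                      clock=None,
                      decimals: int = 2
                      ) -> tuple[ComplianceReport, MonitorState]:
    """Audit the current tree, re-reading only new/changed files."""
    root = Path(root)
    tagmap = tagmap or TagMap()
    changed, state = detect_new(root, state)
    for key in changed:
        path = root / key
        record = None
        try:
            if dicomlite.is_dicom_file(path):
                record = extract_instance_record(
                    dicomlite.read_dicom(path), tagmap)
        except (dicomlite.DicomParseError, OSError, ValueError) as exc:
            logger.warning("skipped unreadable file %s: %s", path, exc)
        state.files[key]["record"] = record
    records = [entry["record"] for entry in state.files.values()
               if entry.get("record") is not None]
    if not records:
        raise EmptyDatasetError(f"no DICOM files found under {root}")
    h = build_hierarchy_from_records(
        records, dataset_name=dataset_name or root.name, tagmap=tagmap)
    summaries = audit_all(h, tol=tol, strata_keys=strata_keys)
    vertical = [d for subject in h.subjects
                for d in vertical_audit(h, subject)]
    t = tol.global_t if isinstance(tol, ToleranceSpec) else float(tol)
    report = build_report(h.dataset_name, summaries, tolerance=t,
                          vertical_deviations=vertical, clock=clock,
                          decimals=decimals)
    state.last_audit = report.timestamp
    return report, state
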