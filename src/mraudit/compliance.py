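"""Compliance engine: reference-protocol inference, tolerance bands,
horizontal and vertical audits, stratification.

A run is compliant when every audited parameter matches the reference;
numeric matches may use a relative tolerance band R ± t·R (inclusive),
categorical parameters always require token equality. A subject is
non-compliant as soon as a single one of its runs deviates. Per-modality
percentages are computed from subject counts:

    non-compliant % = 100 * n_noncompliant / n_total
    compliant %     = 100 * n_compliant   / n_total
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Any, Iterable, Optional, Sequence

from .model import DatasetHierarchy, ParameterValue, Run
from .vocabulary import (CATEGORICAL, DEFAULT_AUDIT_PARAMETERS,
                         FIELDMAP_GEOMETRY_PARAMETERS, NUMERIC, VOCABULARY)

logger = logging.getLogger(__name__)

#: absolute epsilon used for "absolute equivalence" at t=0, absorbing
#: float-representation noise across serialization formats
EXACT_EPSILON = 1e-6
#: slack applied at tolerance-band boundaries (bounds are inclusive)
_BOUND_EPSILON = 1e-9

MISMATCH = "mismatch"
MISSING = "missing"

UNANNOTATED = "unannotated"


# ----------------------------------------------------------------------
# domain types

@dataclass
class ReferenceProtocol:
    """Expected value per audited parameter for one modality.

    Either supplied externally (scanner XML export) or inferred from the
    data as the most frequent observed value per parameter; inference
    records per-parameter support (number of agreeing runs).
    """

    modality_label: str = ""
    entries: dict[str, ParameterValue] = field(default_factory=dict)
    source: str = "inferred"
    support: dict[str, int] = field(default_factory=dict)
    uninferable: list[str] = field(default_factory=list)
    unknown_names: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ToleranceSpec:
    """Relative tolerance level, globally and per-parameter.

    Categorical parameters ignore tolerance entirely.
    """

    global_t: float = 0.0
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for t in (self.global_t, *self.overrides.values()):
            if not 0.0 <= t <= 1.0:
                raise ValueError(f"tolerance out of [0, 1]: {t}")

    def for_name(self, name: str) -> float:
        return self.overrides.get(name, self.global_t)


@dataclass(frozen=True)
class Deviation:
    """One observed departure of a run from the reference."""

    run_id: str
    subject_id: str
    session_id: str
    parameter: str
    reference_value: Any
    observed_value: Any
    type: str  # mismatch | missing
    detail: str = ""

    def __post_init__(self):
        if self.type == MISMATCH and self.observed_value is None:
            raise ValueError("mismatch deviation requires an observed value")
        if self.type == MISSING and self.observed_value is not None:
            raise ValueError("missing deviation cannot carry an observation")

    def to_json(self) -> dict:
        return {
            "run_id": self.run_id, "subject_id": self.subject_id,
            "session_id": self.session_id, "parameter": self.parameter,
            "reference_value": _jsonable(self.reference_value),
            "observed_value": _jsonable(self.observed_value),
            "type": self.type, "detail": self.detail,
        }


def _jsonable(v: Any) -> Any:
    return list(v) if isinstance(v, tuple) else v


@dataclass
class ModalitySummary:
    """Audit outcome for one modality stratum (vendor / PED / ...)."""

    modality_label: str
    stratum: tuple[tuple[str, str], ...]  # ((key, value), ...)
    n_noncompliant: int
    n_total: int
    noncompliant_pct: float
    compliant_pct: float
    deviant_parameters: set[str]
    missing_parameters: set[str]
    subject_status: dict[str, bool]  # subject -> compliant?
    deviations: list[Deviation]
    reference: ReferenceProtocol
    tolerance: float
    low_support: bool = False

    @property
    def n_compliant(self) -> int:
        return self.n_total - self.n_noncompliant

    @property
    def n_noncompliant_mismatch_only(self) -> int:
        """Count under the stricter reading where absent parameters do
        not make a subject non-compliant."""
        bad = {d.subject_id for d in self.deviations if d.type == MISMATCH}
        return len(bad)

    def stratum_label(self) -> str:
        return ",".join(f"{k}={v}" for k, v in self.stratum) or "all"

    def to_json(self) -> dict:
        return {
            "modality_label": self.modality_label,
            "stratum": dict(self.stratum),
            "n_noncompliant": self.n_noncompliant,
            "n_total": self.n_total,
            "n_compliant": self.n_compliant,
            "n_noncompliant_mismatch_only": self.n_noncompliant_mismatch_only,
            "noncompliant_pct": self.noncompliant_pct,
            "compliant_pct": self.compliant_pct,
            "deviant_parameters": sorted(self.deviant_parameters),
            "missing_parameters": sorted(self.missing_parameters),
            "subject_status": dict(sorted(self.subject_status.items())),
            "deviations": [d.to_json() for d in self.deviations],
            "tolerance": self.tolerance,
            "low_support": self.low_support,
            "reference_source": self.reference.source,
        }


# ----------------------------------------------------------------------
# percentages

def noncompliance_percent(n_noncompliant: int, n_total: int
                          ) -> tuple[Fraction, Fraction]:
    """Full-precision (non-compliant %, compliant %) from subject counts.

    Both sides are computed from counts (not as 100 - x) so each is
    independently re-derivable, and they are exact rationals so the two
    always sum to 100 exactly; display truncation is a separate step.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_noncompliant <= n_total:
        raise ValueError("need 0 <= n_noncompliant <= n_total")
    return (Fraction(100 * n_noncompliant, n_total),
            Fraction(100 * (n_total - n_noncompliant), n_total))


def format_percent(value: float, decimals: int = 2) -> str:
    """Display rule for percentages: truncate toward zero."""
    scale = 10 ** decimals
    truncated = math.floor(abs(value) * scale + 1e-9) / scale
    truncated = math.copysign(truncated, value)
    return f"{truncated:.{decimals}f}"


# ----------------------------------------------------------------------
# tolerance logic

def acceptable_range(reference: float, t: float) -> tuple[float, float]:
    """Inclusive acceptable band R ± (t × R) around a numeric reference."""
    if not math.isfinite(reference):
        raise ValueError("reference must be finite")
    if t < 0 or t > 1:
        raise ValueError(f"tolerance out of [0, 1]: {t}")
    delta = abs(t * reference)
    return reference - delta, reference + delta


def value_compliant(observed: ParameterValue, reference: ParameterValue,
                    t: float = 0.0) -> bool:
    """Compare one observed value against the reference.

    Numeric: within the inclusive band (epsilon equality at t=0).
    Categorical / multivalued: exact token or tuple equality, t ignored.
    """
    if observed.name != reference.name or observed.kind != reference.kind:
        raise ValueError(
            f"cannot compare {observed.name}/{observed.kind} against "
            f"{reference.name}/{reference.kind}")
    if not observed.present or not reference.present:
        raise ValueError("value_compliant requires both values present")
    if observed.kind == NUMERIC:
        obs, ref = float(observed.value), float(reference.value)
        if t == 0:
            return abs(obs - ref) <= EXACT_EPSILON
        lo, hi = acceptable_range(ref, t)
        return (lo - _BOUND_EPSILON) <= obs <= (hi + _BOUND_EPSILON)
    return observed.value == reference.value


def check_run(run: Run, ref: ReferenceProtocol,
              tol: ToleranceSpec | float = 0.0) -> list[Deviation]:
    """All deviations of one run w.r.t. the reference; empty == compliant.

    A reference parameter absent from the run yields a missing-type
    deviation.
    """
    if len(ref) == 0:
        raise ValueError("reference protocol is empty; nothing to audit")
    if isinstance(tol, (int, float)):
        tol = ToleranceSpec(global_t=float(tol))
    out: list[Deviation] = []
    for name in sorted(ref.entries):
        ref_pv = ref.entries[name]
        if not ref_pv.present:
            continue
        obs = run.parameters.get(name)
        if obs is None or not obs.present:
            out.append(Deviation(
                run_id=run.run_id, subject_id=run.subject_id,
                session_id=run.session_id, parameter=name,
                reference_value=ref_pv.value, observed_value=None,
                type=MISSING))
            continue
        if not value_compliant(obs, ref_pv, tol.for_name(name)):
            out.append(Deviation(
                run_id=run.run_id, subject_id=run.subject_id,
                session_id=run.session_id, parameter=name,
                reference_value=ref_pv.value, observed_value=obs.value,
                type=MISMATCH))
    return out


# ----------------------------------------------------------------------
# reference inference

def _vote_key(value: Any) -> tuple:
    # total order across values of one parameter for deterministic ties:
    # smallest numeric / lexicographically smallest token wins
    if isinstance(value, (int, float)):
        return (0, float(value))
    if isinstance(value, tuple):
        return (2, tuple(str(v) for v in value))
    return (1, str(value))


def infer_reference(runs: Sequence[Run],
                    names: Optional[Iterable[str]] = None,
                    modality_label: str = "") -> ReferenceProtocol:
    """Majority-vote reference: per parameter, the most frequent value
    over the runs where it is present; ties break to the smallest value
    under a total order so the result is insertion-order independent.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("cannot infer a reference from zero runs")
    names = list(names) if names is not None else list(DEFAULT_AUDIT_PARAMETERS)
    ref = ReferenceProtocol(
        modality_label=modality_label or runs[0].modality_label,
        source="inferred")
    for name in names:
        counts: Counter = Counter()
        for run in runs:
            pv = run.parameters.get(name)
            if pv is not None and pv.present:
                counts[pv.value] += 1
        if not counts:
            ref.uninferable.append(name)
            continue
        top = max(counts.values())
        best = min((v for v in counts if counts[v] == top), key=_vote_key)
        ref.entries[name] = ParameterValue.from_vocab(name, best)
        ref.support[name] = counts[best]
    return ref


# ----------------------------------------------------------------------
# stratification

def _stratum_value(run: Run, key: str) -> str:
    if key == "vendor":
        return run.vendor or UNANNOTATED
    if key == "ped":
        pv = run.parameters.get("PhaseEncodingDirection")
        return str(pv.value) if pv is not None and pv.present else UNANNOTATED
    if key == "entities":
        return run.entities or UNANNOTATED
    if key == "echo_number":
        return str(run.echo_number) if run.echo_number is not None \
            else UNANNOTATED
    raise ValueError(f"unknown stratification key: {key}")


def stratify(runs: Sequence[Run], keys: Sequence[str]
             ) -> dict[tuple[tuple[str, str], ...], list[Run]]:
    """Partition runs by the given keys (disjoint and exhaustive); runs
    lacking a key field fall into an 'unannotated' stratum."""
    out: dict[tuple[tuple[str, str], ...], list[Run]] = {}
    for run in runs:
        stratum = tuple((k, _stratum_value(run, k)) for k in keys)
        out.setdefault(stratum, []).append(run)
    return out


# ----------------------------------------------------------------------
# audits

def horizontal_audit(h: DatasetHierarchy,
                     modality_label: str,
                     ref: Optional[ReferenceProtocol] = None,
                     tol: ToleranceSpec | float = 0.0,
                     strata_keys: Sequence[str] = (),
                     names: Optional[Iterable[str]] = None
                     ) -> list[ModalitySummary]:
    """Audit every subject of one modality against a reference protocol.

    Runs are stratified first (vendor / PED / entities); the reference is
    inferred per stratum unless an external one is supplied. A subject is
    non-compliant as soon as any one of its runs carries a deviation.
    Multi-echo modalities are additionally stratified by echo number so
    legitimate per-echo variation is not flagged.
    """
    if isinstance(tol, (int, float)):
        tol = ToleranceSpec(global_t=float(tol))
    runs = h.runs_for(modality_label)
    if not runs:
        return []
    if ref is not None and len(ref) == 0:
        raise ValueError("external reference protocol is empty")
    keys = list(strata_keys)
    echoes = {r.echo_number for r in runs}
    if len(echoes) > 1 and "echo_number" not in keys:
        keys.append("echo_number")
    summaries: list[ModalitySummary] = []
    strata = stratify(runs, keys)
    for stratum in sorted(strata):
        stratum_runs = strata[stratum]
        stratum_ref = ref if ref is not None else infer_reference(
            stratum_runs, names=names, modality_label=modality_label)
        per_subject: dict[str, list[Deviation]] = {}
        for run in sorted(stratum_runs, key=Run.sort_key):
            per_subject.setdefault(run.subject_id, []).extend(
                check_run(run, stratum_ref, tol))
        status = {s: not devs for s, devs in per_subject.items()}
        n_total = len(status)
        n_nc = sum(1 for ok in status.values() if not ok)
        nc_pct, c_pct = (float(p)
                         for p in noncompliance_percent(n_nc, n_total))
        deviations = [d for s in sorted(per_subject) for d in per_subject[s]]
        low_support = ref is None and n_total == 1
        if low_support:
            logger.warning(
                "stratum %s of %s has a single subject; inferred reference "
                "has low support", dict(stratum), modality_label)
        summaries.append(ModalitySummary(
            modality_label=modality_label,
            stratum=stratum,
            n_noncompliant=n_nc,
            n_total=n_total,
            noncompliant_pct=nc_pct,
            compliant_pct=c_pct,
            deviant_parameters={d.parameter for d in deviations
                                if d.type == MISMATCH},
            missing_parameters={d.parameter for d in deviations
                                if d.type == MISSING},
            subject_status=status,
            deviations=deviations,
            reference=stratum_ref,
            tolerance=tol.global_t,
            low_support=low_support,
        ))
    return summaries


def audit_all(h: DatasetHierarchy,
              ref_by_modality: Optional[dict[str, ReferenceProtocol]] = None,
              tol: ToleranceSpec | float = 0.0,
              strata_keys: Sequence[str] = (),
              names: Optional[Iterable[str]] = None) -> list[ModalitySummary]:
    """Horizontal audit of every modality in the dataset."""
    out: list[ModalitySummary] = []
    for label in h.modalities:
        ref = (ref_by_modality or {}).get(label)
        out.extend(horizontal_audit(h, label, ref=ref, tol=tol,
                                    strata_keys=strata_keys, names=names))
    return out


_FIELDMAP_TOKENS = ("FMAP", "FIELDMAP")
_EPI_TOKENS = ("BOLD", "FUNC", "FMRI", "DWI", "DTI", "EPI", "REST", "TASK")


def is_fieldmap_label(label: str) -> bool:
    return any(tok in label.upper() for tok in _FIELDMAP_TOKENS)


def is_epi_label(label: str) -> bool:
    up = label.upper()
    return not is_fieldmap_label(up) and any(tok in up for tok in _EPI_TOKENS)


def vertical_audit(h: DatasetHierarchy, subject_id: str,
                   geometry_names: Sequence[str] = FIELDMAP_GEOMETRY_PARAMETERS
                   ) -> list[Deviation]:
    """Cross-modality consistency for one subject, session by session.

    Default rules: every fieldmap run must share field-of-view, number of
    slices, slice thickness and angulation with each EPI run of the same
    session; and the shim mode must be a single value across all of the
    subject's runs.
    """
    runs = h.runs_for_subject(subject_id)
    out: list[Deviation] = []
    by_session: dict[str, list[Run]] = {}
    for run in runs:
        by_session.setdefault(run.session_id, []).append(run)
    paired = False
    for session_id in sorted(by_session):
        session_runs = by_session[session_id]
        fmaps = [r for r in session_runs if is_fieldmap_label(r.modality_label)]
        epis = [r for r in session_runs if is_epi_label(r.modality_label)]
        if not fmaps or not epis:
            continue
        paired = True
        for fmap in fmaps:
            for epi in epis:
                for name in geometry_names:
                    ref_pv = epi.parameters.get(name)
                    obs_pv = fmap.parameters.get(name)
                    if ref_pv is None or not ref_pv.present:
                        continue
                    detail = (f"{fmap.modality_label} vs "
                              f"{epi.modality_label}")
                    if obs_pv is None or not obs_pv.present:
                        out.append(Deviation(
                            run_id=fmap.run_id, subject_id=subject_id,
                            session_id=session_id, parameter=name,
                            reference_value=ref_pv.value,
                            observed_value=None, type=MISSING,
                            detail=detail))
                    elif not value_compliant(obs_pv, ref_pv, 0.0):
                        out.append(Deviation(
                            run_id=fmap.run_id, subject_id=subject_id,
                            session_id=session_id, parameter=name,
                            reference_value=ref_pv.value,
                            observed_value=obs_pv.value, type=MISMATCH,
                            detail=detail))
    if not paired:
        logger.info("subject %s has no fieldmap/EPI pair; geometry rules "
                    "skipped", subject_id)
    # shim consistency across the subject's runs
    shim_values = Counter()
    for run in runs:
        pv = run.parameters.get("ShimMode")
        if pv is not None and pv.present:
            shim_values[pv.value] += 1
    if len(shim_values) > 1:
        modal = min((v for v in shim_values
                     if shim_values[v] == max(shim_values.values())),
                    key=_vote_key)
        for run in runs:
            pv = run.parameters.get("ShimMode")
            if pv is not None and pv.present and pv.value != modal:
                out.append(Deviation(
                    run_id=run.run_id, subject_id=subject_id,
                    session_id=run.session_id, parameter="ShimMode",
                    reference_value=modal, observed_value=pv.value,
                    type=MISMATCH,
                    detail=f"inconsistent shim in {run.modality_label}"))
    return out


# ----------------------------------------------------------------------
# tolerance sweep

def tolerance_sweep(h: DatasetHierarchy, modality_label: str,
                    t_values: Sequence[float],
                    ref: Optional[ReferenceProtocol] = None,
                    strata_keys: Sequence[str] = (),
                    names: Optional[Iterable[str]] = None
                    ) -> dict[float, float]:
    """Overall non-compliant % of one modality at each tolerance level.

    With a fixed reference the curve is non-increasing in t; if the only
    deviations are categorical it is constant.
    """
    if list(t_values) != sorted(t_values):
        raise ValueError("t_values must be sorted ascending")
    out: dict[float, float] = {}
    for t in t_values:
        summaries = horizontal_audit(h, modality_label, ref=ref, tol=t,
                                     strata_keys=strata_keys, names=names)
        n_nc = sum(s.n_noncompliant for s in summaries)
        n_total = sum(s.n_total for s in summaries)
        out[t] = float(noncompliance_percent(n_nc, n_total)[0])
    return out
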