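import math
from collections import Counter
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mraudit.compliance import (MISMATCH, MISSING, Deviation,
                                ReferenceProtocol, ToleranceSpec,
                                acceptable_range, check_run, format_percent,
                                horizontal_audit, infer_reference,
                                noncompliance_percent, stratify,
                                tolerance_sweep, value_compliant,
                                vertical_audit)
from mraudit.model import ParameterValue

from conftest import make_hierarchy, make_run


def pv(name, value):
    return ParameterValue.from_vocab(name, value)


def make_ref(**values):
    ref = ReferenceProtocol(modality_label="T1W", source="external")
    for name, value in values.items():
        ref.entries[name] = pv(name, value)
    return ref


# ----------------------------------------------------------------------
# reference inference

class TestInferReference:
    def test_strict_majority(self):
        runs = [make_run(f"r{i}", subject=f"s{i}", RepetitionTime=tr)
                for i, tr in enumerate([2300.0, 2300.0, 2000.0])]
        ref = infer_reference(runs, names=["RepetitionTime"])
        assert ref.entries["RepetitionTime"].value == 2300.0
        assert ref.support["RepetitionTime"] == 2

    def test_tie_breaks_to_smallest_numeric(self):
        runs = [make_run(f"r{i}", subject=f"s{i}", EchoTime=te)
                for i, te in enumerate([2.9, 3.0, 2.9, 3.0])]
        ref = infer_reference(runs, names=["EchoTime"])
        assert ref.entries["EchoTime"].value == 2.9

    def test_tie_breaks_lexicographic_for_tokens(self):
        runs = [make_run(f"r{i}", subject=f"s{i}",
                         PhaseEncodingDirection=t)
                for i, t in enumerate(["ROW", "COL"])]
        ref = infer_reference(runs, names=["PhaseEncodingDirection"])
        assert ref.entries["PhaseEncodingDirection"].value == "COL"

    def test_absent_values_excluded_from_vote(self):
        runs = [make_run("r1", subject="s1", EchoTime=3.0),
                make_run("r2", subject="s2")]
        runs[1].parameters["EchoTime"] = ParameterValue.missing("EchoTime")
        ref = infer_reference(runs, names=["EchoTime"])
        assert ref.entries["EchoTime"].value == 3.0
        assert ref.support["EchoTime"] == 1

    def test_uninferable_listed(self):
        runs = [make_run("r1")]
        ref = infer_reference(runs, names=["EchoTime"])
        assert "EchoTime" not in ref.entries
        assert ref.uninferable == ["EchoTime"]

    def test_zero_runs_error(self):
        with pytest.raises(ValueError):
            infer_reference([])

    def test_brute_force_oracle_500_runs(self):
        import random
        rng = random.Random(42)
        values = [rng.choice([2000.0, 2300.0, 2500.0, 3000.0])
                  for _ in range(500)]
        runs = [make_run(f"r{i}", subject=f"s{i}", RepetitionTime=v)
                for i, v in enumerate(values)]
        ref = infer_reference(runs, names=["RepetitionTime"])
        table = Counter(values)  # independent exhaustive count
        top = max(table.values())
        expected = min(v for v in table if table[v] == top)
        assert ref.entries["RepetitionTime"].value == expected
        assert ref.support["RepetitionTime"] == top

    @given(st.lists(st.sampled_from([1.5, 2.0, 2.5, 3.0, 3.5]),
                    min_size=1, max_size=40))
    def test_mode_equals_argmax_property(self, values):
        runs = [make_run(f"r{i}", subject=f"s{i}", EchoTime=v)
                for i, v in enumerate(values)]
        ref = infer_reference(runs, names=["EchoTime"])
        table = Counter(values)
        top = max(table.values())
        assert ref.entries["EchoTime"].value == min(
            v for v in table if table[v] == top)


# ----------------------------------------------------------------------
# tolerance logic

class TestAcceptableRange:
    def test_reference_3_at_5pct(self):
        assert acceptable_range(3.0, 0.05) == (pytest.approx(2.85),
                                               pytest.approx(3.15))

    def test_reference_6_66_at_5pct(self):
        lo, hi = acceptable_range(6.66, 0.05)
        assert f"{hi:.2f}" == "6.99"
        assert lo == pytest.approx(6.327)

    def test_zero_tolerance_identity(self):
        assert acceptable_range(123.4, 0.0) == (123.4, 123.4)

    def test_negative_tolerance_error(self):
        with pytest.raises(ValueError):
            acceptable_range(3.0, -0.01)

    def test_nonfinite_reference_error(self):
        with pytest.raises(ValueError):
            acceptable_range(float("inf"), 0.05)


class TestValueCompliant:
    def test_exact_mode_rejects_shift(self):
        assert not value_compliant(pv("EchoTime", 2.9), pv("EchoTime", 3.0),
                                   0.0)

    def test_within_band_accepted(self):
        assert value_compliant(pv("EchoTime", 2.9), pv("EchoTime", 3.0),
                               0.05)

    def test_band_bounds_inclusive(self):
        assert value_compliant(pv("EchoTime", 2.85), pv("EchoTime", 3.0),
                               0.05)
        assert value_compliant(pv("EchoTime", 3.15), pv("EchoTime", 3.0),
                               0.05)
        assert not value_compliant(pv("EchoTime", 3.1501),
                                   pv("EchoTime", 3.0), 0.05)

    def test_epsilon_equality_at_zero(self):
        assert value_compliant(pv("EchoTime", 3.0 + 1e-9),
                               pv("EchoTime", 3.0), 0.0)

    def test_categorical_ignores_tolerance(self):
        ap = pv("PhaseEncodingDirection", "AP")
        pa = pv("PhaseEncodingDirection", "PA")
        for t in (0.0, 0.05, 0.5, 1.0):
            assert not value_compliant(ap, pa, t)
            assert value_compliant(ap, pv("PhaseEncodingDirection", "AP"), t)

    def test_kind_mismatch_error(self):
        with pytest.raises(ValueError):
            value_compliant(pv("EchoTime", 3.0),
                            pv("PhaseEncodingDirection", "AP"), 0.0)


class TestCheckRun:
    def test_identical_run_compliant(self):
        ref = make_ref(EchoTime=3.0, PhaseEncodingDirection="ROW")
        run = make_run("r1", EchoTime=3.0, PhaseEncodingDirection="ROW")
        assert check_run(run, ref) == []

    def test_two_deviations_counted(self):
        ref = make_ref(EchoTime=3.0, PhaseEncodingDirection="ROW",
                       RepetitionTime=2300.0)
        run = make_run("r1", EchoTime=3.5, PhaseEncodingDirection="COL",
                       RepetitionTime=2300.0)
        devs = check_run(run, ref)
        assert len(devs) == 2
        assert {d.parameter for d in devs} == {"EchoTime",
                                               "PhaseEncodingDirection"}
        assert all(d.type == MISMATCH for d in devs)

    def test_missing_parameter_typed_missing(self):
        ref = make_ref(PhaseEncodingDirection="ROW")
        run = make_run("r1", EchoTime=3.0)
        devs = check_run(run, ref)
        assert len(devs) == 1
        assert devs[0].type == MISSING
        assert devs[0].observed_value is None

    def test_per_parameter_override(self):
        ref = make_ref(EchoTime=3.0, RepetitionTime=2300.0)
        run = make_run("r1", EchoTime=2.9, RepetitionTime=2200.0)
        tol = ToleranceSpec(global_t=0.0, overrides={"EchoTime": 0.05})
        devs = check_run(run, ref, tol)
        assert [d.parameter for d in devs] == ["RepetitionTime"]

    def test_empty_reference_refused(self):
        with pytest.raises(ValueError):
            check_run(make_run("r1"), ReferenceProtocol())


# ----------------------------------------------------------------------
# percentages

class TestNoncompliancePercent:
    def test_philips_t1w_row(self):
        nc, c = noncompliance_percent(980, 1521)
        assert format_percent(nc) == "64.43"
        assert format_percent(c) == "35.56"

    def test_siemens_dti_row(self):
        nc, c = noncompliance_percent(14, 5873)
        assert format_percent(c) == "99.76"
        assert format_percent(nc) == "0.23"

    def test_siemens_t1w_row(self):
        nc, c = noncompliance_percent(2883, 7214)
        assert format_percent(nc) == "39.96"
        assert format_percent(c) == "60.03"

    def test_all_compliant(self):
        nc, c = noncompliance_percent(0, 57)
        assert format_percent(nc) == "0.00"
        assert format_percent(c) == "100.00"

    def test_zero_total_error(self):
        with pytest.raises(ValueError):
            noncompliance_percent(0, 0)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            noncompliance_percent(5, 4)

    @given(st.integers(min_value=1, max_value=10_000), st.data())
    def test_conservation_exact(self, n_total, data):
        n_nc = data.draw(st.integers(min_value=0, max_value=n_total))
        nc, c = noncompliance_percent(n_nc, n_total)
        assert nc + c == 100
        assert isinstance(nc, Fraction)

    def test_truncation_not_rounding(self):
        assert format_percent(64.439) == "64.43"
        assert format_percent(0.239) == "0.23"
        assert format_percent(99.999) == "99.99"


# ----------------------------------------------------------------------
# stratification

class TestStratify:
    def test_ap_pa_two_strata(self):
        runs = [make_run(f"r{i}", subject=f"s{i}",
                         PhaseEncodingDirection=t)
                for i, t in enumerate(["AP", "PA", "AP", "PA"])]
        strata = stratify(runs, ["ped"])
        assert len(strata) == 2

    def test_single_vendor_one_stratum(self):
        runs = [make_run(f"r{i}", subject=f"s{i}") for i in range(4)]
        assert len(stratify(runs, ["vendor"])) == 1

    def test_unannotated_bucket(self):
        runs = [make_run("r1", PhaseEncodingDirection="AP"),
                make_run("r2", subject="s2")]
        strata = stratify(runs, ["ped"])
        assert (("ped", "unannotated"),) in strata

    def test_unknown_key_error(self):
        with pytest.raises(ValueError):
            stratify([make_run("r1")], ["site"])

    @given(st.lists(st.tuples(
        st.sampled_from(["SIEMENS", "GE", "PHILIPS"]),
        st.sampled_from(["AP", "PA", None])), min_size=1, max_size=30))
    def test_partition_property(self, assignments):
        runs = []
        for i, (vendor, ped) in enumerate(assignments):
            kwargs = {"PhaseEncodingDirection": ped} if ped else {}
            runs.append(make_run(f"r{i}", subject=f"s{i}", vendor=vendor,
                                 **kwargs))
        strata = stratify(runs, ["vendor", "ped"])
        ids = [r.run_id for group in strata.values() for r in group]
        assert sorted(ids) == sorted(r.run_id for r in runs)  # exhaustive
        assert len(ids) == len(set(ids))  # disjoint


# ----------------------------------------------------------------------
# horizontal audit

class TestHorizontalAudit:
    def _three_subject_hierarchy(self):
        runs = [make_run(f"r{i}", subject=f"sub-{i}", RepetitionTime=2300.0,
                         EchoTime=3.0) for i in range(3)]
        runs[2].parameters["EchoTime"] = pv("EchoTime", 3.5)
        return make_hierarchy(runs)

    def test_one_deviant_of_three(self):
        h = self._three_subject_hierarchy()
        (summary,) = horizontal_audit(h, "T1W",
                                      names=["RepetitionTime", "EchoTime"])
        assert summary.n_noncompliant == 1
        assert summary.n_total == 3
        # hand-derived: 1 * 100 / 3
        assert summary.noncompliant_pct == pytest.approx(100.0 / 3.0)
        assert format_percent(summary.noncompliant_pct) == "33.33"
        assert summary.deviant_parameters == {"EchoTime"}

    def test_all_compliant(self):
        runs = [make_run(f"r{i}", subject=f"sub-{i}", EchoTime=3.0)
                for i in range(4)]
        (summary,) = horizontal_audit(make_hierarchy(runs), "T1W",
                                      names=["EchoTime"])
        assert summary.n_noncompliant == 0
        assert format_percent(summary.noncompliant_pct) == "0.00"
        assert format_percent(summary.compliant_pct) == "100.00"

    def test_unknown_modality_empty(self):
        h = self._three_subject_hierarchy()
        assert horizontal_audit(h, "NOPE") == []

    def test_single_run_rule_subject_aggregation(self):
        # flipping any single compliant run flips its subject's status
        runs = [make_run(f"r{i}{j}", subject=f"sub-{i}", session=f"ses-{j}",
                         EchoTime=3.0)
                for i in range(3) for j in range(2)]
        h = make_hierarchy(runs)
        (clean,) = horizontal_audit(h, "T1W", names=["EchoTime"])
        assert all(clean.subject_status.values())
        for flip_idx in range(len(runs)):
            mutated = [make_run(r.run_id, subject=r.subject_id,
                                session=r.session_id,
                                EchoTime=9.9 if k == flip_idx else 3.0)
                       for k, r in enumerate(runs)]
            (summary,) = horizontal_audit(make_hierarchy(mutated), "T1W",
                                          names=["EchoTime"])
            flipped_subject = runs[flip_idx].subject_id
            assert summary.subject_status[flipped_subject] is False
            assert summary.n_noncompliant == 1

    def test_vendor_strata_match_bruteforce(self):
        runs = []
        truth = {}
        for i in range(12):
            vendor = ["SIEMENS", "GE", "PHILIPS"][i % 3]
            te = 3.5 if i in (0, 4) else 3.0
            runs.append(make_run(f"r{i}", subject=f"sub-{i}", vendor=vendor,
                                 EchoTime=te))
            truth.setdefault(vendor, []).append((f"sub-{i}", te))
        h = make_hierarchy(runs)
        summaries = horizontal_audit(h, "T1W", strata_keys=["vendor"],
                                     names=["EchoTime"])
        assert len(summaries) == 3
        for summary in summaries:
            vendor = dict(summary.stratum)["vendor"]
            members = truth[vendor]
            modal = Counter(te for _, te in members).most_common(1)[0][0]
            expected_bad = {s for s, te in members if te != modal}
            observed_bad = {s for s, ok in summary.subject_status.items()
                            if not ok}
            assert observed_bad == expected_bad
            assert summary.n_total == len(members)

    def test_low_support_flagged(self):
        (summary,) = horizontal_audit(
            make_hierarchy([make_run("r1", EchoTime=3.0)]), "T1W",
            names=["EchoTime"])
        assert summary.low_support

    def test_multi_echo_not_flagged(self):
        # per-echo TE variation is legitimate; audits group by echo
        runs = [make_run(f"r{i}e{e}", subject=f"sub-{i}", echo=e,
                         EchoTime=5.0 * e)
                for i in range(3) for e in (1, 2)]
        summaries = horizontal_audit(make_hierarchy(runs), "T1W",
                                     names=["EchoTime"])
        assert len(summaries) == 2
        assert all(s.n_noncompliant == 0 for s in summaries)


# ----------------------------------------------------------------------
# vertical audit

class TestVerticalAudit:
    def _geom(self, fov=256.0, nslices=64, thick=2.4, ang=0.0):
        return dict(FieldOfView=fov, NumberOfSlices=nslices,
                    SliceThickness=thick, Angulation=ang)

    def test_matching_geometry_clean(self):
        h = make_hierarchy([
            make_run("fm", modality="FMAP_AP", **self._geom()),
            make_run("ep", modality="TASK_REST_BOLD", **self._geom())])
        assert vertical_audit(h, "sub-01") == []

    def test_slice_count_mismatch_flagged(self):
        h = make_hierarchy([
            make_run("fm", modality="FMAP_AP", **self._geom(nslices=60)),
            make_run("ep", modality="TASK_REST_BOLD",
                     **self._geom(nslices=64))])
        devs = vertical_audit(h, "sub-01")
        assert len(devs) == 1
        assert devs[0].parameter == "NumberOfSlices"
        assert devs[0].observed_value == 60
        assert devs[0].reference_value == 64

    def test_no_pair_empty(self):
        h = make_hierarchy([make_run("r1", modality="T1W")])
        assert vertical_audit(h, "sub-01") == []

    def test_inconsistent_shim_flagged(self):
        h = make_hierarchy([
            make_run("r1", modality="T1W", ShimMode="STANDARD"),
            make_run("r2", modality="T2W", ShimMode="STANDARD"),
            make_run("r3", modality="BOLD", ShimMode="TUNE_UP")])
        devs = vertical_audit(h, "sub-01")
        assert len(devs) == 1
        assert devs[0].parameter == "ShimMode"
        assert devs[0].observed_value == "TUNE_UP"

    def test_cross_session_pairs_not_mixed(self):
        h = make_hierarchy([
            make_run("fm", session="ses-01", modality="FMAP",
                     **self._geom(nslices=60)),
            make_run("ep", session="ses-02", modality="BOLD",
                     **self._geom(nslices=64))])
        assert vertical_audit(h, "sub-01") == []


# ----------------------------------------------------------------------
# tolerance sweep

SWEEP_TS = [0.0, 0.01, 0.02, 0.03, 0.04, 0.05]


class TestToleranceSweep:
    def test_numeric_within_5pct_reaches_zero(self):
        runs = [make_run(f"r{i}", subject=f"sub-{i}",
                         EchoTime=3.0 if i else 2.9) for i in range(5)]
        curve = tolerance_sweep(make_hierarchy(runs), "T1W", SWEEP_TS,
                                names=["EchoTime"])
        assert curve[0.0] > 0
        assert curve[0.05] == 0.0

    def test_categorical_deviations_constant(self):
        runs = [make_run(f"r{i}", subject=f"sub-{i}",
                         PhaseEncodingDirection="ROW" if i else "COL")
                for i in range(5)]
        curve = tolerance_sweep(make_hierarchy(runs), "T1W", SWEEP_TS,
                                names=["PhaseEncodingDirection"])
        assert len(set(curve.values())) == 1
        assert curve[0.0] == pytest.approx(20.0)

    def test_monotone_nonincreasing(self):
        runs = [make_run(f"r{i}", subject=f"sub-{i}",
                         EchoTime=[3.0, 3.05, 3.2, 4.0][i % 4])
                for i in range(8)]
        curve = tolerance_sweep(make_hierarchy(runs), "T1W", SWEEP_TS,
                                names=["EchoTime"])
        values = [curve[t] for t in SWEEP_TS]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_matches_per_t_reaudit_oracle(self):
        runs = [make_run(f"r{i}", subject=f"sub-{i}",
                         EchoTime=[3.0, 3.0, 3.1, 5.0][i % 4],
                         PhaseEncodingDirection="ROW" if i % 5 else "COL")
                for i in range(10)]
        h = make_hierarchy(runs)
        names = ["EchoTime", "PhaseEncodingDirection"]
        curve = tolerance_sweep(h, "T1W", SWEEP_TS, names=names)
        for t in SWEEP_TS:
            (summary,) = horizontal_audit(h, "T1W", tol=t, names=names)
            expected = float(noncompliance_percent(
                summary.n_noncompliant, summary.n_total)[0])
            assert curve[t] == pytest.approx(expected)

    def test_unsorted_ts_rejected(self):
        with pytest.raises(ValueError):
            tolerance_sweep(make_hierarchy([make_run("r1")]), "T1W",
                            [0.05, 0.0])


def test_deviation_type_invariants():
    with pytest.raises(ValueError):
        Deviation("r", "s", "ses", "EchoTime", 3.0, None, MISMATCH)
    with pytest.raises(ValueError):
        Deviation("r", "s", "ses", "EchoTime", 3.0, 2.9, MISSING)


def test_tolerance_spec_bounds():
    with pytest.raises(ValueError):
        ToleranceSpec(global_t=-0.1)
    with pytest.raises(ValueError):
        ToleranceSpec(global_t=0.0, overrides={"EchoTime": 1.5})
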