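# mraudit

MR acquisition-protocol compliance auditing for DICOM and BIDS datasets.

`mraudit` parses acquisition metadata into a modality / subject / session /
run hierarchy, infers a reference protocol (majority vote per parameter) or
loads one from a flat XML export, and audits the dataset for protocol
compliance:

- **Horizontal audit** — every subject of a modality is checked against the
  reference protocol; a subject is non-compliant as soon as a single run
  deviates. Per-stratum (vendor / phase-encoding direction / BIDS entities)
  summaries report subject counts and percentages.
- **Vertical audit** — cross-modality consistency within a subject:
  fieldmap geometry (field of view, number of slices, slice thickness,
  angulation) must match the paired EPI run, and the shim mode must be
  consistent across the subject's runs.
- **Tolerance bands** — numeric parameters may be compared inside an
  inclusive relative band `R ± t·R`; categorical parameters always require
  exact token equality. `tolerance_sweep` traces non-compliance across a
  range of tolerance levels.
- **Reports** — deterministic HTML / text / JSON / TSV renderings with
  missing-parameter rosters and repeat-offender lists.
- **Continuous monitoring** — an idempotent incremental mode re-reads only
  new or changed files (size/mtime/sha256 state file) while always
  producing the same report as a from-scratch audit.
- **Synthetic fixtures** — a generator that emits valid miniature DICOM
  and/or BIDS datasets with configurable vendors and injected deviations
  (numeric shifts, categorical flips, dropped fields), plus a ground-truth
  manifest, so every stage is testable without external data.

The DICOM layer is layout-agnostic (files are discovered by content, not by
directory structure or extension) and reads Siemens ASCCONV private headers
for shim / parallel-imaging / multi-slice settings; GE and Philips private
headers are skipped.

## CLI

```sh
# one-shot audit of a DICOM tree
mraudit audit --data-root /data/study --tolerance 0.05 \
    --strata vendor,ped --output-dir reports/

# BIDS dataset
mraudit audit --data-root /data/bids --format bids --output-dir reports/

# incremental monitoring (schedule via cron)
mraudit monitor --data-root /data/study --output-dir reports/

# re-render a saved audit
mraudit report --audit-json reports/report.json --format tsv

# generate a synthetic test dataset
mraudit generate-fixture --out /tmp/fx --format both --seed 1 --n-subjects 10
```

Exit codes: `0` success, `1` usage error, `2` dataset error, `3` when
`--fail-on-noncompliance` is set and non-compliant subjects were found.

An external reference protocol is a flat XML file:

```xml
<protocol modality="T1w">
  <param name="RepetitionTime" value="2300" units="ms"/>
  <param name="PhaseEncodingDirection" value="ROW"/>
</protocol>
```

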